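"""Clone-level enrichment: normalization, dispersion, the exact conditional
NB test (checked against independent oracles), hit thresholds, blacklist."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, nbinom, poisson

from phipseq import (
    HitThresholds,
    call_hits,
    conditional_pvalue,
    control_blacklist,
    estimate_dispersion,
    nb_exact_test,
    size_factors,
)
from phipseq.containers import CountMatrix


def nb_split_enumeration_oracle(x, ctrl_sum, n_controls, phi, mu=2.3):
    """Brute-force two-sided p: enumerate all splits of the total between
    NB(mu, phi) and NB(n_controls*mu, phi/n_controls) (Poisson at phi=0),
    condition on the total, and sum the splits no more probable than the
    observed one."""
    t = x + ctrl_sum
    k = np.arange(t + 1)
    if phi == 0:
        pk = poisson.pmf(k, mu) * poisson.pmf(t - k, n_controls * mu)
    else:
        r1 = 1.0 / phi
        r2 = n_controls / phi
        pk = nbinom.pmf(k, r1, r1 / (r1 + mu)) * nbinom.pmf(
            t - k, r2, r2 / (r2 + n_controls * mu)
        )
    pk = pk / pk.sum()
    return min(1.0, float(pk[pk <= pk[x] * (1 + 1e-7)].sum()))


def _cm(data: dict) -> CountMatrix:
    return CountMatrix(pd.DataFrame(data))


class TestSizeFactors:
    def test_examples(self):
        cm = _cm({"a": [500, 500], "b": [600, 400], "c": [300, 700]})
        assert size_factors(cm).tolist() == pytest.approx([1.0, 1.0, 1.0])
        cm2 = _cm({"a": [1_000_000], "b": [4_000_000]})
        assert size_factors(cm2).tolist() == pytest.approx([0.5, 2.0])
        assert size_factors(_cm({"only": [7, 3]})).tolist() == pytest.approx([1.0])

    def test_zero_total_sample_is_named(self):
        with pytest.raises(ValueError, match="bad_sample"):
            size_factors(_cm({"ok": [5], "bad_sample": [0]}))


class TestDispersion:
    def test_moment_formula(self):
        # clone A: mean 100, sample variance 900 on equal-depth controls;
        # clone B absorbs the difference so size factors stay 1
        cm = _cm({"c1": [70, 930], "c2": [100, 900], "c3": [130, 870]})
        model = estimate_dispersion(cm, shrinkage_weight=0.0)
        assert model.phi_raw.iloc[0] == pytest.approx((900 - 100) / 100**2)

    def test_poisson_and_constant_clones_floor_at_zero(self):
        cm = _cm({"c1": [100, 50], "c2": [100, 50], "c3": [100, 50]})
        model = estimate_dispersion(cm)
        assert (model.phi_raw == 0).all()
        assert (model.phi == 0).all()

    def test_shrinkage_moves_toward_common(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(5, 5 / (5 + 100), size=(200, 20))
        cm = CountMatrix(pd.DataFrame(counts, columns=[f"c{i}" for i in range(20)]))
        model = estimate_dispersion(cm, shrinkage_weight=0.7)
        spread_raw = model.phi_raw.std()
        spread_shrunk = model.phi.std()
        assert spread_shrunk == pytest.approx(0.3 * spread_raw)
        assert 0.1 < model.phi_common < 0.35  # true phi = 1/r = 0.2

    def test_needs_replication(self):
        with pytest.raises(ValueError, match=">= 2"):
            estimate_dispersion(_cm({"only": [5, 5]}))


class TestNbExactTest:
    def test_null_case(self):
        p, log2fc = nb_exact_test(10, [10, 10, 10], phi=0.1)
        assert abs(log2fc) < 0.01
        assert p >= 0.5

    def test_binomial_oracle_at_phi_zero(self):
        """phi = 0, equal depths, one control: the conditional test IS the
        two-sided exact binomial test at probability 1/2."""
        p, _ = nb_exact_test(20, [10], phi=0.0)
        assert p == pytest.approx(binomtest(20, 30, 0.5).pvalue, rel=1e-12)

    def test_matches_split_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(120):
            t = int(rng.integers(1, 201))
            x = int(rng.integers(0, t + 1))
            n_c = int(rng.choice([1, 3, 36]))
            phi = float(rng.choice([0.0, 0.1, 1.0]))
            got = conditional_pvalue(x, t - x, n_c, phi)
            want = nb_split_enumeration_oracle(
                x, t - x, n_c, phi, mu=float(rng.uniform(0.5, 8))
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_size_factor_rescaling(self):
        # doubling a sample's library size and counts leaves the test unchanged
        p1, fc1 = nb_exact_test(40, [10, 10], phi=0.1)
        p2, fc2 = nb_exact_test(
            80, [10, 10], phi=0.1, sample_size_factor=2.0
        )
        assert p2 == p1 and fc2 == pytest.approx(fc1)

    def test_p_is_unimodal_in_the_sample_count(self):
        """p decreases monotonically as the sample count moves away from its
        most typical value (in either direction)."""
        n_c, phi, ctrl_sum = 5, 0.2, 250
        xs = list(range(0, 301))
        ps = [conditional_pvalue(x, ctrl_sum, n_c, phi) for x in xs]
        peak = int(np.argmax(ps))
        assert abs(xs[peak] - ctrl_sum / n_c) <= 15  # peak near the null expectation
        up = ps[peak:]
        down = ps[: peak + 1][::-1]
        assert all(a >= b - 1e-12 for a, b in zip(up, up[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(down, down[1:]))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nb_exact_test(-1, [5], phi=0.1)
        with pytest.raises(ValueError):
            nb_exact_test(5, [5], phi=-0.5)


class TestHitCalling:
    @pytest.mark.parametrize(
        "log2fc, p, expected",
        [
            (2.0, 1e-5, True),  # inclusive fold boundary
            (1.99, 1e-9, False),  # fold below threshold despite tiny p
            (8.0, 1e-4, False),  # -log10 p = 4 exactly: strictly-greater rule
            (3.0, 9.9e-5, True),
        ],
    )
    def test_boundary_semantics(self, log2fc, p, expected):
        df = pd.DataFrame({"clone_id": ["c"], "sample_id": ["s"], "log2fc": [log2fc], "p": [p]})
        assert bool(call_hits(df)["is_hit"].iloc[0]) is expected


class TestBlacklist:
    def test_contaminated_control_clone_is_blacklisted(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(100, size=(50, 6))
        base[7, 2] = 10_000  # one clone at 100x its peers in one control
        cm = CountMatrix(pd.DataFrame(base, index=[f"c{i}" for i in range(50)],
                                      columns=[f"b{i}" for i in range(6)]))
        bad = control_blacklist(cm)
        assert "c7" in bad

    def test_homogeneous_controls_have_near_empty_blacklist(self):
        rng = np.random.default_rng(6)
        base = rng.poisson(100, size=(300, 12))
        cm = CountMatrix(pd.DataFrame(base, index=[f"c{i}" for i in range(300)],
                                      columns=[f"b{i}" for i in range(12)]))
        assert len(control_blacklist(cm)) <= 1

    def test_needs_three_controls(self):
        cm = _cm({"a": [5, 5], "b": [5, 5]})
        with pytest.raises(ValueError, match=">= 3"):
            control_blacklist(cm)
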