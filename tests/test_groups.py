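"""Protein-level pooling, Fisher group comparison, z-scores, set overlap."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from phipseq import (
    build_library,
    collapse_to_protein,
    distinct_antigens,
    fisher_exact_2x2,
    group_vs_rest,
    proportion_zscores,
    set_overlap,
)
from phipseq.containers import SampleMeta
from phipseq.groups import pool_rows, truncate_pct
from phipseq.tiling import ProteinRecord


def fisher_fraction_oracle(a, b, c, d):
    """Exact-rational hypergeometric enumeration of the two-sided p."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    if row1 in (0, n) or col1 in (0, n):
        return 1.0
    lo, hi = max(0, col1 - (n - row1)), min(col1, row1)
    weights = {k: math.comb(row1, k) * math.comb(n - row1, col1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    p = sum(w for w in weights.values() if w <= weights[a])
    return float(Fraction(p, total))


@pytest.fixture
def pooling_library():
    return build_library(
        [
            ProteinRecord("P1", "G1", "ACDEFGHIKLMNPQRSTVWY" * 5),  # 100 aa, 4 tiles
            ProteinRecord("P2", "G2", "M" * 49),  # 1 tile
        ]
    )


class TestCollapse:
    def test_any_epitope_pools_to_protein(self, pooling_library):
        clones_p1 = pooling_library.clones_of_protein("P1")
        hits = {
            "s1": {clones_p1[0]},  # one epitope
            "s2": {clones_p1[-1]},  # a different epitope of the same protein
            "s3": set(),
        }
        reactivity = collapse_to_protein(hits, pooling_library)
        assert reactivity.loc["P1"].tolist() == [True, True, False]
        assert not reactivity.loc["P2"].any()

    def test_blacklisted_clones_never_contribute(self, pooling_library):
        clone = pooling_library.clones_of_protein("P2")[0]
        reactivity = collapse_to_protein(
            {"s1": {clone}}, pooling_library, blacklist={clone}
        )
        assert not reactivity.loc["P2", "s1"]

    def test_unknown_clone_is_an_error(self, pooling_library):
        with pytest.raises(ValueError, match="unknown clones"):
            collapse_to_protein({"s1": {"nope"}}, pooling_library)

    def test_collapse_is_idempotent_on_protein_level_matrix(self):
        mat = pd.DataFrame(
            [[True, False], [False, True]], index=["P1", "P2"], columns=["s1", "s2"]
        )
        identity = {"P1": "P1", "P2": "P2"}
        assert pool_rows(mat, identity).equals(mat)


class TestFisher:
    @pytest.mark.parametrize(
        "table, printed",
        [
            ((10, 2, 2, 10), 0.003),  # TNKS1BP1: 10/12 vs 2/12
            ((8, 4, 1, 11), 0.009),  # CASZ1: 8/12 vs 1/12
        ],
    )
    def test_worked_examples_round_to_printed_values(self, table, printed):
        assert round(fisher_exact_2x2(*table), 3) == printed

    def test_degenerate_and_enumerated_values(self):
        assert fisher_exact_2x2(0, 12, 0, 12) == 1.0
        assert fisher_exact_2x2(6, 6, 0, 12) == pytest.approx(
            fisher_fraction_oracle(6, 6, 0, 12), abs=1e-12
        )
        assert fisher_exact_2x2(6, 6, 0, 12) == pytest.approx(0.01373, abs=5e-6)
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    def test_matches_enumeration_and_symmetry(self, a, b, c, d):
        p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_fraction_oracle(a, b, c, d), abs=1e-12)
        assert p == pytest.approx(fisher_exact_2x2(c, d, a, b), abs=1e-12)

    def test_agrees_with_scipy_convention(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], rel=1e-9
            )

    def test_doubled_tail_alternative(self):
        p_min = fisher_exact_2x2(10, 2, 2, 10)
        p_dbl = fisher_exact_2x2(10, 2, 2, 10, convention="doubled")
        assert p_dbl >= p_min


class TestGroupVsRest:
    @pytest.fixture
    def meta(self):
        out = []
        for group, size in {"oMMP": 12, "MMP": 6, "BP": 3, "mcPV": 3}.items():
            out += [SampleMeta(f"{group}_{i}", group) for i in range(size)]
        out.append(SampleMeta("beads_1", "beads", is_control=True))
        return out

    def _reactivity(self, meta, per_protein):
        sera = [m.sample_id for m in meta if not m.is_control]
        df = pd.DataFrame(False, index=list(per_protein), columns=sera)
        for protein, reactive in per_protein.items():
            df.loc[protein, reactive] = True
        return df

    def test_ubiquitous_protein_is_not_distinct(self, meta):
        sera = [m.sample_id for m in meta if not m.is_control]
        react = self._reactivity(meta, {"PX": sera})
        comp = group_vs_rest(react, meta, "oMMP")
        assert comp.iloc[0]["p"] == 1.0
        assert not comp.iloc[0]["distinct"]

    def test_group_enriched_proteins_are_distinct(self, meta):
        omm = [m.sample_id for m in meta if m.group == "oMMP"]
        rest = [m.sample_id for m in meta if not m.is_control and m.group != "oMMP"]
        react = self._reactivity(
            meta,
            {
                "TNKS1BP1_like": omm[:10] + rest[:2],  # 10/12 vs 2/12
                "SRRT_like": omm[:6],  # 6/12 vs 0/12
            },
        )
        comp = group_vs_rest(react, meta, "oMMP").set_index("protein_id")
        assert comp.loc["TNKS1BP1_like", "p"] == pytest.approx(0.003329, abs=5e-6)
        assert comp.loc["TNKS1BP1_like", "distinct"]
        assert (
            comp.loc["TNKS1BP1_like", ["pct_group", "pct_rest"]].tolist() == [83, 16]
        )
        assert comp.loc["SRRT_like", "p"] < 0.05
        assert comp.loc["SRRT_like", "distinct"]
        assert set(distinct_antigens(comp.reset_index())) == {
            "TNKS1BP1_like",
            "SRRT_like",
        }

    def test_missing_group_is_an_error(self, meta):
        react = self._reactivity(meta, {"P": []})
        with pytest.raises(ValueError, match="no serum samples"):
            group_vs_rest(react, meta, "nope")


class TestZScores:
    def test_single_positive_group(self):
        props = pd.DataFrame([[1.0, 0.0, 0.0, 0.0]], index=["P"], columns=list("abcd"))
        z = proportion_zscores(props)
        assert z.loc["P"].tolist() == pytest.approx([1.5, -0.5, -0.5, -0.5])
        assert z.loc["P"].mean() == pytest.approx(0.0)

    def test_flat_row_maps_to_zeros(self):
        props = pd.DataFrame([[0.4, 0.4, 0.4]], index=["P"], columns=list("abc"))
        assert (proportion_zscores(props) == 0).all().all()

    def test_documented_sd_convention(self):
        props = pd.DataFrame([[0.8, 0.2, 0.2, 0.2]], index=["P"], columns=list("abcd"))
        z = proportion_zscores(props)  # sample-sd convention by default
        assert z.loc["P"].tolist() == pytest.approx([1.5, -0.5, -0.5, -0.5])
        z_pop = proportion_zscores(props, ddof=0)
        assert z_pop.loc["P", "a"] == pytest.approx(0.45 / np.sqrt(0.0675))


class TestSetOverlap:
    def test_partitions(self):
        same = {"A", "B"}
        inter, a_only, b_only = set_overlap(same, same)
        assert (inter, a_only, b_only) == (same, set(), set())
        inter, a_only, b_only = set_overlap({"A"}, {"B"})
        assert inter == set() and a_only == {"A"} and b_only == {"B"}

    def test_shared_antigen_example(self):
        phip = {"NCAM2", "ABCB9", "PCDHB3", "PCDH1", "X1"}
        array = {"NCAM2", "ABCB9", "PCDHB3", "PCDH1", "Y1"}
        inter, _, _ = set_overlap(phip, array)
        assert inter == {"NCAM2", "ABCB9", "PCDHB3", "PCDH1"}


def test_truncate_pct_matches_reporting_style():
    assert truncate_pct(8 / 12) == 66
    assert truncate_pct(10 / 12) == 83
    assert truncate_pct(1 / 12) == 8
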