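"""Clone-level enrichment calling against bead-only controls.

The test is an exact conditional negative-binomial test, the classic
two-group exact test for overdispersed counts. One serum library is
compared against the pooled bead-only controls: after equalizing library
sizes, the serum count X and the control sum Y are modeled as
NB(mu, phi) and NB(n_c * mu, phi / n_c). Because both share the same
success probability, the distribution of X conditional on the total
T = X + Y is free of mu:

    P(X = k | T = t)  proportional to  C(k + r1 - 1, k) * C(t - k + r2 - 1, t - k)

with r1 = 1/phi and r2 = n_c/phi. The two-sided p-value sums the
probabilities of all splits no more probable than the observed one
(minimum-likelihood convention, the same convention used for Fisher's
exact test downstream). At phi = 0 the conditional law is
Binomial(t, 1 / (1 + n_c)) — the Poisson limit.

Hit definition: log2 fold change >= 2 (inclusive) and -log10 p > 4
(strict). False discoveries are additionally controlled by a blacklist:
each bead control is tested leave-one-out against the remaining controls,
and any clone called a hit in any control is excluded from downstream
protein pooling for every serum sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import gmean, trim_mean

from .containers import CountMatrix, SampleMeta, control_samples

# relative slack when collecting splits "no more probable than observed";
# makes equal-probability splits robust to floating-point noise (the same
# convention R's exact tests use)
_REL_TIE = 1 + 1e-7


@dataclass(frozen=True)
class HitThresholds:
    """Dual hit thresholds: fold change and significance."""

    min_log2fc: float = 2.0
    min_neglog10p: float = 4.0

    def __post_init__(self) -> None:
        if self.min_log2fc <= 0 or self.min_neglog10p <= 0:
            raise ValueError("thresholds must be positive")

    def is_hit(self, log2fc: float, p: float) -> bool:
        if p <= 0:
            return log2fc >= self.min_log2fc
        return log2fc >= self.min_log2fc and -np.log10(p) > self.min_neglog10p


@dataclass
class DispersionModel:
    """Per-clone NB dispersions moderated toward a common value.

    ``phi = shrinkage_weight * phi_common + (1 - shrinkage_weight) * phi_raw``.
    Method-of-moments tagwise estimates from a few dozen controls are noisy,
    and underestimating phi inflates deep-tail significance, so moderation
    is deliberately strong by default.
    """

    phi_raw: pd.Series
    phi_common: float
    shrinkage_weight: float = 0.7

    @property
    def phi(self) -> pd.Series:
        w = self.shrinkage_weight
        return (w * self.phi_common + (1 - w) * self.phi_raw).clip(lower=0.0)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Per-sample library-size factors: total / geometric mean of totals."""
    totals = counts.totals
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return totals / gmean(totals.to_numpy())


def estimate_dispersion(
    control_counts: CountMatrix,
    shrinkage_weight: float = 0.7,
    trim: float = 0.1,
) -> DispersionModel:
    """Method-of-moments dispersion from bead-only replicates.

    On size-factor-normalized controls, ``phi = (var - mean) / mean^2``
    floored at 0 per clone; the common value is a trimmed mean of the
    per-clone estimates over clones with positive mean.
    """
    if control_counts.df.shape[1] < 2:
        raise ValueError("dispersion estimation needs >= 2 control samples")
    sf = size_factors(control_counts)
    norm = control_counts.df / sf
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (v - m) / (m ** 2)
    phi_raw = phi_raw.where(m > 0, 0.0).clip(lower=0.0).fillna(0.0)
    positive = phi_raw[m > 0]
    phi_common = float(trim_mean(positive, trim)) if len(positive) else 0.0
    phi_common = max(phi_common, 0.0)
    return DispersionModel(
        phi_raw=phi_raw, phi_common=phi_common, shrinkage_weight=shrinkage_weight
    )


def _minlik_pvalue(log_pmf: np.ndarray, x: int) -> float:
    """Two-sided minimum-likelihood p from an unnormalized conditional log-pmf."""
    log_pmf = log_pmf - logsumexp(log_pmf)
    pmf = np.exp(log_pmf)
    p = float(pmf[pmf <= pmf[x] * _REL_TIE].sum())
    return min(1.0, p)


def _log_rising_ratio(r: float, t: int) -> np.ndarray:
    """log of C(k + r - 1, k) for k = 0..t, up to a k-independent constant.

    Computed as a cumulative sum of log((r + i) / (1 + i)) rather than
    gammaln differences: for very large r (phi -> 0) the gammaln route
    cancels catastrophically, while each ratio term here is exact to
    machine precision.
    """
    i = np.arange(t, dtype=float)
    out = np.empty(t + 1)
    out[0] = 0.0
    np.cumsum(np.log((r + i) / (1.0 + i)), out=out[1:])
    return out


def _conditional_logpmf_nb(t: int, r1: float, r2: float) -> np.ndarray:
    a = _log_rising_ratio(r1, t)
    if r2 == r1:
        b = a
    else:
        b = _log_rising_ratio(r2, t)
    return a + b[::-1]


def _conditional_logpmf_binom(t: int, n_controls: int) -> np.ndarray:
    k = np.arange(t + 1)
    p0 = 1.0 / (1.0 + n_controls)
    return (
        gammaln(t + 1)
        - gammaln(k + 1)
        - gammaln(t - k + 1)
        + k * np.log(p0)
        + (t - k) * np.log1p(-p0)
    )


def conditional_pvalue(x: int, control_sum: int, n_controls: int, phi: float) -> float:
    """Exact conditional two-sided p for a serum count vs pooled controls.

    Counts must already be on a common library-size scale.
    """
    if x < 0 or control_sum < 0:
        raise ValueError("counts must be non-negative")
    t = x + control_sum
    if t == 0:
        return 1.0
    if phi > 0:
        log_pmf = _conditional_logpmf_nb(t, 1.0 / phi, n_controls / phi)
    else:
        log_pmf = _conditional_logpmf_binom(t, n_controls)
    return _minlik_pvalue(log_pmf, x)


def nb_exact_test(
    sample_count: float,
    control_counts: Sequence[float] | np.ndarray,
    phi: float,
    sample_size_factor: float = 1.0,
    control_size_factors: Sequence[float] | np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Test one clone in one serum sample against the bead controls.

    Counts are rescaled to the common (geometric-mean) library size and
    rounded before conditioning, because the exact conditional test
    requires exchangeable totals. Returns ``(p, log2fc)`` where the fold
    change is pseudocount-stabilized on the normalized scale.
    """
    control_counts = np.asarray(control_counts, dtype=float)
    if sample_count < 0 or (control_counts < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    n_c = len(control_counts)
    if n_c == 0:
        raise ValueError("no control counts")
    if control_size_factors is None:
        control_size_factors = np.ones(n_c)
    control_size_factors = np.asarray(control_size_factors, dtype=float)
    x_norm = sample_count / sample_size_factor
    ctrl_norm = control_counts / control_size_factors
    x = int(round(x_norm))
    ctrl_sum = int(round(ctrl_norm.sum()))
    p = conditional_pvalue(x, ctrl_sum, n_c, phi)
    log2fc = float(np.log2((x_norm + pseudocount) / (ctrl_norm.mean() + pseudocount)))
    return p, log2fc


def test_sample_column(
    sample_norm: np.ndarray,
    control_pseudo_sum: np.ndarray,
    control_norm_mean: np.ndarray,
    n_controls: int,
    phi: np.ndarray,
    pseudocount: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized driver: p and log2fc for every clone of one sample column."""
    x = np.rint(sample_norm).astype(np.int64)
    p = np.ones(len(x))
    for i in range(len(x)):
        p[i] = conditional_pvalue(
            int(x[i]), int(control_pseudo_sum[i]), n_controls, float(phi[i])
        )
    log2fc = np.log2((sample_norm + pseudocount) / (control_norm_mean + pseudocount))
    return p, log2fc


@dataclass
class EnrichmentOutcome:
    """Full per-clone-per-sample results plus the control blacklist."""

    results: pd.DataFrame  # clone_id, sample_id, log2fc, p, is_hit, blacklisted
    blacklist: frozenset[str]
    thresholds: HitThresholds

    def hits(self, sample_id: str, apply_blacklist: bool = True) -> set[str]:
        sub = self.results[self.results["sample_id"] == sample_id]
        sub = sub[sub["is_hit"]]
        if apply_blacklist:
            sub = sub[~sub["blacklisted"]]
        return set(sub["clone_id"])

    def hits_by_sample(self, apply_blacklist: bool = True) -> dict[str, set[str]]:
        return {
            sid: self.hits(sid, apply_blacklist)
            for sid in self.results["sample_id"].unique()
        }


def _prepare_controls(
    counts: CountMatrix, control_ids: Sequence[str], sf: pd.Series
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized control matrix, its pseudo (rounded) per-clone sums, and means."""
    ctrl = counts.df[list(control_ids)].to_numpy(dtype=float)
    ctrl_norm = ctrl / sf[list(control_ids)].to_numpy()
    pseudo = np.rint(ctrl_norm)
    return ctrl_norm, pseudo.sum(axis=1), ctrl_norm.mean(axis=1)


def call_hits(
    results: pd.DataFrame, thresholds: HitThresholds = HitThresholds()
) -> pd.DataFrame:
    """Set the is_hit flag: log2fc >= threshold (inclusive) and -log10 p strictly > threshold."""
    out = results.copy()
    with np.errstate(divide="ignore"):
        neglog10p = -np.log10(out["p"].to_numpy())
    out["is_hit"] = (out["log2fc"] >= thresholds.min_log2fc) & (
        neglog10p > thresholds.min_neglog10p
    )
    return out


def control_blacklist(
    control_counts: CountMatrix,
    thresholds: HitThresholds = HitThresholds(),
    dispersion: DispersionModel | None = None,
) -> frozenset[str]:
    """Clones enriched in ANY bead-only control, found leave-one-out.

    Each control is treated as a pseudo-sample and tested against the
    remaining controls with the same exact test and hit thresholds used for
    sera. Dispersion is re-estimated from the remaining controls for each
    leave-one-out test (unless a model is supplied), so a contaminated
    control cannot inflate the dispersion used to judge itself.
    """
    n_ctrl = control_counts.df.shape[1]
    if n_ctrl < 3:
        raise ValueError("blacklisting needs >= 3 control samples")
    sf = size_factors(control_counts)
    norm = (control_counts.df / sf).to_numpy()
    pseudo = np.rint(norm)
    pseudo_sum = pseudo.sum(axis=1)
    clone_ids = np.array(control_counts.clones)
    ctrl_names = control_counts.samples
    bad: set[str] = set()
    for j in range(n_ctrl):
        if dispersion is None:
            rest = control_counts.subset_samples(
                [s for i, s in enumerate(ctrl_names) if i != j]
            )
            phi = estimate_dispersion(rest).phi.to_numpy()
        else:
            phi = dispersion.phi.to_numpy()
        rest_sum = pseudo_sum - pseudo[:, j]
        rest_mean = (norm.sum(axis=1) - norm[:, j]) / (n_ctrl - 1)
        p, log2fc = test_sample_column(
            norm[:, j], rest_sum, rest_mean, n_ctrl - 1, phi
        )
        with np.errstate(divide="ignore"):
            is_hit = (log2fc >= thresholds.min_log2fc) & (
                -np.log10(p) > thresholds.min_neglog10p
            )
        bad.update(clone_ids[is_hit])
    return frozenset(bad)


def run_enrichment(
    counts: CountMatrix,
    meta: Iterable[SampleMeta],
    thresholds: HitThresholds = HitThresholds(),
    shrinkage_weight: float = 0.7,
    with_blacklist: bool = True,
) -> EnrichmentOutcome:
    """Full clone-level analysis: every non-control sample vs the bead controls."""
    meta = list(meta)
    ctrl_ids = control_samples(meta)
    if len(ctrl_ids) < 2:
        raise ValueError("need >= 2 bead-only controls")
    test_ids = [m.sample_id for m in meta if not m.is_control]
    sf = size_factors(counts)
    ctrl_cm = counts.subset_samples(ctrl_ids)
    dispersion = estimate_dispersion(ctrl_cm, shrinkage_weight=shrinkage_weight)
    phi = dispersion.phi.to_numpy()
    _, ctrl_pseudo_sum, ctrl_mean = _prepare_controls(counts, ctrl_ids, sf)
    n_c = len(ctrl_ids)

    blacklist: frozenset[str] = frozenset()
    if with_blacklist:
        blacklist = control_blacklist(ctrl_cm, thresholds)

    frames = []
    clone_ids = counts.clones
    for sid in test_ids:
        col_norm = counts.df[sid].to_numpy(dtype=float) / sf[sid]
        p, log2fc = test_sample_column(col_norm, ctrl_pseudo_sum, ctrl_mean, n_c, phi)
        frames.append(
            pd.DataFrame(
                {
                    "clone_id": clone_ids,
                    "sample_id": sid,
                    "log2fc": log2fc,
                    "p": p,
                }
            )
        )
    results = call_hits(pd.concat(frames, ignore_index=True), thresholds)
    results["blacklisted"] = results["clone_id"].isin(blacklist)
    return EnrichmentOutcome(results=results, blacklist=blacklist, thresholds=thresholds)
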