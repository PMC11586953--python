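"""Protein-level pooling and disease-group comparison.

Clone hits are pooled per protein: a sample is reactive to a protein if at
least one non-blacklisted clone of that protein is a hit, regardless of
which epitope. Each disease group is then compared against the pooled
remaining groups, protein by protein, with a two-sided Fisher exact test on
the 2x2 table (reactive / non-reactive x in-group / rest); proteins at
p < 0.05 are flagged as distinct antigens for that group.

The two-sided convention is minimum-likelihood summation (all tables with
the same margins whose hypergeometric probability does not exceed the
observed one), the convention of R's fisher.test. A doubled-one-tail
alternative is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import SampleMeta, serum_samples
from .tiling import LibraryIndex

_REL_TIE = 1 + 1e-7


def pool_rows(bool_df: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """OR-pool the rows of a Boolean matrix by the given row -> group map."""
    unknown = set(bool_df.index) - set(mapping)
    if unknown:
        raise ValueError(f"rows without a mapping: {sorted(unknown)[:5]}")
    groups = pd.Series({r: mapping[r] for r in bool_df.index})
    pooled = bool_df.groupby(groups).any()
    pooled.index.name = "protein_id"
    return pooled


def collapse_to_protein(
    hits_by_sample: Mapping[str, Set[str]],
    library: LibraryIndex,
    blacklist: Iterable[str] = (),
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boolean protein x sample reactivity from per-sample clone hit sets.

    Blacklisted clones never contribute to a protein call.
    """
    blacklist = set(blacklist)
    if samples is None:
        samples = list(hits_by_sample)
    clone_ids = library.clone_ids
    clone_set = set(clone_ids)
    mat = pd.DataFrame(False, index=clone_ids, columns=list(samples))
    for sid in samples:
        hits = set(hits_by_sample.get(sid, set()))
        unknown = hits - clone_set
        if unknown:
            raise ValueError(
                f"sample {sid!r} has hits for unknown clones: {sorted(unknown)[:5]}"
            )
        for cid in hits - blacklist:
            mat.at[cid, sid] = True
    return pool_rows(mat, library.clone_to_protein)


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, convention: str = "min_likelihood"
) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    a/b: reactive / non-reactive in the group of interest; c/d: the same in
    the pooled rest. ``convention`` is ``"min_likelihood"`` (default,
    matches R) or ``"doubled"`` (twice the smaller one-sided tail, capped
    at 1).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    support = np.arange(max(0, col1 - (n - row1)), min(col1, row1) + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    if convention == "min_likelihood":
        p = float(pmf[pmf <= p_obs * _REL_TIE].sum())
    elif convention == "doubled":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return min(1.0, p)


@dataclass(frozen=True)
class GroupComparison:
    protein_id: str
    group: str
    a: int  # reactive in group
    b: int  # non-reactive in group
    c: int  # reactive in rest
    d: int  # non-reactive in rest
    p: float
    prop_group: float
    prop_rest: float
    distinct: bool


def truncate_pct(x: float) -> int:
    """Percentage display truncated toward zero (8/12 -> 66, 10/12 -> 83)."""
    return math.trunc(100.0 * x)


def group_vs_rest(
    reactivity: pd.DataFrame,
    meta: Iterable[SampleMeta],
    group: str,
    alpha: float = 0.05,
    convention: str = "min_likelihood",
) -> pd.DataFrame:
    """Fisher comparison of one disease group against all other sera.

    Bead controls and spike samples are excluded. Returns one row per
    protein with any reactivity among the sera, flagged ``distinct`` at
    p < alpha.
    """
    meta = list(meta)
    sera = [s for s in serum_samples(meta) if s in reactivity.columns]
    group_ids = [
        m.sample_id for m in meta if m.group == group and m.sample_id in sera
    ]
    if not group_ids:
        raise ValueError(f"group {group!r} has no serum samples")
    rest_ids = [s for s in sera if s not in group_ids]
    sub = reactivity[sera]
    rows = []
    for protein_id, row in sub.iterrows():
        if not row.any():
            continue
        a = int(row[group_ids].sum())
        b = len(group_ids) - a
        c = int(row[rest_ids].sum())
        d = len(rest_ids) - c
        p = fisher_exact_2x2(a, b, c, d, convention=convention)
        rows.append(
            {
                "protein_id": protein_id,
                "group": group,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": p,
                "prop_group": a / len(group_ids),
                "prop_rest": c / len(rest_ids) if rest_ids else float("nan"),
                "pct_group": truncate_pct(a / len(group_ids)),
                "pct_rest": truncate_pct(c / len(rest_ids)) if rest_ids else -1,
                "distinct": p < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "group", "a", "b", "c", "d", "p",
            "prop_group", "prop_rest", "pct_group", "pct_rest", "distinct",
        ],
    )


def distinct_antigens(comparison: pd.DataFrame) -> list[str]:
    return list(comparison.loc[comparison["distinct"], "protein_id"])


def proportion_zscores(proportions: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Row-standardize a protein x group proportion matrix.

    Each row is centered and scaled to unit variance (sample sd by default,
    ddof=0 for the population convention); rows with zero spread map to
    all-zero rows.
    """
    if proportions.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 groups")
    values = proportions.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd <= 1e-12  # constant rows (up to float noise) carry no contrast
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(flat, z.shape)] = 0.0
    return pd.DataFrame(z, index=proportions.index, columns=proportions.columns)


def proportion_matrix(comparisons: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble the protein x group matrix of in-group reactive proportions."""
    cols = {}
    for group, comp in comparisons.items():
        cols[group] = comp.set_index("protein_id")["prop_group"]
    return pd.DataFrame(cols).fillna(0.0)


def set_overlap(
    list_a: Iterable[str], list_b: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Venn partition of two protein sets: (shared, a-only, b-only)."""
    a, b = set(list_a), set(list_b)
    return a & b, a - b, b - a
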