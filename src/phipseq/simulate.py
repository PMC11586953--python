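"""Synthetic PhIP-seq experiment generator with known ground truth.

Emulates the statistical structure of a serum-screening experiment:

* a tiled clone library whose baseline abundances are log-normal,
* 36 bead-only mock immunoprecipitations (the null distribution),
* disease-group sera (default group sizes 12/6/3/3) sharing per-group
  "signature" antigens in which a subset of clones (the epitopes) is
  enriched by a common fold,
* sporadic private reactivities per sample,
* an antibody spike-in at two dose levels against one chosen protein.

Counts are drawn with a negative-binomial/multinomial scheme: per-clone
gamma rates (mean = expected count, variance = mu + phi*mu^2) are
renormalized by a multinomial draw at fixed sequencing depth, so column
sums equal the configured depth exactly while per-clone counts remain
NB-overdispersed. Identical configs (including seed) give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CONTROL_GROUP,
    SPIKE_GROUP,
    CountMatrix,
    GroundTruth,
    ReactiveProtein,
    SampleMeta,
)
from .tiling import LibraryIndex, ProteinRecord

DEFAULT_GROUP_SIZES: dict[str, int] = {"oMMP": 12, "MMP": 6, "BP": 3, "mcPV": 3}

# sub-stream tags so that independently callable generators never share draws
_BASELINE_STREAM = 0
_TRUTH_STREAM = 1
_COUNT_STREAM = 2
_SPIKE_STREAM = 3
_PROTEOME_STREAM = 4


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a synthetic experiment.

    Defaults mirror the assay layout being emulated: four disease groups of
    12/6/3/3 sera, 36 bead-only controls, and a two-dose antibody spike-in.
    ``depth_per_sample=None`` resolves to 50 reads per clone, a comfortably
    saturating depth for hit calling.
    """

    seed: int = 0
    n_proteins: int = 200
    protein_len_range: tuple[int, int] = (100, 400)
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.0
    depth_per_sample: int | None = None
    nb_dispersion: float = 0.2
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_bead_controls: int = 36
    signature_proteins_per_group: int = 5
    epitope_fraction: float = 0.5
    fold_change: float = 16.0
    sporadic_rate: float = 1.0
    spike_doses: tuple[float, ...] = (10.0, 2.0)

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 < self.epitope_fraction <= 1:
            raise ValueError("epitope_fraction must be in (0, 1]")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.n_bead_controls < 0 or self.n_proteins <= 0:
            raise ValueError("counts must be non-negative")
        if self.sporadic_rate < 0:
            raise ValueError("sporadic_rate must be >= 0")


def random_proteome(config: SimConfig) -> list[ProteinRecord]:
    """Draw a toy proteome of random amino-acid sequences."""
    rng = np.random.default_rng([config.seed, _PROTEOME_STREAM])
    lo, hi = config.protein_len_range
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        out.append(
            ProteinRecord(protein_id=f"P{i:04d}", gene_symbol=f"G{i:04d}", sequence=seq)
        )
    return out


def _baseline_abundance(config: SimConfig, n_clones: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, _BASELINE_STREAM])
    return rng.lognormal(
        config.abundance_lognormal_mu, config.abundance_lognormal_sigma, n_clones
    )


def _resolve_depth(config: SimConfig, n_clones: int) -> int:
    return config.depth_per_sample if config.depth_per_sample else 50 * n_clones


def _pick_epitope_clones(
    rng: np.random.Generator, clone_ids: Sequence[str], fraction: float
) -> tuple[str, ...]:
    n = max(1, round(fraction * len(clone_ids)))
    picked = rng.choice(len(clone_ids), size=n, replace=False)
    return tuple(clone_ids[i] for i in sorted(picked))


def _draw_column(
    rng: np.random.Generator,
    baseline: np.ndarray,
    fold: np.ndarray,
    depth: int,
    phi: float,
) -> np.ndarray:
    weights = baseline * fold
    mu = depth * weights / weights.sum()
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        total = lam.sum()
        if total <= 0:  # pathological; fall back to the means
            lam, total = mu, mu.sum()
    else:
        lam, total = mu, mu.sum()
    return rng.multinomial(depth, lam / total)


def assign_signatures(
    config: SimConfig, library: LibraryIndex
) -> dict[str, tuple[ReactiveProtein, ...]]:
    """Choose per-group signature antigens and their epitope clones.

    Groups receive disjoint signature proteins, so each group's antigens are
    private to it (the setting under which group-versus-rest comparisons are
    benchmarked).
    """
    rng = np.random.default_rng([config.seed, _TRUTH_STREAM])
    proteins = library.protein_ids
    clones_by_protein = {
        pid: tuple(t.clone_id for t in library.tiles if t.protein_id == pid)
        for pid in proteins
    }
    pool = list(proteins)
    out: dict[str, tuple[ReactiveProtein, ...]] = {}
    for group in config.group_sizes:
        k = min(config.signature_proteins_per_group, len(pool))
        picked_idx = rng.choice(len(pool), size=k, replace=False)
        picked = [pool[i] for i in sorted(picked_idx)]
        entries = []
        for pid in picked:
            clones = _pick_epitope_clones(
                rng, clones_by_protein[pid], config.epitope_fraction
            )
            entries.append(ReactiveProtein(pid, clones, config.fold_change))
            pool.remove(pid)
        out[group] = tuple(entries)
    return out


def simulate_counts(
    config: SimConfig, library: LibraryIndex
) -> tuple[CountMatrix, list[SampleMeta], GroundTruth]:
    """Simulate the full count matrix for sera plus bead-only controls."""
    if library.n_clones == 0:
        raise ValueError("library has no clones")
    n_samples = sum(config.group_sizes.values()) + config.n_bead_controls
    if n_samples == 0:
        raise ValueError("experiment has no samples")

    clone_ids = library.clone_ids
    clone_pos = {cid: i for i, cid in enumerate(clone_ids)}
    n = len(clone_ids)
    baseline = _baseline_abundance(config, n)
    depth = _resolve_depth(config, n)

    signatures = assign_signatures(config, library)
    signature_proteins = {
        e.protein_id for entries in signatures.values() for e in entries
    }
    clones_by_protein = {
        pid: tuple(t.clone_id for t in library.tiles if t.protein_id == pid)
        for pid in library.protein_ids
    }
    sporadic_pool = [
        pid for pid in library.protein_ids if pid not in signature_proteins
    ]

    truth_rng = np.random.default_rng([config.seed, _TRUTH_STREAM, 1])
    count_rng = np.random.default_rng([config.seed, _COUNT_STREAM])

    meta: list[SampleMeta] = []
    truth: dict[str, tuple[ReactiveProtein, ...]] = {}
    columns: dict[str, np.ndarray] = {}

    for group, size in config.group_sizes.items():
        for i in range(size):
            sid = f"{group}_{i + 1}"
            meta.append(SampleMeta(sid, group, is_control=False))
            entries = list(signatures[group])
            if config.sporadic_rate > 0 and sporadic_pool:
                n_sp = int(truth_rng.poisson(config.sporadic_rate))
                n_sp = min(n_sp, len(sporadic_pool))
                if n_sp:
                    idx = truth_rng.choice(len(sporadic_pool), size=n_sp, replace=False)
                    for j in sorted(idx):
                        pid = sporadic_pool[j]
                        clones = _pick_epitope_clones(
                            truth_rng, clones_by_protein[pid], config.epitope_fraction
                        )
                        entries.append(
                            ReactiveProtein(pid, clones, config.fold_change)
                        )
            truth[sid] = tuple(entries)
            fold = np.ones(n)
            for entry in entries:
                for cid in entry.clone_ids:
                    fold[clone_pos[cid]] *= entry.fold
            columns[sid] = _draw_column(
                count_rng, baseline, fold, depth, config.nb_dispersion
            )

    ones = np.ones(n)
    for i in range(config.n_bead_controls):
        sid = f"{CONTROL_GROUP}_{i + 1}"
        meta.append(SampleMeta(sid, CONTROL_GROUP, is_control=True))
        columns[sid] = _draw_column(
            count_rng, baseline, ones, depth, config.nb_dispersion
        )

    df = pd.DataFrame(columns, index=clone_ids)
    return CountMatrix(df), meta, GroundTruth(reactive=truth)


def spike_in(
    config: SimConfig, library: LibraryIndex, target_protein: str
) -> tuple[pd.DataFrame, list[SampleMeta], GroundTruth]:
    """Simulate spike-in samples in which only one protein is enriched.

    The enrichment fold scales linearly with dose (fold - 1 proportional to
    antibody amount), so the highest configured dose reaches the configured
    fold_change and dose 0 reduces to a bead-like column. All clones of the
    target protein are enriched.
    """
    clones = library.clones_of_protein(target_protein)
    if not clones:
        raise ValueError(f"protein {target_protein!r} is not in the library")
    clone_ids = library.clone_ids
    clone_pos = {cid: i for i, cid in enumerate(clone_ids)}
    n = len(clone_ids)
    baseline = _baseline_abundance(config, n)
    depth = _resolve_depth(config, n)
    rng = np.random.default_rng([config.seed, _SPIKE_STREAM])

    max_dose = max(config.spike_doses) if config.spike_doses else 1.0
    meta: list[SampleMeta] = []
    truth: dict[str, tuple[ReactiveProtein, ...]] = {}
    columns: dict[str, np.ndarray] = {}
    for dose in config.spike_doses:
        sid = f"spike_{dose:g}ug"
        fold_value = (
            1.0 + (config.fold_change - 1.0) * dose / max_dose if max_dose > 0 else 1.0
        )
        fold = np.ones(n)
        for cid in clones:
            fold[clone_pos[cid]] = fold_value
        meta.append(SampleMeta(sid, SPIKE_GROUP, is_control=False))
        truth[sid] = (ReactiveProtein(target_protein, tuple(clones), fold_value),)
        columns[sid] = _draw_column(
            rng, baseline, fold, depth, config.nb_dispersion
        )
    df = pd.DataFrame(columns, index=clone_ids)
    return df, meta, GroundTruth(reactive=truth)


def simulate_experiment(
    config: SimConfig,
    library: LibraryIndex,
    spike_target: str | None = None,
) -> tuple[CountMatrix, list[SampleMeta], GroundTruth]:
    """Serum + bead simulation, optionally extended with spike-in columns."""
    counts, meta, truth = simulate_counts(config, library)
    if spike_target is not None and config.spike_doses:
        spike_df, spike_meta, spike_truth = spike_in(config, library, spike_target)
        counts = CountMatrix(pd.concat([counts.df, spike_df], axis=1))
        meta = meta + spike_meta
        truth.reactive.update(spike_truth.reactive)
    return counts, meta, truth


def simulate_reads(
    counts: CountMatrix,
    library: LibraryIndex,
    error_rate: float = 0.0,
    read_len: int = 100,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Expand a count matrix into per-sample reads with substitution errors.

    Each count unit becomes one read taken from the 5' end of the clone's
    amplicon template (5' tag flank + insert + 3' tag flank), with i.i.d.
    per-base substitutions at ``error_rate``. Returns
    ``{sample_id: [(read_id, sequence), ...]}``.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    templates = {c.clone_id: c.template for c in library.clones}
    short = [cid for cid, t in templates.items() if len(t) < read_len]
    if short:
        raise ValueError(
            f"read_len {read_len} exceeds template length for clones "
            f"{short[:3]}..."
        )
    rng = np.random.default_rng([seed, 1])
    out: dict[str, list[tuple[str, str]]] = {}
    for sample in counts.samples:
        col = counts.df[sample]
        reads: list[tuple[str, str]] = []
        for clone_id, count in col.items():
            if count == 0:
                continue
            prefix = templates[clone_id][:read_len]
            for i in range(int(count)):
                seq = prefix
                if error_rate > 0:
                    mask = rng.random(read_len) < error_rate
                    if mask.any():
                        arr = np.array(list(seq))
                        for pos in np.nonzero(mask)[0]:
                            orig = arr[pos]
                            choices = [b for b in "ACGT" if b != orig]
                            arr[pos] = choices[int(rng.integers(3))]
                        seq = "".join(arr)
                reads.append((f"{sample}:{clone_id}:{i}", seq))
        out[sample] = reads
    return out
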