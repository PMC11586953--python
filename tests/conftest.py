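"""Shared fixtures: small handcrafted libraries and two session-scoped
simulated experiments (a null one and an enriched one) reused by the
calibration / recovery / spike-in tests so the heavy enrichment runs happen
once."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from phipseq import (
    HitThresholds,
    ProteinRecord,
    SimConfig,
    build_library,
    random_proteome,
    run_enrichment,
    simulate_counts,
    simulate_experiment,
)
from phipseq.simulate import assign_signatures


@pytest.fixture
def toy_proteins() -> list[ProteinRecord]:
    return [
        ProteinRecord("P1", "GENE1", "ACDEFGHIKLMNPQRSTVWY" * 5),  # length 100
        ProteinRecord("P2", "GENE2", "M" * 49),
        ProteinRecord("P3", "GENE3", "KLMNPQRSTVWYACDEFGHI" * 8),  # length 160
    ]


@pytest.fixture
def toy_library(toy_proteins):
    return build_library(toy_proteins)


@dataclass
class SimulatedExperiment:
    config: SimConfig
    library: object
    counts: object
    meta: list
    truth: object
    outcome: object
    signatures: dict
    spike_target: str | None = None


@pytest.fixture(scope="session")
def null_experiment() -> SimulatedExperiment:
    """Full experiment at fold_change=1 (~2,000 clones): nothing is enriched."""
    config = SimConfig(
        seed=2, n_proteins=300, protein_len_range=(60, 300), fold_change=1.0
    )
    library = build_library(random_proteome(config))
    counts, meta, truth = simulate_counts(config, library)
    outcome = run_enrichment(counts, meta, HitThresholds())
    return SimulatedExperiment(
        config, library, counts, meta, truth, outcome, assign_signatures(config, library)
    )


@pytest.fixture(scope="session")
def enriched_experiment() -> SimulatedExperiment:
    """Default study design (200 proteins, fold 16, epitope fraction 0.5,
    group sizes 12/6/3/3, 36 bead controls, mean control depth 50x) plus a
    two-dose spike-in."""
    config = SimConfig(seed=1)
    library = build_library(random_proteome(config))
    spike_target = library.protein_ids[0]
    counts, meta, truth = simulate_experiment(config, library, spike_target)
    outcome = run_enrichment(counts, meta, HitThresholds())
    return SimulatedExperiment(
        config,
        library,
        counts,
        meta,
        truth,
        outcome,
        assign_signatures(config, library),
        spike_target=spike_target,
    )
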