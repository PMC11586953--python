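"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTROL_GROUP = "beads"
SPIKE_GROUP = "spike"


@dataclass
class CountMatrix:
    """Clones x samples matrix of non-negative integer read counts.

    Thin wrapper over a pandas DataFrame (rows = clone_ids, columns =
    sample_ids) that enforces integrality and non-negativity and exposes
    per-sample totals.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.shape[0] == 0 or self.df.shape[1] == 0:
            raise ValueError("count matrix must have at least one clone and one sample")
        values = self.df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.df = self.df.astype(np.int64)
            values = self.df.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def clones(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def totals(self) -> pd.Series:
        return self.df.sum(axis=0)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.df[list(samples)].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="clone_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="clone_id")
        df.index = df.index.astype(str)
        return cls(df)


@dataclass(frozen=True)
class SampleMeta:
    """One sample: id, disease group (or 'beads'/'spike'), control flag."""

    sample_id: str
    group: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.is_control != (self.group == CONTROL_GROUP):
            raise ValueError(
                f"sample {self.sample_id!r}: is_control must hold exactly for "
                f"the {CONTROL_GROUP!r} group"
            )


def meta_to_frame(meta: Iterable[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.sample_id, m.group, m.is_control) for m in meta],
        columns=["sample_id", "group", "is_control"],
    )


def write_meta_tsv(meta: Iterable[SampleMeta], path: str | Path) -> None:
    meta_to_frame(meta).to_csv(path, sep="\t", index=False)


def read_meta_tsv(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    out = [
        SampleMeta(str(r.sample_id), str(r.group), bool(r.is_control))
        for r in df.itertuples()
    ]
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in metadata")
    return out


def control_samples(meta: Iterable[SampleMeta]) -> list[str]:
    return [m.sample_id for m in meta if m.is_control]


def serum_samples(meta: Iterable[SampleMeta]) -> list[str]:
    """Disease-group samples: everything except bead controls and spikes."""
    return [
        m.sample_id
        for m in meta
        if not m.is_control and m.group != SPIKE_GROUP
    ]


@dataclass(frozen=True)
class ReactiveProtein:
    """Ground-truth enrichment of one protein in one sample."""

    protein_id: str
    clone_ids: tuple[str, ...]
    fold: float


@dataclass
class GroundTruth:
    """Known reactivities injected by the simulator, keyed by sample."""

    reactive: dict[str, tuple[ReactiveProtein, ...]] = field(default_factory=dict)

    def enriched_pairs(self) -> set[tuple[str, str]]:
        """All (clone_id, sample_id) pairs with fold > 1."""
        pairs = set()
        for sample_id, entries in self.reactive.items():
            for entry in entries:
                if entry.fold > 1:
                    pairs.update((cid, sample_id) for cid in entry.clone_ids)
        return pairs

    def proteins_of(self, sample_id: str) -> set[str]:
        return {e.protein_id for e in self.reactive.get(sample_id, ())}

    def to_json(self, path: str | Path) -> None:
        payload = {
            sample: [
                {"protein_id": e.protein_id, "clone_ids": list(e.clone_ids), "fold": e.fold}
                for e in entries
            ]
            for sample, entries in self.reactive.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            reactive={
                sample: tuple(
                    ReactiveProtein(e["protein_id"], tuple(e["clone_ids"]), e["fold"])
                    for e in entries
                )
                for sample, entries in payload.items()
            }
        )
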