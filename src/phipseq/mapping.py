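"""Seed-and-extend read mapping to the clone library, plus coverage QC.

Reads are assigned by ungapped alignment: exact k-mer seeds nominate
(clone, diagonal) candidates, each candidate is scored over the full
read/template overlap with +1 per match and -1 per mismatch (read bases
hanging off the template are soft-clipped and score 0), and the read is
counted to the unique best-scoring clone whose score reaches ``min_score``.
With this scheme the default threshold of 50 reads directly as "at least 50
net matching positions". Ties between distinct clones are discarded as
ambiguous; sub-threshold reads are discarded too, and both are tallied in a
mapping log so that assigned + ambiguous + sub-threshold = total reads.

Amplicon reads are modeled ungapped; clone templates are single-stranded,
so mapping is forward-only by default with an optional both-strands mode.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .fastqio import read_fastq
from .tiling import LibraryIndex

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MappingParams:
    min_score: int = 50
    match: int = 1
    mismatch: int = -1
    gap: int = -2  # reserved; amplicon reads are modeled ungapped
    k_seed: int = 25
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.k_seed <= 0:
            raise ValueError("k_seed must be positive")


@dataclass
class MappingLog:
    """Per-sample tallies of read fates."""

    assigned: dict[str, int] = field(default_factory=dict)
    ambiguous: dict[str, int] = field(default_factory=dict)
    subthreshold: dict[str, int] = field(default_factory=dict)

    def total(self, sample: str) -> int:
        return (
            self.assigned.get(sample, 0)
            + self.ambiguous.get(sample, 0)
            + self.subthreshold.get(sample, 0)
        )

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(self.assigned)
        return pd.DataFrame(
            {
                "sample_id": samples,
                "assigned": [self.assigned[s] for s in samples],
                "ambiguous": [self.ambiguous[s] for s in samples],
                "subthreshold": [self.subthreshold[s] for s in samples],
            }
        )


class SeedIndex:
    """Exact k-mer index over clone amplicon templates."""

    def __init__(self, library: LibraryIndex, k: int):
        if library.n_clones == 0:
            raise ValueError("cannot index an empty library")
        self.k = k
        self.clone_ids = library.clone_ids
        self.templates = [c.template for c in library.clones]
        index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ci, template in enumerate(self.templates):
            for pos in range(len(template) - k + 1):
                index[template[pos : pos + k]].append((ci, pos))
        self.index = dict(index)

    def candidates(self, read: str) -> set[tuple[int, int]]:
        """(clone, diagonal) pairs nominated by non-overlapping seeds."""
        k = self.k
        if len(read) < k:
            return set()
        offsets = list(range(0, len(read) - k + 1, k))
        if offsets[-1] != len(read) - k:
            offsets.append(len(read) - k)
        out: set[tuple[int, int]] = set()
        for off in offsets:
            for ci, pos in self.index.get(read[off : off + k], ()):
                out.add((ci, pos - off))
        return out


def _overlap_score(read: str, template: str, diag: int, params: MappingParams) -> int:
    """Ungapped score of the read against the template on one diagonal."""
    start = max(0, -diag)
    end = min(len(read), len(template) - diag)
    if end <= start:
        return -len(read)
    score = 0
    for i in range(start, end):
        score += params.match if read[i] == template[diag + i] else params.mismatch
    return score


def _best_clone(
    read: str, index: SeedIndex, params: MappingParams
) -> tuple[int | None, bool]:
    """Return (clone index or None, ambiguous flag) for one read."""
    strands = [read]
    if params.both_strands:
        strands.append(reverse_complement(read))
    best_by_clone: dict[int, int] = {}
    for seq in strands:
        for ci, diag in index.candidates(seq):
            s = _overlap_score(seq, index.templates[ci], diag, params)
            if s > best_by_clone.get(ci, -(10 ** 9)):
                best_by_clone[ci] = s
    if not best_by_clone:
        return None, False
    top = max(best_by_clone.values())
    if top < params.min_score:
        return None, False
    winners = [ci for ci, s in best_by_clone.items() if s == top]
    if len(winners) > 1:
        return None, True
    return winners[0], False


def map_reads(
    reads_by_sample: Mapping[str, Iterable[tuple[str, str]] | str | Path],
    library: LibraryIndex,
    params: MappingParams = MappingParams(),
) -> tuple[CountMatrix, MappingLog]:
    """Map per-sample reads to clones and assemble the count matrix.

    ``reads_by_sample`` maps sample ids either to FASTQ paths or to
    iterables of (read_id, sequence) pairs.
    """
    index = SeedIndex(library, params.k_seed)
    clone_ids = library.clone_ids
    log = MappingLog()
    columns: dict[str, np.ndarray] = {}
    for sample, source in reads_by_sample.items():
        if isinstance(source, (str, Path)):
            reads: Iterable[tuple[str, str]] = read_fastq(source)
        else:
            reads = source
        col = np.zeros(len(clone_ids), dtype=np.int64)
        n_assigned = n_ambig = n_sub = 0
        for _read_id, seq in reads:
            ci, ambiguous = _best_clone(seq, index, params)
            if ci is not None:
                col[ci] += 1
                n_assigned += 1
            elif ambiguous:
                n_ambig += 1
            else:
                n_sub += 1
        columns[sample] = col
        log.assigned[sample] = n_assigned
        log.ambiguous[sample] = n_ambig
        log.subthreshold[sample] = n_sub
    df = pd.DataFrame(columns, index=clone_ids)
    return CountMatrix(df), log


def qc_coverage(counts: CountMatrix, library: LibraryIndex) -> pd.DataFrame:
    """Per-sample library coverage: mapped reads divided by clone count.

    Flags the 1x threshold every sample is expected to clear and the 5x
    mean-coverage level used as a stricter guide.
    """
    n_clones = library.n_clones
    mapped = counts.totals
    coverage = mapped / n_clones
    return pd.DataFrame(
        {
            "sample_id": counts.samples,
            "mapped_reads": mapped.to_numpy(),
            "coverage_x": coverage.to_numpy(),
            "pass_1x": (coverage >= 1.0).to_numpy(),
            "pass_5x": (coverage >= 5.0).to_numpy(),
        }
    )
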