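"""Peptidome tiling-library construction.

A T7 display library represents each protein as overlapping 49-mer peptides
with 25 residues of overlap (step 24). Every tile is reverse-translated with
a deterministic E. coli codon table and flanked by FLAG / STREP tag-encoding
sequences, yielding one phage clone per tile. The clone-to-protein map drives
all downstream protein-level pooling.

Tiling rule
-----------
Tiles start at offsets 0, 24, 48, ... as long as a full tile fits. If
residues at the C terminus would be left uncovered, one extra full-length
tile is anchored at ``length - tile_len`` (its overlap with the previous
tile then exceeds 25). Proteins shorter than one tile yield a single
full-length tile. This guarantees every residue is covered by at least one
fixed-length peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .codon import ECOLI_PREFERRED_CODONS, FLAG_TAG_NT, STREP_TAG_NT

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class TilingParams:
    """Tile geometry: 49-mer peptides overlapping by 25 residues."""

    tile_len: int = 49
    overlap: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.overlap < self.tile_len:
            raise ValueError(
                f"require 0 < overlap < tile_len, got overlap={self.overlap}, "
                f"tile_len={self.tile_len}"
            )

    @property
    def step(self) -> int:
        return self.tile_len - self.overlap


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r} contains non-standard residues: "
                f"{sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideTile:
    clone_id: str
    protein_id: str
    start: int
    peptide: str


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    insert_nt: str
    flank_5p: str = FLAG_TAG_NT
    flank_3p: str = STREP_TAG_NT

    @property
    def template(self) -> str:
        """Full amplicon template: 5' flank + insert + 3' flank."""
        return self.flank_5p + self.insert_nt + self.flank_3p


@dataclass
class LibraryIndex:
    """All tiles and clones of a library plus the clone -> protein map."""

    tiles: list[PeptideTile]
    clones: list[CloneRecord]
    clone_to_protein: dict[str, str]
    gene_symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("clone_ids are not unique")
        missing = set(ids) - set(self.clone_to_protein)
        if missing:
            raise ValueError(f"clones without a protein mapping: {sorted(missing)[:5]}")

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def protein_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tiles:
            seen.setdefault(t.protein_id, None)
        return list(seen)

    def clones_of_protein(self, protein_id: str) -> list[str]:
        return [cid for cid, pid in self.clone_to_protein.items() if pid == protein_id]

    def gene_symbol(self, protein_id: str) -> str:
        return self.gene_symbols.get(protein_id, protein_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        clone_by_id = {c.clone_id: c for c in self.clones}
        for t in self.tiles:
            c = clone_by_id[t.clone_id]
            rows.append(
                {
                    "clone_id": t.clone_id,
                    "protein_id": t.protein_id,
                    "gene_symbol": self.gene_symbol(t.protein_id),
                    "start": t.start,
                    "peptide": t.peptide,
                    "insert_nt": c.insert_nt,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_insert_fasta(self, path: str | Path, with_flanks: bool = True) -> None:
        with open(path, "w") as fh:
            for clone in self.clones:
                seq = clone.template if with_flanks else clone.insert_nt
                fh.write(f">{clone.clone_id}\n{seq}\n")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LibraryIndex":
        tiles = [
            PeptideTile(r.clone_id, r.protein_id, int(r.start), r.peptide)
            for r in df.itertuples()
        ]
        clones = [CloneRecord(r.clone_id, r.insert_nt) for r in df.itertuples()]
        c2p = dict(zip(df["clone_id"], df["protein_id"]))
        genes = dict(zip(df["protein_id"], df["gene_symbol"]))
        return cls(tiles=tiles, clones=clones, clone_to_protein=c2p, gene_symbols=genes)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LibraryIndex":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"clone_id": str}))


def tile_starts(length: int, params: TilingParams) -> list[int]:
    """Start offsets of all tiles for a protein of the given length."""
    if length <= 0:
        raise ValueError("protein length must be positive")
    if length <= params.tile_len:
        return [0]
    starts = list(range(0, length - params.tile_len + 1, params.step))
    if starts[-1] + params.tile_len < length:
        starts.append(length - params.tile_len)
    return starts


def tile_protein(
    protein: ProteinRecord, params: TilingParams = TilingParams()
) -> list[PeptideTile]:
    """Tile one protein into overlapping fixed-length peptides.

    Proteins shorter than ``tile_len`` yield a single full-length tile.
    """
    seq = protein.sequence
    tiles = []
    for start in tile_starts(len(seq), params):
        pep = seq[start : start + params.tile_len]
        tiles.append(
            PeptideTile(
                clone_id=f"{protein.protein_id}_{start}",
                protein_id=protein.protein_id,
                start=start,
                peptide=pep,
            )
        )
    return tiles


def reverse_translate(
    tile: PeptideTile,
    codon_table: Mapping[str, str] = ECOLI_PREFERRED_CODONS,
    flank_5p: str = FLAG_TAG_NT,
    flank_3p: str = STREP_TAG_NT,
) -> CloneRecord:
    """Encode a peptide tile as a nucleotide insert with tag flanks.

    Raises a ``KeyError``-style ``ValueError`` naming the residue and its
    position if the codon table lacks a residue.
    """
    codons = []
    for i, aa in enumerate(tile.peptide):
        try:
            codons.append(codon_table[aa])
        except KeyError:
            raise ValueError(
                f"no codon for residue {aa!r} at position {i} of clone "
                f"{tile.clone_id}"
            ) from None
    return CloneRecord(
        clone_id=tile.clone_id,
        insert_nt="".join(codons),
        flank_5p=flank_5p,
        flank_3p=flank_3p,
    )


def build_library(
    proteins: Sequence[ProteinRecord],
    params: TilingParams = TilingParams(),
    codon_table: Mapping[str, str] = ECOLI_PREFERRED_CODONS,
    flank_5p: str = FLAG_TAG_NT,
    flank_3p: str = STREP_TAG_NT,
) -> LibraryIndex:
    """Tile every protein and reverse-translate every tile into a clone.

    Identical peptides arising from different proteins keep distinct
    clone_ids: downstream pooling is protein-scoped, so clone identity must
    stay protein-scoped too.
    """
    if not proteins:
        raise ValueError("cannot build a library from an empty protein list")
    pids = [p.protein_id for p in proteins]
    if len(set(pids)) != len(pids):
        dupes = sorted({p for p in pids if pids.count(p) > 1})
        raise ValueError(f"duplicate protein_ids: {dupes}")
    tiles: list[PeptideTile] = []
    clones: list[CloneRecord] = []
    c2p: dict[str, str] = {}
    genes: dict[str, str] = {}
    for prot in proteins:
        genes[prot.protein_id] = prot.gene_symbol
        for tile in tile_protein(prot, params):
            tiles.append(tile)
            clones.append(
                reverse_translate(tile, codon_table, flank_5p, flank_3p)
            )
            c2p[tile.clone_id] = tile.protein_id
    return LibraryIndex(tiles=tiles, clones=clones, clone_to_protein=c2p, gene_symbols=genes)


def read_proteome_fasta(
    path: str | Path, header_delim: str = "|"
) -> list[ProteinRecord]:
    """Read a proteome FASTA with headers ``protein_id<delim>gene_symbol``.

    A header without the delimiter uses the whole id as both protein_id and
    gene symbol.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split(header_delim, 1)
        pid = parts[0]
        gene = parts[1] if len(parts) == 2 else parts[0]
        records.append(
            ProteinRecord(protein_id=pid, gene_symbol=gene, sequence=str(rec.seq).upper())
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def stitch_tiles(tiles: Iterable[PeptideTile]) -> str:
    """Reconstruct a protein sequence from its tiles (inverse of tiling)."""
    ordered = sorted(tiles, key=lambda t: t.start)
    seq = ordered[0].peptide
    for t in ordered[1:]:
        if t.start > len(seq):
            raise ValueError(f"gap before tile at {t.start}")
        seq = seq[: t.start] + t.peptide
    return seq
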