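"""Protein multiple-sequence-alignment container and gap-based culling.

Mirrors the manual curation step of an HGT screen: sequences that are mostly
gap across the well-occupied ("core") columns of the MSA are removed, and the
caller is told to recompute the alignment whenever anything was dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


@dataclass(frozen=True)
class TrimConfig:
    """Culling thresholds.

    core_col_min_occupancy : minimum non-gap fraction for a column to count as
        part of the alignment core (default 0.8).
    max_core_gap_fraction : a sequence is removed when its gap fraction over
        core columns exceeds this (default 0.5).
    """

    core_col_min_occupancy: float = 0.8
    max_core_gap_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.core_col_min_occupancy <= 1.0):
            raise ValueError("core_col_min_occupancy must be in (0, 1]")
        if not (0.0 <= self.max_core_gap_fraction < 1.0):
            raise ValueError("max_core_gap_fraction must be in [0, 1)")


class Alignment:
    """Equal-length gapped protein sequences with unique, ordered ids."""

    def __init__(self, ids: list[str], rows: list[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if not rows:
            raise ValueError("empty alignment")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        length = len(rows[0])
        ragged = [i for i, r in zip(ids, rows) if len(r) != length]
        if ragged:
            raise ValueError(f"ragged alignment; offending ids: {ragged}")
        if length < 1:
            raise ValueError("alignment has zero columns")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    def subset(self, keep_ids: list[str]) -> "Alignment":
        idx = {i: k for k, i in enumerate(self.ids)}
        return Alignment(list(keep_ids), [self.rows[idx[i]] for i in keep_ids])

    def drop_allgap_columns(self) -> "Alignment":
        m = self.matrix()
        keep = ~(m == GAP).all(axis=0)
        if keep.all():
            return self
        return Alignment(self.ids, ["".join(r) for r in m[:, keep]])

    def write(self, path) -> None:
        recs = [SeqRecord(Seq(r), id=i, description="") for i, r in zip(self.ids, self.rows)]
        SeqIO.write(recs, path, "fasta")


def read_fasta_alignment(path) -> Alignment:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment([r.id for r in recs], [str(r.seq) for r in recs])


def read_fasta(path) -> dict[str, str]:
    """Unaligned FASTA as an ordered id -> sequence mapping."""
    out: dict[str, str] = {}
    for r in SeqIO.parse(str(path), "fasta"):
        if r.id in out:
            raise ValueError(f"duplicate id {r.id!r} in {path}")
        out[r.id] = str(r.seq)
    return out


def cull_gappy_sequences(
    aln: Alignment, cfg: TrimConfig = TrimConfig()
) -> tuple[Alignment, list[str], bool]:
    """Remove sequences that are mostly gap over the alignment core.

    Returns ``(trimmed, removed_ids, recompute_needed)``.  The flag signals the
    orchestrator to recompute the MSA (externally) and re-enter this stage, as
    removal changes the optimal alignment of the remainder.
    """
    if aln.n_sequences < 3:
        raise ValueError("need at least 3 sequences for downstream tree inference")
    m = aln.matrix()
    occupancy = (m != GAP).mean(axis=0)
    core = occupancy >= cfg.core_col_min_occupancy
    removed: list[str] = []
    if core.any():
        gap_frac = (m[:, core] == GAP).mean(axis=1)
        removed = [i for i, g in zip(aln.ids, gap_frac) if g > cfg.max_core_gap_fraction]
    keep = [i for i in aln.ids if i not in set(removed)]
    if len(keep) < 3:
        raise ValueError(
            f"culling left {len(keep)} sequences (< 3); tree inference impossible"
        )
    out = aln.subset(keep).drop_allgap_columns()
    return out, removed, bool(removed)


def core_gap_report(aln: Alignment, cfg: TrimConfig = TrimConfig()) -> list[tuple[str, float]]:
    """Per-sequence gap fraction over core columns (for the removal report)."""
    m = aln.matrix()
    core = (m != GAP).mean(axis=0) >= cfg.core_col_min_occupancy
    if not core.any():
        return [(i, 0.0) for i in aln.ids]
    gap_frac = (m[:, core] == GAP).mean(axis=1)
    return list(zip(aln.ids, (float(g) for g in gap_frac)))
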