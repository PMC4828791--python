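"""Homology-hit screening: E-value/domain-overlap filters and per-taxon picks.

Consumes BLAST tabular (outfmt 6) hit files.  A hit is retained when its
E-value is strictly below the threshold and it overlaps the query's annotated
protein domain by strictly more than the minimum number of residues; each
taxonomic group then contributes its top-scoring subjects (by bitscore), with
the recipient lineage exempt from the cap.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    evalue: float
    aln_len: int
    bitscore: float
    subject_taxon: str | None = None
    domain_overlap: int = 0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.aln_len < 1:
            raise ValueError("aln_len must be a positive integer")
        if not (0 <= self.domain_overlap <= self.aln_len):
            raise ValueError("domain_overlap must be in [0, aln_len]")


@dataclass(frozen=True)
class ScreenConfig:
    max_evalue: float = 0.001
    min_domain_overlap_aa: int = 50
    reps_per_group: tuple[int, int] = (1, 10)
    unlimited_groups: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.max_evalue > 0:
            raise ValueError("max_evalue must be positive")
        if self.min_domain_overlap_aa < 0:
            raise ValueError("min_domain_overlap_aa must be non-negative")
        lo, hi = self.reps_per_group
        if lo > hi or lo < 1:
            raise ValueError("reps_per_group range must satisfy 1 <= lower <= upper")
        object.__setattr__(self, "unlimited_groups", frozenset(self.unlimited_groups))


DIALECTS = ("blast-tab-12col", "blast-tab-custom")


def domain_overlap_length(
    qstart: int, qend: int, domain_span: tuple[int, int] | None
) -> int:
    """Intersection of the hit's query range with a 1-based inclusive span."""
    if domain_span is None:
        return qend - qstart + 1
    ds, de = domain_span
    return max(0, min(qend, de) - max(qstart, ds) + 1)


def read_hit_table(
    path,
    dialect: str = "blast-tab-12col",
    domain_span: tuple[int, int] | None = None,
) -> list[Hit]:
    """Parse a BLAST outfmt-6 file into Hits.

    ``blast-tab-12col`` is the standard qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore layout;
    ``blast-tab-custom`` appends a 13th subject-taxon column.  When a
    ``domain_span`` (1-based inclusive query coordinates) is given, each hit's
    domain overlap is the intersection of [qstart, qend] with the span;
    otherwise the full aligned query range counts as domain overlap.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    n_cols = 12 if dialect == "blast-tab-12col" else 13
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} columns, got {len(row)}"
                )
            try:
                qstart, qend = int(row[6]), int(row[7])
                hit = Hit(
                    query_id=row[0],
                    subject_id=row[1],
                    evalue=float(row[10]),
                    aln_len=int(row[3]),
                    bitscore=float(row[11]),
                    subject_taxon=row[12] if n_cols == 13 else None,
                    domain_overlap=min(
                        int(row[3]), domain_overlap_length(qstart, qend, domain_span)
                    ),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            hits.append(hit)
    return hits


def filter_hits(hits: list[Hit], cfg: ScreenConfig = ScreenConfig()) -> list[Hit]:
    """Keep hits with evalue < max_evalue and overlap > min threshold (strict)."""
    return [
        h
        for h in hits
        if h.evalue < cfg.max_evalue and h.domain_overlap > cfg.min_domain_overlap_aa
    ]


def select_representatives(
    hits: list[Hit], taxonomy: dict[str, str], cfg: ScreenConfig = ScreenConfig()
) -> list[str]:
    """Top-k subjects per taxonomic group by bitscore.

    k is the upper bound of ``cfg.reps_per_group``; groups in
    ``cfg.unlimited_groups`` contribute every subject.  Multiple HSPs for one
    subject are collapsed to the best-scoring one.  Bitscore ties break
    lexicographically by subject id for determinism.
    """
    missing = sorted({h.subject_id for h in hits} - taxonomy.keys())
    if missing:
        raise KeyError(f"subjects without taxonomy entries: {missing}")
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.subject_id)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.subject_id] = h
    by_group: dict[str, list[Hit]] = {}
    for h in best.values():
        by_group.setdefault(taxonomy[h.subject_id], []).append(h)
    k = cfg.reps_per_group[1]
    selected: list[str] = []
    for group in sorted(by_group):
        members = sorted(by_group[group], key=lambda h: (-h.bitscore, h.subject_id))
        if group not in cfg.unlimited_groups:
            members = members[:k]
        selected.extend(h.subject_id for h in members)
    return selected


def read_taxonomy_tsv(path) -> dict[str, str]:
    """Two-column TSV: sequence id <TAB> taxon group."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {lineno}: expected id<TAB>group")
            out[row[0]] = row[1]
    return out
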