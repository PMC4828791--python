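"""Post-transfer amelioration tests: %GC placement and codon-usage adaptation.

A horizontally acquired gene is expected to drift ("ameliorate") toward its
recipient genome's base composition and codon usage.  Two read-outs:

* %GC of the transferred coding sequence placed against empirical recipient
  and donor %GC distributions with two-tailed 95 % confidence intervals
  (2.5th/97.5th percentiles);
* codon adaptation index (CAI, the geometric mean of within-synonymous-family
  relative adaptiveness w) against an expected CAI (E-CAI) computed from a
  null of uniform synonymous-codon choice for the same protein.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

_BASES = set("ACGT")

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
ALL_CODONS = tuple(sorted(CODON_TO_AA) + sorted(STOP_CODONS))
SYN_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _a in CODON_TO_AA.items():
    SYN_FAMILIES.setdefault(_a, ())
for _a in SYN_FAMILIES:
    SYN_FAMILIES[_a] = tuple(sorted(c for c, a in CODON_TO_AA.items() if a == _a))

# single-codon families carry no usage information for CAI
UNINFORMATIVE_CODONS = frozenset(
    c for fam in SYN_FAMILIES.values() if len(fam) == 1 for c in fam
) | STOP_CODONS


@dataclass(frozen=True)
class CodingSequence:
    id: str
    nt: str

    def __post_init__(self):
        object.__setattr__(self, "nt", self.nt.upper().replace("U", "T"))

    def codons(self) -> list[str]:
        if len(self.nt) % 3 != 0:
            raise ValueError(f"{self.id}: length {len(self.nt)} not divisible by 3")
        return [self.nt[i : i + 3] for i in range(0, len(self.nt), 3)]

    def translate(self) -> str:
        return str(Seq(self.nt).translate())


def gc_content(cds: CodingSequence | str) -> float:
    """100 * (G+C)/(G+C+A+T), ambiguity codes excluded from both terms."""
    nt = cds.nt if isinstance(cds, CodingSequence) else str(cds).upper().replace("U", "T")
    gc = sum(1 for b in nt if b in "GC")
    at = sum(1 for b in nt if b in "AT")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return 100.0 * gc / (gc + at)


@dataclass(frozen=True)
class GcDistribution:
    values: tuple
    lower: float
    upper: float
    n: int
    label: str = ""
    reliable: bool = True

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def build_gc_distribution(cds_set, label: str = "", min_n: int = 40) -> GcDistribution:
    """Empirical %GC distribution with two-tailed 95 % CI bounds.

    Bounds are the 2.5th/97.5th percentiles (linear interpolation).  With
    fewer than ``min_n`` sequences the bounds are flagged unreliable.
    """
    values = [gc_content(c) for c in cds_set]
    if not values:
        raise ValueError("empty cds set")
    lower, upper = np.percentile(values, [2.5, 97.5], method="linear")
    reliable = len(values) >= min_n
    if not reliable:
        warnings.warn(f"only {len(values)} cds in {label or 'distribution'}; CI unreliable")
    return GcDistribution(
        tuple(values), float(lower), float(upper), len(values), label, reliable
    )


RECIPIENT_LIKE = "recipient-like"
DONOR_LIKE = "donor-like"
AMBIGUOUS = "ambiguous"
NEITHER = "neither"


def classify_gc(
    value: float, recipient: GcDistribution, donor: GcDistribution
) -> str:
    """Place a %GC value against the recipient and donor 95 % CIs."""
    in_r, in_d = recipient.contains(value), donor.contains(value)
    if in_r and not in_d:
        return RECIPIENT_LIKE
    if in_d and not in_r:
        return DONOR_LIKE
    if in_r and in_d:
        return AMBIGUOUS
    return NEITHER


# ---------------------------------------------------------------------------
# codon usage and CAI


@dataclass(frozen=True)
class CodonUsageTable:
    counts: dict = field(default_factory=dict)  # codon -> count (64 keys)
    label: str = ""

    def __post_init__(self):
        counts = {c: 0.0 for c in ALL_CODONS}
        for c, v in self.counts.items():
            c = c.upper().replace("U", "T")
            if c not in counts:
                raise ValueError(f"not a codon: {c!r}")
            if v < 0:
                raise ValueError(f"negative count for {c}")
            counts[c] = float(v)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_cds_set(cls, cds_set, label: str = "") -> "CodonUsageTable":
        counts: dict[str, float] = {}
        for cds in cds_set:
            for codon in cds.codons():
                if set(codon) <= _BASES:
                    counts[codon] = counts.get(codon, 0.0) + 1.0
        return cls(counts, label)

    @classmethod
    def read_tsv(cls, path, label: str = "") -> "CodonUsageTable":
        counts = {}
        with open(path) as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected codon<TAB>count")
                counts[row[0]] = float(row[1])
        return cls(counts, label or str(path))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c in ALL_CODONS:
                fh.write(f"{c}\t{self.counts[c]:g}\n")


def relative_adaptiveness(table: CodonUsageTable) -> dict[str, float]:
    """w_c = count_c / max count within the synonymous family (0 -> 0.5 first)."""
    w: dict[str, float] = {}
    for fam in SYN_FAMILIES.values():
        counts = {c: (table.counts[c] if table.counts[c] > 0 else 0.5) for c in fam}
        mx = max(counts.values())
        for c in fam:
            w[c] = counts[c] / mx
    return w


def cai(cds: CodingSequence, w: dict[str, float]) -> float:
    """Geometric mean of w over informative codons (ATG/TGG/stops excluded)."""
    logs = [
        math.log(w[c])
        for c in cds.codons()
        if set(c) <= _BASES and c not in UNINFORMATIVE_CODONS
    ]
    if not logs:
        raise ValueError(f"{cds.id}: no informative codons for CAI")
    return math.exp(sum(logs) / len(logs))


def ecai(
    cds: CodingSequence,
    reference_usage: CodonUsageTable,
    n_random: int = 500,
    percentile: float = 95.0,
    seed: int = 0,
) -> float:
    """Expected CAI under a no-adaptation null.

    ``n_random`` sequences encoding the same protein are generated with codons
    drawn uniformly among synonyms; E-CAI is the given percentile of their CAI
    distribution against ``reference_usage``.
    """
    rng = np.random.default_rng(seed)
    protein = [CODON_TO_AA[c] for c in cds.codons() if c in CODON_TO_AA]
    informative = [a for a in protein if len(SYN_FAMILIES[a]) > 1]
    if not informative:
        raise ValueError(f"{cds.id}: protein has only single-codon families")
    w = relative_adaptiveness(reference_usage)
    logw = {a: np.log([w[c] for c in SYN_FAMILIES[a]]) for a in set(informative)}
    nulls = np.empty(n_random)
    for k in range(n_random):
        s = 0.0
        for a in informative:
            s += logw[a][rng.integers(len(logw[a]))]
        nulls[k] = math.exp(s / len(informative))
    if n_random == 1:
        return float(nulls[0])
    return float(np.percentile(nulls, percentile, method="linear"))


@dataclass(frozen=True)
class CaiResult:
    cai: float
    ecai: float
    n_random: int
    reference: str = ""

    @property
    def verdict(self) -> str:
        return "adapted" if self.cai > self.ecai else "not-adapted"


def codon_adaptation_test(
    cds: CodingSequence,
    recipient_usage: CodonUsageTable,
    donor_usage: CodonUsageTable,
    n_random: int = 500,
    percentile: float = 95.0,
    seed: int = 0,
) -> tuple[CaiResult, CaiResult]:
    """CAI vs E-CAI against the recipient and the donor usage tables."""
    out = []
    for table, which in ((recipient_usage, "recipient"), (donor_usage, "donor")):
        w = relative_adaptiveness(table)
        out.append(
            CaiResult(
                cai=cai(cds, w),
                ecai=ecai(cds, table, n_random, percentile, seed),
                n_random=n_random,
                reference=table.label or which,
            )
        )
    return tuple(out)
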