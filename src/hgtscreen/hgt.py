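"""Constrained-monophyly model-selection test for horizontal gene transfer.

The unconstrained ML tree plays the role of the HGT-compatible model; each
vertical-descent alternative forces taxa into monophyletic groups per their
taxonomic classification and is refitted from scratch.  BIC/AICc differences
of 5 or more against every vertical alternative count as very strong evidence
for the transfer scenario.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .alignment import Alignment
from .likelihood import LikelihoodEngine
from .search import ConstraintSet, SearchConfig, constrained_search, nj_start_tree, nni_search
from .selection import (
    EVIDENCE_THRESHOLD,
    ModelComparison,
    ModelFit,
    compare_topologies,
    select_best_model,
)
from .substmodels import SubstitutionModel


@dataclass(frozen=True)
class TaxonomyMap:
    """Sequence id -> ordered lineage labels (broadest first)."""

    lineages: dict = field(default_factory=dict)  # id -> tuple[str, ...]

    def __post_init__(self):
        lin = {}
        for k, v in self.lineages.items():
            labels = tuple(v) if not isinstance(v, str) else (v,)
            if not labels:
                raise ValueError(f"empty lineage for {k!r}")
            lin[k] = labels
        object.__setattr__(self, "lineages", lin)

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyMap":
        """TSV: id <TAB> label [<TAB> label ...]."""
        lin = {}
        with open(path) as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected id<TAB>label")
                lin[row[0]] = tuple(x for x in row[1:] if x)
        return cls(lin)

    def ids_with_label(self, label: str) -> frozenset:
        return frozenset(i for i, lin in self.lineages.items() if label in lin)

    def check_covers(self, ids) -> None:
        missing = sorted(set(ids) - self.lineages.keys())
        if missing:
            raise ValueError(f"taxa without taxonomy entries: {missing}")


def build_constraints(taxmap: TaxonomyMap, spec: list) -> list[ConstraintSet]:
    """One ConstraintSet per spec entry.

    Each entry is either a label string, an ``"A + B"`` merge expression, or an
    iterable of labels; the entry's labels are merged into a single required
    monophyletic group (e.g. ``"Euk + Arch"`` forces all eukaryote and archaeon
    sequences together).
    """
    out = []
    for entry in spec:
        if isinstance(entry, str):
            labels = [x.strip() for x in entry.split("+")]
            name = entry.strip()
        else:
            labels = list(entry)
            name = " + ".join(labels)
        members = frozenset()
        for lab in labels:
            ids = taxmap.ids_with_label(lab)
            if not ids:
                raise ValueError(f"constraint label {lab!r} matches no taxa")
            members |= ids
        if len(members) < 2:
            raise ValueError(f"constraint {name!r} resolves to fewer than 2 taxa")
        out.append(ConstraintSet(groups={name: members}, name=name))
    return out


def taxonomy_constraint(taxmap: TaxonomyMap, ids, name: str = "taxonomy") -> ConstraintSet:
    """One ConstraintSet forcing every top-level taxonomy label monophyletic."""
    groups: dict[str, set] = {}
    for i in ids:
        groups.setdefault(taxmap.lineages[i][0], set()).add(i)
    groups = {k: frozenset(v) for k, v in groups.items() if len(v) >= 2}
    return ConstraintSet(groups=groups, name=name)


def hgt_model_test(
    aln: Alignment,
    model: SubstitutionModel,
    constraint_sets: list[ConstraintSet],
    cfg: SearchConfig = SearchConfig(),
    threshold: float = EVIDENCE_THRESHOLD,
    candidates: list[SubstitutionModel] | None = None,
) -> ModelComparison:
    """Unconstrained search vs one constrained search per set.

    Free model parameters are refitted on every topology.  When ``candidates``
    is given, the full substitution-model family is re-selected (lowest BIC)
    independently per topology instead.  Deterministic for a fixed config.
    """
    if not constraint_sets:
        raise ValueError("need at least one constraint set")

    def fit_on(tree, label) -> ModelFit:
        if candidates is not None:
            fits = select_best_model(aln, tree, candidates, tol=cfg.tol)
            best = fits[0]
            return ModelFit(
                best.model, best.tree, best.lnL, best.K, best.n_sites,
                best.BIC, best.AICc, label=label,
            )
        eng = LikelihoodEngine(aln, model)
        t = tree.copy()
        fitted, lnl = eng.optimize_model(t, tol=cfg.tol)
        return ModelFit.from_fit(fitted, t, lnl, eng.n_sites, label=label)

    start = nj_start_tree(aln, model)
    un_tree, _ = nni_search(aln, model, start, cfg)
    reference = fit_on(un_tree, "Unconstrained")

    rows = []
    for cs in constraint_sets:
        c_tree, _ = constrained_search(aln, model, cs, cfg)
        rows.append(fit_on(c_tree, cs.name or "Constrained"))
    return compare_topologies(reference, rows, threshold)


def hgt_verdict(comparison: ModelComparison, threshold: float = EVIDENCE_THRESHOLD) -> str:
    """"HGT supported" when every vertical-descent row is very strongly worse."""
    if all(
        r.delta_bic >= threshold and r.delta_aicc >= threshold
        for r in comparison.rows
    ):
        return "HGT supported"
    return "HGT not supported"


def read_constraint_spec(path) -> list:
    """Parse a constraint file into hypothesis entries.

    Lines of the form ``name<TAB>id1,id2,...`` each define one monophyletic
    group; together they form a single ConstraintSet (one vertical-descent
    model with every listed group enforced at once).  A bare line is a label
    expression (e.g. ``"Euk + Arch"``) for :func:`build_constraints`; each
    such line is its own single-group alternative, mirroring a constrained
    ladder where every row is one hypothesis.
    """
    entries: list = []
    tab_groups: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" in line:
                name, ids = line.split("\t", 1)
                tab_groups[name] = frozenset(
                    x.strip() for x in ids.split(",") if x.strip()
                )
            else:
                entries.append(line.strip())
    if tab_groups:
        entries.insert(
            0, ConstraintSet(groups=tab_groups, name="vertical-descent")
        )
    return entries
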