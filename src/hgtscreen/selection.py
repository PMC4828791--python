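"""Model scoring and selection with BIC/AICc; constrained-vs-unconstrained tables.

Scores follow the standard penalised-likelihood forms with the number of
alignment columns as the sample size:

    BIC  = -2 lnL + K ln(n)
    AICc = -2 lnL + 2K + 2K(K+1) / (n - K - 1)

Lower is better.  A constrained (vertical-descent) topology whose BIC and
AICc both exceed the unconstrained optimum by at least the evidence threshold
(default 5) counts as very strong evidence for the unconstrained model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignment import Alignment
from .likelihood import LikelihoodEngine
from .substmodels import MODEL_NAMES, SubstitutionModel
from .tree import Tree

EVIDENCE_THRESHOLD = 5.0

VERDICT_VERY_STRONG = "very strong evidence for reference"
VERDICT_INDISTINGUISHABLE = "indistinguishable"
VERDICT_INCONCLUSIVE = "inconclusive"


def count_parameters(
    model: SubstitutionModel, n_taxa: int, count_frequencies: bool = False
) -> int:
    """K = branch lengths (2n - 3) + free rate parameters (+19 for counted +F)."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    k = 2 * n_taxa - 3
    if model.gamma_shape is not None:
        k += 1
    if model.p_inv is not None:
        k += 1
    if count_frequencies and model.frequencies is not None:
        k += 19
    return k


def information_criteria(lnL: float, K: int, n_sites: int) -> tuple[float, float]:
    bic = -2.0 * lnL + K * math.log(n_sites)
    if n_sites <= K + 1:
        raise ValueError(
            f"AICc undefined: n_sites ({n_sites}) must exceed K + 1 ({K + 1})"
        )
    aicc = -2.0 * lnL + 2.0 * K + 2.0 * K * (K + 1) / (n_sites - K - 1)
    return bic, aicc


@dataclass(frozen=True)
class ModelFit:
    model: SubstitutionModel
    tree: Tree
    lnL: float
    K: int
    n_sites: int
    BIC: float
    AICc: float
    label: str = ""

    @classmethod
    def from_fit(cls, model, tree, lnL, n_sites, label="", count_frequencies=False):
        K = count_parameters(model, len(tree.leaf_names()), count_frequencies)
        bic, aicc = information_criteria(lnL, K, n_sites)
        return cls(model, tree, lnL, K, n_sites, bic, aicc, label or model.label)


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    fit: ModelFit
    delta_bic: float
    delta_aicc: float
    verdict: str
    rank: int = 0


@dataclass(frozen=True)
class ModelComparison:
    reference: ModelFit
    rows: list[ComparisonRow]
    threshold: float = EVIDENCE_THRESHOLD

    def to_table(self) -> list[dict]:
        """Rank / Constraint / Sub. Model / K / dBIC / dAICc rows (reference first)."""
        out = [
            {
                "Rank": 1,
                "Constraint": self.reference.label or "Unconstrained",
                "Sub. Model": self.reference.model.label,
                "K": self.reference.K,
                "dBIC": 0.0,
                "dAICc": 0.0,
                "Verdict": "reference",
            }
        ]
        for r in self.rows:
            out.append(
                {
                    "Rank": r.rank,
                    "Constraint": r.label,
                    "Sub. Model": r.fit.model.label,
                    "K": r.fit.K,
                    "dBIC": r.delta_bic,
                    "dAICc": r.delta_aicc,
                    "Verdict": r.verdict,
                }
            )
        return out


def _verdict(d_bic: float, d_aicc: float, threshold: float) -> str:
    if d_bic >= threshold and d_aicc >= threshold:
        return VERDICT_VERY_STRONG
    if abs(d_bic) < 2.0 and abs(d_aicc) < 2.0:
        return VERDICT_INDISTINGUISHABLE
    return VERDICT_INCONCLUSIVE


def compare_topologies(
    reference: ModelFit,
    constrained: list[ModelFit],
    threshold: float = EVIDENCE_THRESHOLD,
) -> ModelComparison:
    """Delta scores (constrained - reference; positive = worse) ranked by BIC."""
    for fit in constrained:
        if fit.n_sites != reference.n_sites:
            raise ValueError(
                f"site-count mismatch: {fit.label} has n={fit.n_sites}, "
                f"reference has n={reference.n_sites}"
            )
    rows = [
        ComparisonRow(
            label=f.label,
            fit=f,
            delta_bic=f.BIC - reference.BIC,
            delta_aicc=f.AICc - reference.AICc,
            verdict=_verdict(f.BIC - reference.BIC, f.AICc - reference.AICc, threshold),
        )
        for f in constrained
    ]
    rows.sort(key=lambda r: (r.fit.BIC, r.fit.AICc, r.label))
    rows = [
        ComparisonRow(r.label, r.fit, r.delta_bic, r.delta_aicc, r.verdict, rank=i)
        for i, r in enumerate(rows, start=2)
    ]
    return ModelComparison(reference, rows, threshold)


def default_candidates() -> list[SubstitutionModel]:
    """The 5 x 4 grid {Poisson, Dayhoff, JTT, WAG, LG} x {-, +G, +I, +G+I}."""
    out = []
    for name in MODEL_NAMES:
        out.append(SubstitutionModel(name))
        out.append(SubstitutionModel(name, gamma_shape=1.0))
        out.append(SubstitutionModel(name, p_inv=0.1))
        out.append(SubstitutionModel(name, gamma_shape=1.0, p_inv=0.1))
    return out


def select_best_model(
    aln: Alignment,
    start_tree: Tree,
    candidates: list[SubstitutionModel] | None = None,
    tol: float = 1e-3,
    count_frequencies: bool = False,
) -> list[ModelFit]:
    """Fit every candidate on the same topology; rank ascending by BIC.

    Free parameters (branch lengths, alpha, p_inv) are optimised per
    candidate; initial values in the candidate specs are starting points.
    Candidates whose fit fails are dropped with a warning.
    """
    import warnings

    if candidates is None:
        candidates = default_candidates()
    if not candidates:
        raise ValueError("no candidate models supplied")
    fits: list[ModelFit] = []
    for cand in candidates:
        tree = start_tree.copy()
        try:
            eng = LikelihoodEngine(aln, cand)
            fitted, lnl = eng.optimize_model(tree, tol=tol)
            fits.append(
                ModelFit.from_fit(
                    fitted, tree, lnl, eng.n_sites, count_frequencies=count_frequencies
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-candidate isolation
            warnings.warn(f"candidate {cand.label} failed to fit: {exc}")
    fits.sort(key=lambda f: (f.BIC, f.AICc, f.label))
    return fits
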