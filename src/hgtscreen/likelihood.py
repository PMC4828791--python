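"""Felsenstein-pruning likelihood engine for protein alignments on trees.

The engine caches the model eigensystem and the alignment's compressed site
patterns, so repeated evaluations during branch-length, model-parameter and
topology optimisation are cheap.  Branch lengths are optimised coordinate-wise
with an outside/inside partial decomposition: for an edge (p, v) the site
likelihood factorises as

    L(t) = sum_ij O_i P_ij(t) D_j
         = sum_k (O @ left)_k exp(lambda_k * t * r) (D @ right^T)_k

so each 1-D objective evaluation costs O(patterns * states) per category.

Gaps and 'X' are treated as missing data (partial likelihood one in every
state).  Likelihood scaling is tracked per category and pattern in log space.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment
from .substmodels import AA_INDEX, N_STATES, SubstitutionModel, site_rates
from .tree import Tree

MAX_BRANCH_LENGTH = 20.0
_TINY = 1e-300


def _encode(aln: Alignment) -> np.ndarray:
    out = np.full((aln.n_sequences, aln.n_sites), -1, dtype=np.int8)
    for i, row in enumerate(aln.rows):
        for j, ch in enumerate(row):
            out[i, j] = AA_INDEX.get(ch, -1)
    return out


class LikelihoodEngine:
    """Bind an alignment and a substitution model for repeated evaluation."""

    def __init__(self, aln: Alignment, model: SubstitutionModel):
        data = _encode(aln)
        if (data == -1).all(axis=0).any():
            warnings.warn("dropping fully missing alignment columns")
            data = data[:, ~(data == -1).all(axis=0)]
            if data.shape[1] == 0:
                raise ValueError("alignment has no informative columns")
        self.taxa = list(aln.ids)
        self._taxon_row = {t: i for i, t in enumerate(self.taxa)}
        patterns, counts = np.unique(data, axis=1, return_counts=True)
        self.patterns = patterns  # (ntaxa, npat)
        self.weights = counts.astype(float)
        self.n_sites = int(counts.sum())
        self.n_patterns = patterns.shape[1]
        # per-taxon leaf partials (npat, 20)
        self._leaf = {}
        eye = np.eye(N_STATES)
        for t, i in self._taxon_row.items():
            col = patterns[i]
            part = np.ones((self.n_patterns, N_STATES))
            obs = col >= 0
            part[obs] = eye[col[obs]]
            self._leaf[t] = part
        self.set_model(model)

    # -- model binding -----------------------------------------------------

    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        cats = site_rates(model)
        self.rates = np.array([r for r, _ in cats])
        self.cat_weights = np.array([w for _, w in cats])
        self.n_cat = len(cats)
        self.eigvals, self.left, self.right = model.eigensystem()
        self.pi = model.pi

    def set_rate_params(
        self, gamma_shape: float | None, p_inv: float | None
    ) -> None:
        """Update +G/+I parameters without touching the eigensystem."""
        self.model = self.model.with_params(gamma_shape=gamma_shape, p_inv=p_inv)
        cats = site_rates(self.model)
        self.rates = np.array([r for r, _ in cats])
        self.cat_weights = np.array([w for _, w in cats])
        self.n_cat = len(cats)

    def _pmats(self, t: float) -> np.ndarray:
        """(ncat, 20, 20) transition matrices for one branch length."""
        e = np.exp(self.eigvals[None, :] * (t * self.rates)[:, None])
        P = np.einsum("ik,ck,kj->cij", self.left, e, self.right)
        # round-off in the eigen reconstruction can leave tiny negatives
        np.clip(P, 0.0, None, out=P)
        return P

    # -- pruning -----------------------------------------------------------

    def _check_tree(self, tree: Tree) -> None:
        t_leaves = set(tree.leaf_names())
        a_leaves = set(self.taxa)
        if t_leaves != a_leaves:
            diff = sorted(t_leaves.symmetric_difference(a_leaves))
            raise ValueError(f"tree/alignment id mismatch: {diff}")

    def _down(self, tree: Tree):
        """Post-order partials D[node] (ncat, npat, 20) and log-scales."""
        D: dict[int, np.ndarray] = {}
        logd: dict[int, np.ndarray] = {}
        for n in tree.postorder():
            if n.is_leaf:
                D[id(n)] = np.broadcast_to(
                    self._leaf[n.name], (self.n_cat, self.n_patterns, N_STATES)
                )
                logd[id(n)] = np.zeros((self.n_cat, self.n_patterns))
            else:
                part = np.ones((self.n_cat, self.n_patterns, N_STATES))
                ls = np.zeros((self.n_cat, self.n_patterns))
                for c in n.children:
                    P = self._pmats(c.length)
                    part = part * np.einsum("cpj,cij->cpi", D[id(c)], P)
                    ls = ls + logd[id(c)]
                scale = np.maximum(part.max(axis=2), _TINY)
                part = part / scale[:, :, None]
                D[id(n)] = part
                logd[id(n)] = ls + np.log(scale)
        return D, logd

    def log_likelihood(self, tree: Tree) -> float:
        self._check_tree(tree)
        D, logd = self._down(tree)
        root = tree.root
        site = np.maximum(
            np.einsum("cpj,j->cp", D[id(root)], self.pi), _TINY
        )
        logcat = (
            np.log(site)
            + logd[id(root)]
            + np.log(np.maximum(self.cat_weights, _TINY))[:, None]
        )
        m = logcat.max(axis=0)
        lnl_pat = m + np.log(np.exp(logcat - m[None, :]).sum(axis=0))
        return float((self.weights * lnl_pat).sum())

    # -- branch-length optimisation ----------------------------------------

    def _edge_lnl_fn(self, O, logo, Dv, logdv):
        """1-D objective for one edge given outside/inside partials."""
        Ot = np.einsum("cpi,ik->cpk", O, self.left)
        Dt = np.einsum("cpj,kj->cpk", Dv, self.right)
        base = (
            logo + logdv + np.log(np.maximum(self.cat_weights, _TINY))[:, None]
        )  # (ncat, npat)
        shift = base.max(axis=0)
        coef = np.exp(base - shift[None, :])
        lam = self.eigvals

        def lnl(t: float) -> float:
            e = np.exp(lam[None, :] * (t * self.rates)[:, None])  # (ncat, 20)
            core = np.einsum("cpk,ck->cp", Ot * Dt, e)
            tot = np.maximum((coef * core).sum(axis=0), _TINY)
            return float((self.weights * (shift + np.log(tot))).sum())

        return lnl

    def optimize_branch_lengths(
        self, tree: Tree, tol: float = 1e-4, max_sweeps: int = 50
    ) -> float:
        """Coordinate-wise branch-length optimisation in place; returns lnL."""
        self._check_tree(tree)
        prev = -np.inf
        lnl = self.log_likelihood(tree)
        sweeps = 0
        while lnl - prev > tol and sweeps < max_sweeps:
            prev = lnl
            self._branch_sweep(tree)
            lnl = self.log_likelihood(tree)
            sweeps += 1
        if sweeps == max_sweeps and lnl - prev > tol:
            warnings.warn("branch-length optimisation did not converge; best kept")
        return lnl

    def _branch_sweep(self, tree: Tree) -> None:
        D, logd = self._down(tree)
        U: dict[int, np.ndarray] = {}
        logu: dict[int, np.ndarray] = {}
        root = tree.root
        U[id(root)] = np.broadcast_to(
            self.pi, (self.n_cat, self.n_patterns, N_STATES)
        )
        logu[id(root)] = np.zeros((self.n_cat, self.n_patterns))
        for p in tree.preorder():
            if p.is_leaf:
                continue
            kids = p.children
            M = {}
            for c in kids:
                P = self._pmats(c.length)
                M[id(c)] = np.einsum("cpj,cij->cpi", D[id(c)], P)
            for v in kids:
                O = U[id(p)].copy()
                logo = logu[id(p)].copy()
                for c in kids:
                    if c is v:
                        continue
                    O = O * M[id(c)]
                    logo = logo + logd[id(c)]
                f = self._edge_lnl_fn(O, logo, D[id(v)], logd[id(v)])
                res = minimize_scalar(
                    lambda t: -f(t),
                    bounds=(0.0, MAX_BRANCH_LENGTH),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                if -res.fun >= f(v.length):
                    v.length = float(res.x)
                    # keep sibling products consistent with the new length
                    P = self._pmats(v.length)
                    M[id(v)] = np.einsum("cpj,cij->cpi", D[id(v)], P)
                if not v.is_leaf:
                    Pv = self._pmats(v.length)
                    Uv = np.einsum("cpi,cij->cpj", O, Pv)
                    scale = np.maximum(Uv.max(axis=2), _TINY)
                    U[id(v)] = Uv / scale[:, :, None]
                    logu[id(v)] = logo + np.log(scale)

    # -- model-parameter optimisation --------------------------------------

    def optimize_model(
        self,
        tree: Tree,
        tol: float = 1e-4,
        max_rounds: int = 5,
        optimize_branches: bool = True,
    ) -> tuple[SubstitutionModel, float]:
        """Jointly fit free +G/+I parameters (and branch lengths) on a topology.

        Shape alpha is bounded to [0.02, 100] (searched in log space) and
        p_inv to [0, 0.99].  Alternates parameter moves with branch sweeps.
        """
        free_gamma = self.model.gamma_shape is not None
        free_pinv = self.model.p_inv is not None
        if not (free_gamma or free_pinv) and not optimize_branches:
            return self.model, self.log_likelihood(tree)
        lnl = (
            self.optimize_branch_lengths(tree, tol=tol)
            if optimize_branches
            else self.log_likelihood(tree)
        )
        if not (free_gamma or free_pinv):
            return self.model, lnl
        for _ in range(max_rounds):
            prev = lnl
            x0, lo, hi = [], [], []
            if free_gamma:
                x0.append(np.log(self.model.gamma_shape))
                lo.append(np.log(0.02))
                hi.append(np.log(100.0))
            if free_pinv:
                x0.append(self.model.p_inv)
                lo.append(0.0)
                hi.append(0.99)

            def neg(x):
                i = 0
                a = np.exp(x[i]) if free_gamma else None
                i += int(free_gamma)
                p = float(np.clip(x[i], 0.0, 0.99)) if free_pinv else None
                self.set_rate_params(a, p)
                return -self.log_likelihood(tree)

            res = minimize(
                neg,
                np.array(x0),
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": 40, "ftol": 1e-9},
            )
            neg(res.x)  # leave engine at the optimum
            lnl = -float(res.fun)
            if optimize_branches:
                lnl = self.optimize_branch_lengths(tree, tol=tol)
            if lnl - prev <= tol:
                break
        return self.model, lnl


# ---------------------------------------------------------------------------
# functional wrappers


def log_likelihood(aln: Alignment, tree: Tree, model: SubstitutionModel) -> float:
    return LikelihoodEngine(aln, model).log_likelihood(tree)


def optimize_branch_lengths(
    aln: Alignment, tree: Tree, model: SubstitutionModel, tol: float = 1e-4
) -> tuple[Tree, float]:
    t = tree.copy()
    lnl = LikelihoodEngine(aln, model).optimize_branch_lengths(t, tol=tol)
    return t, lnl


def optimize_model(
    aln: Alignment, tree: Tree, model: SubstitutionModel, tol: float = 1e-4
) -> tuple[SubstitutionModel, float]:
    t = tree.copy()
    eng = LikelihoodEngine(aln, model)
    return eng.optimize_model(t, tol=tol)
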