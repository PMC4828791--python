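"""Amino-acid substitution models with rate heterogeneity.

Empirical reversible models (Dayhoff, JTT, WAG, LG) are defined by a symmetric
exchangeability matrix ``S`` and equilibrium frequencies ``pi``.  The
instantaneous rate matrix is ``Q_ij = S_ij * pi_j`` (i != j), with the diagonal
set so rows sum to zero, rescaled so the expected number of substitutions per
site per unit branch length at equilibrium is one.  Among-site rate variation
is modelled by a discrete gamma mixture (category means of a mean-1 gamma) and
an optional invariant-sites class of rate zero.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_STATES = 20

EMPIRICAL_MODELS = ("Dayhoff", "JTT", "WAG", "LG")
MODEL_NAMES = ("Poisson",) + EMPIRICAL_MODELS

# md5 of the embedded PAML-format matrix files; guards against silent corruption
_MATRIX_CHECKSUMS = {
    "dayhoff": "74b254e820fbbfa8cecbe8ac4e98360c",
    "jtt": "411dc1660d66883bcc90488bc67a8efe",
    "lg": "dc4613ca2111c4ac1107417aaaa4a961",
    "wag": "424df387a5b7229ce07c1b1e204f051c",
}


import functools


@functools.lru_cache(maxsize=None)
def _load_paml_matrix(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-layout .dat file: 19 lower-triangle rows then frequencies."""
    import hashlib

    raw = (
        importlib.resources.files("hgtscreen.data")
        .joinpath(f"{name.lower()}.dat")
        .read_bytes()
    )
    digest = hashlib.md5(raw).hexdigest()
    if digest != _MATRIX_CHECKSUMS[name.lower()]:
        raise ValueError(f"{name}.dat is corrupted (md5 {digest})")
    text = raw.decode()
    rows = [ln.split() for ln in text.splitlines() if ln.strip()]
    tri, freqs = rows[:19], np.array(rows[19], dtype=float)
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(tri, start=1):
        vals = np.array(row, dtype=float)
        S[i, : len(vals)] = vals
    S = S + S.T
    if freqs.shape != (N_STATES,):
        raise ValueError(f"bad frequency row in {name}.dat")
    return S, freqs / freqs.sum()


@dataclass(frozen=True)
class SubstitutionModel:
    """An amino-acid model, optionally with +G (gamma) and +I (invariant) terms.

    Parameters
    ----------
    name : str
        One of Poisson, Dayhoff, JTT, WAG, LG.
    gamma_shape : float or None
        Shape ``alpha`` of the mean-1 gamma over site rates; None disables +G.
    p_inv : float or None
        Proportion of invariant sites in [0, 1); None disables +I.
    n_categories : int
        Number of discrete gamma categories (ignored without +G).
    frequencies : ndarray or None
        Override frequencies (e.g. empirical +F); defaults to the model's own.
    """

    name: str = "LG"
    gamma_shape: float | None = None
    p_inv: float | None = None
    n_categories: int = 5
    frequencies: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")
        if self.gamma_shape is not None and not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be positive")
        if self.p_inv is not None and not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if self.frequencies is not None:
            f = np.asarray(self.frequencies, dtype=float)
            if f.shape != (N_STATES,) or abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
                raise ValueError("frequencies must be 20 non-negative reals summing to 1")
            object.__setattr__(self, "frequencies", f)

    # -- structure ---------------------------------------------------------

    @property
    def label(self) -> str:
        lab = self.name
        if self.gamma_shape is not None:
            lab += " + G"
        if self.p_inv is not None:
            lab += " + I"
        return lab

    @property
    def exchangeabilities(self) -> np.ndarray:
        if self.name == "Poisson":
            S = np.ones((N_STATES, N_STATES))
            np.fill_diagonal(S, 0.0)
            return S
        return _load_paml_matrix(self.name)[0]

    @property
    def pi(self) -> np.ndarray:
        if self.frequencies is not None:
            return self.frequencies
        if self.name == "Poisson":
            return np.full(N_STATES, 1.0 / N_STATES)
        return _load_paml_matrix(self.name)[1]

    def with_params(self, **kw) -> "SubstitutionModel":
        return replace(self, **kw)

    def rate_matrix(self) -> np.ndarray:
        """Normalised reversible Q with one expected substitution/site."""
        pi = self.pi
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the pi-symmetrised form.

        Returns (eigenvalues, left, right) with P(t) = left @ diag(exp(l*t)) @ right.
        """
        pi = self.pi
        sq = np.sqrt(np.maximum(pi, 1e-300))
        B = self.rate_matrix() * (sq[:, None] / sq[None, :])
        B = 0.5 * (B + B.T)  # symmetric up to round-off
        w, V = np.linalg.eigh(B)
        left = V / sq[:, None]
        right = V.T * sq[None, :]
        return w, left, right


def site_rates(model: SubstitutionModel) -> list[tuple[float, float]]:
    """Rate-mixture categories ``(rate, weight)`` with overall mean rate 1.

    Discrete gamma uses equal-probability categories whose rates are the
    in-category means of a mean-1 gamma(alpha, alpha).  A +I class of rate 0
    and weight p_inv is prepended; the variable-class rates are rescaled by
    1/(1 - p_inv) so the mixture mean stays 1.
    """
    if model.gamma_shape is None:
        cats = [(1.0, 1.0)]
    else:
        a = model.gamma_shape
        k = model.n_categories
        if k == 1:
            cats = [(1.0, 1.0)]
        else:
            # quantile boundaries of gamma(a, scale=1/a), then bin means via the
            # incomplete-gamma identity  E[X; X<q] = F(q; a+1) for rate a.
            bounds = _gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
            upper = gammainc(a + 1.0, a * bounds)
            cum = np.concatenate([[0.0], upper, [1.0]])
            rates = k * np.diff(cum)
            rates = rates / (rates.mean())  # exact mean-1 in floating point
            cats = [(float(r), 1.0 / k) for r in rates]
    if model.p_inv is not None:
        p = model.p_inv
        if p >= 1.0:
            raise ValueError("p_inv = 1 leaves no variable sites")
        cats = [(0.0, p)] + [(r / (1.0 - p), w * (1.0 - p)) for r, w in cats]
    return cats


def transition_matrix(
    model: SubstitutionModel, branch_length: float, rate: float = 1.0
) -> np.ndarray:
    """P(t*r) = exp(Q * t * r); rows sum to one."""
    if not (np.isfinite(branch_length) and np.isfinite(rate)):
        raise ValueError("branch length and rate must be finite")
    if branch_length < 0 or rate < 0:
        raise ValueError("branch length and rate must be non-negative")
    w, left, right = model.eigensystem()
    P = (left * np.exp(w * branch_length * rate)[None, :]) @ right
    np.clip(P, 0.0, None, out=P)
    return P / P.sum(axis=1, keepdims=True)


def parse_model_spec(spec: str) -> SubstitutionModel:
    """Parse labels like ``"LG+G"``, ``"WAG + G + I"`` into a model.

    +G and +I flags start from alpha = 1.0 and p_inv = 0.1; both are refitted
    wherever the model is optimised.
    """
    parts = [p.strip() for p in spec.replace(" ", "").split("+") if p.strip()]
    if not parts:
        raise ValueError("empty model spec")
    name, flags = parts[0], {f.upper() for f in parts[1:]}
    if "F" in flags:
        raise ValueError(
            "+F needs observed frequencies; build the model with "
            "frequencies=empirical_frequencies(alignment.rows) instead"
        )
    unknown = flags - {"G", "I"}
    if unknown:
        raise ValueError(f"unknown model flags: {sorted(unknown)}")
    return SubstitutionModel(
        name,
        gamma_shape=1.0 if "G" in flags else None,
        p_inv=0.1 if "I" in flags else None,
    )


def empirical_frequencies(rows: list[str], pseudocount: float = 0.0) -> np.ndarray:
    """Observed amino-acid frequencies of an alignment (+F); gaps/X ignored."""
    counts = np.full(N_STATES, pseudocount, dtype=float)
    for row in rows:
        for ch in row:
            i = AA_INDEX.get(ch.upper())
            if i is not None:
                counts[i] += 1.0
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous residues")
    return counts / counts.sum()
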