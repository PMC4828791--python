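"""ML tree search: NJ starting trees, NNI hill-climbing, bootstrap, constraints.

The search is deliberately desk-scale: a neighbor-joining start on
Poisson-corrected distances, then nearest-neighbor-interchange hill-climbing
in which each candidate swap is scored by re-optimising only the central edge
against cached outside/inside partials, and accepted moves trigger a full
branch-length re-optimisation.  An exhaustive enumerator over all unrooted
topologies (feasible to ~7 taxa) serves as the correctness oracle and as the
engine for small constrained searches.

Constrained searches force named taxon groups to stay monophyletic: the start
tree is assembled from per-group NJ subtrees joined by NJ on group-level
average distances, and NNI moves that would break any group are rejected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .likelihood import MAX_BRANCH_LENGTH, LikelihoodEngine
from .substmodels import SubstitutionModel
from .tree import Node, Tree, _canon, neighbor_joining, poisson_distance_matrix


@dataclass(frozen=True)
class SearchConfig:
    n_bootstrap: int = 100
    seed: int = 0
    max_nni_rounds: int = 20
    tol: float = 1e-4

    def __post_init__(self):
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass(frozen=True)
class ConstraintSet:
    """Named, pairwise-disjoint taxon groups that must each be monophyletic."""

    groups: dict = field(default_factory=dict)  # name -> frozenset of taxon ids
    name: str = ""

    def __post_init__(self):
        groups = {k: frozenset(v) for k, v in self.groups.items()}
        for (a, ga), (b, gb) in itertools.combinations(groups.items(), 2):
            if ga & gb:
                raise ValueError(f"constraint groups {a!r} and {b!r} overlap")
        object.__setattr__(self, "groups", groups)

    def validate_against(self, taxa) -> None:
        taxa = set(taxa)
        for name, g in self.groups.items():
            unknown = g - taxa
            if unknown:
                raise ValueError(f"group {name!r} names unknown taxa: {sorted(unknown)}")

    def satisfied_by(self, tree: Tree) -> bool:
        return all(tree.is_monophyletic(g) for g in self.groups.values())


def is_monophyletic(tree: Tree, group) -> bool:
    return tree.is_monophyletic(group)


def nj_start_tree(aln: Alignment, model: SubstitutionModel | None = None) -> Tree:
    """Neighbor joining on Poisson-corrected pairwise distances."""
    if aln.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    D = poisson_distance_matrix(aln.ids, aln.rows)
    return neighbor_joining(aln.ids, D)


def _leafset(node: Node) -> frozenset:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.name)
        else:
            stack.extend(n.children)
    return frozenset(out)


def _groups_ok(splits: set, groups, all_leaves: frozenset) -> bool:
    for g in groups:
        if len(g) <= 1 or len(all_leaves - g) <= 1:
            continue
        if _canon(g, all_leaves) not in splits:
            return False
    return True


def nni_search(
    aln: Alignment,
    model: SubstitutionModel,
    start: Tree,
    cfg: SearchConfig = SearchConfig(),
    constraints: ConstraintSet | None = None,
    engine: LikelihoodEngine | None = None,
) -> tuple[Tree, float]:
    """Hill-climb over NNI moves from ``start``; returns (tree, lnL).

    With ``constraints``, only moves preserving every group's monophyly are
    considered (the start tree must already satisfy them).
    """
    eng = engine if engine is not None else LikelihoodEngine(aln, model)
    tree = start.copy()
    if constraints is not None:
        constraints.validate_against(tree.leaf_names())
        if not constraints.satisfied_by(tree):
            raise ValueError("start tree violates the constraint set")
    all_leaves = frozenset(tree.leaf_names())
    groups = list(constraints.groups.values()) if constraints else []
    lnl = eng.optimize_branch_lengths(tree, tol=cfg.tol)
    moves = 0
    while moves < cfg.max_nni_rounds * max(1, len(tree.internal_edges())):
        improved = _nni_pass(tree, eng, lnl, groups, all_leaves)
        if improved is None:
            break
        lnl = eng.optimize_branch_lengths(tree, tol=cfg.tol)
        moves += 1
    return tree, lnl


def _nni_pass(tree, eng, lnl, groups, all_leaves):
    """Scan internal edges; apply the first strictly improving NNI (or None)."""
    examined: set = set()
    while True:
        target = None
        for v in tree.internal_edges():
            s = _canon(_leafset(v), all_leaves)
            if s not in examined:
                target = v
                break
        if target is None:
            return None
        v = target
        examined.add(_canon(_leafset(v), all_leaves))
        p = v.parent
        tree.reroot_at(p)
        if len(tree.root.children) != 3 or len(v.children) != 2:
            continue
        A, B = [c for c in tree.root.children if c is not v]
        C, Dn = v.children
        D, logd = eng._down(tree)
        pi_part = np.broadcast_to(eng.pi, (eng.n_cat, eng.n_patterns, len(eng.pi)))
        zero = np.zeros((eng.n_cat, eng.n_patterns))

        def m_of(node):
            P = eng._pmats(node.length)
            return np.einsum("cpj,cij->cpi", D[id(node)], P)

        M = {id(n): m_of(n) for n in (A, B, C, Dn)}
        if groups:
            splits = tree.bipartitions()
            old = _canon(_leafset(v), all_leaves)
        for inner, outer_pair in (((Dn, B), (A, C)), ((C, B), (A, Dn))):
            # candidate: v subtends `inner`; root keeps `outer_pair`
            if groups:
                newside = _leafset(inner[0]) | _leafset(inner[1])
                cand_splits = (splits - {old}) | {_canon(newside, all_leaves)}
                if not _groups_ok(cand_splits, groups, all_leaves):
                    continue
            Dv = M[id(inner[0])] * M[id(inner[1])]
            scale = np.maximum(Dv.max(axis=2), 1e-300)
            Dv = Dv / scale[:, :, None]
            logdv = logd[id(inner[0])] + logd[id(inner[1])] + np.log(scale)
            O = pi_part * M[id(outer_pair[0])] * M[id(outer_pair[1])]
            logo = zero + logd[id(outer_pair[0])] + logd[id(outer_pair[1])]
            f = eng._edge_lnl_fn(O, logo, Dv, logdv)
            from scipy.optimize import minimize_scalar

            res = minimize_scalar(
                lambda t: -f(t),
                bounds=(0.0, MAX_BRANCH_LENGTH),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > lnl + 1e-7:
                swap_out = C if inner[0] is Dn else Dn  # leaves v
                tree.root.children[tree.root.children.index(B)] = swap_out
                swap_out.parent = tree.root
                v.children[v.children.index(swap_out)] = B
                B.parent = v
                v.length = float(res.x)
                return True


def exhaustive_topologies(taxa: list[str]):
    """Yield every unrooted binary topology over ``taxa`` (3 <= n <= ~7)."""
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def build(current: Tree, remaining: list[str]):
        if not remaining:
            yield current.copy()
            return
        name = remaining[0]
        edges = [n for n in current.postorder() if n.parent is not None]
        for edge_child in edges:
            parent = edge_child.parent
            mid = Node(length=edge_child.length / 2)
            leaf = Node(name=name, length=0.1)
            parent.children[parent.children.index(edge_child)] = mid
            mid.parent = parent
            edge_child.length /= 2
            mid.add(edge_child)
            mid.add(leaf)
            yield from build(current, remaining[1:])
            # undo
            edge_child.length *= 2
            edge_child.parent = parent
            parent.children[parent.children.index(mid)] = edge_child

    root = Node()
    for t in taxa[:3]:
        root.add(Node(name=t, length=0.1))
    yield from build(Tree(root), taxa[3:])


def exhaustive_search(
    aln: Alignment,
    model: SubstitutionModel,
    constraints: ConstraintSet | None = None,
    tol: float = 1e-3,
    engine: LikelihoodEngine | None = None,
) -> tuple[Tree, float]:
    """Optimise branch lengths on every topology; return the best.

    Intended as the small-instance oracle (and constrained-search reference);
    the topology count is (2n-5)!! so keep n <= 7.
    """
    eng = engine if engine is not None else LikelihoodEngine(aln, model)
    best: tuple[Tree, float] | None = None
    for topo in exhaustive_topologies(aln.ids):
        if constraints is not None and not constraints.satisfied_by(topo):
            continue
        lnl = eng.optimize_branch_lengths(topo, tol=tol)
        if best is None or lnl > best[1]:
            best = (topo, lnl)
    if best is None:
        raise ValueError("no topology satisfies the constraints")
    return best


def _constrained_start_tree(aln: Alignment, constraints: ConstraintSet) -> Tree:
    """NJ within groups + NJ over group 'supertaxa', grafted together.

    When the plain NJ tree on all taxa already satisfies the constraints it is
    used directly (its within-group rootings are data-driven); otherwise each
    group subtree is built separately and attached to the group-level NJ
    backbone.
    """
    full = nj_start_tree(aln)
    if constraints.satisfied_by(full):
        return full
    D = poisson_distance_matrix(aln.ids, aln.rows)
    idx = {t: i for i, t in enumerate(aln.ids)}
    units: dict[str, list[str]] = {}
    grouped = set()
    for name, g in constraints.groups.items():
        units[name] = sorted(g)
        grouped |= g
    for t in aln.ids:
        if t not in grouped:
            units[f"__taxon__{t}"] = [t]
    unit_names = sorted(units)
    nU = len(unit_names)
    UD = np.zeros((nU, nU))
    for a, b in itertools.combinations(range(nU), 2):
        pairs = [
            D[idx[x], idx[y]] for x in units[unit_names[a]] for y in units[unit_names[b]]
        ]
        UD[a, b] = UD[b, a] = float(np.mean(pairs))
    if nU < 3:
        # two units: join their subtrees directly at the root
        root = Node()
        for name in unit_names:
            root.add(_group_subtree(units[name], D, idx, stem=UD.max() / 2 or 0.1))
        return Tree(root)
    backbone = neighbor_joining(unit_names, UD)
    for leaf in backbone.leaves():
        members = units[leaf.name]
        if len(members) == 1:
            leaf.name = members[0]
        else:
            sub = _group_subtree(members, D, idx, stem=leaf.length)
            parent = leaf.parent
            parent.children[parent.children.index(leaf)] = sub
            sub.parent = parent
    return backbone


def _group_subtree(members: list[str], D, idx, stem: float) -> Node:
    """A rooted binary subtree over ``members`` with stem length ``stem``."""
    if len(members) == 1:
        return Node(name=members[0], length=stem)
    if len(members) == 2:
        d = D[idx[members[0]], idx[members[1]]]
        top = Node(length=stem)
        top.add(Node(name=members[0], length=d / 2))
        top.add(Node(name=members[1], length=d / 2))
        return top
    sub = neighbor_joining(members, D[np.ix_([idx[m] for m in members], [idx[m] for m in members])])
    r = sub.root  # degree 3: root arbitrarily by pairing the last two children
    a = r.children.pop()
    b = r.children.pop()
    mid = Node(length=0.05)
    mid.add(a)
    mid.add(b)
    r.children.append(mid)
    mid.parent = r
    r.length = stem
    return r


def constrained_search(
    aln: Alignment,
    model: SubstitutionModel,
    constraints: ConstraintSet,
    cfg: SearchConfig = SearchConfig(),
    engine: LikelihoodEngine | None = None,
) -> tuple[Tree, float]:
    """Best tree subject to every group being monophyletic."""
    constraints.validate_against(aln.ids)
    start = _constrained_start_tree(aln, constraints)
    if not constraints.satisfied_by(start):  # pragma: no cover - construction bug guard
        raise RuntimeError("constrained start tree violates constraints")
    tree, lnl = nni_search(aln, model, start, cfg, constraints=constraints, engine=engine)
    if not constraints.satisfied_by(tree):  # pragma: no cover
        raise RuntimeError("constrained search produced a violating tree")
    return tree, lnl


def bootstrap_support(
    aln: Alignment,
    model: SubstitutionModel,
    cfg: SearchConfig,
    best_tree: Tree | None = None,
) -> Tree:
    """Felsenstein bootstrap: column resampling, full search per replicate.

    Support for each internal split of the best ML tree is the percentage of
    replicate ML trees containing that split, rounded to an integer and
    annotated on the corresponding node of the returned tree.
    """
    rng = np.random.default_rng(cfg.seed)
    if best_tree is None:
        start = nj_start_tree(aln, model)
        best_tree, _ = nni_search(aln, model, start, cfg)
    best = best_tree.copy()
    all_leaves = frozenset(best.leaf_names())
    counts: dict[frozenset, int] = {s: 0 for s in best.bipartitions()}
    n = aln.n_sites
    for _ in range(cfg.n_bootstrap):
        cols = rng.integers(0, n, size=n)
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        rep = Alignment(aln.ids, rows)
        try:
            start = nj_start_tree(rep, model)
            rep_tree, _ = nni_search(rep, model, start, cfg)
        except Exception as exc:  # noqa: BLE001 - degenerate resamples
            warnings.warn(f"bootstrap replicate failed: {exc}")
            continue
        rep_splits = rep_tree.bipartitions()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for node in best.postorder():
        if not node.is_leaf and node.parent is not None:
            s = _canon(_leafset(node), all_leaves)
            if s in counts:
                node.support = int(round(100.0 * counts[s] / cfg.n_bootstrap))
    return best
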