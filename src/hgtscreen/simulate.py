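"""Synthetic benchmarks with known transfer history and codon-usage provenance.

Generates (i) Yule trees and protein alignments evolved along them under the
package's substitution models, (ii) a single horizontal transfer modelled as a
subtree-prune-regraft of the recipient into a distant donor clade, and
(iii) coding sequences whose codon usage interpolates between a recipient-like
(AT-rich) and donor-like (GC-rich) usage table with a mixing weight
``lambda`` (0 = fully recipient, 1 = fully donor), so both the %GC and CAI
amelioration signals emerge from one mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .composition import SYN_FAMILIES, CodingSequence, CodonUsageTable
from .hgt import TaxonomyMap, taxonomy_constraint
from .search import ConstraintSet
from .substmodels import AMINO_ACIDS, N_STATES, SubstitutionModel, site_rates
from .tree import Node, Tree

GROUP_LABELS = ("Nematoda", "Actinobacteria", "Fungi", "Proteobacteria")
GROUP_PREFIXES = ("Nem", "Act", "Fun", "Pro")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the benchmark scale used throughout the test-bed: 16 taxa
    in four clades, 300-site protein alignments under LG+G, a single transfer
    of one recipient taxon into a 4-taxon donor clade on a short stalk, and a
    mostly donor-like (lambda = 0.8, i.e. recently transferred) coding
    sequence.
    """

    n_taxa: int = 16
    n_sites: int = 300
    model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel("LG", gamma_shape=1.0)
    )
    birth_rate: float = 8.0
    hgt: bool = True
    donor_clade_size: int = 4
    transfer_stalk_length: float = 0.05
    backbone_length: float = 0.25
    seed: int = 0
    amelioration: float = 0.8  # lambda: 0 = recipient-like usage, 1 = donor-like

    def __post_init__(self):
        if self.n_taxa < 3 or (self.hgt and self.n_taxa < 6):
            raise ValueError("need n_taxa >= 3 (>= 6 with a transfer event)")
        if self.donor_clade_size < 2:
            raise ValueError("donor_clade_size must be >= 2")
        if not (0.0 <= self.amelioration <= 1.0):
            raise ValueError("amelioration (lambda) must be in [0, 1]")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")


def simulate_tree(cfg: SimConfig) -> Tree:
    """Pure-birth (Yule) tree with ``n_taxa`` tips.

    Waiting times between speciations are exponential with rate
    ``k * birth_rate`` at k lineages; branch lengths are in expected
    substitutions/site.  The stem epoch precedes the root split and carries
    no edge, so the mean root-to-tip path is (H(n) - 1)/birth_rate with H(n)
    the n-th harmonic number.
    """
    rng = np.random.default_rng(cfg.seed)
    return _yule(rng, cfg.n_taxa, cfg.birth_rate)


def _yule(rng, n_taxa: int, rate: float, prefix: str = "t") -> Tree:
    root = Node()
    t = 0.0
    active: list[tuple[Node, float]] = [(root, 0.0)]
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * rate))
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.length = t - birth if node.parent is not None else 0.0
        left, right = Node(), Node()
        node.add(left)
        node.add(right)
        active.append((left, t))
        active.append((right, t))
    t += rng.exponential(1.0 / (n_taxa * rate))
    for node, birth in active:
        node.length = t - birth
    tree = Tree(root)
    width = max(2, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.name = f"{prefix}{i:0{width}d}"
    return tree


def inject_hgt(tree: Tree, recipient: str, donor_clade, stalk: float) -> Tree:
    """SPR the recipient leaf onto the donor clade's stem.

    The recipient is pruned and regrafted at the midpoint of the edge above
    the donor clade with pendant length ``stalk``, so afterwards
    donor_clade + recipient is monophyletic and the recipient's original
    group typically is not.
    """
    donor_clade = frozenset(donor_clade)
    if recipient in donor_clade:
        raise ValueError("recipient must not be part of the donor clade")
    t = tree.copy()
    leaf = next((n for n in t.postorder() if n.name == recipient), None)
    if leaf is None:
        raise ValueError(f"recipient {recipient!r} not in tree")
    donor = _find_clade(t, donor_clade)
    if donor is None or donor.parent is None:
        raise ValueError("donor clade is not a (non-root) monophyletic group")
    # prune
    parent = leaf.parent
    parent.children.remove(leaf)
    if len(parent.children) == 1:
        only = parent.children[0]
        if parent.parent is None:
            only.parent = None
            only.length = 0.0
            t.root = only
        else:
            only.length += parent.length
            only.parent = parent.parent
            parent.parent.children[parent.parent.children.index(parent)] = only
    # regraft on the donor stem
    dp = donor.parent
    mid = Node(length=donor.length / 2)
    donor.length /= 2
    dp.children[dp.children.index(donor)] = mid
    mid.parent = dp
    mid.add(donor)
    leaf.length = stalk
    leaf.parent = None
    mid.add(leaf)
    return t


def _find_clade(tree: Tree, group: frozenset) -> Node | None:
    for n in tree.postorder():
        if not n.is_leaf or len(group) == 1:
            leaves = frozenset(
                x.name for x in ([n] if n.is_leaf else Tree(n).leaves())
            )
            if leaves == group:
                return n
    return None


def evolve_alignment(
    tree: Tree, model: SubstitutionModel, n_sites: int, seed: int = 0
) -> Alignment:
    """Simulate a gapless protein alignment along ``tree`` under ``model``.

    The root sequence is drawn from the model frequencies; each site carries a
    rate category drawn from the model's site-rate mixture; substitutions per
    edge follow P(t * r).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    cats = site_rates(model)
    rates = np.array([r for r, _ in cats])
    weights = np.array([w for _, w in cats])
    site_cat = rng.choice(len(cats), size=n_sites, p=weights)
    w_eig, left, right = model.eigensystem()
    pi = model.pi

    def pmat(t: float, r: float) -> np.ndarray:
        P = (left * np.exp(w_eig * t * r)[None, :]) @ right
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[id(root)] = rng.choice(N_STATES, size=n_sites, p=pi)
    for node in tree.preorder():
        if node is root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(n_sites, dtype=np.int64)
        for c in range(len(cats)):
            in_cat = site_cat == c
            if not in_cat.any():
                continue
            P = pmat(node.length, rates[c])
            for s in np.unique(parent_states[in_cat]):
                sel = in_cat & (parent_states == s)
                child[sel] = rng.choice(N_STATES, size=int(sel.sum()), p=P[s])
        states[id(node)] = child
    leaves = tree.leaves()
    rows = ["".join(AMINO_ACIDS[s] for s in states[id(n)]) for n in leaves]
    return Alignment([n.name for n in leaves], rows)


# ---------------------------------------------------------------------------
# codon usage


def synthetic_usage_table(gc_bias: float, label: str = "") -> CodonUsageTable:
    """A usage table whose codon preference scales with G+C content.

    Each codon's count is ``100 * gc_bias ** (#G+C bases)``; gc_bias < 1 gives
    an AT-rich (recipient-like) table, > 1 a GC-rich (donor-like) one.
    """
    counts = {}
    for fam in SYN_FAMILIES.values():
        for c in fam:
            counts[c] = 100.0 * gc_bias ** sum(1 for b in c if b in "GC")
    return CodonUsageTable(counts, label)


RECIPIENT_USAGE = synthetic_usage_table(0.25, "recipient (AT-rich)")
DONOR_USAGE = synthetic_usage_table(4.0, "donor (GC-rich)")


def backtranslate_cds(
    protein: str,
    recipient_usage: CodonUsageTable,
    donor_usage: CodonUsageTable,
    lam: float,
    seed: int = 0,
    cds_id: str = "cds",
) -> CodingSequence:
    """Back-translate with codons drawn from the (1-lam)*recipient + lam*donor
    mixture of within-family normalised usage frequencies."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs_cache: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    out = []
    for aa in protein.upper():
        if aa not in SYN_FAMILIES:
            raise ValueError(f"no codons for residue {aa!r}")
        if aa not in probs_cache:
            fam = SYN_FAMILIES[aa]
            p = np.zeros(len(fam))
            for table, wgt in ((recipient_usage, 1.0 - lam), (donor_usage, lam)):
                c = np.array([table.counts[x] for x in fam])
                tot = c.sum()
                p += wgt * (c / tot if tot > 0 else np.full(len(fam), 1.0 / len(fam)))
            probs_cache[aa] = (fam, p / p.sum())
        fam, p = probs_cache[aa]
        out.append(fam[int(rng.choice(len(fam), p=p))])
    return CodingSequence(cds_id, "".join(out))


# ---------------------------------------------------------------------------
# full benchmark bundles


@dataclass(frozen=True)
class Benchmark:
    alignment: Alignment
    true_tree: Tree
    taxonomy: TaxonomyMap
    vertical_constraint: ConstraintSet
    focal_cds: CodingSequence
    recipient_cds: tuple
    donor_cds: tuple
    recipient_usage: CodonUsageTable
    donor_usage: CodonUsageTable
    truth: dict


def make_hgt_benchmark(cfg: SimConfig, n_background_cds: int = 100) -> Benchmark:
    """A fully labelled dataset: clade-structured tree, optional transfer,
    alignment, taxonomy, vertical-descent constraint, and coding sequences.

    Four clades are simulated as independent Yule subtrees joined on a fixed
    backbone; the donor clade has exactly ``donor_clade_size`` tips and the
    recipient is the first tip of the first clade.  With ``cfg.hgt`` the
    recipient is regrafted into the donor clade before sequences evolve, while
    its taxonomy label stays with its original clade — the signature the
    constrained test must detect.
    """
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=16)
    sizes = _group_sizes(cfg.n_taxa, cfg.donor_clade_size)
    subtrees = []
    for gi, size in enumerate(sizes):
        if size == 1:
            n = Node(name=f"{GROUP_PREFIXES[gi]}01")
            n.length = float(np.random.default_rng(seeds[gi]).exponential(1.0 / cfg.birth_rate))
            subtrees.append(n)
        else:
            sub = _yule(
                np.random.default_rng(seeds[gi]), size, cfg.birth_rate,
                prefix=GROUP_PREFIXES[gi],
            )
            sub.root.length = cfg.backbone_length
            subtrees.append(sub.root)
    root = Node()
    for pair in (subtrees[:2], subtrees[2:]):
        mid = Node(length=cfg.backbone_length)
        for s in pair:
            mid.add(s)
        root.add(mid)
    tree = Tree(root)
    groups = {
        GROUP_LABELS[gi]: frozenset(
            n for n in tree.leaf_names() if n.startswith(GROUP_PREFIXES[gi])
        )
        for gi in range(4)
    }
    recipient = sorted(groups[GROUP_LABELS[0]])[0]
    donor_label = GROUP_LABELS[1]
    if cfg.hgt:
        tree = inject_hgt(tree, recipient, groups[donor_label], cfg.transfer_stalk_length)
    aln = evolve_alignment(tree, cfg.model, cfg.n_sites, seed=int(seeds[4]))
    taxonomy = TaxonomyMap(
        {n: (lab,) for lab, g in groups.items() for n in g}
    )
    constraint = taxonomy_constraint(taxonomy, aln.ids, name="vertical-descent")

    # coding sequences: the focal (possibly transferred) gene at cfg.amelioration,
    # background genes defining the recipient and donor usage/%GC distributions
    focal = backtranslate_cds(
        aln.row(recipient), RECIPIENT_USAGE, DONOR_USAGE,
        cfg.amelioration if cfg.hgt else 0.0,
        seed=int(seeds[5]), cds_id=recipient,
    )
    bg_rng = np.random.default_rng(int(seeds[6]))
    pi = cfg.model.pi
    informative = [a for a in AMINO_ACIDS]

    def random_protein(length: int) -> str:
        return "".join(
            informative[i] for i in bg_rng.choice(N_STATES, size=length, p=pi)
        )

    recipient_cds = tuple(
        backtranslate_cds(
            random_protein(cfg.n_sites), RECIPIENT_USAGE, DONOR_USAGE, 0.0,
            seed=int(bg_rng.integers(2**31 - 1)), cds_id=f"recipient_bg{k:03d}",
        )
        for k in range(n_background_cds)
    )
    donor_cds = tuple(
        backtranslate_cds(
            random_protein(cfg.n_sites), RECIPIENT_USAGE, DONOR_USAGE, 1.0,
            seed=int(bg_rng.integers(2**31 - 1)), cds_id=f"donor_bg{k:03d}",
        )
        for k in range(n_background_cds)
    )
    truth = {
        "hgt": cfg.hgt,
        "lambda": cfg.amelioration if cfg.hgt else 0.0,
        "recipient": recipient,
        "recipient_group": GROUP_LABELS[0],
        "donor_group": donor_label,
        "donor_clade": sorted(groups[donor_label]),
        "seed": cfg.seed,
    }
    return Benchmark(
        aln, tree, taxonomy, constraint, focal, recipient_cds, donor_cds,
        RECIPIENT_USAGE, DONOR_USAGE, truth,
    )


def _group_sizes(n_taxa: int, donor_size: int) -> list[int]:
    rest = n_taxa - donor_size
    if rest < 3:
        raise ValueError("n_taxa too small for a donor clade of that size")
    base, extra = divmod(rest, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    return [sizes[0], donor_size, sizes[1], sizes[2]]
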