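"""Distance phylogeny of haplotype sequences: TN93, neighbor-joining, bootstrap.

The Tamura–Nei (1993) model distinguishes the two transition classes
(A↔G, C↔T) and transversions and allows unequal base frequencies.  With
transition proportions P1 (A↔G), P2 (C↔T), transversion proportion Q and
base frequencies g (g_R = g_A+g_G, g_Y = g_C+g_T):

    d = −k1·ln(1 − P1/k1 − Q/(2 g_R)) − k2·ln(1 − P2/k2 − Q/(2 g_Y))
        − k3·ln(1 − Q/(2 g_R g_Y))

    k1 = 2 g_A g_G / g_R,  k2 = 2 g_C g_T / g_Y,
    k3 = 2 (g_R g_Y − g_A g_G g_Y/g_R − g_C g_T g_R/g_Y)

Any non-positive logarithm argument means the pair is saturated under the
model; these alignments are closely related, so that is an error rather
than a fallback.

Trees are neighbor-joining (exact on additive matrices), held in dendropy
structures; negative NJ branch lengths are clamped to zero with the deficit
logged.  Bootstrap supports resample alignment columns with replacement;
replicate r draws from a child seed master+r, so runs are reproducible and
order-independent.  Rooting places the root on the branch subtending the
outgroup (the ancestral sequence), splitting its length equally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .archaic import AlignedHaplotypeSet

logger = logging.getLogger("archhap")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class SaturationError(ValueError):
    """A TN93 logarithm argument is non-positive: distances are undefined."""


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.isfinite(self.d).all():
            raise ValueError("distance matrix has non-finite entries")
        if np.abs(self.d - self.d.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) != 0.0:
            raise ValueError("distance matrix diagonal must be zero")

    def submatrix(self, taxa: list[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(taxa=list(taxa), d=self.d[np.ix_(idx, idx)])


def _encode(seq) -> np.ndarray:
    """Map a nucleotide sequence to 0..3, anything else (N, gap) to −1."""
    arr = np.asarray(list(seq) if isinstance(seq, str) else seq, dtype="<U1")
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == base] = code
    return out


def base_frequencies(alignment: AlignedHaplotypeSet) -> np.ndarray:
    """Pooled empirical A,C,G,T frequencies over all non-missing cells."""
    enc = _encode(alignment.states.ravel())
    enc = enc[enc >= 0]
    if enc.size == 0:
        raise ValueError("alignment has no called bases")
    counts = np.bincount(enc, minlength=4).astype(float)
    return counts / counts.sum()


def tn93_distance(seq_a, seq_b, base_freqs) -> float:
    """TN93 distance (substitutions/site) between two sequences.

    Columns where either sequence is missing are excluded pairwise;
    ``base_freqs`` are the (externally estimated) A,C,G,T frequencies.
    """
    a = _encode(seq_a)
    b = _encode(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    n = a.size
    if n == 0:
        raise ValueError("no comparable columns between the two sequences")
    g = np.asarray(base_freqs, dtype=float)
    if g.shape != (4,) or (g < 0).any() or abs(g.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must be four non-negative values summing to 1")
    if (g[0] + g[2]) <= 0 or (g[1] + g[3]) <= 0:
        raise ValueError("purine and pyrimidine frequencies must both be positive")

    diff = a != b
    purine = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    pyrim = np.isin(a, (1, 3)) & np.isin(b, (1, 3))
    p1 = float(np.sum(diff & purine)) / n  # A<->G transitions
    p2 = float(np.sum(diff & pyrim)) / n  # C<->T transitions
    q = float(np.sum(diff & ~purine & ~pyrim)) / n  # transversions

    g_a, g_c, g_g, g_t = g
    g_r = g_a + g_g
    g_y = g_c + g_t
    k1 = 2.0 * g_a * g_g / g_r
    k2 = 2.0 * g_c * g_t / g_y
    k3 = 2.0 * (g_r * g_y - g_a * g_g * g_y / g_r - g_c * g_t * g_r / g_y)

    w1 = 1.0 - p1 / k1 - q / (2.0 * g_r) if k1 > 0 else 1.0
    w2 = 1.0 - p2 / k2 - q / (2.0 * g_y) if k2 > 0 else 1.0
    w3 = 1.0 - q / (2.0 * g_r * g_y)
    if (k1 == 0 and p1 > 0) or (k2 == 0 and p2 > 0):
        raise SaturationError("transitions observed between bases of frequency zero")
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError(
            f"sequences saturated under TN93 (P1={p1:.4f}, P2={p2:.4f}, Q={q:.4f})"
        )
    d = -(k1 * math.log(w1) if k1 > 0 else 0.0) \
        - (k2 * math.log(w2) if k2 > 0 else 0.0) \
        - k3 * math.log(w3)
    # identical sequences give exactly 0; guard against -0.0 / tiny negatives
    return max(d, 0.0)


def distance_matrix(
    alignment: AlignedHaplotypeSet, max_missing_frac: float = 0.5
) -> DistanceMatrix:
    """All pairwise TN93 distances, base frequencies pooled from the alignment.

    Columns missing in more than ``max_missing_frac`` of taxa are dropped
    (logged) before anything else; remaining missing cells are handled by
    pairwise deletion.  Saturation on any pair raises, naming the pair.
    """
    if alignment.n_taxa < 3:
        raise ValueError("need at least three taxa for a distance matrix")
    states = alignment.states
    enc = _encode(states.ravel()).reshape(states.shape)
    missing_frac = np.mean(enc < 0, axis=0)
    keep = missing_frac <= max_missing_frac
    if not keep.all():
        logger.info("distance_matrix: dropped %d column(s) missing in >%.0f%% of taxa",
                    int((~keep).sum()), 100 * max_missing_frac)
    states = states[:, keep]
    if states.shape[1] == 0:
        raise ValueError("no alignment columns left after missing-data filtering")
    trimmed = AlignedHaplotypeSet(
        taxa=alignment.taxa,
        sites=None if alignment.sites is None
        else [s for s, k in zip(alignment.sites, keep) if k],
        states=states,
    )
    freqs = base_frequencies(trimmed)
    n = trimmed.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = tn93_distance(states[i], states[j], freqs)
            except SaturationError as e:
                raise SaturationError(
                    f"pair ({trimmed.taxa[i]}, {trimmed.taxa[j]}): {e}"
                ) from None
    return DistanceMatrix(taxa=list(trimmed.taxa), d=d)


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

def _clamped(length: float, context: str) -> float:
    if length < 0:
        logger.info("nj_tree: clamped negative branch length %.3g (%s)", length, context)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; trifurcation at the seed node).

    Deterministic: ties in the Q-criterion are broken by the first
    (row-major) minimum.  Negative branch lengths are clamped to zero with
    the deficit logged.  Exact on additive matrices.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least three taxa for neighbor-joining")
    tns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    for label in dm.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _clamped(li, "join")
        parent.add_child(nodes[j])
        nodes[j].edge.length = _clamped(lj, "join")
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.delete(np.delete(d, (i, j), axis=0), (i, j), axis=1)
        d_new = np.delete(d_new, (i, j))
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d_new
        d[:-1, -1] = d_new
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]

    center = dendropy.Node()
    (i, j, k) = (0, 1, 2)
    lengths = (
        0.5 * (d[i, j] + d[i, k] - d[j, k]),
        0.5 * (d[i, j] + d[j, k] - d[i, k]),
        0.5 * (d[i, k] + d[j, k] - d[i, j]),
    )
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = _clamped(length, "terminal")

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions & bootstrap
# ---------------------------------------------------------------------------

def _leafset(node) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def tree_bipartitions(tree: dendropy.Tree) -> dict:
    """Internal-edge bipartitions as {normalized leafset: node}.

    Each bipartition is represented by the side NOT containing the
    alphabetically first taxon, so representations agree across trees and
    rootings.  Trivial bipartitions (single leaf / all-but-one) excluded.
    """
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    ref = min(all_taxa)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = _leafset(node)
        if ref in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            out[side] = node
    return out


def bootstrap_supports(
    alignment: AlignedHaplotypeSet,
    B: int = 1000,
    seed: int = 0,
    max_missing_frac: float = 0.5,
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports on internal nodes.

    Each of the B replicates resamples alignment columns with replacement
    (replicate r seeded with seed+r), rebuilds the tree, and every internal
    edge of the full-data tree present in the replicate scores one count.
    A replicate whose resample is all-constant (all pairwise distances
    zero) carries no resolved bipartitions and contributes a star — zero
    counts — and is logged.  Supports are attached as integer node labels
    and kept in ``tree.bipartition_supports`` (leafset → count).
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    full_dm = distance_matrix(alignment, max_missing_frac=max_missing_frac)
    tree = nj_tree(full_dm)
    bips = tree_bipartitions(tree)
    counts = {bip: 0 for bip in bips}
    L = alignment.n_sites
    n_degenerate = 0
    for rep in range(B):
        rng = np.random.default_rng(seed + rep)
        cols = rng.integers(0, L, size=L)
        resampled = AlignedHaplotypeSet(
            taxa=alignment.taxa,
            sites=None if alignment.sites is None
            else [alignment.sites[c] for c in cols],
            states=alignment.states[:, cols],
        )
        try:
            dm_r = distance_matrix(resampled, max_missing_frac=max_missing_frac)
        except (SaturationError, ValueError):
            n_degenerate += 1
            continue
        off_diag = dm_r.d[~np.eye(len(dm_r.taxa), dtype=bool)]
        if off_diag.size and off_diag.max() == 0.0:
            n_degenerate += 1  # all-constant resample: star contribution
            continue
        rep_bips = set(tree_bipartitions(nj_tree(dm_r)))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    if n_degenerate:
        logger.info("bootstrap_supports: %d/%d degenerate replicate(s) counted as stars",
                    n_degenerate, B)
    for bip, node in bips.items():
        node.label = str(counts[bip])
    tree.bipartition_supports = dict(counts)
    tree.bootstrap_replicates = B
    return tree


def clade_support(tree: dendropy.Tree, taxa: "set[str] | frozenset") -> "int | None":
    """Bootstrap count for the bipartition separating ``taxa`` from the rest.

    Returns None if the full-data tree does not contain that bipartition.
    """
    supports = getattr(tree, "bipartition_supports", None)
    if supports is None:
        raise ValueError("tree carries no bootstrap supports")
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    ref = min(all_taxa)
    side = frozenset(taxa)
    if ref in side:
        side = all_taxa - side
    return supports.get(side)


def root_tree(tree: dendropy.Tree, outgroup: str = "ancestral") -> dendropy.Tree:
    """Root on the branch subtending the outgroup leaf, splitting it equally.

    Returns a rooted copy; the input tree is left untouched.  Support
    labels are re-derived from the stored bipartition supports (rooting
    does not change any bipartition, only where labels must sit).
    """
    rooted = tree.clone(depth=1)
    leaf = next(
        (l for l in rooted.leaf_node_iter() if l.taxon and l.taxon.label == outgroup), None
    )
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    half = (leaf.edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(leaf.edge, length1=half, length2=half)
    rooted.is_rooted = True
    supports = getattr(tree, "bipartition_supports", None)
    if supports is not None:
        all_taxa = frozenset(t.label for t in rooted.taxon_namespace)
        ref = min(all_taxa)
        for node in rooted.preorder_node_iter():
            if node.is_leaf():
                continue
            node.label = None
            side = _leafset(node)
            if ref in side:
                side = all_taxa - side
            if side in supports:
                node.label = str(supports[side])
        rooted.bipartition_supports = dict(supports)
        rooted.bootstrap_replicates = getattr(tree, "bootstrap_replicates", None)
    return rooted


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (bootstrap labels kept as internal node labels)."""
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
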