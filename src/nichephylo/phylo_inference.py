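"""Distance-based tree inference and ordination of trees.

Neighbor-joining with bootstrap supports stands in for full Bayesian
inference: it produces the same tree-with-supports structure (supports in
[0, 1] on internal nodes) that the downstream clade delineation consumes.
Patristic distance matrices and principal-coordinate embeddings of trees
feed the cophylogenetic congruence test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .core_io import Phylogeny, ValidationError

log = logging.getLogger(__name__)

_JC_MAX_DIST = 5.0  # saturated JC distance cap (p >= 3/4)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix (triangle inequality not
    assumed)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValidationError("negative distances")
        self.values = v

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix, midpoint_root: bool = True,
            outgroup: str | None = None) -> Phylogeny:
    """Saitou–Nei neighbor joining.

    Negative estimated branch lengths are clamped to zero; the unrooted
    result is midpoint-rooted (or rooted on ``outgroup`` when given). Exact
    on additive distance matrices.
    """
    n = len(D.labels)
    if n < 3:
        raise ValidationError("need at least 3 labels for neighbor joining")
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for label in D.labels:
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(label=label)
        nodes.append(nd)
    d = D.values.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        li = 0.5 * sub[i_, j_] + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = sub[i_, j_] - li
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = max(li, 0.0)
        nodes[b].edge.length = max(lj, 0.0)
        # distances from the new node
        dk = 0.5 * (d[a, :] + d[b, :] - d[a, b])
        d = np.vstack([d, dk])
        d = np.column_stack([d, np.append(dk, 0.0)])
        nodes.append(parent)
        new_idx = d.shape[0] - 1
        d[new_idx, new_idx] = 0.0
        active = [k for k in active if k not in (a, b)] + [new_idx]
    # resolve the final three neighbours by the three-point formulas
    x, y, z = active
    center = dendropy.Node()
    for (p, q, s) in ((x, y, z), (y, x, z), (z, x, y)):
        length = 0.5 * (d[p, q] + d[p, s] - d[q, s])
        center.add_child(nodes[p])
        nodes[p].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        nd.support = None
    if outgroup is not None:
        og = next(l for l in tree.leaf_node_iter()
                  if l.taxon.label == outgroup)
        tree.to_outgroup_position(og, update_bipartitions=False,
                                  suppress_unifurcations=True)
    elif midpoint_root:
        tree.reroot_at_midpoint(update_bipartitions=False,
                                suppress_unifurcations=True)
    for nd in tree.preorder_node_iter():
        if not hasattr(nd, "support"):
            nd.support = None
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# bootstrap supports
# ---------------------------------------------------------------------------

def jc69_distance_matrix(labels, seqs: np.ndarray) -> DistanceMatrix:
    """JC69-corrected pairwise distances from an alignment matrix
    (rows = taxa, integer-coded or character-coded sites)."""
    n, L = seqs.shape
    d = np.zeros((n, n))
    for i in range(n):
        diff = (seqs[i] != seqs[i + 1:]).mean(axis=1) if i + 1 < n else []
        for k, p in enumerate(diff, start=i + 1):
            if p >= 0.75 - 1e-12:
                dist = _JC_MAX_DIST
            else:
                dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, k] = d[k, i] = dist
    return DistanceMatrix(list(labels), d)


def _splits(phy: Phylogeny) -> dict[frozenset, object]:
    """Canonical unrooted bipartitions (as the lexicographically smaller
    side) -> internal node, trivial splits excluded."""
    all_tips = frozenset(phy.tip_labels)
    out = {}
    for nd in phy.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        comp = all_tips - side
        if len(side) < 2 or len(comp) < 2:
            continue  # trivial bipartition
        canon = min(side, comp, key=lambda s: (len(s), sorted(s)))
        out[canon] = nd
    return out


def robinson_foulds(a: Phylogeny, b: Phylogeny) -> int:
    """Unrooted Robinson–Foulds distance (symmetric difference of
    non-trivial splits)."""
    sa, sb = set(_splits(a)), set(_splits(b))
    return len(sa ^ sb)


def bootstrap_supports(records, n_boot: int = 100, seed: int = 0,
                       ) -> Phylogeny:
    """NJ tree from JC69-corrected distances with bootstrap supports.

    Columns of the alignment are resampled with replacement ``n_boot``
    times; each internal node's support is the fraction of replicate trees
    containing its bipartition.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    recs = list(records)
    lengths = {len(r.residues) for r in recs}
    if len(lengths) != 1:
        raise ValidationError("sequences must be aligned to equal length")
    L = lengths.pop()
    labels = [r.id for r in recs]
    seqs = np.array([list(r.residues) for r in recs])
    full = nj_tree(jc69_distance_matrix(labels, seqs))
    splits = _splits(full)
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(jc69_distance_matrix(labels, seqs[:, cols]))
        rep_splits = set(_splits(rep))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for s, nd in splits.items():
        nd.support = counts[s] / n_boot
    return full


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------

def patristic_matrix(phy: Phylogeny) -> DistanceMatrix:
    """Sum of branch lengths along the tip-to-tip path, for all pairs."""
    pdm = phy.tree.phylogenetic_distance_matrix()
    labels = sorted(phy.tip_labels)
    taxa = {t.label: t for t in phy.tree.taxon_namespace
            if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray   # rows follow `labels`, columns are axes
    eigenvalues: np.ndarray   # positive retained eigenvalues, descending


def pcoa(D: DistanceMatrix, eig_tol: float = 1e-8) -> PCoAResult:
    """Principal-coordinate analysis by Gower double-centering of −½D².

    Axes with eigenvalue > ``eig_tol`` are retained and scaled by the
    square root of their eigenvalue; negative eigenvalues are dropped
    (with a logged warning about the dropped mass).
    """
    d = D.values
    n = d.shape[0]
    A = -0.5 * d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = 0.5 * (G + G.T)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg_mass = float(-eigval[eigval < -eig_tol].sum())
    if neg_mass > 0:
        log.warning("pcoa: dropping negative eigenvalue mass %.3g "
                    "(non-Euclidean distances)", neg_mass)
    keep = eigval > eig_tol
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return PCoAResult(list(D.labels), coords, eigval[keep])
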