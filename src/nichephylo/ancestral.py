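"""Maximum-likelihood Brownian-motion ancestral state reconstruction.

Under Brownian motion the tip values are jointly Gaussian with covariance
sigma^2 * V, where V holds shared root-to-tip path lengths. The root state
is the generalised-least-squares mean (1' V^-1 1)^-1 1' V^-1 x, each
internal node's state is the same estimator with the tree re-rooted at that
node, and sigma^2 is the ML estimate (divisor n). Everything is computed by
a linear-time two-pass message-passing scheme on the tree (equivalent to
the explicit-matrix GLS, which the test suite checks it against).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Phylogeny, ValidationError, parse_newick, write_newick

log = logging.getLogger(__name__)

_MIN_BRANCH = 1e-9


@dataclass
class ASRResult:
    """Ancestral reconstruction of one continuous trait."""

    node_states: dict[str, float]    # internal node key -> state estimate
    node_variances: dict[str, float]  # (1'V^-1 1)^-1 * sigma2 per node
    sigma2_hat: float                 # ML rate, trait^2 / branch-length unit
    root_state: float
    root_se: float

    def __post_init__(self) -> None:
        if self.sigma2_hat < 0:
            raise ValidationError("negative sigma2 estimate")


def _node_key(node, index: int) -> str:
    if node.is_leaf():
        return node.taxon.label if node.taxon else node.label
    return f"node{index:04d}"


def asr_bm(tree: Phylogeny, tip_values: dict[str, float]) -> ASRResult:
    """Reconstruct ancestral states of a continuous trait under Brownian
    motion.

    Every tip must have a value (no imputation). Zero-length internal
    branches are replaced by 1e-9 (logged), which is the polytomy limit.
    """
    phylo = tree
    tips = phylo.tip_labels
    missing = [t for t in tips if t not in tip_values]
    if missing:
        raise ValidationError(f"missing trait value for tip(s) {missing}")
    if len(tips) < 2:
        raise ValidationError("need at least 2 tips")

    t = phylo.tree
    # branch sanitation
    n_zero = 0
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.edge.length is None or nd.edge.length <= 0:
            nd.edge.length = _MIN_BRANCH
            n_zero += 1
    if n_zero:
        log.warning("asr_bm: %d zero-length branches set to %.0e",
                    n_zero, _MIN_BRANCH)

    nodes = list(t.preorder_node_iter())
    key = {id(nd): _node_key(nd, i) for i, nd in enumerate(nodes)}

    # ---- up pass: message from each node's subtree, seen from its parent
    up_mean: dict[int, float] = {}
    up_var: dict[int, float] = {}
    contrast_q = 0.0
    for nd in t.postorder_node_iter():
        b = nd.edge.length if nd.parent_node is not None else 0.0
        if nd.is_leaf():
            m, s = float(tip_values[key[id(nd)]]), 0.0
        else:
            children = nd.child_nodes()
            m, s = up_mean[id(children[0])], up_var[id(children[0])]
            for ch in children[1:]:
                m2, s2 = up_mean[id(ch)], up_var[id(ch)]
                contrast_q += (m - m2) ** 2 / (s + s2)
                prec = 1.0 / s if s > 0 else np.inf
                prec2 = 1.0 / s2 if s2 > 0 else np.inf
                if np.isinf(prec) and np.isinf(prec2):
                    m, s = 0.5 * (m + m2), 0.0
                else:
                    m = (m / s + m2 / s2) / (1.0 / s + 1.0 / s2)
                    s = 1.0 / (1.0 / s + 1.0 / s2)
        up_mean[id(nd)], up_var[id(nd)] = m, s + b

    n = len(tips)
    sigma2 = contrast_q / n
    root = t.seed_node

    # ---- down pass: message from outside each node's subtree
    down_mean: dict[int, float] = {}
    down_var: dict[int, float] = {}
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent = nd.parent_node
        msgs = []
        if parent.parent_node is not None or id(parent) in down_mean:
            if id(parent) in down_mean:
                msgs.append((down_mean[id(parent)], down_var[id(parent)]))
        for sib in parent.child_nodes():
            if sib is not nd:
                msgs.append((up_mean[id(sib)], up_var[id(sib)]))
        prec = sum(1.0 / s if s > 0 else np.inf for _, s in msgs)
        if np.isinf(prec):
            m = [mm for mm, s in msgs if s <= 0][0]
            s = 0.0
        else:
            m = sum(mm / s for mm, s in msgs) / prec
            s = 1.0 / prec
        down_mean[id(nd)] = m
        down_var[id(nd)] = s + nd.edge.length

    # ---- combine at every internal node
    node_states: dict[str, float] = {}
    node_vars: dict[str, float] = {}
    for nd in t.preorder_node_iter():
        if nd.is_leaf():
            continue
        msgs = [(up_mean[id(ch)], up_var[id(ch)]) for ch in nd.child_nodes()]
        if id(nd) in down_mean:
            msgs.append((down_mean[id(nd)], down_var[id(nd)]))
        prec = sum(1.0 / s if s > 0 else np.inf for _, s in msgs)
        if np.isinf(prec):
            state, var = [mm for mm, s in msgs if s <= 0][0], 0.0
        else:
            state = sum(mm / s for mm, s in msgs) / prec
            var = 1.0 / prec
        k = key[id(nd)]
        node_states[k] = state
        node_vars[k] = var * sigma2

    root_key = key[id(root)]
    root_state = node_states[root_key]
    root_se = float(np.sqrt(node_vars[root_key]))
    return ASRResult(node_states=node_states, node_variances=node_vars,
                     sigma2_hat=sigma2, root_state=root_state,
                     root_se=root_se)


def asr_bm_gls(tree: Phylogeny, tip_values: dict[str, float]
               ) -> tuple[float, float]:
    """Explicit-matrix GLS root estimate and ML sigma^2 (O(n^3)); the
    independent reference for :func:`asr_bm` on small trees."""
    tips = tree.tip_labels
    n = len(tips)
    V = np.zeros((n, n))
    t = tree.tree
    # shared path length from root for each pair
    mrca_cache = {}
    depth = {}
    for nd in t.preorder_node_iter():
        d = 0.0 if nd.parent_node is None else (
            depth[id(nd.parent_node)] + max(nd.edge.length or 0.0, _MIN_BRANCH))
        if nd.parent_node is None:
            d = 0.0
        depth[id(nd)] = d
    leaves = {(_l.taxon.label if _l.taxon else _l.label): _l
              for _l in t.leaf_node_iter()}
    pdm_tree = t
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i > j:
                continue
            if i == j:
                V[i, i] = depth[id(leaves[a])]
            else:
                mrca = pdm_tree.mrca(taxa=[leaves[a].taxon, leaves[b].taxon])
                V[i, j] = V[j, i] = depth[id(mrca)]
    x = np.array([tip_values[tip] for tip in tips])
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    mu = (one @ Vinv @ x) / (one @ Vinv @ one)
    resid = x - mu
    sigma2 = float(resid @ Vinv @ resid) / n
    return float(mu), sigma2


def prune_tips(tree: Phylogeny, drop: set[str]) -> Phylogeny:
    """Remove the given tips, preserving path lengths among those kept."""
    phy = parse_newick(write_newick(tree))  # work on a copy
    t = phy.tree
    taxa = [l.taxon for l in t.leaf_node_iter()
            if (l.taxon.label if l.taxon else l.label) in drop]
    if taxa:
        t.prune_taxa(taxa, suppress_unifurcations=True)
    return Phylogeny(t)


def reconstruct_habitat_traits(
    tree: Phylogeny,
    tip_traits: pd.DataFrame,
    traits: list[str] | None = None,
    drop_tips: set[str] | None = None,
) -> dict[str, ASRResult]:
    """Run one Brownian-motion reconstruction per habitat trait.

    ``tip_traits`` has tips as index and traits as columns (e.g. pH, water
    content, organic matter, nitrate proportion); tips listed in
    ``drop_tips`` (e.g. culture/reference sequences) are pruned first,
    preserving branch-length sums along retained paths.
    """
    if traits is None:
        traits = list(tip_traits.columns)
    work = prune_tips(tree, drop_tips) if drop_tips else tree
    if len(work.tip_labels) < 3:
        raise ValidationError("fewer than 3 tips left after pruning")
    out = {}
    for trait in traits:
        vals = tip_traits[trait].dropna().to_dict()
        out[trait] = asr_bm(work, vals)
    return out


def tip_trait_values(records, env, factors) -> pd.DataFrame:
    """Per-tip abundance-weighted environmental means (tips x traits).

    Each tip's weight in a soil is its share of that soil's reads; the
    trait value is the weighted mean of the factor over soils.
    """
    per_soil: dict[str, dict[str, int]] = {}
    for r in records:
        tip = r.id.split(".")[0]
        soil = per_soil.setdefault(r.sample_id, {})
        soil[tip] = soil.get(tip, 0) + r.count
    tips = sorted({t for d in per_soil.values() for t in d})
    rows = {}
    for tip in tips:
        weights, soils = [], []
        for soil, d in per_soil.items():
            total = sum(d.values())
            if total and d.get(tip):
                weights.append(d[tip] / total)
                soils.append(soil)
        w = np.array(weights)
        row = {}
        for f in factors:
            vals = env.data[f].reindex(soils).to_numpy(dtype=float)
            mask = ~np.isnan(vals)
            row[f] = float((w[mask] * vals[mask]).sum() / w[mask].sum()) \
                if mask.any() else np.nan
        rows[tip] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(factors)]
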