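"""Phylogenetic cluster delineation and environmental preference profiles.

A phylogenetic cluster is a maximal clade whose tips are all mutually
similar (pairwise sequence identity above an identity threshold, default
>0.90) and whose root node is well supported (support above a threshold,
default >0.70). Each cluster's environmental preference is the abundance-
weighted mean of each factor over soils, its pH niche is classified as
acidophilic / neutrophilic / alkalinophilic, and its response along the pH
gradient is summarised by a low-order polynomial chosen by small-sample
corrected AIC.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AbundanceMatrix, EnvTable, Phylogeny, ValidationError

log = logging.getLogger(__name__)

DEFAULT_ID_THRESH = 0.90
DEFAULT_SUPPORT_THRESH = 0.70
#: pH category boundaries: below the first = acidophilic, above the second =
#: alkalinophilic, in between (lower bound closed) = neutrophilic.
DEFAULT_PH_BOUNDS = (5.5, 7.0)
ABUNDANT_READ_FRACTION = 0.05   # "abundant" = >5% of all reads


@dataclass
class CladeCluster:
    """One delineated phylogenetic cluster."""

    id: str
    member_tips: frozenset[str]
    root_support: float | None
    min_pairwise_identity: float
    total_read_fraction: float = 0.0
    unplaced: bool = False        # singleton never captured by the rule
    rule_relaxed: bool = False    # emitted via an explicit override


def delineate_clusters(
    tree: Phylogeny,
    identity_fn,
    id_thresh: float = DEFAULT_ID_THRESH,
    support_thresh: float = DEFAULT_SUPPORT_THRESH,
    overrides: set[frozenset] | None = None,
) -> list[CladeCluster]:
    """Delineate maximal well-supported, high-identity clades.

    Preorder traversal from the root: a clade is emitted as a cluster iff
    the minimum pairwise identity among its tips exceeds ``id_thresh`` AND
    its root support exceeds ``support_thresh`` (an undefined support, e.g.
    at the tree root, is treated as 1.0). On emission the traversal does
    not descend further, so clusters are maximal and disjoint. Tips never
    captured become singleton clusters flagged unplaced.

    ``identity_fn(tip_a, tip_b) -> identity`` supplies the sequence
    identities; ``overrides`` is an optional set of tip-label frozensets to
    emit regardless of the rule (logged, flagged ``rule_relaxed``).
    """
    overrides = overrides or set()
    clusters: list[CladeCluster] = []

    def min_identity(tips: list[str]) -> float:
        if len(tips) == 1:
            return 1.0
        return min(identity_fn(a, b)
                   for a, b in itertools.combinations(tips, 2))

    def visit(node) -> None:
        tips = [l.taxon.label if l.taxon else l.label
                for l in node.leaf_iter()]
        if node.is_leaf():
            clusters.append(CladeCluster(
                id="", member_tips=frozenset(tips), root_support=None,
                min_pairwise_identity=1.0, unplaced=True))
            return
        support = getattr(node, "support", None)
        eff_support = 1.0 if support is None else support
        tipset = frozenset(tips)
        if tipset in overrides:
            log.info("delineation override applied to clade %s", sorted(tips))
            clusters.append(CladeCluster(
                id="", member_tips=tipset, root_support=support,
                min_pairwise_identity=min_identity(tips), rule_relaxed=True))
            return
        mpi = min_identity(tips)
        if mpi > id_thresh and eff_support > support_thresh:
            clusters.append(CladeCluster(
                id="", member_tips=tipset, root_support=support,
                min_pairwise_identity=mpi))
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.tree.seed_node)
    for i, cl in enumerate(clusters, start=1):
        cl.id = f"C{i:02d}"
    return clusters


def annotate_read_fractions(clusters: list[CladeCluster], records) -> None:
    """Fill each cluster's fraction of the data set's total reads.

    Record ids are matched to tips by exact id or by the ``{tip}.{soil}``
    convention of the synthetic generator.
    """
    tip_reads: dict[str, int] = {}
    total = 0
    for r in records:
        tip = r.id.split(".")[0]
        tip_reads[tip] = tip_reads.get(tip, 0) + r.count
        total += r.count
    if total == 0:
        raise ValidationError("no reads to annotate")
    for cl in clusters:
        cl.total_read_fraction = sum(
            tip_reads.get(t, 0) for t in cl.member_tips) / total


@dataclass
class PreferenceProfile:
    """Abundance-weighted environmental preference of one cluster."""

    cluster_id: str
    weighted_mean: dict[str, float]
    category: str
    abundant: bool


def cluster_preference(
    cluster: CladeCluster,
    abundance: AbundanceMatrix,
    env: EnvTable,
    factors: list[str] | None = None,
    ph_bounds: tuple[float, float] = DEFAULT_PH_BOUNDS,
) -> PreferenceProfile:
    """Abundance-weighted mean of each factor over soils for one cluster.

    Weights are the cluster's relative abundance per soil; soils missing a
    factor are dropped for that factor only.
    """
    if cluster.id not in abundance.data.columns:
        raise ValidationError(f"cluster {cluster.id!r} absent from the "
                              "abundance matrix")
    w = abundance.data[cluster.id]
    if w.sum() <= 0:
        raise ValidationError(f"cluster {cluster.id!r} absent from all soils")
    if factors is None:
        factors = env.numeric_factors
    means: dict[str, float] = {}
    for f in factors:
        vals = env.data[f].reindex(w.index)
        mask = vals.notna()
        wm = w[mask]
        if wm.sum() <= 0:
            means[f] = float("nan")
            continue
        means[f] = float((wm * vals[mask]).sum() / wm.sum())
    category = classify_ph_category(means.get("pH", float("nan")), ph_bounds)
    return PreferenceProfile(
        cluster_id=cluster.id, weighted_mean=means, category=category,
        abundant=cluster.total_read_fraction > ABUNDANT_READ_FRACTION)


def classify_ph_category(
    weighted_mean_ph: float,
    bounds: tuple[float, float] = DEFAULT_PH_BOUNDS,
) -> str:
    """acidophilic below the lower bound, alkalinophilic above the upper,
    neutrophilic in between (lower bound closed)."""
    lo, hi = bounds
    if np.isnan(weighted_mean_ph):
        return "unknown"
    if not 3.5 <= weighted_mean_ph <= 8.5:
        log.warning("weighted-mean pH %.2f outside the 3.5-8.5 study range",
                    weighted_mean_ph)
    if weighted_mean_ph < lo:
        return "acidophilic"
    if weighted_mean_ph > hi:
        return "alkalinophilic"
    return "neutrophilic"


@dataclass
class PhResponseFit:
    cluster_id: str
    degree: int
    coefficients: np.ndarray    # highest power first (numpy polyfit order)
    rss: float

    def predict(self, ph, clip: bool = True):
        y = np.polyval(self.coefficients, np.asarray(ph, dtype=float))
        return np.clip(y, 0.0, None) if clip else y


def _aicc(rss: float, n: int, k: int) -> float:
    # gaussian log-likelihood up to constants; k params + variance
    rss = max(rss, 1e-300)
    p = k + 1
    if n - p - 1 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def ph_response_fit(
    cluster_id: str, abundance: AbundanceMatrix, env: EnvTable,
    max_degree: int = 3,
) -> PhResponseFit:
    """Least-squares polynomial (degree 1–3) of the cluster's relative
    abundance on soil pH, degree chosen by small-sample corrected AIC;
    predictions are clipped at zero for reporting."""
    if cluster_id not in abundance.data.columns:
        raise ValidationError(f"cluster {cluster_id!r} absent")
    y = abundance.data[cluster_id]
    ph = env.data["pH"].reindex(y.index)
    mask = ph.notna()
    y, ph = y[mask].to_numpy(float), ph[mask].to_numpy(float)
    if len(y) < 6:
        raise ValidationError(
            f"only {len(y)} soils with the cluster observed (need >= 6); "
            "use the weighted-mean summary instead")
    exact_tol = 1e-10 * max(1.0, float((y ** 2).sum()))
    best = None
    for deg in range(1, max_degree + 1):
        coef = np.polyfit(ph, y, deg)
        rss = float(((np.polyval(coef, ph) - y) ** 2).sum())
        if rss < exact_tol:
            # exact fit: take the smallest such degree (AICc on a ~zero
            # residual is numerically meaningless)
            best = (-np.inf, deg, coef, rss)
            break
        score = _aicc(rss, len(y), deg + 1)
        if best is None or score < best[0] - 1e-12:
            best = (score, deg, coef, rss)
    _, deg, coef, rss = best
    return PhResponseFit(cluster_id=cluster_id, degree=deg,
                         coefficients=coef, rss=rss)


def clade_abundance_matrix(
    clusters: list[CladeCluster], records,
    min_reads_per_soil: int = 1,
) -> AbundanceMatrix:
    """Soils x clade-clusters relative percentages, mapping records to
    clusters through their tip of origin (``{tip}.{soil}`` id convention
    or exact tip id)."""
    tip_to_cluster = {t: cl.id for cl in clusters for t in cl.member_tips}
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        tip = r.id.split(".")[0]
        cid = tip_to_cluster.get(tip)
        if cid is None:
            continue
        soil = counts.setdefault(r.sample_id, {})
        soil[cid] = soil.get(cid, 0) + r.count
    soils = sorted(counts)
    excluded = [s for s in soils
                if sum(counts[s].values()) < min_reads_per_soil]
    kept = [s for s in soils if s not in set(excluded)]
    if not kept:
        raise ValidationError("all soils fall below the read floor")
    cluster_ids = [cl.id for cl in clusters]
    mat = np.zeros((len(kept), len(cluster_ids)))
    col = {c: j for j, c in enumerate(cluster_ids)}
    for i, s in enumerate(kept):
        total = sum(counts[s].values())
        for cid, n in counts[s].items():
            mat[i, col[cid]] = 100.0 * n / total
    df = pd.DataFrame(mat, index=pd.Index(kept, name="soil_id"),
                      columns=cluster_ids)
    return AbundanceMatrix(df, excluded)


def preference_table(
    clusters: list[CladeCluster],
    abundance: AbundanceMatrix,
    env: EnvTable,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Preference profiles for all clusters present in the abundance
    matrix, as a tidy table."""
    rows = []
    for cl in clusters:
        if cl.id not in abundance.data.columns:
            continue
        if abundance.data[cl.id].sum() <= 0:
            continue
        prof = cluster_preference(cl, abundance, env, factors)
        row = {"cluster": cl.id,
               "n_tips": len(cl.member_tips),
               "read_fraction": cl.total_read_fraction,
               "abundant": prof.abundant,
               "category": prof.category}
        row.update({f"mean_{k}": v for k, v in prof.weighted_mean.items()})
        rows.append(row)
    return pd.DataFrame(rows)
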