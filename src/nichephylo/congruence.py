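"""Cross-marker cluster correspondence and the ParaFit congruence test.

The two marker phylogenies are linked by a binary correspondence matrix
built at two confidence tiers: links anchored by shared reference organisms
(high confidence), and suggested links between abundant clusters with
similar relative read abundance and similar pH specialisation. The global
congruence statistic is ParaFit's trace statistic on principal-coordinate
embeddings of the two patristic distance matrices, with significance from
permutations of the association matrix rows (one-tailed upper test: shared
evolutionary history inflates the statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ValidationError
from .phylo_inference import DistanceMatrix, pcoa

DEFAULT_ABUNDANCE_TOL = 0.25   # relative read-fraction tolerance for tier 2
DEFAULT_PH_TOL = 0.5           # pH units
ABUNDANT_READ_FRACTION = 0.05


@dataclass
class ClusterAnnotation:
    """What the correspondence builder needs to know about one cluster."""

    id: str
    read_fraction: float
    mean_ph: float
    references: frozenset[str] = frozenset()

    @property
    def abundant(self) -> bool:
        return self.read_fraction > ABUNDANT_READ_FRACTION


@dataclass
class CorrespondenceMatrix:
    """Binary amoA-clusters x 16S-clusters link matrix with per-link
    confidence tiers (``reference_anchored`` or ``suggested``)."""

    data: pd.DataFrame                      # rows amoA, cols 16S, 0/1
    tier: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("links must be 0/1")
        links = {(self.data.index[i], self.data.columns[j])
                 for i, j in zip(*np.nonzero(vals))}
        extra = set(self.tier) - links
        if extra:
            raise ValidationError(f"tiers on non-existent links: {extra}")

    @property
    def links(self) -> list[tuple[str, str]]:
        vals = self.data.to_numpy()
        return [(self.data.index[i], self.data.columns[j])
                for i, j in zip(*np.nonzero(vals))]


def identity_links(labels: list[str]) -> CorrespondenceMatrix:
    """One-to-one correspondence over a shared label set."""
    eye = pd.DataFrame(np.eye(len(labels), dtype=int),
                       index=labels, columns=labels)
    tier = {(l, l): "reference_anchored" for l in labels}
    return CorrespondenceMatrix(eye, tier)


def build_correspondence(
    clusters_amoa: list[ClusterAnnotation],
    clusters_16s: list[ClusterAnnotation],
    abundance_tolerance: float = DEFAULT_ABUNDANCE_TOL,
    ph_tolerance: float = DEFAULT_PH_TOL,
) -> CorrespondenceMatrix:
    """Two-tier link construction.

    Tier 1 links every amoA/16S cluster pair sharing at least one reference
    organism (many-to-one allowed). Tier 2 then greedily matches the
    remaining *abundant* clusters by closeness of log read fraction
    (within log(1 + abundance_tolerance)) subject to |Δ mean pH| <=
    ph_tolerance, ties broken by smaller |Δ pH|; each cluster links at most
    once at tier 2.
    """
    if abundance_tolerance <= 0 or ph_tolerance <= 0:
        raise ValueError("tolerances must be positive")
    for clusters in (clusters_amoa, clusters_16s):
        seen: dict[str, str] = {}
        for cl in clusters:
            for ref in cl.references:
                if ref in seen and seen[ref] != cl.id:
                    raise ValidationError(
                        f"reference {ref!r} placed in two clusters "
                        f"({seen[ref]!r}, {cl.id!r}) of the same marker")
                seen[ref] = cl.id
    rows = [c.id for c in clusters_amoa]
    cols = [c.id for c in clusters_16s]
    data = pd.DataFrame(np.zeros((len(rows), len(cols)), dtype=int),
                        index=rows, columns=cols)
    tier: dict[tuple[str, str], str] = {}
    for ca in clusters_amoa:
        for cs in clusters_16s:
            if ca.references & cs.references:
                data.loc[ca.id, cs.id] = 1
                tier[(ca.id, cs.id)] = "reference_anchored"
    linked_a = {a for a, _ in tier}
    linked_s = {s for _, s in tier}
    cand = []
    log_tol = math.log1p(abundance_tolerance)
    for ca in clusters_amoa:
        if ca.id in linked_a or not ca.abundant:
            continue
        for cs in clusters_16s:
            if cs.id in linked_s or not cs.abundant:
                continue
            if ca.read_fraction <= 0 or cs.read_fraction <= 0:
                continue
            d_ab = abs(math.log(ca.read_fraction) - math.log(cs.read_fraction))
            d_ph = abs(ca.mean_ph - cs.mean_ph)
            if d_ab <= log_tol and d_ph <= ph_tolerance:
                cand.append((d_ab, d_ph, ca.id, cs.id))
    cand.sort()
    used_a: set[str] = set()
    used_s: set[str] = set()
    for d_ab, d_ph, a, s in cand:
        if a in used_a or s in used_s:
            continue
        used_a.add(a)
        used_s.add(s)
        data.loc[a, s] = 1
        tier[(a, s)] = "suggested"
    return CorrespondenceMatrix(data, tier)


@dataclass
class ParaFitResult:
    """Global ParaFit statistic and its permutation p-value."""

    global_stat: float
    p_value: float
    nperm: int
    null_stats: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.global_stat < -1e-12:
            raise ValidationError("negative ParaFit statistic")
        if not (0 < self.p_value <= 1):
            raise ValidationError("p-value outside (0, 1]")


def parafit_global(
    D_host: DistanceMatrix,
    D_par: DistanceMatrix,
    A: CorrespondenceMatrix,
    nperm: int = 999,
    seed: int = 0,
) -> ParaFitResult:
    """Global ParaFit test of cophylogenetic congruence.

    ``D_host`` labels must equal the columns of ``A`` (here the 16S
    clusters), ``D_par`` labels its rows (amoA clusters). The statistic is
    trace(D'D) with D = C' A B and B, C the principal coordinates of the
    two patristic distance matrices; the null permutes the row order of A;
    p = (#{stat_perm >= stat_obs} + 1) / (nperm + 1).
    """
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    Adf = A.data
    if not Adf.to_numpy().any():
        raise ValidationError("association matrix is all zeros")
    if set(Adf.columns) != set(D_host.labels):
        raise ValidationError("host distance labels != association columns")
    if set(Adf.index) != set(D_par.labels):
        raise ValidationError("parasite distance labels != association rows")
    host = D_host.reorder(list(Adf.columns))
    par = D_par.reorder(list(Adf.index))
    B = pcoa(host).coordinates          # hosts x axes
    C = pcoa(par).coordinates           # parasites x axes
    Amat = Adf.to_numpy(dtype=float)
    def stat(mat: np.ndarray) -> float:
        D = C.T @ mat @ B
        return float((D ** 2).sum())
    obs = stat(Amat)
    rng = np.random.default_rng(seed)
    null = np.empty(nperm)
    exceed = 0
    for k in range(nperm):
        perm = rng.permutation(Amat.shape[0])
        null[k] = stat(Amat[perm])
        if null[k] >= obs:
            exceed += 1
    p = (exceed + 1) / (nperm + 1)
    return ParaFitResult(global_stat=obs, p_value=p, nperm=nperm,
                         null_stats=null)


def congruence_report(
    A: CorrespondenceMatrix,
    result: ParaFitResult,
    annotations_amoa: dict[str, ClusterAnnotation],
    annotations_16s: dict[str, ClusterAnnotation],
    ph_category_fn=None,
) -> pd.DataFrame:
    """Tidy per-link report (tier, read fractions, pH categories) carrying
    the global statistic and p-value on every row."""
    from .clade_analysis import classify_ph_category

    cat = ph_category_fn or classify_ph_category
    rows = []
    for a, s in A.links:
        ca, cs = annotations_amoa[a], annotations_16s[s]
        rows.append({
            "amoA_cluster": a,
            "ssu_cluster": s,
            "tier": A.tier.get((a, s), "suggested"),
            "amoA_read_fraction": ca.read_fraction,
            "ssu_read_fraction": cs.read_fraction,
            "amoA_ph_category": cat(ca.mean_ph),
            "ssu_ph_category": cat(cs.mean_ph),
            "global_stat": result.global_stat,
            "p_value": result.p_value,
        })
    return pd.DataFrame(rows)
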