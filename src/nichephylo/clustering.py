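"""Abundance-ordered greedy centroid clustering across identity thresholds.

Sequences are processed in order of decreasing read count (ties broken by
id) and assigned to the first existing centroid they match at or above the
threshold, otherwise they open a new cluster — the classic greedy OTU
picker. The default threshold ladder spans 100% down to 70% identity, and
relative-abundance matrices (percent of each soil's retained reads per
cluster) are built per threshold.

Identity is defined exactly: global alignment with match +1, mismatch −1,
gap −2 (linear), identity = identical columns / alignment columns after
stripping terminal-gap columns.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .core_io import AbundanceMatrix, SequenceRecord, ValidationError

DEFAULT_THRESHOLDS = (1.00, 0.97, 0.95, 0.90, 0.85, 0.80, 0.70)
DEFAULT_MIN_READS_PER_SOIL = 1000


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the optimal global alignment of
    ``a`` and ``b``, terminal-gap columns excluded. Symmetric, in [0, 1]."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 1.0
    if a > b:
        # canonical argument order: co-optimal alignments may differ in
        # identity, so symmetry is enforced by construction
        a, b = b, a
    aln = _ALIGNER.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    lo, hi = 0, len(s1)
    while lo < hi and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if s1[i] == s2[i])
    return matches / (hi - lo)


@functools.lru_cache(maxsize=1 << 20)
def _identity_cached(a: str, b: str) -> float:
    if a > b:
        a, b = b, a
    return pairwise_identity(a, b)


@dataclass
class ClusterSet:
    """Result of one greedy clustering pass at a single threshold."""

    threshold: float
    assignments: dict[str, str]   # sequence id -> cluster id
    centroids: list[str]          # centroid sequence ids, in opening order

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster_id: str) -> list[str]:
        return [sid for sid, cid in self.assignments.items()
                if cid == cluster_id]


def _sorted_records(records) -> list[SequenceRecord]:
    # aggregate counts per unique id first (same id may appear per soil)
    totals: dict[str, int] = {}
    rep: dict[str, SequenceRecord] = {}
    for r in records:
        key = r.id
        totals[key] = totals.get(key, 0) + r.count
        rep.setdefault(key, r)
    order = sorted(totals, key=lambda k: (-totals[k], k))
    return [rep[k] for k in order]


def greedy_cluster(records, threshold: float,
                   best_match: bool = False) -> ClusterSet:
    """Greedy centroid clustering of dereplicated records.

    Records are taken in decreasing order of total read count (ties:
    lexicographic id). Each record joins the first centroid whose identity
    to it is >= ``threshold`` (or, with ``best_match=True``, the
    highest-identity qualifying centroid), else becomes a new centroid.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = _sorted_records(records)
    centroids: list[SequenceRecord] = []
    assignments: dict[str, str] = {}
    for rec in ordered:
        chosen = None
        best = -1.0
        for cent in centroids:
            ident = _identity_cached(rec.residues, cent.residues)
            if ident >= threshold:
                if not best_match:
                    chosen = cent
                    break
                if ident > best:
                    best, chosen = ident, cent
        if chosen is None:
            centroids.append(rec)
            chosen = rec
        assignments[rec.id] = chosen.id
    return ClusterSet(threshold=threshold,
                      assignments=assignments,
                      centroids=[c.id for c in centroids])


def multiscale_cluster(records, thresholds=DEFAULT_THRESHOLDS,
                       ) -> dict[float, ClusterSet]:
    """One independent greedy pass per threshold on the same ordered input."""
    return {t: greedy_cluster(records, t) for t in thresholds}


def relative_abundance_matrix(
    cluster_set: ClusterSet, records,
    min_reads_per_soil: int = DEFAULT_MIN_READS_PER_SOIL,
) -> AbundanceMatrix:
    """Soils x clusters percentages of each soil's retained reads.

    Soils whose total reads fall below ``min_reads_per_soil`` are excluded
    (flagged, not zero-filled); an error is raised if nothing survives.
    """
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        cid = cluster_set.assignments.get(r.id)
        if cid is None:
            raise ValidationError(f"record {r.id!r} missing from cluster set")
        soil = counts.setdefault(r.sample_id, {})
        soil[cid] = soil.get(cid, 0) + r.count
    soil_ids = sorted(counts)
    excluded = [s for s in soil_ids
                if sum(counts[s].values()) < min_reads_per_soil]
    kept = [s for s in soil_ids if s not in set(excluded)]
    if not kept:
        raise ValidationError(
            "all soils fall below the read floor "
            f"({min_reads_per_soil} reads)")
    cluster_ids = [c for c in cluster_set.centroids]
    mat = np.zeros((len(kept), len(cluster_ids)))
    col = {c: j for j, c in enumerate(cluster_ids)}
    for i, s in enumerate(kept):
        total = sum(counts[s].values())
        for cid, n in counts[s].items():
            mat[i, col[cid]] = 100.0 * n / total
    df = pd.DataFrame(mat, index=pd.Index(kept, name="soil_id"),
                      columns=cluster_ids)
    return AbundanceMatrix(df, excluded)


def reference_cluster(records, threshold: float) -> ClusterSet:
    """Reference greedy clustering that precomputes the full identity
    matrix before assigning — used as an independent check of
    :func:`greedy_cluster` on small inputs."""
    ordered = _sorted_records(records)
    n = len(ordered)
    ident = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(
                ordered[i].residues, ordered[j].residues)
    centroid_idx: list[int] = []
    assignments: dict[str, str] = {}
    for i in range(n):
        target = next((c for c in centroid_idx if ident[i, c] >= threshold),
                      None)
        if target is None:
            centroid_idx.append(i)
            target = i
        assignments[ordered[i].id] = ordered[target].id
    return ClusterSet(threshold=threshold, assignments=assignments,
                      centroids=[ordered[i].id for i in centroid_idx])


def passthrough_recombinant_filter(records):
    """Hook where recombinant/chimera screening would run; returns the
    records unchanged (screening is outside this package's scope)."""
    return list(records)
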