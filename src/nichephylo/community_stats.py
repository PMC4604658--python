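"""Canonical correspondence analysis and multi-scale coherence testing.

The central question — which environmental factors structure the community,
and at which taxonomic resolution — is answered by one constrained
ordination per factor per clustering threshold: a CCA of the soils-by-
clusters relative-abundance matrix on that single factor, with significance
from a permutation test of the pseudo-F statistic (soil labels of the
factor permuted). The per-factor p-values across the threshold ladder and
data sets form the coherence table; Spearman rank correlations between
factors provide the companion collinearity overview.

CCA follows ter Braak: chi-square-standardised residuals of the relative
abundance table are projected, with row-mass weights, onto the constraint
space, and the constrained axes are the singular axes of that projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceMatrix, EnvTable, ValidationError

DEFAULT_NPERM = 999
DEFAULT_ALPHA = 0.05
_EIG_TOL = 1e-12


@dataclass
class CCAResult:
    """Constrained ordination summary for one community table and one
    constraint matrix."""

    constrained_eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    pseudo_F: float
    p_value: float | None = None
    rank: int = 0

    def __post_init__(self) -> None:
        if self.constrained_inertia > self.total_inertia + 1e-8:
            raise ValidationError("constrained inertia exceeds total inertia")


def _as_matrix(Y) -> pd.DataFrame:
    if isinstance(Y, AbundanceMatrix):
        return Y.data
    return pd.DataFrame(Y)


def design_matrix(x, reference: str | None = None) -> pd.DataFrame:
    """Numeric design matrix for one factor.

    Numeric input passes through as a single column; categorical input is
    dummy-coded with the most frequent level (or ``reference``) dropped.
    """
    s = pd.Series(x)
    if pd.api.types.is_numeric_dtype(s):
        return s.to_frame(name=s.name or "x").astype(float)
    counts = s.value_counts()
    ref = reference if reference is not None else counts.index[0]
    levels = [l for l in counts.index if l != ref]
    cols = {f"{s.name or 'x'}[{l}]": (s == l).astype(float) for l in levels}
    return pd.DataFrame(cols, index=s.index)


def cca_fit(Y, X) -> CCAResult:
    """Canonical correspondence analysis of community table ``Y`` on
    constraints ``X`` (rows aligned; categoricals already dummy-coded).

    Returns the constrained eigenvalues (descending), total and constrained
    inertia, and the global pseudo-F
    ``(constrained/q) / (residual/(n − q − 1))`` with ``q = rank(X)``.
    """
    Ydf = _as_matrix(Y)
    Xdf = pd.DataFrame(X, index=Ydf.index) if not isinstance(X, pd.DataFrame) \
        else X.loc[Ydf.index]
    Ymat = Ydf.to_numpy(dtype=float)
    if (Ymat < 0).any():
        raise ValidationError("community table must be non-negative")
    row_tot = Ymat.sum(axis=1)
    if (row_tot <= 0).any():
        raise ValidationError("community table has an all-zero row")
    n, _ = Ymat.shape
    grand = Ymat.sum()
    P = Ymat / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep = c > 0
    P, c = P[:, keep], c[keep]
    E = np.outer(r, c)
    Qbar = (P - E) / np.sqrt(E)
    total_inertia = float((Qbar ** 2).sum())

    Xmat = Xdf.to_numpy(dtype=float)
    if np.isnan(Xmat).any():
        raise ValidationError("constraint matrix contains missing values")
    # weighted centring
    wmean = r @ Xmat / r.sum()
    Xc = Xmat - wmean
    sd = Xc.std(axis=0)
    const = np.where(sd < 1e-12)[0]
    if const.size:
        names = [Xdf.columns[i] for i in const]
        raise ValidationError(f"constant constraint column(s): {names}")
    Xw = np.sqrt(r)[:, None] * Xc
    q = np.linalg.matrix_rank(Xw, tol=1e-10)
    if q < Xw.shape[1]:
        # name the collinear columns: those whose removal restores full rank
        collinear = []
        for j in range(Xw.shape[1]):
            rest = np.delete(Xw, j, axis=1)
            if np.linalg.matrix_rank(rest, tol=1e-10) == q:
                collinear.append(str(Xdf.columns[j]))
        raise ValidationError(f"rank-deficient constraints; collinear "
                              f"column(s): {collinear}")
    # least-squares projection of Qbar onto span(Xw)
    coef, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    Yhat = Xw @ coef
    sv = np.linalg.svd(Yhat, compute_uv=False)
    eigvals = sv ** 2
    eigvals = eigvals[eigvals > _EIG_TOL]
    constrained = float((Yhat ** 2).sum())
    residual = total_inertia - constrained
    if n - q - 1 <= 0:
        raise ValidationError("not enough residual degrees of freedom")
    pseudo_F = (constrained / q) / max(residual, 1e-300) * (n - q - 1)
    return CCAResult(
        constrained_eigenvalues=np.sort(eigvals)[::-1],
        total_inertia=total_inertia,
        constrained_inertia=constrained,
        pseudo_F=float(pseudo_F),
        rank=int(q))


def permutation_test_factor(Y, x, nperm: int = DEFAULT_NPERM,
                            seed: int = 0) -> float:
    """Permutation p-value for one factor's association with the community.

    Soils with a missing factor value are dropped pairwise; the null is
    generated by randomly permuting the factor's soil labels; the p-value
    is ``(#{F_perm >= F_obs} + 1) / (nperm + 1)``.
    """
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    Ydf = _as_matrix(Y)
    s = pd.Series(x)
    s = s.loc[[i for i in Ydf.index if i in s.index]]
    complete = s.dropna().index
    Ysub = Ydf.loc[complete]
    Ysub = Ysub.loc[:, Ysub.sum(axis=0) > 0]
    if len(complete) < 5:
        raise ValidationError(
            f"only {len(complete)} soils with complete data (need >= 5)")
    Xobs = design_matrix(s.loc[complete])
    f_obs = cca_fit(Ysub, Xobs).pseudo_F
    rng = np.random.default_rng(seed)
    xvals = Xobs.to_numpy(dtype=float)
    exceed = 0
    for _ in range(nperm):
        perm = rng.permutation(len(complete))
        Xperm = pd.DataFrame(xvals[perm], index=complete,
                             columns=Xobs.columns)
        try:
            f_perm = cca_fit(Ysub, Xperm).pseudo_F
        except ValidationError:
            continue  # degenerate permutation (e.g. constant) counts as null
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (nperm + 1)


@dataclass
class CoherenceTable:
    """Per-factor permutation p-values across thresholds and data sets.

    ``p_values`` has factors as rows and a (data set, threshold)
    MultiIndex on columns; ``significant`` flags cells with p <= alpha;
    ``n_clusters`` records the cluster count behind each column.
    """

    p_values: pd.DataFrame
    significant: pd.DataFrame
    n_clusters: pd.Series
    alpha: float = DEFAULT_ALPHA
    nperm: int = DEFAULT_NPERM

    def to_frame(self) -> pd.DataFrame:
        out = self.p_values.copy()
        out.loc["n_clusters"] = self.n_clusters
        return out


def coherence_table(
    abundance_by_dataset: dict[str, dict[float, AbundanceMatrix]],
    env: EnvTable,
    factors: list[str] | None = None,
    nperm: int = DEFAULT_NPERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> CoherenceTable:
    """Build the coherence table: one permutation CCA p-value per factor x
    clustering threshold x data set, with cluster counts per column."""
    if factors is None:
        factors = [c for c in env.data.columns]
    cols = []
    pvals: dict[tuple[str, float], list[float]] = {}
    ncl: dict[tuple[str, float], int] = {}
    for ds, by_thresh in abundance_by_dataset.items():
        for t_i, (thresh, mat) in enumerate(sorted(
                by_thresh.items(), reverse=True)):
            key = (ds, thresh)
            cols.append(key)
            ncl[key] = len(mat.cluster_ids)
            col_p = []
            # seeds depend on threshold and factor only, so identical data
            # sets yield identical columns
            for f_i, factor in enumerate(factors):
                x = env.data[factor]
                p = permutation_test_factor(
                    mat, x, nperm=nperm,
                    seed=seed + 101 * t_i + f_i)
                col_p.append(p)
            pvals[key] = col_p
    columns = pd.MultiIndex.from_tuples(cols, names=["dataset", "threshold"])
    pdf = pd.DataFrame({k: pvals[k] for k in cols}, index=factors)
    pdf.columns = columns
    sig = pdf <= alpha
    ncl_s = pd.Series({k: ncl[k] for k in cols})
    ncl_s.index = columns
    return CoherenceTable(p_values=pdf, significant=sig, n_clusters=ncl_s,
                          alpha=alpha, nperm=nperm)


def spearman_matrix(env: EnvTable) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between numeric factors
    (pairwise-complete, ties mid-ranked); constant factors give NA."""
    factors = env.numeric_factors
    n = len(factors)
    out = pd.DataFrame(np.eye(n), index=factors, columns=factors)
    for i in range(n):
        for j in range(i + 1, n):
            a = env.data[factors[i]]
            b = env.data[factors[j]]
            mask = a.notna() & b.notna()
            if mask.sum() < 3:
                rho = np.nan
            else:
                av, bv = a[mask], b[mask]
                if av.nunique() < 2 or bv.nunique() < 2:
                    rho = np.nan
                else:
                    rho = stats.spearmanr(av, bv).statistic
            out.iloc[i, j] = out.iloc[j, i] = rho
        if env.data[factors[i]].dropna().nunique() < 2:
            out.iloc[i, i] = np.nan
    return out
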