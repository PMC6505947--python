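"""Multivariate and univariate statistics: NMDS ordination, two-factor
permutational MANOVA with interaction, Welch's t-test, per-taxon
differential abundance and group standard-deviation ellipses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist

from .community_matrix import AbundanceMatrix, DistanceMatrix
from .io_formats import SampleMetadata

__all__ = [
    "NmdsResult",
    "PermanovaTable",
    "TestResult",
    "GroupEllipse",
    "isotonic_fit",
    "nmds",
    "permanova",
    "welch_t",
    "bh_adjust",
    "differential_abundance",
    "group_ellipses",
]

logger = logging.getLogger(__name__)


@dataclass
class NmdsResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x k, centred and principal-axis rotated
    stress: float  # Kruskal stress-1 of the best start
    converged: bool
    n_starts_used: int
    stress_history: list[float] | None = None  # accepted stresses, best start


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    mean_diff: float


@dataclass
class GroupEllipse:
    group: str
    centroid: np.ndarray
    sds: np.ndarray  # SD along each principal axis, descending
    rotation: np.ndarray  # columns are principal axes


class PermanovaTable:
    """Sequential (Type-I) distance-based ANOVA table.

    ``table`` has rows for each model term plus Residual and Total, and
    columns df, SS, MS, pseudo_F, p.
    """

    def __init__(self, table: pd.DataFrame, n_perm: int):
        self.table = table
        self.n_perm = n_perm

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def to_output_frame(self) -> pd.DataFrame:
        """Columns mirroring the conventional report layout."""
        out = self.table.reset_index().rename(
            columns={
                "index": "Source",
                "df": "df",
                "MS": "Mean square",
                "pseudo_F": "Pseudo-F",
                "p": "P-value",
            }
        )
        return out[["Source", "df", "SS", "Mean square", "Pseudo-F", "P-value"]]


# ---------------------------------------------------------------------------
# isotonic regression (pool-adjacent-violators)
# ---------------------------------------------------------------------------


def isotonic_fit(values: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Least-squares non-decreasing fit by pool-adjacent-violators."""
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("isotonic_fit: empty input")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    # blocks of (mean, weight, count) merged while out of order
    means: list[float] = []
    wsum: list[float] = []
    count: list[int] = []
    for yi, wi in zip(y, w):
        means.append(float(yi))
        wsum.append(float(wi))
        count.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), wsum.pop(), count.pop()
            m1, w1, c1 = means.pop(), wsum.pop(), count.pop()
            wt = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wt)
            wsum.append(wt)
            count.append(c1 + c2)
    out = np.empty_like(y)
    pos = 0
    for m, c in zip(means, count):
        out[pos : pos + c] = m
        pos += c
    return out


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def _stress1(e: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((e**2).sum())
    if denom == 0:
        return 1.0
    return float(np.sqrt(((e - dhat) ** 2).sum() / denom))


def _nmds_single(
    d: np.ndarray, n: int, k: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, float, bool, list[float]]:
    x = rng.normal(size=(n, k))
    best_stress = np.inf
    best_x = x
    converged = False
    history: list[float] = []
    for _ in range(max_iter):
        e = pdist(x)
        if np.any(e == 0):
            e = e + 1e-12
        # Kruskal primary approach to ties: within tied observed blocks,
        # order by the current configuration distances
        order = np.lexsort((e, d))
        dhat = np.empty_like(e)
        dhat[order] = isotonic_fit(e[order])
        stress = _stress1(e, dhat)
        if stress >= best_stress - tol:
            converged = True
            break
        best_stress = stress
        best_x = x.copy()
        history.append(stress)
        # Guttman transform toward the monotone-fitted distances
        ratio = squareform(dhat / e)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = (b @ x) / n
    if not np.isfinite(best_stress):
        best_stress, best_x = stress, x
        history.append(stress)
    return best_x, float(best_stress), converged, history


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NmdsResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Multiple random starts; the lowest-stress configuration is returned,
    centred and rotated to its principal axes.
    """
    n = len(dm.ids)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    d = squareform(dm.values, checks=False)
    if np.allclose(d, d[0]):
        logger.warning("nmds: all distances equal; configuration is arbitrary")
        rng = np.random.default_rng([int(seed), 0x0D5])
        x = rng.normal(size=(n, k))
        x -= x.mean(axis=0)
        return NmdsResult(list(dm.ids), x, 1.0, False, 0, None)
    best: tuple[np.ndarray, float, bool, list[float]] | None = None
    for start in range(n_starts):
        rng = np.random.default_rng([int(seed), 0x0D5, start])
        x, stress, conv, history = _nmds_single(d, n, k, max_iter, tol, rng)
        if best is None or stress < best[1]:
            best = (x, stress, conv, history)
    x, stress, conv, history = best
    x = x - x.mean(axis=0)
    # rotate to principal axes
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    return NmdsResult(list(dm.ids), x, stress, conv, n_starts, history)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _design_columns(factors: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    cols = None
    for part in parts:
        if part not in factors.columns:
            raise ValueError(f"unknown factor {part!r} in term {term!r}")
        dummies = pd.get_dummies(factors[part], drop_first=True).to_numpy(dtype=float)
        if cols is None:
            cols = dummies
        else:
            cols = np.einsum("ij,ik->ijk", cols, dummies).reshape(len(factors), -1)
    return cols


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    dm: DistanceMatrix,
    meta: SampleMetadata | pd.DataFrame,
    terms: tuple[str, ...] = ("species", "stage", "species:stage"),
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaTable:
    """Permutational multivariate ANOVA on a distance matrix.

    Sequential (Type-I) sums of squares from the Gower-centred inner-product
    matrix projected on the factor design, in the order the terms are given;
    pseudo-F of each term against the residual mean square.  Significance by
    unrestricted permutation of sample rows; add-one p-values, so the
    smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(meta, SampleMetadata):
        factors = meta.to_dataframe().set_index("sample")
    else:
        factors = meta
    missing = [s for s in dm.ids if s not in factors.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    factors = factors.loc[list(dm.ids)]
    for term in terms:
        for part in term.split(":"):
            if factors[part].nunique() < 2:
                raise ValueError(f"factor {part!r} has a single level")
    n = len(dm.ids)
    a = -0.5 * dm.values**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    g = j @ a @ j

    # nested sequence of hat matrices: intercept, then +term1, +term2, ...
    ones = np.ones((n, 1))
    design = ones
    hats = [_hat(ones)]
    for term in terms:
        design = np.hstack([design, _design_columns(factors, term)])
        hats.append(_hat(design))
    h_full = hats[-1]
    resid_proj = np.eye(n) - h_full
    term_projs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    df_terms = [int(round(np.trace(p))) for p in term_projs]
    df_resid = int(round(np.trace(resid_proj)))
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def _stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float((p * gmat).sum()) for p in term_projs])
        ss_resid = float((resid_proj * gmat).sum())
        return ss_terms, ss_resid

    ss_terms, ss_resid = _stats(g)
    ms_terms = ss_terms / np.array(df_terms)
    ms_resid = ss_resid / df_resid
    f_obs = ms_terms / ms_resid

    rng = np.random.default_rng([int(seed), 0xBE2])
    exceed = np.zeros(len(terms))
    # tie tolerance: permutations equivalent to the identity relabelling must
    # count as >= despite float jitter in the permuted trace computation
    eps = 1e-10 * np.maximum(1.0, np.abs(f_obs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_r = _stats(gp)
        f_p = (ss_p / np.array(df_terms)) / (ss_r / df_resid)
        exceed += f_p >= f_obs - eps
    p_values = (1.0 + exceed) / (1.0 + n_perm)

    ss_total = float(np.trace(g))
    rows = {}
    for i, term in enumerate(terms):
        rows[term] = {
            "df": df_terms[i],
            "SS": ss_terms[i],
            "MS": ms_terms[i],
            "pseudo_F": f_obs[i],
            "p": p_values[i],
        }
    rows["Residual"] = {"df": df_resid, "SS": ss_resid, "MS": ms_resid,
                        "pseudo_F": np.nan, "p": np.nan}
    rows["Total"] = {"df": n - 1, "SS": ss_total, "MS": np.nan,
                     "pseudo_F": np.nan, "p": np.nan}
    return PermanovaTable(pd.DataFrame(rows).T, n_perm)


# ---------------------------------------------------------------------------
# Welch's t-test and differential abundance
# ---------------------------------------------------------------------------


def welch_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Welch's two-sample t-test with Welch-Satterthwaite degrees of freedom
    and a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, 0.0)
        raise ValueError("both group variances are zero")
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * t_dist.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), float(x.mean() - y.mean()))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj


def differential_abundance(
    rel: AbundanceMatrix,
    meta: SampleMetadata,
    species: str,
    min_prevalence: float = 0.1,
) -> pd.DataFrame:
    """Per-taxon Welch's t-test of feeding vs moulting proportions within one
    species, with Benjamini-Hochberg adjustment.

    ``rel`` holds per-sample proportions (typically rank-aggregated).  Taxa
    present in fewer than ``min_prevalence`` of the species' samples are
    skipped (logged).  Returns a DataFrame with columns taxon,
    mean_feeding, mean_moulting, t, df, p, p_adj.
    """
    meta.require(rel.sample_ids)
    feeding = [s for s in rel.sample_ids
               if meta.species(s) == species and meta.stage(s) == "feeding"]
    moulting = [s for s in rel.sample_ids
                if meta.species(s) == species and meta.stage(s) == "moulting"]
    if len(feeding) < 2 or len(moulting) < 2:
        raise ValueError(f"need >= 2 samples per stage for species {species!r}")
    df_rel = rel.to_dataframe()
    sub = df_rel.loc[feeding + moulting]
    rows = []
    skipped = []
    for taxon in rel.taxon_ids:
        col = sub[taxon].to_numpy()
        if (col > 0).mean() < min_prevalence:
            skipped.append(taxon)
            continue
        x = df_rel.loc[feeding, taxon].to_numpy()
        y = df_rel.loc[moulting, taxon].to_numpy()
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
            res = TestResult(0.0, float(len(x) + len(y) - 2), 1.0, 0.0)
        else:
            res = welch_t(x, y)
        rows.append(
            {
                "taxon": taxon,
                "mean_feeding": x.mean(),
                "mean_moulting": y.mean(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "mean_diff": res.mean_diff,
            }
        )
    if skipped:
        logger.info(
            "differential_abundance: skipped %d low-prevalence taxa", len(skipped)
        )
    out = pd.DataFrame(
        rows,
        columns=["taxon", "mean_feeding", "mean_moulting", "t", "df", "p", "mean_diff"],
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = []
    return out


# ---------------------------------------------------------------------------
# group ellipses
# ---------------------------------------------------------------------------


def group_ellipses(result: NmdsResult, meta: SampleMetadata) -> list[GroupEllipse]:
    """Per-group centroid and 1-SD covariance ellipse in ordination space.

    Groups with fewer than 3 samples are skipped with a warning.
    """
    meta.require(result.sample_ids)
    idx = {s: i for i, s in enumerate(result.sample_ids)}
    out = []
    for label, members in meta.groups().items():
        members = [s for s in members if s in idx]
        if len(members) < 3:
            logger.warning("group_ellipses: group %s has < 3 samples; skipped", label)
            continue
        pts = result.scores[[idx[s] for s in members]]
        centroid = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(cov))
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        out.append(GroupEllipse(label, centroid, np.sqrt(eigvals), eigvecs[:, order]))
    return out
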