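"""Trait-analysis statistics for the 23-trait texture panel.

Given a table of texture-trait instances (rows = images, columns = the
23 traits plus a condition label), this layer provides:

* pairwise correlation matrices (Pearson / Spearman / Kendall) with a
  range-based categorization of each trait (a trait belongs to a range
  category if at least one of its off-diagonal correlations falls in
  that range; the printed ranges overlap, so multiple membership is
  expected and allowed);
* data-suitability checks for factor analysis — the Kaiser-Meyer-Olkin
  (KMO) measure of sampling adequacy and Bartlett's test of sphericity
  (full factor analysis is deliberately not performed);
* agglomerative hierarchical clustering of the traits themselves
  (columns as points, z-scored instances as coordinates, squared
  Euclidean distances) under seven linkage rules, with an SPSS-style
  agglomeration schedule and a cross-linkage membership comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

logger = logging.getLogger(__name__)

#: Correlation-range categories: label -> (lo, hi), inclusive.
CORRELATION_RANGES = {
    "A": (-1.0, 0.09),
    "B": (0.0, 0.49),
    "C": (0.5, 0.89),
    "D": (0.9, 1.0),
}

#: The seven linkage rules compared in the membership analysis.
LINKAGE_METHODS = ("between", "within", "centroid", "furthest",
                   "median", "nearest", "ward")

# scipy names for the rules it implements directly on a squared-Euclidean
# condensed matrix (combinatorial Lance-Williams updates).
_SCIPY_ON_SQDIST = {"nearest": "single", "furthest": "complete",
                    "between": "average"}
# rules scipy implements on raw observations with Euclidean geometry;
# their coefficients are squared to stay on the squared-Euclidean scale.
_SCIPY_ON_POINTS = {"centroid": "centroid", "median": "median",
                    "ward": "ward"}


@dataclass
class CorrelationSummary:
    method: str
    matrix: pd.DataFrame
    #: range label -> sorted list of trait names with >= 1 off-diagonal
    #: correlation in the range (overlap between categories allowed)
    categories: dict[str, list[str]]
    #: traits whose correlations are undefined (constant columns)
    flagged: list[str] = field(default_factory=list)
    membership_rule: str = ("trait listed in a range iff at least one "
                            "off-diagonal correlation falls in it")


def _trait_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the condition label; keep the numeric trait columns."""
    return table.drop(columns=["condition"], errors="ignore")


def correlations(table: pd.DataFrame, method: str = "pearson",
                 ) -> CorrelationSummary:
    """Pairwise trait correlations plus range categorization.

    Parameters
    ----------
    table : pandas.DataFrame
        Trait instances; a ``condition`` column is ignored.
    method : {"pearson", "spearman", "kendall"}

    Constant columns yield undefined correlations; they are flagged and
    excluded from categorization rather than raising.
    """
    data = _trait_frame(table)
    if len(data) < 3:
        raise ValueError("correlation analysis needs at least 3 instances")
    if method not in ("pearson", "spearman", "kendall"):
        raise ValueError(f"unknown correlation method {method!r}")
    flagged = [c for c in data.columns if data[c].nunique() <= 1]
    if flagged:
        logger.warning("constant columns flagged (correlations undefined): %s",
                       flagged)
    corr = data.corr(method=method)
    off = corr.where(~np.eye(len(corr), dtype=bool))
    categories = {}
    for label, (lo, hi) in CORRELATION_RANGES.items():
        hits = off.apply(lambda col: ((col >= lo) & (col <= hi)).any())
        categories[label] = sorted(c for c in corr.columns
                                   if hits[c] and c not in flagged)
    return CorrelationSummary(method=method, matrix=corr,
                              categories=categories, flagged=flagged)


def kmo(table: pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum u_ij^2) over i != j, where u
    are the anti-image partial correlations obtained from the inverse
    correlation matrix.  Values near 1 indicate the traits share enough
    common variance for factor analysis; for exactly two variables the
    partials equal the correlations and KMO is 0.5.

    Raises
    ------
    ValueError
        If the correlation matrix is singular.
    """
    r = _trait_frame(table).corr().to_numpy()
    if not np.all(np.isfinite(r)):
        raise ValueError("correlation matrix contains undefined entries")
    try:
        inv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = np.sum(r[off] ** 2)
    u2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + u2))


def bartlett_sphericity(table: pd.DataFrame) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5) / 6) * ln det(R), df = p(p-1)/2, with n
    instances and p traits; the p-value comes from the chi-square
    survival function.

    Returns
    -------
    (chi2, df, p_value)
    """
    data = _trait_frame(table)
    n, p = data.shape
    if n <= p:
        raise ValueError(f"need more instances ({n}) than traits ({p})")
    r = data.corr().to_numpy()
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(stat), int(df), float(chi2.sf(stat, df))


def _zscore_columns(data: pd.DataFrame) -> np.ndarray:
    """Variables as points: (p, n) array of z-scored columns."""
    x = data.to_numpy(dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return ((x - mu) / sd).T


def _within_groups_linkage(d: np.ndarray) -> np.ndarray:
    """Within-groups average linkage on a square dissimilarity matrix.

    Merges the pair of clusters minimizing the mean of all pairwise
    dissimilarities inside the merged cluster.  Returns a scipy-style
    (n-1, 4) linkage matrix whose coefficient is that mean.
    """
    n = d.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    within_sum = {i: 0.0 for i in range(n)}  # sum of pairwise dists inside
    z = np.zeros((n - 1, 4))
    next_id = n
    for stage in range(n - 1):
        best = None
        ids = sorted(members)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                cross = d[np.ix_(members[a], members[b])].sum()
                m = len(members[a]) + len(members[b])
                total = within_sum[a] + within_sum[b] + cross
                avg = total / (m * (m - 1) / 2.0)
                if best is None or avg < best[0]:
                    best = (avg, a, b, total)
        avg, a, b, total = best
        z[stage] = (a, b, avg, len(members[a]) + len(members[b]))
        members[next_id] = members.pop(a) + members.pop(b)
        within_sum[next_id] = total
        within_sum.pop(a, None)
        within_sum.pop(b, None)
        next_id += 1
    return z


def _linkage_matrix(points: np.ndarray, method: str) -> np.ndarray:
    """scipy-format linkage for one of the seven rules.

    Coefficients are on the squared-Euclidean scale for every rule.
    """
    if method in _SCIPY_ON_SQDIST:
        return scipy_linkage(pdist(points, metric="sqeuclidean"),
                             method=_SCIPY_ON_SQDIST[method])
    if method in _SCIPY_ON_POINTS:
        z = scipy_linkage(points, method=_SCIPY_ON_POINTS[method])
        z = z.copy()
        z[:, 2] **= 2
        return z
    if method == "within":
        return _within_groups_linkage(
            squareform(pdist(points, metric="sqeuclidean")))
    raise ValueError(f"unknown linkage method {method!r}; "
                     f"expected one of {LINKAGE_METHODS}")


def _schedule_from_linkage(z: np.ndarray, n: int) -> pd.DataFrame:
    """SPSS-style agglomeration schedule from a scipy linkage matrix.

    Clusters are labelled by their lowest-numbered member (1-based);
    ``first_appearance_*`` is the earlier stage at which that cluster
    was formed (0 for singletons) and ``next_stage`` the stage at which
    the merged cluster is used again (0 if final).
    """
    rep = {i: i + 1 for i in range(n)}       # cluster id -> 1-based label
    formed = {i: 0 for i in range(n)}        # cluster id -> stage formed
    rows = []
    for stage, (a, b, coeff, _size) in enumerate(z, start=1):
        a, b = int(a), int(b)
        la, lb = rep[a], rep[b]
        c1, c2 = min(la, lb), max(la, lb)
        fa = formed[a] if la == c1 else formed[b]
        fb = formed[b] if la == c1 else formed[a]
        new_id = n + stage - 1
        rep[new_id] = c1
        formed[new_id] = stage
        rows.append({"stage": stage, "cluster_1": c1, "cluster_2": c2,
                     "coefficient": float(coeff),
                     "first_appearance_1": fa, "first_appearance_2": fb,
                     "next_stage": 0})
    # next_stage: first later stage whose inputs include the cluster formed here
    for stage, (a, b, *_rest) in enumerate(z, start=1):
        for src in (int(a), int(b)):
            if src >= n:
                rows[src - n]["next_stage"] = stage
    return pd.DataFrame(rows)


def _canonical_membership(labels: np.ndarray, names) -> pd.Series:
    """Relabel cluster ids by first appearance in variable order."""
    mapping, out = {}, []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out.append(mapping[lab])
    return pd.Series(out, index=list(names), name="cluster")


def agglomerate(table: pd.DataFrame, method: str = "nearest", k: int = 3,
                ) -> tuple[pd.DataFrame, pd.Series]:
    """Cluster the traits bottom-up under one linkage rule.

    The instances are z-scored per trait, each trait becomes a point
    whose coordinates are its instance values, and pairwise squared
    Euclidean distances drive the agglomeration.

    Parameters
    ----------
    table : pandas.DataFrame
        Trait instances (a ``condition`` column is ignored).
    method : str
        One of ``LINKAGE_METHODS``: between(-groups average), within
        (-groups average), centroid, furthest, median, nearest, ward.
    k : int
        Number of clusters at which to cut the tree.

    Returns
    -------
    (schedule, membership)
        The stage-wise merge schedule and a trait -> cluster-id series
        (ids canonicalized by first appearance).
    """
    data = _trait_frame(table)
    p = data.shape[1]
    if p < k:
        raise ValueError(f"cannot form {k} clusters from {p} traits")
    points = _zscore_columns(data)
    z = _linkage_matrix(points, method)
    schedule = _schedule_from_linkage(z, p)
    labels = fcluster(z, t=k, criterion="maxclust")
    return schedule, _canonical_membership(labels, data.columns)


def compare_linkages(table: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Trait-by-linkage membership comparison across all seven rules.

    Returns a DataFrame indexed by trait with one column per linkage
    method; cluster ids are canonicalized by first appearance so that
    agreeing methods produce identical columns.
    """
    cols = {}
    for method in LINKAGE_METHODS:
        _, membership = agglomerate(table, method=method, k=k)
        cols[method] = membership
    return pd.DataFrame(cols)
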