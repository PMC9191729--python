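"""Community-matrix preprocessing and permutation statistics.

Covers the standard toolbox for plot x taxon percent-cover matrices from
road-gradient vegetation surveys: the log10 cover transform that maps
zero to zero, rare-taxon / empty-plot filtering, Sorenson (quantitative
Bray-Curtis) and Euclidean distance matrices, mean-distance outlier
screening, multi-response permutation procedures (MRPP), Dufrene-Legendre
indicator species analysis (IndVal), relativization by species maximum,
orthogonal rotation of ordination scores toward a target variable, axis
overlay correlations, and per-distance-class covariate summaries.

Community matrices are pandas DataFrames indexed by plot_id with taxon
columns.  The nonmetric-MDS embedding itself is consumed, not computed:
ordination scores come in as a plots x axes table from any NMS
implementation and only the rotation/overlay steps are performed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, spearmanr

log = logging.getLogger("dustshed")

#: Permutation tests switch to complete enumeration at or below this many
#: distinct label assignments.
EXHAUSTIVE_LIMIT = 10_000


# ---------------------------------------------------------------------------
# transforms and filters
# ---------------------------------------------------------------------------

def transform_cover(x):
    """log10(x + 0.01) + 2 applied elementwise; maps 0 exactly to 0.

    A cover of 0 gives log10(0.01) + 2 = 0, so absences stay absences
    while positive covers are compressed onto a roughly linear scale.
    """
    arr = np.asarray(x, dtype=float) if not isinstance(x, pd.DataFrame) else x
    if np.any(np.asarray(arr, dtype=float) < 0):
        raise ValueError("cover values must be >= 0")
    out = np.log10(arr + 0.01) + 2.0
    if isinstance(x, pd.DataFrame):
        return out
    return out if np.ndim(x) else float(out)


def filter_matrix(
    m: pd.DataFrame, min_occurrences: int = 1, drop_empty_plots: bool = True
) -> pd.DataFrame:
    """Drop empty plots, then taxa occurring in <= min_occurrences plots.

    Plots are removed before taxa (matching the field protocol for the
    107 x 113 lichen matrix, where 3 empty plots and then 22 taxa with one
    or fewer occurrences were deleted).  No cascade: plots emptied by the
    taxon deletion are kept.
    """
    if min_occurrences < 0:
        raise ValueError("min_occurrences must be >= 0")
    out = m
    if drop_empty_plots:
        empty = out.sum(axis=1) == 0
        if empty.any():
            log.info("dropping %d empty plot(s): %s", empty.sum(), list(out.index[empty]))
            out = out.loc[~empty]
    occurrences = (out > 0).sum(axis=0)
    rare = occurrences <= min_occurrences
    if rare.any():
        log.info("dropping %d rare taxa (<= %d occurrences)", rare.sum(), min_occurrences)
        out = out.loc[:, ~rare]
    if out.shape[1] == 0 or (out.to_numpy().sum() == 0):
        raise ValueError("community matrix is empty after filtering")
    return out


def relativize_by_max(m: pd.DataFrame) -> pd.DataFrame:
    """Divide each taxon column by its maximum so column maxima become 1."""
    col_max = m.max(axis=0)
    if (col_max <= 0).any():
        bad = list(col_max.index[col_max <= 0])
        raise ValueError(f"all-zero taxon columns (filter first): {bad}")
    return m / col_max


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    plot_ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal
    method: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.plot_ids), len(self.plot_ids)):
            raise ValueError("distance matrix shape does not match plot ids")
        if not np.allclose(v, v.T, atol=1e-12) or np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def distance_matrix(m: pd.DataFrame, method: str = "sorenson") -> DistanceMatrix:
    """Pairwise plot dissimilarities.

    ``sorenson`` is the quantitative Bray-Curtis form sum|a-b| / sum(a+b),
    bounded in [0, 1]; it is undefined for a pair of empty plots, so empty
    plots must be removed first (Euclidean distance permits them).
    """
    X = m.to_numpy(dtype=float)
    if method == "sorenson":
        empty = X.sum(axis=1) == 0
        if empty.any():
            raise ValueError(
                f"Sorenson distance undefined with empty plots: {list(m.index[empty])}"
            )
        d = pdist(X, metric="braycurtis")
    elif method == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown method {method!r}")
    return DistanceMatrix(list(m.index), squareform(d), method)


def detect_outliers(d: DistanceMatrix, sd_threshold: float = 2.0) -> list[str]:
    """Plots whose mean distance to all others exceeds mean + t * SD.

    The screen used before ordination: a plot is an outlier when its
    average dissimilarity to every other plot is more than ``sd_threshold``
    standard deviations above the grand mean of those plot averages.
    """
    n = len(d.plot_ids)
    if n < 3:
        raise ValueError("need at least 3 plots for outlier screening")
    mean_d = (d.values.sum(axis=1)) / (n - 1)
    sd = mean_d.std(ddof=1)
    if sd == 0.0:
        return []
    cut = mean_d.mean() + sd_threshold * sd
    return [pid for pid, v in zip(d.plot_ids, mean_d) if v > cut]


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _group_info(groups) -> tuple[np.ndarray, list, np.ndarray]:
    labels = np.asarray(groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    return codes, list(uniq), sizes


def _n_assignments(sizes: np.ndarray) -> int:
    total = math.factorial(int(sizes.sum()))
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _enumerate_assignments(sizes: np.ndarray):
    """Yield every distinct assignment of coded labels to positions."""
    n = int(sizes.sum())

    def rec(positions: tuple, group: int):
        if group == len(sizes) - 1:
            lab = np.empty(n, dtype=int)
            lab[list(positions)] = group  # remaining positions
            yield positions, lab
            return
        for chosen in combinations(positions, int(sizes[group])):
            remaining = tuple(p for p in positions if p not in set(chosen))
            for _, lab in rec(remaining, group + 1):
                lab[list(chosen)] = group
                yield chosen, lab

    for _, lab in rec(tuple(range(n)), 0):
        yield lab


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------

@dataclass
class MrppResult:
    """Chance-corrected within-group agreement A = 1 - delta_obs/delta_exp."""

    A: float
    delta_observed: float
    delta_expected: float
    p: float
    n_permutations: int
    exhaustive: bool = False
    group_labels: list = field(default_factory=list)


def _mrpp_delta(D: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    delta = 0.0
    N = codes.size
    for g, ng in enumerate(sizes):
        idx = np.flatnonzero(codes == g)
        sub = D[np.ix_(idx, idx)]
        delta += (ng / N) * (sub.sum() / (ng * (ng - 1)))
    return delta


def mrpp(
    d: DistanceMatrix, groups, n_permutations: int = 4_999, seed: int = 0
) -> MrppResult:
    """Multi-response permutation procedure with group weights n_i/N.

    delta is the weighted mean within-group dissimilarity; its null
    distribution comes from relabelling plots (complete enumeration when
    there are at most 10,000 distinct assignments, otherwise seeded Monte
    Carlo with the +1 correction).  A > 0 means plots agree within groups
    more than chance; the p-value is the fraction of relabellings at least
    as concentrated (delta <= observed).
    """
    codes, uniq, sizes = _group_info(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sizes < 2):
        small = [u for u, s in zip(uniq, sizes) if s < 2]
        raise ValueError(f"groups of size 1 not allowed: {small}")
    D = d.values
    delta_obs = _mrpp_delta(D, codes, sizes)

    total = _n_assignments(sizes)
    if total <= EXHAUSTIVE_LIMIT:
        deltas = np.array(
            [_mrpp_delta(D, lab, sizes) for lab in _enumerate_assignments(sizes)]
        )
        delta_exp = float(deltas.mean())
        p = float(np.mean(deltas <= delta_obs + 1e-12))
        n_perm, exhaustive = total, True
    else:
        rng = np.random.default_rng(seed)
        deltas = np.empty(n_permutations)
        perm = codes.copy()
        for i in range(n_permutations):
            rng.shuffle(perm)
            deltas[i] = _mrpp_delta(D, perm, sizes)
        delta_exp = float(deltas.mean())
        p = float((np.sum(deltas <= delta_obs + 1e-12) + 1) / (n_permutations + 1))
        n_perm, exhaustive = n_permutations, False

    A = 1.0 - delta_obs / delta_exp if delta_exp > 0 else 1.0
    return MrppResult(A, delta_obs, delta_exp, p, n_perm, exhaustive, uniq)


def mrpp_pairwise(
    d: DistanceMatrix, groups, n_permutations: int = 4_999, seed: int = 0
) -> pd.DataFrame:
    """MRPP A and p for every pair of groups (the pairwise-comparison table)."""
    labels = np.asarray(groups)
    uniq = list(pd.unique(labels))
    rows = []
    for i, ga in enumerate(uniq):
        for gb in uniq[i + 1 :]:
            mask = (labels == ga) | (labels == gb)
            sub_ids = [pid for pid, m in zip(d.plot_ids, mask) if m]
            sub = DistanceMatrix(sub_ids, d.values[np.ix_(mask, mask)], d.method)
            res = mrpp(sub, labels[mask], n_permutations, seed)
            rows.append({"group_a": ga, "group_b": gb, "A": res.A, "p": res.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# indicator species analysis
# ---------------------------------------------------------------------------

@dataclass
class IsaResult:
    """Per-taxon indicator values (Dufrene-Legendre IndVal, stored in [0,1])."""

    table: pd.DataFrame  # index taxon; columns indval, group, p
    indval_matrix: pd.DataFrame  # taxa x groups
    n_permutations: int
    exhaustive: bool = False


def _indval_matrix(X: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """IndVal_jk = relative mean abundance x relative frequency, (taxa, groups)."""
    n_taxa = X.shape[1]
    means = np.empty((n_groups, n_taxa))
    freqs = np.empty((n_groups, n_taxa))
    for g in range(n_groups):
        sub = X[codes == g]
        means[g] = sub.mean(axis=0)
        freqs[g] = (sub > 0).mean(axis=0)
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ra = np.where(denom > 0, means / np.where(denom > 0, denom, 1.0), 0.0)
    return (ra * freqs).T


def indicator_species_analysis(
    m: pd.DataFrame, groups, n_permutations: int = 4_999, seed: int = 0
) -> IsaResult:
    """Indicator species analysis over plot groups.

    For each taxon the reported indicator value is the maximum over groups
    of (relative abundance x relative frequency); significance comes from
    permuting plot labels, with the same enumeration rule as
    :func:`mrpp` and p = (count of permuted maxima >= observed + 1) /
    (n + 1) under Monte Carlo.
    """
    codes, uniq, sizes = _group_info(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sizes == 0):
        raise ValueError("empty group")
    X = m.to_numpy(dtype=float)
    iv = _indval_matrix(X, codes, len(uniq))
    obs = iv.max(axis=1)
    best = np.asarray(uniq, dtype=object)[iv.argmax(axis=1)]

    total = _n_assignments(sizes)
    if total <= EXHAUSTIVE_LIMIT:
        count = np.zeros(X.shape[1])
        for lab in _enumerate_assignments(sizes):
            stat = _indval_matrix(X, lab, len(uniq)).max(axis=1)
            count += stat >= obs - 1e-12
        p = count / total
        n_perm, exhaustive = total, True
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(X.shape[1])
        perm = codes.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            stat = _indval_matrix(X, perm, len(uniq)).max(axis=1)
            count += stat >= obs - 1e-12
        p = (count + 1) / (n_permutations + 1)
        n_perm, exhaustive = n_permutations, False

    table = pd.DataFrame(
        {"indval": obs, "group": best, "p": p}, index=m.columns
    )
    ivm = pd.DataFrame(iv, index=m.columns, columns=uniq)
    return IsaResult(table, ivm, n_perm, exhaustive)


# ---------------------------------------------------------------------------
# ordination overlays
# ---------------------------------------------------------------------------

def _corr_with(scores: np.ndarray, u: np.ndarray, target: np.ndarray) -> float:
    v = scores @ u
    sv = v.std()
    if sv == 0:
        return 0.0
    return float(np.dot(v - v.mean(), target - target.mean()) / (len(v) * sv * target.std()))


def rotate_scores(scores: pd.DataFrame, target) -> pd.DataFrame:
    """Orthogonally rotate ordination scores so axis 1 tracks a target.

    Finds the direction in axis space whose scores correlate maximally (in
    absolute value) with the target variable, makes it the new axis 1, and
    completes the rotation with an orthonormal basis.  Being a rotation it
    preserves all inter-plot distances; the target must not be constant.
    """
    S = scores.to_numpy(dtype=float)
    if S.shape[1] < 2:
        raise ValueError("need at least 2 axes to rotate")
    t = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("target must be finite")
    if t.std() == 0:
        raise ValueError("target is constant; correlation undefined")

    k = S.shape[1]
    Sc = S - S.mean(axis=0)
    starts = [np.eye(k)[i] for i in range(k)]
    lstsq = np.linalg.lstsq(Sc, t - t.mean(), rcond=None)[0]
    if np.linalg.norm(lstsq) > 0:
        starts.append(lstsq / np.linalg.norm(lstsq))

    def neg_abs_corr(v):
        nv = np.linalg.norm(v)
        if nv == 0:
            return 0.0
        return -abs(_corr_with(Sc, v / nv, t))

    best_u, best_val = None, np.inf
    for s0 in starts:
        res = minimize(neg_abs_corr, s0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if res.fun < best_val:
            best_val, best_u = res.fun, res.x / np.linalg.norm(res.x)
    if _corr_with(Sc, best_u, t) < 0:
        best_u = -best_u

    # complete best_u to an orthonormal basis (QR on [u | identity])
    M = np.column_stack([best_u, np.eye(k)])
    Q, _ = np.linalg.qr(M)
    Q[:, 0] *= np.sign(Q[:, 0] @ best_u)  # keep axis 1 aligned with u
    rotated = S @ Q
    return pd.DataFrame(
        rotated, index=scores.index, columns=[f"axis{i + 1}" for i in range(k)]
    )


def axis_correlations(
    scores: pd.DataFrame, covariates: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Rank correlations of every covariate with every ordination axis.

    Missing covariate entries are dropped pairwise; entries with fewer
    than 3 paired observations are reported as NaN.
    """
    if method != "spearman":
        raise ValueError("only spearman correlations are supported")
    cov = covariates.loc[scores.index]
    out = pd.DataFrame(index=cov.columns, columns=scores.columns, dtype=float)
    for c in cov.columns:
        x = pd.to_numeric(cov[c], errors="coerce")
        for a in scores.columns:
            mask = x.notna() & scores[a].notna()
            if mask.sum() < 3:
                out.loc[c, a] = np.nan
                continue
            out.loc[c, a] = spearmanr(x[mask], scores.loc[mask, a]).statistic
    return out


# ---------------------------------------------------------------------------
# per-class summaries
# ---------------------------------------------------------------------------

def summarize_by_class(
    table: pd.DataFrame, variable: str, edges
) -> tuple[pd.DataFrame, dict | None]:
    """Per-distance-class mean, SE and n, plus one-way ANOVA across classes.

    SE is SD/sqrt(n).  ANOVA needs at least two classes with two or more
    plots; otherwise only the summary table is returned (ANOVA None).
    Empty classes are omitted with a warning.
    """
    from .io import distance_class, class_labels

    cls = distance_class(table["dist_road"].to_numpy(), edges)
    labels = class_labels(edges)
    x = pd.to_numeric(table[variable], errors="coerce")
    rows, samples = [], []
    for c, lab in enumerate(labels):
        vals = x[(cls == c) & x.notna()]
        if len(vals) == 0:
            log.warning("distance class %s is empty for %r; omitted", lab, variable)
            continue
        rows.append(
            {
                "class": lab,
                "n": len(vals),
                "mean": vals.mean(),
                "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
            }
        )
        if len(vals) >= 2:
            samples.append(vals.to_numpy())
    summary = pd.DataFrame(rows)
    anova = None
    if len(samples) >= 2:
        F, p = f_oneway(*samples)
        k = len(samples)
        n_tot = sum(len(s) for s in samples)
        anova = {"F": float(F), "p": float(p), "df_between": k - 1, "df_within": n_tot - k}
    return summary, anova
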