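"""Longitudinal study statistics.

Implements the analysis applied to the animal study table:

* a three-way mixed-design (repeated-measures) ANOVA with time and
  measurement side as within-subject factors and group as the
  between-subjects factor, on the complete-timepoint subset;
* Mauchly's sphericity test per within effect;
* Tukey HSD pairwise comparisons of the time means;
* the per-animal-per-day heart-rate/blood-flow confound correlation;
* Ward hierarchical clustering of experimental-animal BF time courses with
  an elbow choice of k, confirmatory k-means, and row-order stability checks.

ANOVA machinery
---------------
The design is balanced within subjects (one value per animal x day x side
after repeat aggregation) but the groups may have unequal sizes.  Each
within-subject stratum is isolated by orthonormal (Helmert) contrasts of the
subject-level cell means; within every stratum the group structure is tested
with SPSS-style Type III (unweighted-means) sums of squares, which reproduces
the reference degrees-of-freedom structure -- e.g. (1, 10) for between and
(5, 50) for time effects in a 12-subject, 6-timepoint, 2-side design.  With
unequal group sizes the unweighted-means SS of a within-effect main is not
additive with its stratum total (standard for Type III); with equal sizes the
full decomposition is exactly additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import helmert
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .dtof import InputError
from .perfusion import aggregate_measurements


# ---------------------------------------------------------------------------
# table preparation


def complete_timepoints(table: pd.DataFrame) -> list:
    """Days on which every animal in the table has at least one measurement."""
    animals = set(table["animal"].unique())
    days = []
    for day, sub in table.groupby("day", sort=False):
        if set(sub["animal"].unique()) == animals:
            days.append((sub["day_num"].iloc[0] if "day_num" in sub else 0, day))
    days.sort()
    return [d for _, d in days]


def _pivot_balanced(table: pd.DataFrame) -> tuple[np.ndarray, list, list, np.ndarray, list]:
    """Aggregate repeats and pivot to Y[subject, time, side] over complete days.

    Returns (Y, subjects, days, group_labels, sides).  Raises if any cell is
    empty after restriction to complete timepoints.
    """
    agg = aggregate_measurements(table)
    days = complete_timepoints(agg)
    if len(days) < 2:
        raise InputError("need at least two complete timepoints")
    sub = agg[agg["day"].isin(days)]
    sides = sorted(sub["side"].unique())
    subjects = sorted(sub["animal"].unique())
    groups = sub.drop_duplicates("animal").set_index("animal")["group"]
    wide = sub.pivot_table(index="animal", columns=["day", "side"], values="bf", aggfunc="mean")
    try:
        wide = wide.reindex(index=subjects)[[(d, s) for d in days for s in sides]]
    except KeyError as e:
        raise InputError(
            "unbalanced design: some animal x day x side cell is empty; aggregate "
            "repeats and restrict to complete timepoints first"
        ) from e
    if wide.isna().any().any():
        raise InputError(
            "unbalanced design: some animal x day x side cell is empty; aggregate "
            "repeats and restrict to complete timepoints first"
        )
    y = wide.to_numpy().reshape(len(subjects), len(days), len(sides))
    return y, subjects, days, groups.loc[subjects].to_numpy(), sides


def _effects_coding(group_labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(group_labels))
    g = len(levels)
    E = np.zeros((group_labels.size, g - 1))
    for j, lev in enumerate(levels[:-1]):
        E[:, j] = np.where(group_labels == lev, 1.0, 0.0)
    E[np.isin(group_labels, [levels[-1]])] = -1.0
    return E, levels


def _ssres(X: np.ndarray, Z: np.ndarray) -> float:
    """Summed squared residuals of least-squares fits of each column of Z on X."""
    if X.size == 0:
        return float(np.sum(Z**2))
    _, res, rank, _ = np.linalg.lstsq(X, Z, rcond=None)
    if res.size == Z.shape[1] and rank == X.shape[1]:
        return float(res.sum())
    fitted = X @ np.linalg.lstsq(X, Z, rcond=None)[0]
    return float(np.sum((Z - fitted) ** 2))


def _type3_stratum(scores: np.ndarray, group_labels: np.ndarray) -> tuple[float, float, float]:
    """(SS_constant, SS_group, SS_error) for one within-subject stratum.

    ``scores`` is n_subjects x n_contrasts.  The constant term tests the
    within-effect main (unweighted across groups); the group term tests its
    interaction with group; the residual is the stratum error.
    """
    Z = np.atleast_2d(scores.T).T
    n = Z.shape[0]
    ones = np.ones((n, 1))
    E, _ = _effects_coding(group_labels)
    full = np.hstack([ones, E])
    ss_full = _ssres(full, Z)
    ss_const = _ssres(E, Z) - ss_full
    ss_group = _ssres(ones, Z) - ss_full
    return max(ss_const, 0.0), max(ss_group, 0.0), ss_full


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effect, ss, df1, df2, ms, f, p, partial_eta_sq, error stratum
    mauchly: dict  # within effect -> dict(W, chi2, df, p)
    shapiro_p: float
    n_subjects: int
    group_sizes: dict
    days: list
    sides: list
    ss_total: float
    ss_decomposition_sum: float


def _f_row(effect, ss, df1, ss_err, df_err, stratum, ss_floor=0.0):
    # SS below the numerical floor (round-off on constant data) count as zero
    ss = 0.0 if ss < ss_floor else ss
    ss_err = 0.0 if ss_err < ss_floor else ss_err
    ms = ss / df1 if df1 > 0 else np.nan
    mse = ss_err / df_err if df_err > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms / mse if mse and mse > 0 else np.nan
        p = float(stats.f.sf(f, df1, df_err)) if np.isfinite(f) else np.nan
        pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else np.nan
    return dict(
        effect=effect, ss=ss, df1=df1, df2=df_err, ms=ms, F=f, p=p,
        partial_eta_sq=pes, error_ss=ss_err, stratum=stratum,
    )


def rm_anova(table: pd.DataFrame) -> AnovaResult:
    """Three-way mixed ANOVA (time x side within, group between) on a study table.

    Repeats are aggregated per ankle-day first; analysis is restricted to
    timepoints with data from every animal.  Zero-variance data yields zero
    effect SS and undefined (NaN) F ratios rather than an error.
    """
    y, subjects, days, groups, sides = _pivot_balanced(table)
    n, T, D = y.shape
    g = len(set(groups))
    if n <= g:
        raise InputError("need more subjects than groups")

    C_T = helmert(T, full=False)  # (T-1, T) orthonormal, orthogonal to constant
    C_D = helmert(D, full=False)

    # between stratum: subject means scaled to the univariate metric
    b = np.sqrt(T * D) * y.mean(axis=(1, 2))[:, None]
    _, ss_group, ss_subj = _type3_stratum(b, groups)

    # time stratum: contrasts of side-averaged time means
    u_t = np.sqrt(D) * (y.mean(axis=2) @ C_T.T)
    ss_time, ss_tg, ss_err_t = _type3_stratum(u_t, groups)

    # side stratum
    u_d = np.sqrt(T) * (y.mean(axis=1) @ C_D.T)
    ss_side, ss_sg, ss_err_d = _type3_stratum(u_d, groups)

    # time x side stratum
    u_td = np.einsum("jt,std,ld->sjl", C_T, y, C_D).reshape(n, (T - 1) * (D - 1))
    ss_ts, ss_tsg, ss_err_td = _type3_stratum(u_td, groups)

    floor = y.size * (1e-10 * max(1.0, float(np.abs(y).max()))) ** 2
    rows = [
        _f_row("group", ss_group, g - 1, ss_subj, n - g, "between", floor),
        _f_row("time", ss_time, T - 1, ss_err_t, (T - 1) * (n - g), "time", floor),
        _f_row("time*group", ss_tg, (T - 1) * (g - 1), ss_err_t, (T - 1) * (n - g), "time", floor),
        _f_row("side", ss_side, D - 1, ss_err_d, (D - 1) * (n - g), "side", floor),
        _f_row("group*side", ss_sg, (D - 1) * (g - 1), ss_err_d, (D - 1) * (n - g), "side", floor),
        _f_row("time*side", ss_ts, (T - 1) * (D - 1), ss_err_td,
               (T - 1) * (D - 1) * (n - g), "time*side", floor),
        _f_row("time*group*side", ss_tsg, (T - 1) * (D - 1) * (g - 1), ss_err_td,
               (T - 1) * (D - 1) * (n - g), "time*side", floor),
    ]
    result = pd.DataFrame(rows)

    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_sum = float(
        result["ss"].sum() + ss_subj + ss_err_t + ss_err_d + ss_err_td
    )

    mauchly = {
        "time": _mauchly_from_scores(y.mean(axis=2) @ C_T.T, groups),
        "side": _mauchly_from_scores(y.mean(axis=1) @ C_D.T, groups),
        "time*side": _mauchly_from_scores(
            np.einsum("jt,std,ld->sjl", C_T, y, C_D).reshape(n, -1), groups
        ),
    }

    # residual normality: within-cell residuals of the group x day x side means
    cell_means = np.stack([y[groups == lev].mean(axis=0) for lev in sorted(set(groups))])
    lev_index = {lev: i for i, lev in enumerate(sorted(set(groups)))}
    resid = (y - cell_means[[lev_index[gr] for gr in groups]]).ravel()
    shapiro_p = float(stats.shapiro(resid).pvalue) if np.ptp(resid) > 0 else np.nan

    sizes = {lev: int((groups == lev).sum()) for lev in sorted(set(groups))}
    return AnovaResult(result, mauchly, shapiro_p, n, sizes, days, sides, ss_total, ss_sum)


def _mauchly_from_scores(z: np.ndarray, group_labels: np.ndarray) -> dict:
    """Mauchly's W and its chi-square approximation from contrast scores."""
    z = np.atleast_2d(z.T).T
    n, p = z.shape
    if p < 2:
        return dict(W=1.0, chi2=0.0, df=0, p=1.0,
                    note="2-level effect: sphericity trivially satisfied")
    levels = sorted(pd.unique(group_labels))
    g = len(levels)
    dof = n - g
    S = np.zeros((p, p))
    for lev in levels:
        zi = z[group_labels == lev]
        zc = zi - zi.mean(axis=0)
        S += zc.T @ zc
    S /= dof
    eig = np.linalg.eigvalsh(S)
    if np.any(eig <= 0):
        return dict(W=0.0, chi2=np.inf, df=p * (p + 1) // 2 - 1, p=0.0,
                    note="singular covariance")
    W = float(np.prod(eig) / (eig.mean() ** p))
    # Box's chi-square approximation with the standard second-order term
    # (k = p + 1 is the number of repeated-measure levels)
    d = 1.0 - (2 * p**2 + p + 2) / (6.0 * p * dof)
    chi2 = -dof * d * np.log(W)
    df_chi = p * (p + 1) // 2 - 1
    k = p + 1
    w2 = ((p + 2) * (p - 1) * (p - 2) * (2 * p**3 + 6 * p**2 + 3 * k + 2)
          / (288.0 * (dof * p * d) ** 2))
    p1 = stats.chi2.sf(chi2, df_chi)
    p2 = stats.chi2.sf(chi2, df_chi + 4)
    pval = float(min(max(p1 + w2 * (p2 - p1), 0.0), 1.0))
    return dict(W=W, chi2=float(chi2), df=df_chi, p=pval)


def mauchly_sphericity(table: pd.DataFrame, effect: str = "time") -> dict:
    """Mauchly's test of sphericity for a within-subject effect of the design."""
    y, _, days, groups, sides = _pivot_balanced(table)
    n, T, D = y.shape
    C_T = helmert(T, full=False)
    C_D = helmert(D, full=False)
    if effect == "time":
        z = y.mean(axis=2) @ C_T.T
    elif effect == "side":
        z = y.mean(axis=1) @ C_D.T
    elif effect == "time*side":
        z = np.einsum("jt,std,ld->sjl", C_T, y, C_D).reshape(n, -1)
    else:
        raise InputError(f"unknown within effect {effect!r}")
    return _mauchly_from_scores(z, groups)


def tukey_hsd_time(table: pd.DataFrame, anova: AnovaResult | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD comparisons of all time-mean pairs.

    Uses the time-stratum error mean square and studentized-range quantiles;
    time means pool subjects and sides (side had no effect in the reference
    design, so pooling is the declared convention).
    """
    if anova is None:
        anova = rm_anova(table)
    y, _, days, _, sides = _pivot_balanced(table)
    n, T, D = y.shape
    time_row = anova.table.set_index("effect").loc["time"]
    mse = time_row["error_ss"] / time_row["df2"]
    df_err = time_row["df2"]
    means = y.mean(axis=(0, 2))
    n_per_mean = n * D
    se = np.sqrt(mse / n_per_mean)
    rows = []
    for i in range(T):
        for j in range(i + 1, T):
            diff = means[i] - means[j]
            q = abs(diff) / se if se > 0 else np.nan
            p = float(stats.studentized_range.sf(q, T, df_err)) if np.isfinite(q) else np.nan
            rows.append(dict(day_a=days[i], day_b=days[j], mean_a=means[i], mean_b=means[j],
                             diff=diff, se=se, q=q, p=p,
                             reject=bool(np.isfinite(p) and p < alpha)))
    return pd.DataFrame(rows)


@dataclass
class HrConfoundResult:
    average_r: float
    per_day: pd.DataFrame
    n_skipped: int


def hr_confound(table: pd.DataFrame, n_raw_per_day: int = 4) -> HrConfoundResult:
    """Average per-animal-per-day Pearson correlation between raw BF and HR.

    Only complete days (all animals measured) and animal-days with the full
    set of raw repeats enter; animal-days without variation in BF or HR are
    skipped (logged in ``n_skipped``).
    """
    days = complete_timepoints(table)
    sub = table[table["day"].isin(days)]
    rows, skipped = [], 0
    for (animal, day), grp in sub.groupby(["animal", "day"], sort=False):
        if len(grp) != n_raw_per_day:
            skipped += 1
            continue
        bf, hr = grp["bf"].to_numpy(), grp["hr"].to_numpy()
        if np.ptp(bf) == 0 or np.ptp(hr) == 0:
            skipped += 1
            continue
        r = float(stats.pearsonr(bf, hr).statistic)
        rows.append(dict(animal=animal, day=day, r=r))
    per_day = pd.DataFrame(rows)
    avg = float(per_day["r"].mean()) if len(per_day) else np.nan
    return HrConfoundResult(avg, per_day, skipped)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusteringResult:
    labels: pd.Series  # animal -> cluster id (Ward partition at the elbow k)
    k: int
    wss: dict  # k -> within-cluster sum of squares
    kmeans_labels: pd.Series
    kmeans_agreement: float  # adjusted Rand index Ward vs k-means
    stable: bool  # partition invariant under row-order shuffles
    features: pd.DataFrame  # the animal x day feature matrix used


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        tot += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return tot


def _elbow(wss: dict, k_max: int) -> int:
    if wss[1] < 1e-12:
        return 1
    ks = sorted(wss)
    candidates = [k for k in ks if 2 <= k <= k_max - 1 and (k - 1) in wss and (k + 1) in wss]
    if not candidates:
        return 1 if wss[1] < 1e-12 else min(2, max(ks))
    curv = {k: wss[k - 1] - 2 * wss[k] + wss[k + 1] for k in candidates}
    best = max(curv.values())
    tied = [k for k in candidates if abs(curv[k] - best) <= 1e-9 * max(best, 1.0)]
    if len(tied) == 1:
        return tied[0]
    # distance-to-chord fallback: farthest point from the (1, k_max) chord
    k1, k2 = min(ks), max(ks)
    p1 = np.array([k1, wss[k1]])
    p2 = np.array([k2, wss[k2]])
    chord = p2 - p1
    chord = chord / np.linalg.norm(chord)
    dists = {}
    for k in tied:
        vec = np.array([k, wss[k]]) - p1
        dists[k] = abs(chord[0] * vec[1] - chord[1] * vec[0])
    return max(tied, key=lambda k: dists[k])


def cluster_features(table: pd.DataFrame, last_day: int = 15) -> pd.DataFrame:
    """Per-experimental-animal BF feature vectors: side-averaged values from
    the first baseline day through ``last_day``."""
    exp = table[table["group"] == "experimental"]
    if exp.empty:
        raise InputError("no experimental animals in the table")
    agg = aggregate_measurements(exp)
    days = [d for d in complete_timepoints(agg)
            if agg.loc[agg["day"] == d, "day_num"].iloc[0] <= last_day]
    sub = agg[agg["day"].isin(days)]
    feats = sub.pivot_table(index="animal", columns="day", values="bf", aggfunc="mean")
    order = sub.drop_duplicates("day").sort_values("day_num")["day"].tolist()
    return feats[order]


def cohort_clustering(table: pd.DataFrame, k_max: int = 6, n_shuffles: int = 3,
                      seed: int = 0, last_day: int = 15) -> ClusteringResult:
    """Ward / squared-Euclidean clustering of experimental BF time courses.

    The number of clusters is picked by the elbow (maximum second difference
    of the within-cluster SS over k, distance-to-chord on ties), confirmed by
    k-means at that k, and checked for invariance to the row order of the
    data (Ward is order-independent up to ties; the shuffle check makes that
    explicit).
    """
    feats = cluster_features(table, last_day)
    X = feats.to_numpy()
    n = X.shape[0]
    k_max = min(k_max, n)
    rng = np.random.default_rng(seed)

    def ward_labels(Xm: np.ndarray, k: int) -> np.ndarray:
        if k == 1:
            return np.ones(Xm.shape[0], dtype=int)
        Z = linkage(Xm, method="ward")
        return fcluster(Z, t=k, criterion="maxclust")

    wss = {k: _wss(X, ward_labels(X, k)) for k in range(1, k_max + 1)}
    k_hat = _elbow(wss, k_max)
    labels = ward_labels(X, k_hat)

    km = KMeans(n_clusters=k_hat, n_init=10, random_state=int(rng.integers(2**31)))
    km_labels = km.fit_predict(X) if k_hat > 1 else np.zeros(n, dtype=int)
    agreement = float(adjusted_rand_score(labels, km_labels)) if k_hat > 1 else 1.0

    stable = True
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        wss_p = {k: _wss(X[perm], ward_labels(X[perm], k)) for k in range(1, k_max + 1)}
        k_p = _elbow(wss_p, k_max)
        lab_p = np.empty(n, dtype=int)
        lab_p[perm] = ward_labels(X[perm], k_p)
        if k_p != k_hat or adjusted_rand_score(labels, lab_p) < 1.0:
            stable = False
    return ClusteringResult(
        pd.Series(labels, index=feats.index, name="cluster"),
        int(k_hat), wss,
        pd.Series(km_labels, index=feats.index, name="kmeans"),
        agreement, stable, feats,
    )
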