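"""Longitudinal three-class feature processing.

Stages in the order the gastrointestinal pipeline applies them:

1. ``peak_width_filter`` — retain chromatographic peaks 0.05-1.00 min wide
   (inclusive bounds);
2. ``deisotope`` — flag isotopologue peaks (spacing ~1.003355/z Da,
   co-eluting, intensity-correlated) so only monoisotopic features remain;
3. ``differential_profile_stat`` — an EDGE-style spline F statistic for
   class-dependent time profiles, with a within-time-point permutation
   p-value;
4. ``profile_descriptors`` — a fixed-length numeric summary of each
   feature's temporal behaviour across the three arms;
5. ``train_scorer`` / ``score_features`` — a random-forest model trained on
   expert interesting/uninteresting ratings, yielding a [0, 1] score per
   feature;
6. ``select_candidates`` — score > 0.8, retention time in [2, 25] min and a
   minimum intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .feature_table import FeatureTable

__all__ = [
    "IsotopeParams",
    "ProfileScore",
    "deisotope",
    "natural_spline_basis",
    "differential_profile_stat",
    "differential_profile_table",
    "DESCRIPTOR_NAMES",
    "profile_descriptors",
    "descriptor_table",
    "train_scorer",
    "score_features",
    "select_candidates",
    "peak_width_filter",
]

ISOTOPE_SPACING = 1.003355  # Da, the 13C-12C mass difference


@dataclass(frozen=True)
class IsotopeParams:
    """Deisotoping parameters; defaults are the upstream tool's printed values.

    ``rt_diff`` is in seconds (the upstream convention); feature retention
    times are stored in minutes and converted internally.
    """

    iso_mass: float = ISOTOPE_SPACING
    iso_mass_max_diff: float = 0.05
    rt_diff: float = 10.0
    corr_threshold: float = 0.8
    ppm_iso_diff_threshold: float = 5.0
    charges: Tuple[int, ...] = (1, 2)
    max_k: int = 3


def _pearson_shared(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over shared non-missing samples; NaN when < 3 shared."""
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return np.nan
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def deisotope(table: FeatureTable, params: IsotopeParams = IsotopeParams()) -> FeatureTable:
    """Flag isotopologue peaks, keeping the lowest-m/z member of each chain.

    Feature j is linked to i (mz_i < mz_j) when for some charge z and
    k in 1..max_k: ``|(mz_j - mz_i) - k*iso_mass/z| <= min(iso_mass_max_diff,
    ppm_iso_diff_threshold * mz_j * 1e-6)``, the retention times agree within
    ``rt_diff`` seconds, and the intensity vectors correlate at
    ``corr_threshold`` or better over >= 3 shared samples.
    """
    if table.n_features == 0:
        raise ValueError("deisotope requires a non-empty feature table")
    feats = table.features
    order = np.argsort(feats["mz"].to_numpy())
    ids = feats.index.to_numpy()[order]
    mz = feats["mz"].to_numpy()[order]
    rt = feats["rt_min"].to_numpy()[order]
    X = table.intensities.to_numpy(dtype=float)[order]
    rt_tol_min = params.rt_diff / 60.0

    n = len(ids)
    parent = np.arange(n)  # union-find

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    deltas = sorted(
        {params.iso_mass * k / z for z in params.charges for k in range(1, params.max_k + 1)}
    )
    max_delta = max(deltas) + params.iso_mass_max_diff
    for i in range(n):
        for j in range(i + 1, n):
            d = mz[j] - mz[i]
            if d > max_delta:
                break
            if abs(rt[j] - rt[i]) > rt_tol_min:
                continue
            tol = min(params.iso_mass_max_diff, params.ppm_iso_diff_threshold * mz[j] * 1e-6)
            if not any(abs(d - delta) <= tol for delta in deltas):
                continue
            r = _pearson_shared(X[i], X[j])
            if np.isnan(r) or r < params.corr_threshold:
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)  # root = lowest m/z member

    roots = np.array([find(i) for i in range(n)])
    is_iso_sorted = roots != np.arange(n)
    iso_of_sorted = np.where(is_iso_sorted, ids[roots], None)

    out = table.copy()
    is_iso = pd.Series(is_iso_sorted, index=ids).reindex(feats.index)
    iso_of = pd.Series(iso_of_sorted, index=ids).reindex(feats.index)
    out.features["is_isotope"] = is_iso.astype(bool)
    out.features["isotope_of"] = iso_of
    return out


# ---------------------------------------------------------------------------
# EDGE-style differential profile statistic
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, df: int = 4, knots: Optional[np.ndarray] = None) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), ``df`` columns.

    Boundary knots at min/max of ``x``; ``df - 1`` interior knots at
    quantiles.  Linear beyond the boundaries (the natural constraint).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        uniq = np.unique(x)
        if len(uniq) < 2:
            raise ValueError("need at least two distinct x values for a spline basis")
        qs = np.linspace(0, 1, df + 1)  # boundary + df-1 interior knots
        knots = np.quantile(uniq, qs)
        knots = np.unique(knots)
    if len(knots) < 3:
        # degenerate grid: fall back to a polynomial basis
        return np.column_stack([x ** p for p in range(1, df + 1)])
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[K - 1], 0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dK2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK2)
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(np.sum((y - X @ beta) ** 2))


def _f_statistic(y: np.ndarray, B: np.ndarray, labels: np.ndarray) -> float:
    """F for class-specific vs class-shared spline fits of y on basis B."""
    n = len(y)
    X0 = np.column_stack([np.ones(n), B])
    rss0 = _rss(X0, y)
    rss1 = 0.0
    p1 = 0
    for c in np.unique(labels):
        m = labels == c
        Xc = np.column_stack([np.ones(m.sum()), B[m]])
        rss1 += _rss(Xc, y[m])
        p1 += Xc.shape[1]
    p0 = X0.shape[1]
    dof1 = max(n - p1, 1)
    if rss1 <= 0:
        rss1 = np.finfo(float).tiny
    return ((rss0 - rss1) / max(p1 - p0, 1)) / (rss1 / dof1)


def _permute_within_time(labels: np.ndarray, time: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = labels.copy()
    for t in np.unique(time):
        idx = np.flatnonzero(time == t)
        out[idx] = out[rng.permutation(idx)]
    return out


def differential_profile_stat(
    intensities: np.ndarray,
    time: np.ndarray,
    classes: np.ndarray,
    basis_df: int = 4,
    n_perm: int = 499,
    seed: int | np.random.Generator = 0,
    log_offset: float = 1.0,
) -> Tuple[float, float]:
    """(F statistic, permutation p) for class-dependent temporal profiles.

    Fits log(intensity + ``log_offset``) ~ natural-spline(time) with
    class-specific coefficients (full) versus class-shared (null) by least
    squares; significance by permuting class labels within time points.
    Missing intensities are excluded from both fits.  All-constant profiles
    return (0, 1).  ``p >= 1/(n_perm + 1)`` by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y_all = np.log(np.asarray(intensities, dtype=float) + log_offset)
    time = np.asarray(time, dtype=float)
    classes = np.asarray(classes)
    ok = ~np.isnan(y_all)
    y, t, cls = y_all[ok], time[ok], classes[ok]
    if len(np.unique(cls)) < 2:
        raise ValueError("differential profile statistic needs >= 2 classes present")
    if len(np.unique(t)) < 4:
        raise ValueError("differential profile statistic needs >= 4 time points")
    if np.allclose(y, y[0]):
        return 0.0, 1.0
    B = natural_spline_basis(t, df=basis_df)
    f_obs = _f_statistic(y, B, cls)
    hits = 0
    for _ in range(n_perm):
        perm = _permute_within_time(cls, t, rng)
        if _f_statistic(y, B, perm) >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (n_perm + 1)


def differential_profile_table(
    table: FeatureTable,
    basis_df: int = 4,
    n_perm: int = 499,
    seed: int = 0,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Vectorised per-feature F statistics and permutation p-values.

    Permutation label shuffles are shared across complete features so the
    class-wise hat matrices can be reused; features with missing values fall
    back to the per-feature path.  Returns columns ``stat``, ``p``, ``q``
    (Benjamini-Hochberg).
    """
    rng = np.random.default_rng(seed)
    samples = table.samples
    time_all = samples["time_h"].to_numpy(dtype=float)
    classes_all = samples["class_"].to_numpy()
    Y = np.log(table.intensities.to_numpy(dtype=float) + log_offset)  # features x samples
    n_feat = Y.shape[0]
    stat = np.zeros(n_feat)
    pval = np.ones(n_feat)

    finite = np.isfinite(Y)
    groups: Dict[bytes, List[int]] = {}
    for i in range(n_feat):
        groups.setdefault(finite[i].tobytes(), []).append(i)

    for key in sorted(groups):  # deterministic group order
        idx = np.asarray(groups[key])
        mask = np.frombuffer(key, dtype=bool)
        if mask.sum() == 0:
            continue
        t = time_all[mask]
        cls = classes_all[mask]
        if len(np.unique(cls)) < 2 or len(np.unique(t)) < 4:
            continue  # contrast undefined: stat 0, p 1
        Yg = Y[np.ix_(idx, np.flatnonzero(mask))]
        const = np.all(np.isclose(Yg, Yg[:, [0]], atol=1e-12), axis=1)
        n = Yg.shape[1]
        B = natural_spline_basis(t, df=basis_df)

        def rss_all(labels: np.ndarray) -> Tuple[np.ndarray, int]:
            rss1 = np.zeros(Yg.shape[0])
            p1 = 0
            for c in np.unique(labels):
                m = labels == c
                Xc = np.column_stack([np.ones(m.sum()), B[m]])
                Q, _ = np.linalg.qr(Xc)
                R = Yg[:, m] - (Yg[:, m] @ Q) @ Q.T
                rss1 += np.sum(R ** 2, axis=1)
                p1 += Xc.shape[1]
            return rss1, p1

        X0 = np.column_stack([np.ones(n), B])
        Q0, _ = np.linalg.qr(X0)
        rss0 = np.sum((Yg - (Yg @ Q0) @ Q0.T) ** 2, axis=1)
        rss1, p1 = rss_all(cls)
        p0 = X0.shape[1]
        dof = max(n - p1, 1)
        rss1s = np.where(rss1 <= 0, np.finfo(float).tiny, rss1)
        f_obs = ((rss0 - rss1) / max(p1 - p0, 1)) / (rss1s / dof)
        hits = np.zeros(Yg.shape[0])
        for _ in range(n_perm):
            perm = _permute_within_time(cls, t, rng)
            rss1p, _ = rss_all(perm)
            rss1ps = np.where(rss1p <= 0, np.finfo(float).tiny, rss1p)
            f_perm = ((rss0 - rss1p) / max(p1 - p0, 1)) / (rss1ps / dof)
            hits += f_perm >= f_obs
        stat[idx] = np.where(const, 0.0, f_obs)
        pval[idx] = np.where(const, 1.0, (1 + hits) / (n_perm + 1))

    q = _benjamini_hochberg(pval)
    return pd.DataFrame({"stat": stat, "p": pval, "q": q}, index=table.features.index)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# Profile descriptors and the ratings-trained scorer
# ---------------------------------------------------------------------------

#: Documented descriptor order.
DESCRIPTOR_NAMES = (
    "hex_colon_slope",      # log-intensity slope over colon time, HEX
    "nchex_colon_slope",    # same, NCHEX
    "mb_colon_slope",       # same, MB
    "hex_nchex_divergence", # time-integrated |HEX - NCHEX| colon log divergence
    "mb_mean_rel",          # MB mean intensity / feature max
    "frac_missing",         # fraction of missing (NaN or 0) samples
    "hex_monotonicity",     # Spearman rho of HEX colon profile vs time
    "hex_fold_change_log",  # log((72h + 1) / (t0 + 1)) in HEX
)


def _colon_profile(table: FeatureTable, fid, class_: str) -> Tuple[np.ndarray, np.ndarray]:
    cols = table.class_columns(class_, "COLON")
    sub = table.samples.loc[cols]
    t = sub["time_h"].to_numpy(dtype=float)
    y = table.intensities.loc[fid, cols].to_numpy(dtype=float)
    # average replicates at each time point (all-missing -> NaN)
    times = np.unique(t)
    prof = np.empty(len(times))
    for i, tt in enumerate(times):
        vals = y[t == tt]
        vals = vals[~np.isnan(vals)]
        prof[i] = vals.mean() if vals.size else np.nan
    return times, prof


def profile_descriptors(table: FeatureTable, fid) -> np.ndarray:
    """Fixed-length descriptor vector for one feature (order: DESCRIPTOR_NAMES).

    Intensities of 0 are treated as missing.  An all-missing feature yields
    the zero vector with ``frac_missing`` = 1.
    """
    x = table.intensities.loc[fid].to_numpy(dtype=float)
    x = np.where(x <= 0, np.nan, x)
    frac_missing = float(np.isnan(x).mean())
    out = np.zeros(len(DESCRIPTOR_NAMES))
    out[5] = frac_missing
    if np.all(np.isnan(x)):
        return out

    xmax = np.nanmax(x)
    logs: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for k, cls in enumerate(("HEX", "NCHEX", "MB")):
        t, prof = _colon_profile(table, fid, cls)
        logs[cls] = (t, np.log(np.where(np.isnan(prof), np.nan, prof) + 1.0))
        tt, yy = t, logs[cls][1]
        ok = ~np.isnan(yy)
        if ok.sum() >= 3 and np.ptp(yy[ok]) > 0:
            out[k] = stats.theilslopes(yy[ok], tt[ok])[0]

    # divergence area: trapezoid integral of |HEX - NCHEX| over shared colon grid
    tH, yH = logs["HEX"]
    _, yN = logs["NCHEX"]
    yHf = np.nan_to_num(yH)
    yNf = np.nan_to_num(yN)
    if len(tH) >= 2:
        out[3] = float(np.trapezoid(np.abs(yHf - yNf), tH) / (tH[-1] - tH[0]))

    mb_cols = table.class_columns("MB")
    mb = table.intensities.loc[fid, mb_cols].to_numpy(dtype=float)
    mb = np.where(mb <= 0, np.nan, mb)
    if not np.all(np.isnan(mb)) and xmax > 0:
        out[4] = float(np.nanmean(mb) / xmax)

    ok = ~np.isnan(yH)
    if ok.sum() >= 3 and np.ptp(yH[ok]) > 0:
        rho = stats.spearmanr(tH[ok], yH[ok]).statistic
        out[6] = 0.0 if np.isnan(rho) else float(rho)

    hex_cols = table.class_columns("HEX")
    sub = table.samples.loc[hex_cols]
    t0_cols = hex_cols[sub["phase"] == "T0"]
    t72_cols = hex_cols[sub["time_h"] == sub["time_h"].max()]
    i0 = np.nan_to_num(table.intensities.loc[fid, t0_cols].to_numpy(dtype=float)).mean()
    i72 = np.nan_to_num(table.intensities.loc[fid, t72_cols].to_numpy(dtype=float)).mean()
    out[7] = float(np.log((i72 + 1.0) / (i0 + 1.0)))
    return out


def descriptor_table(table: FeatureTable) -> pd.DataFrame:
    rows = [profile_descriptors(table, fid) for fid in table.features.index]
    return pd.DataFrame(rows, index=table.features.index, columns=list(DESCRIPTOR_NAMES))


def train_scorer(
    descriptors: pd.DataFrame,
    ratings: pd.Series,
    seed: int = 0,
    n_trees: int = 500,
) -> RandomForestClassifier:
    """Fit the interestingness scorer on expert 0/1 ratings.

    ``ratings`` is indexed by feature id with values in {0, 1}; both labels
    must be present.  Deterministic for a fixed seed.
    """
    ratings = ratings.dropna().astype(int)
    if set(ratings.unique()) != {0, 1}:
        raise ValueError(
            "ratings must contain both labels 0 (uninteresting) and 1 (interesting)"
        )
    X = descriptors.loc[ratings.index].to_numpy(dtype=float)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=int(seed))
    model.fit(X, ratings.to_numpy())
    return model


def score_features(model: RandomForestClassifier, descriptors: pd.DataFrame) -> pd.Series:
    """Fraction of trees voting 'interesting', in [0, 1], per feature."""
    proba = model.predict_proba(descriptors.to_numpy(dtype=float))
    pos = list(model.classes_).index(1)
    return pd.Series(proba[:, pos], index=descriptors.index, name="score")


def select_candidates(
    scores: pd.Series,
    features: pd.DataFrame,
    intensities: Optional[pd.DataFrame] = None,
    score_min: float = 0.8,
    rt_window: Tuple[float, float] = (2.0, 25.0),
    intensity_min: float = 0.0,
) -> List:
    """Feature ids with score strictly above ``score_min``, retention time
    inside ``rt_window`` (inclusive) and maximum intensity >=
    ``intensity_min``; ordered by descending score (stable)."""
    ids = []
    for fid in scores.sort_values(ascending=False, kind="stable").index:
        if scores[fid] <= score_min:
            continue
        rt = features.loc[fid, "rt_min"]
        if not (rt_window[0] <= rt <= rt_window[1]):
            continue
        if intensity_min > 0 and intensities is not None:
            if np.nan_to_num(intensities.loc[fid].to_numpy(dtype=float)).max() < intensity_min:
                continue
        ids.append(fid)
    return ids


def peak_width_filter(
    table: FeatureTable, width_min: float = 0.05, width_max: float = 1.00
) -> FeatureTable:
    """Retain features whose chromatographic width lies in the inclusive
    interval [``width_min``, ``width_max``] minutes."""
    if "width_min" not in table.features.columns:
        raise ValueError("peak_width_filter requires a 'width_min' feature column")
    w = table.features["width_min"]
    keep = table.features.index[(w >= width_min) & (w <= width_max)]
    return table.subset(keep)
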