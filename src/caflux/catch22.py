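"""The 22 canonical time-series features (Catch-22) for trace clustering.

Implements the published Catch-22 feature set — 22 summary statistics of
a univariate series spanning distribution shape, autocorrelation
structure, outlier timing, symbolic motifs, spectral summaries,
fluctuation scaling and simple forecastability — used here to embed
calcium traces for PCA + DBSCAN clustering.

Conventions (fixed, and locked by the test suite's independent
re-implementations):

* the series is z-scored (population SD) before feature extraction, so
  every feature is invariant to the trace's offset and scale;
* a constant series, whose features are largely undefined, maps to the
  all-zero vector;
* any individually non-finite feature value is imputed to 0;
* autocorrelation is the biased (1/N) estimate, normalized to lag 0;
* natural logarithms throughout the entropy/information features.

Feature order follows :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["FEATURE_NAMES", "catch22_features", "MIN_LENGTH"]

FEATURE_NAMES: tuple[str, ...] = (
    "DN_HistogramMode_5",
    "DN_HistogramMode_10",
    "SB_BinaryStats_diff_longstretch0",
    "DN_OutlierInclude_p_001_mdrmd",
    "DN_OutlierInclude_n_001_mdrmd",
    "CO_f1ecac",
    "CO_FirstMin_ac",
    "SP_Summaries_welch_rect_area_5_1",
    "SB_BinaryStats_mean_longstretch1",
    "SB_MotifThree_quantile_hh",
    "FC_LocalSimple_mean1_tauresrat",
    "CO_HistogramAMI_even_2_5",
    "CO_trev_1_num",
    "MD_hrv_classic_pnn40",
    "SB_TransitionMatrix_3ac_sumdiagcov",
    "PD_PeriodicityWang_th0_01",
    "CO_Embed2_Dist_tau_d_expfit_meandiff",
    "IN_AutoMutualInfoStats_40_gaussian_fmmi",
    "FC_LocalSimple_mean3_stderr",
    "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1",
    "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1",
    "SP_Summaries_welch_rect_centroid",
)

MIN_LENGTH = 20


# ---------------------------------------------------------------- helpers


def _acf(y: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased autocorrelation of a zero-mean series, acf[0] = 1."""
    n = y.size
    if max_lag is None:
        max_lag = n - 1
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(y, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1].real / n
    if acov[0] == 0:
        return np.zeros(max_lag + 1)
    return acov / acov[0]


def _first_zero_ac(acf: np.ndarray) -> int:
    """First lag at which the autocorrelation drops to <= 0."""
    for i in range(1, acf.size):
        if acf[i] <= 0:
            return i
    return acf.size


def _longest_run(binary: np.ndarray, target: bool) -> int:
    best = cur = 0
    for b in binary:
        if bool(b) == target:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def _quantile_symbols(y: np.ndarray, n_symbols: int = 3) -> np.ndarray:
    """Coarse-grain into equiprobable symbols 0..n_symbols-1."""
    qs = np.quantile(y, np.arange(1, n_symbols) / n_symbols)
    return np.searchsorted(qs, y, side="left")


def _ols_line_residuals(v: np.ndarray) -> np.ndarray:
    """Residuals of a least-squares line fit against the sample index."""
    n = v.size
    x = np.arange(n, dtype=float)
    xm = x - x.mean()
    denom = (xm**2).sum()
    slope = (xm * (v - v.mean())).sum() / denom if denom > 0 else 0.0
    return v - (v.mean() + slope * xm)


# ---------------------------------------------------------------- features


def _histogram_mode(y: np.ndarray, n_bins: int) -> float:
    counts, edges = np.histogram(y, bins=np.linspace(y.min(), y.max(), n_bins + 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[counts == counts.max()].mean())


def _f1ecac(acf: np.ndarray) -> float:
    thresh = 1.0 / math.e
    for i in range(1, acf.size):
        if acf[i] < thresh:
            # linear interpolation of the crossing between lags i-1 and i
            return (i - 1) + (acf[i - 1] - thresh) / (acf[i - 1] - acf[i])
    return float(acf.size)


def _first_min_ac(acf: np.ndarray) -> float:
    for i in range(1, acf.size - 1):
        if acf[i] < acf[i - 1] and acf[i] < acf[i + 1]:
            return float(i)
    return float(acf.size)


def _histogram_ami_even_2_5(y: np.ndarray) -> float:
    tau, n_bins = 2, 5
    y1, y2 = y[:-tau], y[tau:]
    edges = np.linspace(y.min(), y.max(), n_bins + 1)
    edges[-1] += 1e-12  # close the right edge
    joint, _, _ = np.histogram2d(y1, y2, bins=(edges, edges))
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def _transition_matrix_sumdiagcov(y: np.ndarray, acf: np.ndarray) -> float:
    tau = max(_first_zero_ac(acf), 1)
    ds = y[::tau]
    if ds.size < 4:
        return 0.0
    sym = _quantile_symbols(ds, 3)
    T = np.zeros((3, 3))
    for a, b in zip(sym[:-1], sym[1:]):
        T[a, b] += 1.0
    T /= max(sym.size - 1, 1)
    cov = np.cov(T, rowvar=False, ddof=1)
    return float(np.trace(cov))


def _periodicity_wang(y: np.ndarray) -> float:
    """Wang's periodicity: spline-detrend, then first autocorrelation
    peak after a trough with rise >= 0.01 and positive value."""
    from scipy.interpolate import LSQUnivariateSpline

    n = y.size
    x = np.arange(n, dtype=float)
    try:
        spline = LSQUnivariateSpline(x, y, t=[x[n // 2]], k=3)
        resid = y - spline(x)
    except Exception:
        resid = y - y.mean()
    resid = resid - resid.mean()
    max_lag = max(int(math.ceil(n / 3.0)), 3)
    ac = _acf(resid, max_lag)
    troughs, peaks = [], []
    for i in range(1, ac.size - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            troughs.append(i)
        elif ac[i] > ac[i - 1] and ac[i] > ac[i + 1]:
            peaks.append(i)
    for tr in troughs:
        after = [p for p in peaks if p > tr]
        if not after:
            continue
        pk = after[0]
        if ac[pk] - ac[tr] >= 0.01 and ac[pk] > 0:
            return float(pk)
    return 0.0


def _embed2_dist_expfit_meandiff(y: np.ndarray, acf: np.ndarray) -> float:
    n = y.size
    tau = _first_zero_ac(acf)
    if tau > n / 10:
        tau = max(int(n // 10), 1)
    m = n - tau - 1
    if m < 3:
        return 0.0
    d = np.hypot(y[1 : m + 1] - y[:m], y[1 + tau : m + 1 + tau] - y[tau : m + tau])
    lam = d.mean()
    if lam <= 0:
        return 0.0
    n_bins = int(math.ceil(math.sqrt(d.size)))
    counts, edges = np.histogram(d, bins=n_bins)
    width = edges[1] - edges[0]
    if width <= 0:
        return 0.0
    density = counts / (d.size * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    expected = np.exp(-centers / lam) / lam
    return float(np.abs(density - expected).mean())


def _ami_gaussian_fmmi(acf: np.ndarray, n: int) -> float:
    tau_max = min(40, n // 2)
    rho = np.clip(acf[1 : tau_max + 1], -0.999999, 0.999999)
    ami = -0.5 * np.log(1.0 - rho**2)
    for k in range(1, ami.size - 1):
        if ami[k] < ami[k - 1] and ami[k] < ami[k + 1]:
            return float(k + 1)  # lags are 1-based
    return float(ami.size)


def _local_simple_mean_residuals(y: np.ndarray, train: int) -> np.ndarray:
    """Residuals of forecasting each point by the mean of the previous
    ``train`` points."""
    n = y.size
    if n <= train:
        return np.zeros(0)
    kernel = np.ones(train) / train
    preds = np.convolve(y, kernel, mode="valid")[: n - train]
    return y[train:] - preds


def _tauresrat(y: np.ndarray, acf_y: np.ndarray) -> float:
    res = _local_simple_mean_residuals(y, 1)
    if res.size < 3:
        return 0.0
    acf_res = _acf(res - res.mean())
    denom = _first_zero_ac(acf_y)
    return float(_first_zero_ac(acf_res)) / float(denom) if denom > 0 else 0.0


def _outlier_include_mdrmd(y: np.ndarray) -> float:
    """Median, over retained thresholds, of the median relative timing of
    threshold exceedances (timing rescaled to [-1, 1]).

    Thresholds rise from 0 in steps of 0.01 (SD units); thresholds
    retained while at least 2% of points exceed them.
    """
    n = y.size
    top = float(y.max())
    if top < 0.01:
        return 0.0
    ths = np.arange(0.0, top, 0.01)
    stats = []
    for th in ths:
        idx = np.flatnonzero(y >= th)
        if idx.size / n * 100.0 < 2.0:
            break
        rel = (idx + 1) / n  # 1-based relative position in (0, 1]
        stats.append(2.0 * float(np.median(rel)) - 1.0)
    if not stats:
        return 0.0
    return float(np.median(stats))


def _welch_rect(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-segment rectangular-window power spectral density.

    S(ω_k) = |FFT|² / (2πN) at ω_k = 2πk/N, k = 0..⌊N/2⌋ (rad/sample).
    """
    n = y.size
    f = np.fft.rfft(y - y.mean())
    S = (np.abs(f) ** 2) / (2.0 * np.pi * n)
    w = 2.0 * np.pi * np.arange(S.size) / n
    return w, S


def _spectral_area_5_1(w: np.ndarray, S: np.ndarray) -> float:
    dw = w[1] - w[0]
    n_first = int(math.ceil(S.size / 5.0))
    return float(S[:n_first].sum() * dw)


def _spectral_centroid(w: np.ndarray, S: np.ndarray) -> float:
    dw = w[1] - w[0]
    csum = np.cumsum(S) * dw
    half = csum[-1] / 2.0
    if csum[-1] <= 0:
        return 0.0
    k = int(np.searchsorted(csum, half, side="right"))
    return float(w[min(k, w.size - 1)])


def _motif_three_hh(y: np.ndarray) -> float:
    sym = _quantile_symbols(y, 3)
    pairs = sym[:-1] * 3 + sym[1:]
    counts = np.bincount(pairs, minlength=9).astype(float)
    p = counts / counts.sum()
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def _fluct_anal_prop_r1(y: np.ndarray, how: str, lag: int) -> float:
    """Two-regime fluctuation-scaling fit.

    Cumulatively sum every ``lag``-th sample, compute the fluctuation
    function F(τ) over ~50 log-spaced window sizes τ (linearly detrended
    windows; ``dfa``: RMS of residuals, ``rsrangefit``: RMS of residual
    range), then fit two lines to log F vs log τ over every admissible
    split (>= 6 points per regime) and return the proportion of window
    sizes assigned to the first regime at the best split.
    """
    x = np.cumsum(y[::lag])
    n = x.size
    lo, hi = 5, n // 2
    if hi < lo + 1:
        return 0.0
    taus = np.unique(
        np.floor(np.logspace(math.log10(lo), math.log10(hi), 50)).astype(int)
    )
    taus = taus[(taus >= lo) & (taus <= hi)]
    n_tau = taus.size
    min_points = 6
    if n_tau < 2 * min_points:
        return 0.0
    F = np.empty(n_tau)
    for j, tau in enumerate(taus):
        n_buf = n // tau
        segs = x[: n_buf * tau].reshape(n_buf, tau)
        xi = np.arange(tau, dtype=float)
        xm = xi - xi.mean()
        denom = (xm**2).sum()
        means = segs.mean(axis=1, keepdims=True)
        slopes = ((segs - means) * xm).sum(axis=1, keepdims=True) / denom
        resid = segs - (means + slopes * xm)
        if how == "dfa":
            acc = (resid**2).mean(axis=1)
        else:  # rsrangefit
            acc = (resid.max(axis=1) - resid.min(axis=1)) ** 2
        F[j] = math.sqrt(float(acc.mean()))
    if np.any(F <= 0):
        return 0.0
    lt, lF = np.log(taus.astype(float)), np.log(F)

    def sse(xs: np.ndarray, ys: np.ndarray) -> float:
        return float((_ols_line_residuals_xy(xs, ys) ** 2).sum())

    best_sse, best_i = math.inf, min_points
    for i in range(min_points, n_tau - min_points + 1):
        s = sse(lt[:i], lF[:i]) + sse(lt[i:], lF[i:])
        if s < best_sse:
            best_sse, best_i = s, i
    return best_i / n_tau


def _ols_line_residuals_xy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xm = x - x.mean()
    denom = (xm**2).sum()
    slope = (xm * (y - y.mean())).sum() / denom if denom > 0 else 0.0
    return y - (y.mean() + slope * xm)


# ---------------------------------------------------------------- entry


def catch22_features(values: "np.ndarray | object") -> np.ndarray:
    """Compute the 22-feature vector for one trace.

    Accepts a raw 1-D array or any object with a ``values`` attribute
    (e.g. a ``CellTrace``).  The series is z-scored first; a constant
    series returns the all-zero vector; non-finite feature values are
    imputed to 0.  Raises for series shorter than :data:`MIN_LENGTH`.
    """
    y = np.asarray(getattr(values, "values", values), dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1-D series")
    if y.size < MIN_LENGTH:
        raise ValueError(f"series too short for feature extraction (need >= {MIN_LENGTH})")
    sd = y.std()
    if sd == 0 or not np.isfinite(sd):
        return np.zeros(len(FEATURE_NAMES))
    z = (y - y.mean()) / sd
    acf = _acf(z)
    w, S = _welch_rect(z)
    diffs = np.diff(z)

    out = np.array(
        [
            _histogram_mode(z, 5),
            _histogram_mode(z, 10),
            float(_longest_run(diffs > 0, False)),
            _outlier_include_mdrmd(z),
            _outlier_include_mdrmd(-z),
            _f1ecac(acf),
            _first_min_ac(acf),
            _spectral_area_5_1(w, S),
            float(_longest_run(z > 0, True)),
            _motif_three_hh(z),
            _tauresrat(z, acf),
            _histogram_ami_even_2_5(z),
            float((diffs**3).mean()),
            float((np.abs(diffs) > 0.04).mean()),
            _transition_matrix_sumdiagcov(z, acf),
            _periodicity_wang(z),
            _embed2_dist_expfit_meandiff(z, acf),
            _ami_gaussian_fmmi(acf, z.size),
            float(np.std(_local_simple_mean_residuals(z, 3), ddof=1))
            if z.size > 4
            else 0.0,
            _fluct_anal_prop_r1(z, "dfa", 2),
            _fluct_anal_prop_r1(z, "rsrangefit", 1),
            _spectral_centroid(w, S),
        ]
    )
    out[~np.isfinite(out)] = 0.0
    return out
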