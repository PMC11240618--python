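"""Classification of calcium traces into spiking vs non-spiking cells.

A trace is called **non-spiking** only when every applicable criterion
below indicates so (conjunction; a disjunction mode exists because the
rule wording is ambiguous in general use):

A. the least-squares slope of the trace is indistinguishable from zero;
B. the baseline-adjusted trace has mean < 0.05 and SD < 0.01 (ratio units);
C. the trace falls in the DBSCAN cluster (over a PCA of the Catch-22
   feature embedding) that maximally overlaps cells satisfying A∧B;
D. no Fourier magnitude at a nonzero frequency exceeds 10 (no strong
   periodic component);
E. no baseline-adjusted value exceeds 0.17 (no excursion of spike size).

``is_spiking`` is the negation.  Criteria B and E are evaluated on
baseline-subtracted values (per-cell rolling minimum, 60-s window by
default): the thresholds quantify excursions above the cell's own
resting level, not the raw ratio.  A configurable number of leading
frames can be excluded before all criteria (used under ATP stimulation,
where the first 10 frames carry addition artifacts).

Calbryte (single-wavelength, bleaching) recordings are handled by a
separate annotation rule, :func:`annotate_calbryte`, which emulates the
manual call "at least one clear spike": an excursion above a robust
noise scale after detrending the bleaching decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .catch22 import catch22_features
from .traceio import CellTrace, TracePopulation

__all__ = [
    "SpikeCriteriaConfig",
    "SpikeCall",
    "baseline_adjust",
    "criterion_zero_slope",
    "criterion_flat",
    "cluster_nonspiking",
    "criterion_fft",
    "criterion_threshold",
    "classify_population",
    "overestimation_rate",
    "annotate_calbryte",
    "calls_to_frame",
    "spiking_fraction",
]

CRITERIA = ("A_slope", "B_flat", "C_cluster", "D_fft", "E_threshold")


@dataclass(frozen=True)
class SpikeCriteriaConfig:
    """Thresholds and knobs of the five-criterion classifier.

    ``slope_tolerance`` (ratio units per sample) is an absolute override
    for criterion A; when unset, a slope counts as zero if it is within
    2 standard errors of zero or smaller than ``flat_mean_max/n`` (a
    total drift over the whole recording below the flat-mean threshold —
    slopes that small are biologically inert regardless of statistical
    significance).

    ``pca_components`` defaults to 2: the DBSCAN radius (eps = 2) is a
    distance in the PCA score space, and is only a meaningful
    neighborhood size in a low-dimensional projection — in the 10+
    dimensions needed to reach 90% explained variance it strands
    borderline quiescent cells as noise and inflates the spiking
    fraction.  Set ``pca_components=None`` to fall back to retaining
    ``pca_variance`` explained variance instead.
    """

    flat_mean_max: float = 0.05
    flat_sd_max: float = 0.01
    dbscan_epsilon: float = 2.0
    dbscan_min_points: int = 20
    fft_magnitude_max: float = 10.0
    amplitude_threshold: float = 0.17
    slope_tolerance: float | None = None
    combination_rule: str = "conjunction"
    exclude_first_frames: int = 0
    baseline_method: str = "rolling_min"  # rolling_min | none
    baseline_window_s: float = 60.0
    pca_variance: float = 0.90
    pca_components: int | None = 2
    calbryte_noise_multiple: float = 5.0
    calbryte_detrend_window_s: float = 125.0

    def __post_init__(self) -> None:
        for name in (
            "flat_mean_max",
            "flat_sd_max",
            "dbscan_epsilon",
            "fft_magnitude_max",
            "amplitude_threshold",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name}: must be > 0")
        if self.dbscan_min_points < 2:
            raise ValueError("dbscan_min_points: must be >= 2")
        if self.combination_rule not in ("conjunction", "disjunction"):
            raise ValueError(f"combination_rule: unknown rule {self.combination_rule!r}")
        if self.exclude_first_frames < 0:
            raise ValueError("exclude_first_frames: must be >= 0")
        if self.baseline_method not in ("rolling_min", "none"):
            raise ValueError(f"baseline_method: unknown method {self.baseline_method!r}")


@dataclass(frozen=True)
class SpikeCall:
    """Per-cell verdict with the per-criterion outcomes behind it.

    Each flag is True when the criterion indicates *non-spiking*; the
    C flag is None when clustering was inapplicable.  ``cluster_id`` is
    the DBSCAN label (-1 = noise, None = inapplicable).
    """

    cell_id: str
    is_spiking: bool
    criterion_flags: dict[str, bool | None]
    cluster_id: int | None


def baseline_adjust(trace: CellTrace, cfg: SpikeCriteriaConfig) -> np.ndarray:
    """Values minus the per-cell baseline (trailing rolling minimum)."""
    if cfg.baseline_method == "none":
        return trace.values.copy()
    window = max(1, int(round(cfg.baseline_window_s / trace.interval)))
    baseline = (
        pd.Series(trace.values).rolling(window, min_periods=1).min().to_numpy()
    )
    return trace.values - baseline


def criterion_zero_slope(trace: CellTrace, cfg: SpikeCriteriaConfig | None = None) -> bool:
    """A: no systematic linear trend (OLS slope consistent with zero)."""
    cfg = cfg or SpikeCriteriaConfig()
    x = np.arange(trace.n_points, dtype=float)  # slope in units per sample
    fit = stats.linregress(x, trace.values)
    if cfg.slope_tolerance is not None:
        return abs(fit.slope) <= cfg.slope_tolerance
    floor = cfg.flat_mean_max / trace.n_points
    return abs(fit.slope) <= max(2.0 * fit.stderr, floor)


def criterion_flat(trace: CellTrace, cfg: SpikeCriteriaConfig | None = None) -> bool:
    """B: baseline-adjusted mean < 0.05 and SD < 0.01."""
    cfg = cfg or SpikeCriteriaConfig()
    adj = baseline_adjust(trace, cfg)
    return bool(adj.mean() < cfg.flat_mean_max and adj.std(ddof=1) < cfg.flat_sd_max)


def criterion_fft(trace: CellTrace, cfg: SpikeCriteriaConfig | None = None) -> bool:
    """D: no DFT magnitude above threshold at any nonzero frequency.

    Unnormalized DFT of the mean-subtracted trace; the DC term is
    excluded so a trace's offset cannot trigger the criterion.
    """
    cfg = cfg or SpikeCriteriaConfig()
    y = trace.values - trace.values.mean()
    mags = np.abs(np.fft.rfft(y))[1:]
    return bool(not np.any(mags > cfg.fft_magnitude_max))


def criterion_threshold(trace: CellTrace, cfg: SpikeCriteriaConfig | None = None) -> bool:
    """E: no baseline-adjusted value strictly above the spike threshold."""
    cfg = cfg or SpikeCriteriaConfig()
    adj = baseline_adjust(trace, cfg)
    return bool(adj.max() <= cfg.amplitude_threshold)


def cluster_nonspiking(
    population: TracePopulation,
    flags_AB: Sequence[bool],
    cfg: SpikeCriteriaConfig | None = None,
) -> tuple[list[bool | None], list[int | None]]:
    """C: DBSCAN over a PCA of the Catch-22 embedding.

    Features are imputed (non-finite → 0), zero-variance features
    dropped, standardized, projected onto the leading principal
    components (enough to explain ``pca_variance``, or a fixed count),
    and clustered with DBSCAN(eps, min_points).  The cluster with the
    highest fraction of members already satisfying A∧B — provided that
    fraction is positive — is designated non-spiking; its members get
    True, everything else (other clusters and DBSCAN noise) False.

    With fewer traces than ``dbscan_min_points`` the criterion is
    inapplicable: all flags None, all cluster ids None.
    """
    cfg = cfg or SpikeCriteriaConfig()
    n = len(population)
    if len(flags_AB) != n:
        raise ValueError("flags_AB must align with the population")
    if n < cfg.dbscan_min_points:
        return [None] * n, [None] * n
    X = np.vstack([catch22_features(t) for t in population])
    keep = np.ptp(X, axis=0) > 0  # range, not std: exact for identical rows
    if keep.any():
        Xs = StandardScaler().fit_transform(X[:, keep])
        n_comp = cfg.pca_components
        if n_comp is None:
            n_comp = cfg.pca_variance if Xs.shape[1] > 1 else 1
        pca = PCA(n_components=min(n_comp, min(Xs.shape)) if isinstance(n_comp, int) else n_comp,
                  svd_solver="full")
        Xp = pca.fit_transform(Xs)
    else:
        # all features identical across cells: degenerate geometry,
        # every cell sits at the origin and forms one cluster
        Xp = np.zeros((n, 1))
    labels = DBSCAN(eps=cfg.dbscan_epsilon, min_samples=cfg.dbscan_min_points).fit_predict(Xp)
    flags_AB = np.asarray(flags_AB, dtype=bool)
    cluster_ids = [int(l) for l in labels]
    if np.all(labels == -1):
        # no density structure at all: nothing to designate, criterion
        # is uninformative rather than an indictment of every cell
        return [None] * n, cluster_ids
    designated: int | None = None
    best_overlap = 0.0
    for cid in sorted(set(labels) - {-1}):
        members = labels == cid
        overlap = float(flags_AB[members].mean())
        if overlap > best_overlap:
            best_overlap, designated = overlap, cid
    flags_C: list[bool | None] = [
        bool(designated is not None and l == designated) for l in labels
    ]
    return flags_C, cluster_ids


def _combine(flags: dict[str, bool | None], rule: str) -> bool:
    applicable = [v for v in flags.values() if v is not None]
    if rule == "conjunction":
        non_spiking = all(applicable)
    else:
        non_spiking = any(applicable)
    return not non_spiking


def classify_population(
    population: TracePopulation, cfg: SpikeCriteriaConfig | None = None
) -> list[SpikeCall]:
    """Run all five criteria over a population and combine them.

    Leading-frame exclusion (``cfg.exclude_first_frames``) is applied
    before every criterion.
    """
    cfg = cfg or SpikeCriteriaConfig()
    pop = population.drop_leading(cfg.exclude_first_frames)
    a = [criterion_zero_slope(t, cfg) for t in pop]
    b = [criterion_flat(t, cfg) for t in pop]
    d = [criterion_fft(t, cfg) for t in pop]
    e = [criterion_threshold(t, cfg) for t in pop]
    flags_ab = [ai and bi for ai, bi in zip(a, b)]
    c, cluster_ids = cluster_nonspiking(pop, flags_ab, cfg)
    calls = []
    for i, t in enumerate(pop):
        flags: dict[str, bool | None] = {
            "A_slope": a[i],
            "B_flat": b[i],
            "C_cluster": c[i],
            "D_fft": d[i],
            "E_threshold": e[i],
        }
        calls.append(
            SpikeCall(
                cell_id=t.cell_id,
                is_spiking=_combine(flags, cfg.combination_rule),
                criterion_flags=flags,
                cluster_id=cluster_ids[i],
            )
        )
    return calls


def spiking_fraction(calls: Sequence[SpikeCall]) -> float:
    if not calls:
        raise ValueError("no calls")
    return sum(c.is_spiking for c in calls) / len(calls)


def overestimation_rate(
    calls: Sequence[SpikeCall], reference_labels: Mapping[str, bool]
) -> float:
    """Automatic minus reference spiking fraction (signed).

    ``reference_labels`` maps cell_id to the reference (e.g. manual)
    spiking annotation; the cell sets must match exactly.
    """
    call_ids = {c.cell_id for c in calls}
    if call_ids != set(reference_labels):
        raise ValueError("reference labels do not cover the same cells as the calls")
    auto = spiking_fraction(calls)
    ref = sum(bool(v) for v in reference_labels.values()) / len(reference_labels)
    return auto - ref


def _bleach_trend(
    times: np.ndarray, values: np.ndarray, cfg: SpikeCriteriaConfig, interval: float
) -> np.ndarray:
    """Photobleaching trend: exponential-decay fit, falling back to a
    centered rolling median when the fit does not converge."""
    from scipy.optimize import curve_fit

    tt = times - times[0]

    def model(x, a, b, c):
        return a * np.exp(-b * x) + c

    try:
        p0 = (max(values[0] - values[-1], 1e-9), 1.0 / (tt[-1] + 1.0), float(values[-1]))
        popt, _ = curve_fit(
            model, tt, values, p0=p0,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=5000,
        )
        return model(tt, *popt)
    except (RuntimeError, ValueError):
        window = max(3, int(round(cfg.calbryte_detrend_window_s / interval)))
        return (
            pd.Series(values).rolling(window, min_periods=1, center=True).median().to_numpy()
        )


def annotate_calbryte(trace: CellTrace, cfg: SpikeCriteriaConfig | None = None) -> bool:
    """Automated surrogate for the manual Calbryte spike call.

    Detrends the photobleaching decay (exponential fit; rolling-median
    fallback) and works on the *relative* residual v/trend − 1: because
    bleaching is multiplicative, both spikes and noise shrink with the
    trend, so relative excursions are homoscedastic across the
    recording.  The cell is called spiking when any relative excursion
    exceeds ``calbryte_noise_multiple`` times a robust noise scale
    (successive differences, median-absolute-deviation based).  Returns
    True = spiking.  Leading-frame exclusion is honored.
    """
    cfg = cfg or SpikeCriteriaConfig()
    t = trace.drop_leading(cfg.exclude_first_frames)
    v = t.values
    trend = _bleach_trend(t.times, v, cfg, t.interval)
    floor = max(1e-12, 1e-6 * float(np.abs(v).max() or 1.0))
    rel = v / np.maximum(trend, floor) - 1.0
    d = np.diff(rel)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    sigma = max(float(sigma), 1e-12)
    return bool(rel.max() > cfg.calbryte_noise_multiple * sigma)


def calls_to_frame(calls: Sequence[SpikeCall]) -> pd.DataFrame:
    """Call table: cell_id, is_spiking, one column per criterion, cluster."""
    rows = []
    for c in calls:
        row: dict[str, object] = {"cell_id": c.cell_id, "is_spiking": c.is_spiking}
        for k in CRITERIA:
            v = c.criterion_flags.get(k)
            row[k] = "" if v is None else bool(v)
        row["cluster_id"] = "" if c.cluster_id is None else c.cluster_id
        rows.append(row)
    return pd.DataFrame(rows)
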