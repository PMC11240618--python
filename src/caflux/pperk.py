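"""ppERK immunofluorescence scoring and dose-response analysis.

Operates on per-cell object tables (one row per segmented cell) with
area (pixels²) and integrated ppERK staining intensity.  The stages are:

1. **filtering** — keep objects with area in [50, 4500] px² and
   integrated intensity < 5e6 (debris and segmentation artifacts out);
2. **positivity** — a cell is ppERK-positive when its staining exceeds
   the background threshold, supplied explicitly or derived as a high
   quantile of a no-primary-antibody control table; cells without
   detectable staining are assigned a sentinel value (-0.5) for
   plotting the zero-inflated intensity distributions;
3. **scoring** — percent positive per group; a ppERK intensity score
   combining the positive fraction with the mean log10 per-pixel
   intensity of positive cells, normalized to the earliest (1 min)
   timepoint;
4. **inhibition arithmetic** — percent inhibition vs control, and
   ATP-stimulated inhibition (baseline-subtracted 30-min vs 1-min
   proportions, drug over vehicle);
5. **dose-response** — four-parameter log-logistic fits of response
   (fraction of vehicle control) vs inhibitor concentration, with the
   conservative low-dose anchor (1 nM assumed to have no effect)
   appended as a data point.

The intensity-score formula is an explicit package choice
(fraction_positive × mean log10 mean-intensity of positives) — monotone
in both quantities it combines, and pluggable via
``PpERKConfig.score_formula``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PpERKConfig",
    "DoseResponseFit",
    "filter_objects",
    "call_positive",
    "percent_positive",
    "pperk_score",
    "percent_inhibition",
    "atp_stim_inhibition",
    "fit_loglogistic",
]


def _default_score(fraction_positive: float, log_intensities: np.ndarray) -> float:
    if log_intensities.size == 0:
        return 0.0
    return float(fraction_positive * log_intensities.mean())


@dataclass(frozen=True)
class PpERKConfig:
    """Filter bounds, positivity threshold source and scoring knobs.

    ``background_threshold`` may be left unset if a control table (cells
    stained without primary antibody) is passed to
    :func:`call_positive`; the threshold is then the
    ``control_quantile`` quantile of the control intensities.
    ``detect_on`` selects whether positivity compares integrated or
    mean (per-pixel) intensity against the threshold.
    """

    area_min: float = 50.0
    area_max: float = 4500.0
    integrated_intensity_max: float = 5.0e6
    background_threshold: float | None = None
    not_detected_value: float = -0.5
    reference_timepoint: str = "1 min"
    detect_on: str = "integrated"  # integrated | mean
    control_quantile: float = 0.99
    score_formula: Callable[[float, np.ndarray], float] = field(default=_default_score)

    def __post_init__(self) -> None:
        if not 0 < self.area_min < self.area_max:
            raise ValueError("require 0 < area_min < area_max")
        if not self.integrated_intensity_max > 0:
            raise ValueError("integrated_intensity_max: must be > 0")
        if self.detect_on not in ("integrated", "mean"):
            raise ValueError(f"detect_on: unknown mode {self.detect_on!r}")


def filter_objects(table: pd.DataFrame, cfg: PpERKConfig | None = None) -> pd.DataFrame:
    """Flag objects passing the area and intensity filters.

    Area bounds are inclusive; the intensity bound is strict (<).
    Non-passing rows are retained but flagged False, and excluded from
    every downstream proportion.  Idempotent.
    """
    cfg = cfg or PpERKConfig()
    for col in ("area_px2", "integrated_intensity"):
        if col not in table.columns:
            raise ValueError(f"table missing required column {col!r}")
    if (table["area_px2"] < 0).any():
        raise ValueError("negative object areas")
    out = table.copy()
    out["passes_filter"] = (
        (out["area_px2"] >= cfg.area_min)
        & (out["area_px2"] <= cfg.area_max)
        & (out["integrated_intensity"] < cfg.integrated_intensity_max)
    )
    return out


def _resolve_threshold(
    cfg: PpERKConfig, control_table: pd.DataFrame | None
) -> float:
    if cfg.background_threshold is not None:
        return float(cfg.background_threshold)
    if control_table is None:
        raise ValueError(
            "no background threshold: set PpERKConfig.background_threshold or "
            "pass a no-primary-antibody control table"
        )
    col = "integrated_intensity" if cfg.detect_on == "integrated" else "mean_intensity"
    if col == "mean_intensity" and "mean_intensity" not in control_table.columns:
        control_table = control_table.assign(
            mean_intensity=control_table["integrated_intensity"] / control_table["area_px2"]
        )
    return float(control_table[col].quantile(cfg.control_quantile))


def call_positive(
    table: pd.DataFrame,
    cfg: PpERKConfig | None = None,
    control_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Add detected/positive flags, mean intensity and the plot value.

    A cell is detected (= positive) when its staining intensity exceeds
    the background threshold; undetected cells get
    ``cfg.not_detected_value`` in the ``plot_value`` column, detected
    cells their log10 mean intensity.  Runs :func:`filter_objects`
    first if the table is not yet flagged.
    """
    cfg = cfg or PpERKConfig()
    if "passes_filter" not in table.columns:
        table = filter_objects(table, cfg)
    threshold = _resolve_threshold(cfg, control_table)
    out = table.copy()
    out["mean_intensity"] = out["integrated_intensity"] / out["area_px2"]
    signal = out["integrated_intensity"] if cfg.detect_on == "integrated" else out["mean_intensity"]
    out["detected"] = signal > threshold
    out["positive"] = out["detected"]
    out["background_threshold"] = threshold
    out["plot_value"] = np.where(
        out["detected"], np.log10(out["mean_intensity"].clip(lower=1e-12)), cfg.not_detected_value
    )
    return out


def percent_positive(
    table: pd.DataFrame, grouping: Sequence[str] = ("condition", "timepoint")
) -> pd.DataFrame:
    """Positive-cell percentage per group among filter-passing cells."""
    grouping = list(grouping)
    for col in grouping + ["positive", "passes_filter"]:
        if col not in table.columns:
            raise ValueError(f"table missing required column {col!r}")
    kept = table[table["passes_filter"]]
    if kept.empty:
        raise ValueError("no cells pass the filters")
    rows = []
    for keys, grp in kept.groupby(grouping, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        frac = float(grp["positive"].mean())
        rows.append(
            dict(zip(grouping, keys))
            | {"n": len(grp), "fraction_positive": frac, "percent_positive": 100.0 * frac}
        )
    return pd.DataFrame(rows)


def pperk_score(table: pd.DataFrame, cfg: PpERKConfig | None = None) -> pd.DataFrame:
    """Per-(condition, timepoint) intensity score, normalized to the
    reference timepoint within each condition.

    score = fraction_positive × mean(log10 signal/background of the
    positives) — the staining signal of each positive cell expressed in
    decades above the background threshold, so the score is
    dimensionless, strictly positive for any positive cell, monotone in
    both the positive fraction and the staining intensities, and exactly
    invariant to rescaling all intensities together with the background.
    normalized_score = score / score(reference timepoint).  Raises if a
    condition lacks the reference timepoint or has no positive cells
    there (the normalization would be undefined — supply a different
    ``reference_timepoint`` in that case).
    """
    cfg = cfg or PpERKConfig()
    kept = table[table["passes_filter"]]
    if kept.empty:
        raise ValueError("no cells pass the filters")
    if "background_threshold" in kept.columns:
        threshold = float(kept["background_threshold"].iloc[0])
    elif cfg.background_threshold is not None:
        threshold = float(cfg.background_threshold)
    else:
        raise ValueError("table lacks a background threshold; run call_positive first")
    signal_col = "integrated_intensity" if cfg.detect_on == "integrated" else "mean_intensity"
    rows = []
    for (cond, tp), grp in kept.groupby(["condition", "timepoint"], sort=True):
        frac = float(grp["positive"].mean())
        logs = np.log10(
            (grp.loc[grp["positive"], signal_col] / threshold).clip(lower=1e-12).to_numpy()
        )
        rows.append(
            {
                "condition": cond,
                "timepoint": tp,
                "n": len(grp),
                "fraction_positive": frac,
                "intensity_summary": float(logs.mean()) if logs.size else float("nan"),
                "score": cfg.score_formula(frac, logs),
            }
        )
    scores = pd.DataFrame(rows)
    normalized = []
    for cond, grp in scores.groupby("condition", sort=False):
        ref = grp[grp["timepoint"] == cfg.reference_timepoint]
        if ref.empty:
            raise ValueError(
                f"condition {cond!r}: reference timepoint {cfg.reference_timepoint!r} missing"
            )
        ref_score = float(ref["score"].iloc[0])
        if ref_score == 0.0:
            raise ValueError(
                f"condition {cond!r}: no positive cells at the reference timepoint; "
                "normalization undefined (choose another reference_timepoint)"
            )
        normalized.append(grp.assign(normalized_score=grp["score"] / ref_score))
    return pd.concat(normalized, ignore_index=True)


def percent_inhibition(treated: float, control: float) -> float:
    """100 × (1 − treated/control); the control proportion is the denominator."""
    if control <= 0:
        raise ValueError("control proportion must be > 0")
    return 100.0 * (1.0 - treated / control)


def atp_stim_inhibition(
    p30_drug: float, p1_drug: float, p30_vehicle: float, p1_vehicle: float
) -> float:
    """Percent inhibition of ATP-stimulated ppERK.

    Stimulation = (proportion positive at 30 min) − (baseline at 1 min)
    per condition; inhibition = 100 × (1 − drug stimulation / vehicle
    stimulation).  May exceed 100 or go negative; nothing is clamped.
    """
    vehicle_stim = p30_vehicle - p1_vehicle
    if vehicle_stim <= 0:
        raise ValueError("vehicle stimulation (p30 - p1) must be > 0")
    drug_stim = p30_drug - p1_drug
    return 100.0 * (1.0 - drug_stim / vehicle_stim)


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter log-logistic fit of response vs concentration.

    response(c) = lower + (upper − lower) / (1 + (c/midpoint)^hill);
    with hill > 0 the response falls from ``upper`` toward ``lower`` as
    the concentration rises (inhibitor convention).
    """

    lower: float
    upper: float
    midpoint: float  # EC50/IC50, molar
    hill: float
    converged: bool
    degenerate: bool
    residuals: np.ndarray
    concentrations: np.ndarray
    responses: np.ndarray

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return _ll4(np.log10(c), self.lower, self.upper, np.log10(self.midpoint), self.hill)

    def curve_table(self, n: int = 100) -> pd.DataFrame:
        c = np.logspace(
            np.log10(self.concentrations.min()), np.log10(self.concentrations.max()), n
        )
        return pd.DataFrame({"concentration_M": c, "response": self.predict(c)})


def _ll4(logc: np.ndarray, lower: float, upper: float, logmid: float, hill: float) -> np.ndarray:
    return lower + (upper - lower) / (1.0 + 10.0 ** (hill * (logc - logmid)))


def fit_loglogistic(
    concentrations: Sequence[float],
    responses: Sequence[float],
    anchor: tuple[float, float] | None = (1.0e-9, 1.0),
) -> DoseResponseFit:
    """Fit the 4-parameter log-logistic model by least squares.

    ``anchor`` is appended as an extra data point before fitting — the
    conservative assumption that a very low dose (1 nM) leaves the
    response at vehicle level, which pins down the upper plateau when
    the tested range lacks a true no-effect dose.  Bounds keep
    0 ≤ lower, upper ≤ 1.2 (responses are fractions of vehicle control).

    Non-convergence is reported via ``converged=False``; an essentially
    flat response via ``degenerate=True``.  Neither raises.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size:
        raise ValueError("concentrations and responses must align")
    if anchor is not None:
        c = np.append(c, anchor[0])
        r = np.append(r, anchor[1])
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (molar)")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations (anchor included)")
    logc = np.log10(c)
    flat = float(np.ptp(r)) < 1e-3
    if flat:
        mid = 10.0 ** float(logc.mean())
        return DoseResponseFit(
            lower=float(r.mean()), upper=float(r.mean()), midpoint=mid, hill=1.0,
            converged=True, degenerate=True, residuals=r - r.mean(),
            concentrations=c, responses=r,
        )
    p0 = (max(float(r.min()), 0.0), min(float(r.max()), 1.2), float(logc.mean()), 1.0)
    bounds = ([0.0, 0.0, logc.min() - 3.0, 1e-3], [1.2, 1.2, logc.max() + 3.0, 20.0])
    try:
        popt, _ = curve_fit(_ll4, logc, r, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except (RuntimeError, ValueError):
        popt, converged = np.array(p0), False
    lower, upper, logmid, hill = (float(v) for v in popt)
    resid = r - _ll4(logc, lower, upper, logmid, hill)
    return DoseResponseFit(
        lower=lower, upper=upper, midpoint=10.0**logmid, hill=hill,
        converged=converged, degenerate=False, residuals=resid,
        concentrations=c, responses=r,
    )
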