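"""Store-operated calcium entry (SOCE) quantification.

The assay is a three-phase perfusion protocol on Fura-2-loaded cells:

1. equilibration in Ca²⁺-free buffer (baseline acquisition),
2. SERCA inhibition (CPA) in Ca²⁺-free buffer — passive release of ER
   Ca²⁺ stores into the cytoplasm; the transient's size reports ER
   Ca²⁺ content,
3. re-addition of extracellular Ca²⁺ (still under CPA) — influx through
   store-operated channels; the rise reports SOCE activity.

ER content and SOCE activity are the time integrals of the
baseline-subtracted ratio trace over phases 2 and 3 respectively
(trapezoid rule on the sampled grid), with the baseline taken as the
mean signal over a window at the end of the equilibration phase.
Negative-going excursions integrate negative; nothing is clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traceio import CellTrace

__all__ = ["SOCESchedule", "SOCEResult", "quantify_soce", "summarize_soce", "fit_clearance"]


@dataclass(frozen=True)
class SOCESchedule:
    """Phase timing of a three-phase SOCE assay, in seconds.

    Defaults follow the standard protocol: 10 min equilibration,
    8 min of CPA in Ca²⁺-free buffer, 8 min of Ca²⁺ re-addition.
    ``baseline_window`` must lie inside phase 1; the default is the last
    2 min of equilibration, when the signal has settled.
    """

    phase1_span: tuple[float, float] = (0.0, 600.0)
    phase2_span: tuple[float, float] = (600.0, 1080.0)
    phase3_span: tuple[float, float] = (1080.0, 1560.0)
    baseline_window: tuple[float, float] = field(default=(480.0, 600.0))

    def __post_init__(self) -> None:
        spans = [self.phase1_span, self.phase2_span, self.phase3_span]
        for name, (a, b) in zip(("phase1", "phase2", "phase3"), spans):
            if not b > a:
                raise ValueError(f"{name}_span must be increasing, got ({a}, {b})")
        if not (
            self.phase1_span[1] <= self.phase2_span[0]
            and self.phase2_span[1] <= self.phase3_span[0]
        ):
            raise ValueError("phases must be ordered and non-overlapping")
        lo, hi = self.baseline_window
        if not (self.phase1_span[0] <= lo < hi <= self.phase1_span[1]):
            raise ValueError("baseline_window must lie within phase1_span")

    @property
    def total_span(self) -> tuple[float, float]:
        return (self.phase1_span[0], self.phase3_span[1])


@dataclass(frozen=True)
class SOCEResult:
    """Per-cell baseline and phase integrals (signal·s)."""

    cell_id: str
    er_content: float
    soce_activity: float
    baseline: float


def _phase_mask(times: np.ndarray, span: tuple[float, float]) -> np.ndarray:
    return (times >= span[0]) & (times <= span[1])


def quantify_soce(trace: CellTrace, schedule: SOCESchedule | None = None) -> SOCEResult:
    """Baseline-subtracted phase-2 / phase-3 integrals for one cell.

    Raises if the trace does not span the full schedule.
    """
    schedule = schedule or SOCESchedule()
    t, v = trace.times, trace.values
    lo, hi = schedule.total_span
    if t[0] > lo or t[-1] < hi:
        raise ValueError(
            f"trace {trace.cell_id!r} spans [{t[0]}, {t[-1]}] s but the schedule "
            f"requires [{lo}, {hi}] s"
        )
    bmask = _phase_mask(t, schedule.baseline_window)
    if not bmask.any():
        raise ValueError(f"trace {trace.cell_id!r}: no samples in baseline window")
    baseline = float(v[bmask].mean())

    def integral(span: tuple[float, float]) -> float:
        m = _phase_mask(t, span)
        if m.sum() < 2:
            raise ValueError(
                f"trace {trace.cell_id!r}: fewer than 2 samples in phase {span}"
            )
        return float(np.trapezoid(v[m] - baseline, t[m]))

    return SOCEResult(
        cell_id=trace.cell_id,
        er_content=integral(schedule.phase2_span),
        soce_activity=integral(schedule.phase3_span),
        baseline=baseline,
    )


def summarize_soce(
    results: list[SOCEResult], conditions: dict[str, str] | list[str]
) -> pd.DataFrame:
    """Per-condition distribution summaries of ER content and SOCE activity.

    ``conditions`` maps cell_id -> condition label (or is a list aligned
    with ``results``).  Returns one row per condition with n, mean,
    median and quartiles of both integrals.
    """
    if not results:
        raise ValueError("no results to summarize")
    if isinstance(conditions, dict):
        missing = [r.cell_id for r in results if r.cell_id not in conditions]
        if missing:
            raise ValueError(f"no condition label for cells: {missing}")
        labels = [conditions[r.cell_id] for r in results]
    else:
        if len(conditions) != len(results):
            raise ValueError("conditions list must align with results")
        labels = list(conditions)
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "condition": labels,
            "er_content": [r.er_content for r in results],
            "soce_activity": [r.soce_activity for r in results],
        }
    )
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        row: dict[str, object] = {"condition": cond, "n": len(grp)}
        for col in ("er_content", "soce_activity"):
            x = grp[col].to_numpy()
            row[f"{col}_mean"] = float(x.mean())
            row[f"{col}_median"] = float(np.median(x))
            row[f"{col}_q1"] = float(np.percentile(x, 25))
            row[f"{col}_q3"] = float(np.percentile(x, 75))
        rows.append(row)
    return pd.DataFrame(rows)


def fit_clearance(trace: CellTrace, schedule: SOCESchedule | None = None) -> dict:
    """Exploratory cytoplasmic-clearance time constant.

    Fits ``A·exp(-t/tau) + c`` to the post-peak segment of phase 2 (the
    decay after the CPA-evoked ER-release transient) by nonlinear least
    squares and reports ``tau`` in seconds.  Returns
    ``{"tau_s": float, "converged": bool}``; a flat or non-decaying
    segment reports ``converged=False`` rather than raising.
    """
    from scipy.optimize import curve_fit

    schedule = schedule or SOCESchedule()
    t, v = trace.times, trace.values
    m = _phase_mask(t, schedule.phase2_span)
    tt, vv = t[m], v[m]
    if tt.size < 5:
        return {"tau_s": float("nan"), "converged": False}
    ipk = int(np.argmax(vv))
    tt, vv = tt[ipk:] - tt[ipk], vv[ipk:]
    if tt.size < 5 or np.ptp(vv) == 0:
        return {"tau_s": float("nan"), "converged": False}

    def model(x, a, tau, c):
        return a * np.exp(-x / tau) + c

    try:
        popt, _ = curve_fit(
            model,
            tt,
            vv,
            p0=(max(vv[0] - vv[-1], 1e-6), max(tt[-1] / 3.0, 1.0), vv[-1]),
            maxfev=5000,
        )
    except RuntimeError:
        return {"tau_s": float("nan"), "converged": False}
    tau = float(popt[1])
    return {"tau_s": tau, "converged": bool(np.isfinite(tau) and tau > 0)}
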