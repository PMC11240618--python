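"""Synthetic single-cell calcium traces, SOCE assay traces and ppERK tables.

Everything here is a pure function of (parameters, seed), so every
downstream stage — spike classification, bootstrap statistics, SOCE
integrals, ppERK scoring — can be exercised against known ground truth.

The generators emulate the acquisition the analysis assumes:

* 40-min recordings sampled every 5 s (481 points), either as Fura-2
  340/380 ratio traces (dimensionless, resting ratio ~0.8) or as
  Calbryte-520 intensity traces subject to multiplicative exponential
  photobleaching;
* spiking cells carry heterogeneous spike shapes — isolated transients,
  oscillatory transient trains, and plateaus — spanning magnitudes,
  shapes and frequencies from near-constant spiking down to a single
  event per recording;
* three-phase SOCE traces with prescribed ER-release and SOCE bump
  areas;
* zero-inflated ppERK object tables with a log-normal positive
  subpopulation.

Default numeric choices (spike amplitudes, kinetics, noise) are stated
assumptions, not measured values; see ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .soce import SOCESchedule
from .traceio import CellTrace, TracePopulation

__all__ = [
    "SpikeShapeParams",
    "AcquisitionParams",
    "GroundTruth",
    "gen_trace",
    "gen_population",
    "gen_soce_trace",
    "gen_pperk_table",
    "default_shape_mix",
    "transient_peak_offset",
    "ground_truth_frame",
]


@dataclass(frozen=True)
class SpikeShapeParams:
    """Parameters of one cell's spiking pattern.

    ``transient`` events are difference-of-exponentials kernels
    (rise/decay time constants in seconds) peak-normalized to
    ``amplitude``.  ``oscillatory`` is a periodic train of such
    transients at ``frequency`` Hz.  ``plateau`` is a smoothed boxcar of
    width ``decay_time`` with tanh edges of time constant ``rise_time``,
    also peak-normalized.

    ``event_times`` (seconds, event onsets) may be given explicitly;
    otherwise events are placed deterministically within the recording.
    """

    shape_kind: str  # transient | oscillatory | plateau
    amplitude: float
    rise_time: float = 10.0
    decay_time: float = 40.0
    frequency: float | None = None
    n_events: int = 1
    event_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.shape_kind not in ("transient", "oscillatory", "plateau"):
            raise ValueError(f"shape_kind: unknown kind {self.shape_kind!r}")
        if not self.amplitude > 0:
            raise ValueError("amplitude: must be > 0")
        if not self.rise_time > 0:
            raise ValueError("rise_time: must be > 0")
        if not self.decay_time > 0:
            raise ValueError("decay_time: must be > 0")
        if self.shape_kind == "oscillatory":
            if self.frequency is None or not self.frequency > 0:
                raise ValueError("frequency: required and > 0 for oscillatory shapes")
        if self.n_events < 1:
            raise ValueError("n_events: must be >= 1 for spiking traces")
        if self.event_times is not None:
            object.__setattr__(self, "event_times", tuple(float(t) for t in self.event_times))


@dataclass(frozen=True)
class AcquisitionParams:
    """Sampling grid, dye mode and nuisance-signal parameters."""

    interval: float = 5.0
    duration: float = 2400.0
    dye_mode: str = "fura_ratio"  # fura_ratio | calbryte_intensity
    bleach_rate: float = 0.0
    baseline_level: float = 0.8
    noise_sd: float = 0.005
    drift_slope: float = 0.0

    def __post_init__(self) -> None:
        if not self.interval > 0:
            raise ValueError("interval: must be > 0")
        if self.duration < self.interval:
            raise ValueError("duration: must be >= interval")
        if self.dye_mode not in ("fura_ratio", "calbryte_intensity"):
            raise ValueError(f"dye_mode: unknown mode {self.dye_mode!r}")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate: must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd: must be >= 0")

    @property
    def channel(self) -> str:
        return "fura_ratio" if self.dye_mode == "fura_ratio" else "calbryte"

    def time_grid(self) -> np.ndarray:
        n = int(math.floor(self.duration / self.interval)) + 1
        return np.arange(n, dtype=float) * self.interval


@dataclass(frozen=True)
class GroundTruth:
    """True label for one synthetic cell (shape present iff spiking)."""

    cell_id: str
    is_spiking: bool
    shape: SpikeShapeParams | None = None

    def __post_init__(self) -> None:
        if self.is_spiking != (self.shape is not None):
            raise ValueError("is_spiking must hold exactly when a shape is present")


def transient_peak_offset(rise_time: float, decay_time: float) -> float:
    """Time from event onset to the peak of the transient kernel.

    For the difference-of-exponentials kernel exp(-s/d) - exp(-s/r) the
    maximum sits at s* = (r·d/(d-r))·ln(d/r) (limit r·1 at r = d).
    """
    r, d = rise_time, decay_time
    if math.isclose(r, d):
        return r  # limit of the expression as d -> r
    return (r * d / (d - r)) * math.log(d / r)


def _transient_kernel(s: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials; zero for s < 0."""
    out = np.zeros_like(s)
    pos = s >= 0
    sp = s[pos]
    if math.isclose(rise, decay):
        # limiting alpha-function (s/r)·exp(1 - s/r), peak 1 at s = r
        out[pos] = (sp / rise) * np.exp(1.0 - sp / rise)
        return out
    raw = np.exp(-sp / decay) - np.exp(-sp / rise)
    speak = transient_peak_offset(rise, decay)
    peak = math.exp(-speak / decay) - math.exp(-speak / rise)
    out[pos] = raw / peak
    return out


def _plateau_kernel(t: np.ndarray, onset: float, width: float, edge: float) -> np.ndarray:
    """Smoothed boxcar with tanh edges, peak-normalized."""
    raw = 0.5 * (np.tanh((t - onset) / edge) - np.tanh((t - onset - width) / edge))
    peak = math.tanh(width / (2.0 * edge))
    return raw / peak


def _resolve_event_times(shape: SpikeShapeParams, acq: AcquisitionParams) -> np.ndarray:
    if shape.event_times is not None:
        times = np.asarray(shape.event_times, dtype=float)
    elif shape.shape_kind == "oscillatory":
        start = 0.15 * acq.duration
        times = start + np.arange(shape.n_events) / shape.frequency
    else:
        # spread events through the middle of the recording
        times = np.linspace(0.2 * acq.duration, 0.8 * acq.duration, shape.n_events)
    if np.any(times < 0) or np.any(times > acq.duration):
        raise ValueError("event_times: events must lie within the trace duration")
    return times


def _deterministic_signal(
    shape: SpikeShapeParams | None, acq: AcquisitionParams, t: np.ndarray
) -> np.ndarray:
    signal = np.full_like(t, acq.baseline_level) + acq.drift_slope * t
    if shape is None:
        return signal
    events = _resolve_event_times(shape, acq)
    if shape.shape_kind == "plateau":
        for e in events:
            signal += shape.amplitude * _plateau_kernel(
                t, e, shape.decay_time, shape.rise_time
            )
    else:
        for e in events:
            signal += shape.amplitude * _transient_kernel(
                t - e, shape.rise_time, shape.decay_time
            )
    return signal


def gen_trace(
    shape: SpikeShapeParams | None,
    acq: AcquisitionParams | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    cell_id: str = "c0",
    well: str | None = None,
) -> CellTrace:
    """One synthetic trace: baseline + events + drift + Gaussian noise,
    multiplied by exp(-bleach_rate·t) in Calbryte mode.

    ``shape=None`` yields a non-spiking trace.  Identical inputs and seed
    give bit-identical traces.
    """
    acq = acq or AcquisitionParams()
    t = acq.time_grid()
    signal = _deterministic_signal(shape, acq, t)
    if acq.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, acq.noise_sd, size=t.size)
    if acq.dye_mode == "calbryte_intensity" and acq.bleach_rate > 0:
        signal = signal * np.exp(-acq.bleach_rate * t)
    return CellTrace(cell_id=cell_id, times=t, values=signal, channel=acq.channel, well=well)


def default_shape_mix(amplitude_scale: float = 1.0) -> list[SpikeShapeParams]:
    """The heterogeneous spike-shape repertoire used as the default mix.

    Spans single large transients, repeated transients, minute-scale
    oscillatory trains and plateaus; amplitudes are ratio-unit excursions
    of 0.35-0.6, about 2-3.5x the 0.17 spike-amplitude threshold.
    """
    a = amplitude_scale
    return [
        SpikeShapeParams("transient", amplitude=0.6 * a, rise_time=8, decay_time=45, n_events=1),
        SpikeShapeParams("transient", amplitude=0.4 * a, rise_time=10, decay_time=40, n_events=3),
        SpikeShapeParams(
            "oscillatory", amplitude=0.35 * a, rise_time=6, decay_time=20,
            frequency=1.0 / 90.0, n_events=12,
        ),
        SpikeShapeParams("plateau", amplitude=0.4 * a, rise_time=15, decay_time=300, n_events=1),
    ]


def gen_population(
    n: int,
    spike_fraction: float,
    shape_mix: Sequence[SpikeShapeParams] | SpikeShapeParams | None = None,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
    condition: str = "synthetic",
) -> tuple[TracePopulation, list[GroundTruth]]:
    """A population of ``n`` traces with exactly round(n·spike_fraction)
    spiking members, plus its ground truth.

    One top-level seed spawns an independent random substream per cell,
    so each cell's trace is invariant to population size and ordering.
    Spiking cells draw a shape from ``shape_mix`` (default:
    :func:`default_shape_mix`) with a per-cell jitter of event times.
    """
    if n < 1:
        raise ValueError("n: need at least one cell")
    if not 0.0 <= spike_fraction <= 1.0:
        raise ValueError("spike_fraction: must be in [0, 1]")
    acq = acq or AcquisitionParams()
    if shape_mix is None:
        shape_mix = default_shape_mix()
    elif isinstance(shape_mix, SpikeShapeParams):
        shape_mix = [shape_mix]
    n_spiking = int(round(n * spike_fraction))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    assign_rng = np.random.default_rng(children[n])
    flags = np.zeros(n, dtype=bool)
    flags[assign_rng.permutation(n)[:n_spiking]] = True

    traces: list[CellTrace] = []
    truth: list[GroundTruth] = []
    width = max(3, len(str(n - 1)))
    for i in range(n):
        cid = f"c{i:0{width}d}"
        cell_rng = np.random.default_rng(children[i])
        shape: SpikeShapeParams | None = None
        if flags[i]:
            shape = shape_mix[int(cell_rng.integers(len(shape_mix)))]
            if shape.event_times is None:
                # jitter event placement per cell so events decorrelate
                events = _resolve_event_times(shape, acq)
                span = 0.1 * acq.duration
                jitter = cell_rng.uniform(-span, span)
                events = np.clip(events + jitter, 0.0, acq.duration)
                shape = replace(shape, event_times=tuple(events))
        traces.append(gen_trace(shape, acq, seed=cell_rng, cell_id=cid))
        truth.append(GroundTruth(cell_id=cid, is_spiking=bool(flags[i]), shape=shape))
    return TracePopulation(traces=traces, condition=condition), truth


def ground_truth_frame(truth: list[GroundTruth]) -> pd.DataFrame:
    """Ground truth as a flat table (sidecar for the trace table)."""
    return pd.DataFrame(
        {
            "cell_id": [g.cell_id for g in truth],
            "is_spiking": [g.is_spiking for g in truth],
            "shape_kind": [g.shape.shape_kind if g.shape else "" for g in truth],
            "amplitude": [g.shape.amplitude if g.shape else np.nan for g in truth],
        }
    )


def _hann_bump(t: np.ndarray, start: float, width: float, area: float) -> np.ndarray:
    """Raised-cosine bump supported on [start, start+width] with exact
    analytic integral ``area``."""
    out = np.zeros_like(t)
    if area == 0.0:
        return out
    u = (t - start) / width
    inside = (u >= 0) & (u <= 1)
    out[inside] = (area / width) * (1.0 - np.cos(2.0 * np.pi * u[inside]))
    return out


def gen_soce_trace(
    er_area: float,
    soce_area: float,
    schedule: SOCESchedule | None = None,
    acq: AcquisitionParams | None = None,
    seed: int | np.random.Generator = 0,
    cell_id: str = "c0",
    bump_margin_frac: float = 0.1,
) -> CellTrace:
    """Three-phase SOCE assay trace with prescribed bump areas.

    Phase 1 is flat baseline; phases 2 and 3 each carry one raised-cosine
    bump whose analytic integral above baseline equals ``er_area`` and
    ``soce_area`` (signal·s).  Bump supports are inset from the phase
    edges by ``bump_margin_frac`` of the phase length and snapped to the
    sampling grid, so the trapezoid integral of a noiseless trace matches
    the requested area to well within 1%.
    """
    if er_area < 0 or soce_area < 0:
        raise ValueError("er_area/soce_area: bump areas must be >= 0")
    schedule = schedule or SOCESchedule()
    acq = acq or AcquisitionParams(duration=schedule.total_span[1])
    t = acq.time_grid()
    if t[-1] < schedule.total_span[1]:
        raise ValueError(
            "duration: acquisition must cover the full schedule "
            f"(needs {schedule.total_span[1]} s, trace ends at {t[-1]} s)"
        )
    signal = np.full_like(t, acq.baseline_level)

    def add_bump(span: tuple[float, float], area: float) -> None:
        lo, hi = span
        margin = bump_margin_frac * (hi - lo)
        start = math.ceil((lo + margin) / acq.interval) * acq.interval
        end = math.floor((hi - margin) / acq.interval) * acq.interval
        width = end - start
        if width < 4 * acq.interval:
            raise ValueError(
                f"phase {span}: bump support of {width} s does not fit the phase window"
            )
        nonlocal signal
        signal = signal + _hann_bump(t, start, width, area)

    add_bump(schedule.phase2_span, er_area)
    add_bump(schedule.phase3_span, soce_area)
    if acq.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, acq.noise_sd, size=t.size)
    return CellTrace(cell_id=cell_id, times=t, values=signal, channel=acq.channel)


def gen_pperk_table(
    n_cells: int,
    frac_positive: float,
    intensity_mean: float = 5.2,
    intensity_sd: float = 0.35,
    area_range: tuple[float, float] = (100.0, 2000.0),
    seed: int = 0,
    condition: str = "synthetic",
    timepoint: str = "1 min",
    background_level: float = 1.0e3,
) -> pd.DataFrame:
    """Zero-inflated synthetic ppERK object table.

    Exactly round(n_cells·frac_positive) cells are truly positive, with
    log10 integrated intensity ~ Normal(``intensity_mean``,
    ``intensity_sd``); the remainder are not-detected, with integrated
    intensity uniform below ``background_level``.  Object areas are
    uniform over ``area_range`` (pixels²).  Columns: cell_id, condition,
    timepoint, area_px2, integrated_intensity, true_positive.
    """
    if n_cells < 1:
        raise ValueError("n_cells: need at least one cell")
    if not 0.0 <= frac_positive <= 1.0:
        raise ValueError("frac_positive: must be in [0, 1]")
    if intensity_sd < 0:
        raise ValueError("intensity_sd: must be >= 0")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_cells * frac_positive))
    flags = np.zeros(n_cells, dtype=bool)
    flags[rng.permutation(n_cells)[:n_pos]] = True
    area = rng.uniform(area_range[0], area_range[1], size=n_cells)
    intensity = np.empty(n_cells)
    intensity[flags] = 10.0 ** rng.normal(intensity_mean, intensity_sd, size=n_pos)
    intensity[~flags] = rng.uniform(0.0, 0.8 * background_level, size=n_cells - n_pos)
    width = max(3, len(str(n_cells - 1)))
    return pd.DataFrame(
        {
            "cell_id": [f"p{i:0{width}d}" for i in range(n_cells)],
            "condition": condition,
            "timepoint": timepoint,
            "area_px2": area,
            "integrated_intensity": intensity,
            "true_positive": flags,
        }
    )
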