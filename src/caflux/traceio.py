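"""Trace containers and I/O for single-cell calcium imaging.

A recording is represented per cell as a :class:`CellTrace`: a uniformly
sampled fluorescence (or excitation-ratio) time series.  Populations of
traces sharing one acquisition grid are grouped in a
:class:`TracePopulation`, the unit consumed by the spike classifier and
the SOCE quantifier.

Trace tables travel as long-format delimited text with columns
``cell_id, time_s, value, channel[, well]``; CSV or TSV is selected by
file extension.  Image time series are multipage grayscale TIFF stacks;
segmentation is consumed, never produced, as a labeled mask image in
which each object's pixels carry a unique positive integer region ID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CellTrace",
    "TracePopulation",
    "LabeledMask",
    "load_traces",
    "save_traces",
    "read_stack",
    "read_mask",
    "extract_object_traces",
    "compute_fura_ratio",
]

CHANNELS = ("fura_340", "fura_380", "fura_ratio", "calbryte")

# relative tolerance when asserting a uniform sampling grid
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class CellTrace:
    """One cell's uniformly sampled fluorescence time series.

    Parameters
    ----------
    cell_id:
        Identifier unique within a population.
    times:
        Sample times in seconds, strictly increasing with constant step.
    values:
        Signal at each time point: a 340/380 excitation ratio
        (dimensionless) or an integrated dye intensity (arbitrary units).
    channel:
        One of ``fura_340``, ``fura_380``, ``fura_ratio``, ``calbryte``.
    well:
        Optional well/position identifier.
    """

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    channel: str = "fura_ratio"
    well: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError(
                f"trace {self.cell_id!r}: times and values must be 1-D of equal length"
            )
        if times.size < 2:
            raise ValueError(f"trace {self.cell_id!r}: need at least 2 time points")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError(f"trace {self.cell_id!r}: times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_GRID_RTOL, atol=1e-9):
            raise ValueError(f"trace {self.cell_id!r}: non-uniform sampling grid")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"trace {self.cell_id!r}: non-finite values")
        if self.channel not in CHANNELS:
            raise ValueError(
                f"trace {self.cell_id!r}: unknown channel {self.channel!r}; "
                f"expected one of {CHANNELS}"
            )

    @property
    def interval(self) -> float:
        """Sampling interval in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def drop_leading(self, n_frames: int) -> "CellTrace":
        """Return a copy with the first ``n_frames`` samples removed."""
        if n_frames <= 0:
            return self
        if self.times.size - n_frames < 2:
            raise ValueError(
                f"trace {self.cell_id!r}: dropping {n_frames} frames leaves <2 points"
            )
        return replace(self, times=self.times[n_frames:], values=self.values[n_frames:])


@dataclass
class TracePopulation:
    """A set of traces sharing a condition and one sampling grid."""

    traces: list[CellTrace]
    condition: str = ""
    manual_labels: dict[str, bool] | None = field(default=None)

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cell_ids in population: {dupes}")
        if self.traces:
            ref = self.traces[0].times
            for t in self.traces[1:]:
                if t.times.size != ref.size or not np.allclose(
                    t.times, ref, rtol=_GRID_RTOL, atol=1e-9
                ):
                    raise ValueError(
                        f"trace {t.cell_id!r} is not on the shared sampling grid"
                    )
        if self.manual_labels is not None:
            unknown = set(self.manual_labels) - set(ids)
            if unknown:
                raise ValueError(f"manual labels for unknown cells: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[CellTrace]:
        return iter(self.traces)

    @property
    def cell_ids(self) -> list[str]:
        return [t.cell_id for t in self.traces]

    @property
    def times(self) -> np.ndarray:
        if not self.traces:
            raise ValueError("empty population has no time grid")
        return self.traces[0].times

    def values_matrix(self) -> np.ndarray:
        """Stack values as an (n_cells, n_timepoints) array."""
        return np.vstack([t.values for t in self.traces])

    def drop_leading(self, n_frames: int) -> "TracePopulation":
        if n_frames <= 0:
            return self
        return TracePopulation(
            traces=[t.drop_leading(n_frames) for t in self.traces],
            condition=self.condition,
            manual_labels=self.manual_labels,
        )


@dataclass(frozen=True)
class LabeledMask:
    """Segmentation label image: 0 is background, each object a unique ID."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("mask must be a 2-D label image")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("mask must be integer-typed (0 = background)")
        if labels.min() < 0:
            raise ValueError("mask labels must be non-negative")
        object.__setattr__(self, "labels", labels)

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


_REQUIRED_COLUMNS = ("cell_id", "time_s", "value", "channel")


def load_traces(path: str | Path, condition: str = "") -> TracePopulation:
    """Read a long-format trace table into a :class:`TracePopulation`.

    The file must contain columns ``cell_id, time_s, value, channel`` and
    may carry an optional ``well`` column.  Every cell must share one
    uniform sampling grid; a ragged or non-uniform grid raises with the
    offending cell named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_s")
        well = None
        if "well" in grp.columns:
            w = grp["well"].iloc[0]
            well = None if pd.isna(w) else str(w)
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                times=grp["time_s"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                channel=str(grp["channel"].iloc[0]),
                well=well,
            )
        )
    return TracePopulation(traces=traces, condition=condition)


def save_traces(population: TracePopulation, path: str | Path) -> None:
    """Write a population as long-format delimited text (round-trips with
    :func:`load_traces`)."""
    path = Path(path)
    rows = []
    has_well = any(t.well is not None for t in population)
    for t in population:
        block = pd.DataFrame(
            {
                "cell_id": t.cell_id,
                "time_s": t.times,
                "value": t.values,
                "channel": t.channel,
            }
        )
        if has_well:
            block["well"] = t.well
        rows.append(block)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=list(_REQUIRED_COLUMNS)
    )
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multipage grayscale TIFF time series as (n_frames, H, W)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D multipage stack, got shape {arr.shape}")
    return arr


def read_mask(path: str | Path) -> LabeledMask:
    """Read a labeled segmentation mask image."""
    arr = tifffile.imread(str(path))
    return LabeledMask(labels=np.asarray(arr).astype(np.int64))


def extract_object_traces(
    stack: np.ndarray,
    mask: LabeledMask,
    interval: float = 5.0,
    channel: str = "calbryte",
    well: str | None = None,
    include_border_objects: bool = True,
) -> TracePopulation:
    """Integrated-intensity trace per mask object across a time series.

    The mask (derived once, from the first frame of the well's series) is
    applied unchanged to every frame; per object per frame the value is
    the sum of pixel intensities under the object's label.  Traces are
    keyed ``obj<region_id>``.

    ``include_border_objects=False`` drops objects touching the image
    border before extraction.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"stack must be (frames, H, W); got shape {stack.shape}")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames to form traces")
    if stack.shape[1:] != mask.labels.shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} does not match frame shape {stack.shape[1:]}"
        )
    labels = mask.labels
    region_ids = mask.region_ids
    if not include_border_objects and region_ids.size:
        border = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        touching = np.unique(border[border > 0])
        region_ids = region_ids[~np.isin(region_ids, touching)]
    if region_ids.size == 0:
        warnings.warn("mask contains no objects; returning empty population")
        return TracePopulation(traces=[])
    n_frames = stack.shape[0]
    times = np.arange(n_frames, dtype=float) * float(interval)
    # sum pixel intensities per label per frame in one bincount pass per frame
    flat_labels = labels.ravel()
    max_label = int(labels.max())
    traces = []
    sums = np.empty((n_frames, max_label + 1), dtype=float)
    for f in range(n_frames):
        sums[f] = np.bincount(
            flat_labels, weights=stack[f].ravel().astype(float), minlength=max_label + 1
        )
    for rid in region_ids:
        traces.append(
            CellTrace(
                cell_id=f"obj{int(rid)}",
                times=times,
                values=sums[:, int(rid)],
                channel=channel,
                well=well,
            )
        )
    return TracePopulation(traces=traces)


def compute_fura_ratio(trace340: CellTrace, trace380: CellTrace) -> CellTrace:
    """Elementwise 340/380 excitation ratio for one cell.

    The ratio of Ca²⁺-bound (340 nm-excited) to Ca²⁺-free (380 nm-excited)
    Fura-2 signal rises monotonically with cytoplasmic Ca²⁺, making the
    ratio trace a direct per-cell calcium readout.
    """
    if trace340.cell_id != trace380.cell_id:
        raise ValueError(
            f"cell_id mismatch: {trace340.cell_id!r} vs {trace380.cell_id!r}"
        )
    allowed = {"fura_340", "fura_380"}
    if trace340.channel not in allowed or trace380.channel not in allowed:
        raise ValueError(
            "ratio requires single-wavelength Fura channels, got "
            f"{trace340.channel!r} and {trace380.channel!r}"
        )
    if trace340.times.size != trace380.times.size or not np.allclose(
        trace340.times, trace380.times, rtol=_GRID_RTOL, atol=1e-9
    ):
        raise ValueError(f"cell {trace340.cell_id!r}: sampling grids differ")
    if np.any(trace380.values <= 0):
        raise ValueError(
            f"cell {trace340.cell_id!r}: non-positive 380 nm values; ratio undefined"
        )
    return CellTrace(
        cell_id=trace340.cell_id,
        times=trace340.times.copy(),
        values=trace340.values / trace380.values,
        channel="fura_ratio",
        well=trace340.well,
    )
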