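"""Bootstrap estimation of population proportions.

Two resampling procedures over per-cell boolean labels (spiking /
ppERK-positive):

* :func:`bootstrap_proportion` — repeated with-replacement draws of a
  fixed sample size; the mean of the per-draw proportions is the point
  estimate and the 2.5/97.5 percentiles form the confidence interval.
  Standard study settings: 200 cells × 100 iterations when ~1000 cells
  are annotated (Fura recordings), 50 × 100 for the smaller Calbryte
  annotation sets; when no sample size is given it defaults to at least
  20% of the annotated cells and no fewer than 50.
* :func:`sampled_mean_proportion` — mean ± SD of the proportion over a
  small number of large draws (1000 cells × 10 repeats by default),
  used as the error model for ppERK percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["BootstrapConfig", "BootstrapEstimate", "bootstrap_proportion", "sampled_mean_proportion"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings.

    ``sample_size=None`` resolves to max(``min_cells``,
    ceil(``min_fraction`` · n_annotated)).
    """

    sample_size: int | None = None
    n_iterations: int = 100
    seed: int = 0
    min_fraction: float = 0.20
    min_cells: int = 50
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.sample_size is not None and self.sample_size < 1:
            raise ValueError("sample_size: must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations: must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level: must be in (0, 1)")

    def resolve_sample_size(self, n_annotated: int) -> int:
        if self.sample_size is not None:
            return self.sample_size
        return max(self.min_cells, math.ceil(self.min_fraction * n_annotated))


@dataclass(frozen=True)
class BootstrapEstimate:
    """Point estimate, percentile CI and the full resample distribution."""

    point: float
    ci_low: float
    ci_high: float
    resamples: np.ndarray
    n_annotated: int
    config: BootstrapConfig = field(default_factory=BootstrapConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
            raise ValueError("CI bounds must satisfy 0 <= low <= high <= 1")


def bootstrap_proportion(
    labels: Sequence[bool], cfg: BootstrapConfig | None = None
) -> BootstrapEstimate:
    """Bootstrap the proportion of True labels.

    Draws ``n_iterations`` samples of the resolved sample size with
    replacement, records each sample's proportion, and summarizes with
    the mean and the percentile interval at ``ci_level``.  Deterministic
    given ``cfg.seed``.
    """
    cfg = cfg or BootstrapConfig()
    arr = np.asarray(labels, dtype=bool)
    if arr.size == 0:
        raise ValueError("labels must be non-empty")
    k = cfg.resolve_sample_size(arr.size)
    rng = np.random.default_rng(cfg.seed)
    draws = rng.integers(0, arr.size, size=(cfg.n_iterations, k))
    props = arr[draws].mean(axis=1)
    alpha = (1.0 - cfg.ci_level) / 2.0
    lo, hi = np.percentile(props, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapEstimate(
        point=float(props.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        resamples=props,
        n_annotated=int(arr.size),
        config=cfg,
    )


def sampled_mean_proportion(
    labels: Sequence[bool],
    n_sample: int = 1000,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean ± SD of the positive proportion over repeated large draws.

    Each repeat draws ``n_sample`` cells with replacement and records
    the proportion of True labels; returns (mean, SD) of the per-repeat
    proportions.  A single repeat has no spread and reports SD 0 with a
    warning.
    """
    arr = np.asarray(labels, dtype=bool)
    if arr.size == 0:
        raise ValueError("labels must be non-empty")
    if n_sample < 1 or n_repeats < 1:
        raise ValueError("n_sample and n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, arr.size, size=(n_repeats, n_sample))
    props = arr[draws].mean(axis=1)
    if n_repeats == 1:
        warnings.warn("n_repeats=1: spread undefined, reporting SD 0")
        return float(props.mean()), 0.0
    return float(props.mean()), float(props.std(ddof=1))
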