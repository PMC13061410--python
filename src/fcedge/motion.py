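"""Head-motion quality control for parcellated BOLD runs.

Framewise displacement is computed from the six rigid-body realignment
parameters (three translations in mm, three rotations in rad).  Rotations
are converted to arc displacement on a sphere of configurable radius
(default 50 mm, the convention of the scrubbing literature) before the six
differenced channels are pooled.  Volumes flanking supra-threshold
transitions are censored, and runs retaining too few volumes mark the
subject for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_THRESHOLD_MM = 0.5
DEFAULT_MIN_RETENTION = 0.5
DEFAULT_HALF_WIDTH = 1


@dataclass
class MotionTrace:
    """Rigid-body motion parameters for one run.

    ``params`` is volumes x 6: tx, ty, tz in mm then rx, ry, rz in rad.
    """

    subject_id: str
    run_id: str
    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion params must be volumes x 6, got {self.params.shape}"
            )
        if self.params.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 volumes")
        if not np.all(np.isfinite(self.params)):
            raise ValueError(
                f"motion trace {self.subject_id}/{self.run_id} has missing values"
            )

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class CensorResult:
    """Outcome of motion censoring for one run."""

    keep_mask: np.ndarray
    n_censored: int
    retention_fraction: float
    excluded: bool
    mean_motion_mm: float
    subject_id: str = ""
    run_id: str = ""
    displacement: np.ndarray = field(default=None, repr=False)

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())


def framewise_displacement(
    params: np.ndarray | MotionTrace,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    pooling: str = "rms",
) -> np.ndarray:
    """Per-transition head displacement (length = volumes - 1).

    Rotations are converted to arc length (radius * angle) so all six
    channels are in mm.  ``pooling="rms"`` returns sqrt(mean of squared
    channel differences); ``pooling="sum"`` returns the sum of absolute
    differences (the Power et al. FD convention).
    """
    if isinstance(params, MotionTrace):
        params = params.params
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"expected volumes x 6 motion parameters, got {params.shape}")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute displacement")
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    delta = np.diff(params, axis=0)
    delta[:, 3:] *= head_radius_mm
    if pooling == "rms":
        return np.sqrt(np.mean(delta**2, axis=1))
    if pooling == "sum":
        return np.sum(np.abs(delta), axis=1)
    raise ValueError(f"unknown pooling {pooling!r}; use 'rms' or 'sum'")


def censor_mask(
    displacement: np.ndarray,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> np.ndarray:
    """Boolean keep-mask over volumes given per-transition displacement.

    Transition ``i`` joins volumes ``i`` and ``i+1``.  When its displacement
    strictly exceeds the threshold, both flanking volumes plus ``half_width``
    neighbors on each side are censored (window ``[i-half_width,
    i+1+half_width]``, clipped to the run).  Displacement exactly at the
    threshold is kept.
    """
    displacement = np.asarray(displacement, dtype=float)
    if displacement.ndim != 1 or displacement.size == 0:
        raise ValueError("displacement must be a non-empty 1-D series")
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    n_volumes = displacement.size + 1
    keep = np.ones(n_volumes, dtype=bool)
    for i in np.flatnonzero(displacement > threshold_mm):
        lo = max(0, i - half_width)
        hi = min(n_volumes, i + 2 + half_width)
        keep[lo:hi] = False
    return keep


def retention_check(
    n_kept: int, original_volumes: int, min_fraction: float = DEFAULT_MIN_RETENTION
) -> bool:
    """True when the run fails the retention rule (strictly below the floor).

    A run keeping exactly ``min_fraction`` of its volumes is retained: the
    exclusion rule is "less than" the floor, evaluated per run.
    """
    if original_volumes <= 0:
        raise ValueError("original_volumes must be positive")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    return n_kept / original_volumes < min_fraction


def censor_run(
    trace: MotionTrace,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    min_retention: float = DEFAULT_MIN_RETENTION,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    half_width: int = DEFAULT_HALF_WIDTH,
    pooling: str = "rms",
) -> CensorResult:
    """Full QC for one run: displacement, censoring, retention flag.

    ``mean_motion_mm`` averages displacement over all transitions before any
    censoring; it is the per-run ingredient of the mean-head-motion covariate.
    """
    fd = framewise_displacement(trace, head_radius_mm=head_radius_mm, pooling=pooling)
    keep = censor_mask(fd, threshold_mm=threshold_mm, half_width=half_width)
    n_total = trace.n_volumes
    n_kept = int(keep.sum())
    retention = n_kept / n_total
    return CensorResult(
        keep_mask=keep,
        n_censored=n_total - n_kept,
        retention_fraction=retention,
        excluded=retention_check(n_kept, n_total, min_retention),
        mean_motion_mm=float(fd.mean()),
        subject_id=trace.subject_id,
        run_id=trace.run_id,
        displacement=fd,
    )
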