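"""Tracking-derived behavioral metrics, NOR discrimination index, and
IEG cell-density computation.

The behavioral tasks modelled here take place in a 40 x 40 cm arena:
open field (locomotion, center/periphery dwell), novel object
exploration (NOE; dwell time inside object zones), and novel object
recognition (NOR), whose discrimination index is the time on the novel
object over the total object-exploration time (0.5 = chance).

Immediate-early-gene quantification consumes per-image positive-cell
counts with the granule-cell-layer area of each image; densities are
cells/mm², averaged per animal before any group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spiketrains import ParameterError, ValidationError

logger = logging.getLogger(__name__)

ARENA_SIZE_CM = 40.0
#: default center zone = central 50% of each side (25% of the area)
DEFAULT_CENTER_FRACTION = 0.5
#: default mobility threshold (cm/s)
DEFAULT_MOBILITY_THRESHOLD = 2.0
#: default object zone radius (cm): ~2 cm beyond a small object's footprint
DEFAULT_OBJECT_RADIUS = 4.0

AGE_BANDS = ("P19-P21", "P25-P27")


@dataclass(frozen=True)
class TrackingTrace:
    """Timestamped (x, y) trajectory in arena coordinates (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    animal_id: str = ""
    group: str = ""
    age_band: str = ""
    arena_size: float = ARENA_SIZE_CM

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, arr in (("t", t), ("x", x), ("y", y)):
            object.__setattr__(self, name, arr)
        if not (t.size == x.size == y.size):
            raise ValidationError("t, x, y must have equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            k = int(np.argmax(np.diff(t) <= 0))
            raise ValidationError(
                f"timestamps must be strictly increasing (violation at sample {k + 1})"
            )
        eps = 1e-9
        if x.size and (
            x.min() < -eps
            or x.max() > self.arena_size + eps
            or y.min() < -eps
            or y.max() > self.arena_size + eps
        ):
            raise ValidationError(
                f"coordinates outside the {self.arena_size} cm arena"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size >= 2 else 0.0


@dataclass(frozen=True)
class ObjectLayout:
    """Object centers and a shared circular exploration zone radius."""

    centers: tuple[tuple[float, float], ...]
    radius: float = DEFAULT_OBJECT_RADIUS
    arena_size: float = ARENA_SIZE_CM

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "centers", tuple((float(a), float(b)) for a, b in self.centers)
        )
        if self.radius <= 0:
            raise ParameterError("object radius must be > 0")
        for cx, cy in self.centers:
            if not (0 <= cx <= self.arena_size and 0 <= cy <= self.arena_size):
                raise ValidationError(f"object center ({cx}, {cy}) outside arena")
        for i in range(len(self.centers)):
            for j in range(i + 1, len(self.centers)):
                d = float(np.hypot(
                    self.centers[i][0] - self.centers[j][0],
                    self.centers[i][1] - self.centers[j][1],
                ))
                if d < 2 * self.radius:
                    logger.warning(
                        "object zones %d and %d overlap (separation %.1f cm "
                        "< 2 x radius %.1f cm); samples go to the nearest center",
                        i + 1,
                        j + 1,
                        d,
                        self.radius,
                    )

    @classmethod
    def noe_default(cls, arena_size: float = ARENA_SIZE_CM) -> "ObjectLayout":
        """Four objects on a square, as in the novel-object-exploration task."""
        lo, hi = 0.3 * arena_size, 0.7 * arena_size
        return cls(centers=((lo, lo), (lo, hi), (hi, lo), (hi, hi)),
                   arena_size=arena_size)

    @classmethod
    def nor_default(cls, arena_size: float = ARENA_SIZE_CM) -> "ObjectLayout":
        """Two objects (familiar, novel) for the recognition task."""
        mid = 0.5 * arena_size
        return cls(centers=((0.3 * arena_size, mid), (0.7 * arena_size, mid)),
                   arena_size=arena_size)


@dataclass(frozen=True)
class NORTrial:
    """Exploration times (s) for the familiar and novel object."""

    time_familiar: float
    time_novel: float

    def __post_init__(self) -> None:
        if self.time_familiar < 0 or self.time_novel < 0:
            raise ValidationError("exploration times must be >= 0")


# ---------------------------------------------------------------------------
# tracking metrics
# ---------------------------------------------------------------------------


def _sample_weights(trace: TrackingTrace) -> np.ndarray:
    """Dwell-time weight of each sample: the interval to the next one.

    The last sample carries zero weight so that the weights sum exactly
    to the trace duration.
    """
    w = np.zeros(trace.n_samples)
    w[:-1] = np.diff(trace.t)
    return w


def locomotion_summary(
    trace: TrackingTrace,
    mobility_threshold: float = DEFAULT_MOBILITY_THRESHOLD,
) -> dict[str, float]:
    """Distance, speed and mobility of one trace.

    Step speeds are step length / dt; a step is mobile when its speed
    is at or above ``mobility_threshold`` (cm/s).  Percentages are
    relative to the trace duration.
    """
    if trace.n_samples < 2:
        raise ValidationError("locomotion needs at least 2 samples")
    dx = np.diff(trace.x)
    dy = np.diff(trace.y)
    dt = np.diff(trace.t)
    step = np.hypot(dx, dy)
    speed = step / dt
    mobile = speed >= mobility_threshold
    duration = trace.duration
    time_mobile = float(dt[mobile].sum())
    return {
        "total_distance_m": float(step.sum() / 100.0),
        "mean_speed_cm_s": float(step.sum() / duration),
        "time_mobile_s": time_mobile,
        "pct_time_mobile": 100.0 * time_mobile / duration,
    }


def zone_times(
    trace: TrackingTrace,
    center_fraction: float = DEFAULT_CENTER_FRACTION,
) -> dict[str, float]:
    """Center vs periphery dwell times of one trace.

    The center zone is the central square covering ``center_fraction``
    of each side (default 50%, i.e. 25% of the arena area).  Dwell is
    sample-weighted so center + periphery equals the trace duration.
    """
    if not 0 < center_fraction < 1:
        raise ParameterError("center_fraction must be in (0, 1)")
    half = trace.arena_size * center_fraction / 2
    mid = trace.arena_size / 2
    lo, hi = mid - half, mid + half
    inside = (
        (trace.x >= lo) & (trace.x <= hi) & (trace.y >= lo) & (trace.y <= hi)
    )
    w = _sample_weights(trace)
    duration = trace.duration
    t_center = float(w[inside].sum())
    t_periph = float(w[~inside].sum())
    return {
        "time_center_s": t_center,
        "time_periphery_s": t_periph,
        "pct_center": 100.0 * t_center / duration if duration else float("nan"),
        "pct_periphery": 100.0 * t_periph / duration if duration else float("nan"),
    }


def object_exploration_time(
    trace: TrackingTrace, layout: ObjectLayout
) -> dict[str, float]:
    """Dwell time (s) inside each object's exploration zone.

    A sample inside several overlapping zones is assigned to the
    nearest object center.  Keys are ``object_1`` .. ``object_k`` plus
    ``total``.
    """
    w = _sample_weights(trace)
    centers = np.array(layout.centers)  # (k, 2)
    pos = np.column_stack([trace.x, trace.y])  # (n, 2)
    d = np.linalg.norm(pos[:, None, :] - centers[None, :, :], axis=2)  # (n, k)
    nearest = np.argmin(d, axis=1)
    in_zone = d[np.arange(len(pos)), nearest] <= layout.radius
    out: dict[str, float] = {}
    total = 0.0
    for k in range(len(layout.centers)):
        t_k = float(w[in_zone & (nearest == k)].sum())
        out[f"object_{k + 1}"] = t_k
        total += t_k
    out["total"] = total
    return out


def discrimination_index(trial: NORTrial) -> float:
    """NOR discrimination index: novel / (novel + familiar).

    0.5 is chance.  Undefined (NaN, logged) when the animal explored
    neither object; such trials are excluded from cohort statistics.
    """
    total = trial.time_familiar + trial.time_novel
    if total <= 0:
        logger.warning("zero total exploration: discrimination index undefined")
        return float("nan")
    return trial.time_novel / total


# ---------------------------------------------------------------------------
# IEG densities
# ---------------------------------------------------------------------------

IEG_COLUMNS = [
    "animal_id",
    "group",
    "condition",
    "marker",
    "image_id",
    "positive_cells",
    "gcl_area_mm2",
]


@dataclass(frozen=True)
class IEGDensityResult:
    per_image: pd.DataFrame   # adds a density column (cells/mm²)
    per_animal: pd.DataFrame  # animal mean density across its images
    group_summary: pd.DataFrame  # group x condition x marker mean of animal means
    n_rejected_rows: int


def ieg_density(table: pd.DataFrame) -> IEGDensityResult:
    """Positive-cell densities (cells/mm²) from an IEG count table.

    Per-image density = count / GCL area; per-animal value = mean over
    that animal's images; group summary = mean of animal means with n
    and SEM.  Rows with non-positive area are rejected with a message;
    images with zero cells keep density 0.
    """
    missing = [c for c in IEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"IEG table missing columns {missing}")
    df = table.copy()
    if (df["positive_cells"] < 0).any():
        raise ValidationError("negative cell counts in IEG table")
    bad = df["gcl_area_mm2"] <= 0
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning(
            "rejected %d IEG rows with non-positive GCL area (rows %s)",
            n_rejected,
            list(df.index[bad]),
        )
        df = df[~bad]
    df = df.assign(density=df["positive_cells"] / df["gcl_area_mm2"])
    keys = ["marker", "group", "condition", "animal_id"]
    per_animal = df.groupby(keys, as_index=False)["density"].mean()
    group_summary = (
        per_animal.groupby(["marker", "group", "condition"])["density"]
        .agg(mean="mean", n="count", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        .reset_index()
    )
    return IEGDensityResult(
        per_image=df,
        per_animal=per_animal,
        group_summary=group_summary,
        n_rejected_rows=n_rejected,
    )


# ---------------------------------------------------------------------------
# tracking CSV I/O
# ---------------------------------------------------------------------------


def write_tracking(trace: TrackingTrace, path) -> None:
    """Write a trace as CSV (t_s, x_cm, y_cm) with metadata columns."""
    pd.DataFrame(
        {
            "t_s": [f"{v:.3f}" for v in trace.t],
            "x_cm": [f"{v:.3f}" for v in trace.x],
            "y_cm": [f"{v:.3f}" for v in trace.y],
            "animal_id": trace.animal_id,
            "group": trace.group,
            "age_band": trace.age_band,
        }
    ).to_csv(path, index=False)


def read_tracking(path) -> TrackingTrace:
    df = pd.read_csv(path)
    for col in ("t_s", "x_cm", "y_cm"):
        if col not in df.columns:
            raise ValidationError(f"tracking file missing column {col!r}")
    meta = {
        k: (str(df[c].iloc[0]) if c in df.columns and len(df) else "")
        for k, c in (
            ("animal_id", "animal_id"),
            ("group", "group"),
            ("age_band", "age_band"),
        )
    }
    return TrackingTrace(
        t=df["t_s"].to_numpy(float),
        x=df["x_cm"].to_numpy(float),
        y=df["y_cm"].to_numpy(float),
        **meta,
    )
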