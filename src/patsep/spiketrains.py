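"""Core spike-train containers, binning, validation and CSV I/O.

A :class:`SpikeTrain` is an ordered set of spike times inside a sweep of
fixed duration.  A :class:`RecordingSet` bundles one recorded granule
cell: the five stimulation input trains plus the evoked output sweeps,
each labelled with (input id, repetition).  Binned spike counts
(:class:`BinnedTrain`) are the common currency of every similarity
metric downstream.

Conventions
-----------
* Bins are half-open ``[k*w, (k+1)*w)`` with 0-based indices; a spike at
  exactly ``t = duration`` is invalid, so bin assignment is unambiguous.
* The number of bins is ``ceil(duration / bin_width)``; a ragged final
  bin is allowed for non-divisible widths and logged.
* Spike times are seconds stored as floats; files carry 6 decimal
  places (1 µs), finer than the 10 kHz sampling of the recordings this
  format models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: decimal places used by the CSV format for times and durations
TIME_DECIMALS = 6

VALID_GROUPS = ("SH", "EE")


class ValidationError(ValueError):
    """Raised when data violate a domain invariant."""


class ParameterError(ValueError):
    """Raised when a caller supplies an invalid parameter."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) within a sweep of fixed duration.

    ``times`` must be strictly increasing and lie in ``[0, duration)``;
    empty trains are valid.
    """

    times: np.ndarray
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.duration <= 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if times.ndim != 1:
            raise ValidationError("spike times must be a 1-d sequence")
        if times.size:
            if np.any(np.diff(times) <= 0):
                k = int(np.argmax(np.diff(times) <= 0))
                raise ValidationError(
                    f"spike times must be strictly increasing "
                    f"(violation at index {k + 1}, label={self.label!r})"
                )
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValidationError(
                    f"spike times must lie in [0, {self.duration}) "
                    f"(label={self.label!r})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate_hz(self) -> float:
        """Mean firing rate over the sweep (spikes / duration)."""
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class BinnedTrain:
    """Non-negative spike counts on a regular bin grid."""

    counts: np.ndarray
    bin_width: float
    duration: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be > 0")
        if np.any(counts < 0):
            raise ValidationError("bin counts must be non-negative")
        expected = n_bins(self.duration, self.bin_width)
        if counts.size != expected:
            raise ValidationError(
                f"expected {expected} bins for duration {self.duration} at "
                f"width {self.bin_width}, got {counts.size}"
            )

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


def n_bins(duration: float, bin_width: float) -> int:
    """Number of bins ``ceil(duration / bin_width)``.

    The quotient is snapped to the nearest integer when it is within
    1e-9 (relative) of one, so that e.g. 2.0 s at 0.01 s always gives
    exactly 200 bins despite binary rounding of 0.01.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    q = duration / bin_width
    nearest = round(q)
    if nearest > 0 and abs(q - nearest) <= 1e-9 * nearest:
        return int(nearest)
    return int(math.ceil(q))


def bin_spike_train(train: SpikeTrain, bin_width: float) -> BinnedTrain:
    """Bin a spike train into half-open bins ``[k*w, (k+1)*w)``.

    The total count is conserved.  A spike at ``t`` lands in bin
    ``floor(t / w)``; because times are validated to ``< duration`` the
    index is clipped into the final (possibly ragged) bin only to guard
    against floating-point round-up at the boundary.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if bin_width > train.duration:
        raise ParameterError(
            f"bin_width {bin_width} exceeds sweep duration {train.duration}"
        )
    nb = n_bins(train.duration, bin_width)
    if abs(nb * bin_width - train.duration) > 1e-9 * train.duration:
        logger.debug(
            "ragged final bin: duration %s not divisible by width %s",
            train.duration,
            bin_width,
        )
    if train.n_spikes:
        idx = np.floor(train.times / bin_width).astype(int)
        idx = np.minimum(idx, nb - 1)
        counts = np.bincount(idx, minlength=nb)
    else:
        counts = np.zeros(nb, dtype=int)
    return BinnedTrain(counts=counts, bin_width=bin_width, duration=train.duration)


@dataclass(frozen=True)
class RecordingSet:
    """One cell's input trains and labelled output sweeps.

    ``outputs`` maps ``(input_id, repetition)`` (both 1-based) to the
    evoked output train.  Under the standard stimulation protocol of
    10 repetitions of 5 trains there are 50 output sweeps.
    """

    cell_id: str
    group: str
    inputs: tuple[SpikeTrain, ...]
    outputs: dict[tuple[int, int], SpikeTrain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"unknown group label {self.group!r}; expected one of {VALID_GROUPS}"
            )
        if len(self.inputs) < 2:
            raise ValidationError("a recording needs at least 2 input trains")
        object.__setattr__(self, "inputs", tuple(self.inputs))
        durations = {t.duration for t in self.inputs} | {
            t.duration for t in self.outputs.values()
        }
        if len(durations) > 1:
            raise ValidationError(
                f"all sweeps of cell {self.cell_id!r} must share one duration, "
                f"got {sorted(durations)}"
            )
        for (iid, rep) in self.outputs:
            if not (1 <= iid <= self.n_inputs):
                raise ValidationError(
                    f"output labelled with input_id {iid} outside 1..{self.n_inputs}"
                )
            if rep < 1:
                raise ValidationError("repetition indices are 1-based")

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def duration(self) -> float:
        return self.inputs[0].duration

    @property
    def n_repetitions(self) -> int:
        if not self.outputs:
            return 0
        return max(rep for (_, rep) in self.outputs)

    @property
    def n_output_sweeps(self) -> int:
        return len(self.outputs)

    def output_sweeps(self, input_id: int) -> list[SpikeTrain]:
        """Output sweeps evoked by one input train, in repetition order."""
        keys = sorted(k for k in self.outputs if k[0] == input_id)
        return [self.outputs[k] for k in keys]

    def input_train(self, input_id: int) -> SpikeTrain:
        return self.inputs[input_id - 1]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "cell_id",
    "group",
    "role",
    "input_id",
    "repetition",
    "spike_time_s",
    "duration_s",
]


def _fmt(x: float) -> str:
    return f"{x:.{TIME_DECIMALS}f}"


def write_spiketrains(
    sets: RecordingSet | Iterable[RecordingSet], path
) -> None:
    """Write one or more recording sets to the spike-train CSV format.

    One row per spike; a train with zero spikes is declared by a single
    row with an empty ``spike_time_s`` field.  Times carry 6 decimals.
    """
    if isinstance(sets, RecordingSet):
        sets = [sets]
    rows: list[dict] = []

    def _train_rows(rec: RecordingSet, role: str, iid: int, rep, train: SpikeTrain):
        base = {
            "cell_id": rec.cell_id,
            "group": rec.group,
            "role": role,
            "input_id": iid,
            "repetition": "" if rep is None else rep,
            "duration_s": _fmt(train.duration),
        }
        if train.n_spikes == 0:
            rows.append({**base, "spike_time_s": ""})
        else:
            for t in train.times:
                rows.append({**base, "spike_time_s": _fmt(t)})

    for rec in sets:
        for i, train in enumerate(rec.inputs, start=1):
            _train_rows(rec, "input", i, None, train)
        for (iid, rep) in sorted(rec.outputs):
            _train_rows(rec, "output", iid, rep, rec.outputs[(iid, rep)])

    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_spiketrains(path) -> list[RecordingSet]:
    """Read recording sets from the spike-train CSV format.

    Validation failures (unsorted or out-of-range times, unknown group,
    missing columns) raise :class:`ValidationError` naming the
    offending row (1-based data row index, header excluded).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    sets: list[RecordingSet] = []
    for cell_id, cell_df in df.groupby("cell_id", sort=False):
        groups = cell_df["group"].unique()
        if len(groups) != 1:
            raise ValidationError(
                f"cell {cell_id!r} has inconsistent group labels {list(groups)}"
            )
        group = groups[0]
        if group not in VALID_GROUPS:
            row = cell_df.index[0] + 1
            raise ValidationError(
                f"row {row}: unknown group label {group!r} for cell {cell_id!r}"
            )
        inputs: dict[int, SpikeTrain] = {}
        outputs: dict[tuple[int, int], SpikeTrain] = {}
        key_cols = ["role", "input_id", "repetition"]
        for (role, iid_s, rep_s), tdf in cell_df.groupby(key_cols, sort=False):
            first_row = tdf.index[0] + 1
            if role not in ("input", "output"):
                raise ValidationError(f"row {first_row}: unknown role {role!r}")
            try:
                iid = int(iid_s)
            except ValueError:
                raise ValidationError(
                    f"row {first_row}: input_id {iid_s!r} is not an integer"
                ) from None
            durations = tdf["duration_s"].unique()
            if len(durations) != 1:
                raise ValidationError(
                    f"row {first_row}: inconsistent duration for one train"
                )
            duration = float(durations[0])
            times: list[float] = []
            prev = -math.inf
            for row_idx, t_s in zip(tdf.index, tdf["spike_time_s"]):
                if t_s == "":
                    continue  # empty-train marker row
                t = float(t_s)
                if t < 0 or t >= duration:
                    raise ValidationError(
                        f"row {row_idx + 1}: spike_time_s {t} outside "
                        f"[0, {duration})"
                    )
                if t <= prev:
                    raise ValidationError(
                        f"row {row_idx + 1}: spike times not strictly increasing"
                    )
                prev = t
                times.append(t)
            if role == "input":
                train = SpikeTrain(
                    np.array(times), duration, label=f"{cell_id}-input-{iid}"
                )
                inputs[iid] = train
            else:
                try:
                    rep = int(rep_s)
                except ValueError:
                    raise ValidationError(
                        f"row {first_row}: output row missing repetition"
                    ) from None
                if (iid, rep) in outputs:
                    raise ValidationError(
                        f"row {first_row}: duplicate output sweep ({iid}, {rep})"
                    )
                outputs[(iid, rep)] = SpikeTrain(
                    np.array(times),
                    duration,
                    label=f"{cell_id}-output-{iid}-{rep}",
                )
        ordered_ids = sorted(inputs)
        if ordered_ids != list(range(1, len(ordered_ids) + 1)):
            raise ValidationError(
                f"cell {cell_id!r}: input ids must be contiguous from 1, "
                f"got {ordered_ids}"
            )
        sets.append(
            RecordingSet(
                cell_id=str(cell_id),
                group=group,
                inputs=tuple(inputs[i] for i in ordered_ids),
                outputs=outputs,
            )
        )
    return sets
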