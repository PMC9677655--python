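"""Synthetic data generators emulating the study's raw inputs.

Every stage of the analysis can be exercised without recorded data:

* correlated Poisson input-train sets (five 2-s, 10 Hz trains whose
  mean pairwise binned-count correlation is calibrated to a target,
  0.76 at 10 ms bins by default, matching the stimulation protocol);
* a stochastic granule-cell responder producing labelled output sweeps
  (per-stimulus spike probability, latency jitter, burst doublets,
  refractoriness, spontaneous background);
* arena trajectories (reflected Ornstein-Uhlenbeck walk with rest
  bouts and optional attraction toward an object zone);
* NOR trial tables with a target discrimination-index distribution;
* sparse IEG count tables with a task (condition) effect and, by
  default, no housing effect.

Correlated trains use mother-process thinning: a mother Poisson train
at rate ``rate / p`` is copied into each child train by keeping each
mother spike independently with probability ``p``, then jittering the
kept spikes.  Without jitter and with fine bins the pairwise count
correlation of two children is exactly ``p`` (shared thinning), which
gives the generator a closed-form oracle; ``p`` is then calibrated by
bisection against a Monte-Carlo estimate of the realized mean pairwise
correlation at the analysis bin width, and candidate sets are
rejection-sampled into the acceptance band.

All generators draw from a single ``numpy`` Generator seeded per call
and are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as st

from .behavior import (
    ARENA_SIZE_CM,
    IEG_COLUMNS,
    NORTrial,
    ObjectLayout,
    TrackingTrace,
)
from .spiketrains import (
    ParameterError,
    RecordingSet,
    SpikeTrain,
    TIME_DECIMALS,
    bin_spike_train,
)

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Raised when the copy probability cannot reach the target correlation."""

    def __init__(self, message: str, curve: list[tuple[float, float]]):
        super().__init__(message)
        #: probed (copy probability, estimated mean pairwise R) pairs
        self.curve = curve


# ---------------------------------------------------------------------------
# correlated Poisson input sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputGenConfig:
    """Configuration of the correlated input-train generator.

    Defaults reproduce the stimulation protocol: five distinct 2-s,
    10 Hz Poisson trains with mean pairwise Pearson correlation 0.76 on
    10 ms binned counts, accepted within ±0.02.
    """

    rate: float = 10.0          # Hz
    duration: float = 2.0       # s
    n_trains: int = 5
    target_r: float = 0.76
    bin_width: float = 0.01     # s, bin width at which target_r is defined
    tolerance: float = 0.02     # acceptance band on the realized mean R
    jitter_sd: float = 0.001    # s, per-spike Gaussian latency jitter
    seed: int | None = None
    max_candidates: int = 10000

    def __post_init__(self) -> None:
        if not 0 < self.target_r < 1:
            raise ParameterError("target_r must be in (0, 1)")
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be > 0")
        if self.rate <= 0 or self.duration <= 0 or self.n_trains < 2:
            raise ParameterError("invalid rate/duration/n_trains")


@dataclass(frozen=True)
class InputSetResult:
    trains: tuple[SpikeTrain, ...]
    realized_r: float                 # mean pairwise R at cfg.bin_width
    pair_r: dict[tuple[int, int], float]
    copy_p: float                     # calibrated thinning probability
    n_rejected: int
    config: InputGenConfig

    def metadata(self) -> dict:
        """Config + seed, suitable for a JSON sidecar."""
        return {
            "config": asdict(self.config),
            "copy_p": self.copy_p,
            "realized_r": self.realized_r,
            "n_rejected": self.n_rejected,
        }


def _round_times(times: np.ndarray) -> np.ndarray:
    """Sort, round to file precision (µs) and drop exact duplicates."""
    return np.unique(np.round(np.sort(times), TIME_DECIMALS))


def _draw_child_set(
    rng: np.random.Generator,
    copy_p: float,
    rate: float,
    duration: float,
    n_trains: int,
    jitter_sd: float,
) -> list[np.ndarray]:
    """One candidate set of thinned, jittered child spike-time arrays."""
    n_mother = rng.poisson(rate / copy_p * duration)
    mother = np.sort(rng.uniform(0.0, duration, n_mother))
    children = []
    for _ in range(n_trains):
        keep = rng.random(n_mother) < copy_p
        times = mother[keep]
        if jitter_sd > 0 and times.size:
            times = times + rng.normal(0.0, jitter_sd, times.size)
            times = times[(times >= 0) & (times < duration)]
        children.append(_round_times(times))
    return children


def _mean_pairwise_r(
    children: list[np.ndarray], duration: float, bin_width: float
) -> tuple[float, dict[tuple[int, int], float]]:
    binned = [
        bin_spike_train(SpikeTrain(c, duration), bin_width).counts.astype(float)
        for c in children
    ]
    C = np.stack(binned)
    Cc = C - C.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Cc, Cc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Cc @ Cc.T) / np.sqrt(np.outer(ss, ss))
    pair_r: dict[tuple[int, int], float] = {}
    vals = []
    n = len(children)
    for i in range(n):
        for j in range(i + 1, n):
            v = corr[i, j] if ss[i] > 0 and ss[j] > 0 else float("nan")
            pair_r[(i + 1, j + 1)] = float(v)
            vals.append(v)
    arr = np.array(vals)
    finite = arr[np.isfinite(arr)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return mean, pair_r


@functools.lru_cache(maxsize=32)
def _calibrate_copy_probability(
    rate: float,
    duration: float,
    n_trains: int,
    target_r: float,
    bin_width: float,
    jitter_sd: float,
    n_sets: int = 200,
    n_iter: int = 12,
) -> float:
    """Bisect the thinning probability so E[mean pairwise R] = target.

    The Monte-Carlo estimate uses ``n_sets`` candidate sets per probe
    and a fixed internal RNG stream, making calibration deterministic
    for a given parameter set (and therefore cacheable) independently
    of the caller's seed.
    """
    rng = np.random.default_rng(987654321)

    def estimate(p: float) -> float:
        vals = [
            _mean_pairwise_r(
                _draw_child_set(rng, p, rate, duration, n_trains, jitter_sd),
                duration,
                bin_width,
            )[0]
            for _ in range(n_sets)
        ]
        return float(np.nanmean(vals))

    lo = max(0.05, target_r - 0.15)
    hi = min(0.99, target_r + 0.15)
    curve: list[tuple[float, float]] = []
    f_lo, f_hi = estimate(lo), estimate(hi)
    curve += [(lo, f_lo), (hi, f_hi)]
    if not (f_lo <= target_r <= f_hi):
        raise CalibrationError(
            f"target mean pairwise R {target_r} unreachable for copy "
            f"probabilities in [{lo:.2f}, {hi:.2f}] at rate {rate} Hz, "
            f"bin {bin_width}s, jitter {jitter_sd}s "
            f"(estimates {f_lo:.3f}..{f_hi:.3f})",
            curve,
        )
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid = estimate(mid)
        curve.append((mid, f_mid))
        if f_mid < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_input_set(cfg: InputGenConfig | None = None) -> InputSetResult:
    """Generate one accepted set of correlated Poisson input trains.

    Candidate sets are drawn with the calibrated thinning probability
    and rejection-sampled until the realized mean pairwise R at
    ``cfg.bin_width`` falls within ``target_r ± tolerance`` and every
    train's spike count is within ±40% of ``rate * duration``.
    """
    cfg = cfg or InputGenConfig()
    rng = np.random.default_rng(cfg.seed)
    copy_p = _calibrate_copy_probability(
        cfg.rate, cfg.duration, cfg.n_trains, cfg.target_r, cfg.bin_width,
        cfg.jitter_sd,
    )
    expected = cfg.rate * cfg.duration
    lo_n, hi_n = 0.6 * expected, 1.4 * expected
    for attempt in range(cfg.max_candidates):
        children = _draw_child_set(
            rng, copy_p, cfg.rate, cfg.duration, cfg.n_trains, cfg.jitter_sd
        )
        if not all(lo_n <= c.size <= hi_n for c in children):
            continue
        mean_r, pair_r = _mean_pairwise_r(children, cfg.duration, cfg.bin_width)
        if abs(mean_r - cfg.target_r) <= cfg.tolerance:
            trains = tuple(
                SpikeTrain(c, cfg.duration, label=f"input-{k + 1}")
                for k, c in enumerate(children)
            )
            logger.debug(
                "input set accepted after %d rejections (R = %.3f, p = %.3f)",
                attempt,
                mean_r,
                copy_p,
            )
            return InputSetResult(
                trains=trains,
                realized_r=mean_r,
                pair_r=pair_r,
                copy_p=copy_p,
                n_rejected=attempt,
                config=cfg,
            )
    raise CalibrationError(
        f"no candidate set accepted within {cfg.max_candidates} draws "
        f"(target {cfg.target_r} ± {cfg.tolerance})",
        [],
    )


# ---------------------------------------------------------------------------
# granule-cell responder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponderConfig:
    """Stochastic point-process model of an evoked granule cell.

    Each input spike elicits an output spike with probability
    ``p_spike`` at a non-negative Gaussian latency; a responded
    stimulus adds a burst doublet with probability ``p_extra`` at
    ``extra_lag`` after the first spike.  Spikes violating the
    refractory period are dropped, and an independent Poisson
    background at ``spontaneous_rate`` is superimposed.
    """

    p_spike: float = 0.5            # per-stimulus response probability
    latency_mean: float = 0.004     # s
    latency_sd: float = 0.001       # s
    p_extra: float = 0.15           # burst-doublet probability
    extra_lag: float = 0.003        # s between doublet spikes
    refractory: float = 0.002       # s
    spontaneous_rate: float = 0.2   # Hz background firing
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_spike", "p_extra"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("latency_mean", "latency_sd", "extra_lag", "refractory",
                     "spontaneous_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @classmethod
    def identity(cls, seed: int | None = None) -> "ResponderConfig":
        """Deterministic responder whose outputs equal the inputs."""
        return cls(
            p_spike=1.0,
            latency_mean=0.0,
            latency_sd=0.0,
            p_extra=0.0,
            refractory=0.0,
            spontaneous_rate=0.0,
            seed=seed,
        )


def _apply_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    if refractory <= 0 or times.size < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.array(kept)


def simulate_granule_cell(
    inputs: tuple[SpikeTrain, ...] | list[SpikeTrain],
    cfg: ResponderConfig | None = None,
    n_repetitions: int = 10,
    cell_id: str = "sim-cell",
    group: str = "SH",
) -> RecordingSet:
    """Simulate the full stimulation protocol on one model cell.

    Each of the ``n_repetitions`` repetitions delivers every input
    train once, yielding ``n_repetitions * len(inputs)`` labelled
    output sweeps (50 under the default protocol).
    """
    cfg = cfg or ResponderConfig()
    rng = np.random.default_rng(cfg.seed)
    duration = inputs[0].duration
    outputs: dict[tuple[int, int], SpikeTrain] = {}
    for rep in range(1, n_repetitions + 1):
        for iid, train in enumerate(inputs, start=1):
            t_in = train.times
            responded = rng.random(t_in.size) < cfg.p_spike
            if cfg.latency_sd > 0:
                lat = rng.normal(cfg.latency_mean, cfg.latency_sd, t_in.size)
                lat = np.maximum(lat, 0.0)  # truncate at zero latency
            else:
                lat = np.full(t_in.size, cfg.latency_mean)
            spikes = t_in[responded] + lat[responded]
            extra = rng.random(spikes.size) < cfg.p_extra
            spikes = np.concatenate([spikes, spikes[extra] + cfg.extra_lag])
            if cfg.spontaneous_rate > 0:
                n_bg = rng.poisson(cfg.spontaneous_rate * duration)
                spikes = np.concatenate(
                    [spikes, rng.uniform(0.0, duration, n_bg)]
                )
            spikes = np.sort(spikes)
            spikes = spikes[(spikes >= 0) & (spikes < duration)]
            spikes = _apply_refractory(spikes, cfg.refractory)
            if cfg.latency_sd > 0 or cfg.spontaneous_rate > 0:
                spikes = _round_times(spikes)
            else:
                spikes = np.unique(spikes)
            outputs[(iid, rep)] = SpikeTrain(
                spikes, duration, label=f"{cell_id}-out-{iid}-{rep}"
            )
    return RecordingSet(
        cell_id=cell_id, group=group, inputs=tuple(inputs), outputs=outputs
    )


# ---------------------------------------------------------------------------
# arena trajectories
# ---------------------------------------------------------------------------


def generate_tracking_trace(
    duration: float = 600.0,
    dt: float = 0.1,
    rest_fraction: float = 0.2,
    speed_sd: float = 8.0,
    persistence: float = 0.5,
    attraction_point: tuple[float, float] | None = None,
    attraction_strength: float = 0.0,
    mean_rest_bout: float = 2.0,
    seed: int | None = None,
    animal_id: str = "sim",
    group: str = "SH",
    age_band: str = "P25-P27",
    arena_size: float = ARENA_SIZE_CM,
) -> TrackingTrace:
    """Reflected Ornstein-Uhlenbeck walk inside the square arena.

    Velocity follows an OU process with relaxation time ``persistence``
    (s) and stationary per-component SD ``speed_sd`` (cm/s); positions
    reflect off the walls.  A two-state Markov chain inserts rest bouts
    (zero velocity) occupying ``rest_fraction`` of the time on average.
    ``attraction_point`` adds a constant drift of
    ``attraction_strength`` cm/s toward that point while mobile.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if not 0 <= rest_fraction < 1:
        raise ParameterError("rest_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    theta = 1.0 / persistence
    sigma = speed_sd * np.sqrt(2.0 * theta)
    # rest/mobile Markov chain with the requested stationary occupancy
    p_leave_rest = dt / mean_rest_bout
    if rest_fraction > 0:
        mean_mobile_bout = mean_rest_bout * (1 - rest_fraction) / rest_fraction
        p_enter_rest = dt / mean_mobile_bout
    else:
        p_enter_rest = 0.0

    pos = np.empty((n, 2))
    pos[0] = rng.uniform(0.25 * arena_size, 0.75 * arena_size, 2)
    v = np.zeros(2)
    resting = rng.random() < rest_fraction
    sq_dt = np.sqrt(dt)
    for k in range(1, n):
        if resting:
            if rng.random() < p_leave_rest:
                resting = False
        else:
            if rng.random() < p_enter_rest:
                resting = True
        if resting:
            v = np.zeros(2)
            pos[k] = pos[k - 1]
            continue
        drift = np.zeros(2)
        if attraction_point is not None and attraction_strength > 0:
            delta = np.asarray(attraction_point) - pos[k - 1]
            norm = np.linalg.norm(delta)
            if norm > 1e-9:
                drift = attraction_strength * delta / norm
        v = v + theta * (drift - v) * dt + sigma * sq_dt * rng.standard_normal(2)
        p = pos[k - 1] + v * dt
        # reflect off the walls, flipping the wall-normal velocity
        for d in range(2):
            if p[d] < 0:
                p[d] = -p[d]
                v[d] = -v[d]
            elif p[d] > arena_size:
                p[d] = 2 * arena_size - p[d]
                v[d] = -v[d]
            p[d] = min(max(p[d], 0.0), arena_size)
        pos[k] = p
    t = np.arange(n) * dt
    return TrackingTrace(
        t=t,
        x=pos[:, 0],
        y=pos[:, 1],
        animal_id=animal_id,
        group=group,
        age_band=age_band,
        arena_size=arena_size,
    )


# ---------------------------------------------------------------------------
# NOR cohorts and IEG count tables
# ---------------------------------------------------------------------------


def generate_nor_cohort(
    n_per_group: int = 12,
    mean_di: float = 0.66,
    sd: float = 0.10,
    seed: int | None = None,
    group: str = "SH",
    age_band: str = "P25-P27",
    mean_total_s: float = 40.0,
    total_cv: float = 0.3,
) -> pd.DataFrame:
    """One group's NOR trials with a target DI distribution.

    Realized discrimination indices follow a normal distribution
    truncated to [0, 1]; total exploration time is log-normal around
    ``mean_total_s``.  Columns: animal_id, group, age_band,
    time_familiar, time_novel, di.
    """
    rng = np.random.default_rng(seed)
    a, b = (0.0 - mean_di) / sd, (1.0 - mean_di) / sd
    di = st.truncnorm.rvs(a, b, loc=mean_di, scale=sd, size=n_per_group,
                          random_state=rng)
    log_sd = np.sqrt(np.log(1 + total_cv**2))
    total = rng.lognormal(np.log(mean_total_s) - log_sd**2 / 2, log_sd,
                          n_per_group)
    rows = []
    for k in range(n_per_group):
        trial = NORTrial(
            time_familiar=float(total[k] * (1 - di[k])),
            time_novel=float(total[k] * di[k]),
        )
        rows.append(
            {
                "animal_id": f"{group}-{age_band}-{k + 1}",
                "group": group,
                "age_band": age_band,
                "time_familiar": trial.time_familiar,
                "time_novel": trial.time_novel,
                "di": di[k],
            }
        )
    return pd.DataFrame(rows)


#: default per-(group, condition) densities, cells/mm² of GCL, for the
#: two activity markers; a task (HC -> NOE) effect with essentially no
#: housing effect
DEFAULT_IEG_DENSITIES: dict[str, dict[tuple[str, str], float]] = {
    "cFOS": {
        ("SH", "HC"): 0.36,
        ("SH", "NOE"): 0.66,
        ("EE", "HC"): 0.26,
        ("EE", "NOE"): 0.60,
    },
    "NPAS4": {
        ("SH", "HC"): 0.16,
        ("SH", "NOE"): 0.43,
        ("EE", "HC"): 0.24,
        ("EE", "NOE"): 0.42,
    },
}


def generate_ieg_counts(
    effects: dict[str, dict[tuple[str, str], float]] | None = None,
    n_animals: int = 4,
    images_per_animal: int = 10,
    mean_area_mm2: float = 2.0,
    area_cv: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sparse IEG count table: counts ~ Poisson(area x density).

    ``effects`` maps marker -> {(group, condition): density in
    cells/mm²}; the default reproduces a novelty-task effect with no
    housing effect.  Image GCL areas are log-normal around
    ``mean_area_mm2``.
    """
    effects = effects or DEFAULT_IEG_DENSITIES
    rng = np.random.default_rng(seed)
    log_sd = np.sqrt(np.log(1 + area_cv**2))
    rows = []
    for marker, cells in effects.items():
        for (grp, cond), density in cells.items():
            for a in range(1, n_animals + 1):
                animal = f"{grp}-{cond}-{a}"
                for img in range(1, images_per_animal + 1):
                    area = rng.lognormal(
                        np.log(mean_area_mm2) - log_sd**2 / 2, log_sd
                    )
                    count = rng.poisson(area * density)
                    rows.append(
                        {
                            "animal_id": animal,
                            "group": grp,
                            "condition": cond,
                            "marker": marker,
                            "image_id": f"{animal}-{marker}-img{img}",
                            "positive_cells": int(count),
                            "gcl_area_mm2": float(area),
                        }
                    )
    return pd.DataFrame(rows, columns=IEG_COLUMNS)
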