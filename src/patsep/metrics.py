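"""Pairwise spike-train similarity metrics and spike-pattern statistics.

Three similarity metrics are computed on binned spike-count vectors,
each sensitive to a different putative neural code:

* ``R``   — Pearson correlation of the two count vectors (temporal
  code / decorrelation).
* ``NDP`` — normalized dot product, the cosine of the angle between the
  two vectors (orthogonalization).
* ``SF``  — scaling factor, the ratio of the smaller to the larger
  Euclidean norm (up/down scaling of spikes per bin).

Pattern separation at the single-neuron level is quantified by
comparing the similarity of a pair of input trains with the mean
similarity of the output sweeps they evoke: output similarity below
input similarity (below the identity line) is separation, above it is
convergence.

Undefined values — zero-variance vectors for R, zero-norm vectors for
NDP/SF — are returned as ``nan`` and excluded from every mean; each
summary carries the number of undefined pairs so exclusions are never
silent.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spiketrains import (
    BinnedTrain,
    ParameterError,
    RecordingSet,
    SpikeTrain,
    ValidationError,
    bin_spike_train,
)

logger = logging.getLogger(__name__)

METRICS = ("R", "NDP", "SF")

#: default bin width (s) for all binned-count metrics
DEFAULT_BIN_WIDTH = 0.01
#: bin widths supported by the sensitivity sweep
BIN_WIDTH_SWEEP = (0.005, 0.01, 0.02, 0.05, 0.1)
#: default cap (s) on the per-stimulus response window, always further
#: truncated at the next stimulus
DEFAULT_WINDOW_CAP = 0.05
#: spike-probability range accepted by quality control
QC_RANGE = (0.30, 0.80)


def _check_compatible(a: BinnedTrain, b: BinnedTrain) -> None:
    if a.bin_width != b.bin_width or a.n_bins != b.n_bins:
        raise ParameterError(
            "binned trains are incompatible: "
            f"({a.n_bins} bins @ {a.bin_width}s) vs "
            f"({b.n_bins} bins @ {b.bin_width}s)"
        )


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def pearson_r(a: BinnedTrain, b: BinnedTrain) -> float:
    """Pearson correlation of two binned-count vectors.

    Returns ``nan`` when either vector has zero variance (constant
    counts, e.g. an empty sweep): the correlation is undefined there.
    """
    _check_compatible(a, b)
    x = a.counts.astype(float)
    y = b.counts.astype(float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xc @ yc) / np.sqrt(sx * sy))


def ndp(a: BinnedTrain, b: BinnedTrain) -> float:
    """Normalized dot product (cosine) of two binned-count vectors.

    1 for colinear vectors, 0 when no bin is co-occupied; ``nan`` when
    either vector is all-zero.
    """
    _check_compatible(a, b)
    x = a.counts.astype(float)
    y = b.counts.astype(float)
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float((x @ y) / (nx * ny))


def scaling_factor(a: BinnedTrain, b: BinnedTrain) -> float:
    """Scaling factor: min over max of the two Euclidean norms.

    Symmetric, in (0, 1]; 1 means equal norms (no scaling).  ``nan``
    when either train is empty.  The smaller-over-larger convention
    bounds SF by 1 regardless of argument order.
    """
    _check_compatible(a, b)
    nx = float(np.linalg.norm(a.counts.astype(float)))
    ny = float(np.linalg.norm(b.counts.astype(float)))
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return min(nx, ny) / max(nx, ny)


_SCALAR = {"R": pearson_r, "NDP": ndp, "SF": scaling_factor}


def _metric_fn(metric: str):
    if metric not in _SCALAR:
        raise ParameterError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return _SCALAR[metric]


# ---------------------------------------------------------------------------
# vectorized cross-metric matrices (internal)
# ---------------------------------------------------------------------------


def _cross_metric(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    """Metric values for every row of ``A`` against every row of ``B``.

    ``A`` (m, nbins) and ``B`` (k, nbins) are count matrices; the
    result is (m, k) with ``nan`` where the metric is undefined.
    """
    A = A.astype(float)
    B = B.astype(float)
    if metric == "R":
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        sa = np.einsum("ij,ij->i", Ac, Ac)
        sb = np.einsum("ij,ij->i", Bc, Bc)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (Ac @ Bc.T) / np.sqrt(np.outer(sa, sb))
        out[sa == 0, :] = np.nan
        out[:, sb == 0] = np.nan
        return out
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if metric == "NDP":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (A @ B.T) / np.outer(na, nb)
    elif metric == "SF":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.minimum.outer(na, nb) / np.maximum.outer(na, nb)
    else:
        raise ParameterError(f"unknown metric {metric!r}")
    out[na == 0, :] = np.nan
    out[:, nb == 0] = np.nan
    return out


def _exact_mean(values: np.ndarray) -> float:
    """Mean of finite entries; exact when all finite entries are equal.

    The all-equal shortcut keeps identity-responder output similarity
    bit-identical to the input similarity (no floating-point summation
    error on averages of identical values).
    """
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return float("nan")
    if np.all(finite == finite[0]):
        return float(finite[0])
    return float(finite.mean())


# ---------------------------------------------------------------------------
# pairwise similarity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputSimilarity:
    """Pairwise similarity among a set of input trains under one metric."""

    metric: str
    bin_width: float
    values: dict[tuple[int, int], float]  # (i, j) 1-based, i < j
    mean: float
    n_undefined: int


def pairwise_input_similarity(
    binned: list[BinnedTrain] | tuple[BinnedTrain, ...],
    metric: str,
) -> InputSimilarity:
    """Similarity of every unordered pair of input trains.

    Undefined pairs are kept in ``values`` as ``nan``, excluded from
    the mean, and counted in ``n_undefined``.
    """
    fn = _metric_fn(metric)
    n = len(binned)
    if n < 2:
        raise ParameterError("need at least 2 trains")
    values: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(1, n + 1), 2):
        values[(i, j)] = fn(binned[i - 1], binned[j - 1])
    arr = np.array(list(values.values()))
    n_undef = int(np.sum(~np.isfinite(arr)))
    if n_undef:
        logger.info("%d undefined %s input pairs excluded from mean", n_undef, metric)
    return InputSimilarity(
        metric=metric,
        bin_width=binned[0].bin_width,
        values=values,
        mean=_exact_mean(arr),
        n_undefined=n_undef,
    )


@dataclass(frozen=True)
class PairSimilarity:
    """Input and output similarity for one unordered input-train pair.

    ``s_output`` is the mean of the metric over all cross pairs of
    output sweeps (every sweep evoked by input i against every sweep
    evoked by input j; same-input sweep pairs are never included).
    """

    metric: str
    bin_width: float
    input_pair: tuple[int, int]
    s_input: float
    s_output: float
    n_output_pairs: int
    n_undefined: int
    incomplete: bool = False


def input_output_similarity(
    rec: RecordingSet,
    metric: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> list[PairSimilarity]:
    """Input vs output similarity for every unordered input pair.

    For each pair (i, j) of input trains, the input similarity is the
    metric on the two input count vectors and the output similarity is
    the mean metric over all cross pairs of their evoked output sweeps
    (10 repetitions each under the full protocol -> 100 cross pairs).
    Input pairs with no output sweep on one side are flagged
    ``incomplete`` with ``s_output = nan``.

    All count vectors of the cell (inputs and output sweeps) enter one
    stacked metric-matrix computation, so identical vectors always map
    to bit-identical similarity values: an identity responder sits on
    the diagonal exactly, for every metric.
    """
    _metric_fn(metric)
    rows = [bin_spike_train(t, bin_width).counts for t in rec.inputs]
    sweep_rows: dict[int, list[int]] = {}
    for i in range(1, rec.n_inputs + 1):
        sweep_rows[i] = []
        for sweep in rec.output_sweeps(i):
            sweep_rows[i].append(len(rows))
            rows.append(bin_spike_train(sweep, bin_width).counts)
    G = _cross_metric(np.stack(rows), np.stack(rows), metric)
    results: list[PairSimilarity] = []
    for i, j in itertools.combinations(range(1, rec.n_inputs + 1), 2):
        s_input = float(G[i - 1, j - 1])
        if not sweep_rows[i] or not sweep_rows[j]:
            logger.warning(
                "cell %s: input pair (%d, %d) incomplete (missing output sweeps)",
                rec.cell_id,
                i,
                j,
            )
            results.append(
                PairSimilarity(
                    metric=metric,
                    bin_width=bin_width,
                    input_pair=(i, j),
                    s_input=s_input,
                    s_output=float("nan"),
                    n_output_pairs=0,
                    n_undefined=0,
                    incomplete=True,
                )
            )
            continue
        cross = G[np.ix_(sweep_rows[i], sweep_rows[j])].ravel()
        n_undef = int(np.sum(~np.isfinite(cross)))
        results.append(
            PairSimilarity(
                metric=metric,
                bin_width=bin_width,
                input_pair=(i, j),
                s_input=s_input,
                s_output=_exact_mean(cross),
                n_output_pairs=int(cross.size - n_undef),
                n_undefined=n_undef,
            )
        )
    return results


def reliability(
    rec: RecordingSet, metric: str, bin_width: float = DEFAULT_BIN_WIDTH
) -> dict[int, float]:
    """Same-input output similarity (sweep-to-sweep reliability).

    Mean metric over all unordered pairs of repetitions of the same
    input train; a diagnostic, kept separate from the cross-input
    output similarity used for pattern separation.
    """
    _metric_fn(metric)
    out: dict[int, float] = {}
    for i in range(1, rec.n_inputs + 1):
        sweeps = rec.output_sweeps(i)
        if len(sweeps) < 2:
            out[i] = float("nan")
            continue
        counts = np.stack([bin_spike_train(s, bin_width).counts for s in sweeps])
        m = _cross_metric(counts, counts, metric)
        iu = np.triu_indices(len(sweeps), k=1)
        out[i] = _exact_mean(m[iu])
    return out


@dataclass(frozen=True)
class SeparationSummary:
    mean_s_input: float
    mean_s_output: float
    fraction_below_diagonal: float
    n_pairs: int
    n_excluded: int


def separation_summary(pairs: list[PairSimilarity]) -> SeparationSummary:
    """Summarize a set of pair similarities.

    ``fraction_below_diagonal`` is the share of usable pairs with
    ``s_output < s_input`` (the pattern-separation side of the identity
    line).  Pairs with an undefined input or output similarity are
    excluded and counted.
    """
    if not pairs:
        raise ParameterError("empty pair list")
    s_in = np.array([p.s_input for p in pairs])
    s_out = np.array([p.s_output for p in pairs])
    usable = np.isfinite(s_in) & np.isfinite(s_out)
    n_excluded = int(np.sum(~usable))
    if n_excluded:
        logger.info("%d pairs with undefined similarity excluded", n_excluded)
    if not np.any(usable):
        raise ValidationError("all pairs have undefined similarity")
    return SeparationSummary(
        mean_s_input=_exact_mean(s_in[usable]),
        mean_s_output=_exact_mean(s_out[usable]),
        fraction_below_diagonal=float(np.mean(s_out[usable] < s_in[usable])),
        n_pairs=int(usable.sum()),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# spike-pattern statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiringRateSummary:
    per_sweep: pd.DataFrame  # input_id, repetition, n_spikes, rate_hz
    mean_spikes_per_sweep: float
    mean_rate_hz: float


def firing_rate(rec: RecordingSet) -> FiringRateSummary:
    """Firing rate of the output sweeps: spikes per sweep and Hz."""
    if not rec.outputs:
        raise ValidationError(f"cell {rec.cell_id!r} has no output sweeps")
    rows = [
        {
            "input_id": iid,
            "repetition": rep,
            "n_spikes": train.n_spikes,
            "rate_hz": train.rate_hz,
        }
        for (iid, rep), train in sorted(rec.outputs.items())
    ]
    df = pd.DataFrame(rows)
    return FiringRateSummary(
        per_sweep=df,
        mean_spikes_per_sweep=float(df["n_spikes"].mean()),
        mean_rate_hz=float(df["rate_hz"].mean()),
    )


def _response_windows(
    input_train: SpikeTrain, window_cap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stimulus response windows ``[t, min(t+cap, t_next, duration))``."""
    t = input_train.times
    starts = t
    ends = np.minimum(t + window_cap, input_train.duration)
    ends[:-1] = np.minimum(ends[:-1], t[1:])
    return starts, ends


def _window_counts(
    output: SpikeTrain, input_train: SpikeTrain, window_cap: float
) -> np.ndarray:
    starts, ends = _response_windows(input_train, window_cap)
    lo = np.searchsorted(output.times, starts, side="left")
    hi = np.searchsorted(output.times, ends, side="left")
    return hi - lo


def p_burst(
    output: SpikeTrain,
    input_train: SpikeTrain,
    window_cap: float = DEFAULT_WINDOW_CAP,
) -> float:
    """Probability that a single stimulus evokes a small burst.

    A stimulus counts as bursting when at least 2 output spikes fall in
    its response window (capped at ``window_cap`` and truncated at the
    next stimulus).
    """
    if input_train.n_spikes == 0:
        raise ParameterError("p_burst requires a non-empty input train")
    counts = _window_counts(output, input_train, window_cap)
    return float(np.mean(counts >= 2))


def p_burst_summary(
    rec: RecordingSet, window_cap: float = DEFAULT_WINDOW_CAP
) -> float:
    """Per-cell burst probability: mean of per-sweep values."""
    if not rec.outputs:
        raise ValidationError(f"cell {rec.cell_id!r} has no output sweeps")
    vals = [
        p_burst(train, rec.input_train(iid), window_cap)
        for (iid, _), train in sorted(rec.outputs.items())
    ]
    return float(np.mean(vals))


def compactness(b: BinnedTrain) -> float:
    """Fraction of bins occupied by at least one spike."""
    return b.n_occupied / b.n_bins


def occupancy(b: BinnedTrain) -> float:
    """Mean number of spikes per occupied bin; ``nan`` for empty trains."""
    if b.n_occupied == 0:
        return float("nan")
    return b.total / b.n_occupied


def _mean_abs_pairwise_diff(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    iu = np.triu_indices(x.size, k=1)
    return float(np.abs(x[:, None] - x[None, :])[iu].mean())


@dataclass(frozen=True)
class DispersionSummary:
    binwise_compactness: float
    occupancy_variation: float
    fr_variation: float
    n_sweeps: int
    n_empty_excluded: int


def dispersion_summary(
    rec: RecordingSet, bin_width: float = DEFAULT_BIN_WIDTH
) -> DispersionSummary:
    """Across-sweep dispersion of the output spike-pattern statistics.

    ``binwise_compactness`` is the mean compactness over output sweeps;
    the occupancy and firing-rate variations are the mean absolute
    pairwise difference of the per-sweep values across all sweep pairs.
    Empty sweeps carry no occupancy and are excluded from the occupancy
    pairs (their number is reported).
    """
    sweeps = [rec.outputs[k] for k in sorted(rec.outputs)]
    if len(sweeps) < 2:
        raise ValidationError("dispersion needs at least 2 output sweeps")
    binned = [bin_spike_train(s, bin_width) for s in sweeps]
    comp = np.array([compactness(b) for b in binned])
    occ = np.array([occupancy(b) for b in binned])
    fr = np.array([s.n_spikes for s in sweeps], dtype=float)
    occ_ok = np.isfinite(occ)
    n_empty = int(np.sum(~occ_ok))
    if n_empty:
        logger.info(
            "cell %s: %d empty sweeps excluded from occupancy pairs",
            rec.cell_id,
            n_empty,
        )
    if occ_ok.sum() < 2:
        occ_var = float("nan")
    else:
        occ_var = _mean_abs_pairwise_diff(occ[occ_ok])
    return DispersionSummary(
        binwise_compactness=float(comp.mean()),
        occupancy_variation=occ_var,
        fr_variation=_mean_abs_pairwise_diff(fr),
        n_sweeps=len(sweeps),
        n_empty_excluded=n_empty,
    )


@dataclass(frozen=True)
class SpikeProbability:
    probability: float
    qc_pass: bool
    n_stimuli: int
    n_responded: int


def spike_probability(
    rec: RecordingSet,
    window_cap: float = DEFAULT_WINDOW_CAP,
    qc_range: tuple[float, float] = QC_RANGE,
) -> SpikeProbability:
    """Per-stimulus spike probability across all sweeps, with QC flag.

    The probability is the fraction of stimuli (over every output
    sweep) whose response window contains at least one output spike.
    Recordings outside the 30-80% window used to titrate stimulation
    intensity fail QC and should be excluded from group summaries.
    """
    n_stim = 0
    n_resp = 0
    for (iid, _), train in sorted(rec.outputs.items()):
        counts = _window_counts(train, rec.input_train(iid), window_cap)
        n_stim += counts.size
        n_resp += int(np.sum(counts >= 1))
    prob = n_resp / n_stim if n_stim else float("nan")
    qc = bool(n_stim and qc_range[0] <= prob <= qc_range[1])
    if not qc:
        logger.info(
            "cell %s fails spike-probability QC (p=%.3f outside %s)",
            rec.cell_id,
            prob,
            qc_range,
        )
    return SpikeProbability(
        probability=prob, qc_pass=qc, n_stimuli=n_stim, n_responded=n_resp
    )


# ---------------------------------------------------------------------------
# tidy export
# ---------------------------------------------------------------------------


def similarity_table(
    recs: list[RecordingSet],
    metrics: tuple[str, ...] = METRICS,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Tidy table: one row per (cell, metric, bin width, input pair)."""
    rows = []
    for rec in recs:
        for metric in metrics:
            for p in input_output_similarity(rec, metric, bin_width):
                rows.append(
                    {
                        "cell_id": rec.cell_id,
                        "group": rec.group,
                        "metric": metric,
                        "bin_width": bin_width,
                        "i": p.input_pair[0],
                        "j": p.input_pair[1],
                        "s_input": p.s_input,
                        "s_output": p.s_output,
                        "n_output_pairs": p.n_output_pairs,
                        "n_undefined": p.n_undefined,
                    }
                )
    return pd.DataFrame(rows)


def pattern_summary_table(
    recs: list[RecordingSet],
    bin_width: float = DEFAULT_BIN_WIDTH,
    window_cap: float = DEFAULT_WINDOW_CAP,
) -> pd.DataFrame:
    """Tidy table of per-cell spike-pattern statistics and QC."""
    rows = []
    for rec in recs:
        fr = firing_rate(rec)
        disp = dispersion_summary(rec, bin_width)
        sp = spike_probability(rec, window_cap)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "group": rec.group,
                "mean_spikes_per_sweep": fr.mean_spikes_per_sweep,
                "mean_rate_hz": fr.mean_rate_hz,
                "p_burst": p_burst_summary(rec, window_cap),
                "binwise_compactness": disp.binwise_compactness,
                "occupancy_variation": disp.occupancy_variation,
                "fr_variation": disp.fr_variation,
                "spike_probability": sp.probability,
                "qc_pass": sp.qc_pass,
            }
        )
    return pd.DataFrame(rows)
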