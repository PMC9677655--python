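"""End-to-end orchestration: generate -> simulate -> metrics -> stats -> report.

A run simulates the full study under a single seed: per-cell input-train
sets and granule-cell recordings for the two housing groups, similarity
metrics and spike-pattern statistics, group inference (ANCOVA per
metric, two-sample t-tests), and the behavioral arm (open field, NOR
discrimination indices, IEG densities with two-way ANOVA).

The output directory layout is fixed::

    inputs/      per-cell realized input-correlation table
    recordings/  all simulated recording sets (spike-train CSV)
    metrics/     tidy similarity and pattern-summary tables
    stats/       ANCOVA / t-test / ANOVA result tables
    figures/     similarity scatters and group bar summaries (PNG)
    report.txt   human-readable summary

Every table carries provenance columns (seed, config hash); reruns with
the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, inference, synthetic
from . import metrics as metrics_mod
from .spiketrains import ParameterError, read_spiketrains, write_spiketrains

logger = logging.getLogger(__name__)

STAGES = ("generate", "simulate", "metrics", "stats", "report")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulated study run."""

    seed: int = 0
    n_cells_per_group: int = 15     # recordings per housing group
    n_repetitions: int = 10
    bin_width: float = 0.01
    metrics: tuple[str, ...] = metrics_mod.METRICS
    window_cap: float = metrics_mod.DEFAULT_WINDOW_CAP
    alpha: float = 0.05
    input_cfg: dict = field(default_factory=dict)      # InputGenConfig overrides
    responder_cfg: dict = field(default_factory=dict)  # ResponderConfig overrides
    # behavioral arm
    n_animals_behavior: int = 12
    nor_mean_di: dict = field(
        default_factory=lambda: {"SH": 0.66, "EE": 0.69}
    )
    nor_sd: float = 0.10
    of_duration_s: float = 120.0
    ieg_n_animals: int = 4
    ieg_images_per_animal: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["metrics"] = list(d["metrics"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["metrics"] = list(d["metrics"])
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _provenance(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["seed"] = cfg.seed
    df["config_hash"] = cfg.config_hash()
    return df


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_generate_simulate(cfg: RunConfig, outdir: Path) -> None:
    """Generate input sets and simulate one recording per cell."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(
        4 * cfg.n_cells_per_group
    ) % (2**31)
    recs = []
    input_rows = []
    k = 0
    for group in ("SH", "EE"):
        for c in range(cfg.n_cells_per_group):
            cell_id = f"{group}-{c + 1:02d}"
            icfg = synthetic.InputGenConfig(
                seed=int(seeds[k]), bin_width=cfg.bin_width, **cfg.input_cfg
            )
            gen = synthetic.generate_input_set(icfg)
            rcfg = synthetic.ResponderConfig(
                seed=int(seeds[k + 1]), **cfg.responder_cfg
            )
            rec = synthetic.simulate_granule_cell(
                gen.trains,
                rcfg,
                n_repetitions=cfg.n_repetitions,
                cell_id=cell_id,
                group=group,
            )
            recs.append(rec)
            input_rows.append(
                {
                    "cell_id": cell_id,
                    "group": group,
                    "realized_r": gen.realized_r,
                    "copy_p": gen.copy_p,
                    "n_rejected": gen.n_rejected,
                }
            )
            k += 2
    _write(
        _provenance(pd.DataFrame(input_rows), cfg), outdir / "inputs" / "inputs.csv"
    )
    write_spiketrains(recs, outdir / "recordings" / "recordings.csv")
    with open(outdir / "recordings" / "metadata.json", "w") as fh:
        json.dump(
            {"seed": cfg.seed, "config_hash": cfg.config_hash(),
             "n_cells": len(recs)},
            fh,
            indent=2,
        )


def _stage_metrics(cfg: RunConfig, outdir: Path) -> None:
    recs = read_spiketrains(outdir / "recordings" / "recordings.csv")
    sim = metrics_mod.similarity_table(recs, cfg.metrics, cfg.bin_width)
    summary = metrics_mod.pattern_summary_table(recs, cfg.bin_width, cfg.window_cap)
    _write(_provenance(sim, cfg), outdir / "metrics" / "similarity.csv")
    _write(_provenance(summary, cfg), outdir / "metrics" / "pattern_summary.csv")
    n_fail = int((~summary["qc_pass"]).sum())
    if n_fail:
        logger.info(
            "%d cells fail spike-probability QC and are excluded from stats: %s",
            n_fail,
            list(summary.loc[~summary["qc_pass"], "cell_id"]),
        )


def _stage_stats(cfg: RunConfig, outdir: Path) -> dict:
    sim = pd.read_csv(outdir / "metrics" / "similarity.csv")
    summary = pd.read_csv(outdir / "metrics" / "pattern_summary.csv")
    qc_cells = set(summary.loc[summary["qc_pass"], "cell_id"])
    sim_qc = sim[sim["cell_id"].isin(qc_cells)]

    ancova_rows = []
    ttest_rows = []
    for metric in cfg.metrics:
        pts = sim_qc[sim_qc["metric"] == metric]
        res = inference.ancova_compare(pts)
        ancova_rows.append(
            {
                "metric": metric,
                "group_a": res.groups[0],
                "group_b": res.groups[1],
                "slope_a": res.slopes[res.groups[0]],
                "slope_b": res.slopes[res.groups[1]],
                "intercept_a": res.intercepts[res.groups[0]],
                "intercept_b": res.intercepts[res.groups[1]],
                "common_slope": res.common_slope,
                "group_offset": res.group_offset,
                "p_group": res.p_group,
                "p_interaction": res.p_interaction,
                "n_a": res.n[res.groups[0]],
                "n_b": res.n[res.groups[1]],
            }
        )
        # mean output similarity per cell, then SH vs EE t-test
        cell_means = pts.groupby(["cell_id", "group"])["s_output"].mean().reset_index()
        sh = cell_means.loc[cell_means["group"] == "SH", "s_output"]
        ee = cell_means.loc[cell_means["group"] == "EE", "s_output"]
        t = inference.two_sample_t(sh, ee)
        ttest_rows.append(
            {
                "quantity": f"mean_{metric}_output",
                "mean_SH": t.means[0],
                "mean_EE": t.means[1],
                "t": t.statistic,
                "df": t.df,
                "p": t.p_value,
            }
        )
    for col in ("mean_spikes_per_sweep", "p_burst", "binwise_compactness",
                "occupancy_variation", "fr_variation"):
        qc = summary[summary["qc_pass"]]
        t = inference.two_sample_t(
            qc.loc[qc["group"] == "SH", col], qc.loc[qc["group"] == "EE", col]
        )
        ttest_rows.append(
            {
                "quantity": col,
                "mean_SH": t.means[0],
                "mean_EE": t.means[1],
                "t": t.statistic,
                "df": t.df,
                "p": t.p_value,
            }
        )
    ancova_df = pd.DataFrame(ancova_rows)
    ttest_df = pd.DataFrame(ttest_rows)
    _write(_provenance(ancova_df, cfg), outdir / "stats" / "ancova.csv")
    _write(_provenance(ttest_df, cfg), outdir / "stats" / "group_tests.csv")

    # ---- behavioral arm -------------------------------------------------
    bseeds = np.random.SeedSequence((cfg.seed, 1)).generate_state(64) % (2**31)
    nor_frames = []
    nor_rows = []
    for k, group in enumerate(("SH", "EE")):
        cohort = synthetic.generate_nor_cohort(
            n_per_group=cfg.n_animals_behavior,
            mean_di=cfg.nor_mean_di[group],
            sd=cfg.nor_sd,
            seed=int(bseeds[k]),
            group=group,
        )
        nor_frames.append(cohort)
        di = [
            behavior.discrimination_index(
                behavior.NORTrial(r.time_familiar, r.time_novel)
            )
            for r in cohort.itertuples()
        ]
        t = inference.one_sample_t(di, 0.5)
        nor_rows.append(
            {"group": group, "mean_di": t.means[0], "t_vs_chance": t.statistic,
             "df": t.df, "p_vs_chance": t.p_value, "n": t.n[0]}
        )
    nor = pd.concat(nor_frames, ignore_index=True)
    t_groups = inference.two_sample_t(
        nor.loc[nor["group"] == "SH", "di"], nor.loc[nor["group"] == "EE", "di"]
    )
    _write(_provenance(nor, cfg), outdir / "stats" / "nor_trials.csv")
    _write(_provenance(pd.DataFrame(nor_rows), cfg), outdir / "stats" / "nor_tests.csv")

    of_rows = []
    for k, group in enumerate(("SH", "EE")):
        for a in range(cfg.n_animals_behavior):
            trace = synthetic.generate_tracking_trace(
                duration=cfg.of_duration_s,
                seed=int(bseeds[8 + k * cfg.n_animals_behavior + a]),
                animal_id=f"{group}-of-{a + 1}",
                group=group,
            )
            row = {"animal_id": trace.animal_id, "group": group}
            row.update(behavior.locomotion_summary(trace))
            row.update(behavior.zone_times(trace))
            of_rows.append(row)
    of_df = pd.DataFrame(of_rows)
    _write(_provenance(of_df, cfg), outdir / "stats" / "openfield.csv")

    ieg = synthetic.generate_ieg_counts(
        n_animals=cfg.ieg_n_animals,
        images_per_animal=cfg.ieg_images_per_animal,
        seed=int(bseeds[40]),
    )
    dens = behavior.ieg_density(ieg)
    ieg_rows = []
    for marker, sub in dens.per_animal.groupby("marker"):
        res = inference.two_way_anova_tukey(sub)
        ieg_rows.append(
            {
                "marker": marker,
                "p_housing": res.p_housing,
                "p_condition": res.p_condition,
                "p_interaction": res.p_interaction,
            }
        )
    _write(_provenance(dens.per_animal, cfg), outdir / "stats" / "ieg_densities.csv")
    _write(_provenance(pd.DataFrame(ieg_rows), cfg), outdir / "stats" / "ieg_anova.csv")
    return {
        "ancova": ancova_df,
        "group_tests": ttest_df,
        "nor": pd.DataFrame(nor_rows),
        "nor_between": t_groups,
        "ieg": pd.DataFrame(ieg_rows),
        "openfield": of_df,
    }


def _stage_figures(cfg: RunConfig, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sim = pd.read_csv(outdir / "metrics" / "similarity.csv")
    fig, axes = plt.subplots(1, len(cfg.metrics), figsize=(4 * len(cfg.metrics), 4))
    axes = np.atleast_1d(axes)
    colors = {"SH": "tab:blue", "EE": "tab:orange"}
    for ax, metric in zip(axes, cfg.metrics):
        pts = sim[sim["metric"] == metric]
        for group, sub in pts.groupby("group"):
            ax.scatter(sub["s_input"], sub["s_output"], s=8, alpha=0.5,
                       color=colors.get(group, "k"), label=group)
        lims = (0, 1) if metric != "R" else (-0.2, 1)
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(f"{metric} input")
        ax.set_ylabel(f"{metric} output")
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / "figures" / "similarity_scatter.png", dpi=120)
    plt.close(fig)

    summary = pd.read_csv(outdir / "metrics" / "pattern_summary.csv")
    fig, axes = plt.subplots(1, 2, figsize=(7, 4))
    for ax, col in zip(axes, ("mean_spikes_per_sweep", "p_burst")):
        means = summary.groupby("group")[col].mean()
        sems = summary.groupby("group")[col].sem()
        ax.bar(means.index, means.values, yerr=sems.values,
               color=[colors.get(g, "k") for g in means.index])
        ax.set_ylabel(col)
    fig.tight_layout()
    fig.savefig(outdir / "figures" / "pattern_summary.png", dpi=120)
    plt.close(fig)


def _stage_report(cfg: RunConfig, outdir: Path) -> None:
    ancova = pd.read_csv(outdir / "stats" / "ancova.csv")
    tests = pd.read_csv(outdir / "stats" / "group_tests.csv")
    nor = pd.read_csv(outdir / "stats" / "nor_tests.csv")
    ieg = pd.read_csv(outdir / "stats" / "ieg_anova.csv")
    summary = pd.read_csv(outdir / "metrics" / "pattern_summary.csv")
    lines = [
        "patsep simulated-study report",
        f"seed = {cfg.seed}, config hash = {cfg.config_hash()}",
        f"cells per group = {cfg.n_cells_per_group}, "
        f"bin width = {cfg.bin_width * 1000:g} ms",
        "",
        "QC: spike probability in [0.30, 0.80]",
        f"  cells passing: {int(summary['qc_pass'].sum())} / {len(summary)}",
        "",
        "Input-output similarity (ANCOVA, EE vs SH):",
    ]
    for r in ancova.itertuples():
        lines.append(
            f"  {r.metric}: common slope = {r.common_slope:.3f}, "
            f"group offset = {r.group_offset:+.4f}, "
            f"p_group = {r.p_group:.4f}, p_interaction = {r.p_interaction:.4f}"
        )
    lines.append("")
    lines.append("Group t-tests (SH vs EE):")
    for r in tests.itertuples():
        lines.append(
            f"  {r.quantity}: SH = {r.mean_SH:.4f}, EE = {r.mean_EE:.4f}, "
            f"t = {r.t:.3f}, p = {r.p:.4f}"
        )
    lines.append("")
    lines.append("NOR discrimination index vs chance (0.5):")
    for r in nor.itertuples():
        lines.append(
            f"  {r.group}: DI = {r.mean_di:.3f}, t = {r.t_vs_chance:.3f}, "
            f"p = {r.p_vs_chance:.4f} (n = {r.n})"
        )
    lines.append("")
    lines.append("IEG densities (two-way ANOVA housing x condition):")
    for r in ieg.itertuples():
        lines.append(
            f"  {r.marker}: p_housing = {r.p_housing:.4f}, "
            f"p_condition = {r.p_condition:.4f}, "
            f"p_interaction = {r.p_interaction:.4f}"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: RunConfig,
    outdir,
    from_stage: str = "generate",
) -> Path:
    """Run the pipeline into ``outdir`` and return its path.

    ``from_stage`` skips earlier stages and reuses their on-disk
    outputs unchanged (they must exist).
    """
    if from_stage not in STAGES:
        raise ParameterError(f"unknown stage {from_stage!r}; expected one of {STAGES}")
    outdir = Path(outdir)
    for sub in ("inputs", "recordings", "metrics", "stats", "figures"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    start = STAGES.index(from_stage)
    plan = [
        ("generate", lambda: _stage_generate_simulate(config, outdir)),
        ("simulate", lambda: None),  # folded into generate
        ("metrics", lambda: _stage_metrics(config, outdir)),
        ("stats", lambda: _stage_stats(config, outdir)),
        ("report", lambda: (_stage_figures(config, outdir),
                            _stage_report(config, outdir))),
    ]
    for name, fn in plan[start:]:
        logger.info("running stage %s", name)
        try:
            fn()
        except (ParameterError, FileNotFoundError, KeyError) as exc:
            raise PipelineError(name, str(exc)) from exc
    return outdir
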