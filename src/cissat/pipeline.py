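"""End-to-end orchestration: simulate -> scan series -> dynamics -> scaling fit.

One :class:`RunConfig` (single master seed, stage sub-seeds derived by fixed
offsets) drives a deterministic run that persists every stage as TSV under
one output directory:

    config.yaml            the resolved configuration
    cohort/                simulated cohort (VCF, expression TSVs, BED, truth)
    runs/rep{r}/step{i}/{tissue}.tsv   per-scan lead tables
    manifest.tsv           replicate, step, n, tissue, q, s, p_threshold
    class_counts.tsv       7-class membership counts per step
    rates.tsv              creation/deletion/move-in/move-out per class
    overlaps.tsv           consecutive and reference overlap fractions
    summaries.tsv          per-class distance / strength means (last step)
    specificity.tsv        per-tissue specific% and shared-all% per step
    scaling.tsv            per-tissue (and per-replicate) scaling-law fits
    run.log                stage-by-stage log with seeds and counts
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dynamics import (build_trajectory, distance_strength_summary,
                       overlap_frame, specificity_percentages)
from .io import Cohort, read_cohort
from .scaling import fit_scaling_law
from .series import SeriesResult, log_spaced_sizes, run_series, write_series
from .simulate import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger("cissat")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort_dir: str | None = None  # read a cohort instead of simulating
    n_min: int = 50
    k: int = 20
    replicates: int = 5
    fdr_target: float = 0.10
    n_permutations: int = 10
    window_bp: int = 1_000_000
    maf_threshold: float = 0.05
    seed: int = 0
    out_dir: str = "cissat_run"

    def to_yaml(self, path: str | os.PathLike) -> None:
        from .simulate import plain_types

        data = {k: v for k, v in dataclasses.asdict(self).items()
                if k != "simulation"}
        sim = dataclasses.asdict(self.simulation)
        sim["maf_range"] = list(self.simulation.maf_range)
        data.update(sim)  # flat key-value file; namespaces do not collide
        data = plain_types(data)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        run_fields = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(data) - sim_fields - run_fields
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        sim_kwargs = {k: v for k, v in data.items() if k in sim_fields}
        if "maf_range" in sim_kwargs:
            sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
        run_kwargs = {k: v for k, v in data.items() if k in run_fields}
        return cls(simulation=SimulationConfig(**sim_kwargs), **run_kwargs)


@dataclass
class RunResult:
    """In-memory view of a completed run (everything is also on disk)."""

    config: RunConfig
    cohort: Cohort
    series: list[SeriesResult]
    manifest: pd.DataFrame
    class_counts: pd.DataFrame
    rates: pd.DataFrame
    overlaps: pd.DataFrame
    summaries: pd.DataFrame
    specificity: pd.DataFrame
    scaling: pd.DataFrame


def _stage(name: str):
    logger.info("stage: %s", name)


def fit_scaling_table(manifest: pd.DataFrame,
                      predict_at: dict[str, float] | None = None,
                      ) -> pd.DataFrame:
    """Scaling-law fits per (tissue, replicate) plus a pooled fit per tissue."""
    from .scaling import predict_count

    rows = []
    for tissue, per_tissue in manifest.groupby("tissue"):
        scopes = [(f"rep{r}", group) for r, group in
                  per_tissue.groupby("replicate")]
        scopes.append(("pooled", per_tissue))
        for scope, group in scopes:
            fit = fit_scaling_law(group["n"].to_numpy(),
                                  group["q"].to_numpy())
            row = {"tissue": tissue, "scope": scope,
                   "alpha": fit.alpha, "beta": fit.beta,
                   "r_squared": fit.r_squared, "n_points": fit.n_points}
            if predict_at and tissue in predict_at:
                row["predict_n"] = predict_at[tissue]
                row["predicted_q"] = predict_count(fit, predict_at[tissue])
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage deterministically and persist all outputs."""
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("master seed: %d", config.seed)
        config.to_yaml(os.path.join(out_dir, "config.yaml"))

        _stage("cohort")
        if config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
            logger.info("read cohort from %s: %d samples", config.cohort_dir,
                        cohort.n_samples)
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim)
            write_cohort(cohort, os.path.join(out_dir, "cohort"))
            logger.info("simulated cohort: %d samples, %d SNPs, %d transcripts",
                        cohort.n_samples, len(cohort.snps),
                        len(cohort.transcripts))

        _stage("subsample series")
        sizes = log_spaced_sizes(config.n_min, cohort.n_samples, config.k)
        logger.info("sizes: %s", sizes)
        series = run_series(
            cohort, n_min=config.n_min, k=config.k,
            fdr_target=config.fdr_target,
            n_permutations=config.n_permutations,
            replicates=config.replicates, seed=config.seed,
            window_bp=config.window_bp, maf_threshold=config.maf_threshold)
        write_series(series, out_dir)
        manifest = pd.concat([r.manifest_frame() for r in series],
                             ignore_index=True)
        for r in series:
            logger.info("replicate %d: q at n=%d: %s", r.replicate, sizes[-1],
                        {t: r.counts(t)[-1] for t in r.tissues})

        _stage("overlap dynamics")
        counts_frames, rates_frames, overlap_frames = [], [], []
        summary_frames, specificity_frames = [], []
        for result in series:
            trajectory = build_trajectory(result)
            counts_frames.append(trajectory.counts_frame())
            rates_frames.append(trajectory.rates_frame())
            overlap_frames.append(overlap_frame(result))
            last = trajectory.k
            summary = distance_strength_summary(
                trajectory.memberships[-1],
                {t: result.scans[(last, t)] for t in result.tissues})
            summary.insert(0, "replicate", result.replicate)
            summary_frames.append(summary)
            for step in (1, last):
                specificity = specificity_percentages(trajectory, step)
                specificity.insert(0, "replicate", result.replicate)
                specificity_frames.append(specificity)
        class_counts = pd.concat(counts_frames, ignore_index=True)
        rates = pd.concat(rates_frames, ignore_index=True)
        overlaps = pd.concat(overlap_frames, ignore_index=True)
        summaries = pd.concat(summary_frames, ignore_index=True)
        specificity = pd.concat(specificity_frames, ignore_index=True)

        _stage("scaling fit")
        scaling = fit_scaling_table(manifest)
        for _, row in scaling[scaling["scope"] == "pooled"].iterrows():
            logger.info("tissue %s: alpha=%.3f beta=%.3f R2=%.4f",
                        row["tissue"], row["alpha"], row["beta"],
                        row["r_squared"])

        for name, frame in (("class_counts", class_counts), ("rates", rates),
                            ("overlaps", overlaps), ("summaries", summaries),
                            ("specificity", specificity),
                            ("scaling", scaling)):
            frame.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t",
                         index=False, float_format="%.6g")
        logger.info("run complete")
    except Exception as exc:  # annotate which stage died
        logger.error("run aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return RunResult(config, cohort, series, manifest, class_counts, rates,
                     overlaps, summaries, specificity, scaling)


def report_summary(run_dir: str | os.PathLike) -> str:
    """Human-readable summary of a completed run, re-read from stage files."""
    paths = {name: os.path.join(run_dir, f"{name}.tsv")
             for name in ("scaling", "specificity", "overlaps")}
    manifest_path = os.path.join(run_dir, "manifest.tsv")
    for label, path in {**paths, "manifest": manifest_path}.items():
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"{run_dir}: missing stage file {os.path.basename(path)} "
                f"({label}); the run is incomplete")
    scaling = pd.read_csv(paths["scaling"], sep="\t")
    specificity = pd.read_csv(paths["specificity"], sep="\t")
    overlaps = pd.read_csv(paths["overlaps"], sep="\t")
    manifest = pd.read_csv(manifest_path, sep="\t")

    lines = [f"run directory: {run_dir}", ""]
    lines.append("scaling law (sqrt q = alpha + beta ln n), pooled per tissue:")
    pooled = scaling[scaling["scope"] == "pooled"]
    for _, row in pooled.iterrows():
        lines.append(f"  {row['tissue']}: alpha={row['alpha']:.3f} "
                     f"beta={row['beta']:.3f} R2={row['r_squared']:.3f}")
    lines.append("")
    lines.append("eQTL counts q per step (replicate 1):")
    rep1 = manifest[manifest["replicate"] == manifest["replicate"].min()]
    for tissue, group in rep1.groupby("tissue"):
        ordered = group.sort_values("step")
        pairs = ", ".join(f"{int(n)}:{int(q)}" for n, q in
                          zip(ordered["n"], ordered["q"]))
        lines.append(f"  {tissue}: {pairs}")
    lines.append("")
    lines.append("tissue specificity (% of a tissue's detections):")
    for (rep, step), group in specificity.groupby(["replicate", "step"]):
        for _, row in group.iterrows():
            lines.append(f"  rep{rep} step{int(step)} {row['tissue']}: "
                         f"specific {row['pct_specific']:.1f}%, "
                         f"shared-all {row['pct_shared_all']:.1f}%")
    lines.append("")
    consecutive = overlaps[overlaps["kind"] == "consecutive"]
    for level, group in consecutive.groupby("level"):
        lines.append(f"mean consecutive {level} overlap: "
                     f"{group['value'].mean():.3f}")
    return "\n".join(lines)
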