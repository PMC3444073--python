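"""End-to-end pipeline: load/simulate -> select -> group -> separability.

Orchestrates the full band-selection study on one configuration and writes
a CSV report bundle plus a plain-text summary. Identical configuration and
seed give byte-identical outputs; an existing non-empty output directory is
never overwritten (a versioned sibling is created instead).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ga, sam, separability as sep
from .simulate import SimConfig, generate_library, planted_truth
from .spectra import SpectralLibrary, kirchhoff_to_emissivity, read_library, split_per_species, write_library

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    library_path: str | None = None
    reflectance_input: bool = False
    sim: SimConfig | None = None
    ga: ga.GAConfig = field(default_factory=lambda: ga.GAConfig(k=5))
    n_runs: int = 40
    n_train: int = 17
    k_sweep: tuple[int, ...] | None = None
    n_random: int = 40
    alpha: float = 0.05
    ridge: float = sep.DEFAULT_RIDGE
    gap_um: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_path is None and self.sim is None:
            raise ValueError(
                "configuration must provide a library path or a simulation config"
            )


@dataclass(frozen=True)
class PipelineResult:
    """Everything the pipeline computed, for rendering and inspection."""

    library: SpectralLibrary
    sweep: ga.SweepResult | None
    repeats: ga.RepeatResult
    groups: list[ga.BandGroup]
    train_confusion: sam.ConfusionMatrix | None
    validation_confusion_mean: np.ndarray
    validation_accuracy_mean: float
    report: sep.SeparabilityReport
    out_dir: Path


def _resolve_out_dir(path: str | Path) -> Path:
    """Return ``path`` if absent/empty, else the first free versioned sibling."""
    base = Path(path)
    candidate = base
    v = 0
    while candidate.exists() and any(candidate.iterdir()):
        v += 1
        candidate = base.with_name(f"{base.name}-{v}")
    if candidate != base:
        logger.info("output dir %s not empty; writing to %s", base, candidate)
    candidate.mkdir(parents=True, exist_ok=True)
    return candidate


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def _load_library(cfg: PipelineConfig, out: Path) -> SpectralLibrary:
    if cfg.library_path is not None:
        lib = read_library(cfg.library_path)
        if cfg.reflectance_input:
            values = np.vstack(
                [kirchhoff_to_emissivity(row) for row in lib.values]
            )
            lib = SpectralLibrary(
                grid=lib.grid,
                values=values,
                species_codes=lib.species_codes,
                leaf_ids=lib.leaf_ids,
            )
        return lib
    assert cfg.sim is not None
    lib = generate_library(cfg.sim)
    write_library(lib, out / "library.csv")
    (out / "truth.json").write_text(json.dumps(planted_truth(cfg.sim), indent=2))
    return lib


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the report bundle.

    Stages: load/simulate -> optional chromosome-size sweep -> repeated GA
    runs with reshuffled splits -> winner-gene grouping -> J-M comparison
    against random bands. Each stage fails loudly with its name; outputs
    written before a failure are retained.
    """
    out = _resolve_out_dir(cfg.out_dir)
    try:
        _stage("load")
        lib = _load_library(cfg, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load' failed: {exc}") from exc

    sweep = None
    if cfg.k_sweep:
        try:
            _stage("k-sweep")
            split = split_per_species(lib, cfg.n_train, cfg.seed)
            sweep = ga.sweep_chromosome_size(split, cfg.ga, cfg.k_sweep)
            pd.DataFrame(
                {"k": sweep.k_values, "winner_fitness_pct": sweep.winner_fitness_by_k}
            ).to_csv(out / "ksweep.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'k-sweep' failed: {exc}") from exc

    try:
        _stage("select")
        repeats = ga.repeat_runs(lib, cfg.ga, cfg.n_runs, cfg.n_train)
        runs_df = pd.DataFrame(
            {
                "run": np.arange(1, cfg.n_runs + 1),
                "split_seed": repeats.split_seeds,
                "ga_seed": [r.seed for r in repeats.runs],
                "winner_fitness_pct": [r.winner_fitness for r in repeats.runs],
                "generations": [r.generations_run for r in repeats.runs],
                "winner_wavelengths_um": [
                    ";".join(f"{w:.4f}" for w in r.winner.wavelengths(lib.grid))
                    for r in repeats.runs
                ],
            }
        )
        runs_df.to_csv(out / "runs.csv", index=False)
        pd.DataFrame(
            {
                "wavelength_um": lib.grid.wavelengths_um,
                "winner_gene_count": repeats.pooled_gene_counts,
            }
        ).to_csv(out / "gene_frequency.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'select' failed: {exc}") from exc

    try:
        _stage("group")
        groups = ga.group_bands(repeats.pooled_wavelengths, cfg.gap_um)
        pd.DataFrame(
            [
                {
                    "region": g.region,
                    "n_genes": g.n_genes,
                    "wl_min_um": g.wl_min_um,
                    "wl_max_um": g.wl_max_um,
                    "mean_um": g.mean_um,
                    "sd_um": g.sd_um,
                }
                for g in groups
            ]
        ).to_csv(out / "band_groups.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'group' failed: {exc}") from exc

    try:
        _stage("confusion")
        # average validation confusion across runs, and the training-set
        # confusion of the best run (classifying the training half against
        # its own references)
        val_sum = None
        best = max(repeats.runs, key=lambda r: r.winner_fitness)
        train_cm = None
        for r, split_seed in zip(repeats.runs, repeats.split_seeds):
            split = split_per_species(lib, cfg.n_train, split_seed)
            cm, _ = sam.evaluate(split, r.winner.genes)
            val_sum = cm.counts if val_sum is None else val_sum + cm.counts
            if r is best:
                refs = sam.build_references(split.train, r.winner.genes)
                train_cm = sam.confusion_for(split.train, refs)
        assert val_sum is not None
        val_mean = val_sum / len(repeats.runs)
        val_acc = 100.0 * float(np.trace(val_mean)) / float(val_mean.sum())
        labels = lib.species
        df = pd.DataFrame(val_mean, index=list(labels), columns=list(labels))
        with (out / "confusion_validation_mean.csv").open("w") as fh:
            df.to_csv(fh, float_format="%.3f")
            fh.write(f"overall_accuracy,{val_acc:.2f}%\n")
        if train_cm is not None:
            train_cm.write_csv(out / "confusion_training_best.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'confusion' failed: {exc}") from exc

    try:
        _stage("separability")
        winners = [r.winner.genes for r in repeats.runs]
        report = sep.compare_jm(
            winners,
            lib,
            n_random=cfg.n_random,
            alpha=cfg.alpha,
            ridge=cfg.ridge,
            seed=cfg.seed + 1,
        )
        report.pairs.to_csv(out / "separability_pairs.csv", index=False)
        report.p_value_matrix().to_csv(out / "pvalue_matrix.csv", float_format="%.4f")
        pooled_bands = sorted({int(b) for ch in winners for b in ch})
        norm_df, lev_df = sep.assumption_checks(lib, pooled_bands)
        norm_df.to_csv(out / "assumption_normality.csv", index=False)
        lev_df.to_csv(out / "assumption_homoscedasticity.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'separability' failed: {exc}") from exc

    result = PipelineResult(
        library=lib,
        sweep=sweep,
        repeats=repeats,
        groups=groups,
        train_confusion=train_cm,
        validation_confusion_mean=val_mean,
        validation_accuracy_mean=val_acc,
        report=report,
        out_dir=out,
    )
    (out / "summary.txt").write_text(render_summary(result))
    return result


def _fmt_confusion(labels, counts, accuracy) -> list[str]:
    df = pd.DataFrame(np.asarray(counts), index=list(labels), columns=list(labels))
    lines = df.to_string(float_format=lambda v: f"{v:.2f}").splitlines()
    lines.append(f"overall accuracy = {accuracy:.2f}%")
    return lines


def render_summary(result: PipelineResult) -> str:
    """Plain-text report in fixed section order: data summary, chromosome
    -size sweep, per-run winners, band groups, confusion matrices,
    separability."""
    lib = result.library
    lines: list[str] = []
    lines.append("== Data summary ==")
    lines.append(
        f"{len(lib.species)} species, {lib.n_spectra} spectra, "
        f"{lib.grid.n_bands} bands ({lib.grid.n_valid} valid)"
    )
    for lo, hi in lib.grid.excluded_regions():
        lines.append(f"excluded region: {lo:.3f}-{hi:.3f} um")
    lines.append("")

    lines.append("== Chromosome-size sweep ==")
    if result.sweep is None:
        lines.append("(not run)")
    else:
        for k, f in zip(result.sweep.k_values, result.sweep.winner_fitness_by_k):
            lines.append(f"k={k:2d}  winner fitness {f:.2f}%")
        lines.append(
            f"minimal k meeting threshold: "
            f"{result.sweep.minimal_k if result.sweep.minimal_k is not None else 'none met'}"
        )
    lines.append("")

    lines.append("== Per-run winners ==")
    if not result.repeats.runs:
        lines.append("(no runs)")
    else:
        for i, r in enumerate(result.repeats.runs, start=1):
            wl = ", ".join(f"{w:.3f}" for w in r.winner.wavelengths(lib.grid))
            lines.append(f"run {i:2d}: fitness {r.winner_fitness:.2f}%  bands [{wl}] um")
    lines.append("")

    lines.append("== Band groups ==")
    for g in result.groups:
        lines.append(
            f"{g.region:>16s}  n={g.n_genes:3d}  "
            f"{g.wl_min_um:.2f}-{g.wl_max_um:.2f} um  "
            f"mean {g.mean_um:.2f} um  sd {g.sd_um:.3f} um"
        )
    lines.append("")

    lines.append("== Confusion matrices ==")
    if result.train_confusion is not None:
        lines.append("training (best run):")
        lines.extend(
            _fmt_confusion(
                result.train_confusion.labels,
                result.train_confusion.counts,
                result.train_confusion.accuracy,
            )
        )
    lines.append("validation (mean over runs):")
    lines.extend(
        _fmt_confusion(
            lib.species, result.validation_confusion_mean, result.validation_accuracy_mean
        )
    )
    lines.append("")

    lines.append("== Separability ==")
    rep = result.report
    for _, row in rep.pairs.iterrows():
        lines.append(
            f"{row['species_a']}-{row['species_b']}: "
            f"JM(selected) {row['jm_ga_mean']:.3f}  "
            f"JM(random) {row['jm_random_mean']:.3f}  p={row['p']:.4f}"
        )
    lines.append(
        f"significant pairs at alpha={rep.alpha}: {rep.n_significant} of {rep.n_pairs}"
    )
    lines.append("")
    return "\n".join(lines)
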