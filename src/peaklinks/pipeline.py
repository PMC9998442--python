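"""Configuration, orchestration and reproducibility shell over the library.

A single :class:`PipelineConfig` (YAML-serializable) drives every stage.
Per-stage seeds are derived from the master seed through a fixed counter so a
stage can be rerun in isolation and still reproduce. Each run writes a
machine-readable manifest (config hash, per-stage seeds, package versions)
next to its outputs; two runs with equal manifests produce equal outputs.
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

from . import __version__
from .core import ConfigError, cis_candidates, load_multiome
from .diagnostics import DEFAULT_N_BOOT, diagnose_null
from .markers import assign_link_celltypes, assign_markers, downsampling_experiment
from .scoring import (
    DEFAULT_BANDWIDTH,
    DEFAULT_MIN_BOTH_NONZERO,
    DEFAULT_N_DRAWS,
    DEFAULT_R_THRESHOLD,
    DIAGNOSTIC_N_DRAWS,
    LinkScorer,
)
from .simulate import SimulationConfig, simulate_multiome, write_fixture
from .validation import compare_methods, truth_reference

logger = logging.getLogger("peaklinks")

STAGES = ("simulate", "score", "diagnose", "markers", "downsample", "validate")
_STAGE_SEED_OFFSET = {s: i for i, s in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run, with the field-standard defaults:
    500 kb cis window, 200 null draws (1,000 for modality diagnostics),
    |R| > 0.01 (0.1 for the stringent variant), >= 15 both-nonzero cells,
    marker thresholds AUC 0.55 / FDR 1e-5 / > 50 cells, and a bootstrap
    modality test with k = 2 and EM tolerance 1e-3."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None        # load a fixture instead of simulating
    window: int = 500_000
    n_draws: int = DEFAULT_N_DRAWS
    diagnostic_draws: int = DIAGNOSTIC_N_DRAWS
    r_threshold: float = DEFAULT_R_THRESHOLD
    min_both_nonzero: int = DEFAULT_MIN_BOTH_NONZERO
    bandwidth: float = DEFAULT_BANDWIDTH
    normalization: str = "lognorm"
    methods: tuple[str, ...] = ("pearson", "zscore", "wdist", "wdist_r")
    class_filter_nulls: bool = False
    marker_auc_threshold: float = 0.55
    marker_fdr_threshold: float = 1e-5
    marker_min_cells: int = 50
    n_boot: int = DEFAULT_N_BOOT
    n_diagnose: int = 50                # cap on links sent to the modality test
    downsample_types: tuple[str, ...] = ()
    downsample_n_keep: int = 500
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * len(STAGES) + _STAGE_SEED_OFFSET[stage]) % (2**31)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim_kwargs = d.pop("simulation", {})
        for key in ("gc_beta_params", "libsize_lognormal_params"):
            if key in sim_kwargs and sim_kwargs[key] is not None:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim = SimulationConfig(**sim_kwargs)
        for key in ("methods", "downsample_types"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(simulation=sim, **d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def run(config: PipelineConfig, stages: list[str], outdir: str | Path) -> Path:
    """Execute the requested stages in dependency order under ``outdir``."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}; choose from {STAGES}")
    stages = [s for s in STAGES if s in stages]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = truth = None
    fixture_dir = out / "fixture"
    if "simulate" in stages:
        sim = dataclasses.replace(config.simulation, seed=config.stage_seed("simulate"))
        dataset, truth = simulate_multiome(sim)
        write_fixture(dataset, truth, fixture_dir)
        logger.info("simulate: %d cells, %d peaks, %d genes, %d true links",
                    dataset.n_cells, len(dataset.peaks), len(dataset.genes),
                    len(truth.true_links))
    elif config.input_dir is not None:
        dataset = load_multiome(config.input_dir)
    elif fixture_dir.exists():
        dataset = load_multiome(fixture_dir)
    elif set(stages) - {"simulate"}:
        raise ConfigError("no input data: run the 'simulate' stage first or set input_dir")

    if dataset is None:
        raise ConfigError("no stages produced or loaded a dataset")

    truth_path = (Path(config.input_dir) if config.input_dir else fixture_dir) / "truth.tsv"
    if truth is None and truth_path.exists():
        truth = _read_truth(truth_path)

    candidates = cis_candidates(dataset.peaks, dataset.genes, window=config.window)
    links = None
    links_path = out / "links.tsv"

    def _scorer(class_filter: bool = False) -> LinkScorer:
        return LinkScorer(
            dataset,
            normalization=config.normalization,
            n_draws=config.n_draws,
            bandwidth=config.bandwidth,
            seed=config.stage_seed("score"),
            class_filter_nulls=class_filter or config.class_filter_nulls,
        )

    if "score" in stages:
        links = _scorer().score(
            candidates, methods=config.methods,
            r_threshold=config.r_threshold,
            min_both_nonzero=config.min_both_nonzero,
        )
        links.to_csv(links_path, sep="\t", index=False)
        logger.info("score: %d links written to %s", len(links), links_path)
    elif links_path.exists():
        links = pd.read_csv(links_path, sep="\t")

    def _need_links(stage: str) -> pd.DataFrame:
        if links is None:
            raise ConfigError(f"stage '{stage}' needs a link table: run 'score' first")
        return links

    if "markers" in stages:
        marker_table = assign_markers(
            dataset,
            auc_threshold=config.marker_auc_threshold,
            fdr_threshold=config.marker_fdr_threshold,
            min_cells=config.marker_min_cells,
        )
        marker_table.table.to_csv(out / "markers.tsv", sep="\t", index=False)
        labeled = assign_link_celltypes(_need_links("markers"), marker_table)
        labeled.to_csv(links_path, sep="\t", index=False)
        links = labeled

    if "diagnose" in stages:
        tbl = _need_links("diagnose")
        subset = tbl.nlargest(config.n_diagnose, "pearson_r")
        scorer = _scorer(class_filter=config.class_filter_nulls)
        rows = []
        for r in subset.itertuples():
            null, verdict = diagnose_null(
                scorer, r.peak_id, r.gene_id,
                n_draws=config.diagnostic_draws,
                seed=config.stage_seed("diagnose"),
                n_boot=config.n_boot,
                class_filter=config.class_filter_nulls,
            )
            rows.append({
                "peak_id": r.peak_id, "gene_id": r.gene_id,
                "n_draws": null.n_draws, "lrt": verdict.lrt_observed,
                "p_value": verdict.p_value, "multimodal": verdict.multimodal,
            })
        pd.DataFrame(rows).to_csv(out / "diagnostics.tsv", sep="\t", index=False)
        logger.info("diagnose: %d nulls tested, %d multimodal",
                    len(rows), sum(r["multimodal"] for r in rows))

    if "downsample" in stages:
        if not config.downsample_types:
            raise ConfigError("downsample stage needs downsample_types in the config")
        result = downsampling_experiment(
            dataset, set(config.downsample_types), config.downsample_n_keep,
            candidates, seed=config.stage_seed("downsample"),
            r_threshold=max(config.r_threshold, 0.1),
            normalization=config.normalization,
            n_draws=config.n_draws, bandwidth=config.bandwidth,
        )
        result.pairs.to_csv(out / "downsample_pairs.tsv", sep="\t", index=False)
        result.summary.to_csv(out / "downsample_summary.tsv", sep="\t", index=False)

    if "validate" in stages:
        tbl = _need_links("validate")
        if truth is None:
            raise ConfigError("validate stage needs ground truth (simulate first)")
        reference = truth_reference(dataset, truth.true_links)
        score_cols = [c for c in ("pearson_r", "zscore", "wdist", "wdist_r", "zinb_absz")
                      if c in tbl.columns]
        universe = tbl.copy()
        if "pearson_r" in score_cols:
            universe["abs_pearson_r"] = universe["pearson_r"].abs()
            score_cols[score_cols.index("pearson_r")] = "abs_pearson_r"
        aucs = compare_methods(
            universe, reference, score_cols,
            {p.id: p.interval for p in dataset.peaks},
        )
        aucs.to_csv(out / "auc.tsv", sep="\t", index=False)
        logger.info("validate:\n%s", aucs.to_string(index=False))

    manifest = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in stages},
        "stages": stages,
        "versions": {"peaklinks": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    config.to_yaml(out / "config.yaml")
    return out


def _read_truth(path: Path):
    from .simulate import GroundTruth

    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        true_links=set(zip(df["peak_id"].astype(str), df["gene_id"].astype(str))),
        peak_owner_type=dict(zip(df["peak_id"], df["peak_owner_type"])),
        gene_marker_type=dict(zip(df["gene_id"], df["gene_marker_type"])),
    )
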