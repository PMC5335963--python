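"""End-to-end screening pipeline and run manifest.

Order of operations: background subtraction -> univariate significance
screen -> minority oversampling -> exhaustive subset screen (LOOCV SVM)
-> best-per-size sweep -> rank tables -> VOC frequency tables ->
stage-distance analysis. Each product is written as a CSV into the output
directory together with a ``manifest.json`` recording the configuration,
seed, package version and a fingerprint of the input data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (VOCTable, read_voc_table, significance_screen,
                     subtract_background, write_voc_table)
from .oversample import OversampleConfig
from .search import (ResultCache, SubsetScreen, data_fingerprint,
                     voc_frequency)
from .stages import stage_distances
from .svm import KernelParams

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An error in a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON serialisable)."""

    cohort_csv: str
    out_dir: str
    background_csv: str | None = None
    schema: dict | None = None
    sigma: float = 1.5
    c_penalty: float = 1000.0
    sizes: list = field(default_factory=lambda: list(range(1, 11)))
    metrics: list = field(default_factory=lambda: ["acc", "tpr", "tnr"])
    top_k: int = 10
    oversample_k: int = 2
    oversample_target: int | None = None
    seed: int = 0
    cache_path: str | None = None
    n_jobs: int = 1
    #: VOC subset for the stage analysis; None = best-TPR subset of the
    #: largest screened size
    stage_subset: list | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def kernel(self) -> KernelParams:
        return KernelParams(sigma=self.sigma, c_penalty=self.c_penalty)


def run_pipeline(config: RunConfig, table: VOCTable | None = None) -> dict:
    """Execute the full screening pipeline; returns the output paths.

    ``table`` may be passed directly (e.g. from the simulator) to skip
    the CSV-reading stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    warnings: list[str] = []
    t0 = time.time()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # tag errors with the failing stage
            raise PipelineError(name, exc) from exc

    if table is None:
        table = _stage("read", lambda: read_voc_table(
            config.cohort_csv, schema=config.schema))

    if config.background_csv:
        def _bg():
            bg = pd.read_csv(config.background_csv)
            series = pd.Series(bg.iloc[:, 1].values, index=bg.iloc[:, 0])
            return subtract_background(table, series)
        table = _stage("background", _bg)

    screen_df = _stage("significance", lambda: significance_screen(table))
    path = out / "significance_screen.csv"
    screen_df.to_csv(path)
    outputs["significance_screen"] = str(path)

    oconf = OversampleConfig(target_n=config.oversample_target,
                             k_neighbors=config.oversample_k,
                             seed=config.seed)
    model = SubsetScreen(table, sizes=config.sizes, kernel=config.kernel(),
                         oversample=oconf)
    prepared = _stage("oversample", model.prepared_table)
    path = out / "cohort_oversampled.csv"
    write_voc_table(prepared, path)
    outputs["cohort_oversampled"] = str(path)

    cache = ResultCache(config.cache_path) if config.cache_path else None

    def _screen():
        from .search import screen_all
        return screen_all(prepared, config.sizes, config.kernel(),
                          cache=cache, n_jobs=config.n_jobs)
    results = _stage("screen", _screen)
    from .search import SubsetScreenResults
    fitted = SubsetScreenResults(model, prepared, results)
    path = out / "subset_results.csv"
    fitted.to_dataframe().round(6).to_csv(path, index=False)
    outputs["subset_results"] = str(path)

    sweep = _stage("sweep", fitted.size_sweep)
    path = out / "size_sweep.csv"
    sweep.round(6).to_csv(path)
    outputs["size_sweep"] = str(path)

    rank_sizes = {}
    for metric in config.metrics:
        def _rank(metric=metric):
            # rank at the size whose best-metric model is simplest
            # (fewest support vectors), the parsimony criterion
            s = int(sweep[f"best_{metric}_sv"].idxmin())
            rank_sizes[metric] = s
            return fitted.rank_table(metric, size=s, top_k=min(
                config.top_k, sum(1 for r in results if len(r.subset) == s)))
        rank = _stage(f"rank[{metric}]", _rank)
        path = out / f"rank_{metric}.csv"
        rank.assign(subset=rank["subset"].map(",".join)).to_csv(path, index=False)
        outputs[f"rank_{metric}"] = str(path)
        freq = _stage(f"frequency[{metric}]", lambda rank=rank: voc_frequency(rank))
        path = out / f"frequency_{metric}.csv"
        freq.to_csv(path, index=False)
        outputs[f"frequency_{metric}"] = str(path)
        if metric == "tpr" and config.stage_subset is None:
            config.stage_subset = list(rank.iloc[0]["subset"])

    if config.stage_subset and any(s is not None for s in prepared.stage):
        sd = _stage("stage", lambda: stage_distances(
            prepared, config.stage_subset, config.kernel()))
        path = out / "stage_distances.csv"
        sd.per_sample.to_csv(path, index=False)
        outputs["stage_distances"] = str(path)
        path = out / "stage_summary.csv"
        sd.per_stage.assign(spearman_rho=sd.spearman_rho).to_csv(path, index=False)
        outputs["stage_summary"] = str(path)

    manifest = {
        "package": "breathscreen",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "data_fingerprint": data_fingerprint(table),
        "rank_sizes": rank_sizes,
        "n_subsets": len(results),
        "warnings": warnings,
        "elapsed_s": round(time.time() - t0, 2),
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    outputs["manifest"] = str(path)
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out)
    return outputs
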