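"""End-to-end orchestration of the profiling pipeline, in memory.

simulate -> bin -> median-normalize -> per-batch PCA -> top-20 PC1
factors -> cross-batch intersection -> exact-mass annotation ->
relative XIC quantification.  The CLI wraps this with file output; tests
and reproduction scripts call it directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotate import AnnotationConfig, AnnotationRecord, annotate_factors, report_frame
from .binning import BinGrid, FeatureMatrix, bin_run, build_matrix
from .profile import (
    Factor,
    FactorPair,
    PcaResult,
    common_factors,
    median_scale_factors,
    run_pca,
    top_loadings,
)
from .quantify import QuantSeries, QuantWindow, quant_frame, relative_series
from .simulate import NoiseModel, Run, Scenario, default_scenario, ground_truth_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable for the manifest."""

    seed: int = 0
    n_decoys: int = 50
    scenario_seed: int = 101
    baseline_density: float = 60.0
    baseline_scale: float = 1000.0
    intensity_cv: float = 0.05
    mz_jitter_ppm: float = 1.0
    scan_width: int = 50
    mz_width: float = 1.0
    components: int = 2
    top_k: int = 20
    merge_adjacent: bool = True
    formula_tol_ppm: float = 10.0
    peptide_tol_ppm: float = 5.0
    xic_half_width: float = 0.01
    rt_halfspan: float = 1.5

    def noise(self) -> NoiseModel:
        return NoiseModel(
            baseline_density=self.baseline_density,
            baseline_scale=self.baseline_scale,
            intensity_cv=self.intensity_cv,
            mz_jitter_ppm=self.mz_jitter_ppm,
            seed=self.seed,
        )

    def grid(self) -> BinGrid:
        return BinGrid(scan_width=self.scan_width, mz_width=self.mz_width)

    def annotation(self) -> AnnotationConfig:
        from .search import SearchConfig

        return AnnotationConfig(
            formula_cfg=SearchConfig(tolerance_ppm=self.formula_tol_ppm),
            peptide_cfg=SearchConfig(tolerance_ppm=self.peptide_tol_ppm),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    scenario: Scenario
    runs: list[Run]
    matrix: FeatureMatrix
    normalized: FeatureMatrix
    pca: Mapping[str, PcaResult]
    factors: Mapping[str, list[Factor]]
    pairs: list[FactorPair]
    records: list[AnnotationRecord]
    series: list[QuantSeries]

    def annotation_report(self) -> pd.DataFrame:
        return report_frame(self.records)

    def quant_report(self) -> pd.DataFrame:
        return quant_frame(self.series)

    def truth(self) -> pd.DataFrame:
        return ground_truth_table(self.scenario)


def _batch_view(matrix: FeatureMatrix, batch: str) -> FeatureMatrix:
    cols = matrix.meta.index[matrix.meta["batch"] == batch]
    return FeatureMatrix(matrix.values[list(cols)], matrix.meta.loc[cols], matrix.grid)


def run_pipeline(
    config: PipelineConfig | None = None, scenario: Scenario | None = None
) -> PipelineResult:
    """Execute the whole profiling pipeline on the (default) scenario."""
    config = config or PipelineConfig()
    scenario = scenario or default_scenario(config.n_decoys, config.scenario_seed)
    runs = scenario.runs(config.noise())
    grid = config.grid()
    matrix = build_matrix([bin_run(r, grid) for r in runs])
    scale = median_scale_factors(matrix)
    normalized = FeatureMatrix(matrix.values * scale, matrix.meta.copy(), grid)

    pca: dict[str, PcaResult] = {}
    factors: dict[str, list[Factor]] = {}
    for batch in scenario.batches:
        view = _batch_view(normalized, batch)
        pca[batch] = run_pca(view, components=config.components)
        factors[batch] = top_loadings(pca[batch], 0, config.top_k, batch=batch)

    batches = scenario.batches
    pairs = common_factors(
        factors[batches[0]], factors[batches[1]], merge_adjacent=config.merge_adjacent
    )

    # annotate on the final-day run of the first batch, where the rising
    # compounds are at full strength
    last_day = max(scenario.day_grid[batches[0]])
    anno_run = next(
        r for r in runs if r.batch == batches[0] and r.day == last_day and r.replicate == 1
    )
    records = annotate_factors([p.factor_a for p in pairs], anno_run, config.annotation())

    windows: dict[str, QuantWindow] = {}
    for rec in records:
        if rec.error is not None or rec.background is not None or rec.isotope_shift:
            continue
        windows[rec.factor.feature_id] = QuantWindow.around(
            rec.apex.mz,
            rec.apex.rt,
            rt_halfspan=config.rt_halfspan,
            mz_half_width=config.xic_half_width,
        )
    series = relative_series(runs, windows, scale=scale.to_dict()) if windows else []

    return PipelineResult(
        config=config,
        scenario=scenario,
        runs=runs,
        matrix=matrix,
        normalized=normalized,
        pca=pca,
        factors=factors,
        pairs=pairs,
        records=records,
        series=series,
    )
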