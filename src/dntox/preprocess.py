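"""Five-step noise correction for reporter-plate time series.

Raw GFP fluorescence from a live-cell array mixes promoter activity with
cell density, plate autofluorescence and instrument noise.  The pipeline
applies, in order:

1. OD normalization — divide each well's series by its pre-treatment
   optical density, converting fluorescence to per-cell promoter activity.
2. Temporal smoothing — centered three-point moving average; the window
   shrinks at the endpoints so the series keeps its length.
3. Background subtraction — the promoterless wells (reporter plasmid with
   no promoter) measure cellular autofluorescence; their values are pooled
   over wells and treatments into one mean per time point and subtracted
   from every other well.
4. Baseline alignment — per gene, the four treatments' first-time-point
   values are replaced by their common mean and each treatment's series is
   shifted by its offset, removing well-to-well starting-level differences.
5. Noise floor — any value below twice the pooled standard deviation of
   the processed promoterless values is set to zero.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError, ValidationError
from .io import LcaExperiment, WellRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "NoiseModel",
    "PreprocessResult",
    "normalize_by_od",
    "smooth_moving_average",
    "subtract_promoterless_background",
    "align_baseline",
    "apply_noise_floor",
    "preprocess_pipeline",
]


@dataclass
class ExpressionMatrix:
    """Preprocessed genes x time-points values for one treatment."""

    genes: list[str]
    times: np.ndarray
    values: np.ndarray          # (N, T)
    treatment: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != (len(self.genes), len(self.times)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.times)} times"
            )
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.times)

    def series(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


@dataclass
class NoiseModel:
    """Pooled promoterless background: per-time mean and a single sd."""

    promoterless_mean: np.ndarray     # (T,) pooled over wells and treatments
    promoterless_sd: float            # pooled over all processed values

    def __post_init__(self) -> None:
        if self.promoterless_sd < 0:
            raise ValidationError("promoterless_sd must be nonnegative")


@dataclass
class PreprocessResult:
    """Pipeline output: per-treatment gene matrices plus well-level views.

    ``gene_matrices`` average replicate promoter wells per gene and feed
    network reconstruction and the fold-change screen.  ``well_matrices``
    keep individual promoter wells (ids paired with their gene) for
    well-level activity scoring; ``empty_matrices`` carry the cell-free
    wells through the identical steps so they can serve as score cutoffs.
    """

    gene_matrices: dict[str, ExpressionMatrix]
    well_matrices: dict[str, ExpressionMatrix]      # rows are well ids
    well_genes: dict[str, str]                      # well id -> gene
    empty_matrices: dict[str, ExpressionMatrix]     # rows are empty-well ids
    noise: NoiseModel
    treatments: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def normalize_by_od(experiment: LcaExperiment) -> LcaExperiment:
    """Divide every non-empty well's series by its pre-treatment OD."""
    out = copy.deepcopy(experiment)
    for well in out.wells:
        if well.role == "empty":
            continue
        if well.od is None or not well.od > 0:
            raise ValidationError(f"well {well.well_id}: OD must be positive, got {well.od}")
        for label in well.series:
            well.series[label] = well.series[label] / well.od
    return out


def smooth_moving_average(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with a shrinking window at the endpoints.

    The window must be odd and no longer than the series; output length
    equals input length so downstream time indexing is unchanged.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd, got {window}")
    if window > series.size:
        raise ParameterError(f"window {window} exceeds series length {series.size}")
    return (
        pd.Series(series)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _smooth_experiment(experiment: LcaExperiment, window: int) -> LcaExperiment:
    out = copy.deepcopy(experiment)
    for well in out.wells:
        for label in well.series:
            well.series[label] = smooth_moving_average(well.series[label], window)
    return out


def subtract_promoterless_background(
    experiment: LcaExperiment,
) -> tuple[LcaExperiment, NoiseModel]:
    """Subtract the pooled promoterless mean (one value per time point,
    pooled across promoterless wells and all treatments) from every
    promoter and empty well; record the pooled sd of the processed
    promoterless values."""
    promoterless = [w for w in experiment.wells if w.role == "promoterless"]
    if not promoterless:
        raise ConfigurationError("experiment has no promoterless well")
    stacked = np.vstack([
        w.series[label] for w in promoterless for label in experiment.treatment_labels()
    ])
    mean = stacked.mean(axis=0)
    sd = float(stacked.std(ddof=1)) if stacked.size > 1 else 0.0
    out = copy.deepcopy(experiment)
    for well in out.wells:
        if well.role == "promoterless":
            continue
        for label in well.series:
            well.series[label] = well.series[label] - mean
    return out, NoiseModel(promoterless_mean=mean, promoterless_sd=sd)


def align_baseline(per_treatment: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Align one gene's series across treatments at the first time point.

    Let ``m`` be the mean of the first-time-point values over treatments;
    each treatment's whole series is shifted by ``-(value_at_t1 - m)`` so
    that after alignment all treatments share the value ``m`` at t1.
    """
    t1 = np.array([v[0] for v in per_treatment.values()])
    m = t1.mean()
    return {
        label: np.asarray(v, dtype=float) - (v[0] - m)
        for label, v in per_treatment.items()
    }


def apply_noise_floor(matrix: ExpressionMatrix, noise: NoiseModel,
                      multiplier: float = 2.0) -> ExpressionMatrix:
    """Zero every value below ``multiplier * promoterless_sd``.

    The comparison is on the signed value and strict, so ties at the
    threshold are kept; the operation is idempotent.
    """
    threshold = multiplier * noise.promoterless_sd
    values = matrix.values.copy()
    values[values < threshold] = 0.0
    return ExpressionMatrix(
        genes=list(matrix.genes), times=matrix.times.copy(), values=values,
        treatment=matrix.treatment,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _wells_to_matrices(experiment: LcaExperiment, wells: list[WellRecord]) -> dict[str, ExpressionMatrix]:
    labels = experiment.treatment_labels()
    out = {}
    for label in labels:
        values = np.vstack([w.series[label] for w in wells]) if wells else np.empty((0, len(experiment.time_points)))
        out[label] = ExpressionMatrix(
            genes=[w.well_id for w in wells],
            times=experiment.time_points,
            values=values,
            treatment=label,
        )
    return out


def _align_matrices(matrices: dict[str, ExpressionMatrix]) -> dict[str, ExpressionMatrix]:
    labels = list(matrices)
    if not labels:
        return matrices
    rows = matrices[labels[0]].genes
    aligned = {label: matrices[label].values.copy() for label in labels}
    for i, _row in enumerate(rows):
        per_treat = {label: matrices[label].values[i] for label in labels}
        adj = align_baseline(per_treat)
        for label in labels:
            aligned[label][i] = adj[label]
    return {
        label: ExpressionMatrix(
            genes=list(rows), times=matrices[label].times.copy(),
            values=aligned[label], treatment=label,
        )
        for label in labels
    }


def preprocess_pipeline(
    experiment: LcaExperiment,
    window: int = 3,
    floor_multiplier: float = 2.0,
) -> PreprocessResult:
    """Run the full correction pipeline.

    Order is fixed: OD-normalize, smooth, background-subtract,
    baseline-align, noise-floor.  Promoterless wells are OD-normalized and
    smoothed before their pooled mean and sd are taken, so the noise model
    refers to the same scale as the corrected gene values.
    """
    promoter = [w for w in experiment.wells if w.role == "promoter"]
    if not promoter:
        raise ConfigurationError("experiment has no promoter wells")

    exp = normalize_by_od(experiment)
    exp = _smooth_experiment(exp, window)
    exp, noise = subtract_promoterless_background(exp)

    promoter = [w for w in exp.wells if w.role == "promoter"]
    empty = [w for w in exp.wells if w.role == "empty"]

    well_matrices = _align_matrices(_wells_to_matrices(exp, promoter))
    empty_matrices = _align_matrices(_wells_to_matrices(exp, empty))

    # replicate promoter wells are averaged per gene after alignment
    genes = sorted({w.gene for w in promoter})
    gene_matrices = {}
    for label, wm in well_matrices.items():
        rows = np.vstack([
            wm.values[[i for i, w in enumerate(promoter) if w.gene == g]].mean(axis=0)
            for g in genes
        ])
        gene_matrices[label] = ExpressionMatrix(
            genes=genes, times=wm.times.copy(), values=rows, treatment=label,
        )

    gene_matrices = {
        label: apply_noise_floor(m, noise, floor_multiplier)
        for label, m in gene_matrices.items()
    }
    well_matrices = {
        label: apply_noise_floor(m, noise, floor_multiplier)
        for label, m in well_matrices.items()
    }
    empty_matrices = {
        label: apply_noise_floor(m, noise, floor_multiplier)
        for label, m in empty_matrices.items()
    }

    return PreprocessResult(
        gene_matrices=gene_matrices,
        well_matrices=well_matrices,
        well_genes={w.well_id: w.gene for w in promoter},
        empty_matrices=empty_matrices,
        noise=noise,
        treatments=experiment.treatment_labels(),
    )
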