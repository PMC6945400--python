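"""Spike-in dose-response calibration and the expression-detection filter.

Spike-in standards of known concentration serve two purposes here:

1. a log-log dose-response fit (observed count vs nominal concentration)
   that validates quantification fidelity, and
2. an empirical estimate of the count level above which species are
   reliably observed in every library — the expression detection threshold.

The pipeline default threshold is a count of 5: genes are "analyzable" in a
pairwise comparison when their raw count exceeds the threshold in at least
half of the six libraries involved.  The filter is comparison-scoped: a
gene may be analyzable in one contrast and not another.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateFitError,
    DesignError,
    InsufficientDataError,
    ParameterError,
)
from .synthetic_data import CountMatrix, SpikeInReference

logger = logging.getLogger(__name__)

DEFAULT_DETECTION_THRESHOLD = 5.0
MIN_SPIKE_SPECIES = 8


@dataclass(frozen=True)
class DoseResponseFit:
    """OLS fit of log2(mean count + 0.5) on log2(nominal concentration)."""

    slope: float
    intercept: float
    r_squared: float
    detection_threshold: float
    per_species_table: pd.DataFrame  # spike_id, mix, nominal_conc, mean_observed_count, detected

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")
        if self.detection_threshold <= 0:
            raise ValueError("detection_threshold must be > 0")


@dataclass(frozen=True)
class DetectionFilterResult:
    """Genes passing the detection rule for one pairwise comparison."""

    comparison_id: str
    analyzable_genes: frozenset[str]
    n_libraries: int
    min_detected_libraries: int
    threshold: float

    def __post_init__(self) -> None:
        if self.min_detected_libraries != math.ceil(self.n_libraries / 2):
            raise ValueError("min_detected_libraries must be ceil(n/2)")


def _spike_observations(
    matrix: CountMatrix, spikes: SpikeInReference
) -> pd.DataFrame:
    """Per (species, mix) nominal concentration and mean observed count.

    Each library contributes to the mix it received; a species appears once
    per mix present in the design.
    """
    spike_counts = matrix.spikes()
    rows = []
    design_df = matrix.design.to_frame()
    for mix, group in design_df.groupby("spike_mix"):
        libs = group["library_id"].tolist()
        conc = spikes.concentrations(mix)
        shared = [s for s in spikes.spike_ids if s in spike_counts.index]
        mean_counts = spike_counts.loc[shared, libs].mean(axis=1)
        for sid in shared:
            rows.append(
                {
                    "spike_id": sid,
                    "mix": mix,
                    "nominal_conc": float(conc[sid]),
                    "mean_observed_count": float(mean_counts[sid]),
                }
            )
    return pd.DataFrame(rows)


def fit_dose_response(
    matrix: CountMatrix,
    spikes: SpikeInReference,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> DoseResponseFit:
    """Fit the spike-in dose-response line.

    Ordinary least squares of log2(mean observed count + 0.5) on
    log2(nominal concentration), pooling (species, mix) observations across
    the design.  The half-count offset admits zero counts.  A species-mix
    pair is flagged ``detected`` when its mean observed count exceeds
    ``detection_threshold``.
    """
    table = _spike_observations(matrix, spikes)
    if table["spike_id"].nunique() < MIN_SPIKE_SPECIES:
        raise InsufficientDataError(
            f"need >= {MIN_SPIKE_SPECIES} spike species with nominal "
            f"concentrations, found {table['spike_id'].nunique()}"
        )
    x = np.log2(table["nominal_conc"].to_numpy())
    y = np.log2(table["mean_observed_count"].to_numpy() + 0.5)
    if np.ptp(x) == 0:
        raise DegenerateFitError("all nominal concentrations equal; no predictor variance")
    if (table["mean_observed_count"] == 0).all():
        raise DegenerateFitError("all spike counts are zero")
    res = stats.linregress(x, y)
    table = table.assign(detected=table["mean_observed_count"] > detection_threshold)
    return DoseResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        detection_threshold=float(detection_threshold),
        per_species_table=table,
    )


def estimate_detection_threshold(
    matrix: CountMatrix,
    spikes: SpikeInReference,
    target_detect_prob: float = 0.95,
    default: float = DEFAULT_DETECTION_THRESHOLD,
    max_scan: int = 100,
) -> float:
    """Estimate the count detection threshold from spike-in behaviour.

    Scans integer candidate thresholds c = 1..``max_scan`` and returns the
    smallest c for which, among spike species whose mean count is >= c, the
    fraction observed (count > 0) in *every* library reaches
    ``target_detect_prob``.  Falls back to ``default`` (with a logged
    warning) when the spike data are insufficient or the detected-fraction
    scan is not monotone non-decreasing.
    """
    if not (0.0 < target_detect_prob < 1.0):
        raise ParameterError("target_detect_prob must be in (0, 1)")
    spike_counts = matrix.spikes()
    if spike_counts.shape[0] < MIN_SPIKE_SPECIES:
        logger.warning(
            "insufficient spike species (%d) for threshold estimation; "
            "using default %g",
            spike_counts.shape[0],
            default,
        )
        return float(default)
    conc_span = _spike_observations(matrix, spikes)["nominal_conc"]
    if conc_span.max() / conc_span.min() < 100:
        logger.warning(
            "spike concentrations span < 2 orders of magnitude; using default %g",
            default,
        )
        return float(default)

    mean_counts = spike_counts.mean(axis=1).to_numpy()
    always_observed = (spike_counts.to_numpy() > 0).all(axis=1)

    fractions: list[float] = []
    candidates: list[int] = []
    for c in range(1, max_scan + 1):
        sel = mean_counts >= c
        if not sel.any():
            break
        candidates.append(c)
        fractions.append(float(always_observed[sel].mean()))
    if not candidates:
        logger.warning("no spike species reach any scan level; using default %g", default)
        return float(default)
    if any(b < a - 1e-12 for a, b in zip(fractions, fractions[1:])):
        logger.warning(
            "detected-fraction scan is non-monotone; using default %g", default
        )
        return float(default)
    for c, f in zip(candidates, fractions):
        if f >= target_detect_prob:
            return float(c)
    logger.warning(
        "no scan level reaches detect probability %g; using default %g",
        target_detect_prob,
        default,
    )
    return float(default)


def detection_filter(
    matrix: CountMatrix,
    comparison_libraries: list[str],
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    comparison_id: str = "",
    expected_libraries: int | None = 6,
) -> DetectionFilterResult:
    """Apply the per-comparison expression detection filter.

    A gene is retained when its raw count strictly exceeds ``threshold`` in
    at least half (ceil(n/2)) of the comparison's libraries.  The canonical
    design compares 6 libraries (3 vs 3); pass ``expected_libraries=None``
    to permit other sizes.  Spike rows are never retained.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    missing = [l for l in comparison_libraries if l not in matrix.counts.columns]
    if missing:
        raise LookupError(f"libraries not in matrix: {missing}")
    n = len(comparison_libraries)
    if expected_libraries is not None and n != expected_libraries:
        raise DesignError(
            f"comparison uses {n} libraries; expected {expected_libraries} "
            "(pass expected_libraries=None to override)"
        )
    need = math.ceil(n / 2)
    endo = matrix.endogenous()[comparison_libraries]
    n_detected = (endo > threshold).sum(axis=1)
    kept = frozenset(endo.index[n_detected >= need])
    return DetectionFilterResult(
        comparison_id=comparison_id,
        analyzable_genes=kept,
        n_libraries=n,
        min_detected_libraries=need,
        threshold=float(threshold),
    )
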