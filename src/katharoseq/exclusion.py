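"""Read-count sample exclusion and contamination reporting.

Two strategies derive a per-study read-count threshold from the positive
controls:

``fit_half_max``
    Invert the reads-vs-composition Hill fit at 50% target composition —
    the read count below which a sample's reads are expected to be mostly
    contaminant.  Equals the fit's half-saturation constant when Ymax = 1.

``max_input_median``
    The median read depth of the positive controls at the highest
    titration level; the conservative default.

Both thresholds are per-study/per-run quantities: sequencing depth and
well-to-well contamination vary between runs, so a threshold from one
experiment must not be reused on another.  Exclusion is boundary
inclusive — a sample with at least the threshold's reads is retained —
and never renormalizes the retained counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .composition import CompositionPoint, composition_points
from .data_model import (
    NEGATIVE_CLASSES,
    FeatureTable,
    StudyDesign,
    TargetSpec,
)
from .errors import (
    ComputationError,
    MissingControlsError,
    UnreachableHalfMaxError,
    ValidationError,
)
from .hill import HillFit, invert_hill

STRATEGIES = ("fit_half_max", "max_input_median", "fixed")

#: Control design the method needs to derive thresholds reliably.
RECOMMENDED_DESIGN = (
    "at least 24 total positive and 12 negative DNA extraction controls "
    "per project (with at least 8 and 4 per 96-well plate)"
)


@dataclass(frozen=True)
class ExclusionDecision:
    """One sample's read depth, the applied threshold, and the verdict."""

    sample_id: str
    depth: int
    threshold: float
    retained: bool
    strategy: str

    def __post_init__(self) -> None:
        if self.retained != (self.depth >= self.threshold):
            raise ValidationError(
                f"{self.sample_id!r}: retained flag inconsistent with depth/threshold"
            )


def threshold_fit_half_max(reads_fit: HillFit) -> int:
    """Read threshold where 50% of reads are expected to be the target.

    Requires a converged reads-vs-composition fit whose plateau exceeds
    0.5; the inverted read count is rounded up to an integer.
    """
    if not reads_fit.converged:
        raise ComputationError("reads-vs-composition fit did not converge")
    if reads_fit.ymax <= 0.5:
        raise UnreachableHalfMaxError(
            f"fitted plateau Ymax={reads_fit.ymax:.3f} never reaches 50% target "
            "composition; use the max_input_median strategy instead"
        )
    return int(math.ceil(invert_hill(reads_fit, 0.5)))


def threshold_max_input_median(points: Sequence[CompositionPoint]) -> int:
    """Median read depth of positive controls at the highest titration level.

    For an even number of controls the lower of the two central depths is
    taken, so the median is always an observed integer depth and the rule
    never excludes a sample that outperformed half of the top controls.
    """
    with_cells = [p for p in points if p.input_cells is not None]
    if not with_cells:
        raise MissingControlsError(
            "no positive controls with known input_cells; the method needs "
            + RECOMMENDED_DESIGN
        )
    top = max(p.input_cells for p in with_cells)
    depths = sorted(p.depth for p in with_cells if p.input_cells == top)
    return int(depths[(len(depths) - 1) // 2])


def apply_exclusion(
    table: FeatureTable,
    design: StudyDesign,
    threshold: float,
    strategy: str = "fixed",
) -> Tuple[List[ExclusionDecision], FeatureTable]:
    """Decide retention for every sample and filter the table.

    Every sample in the table receives exactly one decision; the filtered
    table contains exactly the retained samples with untouched counts.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}")
    depths = table.depths()
    decisions = [
        ExclusionDecision(
            sample_id=sid,
            depth=int(depths[sid]),
            threshold=float(threshold),
            retained=bool(depths[sid] >= threshold),
            strategy=strategy,
        )
        for sid in table.sample_ids
    ]
    retained_ids = [d.sample_id for d in decisions if d.retained]
    return decisions, table.select_samples(retained_ids)


def success_rate(
    decisions: Iterable[ExclusionDecision], subset: Iterable[str]
) -> float:
    """Fraction of the subset's samples retained by the exclusion rule."""
    subset = set(subset)
    if not subset:
        raise ValidationError("empty subset")
    chosen = [d for d in decisions if d.sample_id in subset]
    if not chosen:
        raise ValidationError("subset matches no decisions")
    return sum(d.retained for d in chosen) / len(chosen)


def gel_comparison(
    band_flags: Mapping[str, bool], decisions: Iterable[ExclusionDecision]
) -> float:
    """False-negativity rate of gel-band QC against read-count retention.

    The rate is the fraction of read-retained libraries that showed no
    visible band — libraries a gel-based QC would wrongly have discarded.
    """
    decisions = list(decisions)
    missing = [d.sample_id for d in decisions if d.sample_id not in band_flags]
    if missing:
        raise ValidationError(f"band flags missing for {missing[:5]}")
    retained = [d for d in decisions if d.retained]
    if not retained:
        raise ComputationError("no read-retained libraries; rate undefined")
    no_band = sum(1 for d in retained if not band_flags[d.sample_id])
    return no_band / len(retained)


@dataclass
class ContaminationReport:
    """Background load and cross-well leakage of the control organism.

    ``background_cells`` is the half-saturation constant of the
    cells-vs-composition fit: the contamination load of the pipeline in
    cell equivalents.  The summaries describe the target organism's
    composition in negatives (expected: reagent/background level) and in
    true samples (expected: none, barring well-to-well leakage); samples
    above the stated quantile of the negatives' distribution are flagged.
    """

    background_cells: float
    quantile: float
    target_in_negatives: Optional[Dict[str, float]] = None
    target_in_samples: Optional[Dict[str, float]] = None
    flagged_samples: List[str] = field(default_factory=list)
    zero_depth_samples: List[str] = field(default_factory=list)


def _summary(fractions: np.ndarray) -> Dict[str, float]:
    return {
        "n": int(len(fractions)),
        "median": float(np.median(fractions)),
        "mean": float(np.mean(fractions)),
        "max": float(np.max(fractions)),
        "q95": float(np.quantile(fractions, 0.95)),
    }


def contamination_report(
    table: FeatureTable,
    design: StudyDesign,
    target_spec: TargetSpec,
    cells_fit: HillFit,
    quantile: float = 0.95,
) -> ContaminationReport:
    """Summarize control-organism leakage across negatives and samples."""
    if cells_fit.x_variable != "cells":
        raise ValidationError("contamination_report needs a cells-vs-composition fit")
    neg_points, neg_zero = composition_points(
        table, design, NEGATIVE_CLASSES, target_spec=target_spec
    )
    sample_points, sample_zero = composition_points(
        table, design, {"sample"}, target_spec=target_spec
    )
    report = ContaminationReport(
        background_cells=cells_fit.k_half,
        quantile=quantile,
        zero_depth_samples=neg_zero + sample_zero,
    )
    neg_fracs = np.array([p.target_fraction for p in neg_points])
    if len(neg_fracs):
        report.target_in_negatives = _summary(neg_fracs)
    if sample_points:
        fracs = np.array([p.target_fraction for p in sample_points])
        report.target_in_samples = _summary(fracs)
        if len(neg_fracs):
            cutoff = float(np.quantile(neg_fracs, quantile))
            report.flagged_samples = [
                p.sample_id for p in sample_points if p.target_fraction > cutoff
            ]
    return report


class ReadCountFilter(BaseEstimator):
    """Estimator that learns a read-count threshold and filters samples.

    Follows the scikit-learn fit/transform idiom over the package's domain
    containers: ``fit(table, design)`` derives ``threshold_`` from the
    extraction positive controls with the configured strategy, and
    ``transform(table)`` returns the filtered table, recording per-sample
    verdicts in ``decisions_``.

    Parameters
    ----------
    strategy : {"max_input_median", "fit_half_max", "fixed"}
        ``fixed`` requires ``threshold``; the others derive it from controls.
    threshold : float, optional
        The fixed threshold (``strategy="fixed"`` only).
    target_spec : lineage substring or feature-id set, optional
        Expected organism of the positive controls; defaults to each
        control's own metadata annotation.  Needed by ``fit_half_max``.
    ymax_mode : {"free", "fixed_1"}
        Plateau handling for the internal reads-vs-composition fit.
    """

    def __init__(
        self,
        strategy: str = "max_input_median",
        threshold: Optional[float] = None,
        target_spec: Optional[TargetSpec] = None,
        ymax_mode: str = "free",
    ):
        self.strategy = strategy
        self.threshold = threshold
        self.target_spec = target_spec
        self.ymax_mode = ymax_mode

    def fit(self, table: FeatureTable, design: Optional[StudyDesign] = None):
        from .hill import fit_hill

        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.strategy == "fixed":
            if self.threshold is None or self.threshold <= 0:
                raise ValidationError("strategy 'fixed' needs a positive threshold")
            self.threshold_ = float(self.threshold)
            self.reads_fit_ = None
            return self
        if design is None:
            raise ValidationError("control-derived strategies need a StudyDesign")
        points, _ = composition_points(
            table, design, {"extraction_positive"}, target_spec=self.target_spec
        )
        if not points:
            raise MissingControlsError(
                f"strategy {self.strategy!r} needs extraction positive controls; "
                "none usable. The method needs " + RECOMMENDED_DESIGN
            )
        if self.strategy == "max_input_median":
            self.threshold_ = float(threshold_max_input_median(points))
            self.reads_fit_ = None
        else:
            reads_fit = fit_hill(
                [(p.depth, p.target_fraction) for p in points],
                ymax_mode=self.ymax_mode,
                x_variable="reads",
            )
            self.reads_fit_ = reads_fit
            self.threshold_ = float(threshold_fit_half_max(reads_fit))
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        check_is_fitted(self, "threshold_")
        decisions, filtered = apply_exclusion(
            table, StudyDesign(records={}), self.threshold_, strategy=self.strategy
        )
        self.decisions_ = decisions
        return filtered

    def fit_transform(
        self, table: FeatureTable, design: Optional[StudyDesign] = None
    ) -> FeatureTable:
        return self.fit(table, design).transform(table)
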