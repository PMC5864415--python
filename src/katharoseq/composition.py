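"""Per-sample read depth and target composition.

The read depth of a sample is the sum of all feature counts in its column;
the target fraction is the share of those reads assigned to features that
match the expected control organism.  Both are computed on raw integer
counts — the single division happens last, so target and non-target
fractions always sum to exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Tuple

from .data_model import FeatureTable, StudyDesign, TargetSpec
from .errors import (
    MissingTaxonomyError,
    UndefinedCompositionError,
    UnknownSampleError,
)


@dataclass(frozen=True)
class CompositionPoint:
    """Depth and target fraction of one sample, with its known cell input."""

    sample_id: str
    depth: int
    target_fraction: float
    input_cells: Optional[float] = None

    def metric(self, name: str) -> float:
        if name == "target_fraction":
            return self.target_fraction
        if name == "depth":
            return float(self.depth)
        raise ValueError(f"unknown metric {name!r}")


def sample_depth(table: FeatureTable, sample_id: str) -> int:
    """Total reads of one sample: the sum of its feature counts."""
    return int(table.sample_counts(sample_id).sum())


def match_target_features(table: FeatureTable, target_spec: TargetSpec) -> FrozenSet[str]:
    """Resolve a target specification to a set of feature ids.

    An explicit feature-id set is validated and returned verbatim; a string
    is treated as a lineage substring matched case-insensitively against
    the table's taxonomy annotations.
    """
    if isinstance(target_spec, (set, frozenset)):
        spec = frozenset(str(f) for f in target_spec)
        missing = spec - set(table.feature_ids)
        if missing:
            raise UnknownSampleError(
                f"target feature ids not in table: {sorted(missing)[:5]}"
            )
        return spec
    if not isinstance(target_spec, str):
        raise TypeError(
            f"target_spec must be a lineage substring or a feature-id set, "
            f"got {type(target_spec).__name__}"
        )
    if table.taxonomy is None:
        raise MissingTaxonomyError(
            "lineage-substring target given but the table has no taxonomy column"
        )
    needle = target_spec.lower()
    return frozenset(
        fid
        for fid in table.feature_ids
        if fid in table.taxonomy and needle in table.taxonomy[fid].lower()
    )


def target_fraction(
    table: FeatureTable, sample_id: str, target_spec: TargetSpec
) -> float:
    """Fraction of a sample's reads assigned to the target features.

    Raises :class:`UndefinedCompositionError` for zero-depth samples:
    a composition is not defined where there are no reads, and silently
    returning 0 would masquerade as "no target detected".
    """
    column = table.sample_counts(sample_id)
    depth = int(column.sum())
    if depth == 0:
        raise UndefinedCompositionError(
            f"sample {sample_id!r} has zero reads; composition undefined"
        )
    matched = match_target_features(table, target_spec)
    target_reads = int(
        sum(column[i] for i, fid in enumerate(table.feature_ids) if fid in matched)
    )
    return target_reads / depth


def composition_points(
    table: FeatureTable,
    design: StudyDesign,
    classes: Iterable[str],
    target_spec: Optional[TargetSpec] = None,
) -> Tuple[List[CompositionPoint], List[str]]:
    """Assemble composition points for the samples of the given classes.

    Returns ``(points, zero_depth_ids)``: one point per selected sample with
    positive depth, and the ids of selected samples with zero depth (these
    are reported, never silently dropped).  The target specification
    defaults to each record's own ``target_spec``.
    """
    classes = set(classes)
    points: List[CompositionPoint] = []
    zero_depth: List[str] = []
    for sid in table.sample_ids:
        rec = design.records.get(sid)
        if rec is None or rec.control_class not in classes:
            continue
        depth = sample_depth(table, sid)
        if depth == 0:
            zero_depth.append(sid)
            continue
        spec = target_spec if target_spec is not None else rec.target_spec
        frac = target_fraction(table, sid, spec) if spec is not None else 0.0
        points.append(
            CompositionPoint(
                sample_id=sid,
                depth=depth,
                target_fraction=frac,
                input_cells=rec.input_cells,
            )
        )
    return points, zero_depth
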