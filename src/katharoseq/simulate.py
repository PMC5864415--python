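"""Synthetic low-biomass titration experiments.

Emulates the count-level outcome of a control titration: positive wells
receive known cell inputs (default 5, 50, 500 and 5,000 cells of a single
target organism), negatives receive none, and every well additionally
carries a reagent/background contaminant community.  Two couplings drive
the generated data:

* **Composition.**  The fraction of a control's reads that map to the
  target follows the Hill curve ``ymax * c^h / (k^h + c^h)`` of the cell
  input ``c`` (defaults ``k = 96.88`` cells, ``h = 1.377``, ``ymax = 1``);
  target reads are Binomial(depth, fraction) draws, the remainder is
  spread over background taxa by a Dirichlet-multinomial.

* **Depth.**  Read depth grows monotonically with input biomass: the mean
  is ``D_neg + (D_max - D_neg) * hill(c; k_depth, h_depth) / hill(c_max)``
  with multiplicative log-normal noise ``exp(N(0, sigma))``.  Blank wells
  still produce ``D_neg`` reads on average — DNA-free wells amplify
  reagent contaminants, they do not come back empty.

True samples (class ``sample``) carry their own community of environment
taxa; the share of their reads that is genuine signal rather than
background follows the same Hill curve of their (latent, log-uniform)
biomass, and ``leakage_rate`` injects target-organism reads into
non-positive wells to mimic well-to-well contamination.

Everything is driven by one ``numpy`` Generator, so a fixed seed yields a
bit-identical experiment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

import numpy as np

from .data_model import FeatureTable, SampleRecord, StudyDesign
from .errors import ValidationError
from .hill import hill_curve

TARGET_FEATURE_ID = "target_0001"
TARGET_LINEAGE = (
    "k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;"
    "f__Bacillaceae;g__Bacillus;s__subtilis"
)
TARGET_SPEC = "g__Bacillus"

_BACKGROUND_GENERA = (
    "Acinetobacter",
    "Ralstonia",
    "Pseudomonas",
    "Sphingomonas",
    "Methylobacterium",
    "Bradyrhizobium",
    "Propionibacterium",
    "Corynebacterium",
)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of a synthetic titration experiment.

    Defaults mirror a single-organism control titration: four levels of 5
    to 5,000 cells, 18 replicates per level, 24 extraction negatives, a
    background half-saturation of 96.88 cell equivalents and a median top-
    level depth of 2,000 reads.
    """

    titration_levels: Tuple[float, ...] = (5.0, 50.0, 500.0, 5000.0)
    replicates_per_level: int = 18
    n_negatives: int = 24
    n_samples: int = 50
    true_k_half: float = 96.88
    true_h: float = 1.377
    true_ymax: float = 1.0
    depth_max_median: float = 2000.0
    depth_sigma: float = 0.5
    depth_k_half: Optional[float] = None  # defaults to true_k_half
    depth_h: float = 1.0
    negative_depth: float = 150.0
    background_taxa: int = 40
    background_concentration: float = 0.5
    community_taxa: int = 30
    sample_biomass_range: Tuple[float, float] = (5.0, 5000.0)
    leakage_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.titration_levels or any(c <= 0 for c in self.titration_levels):
            raise ValidationError("titration_levels must be positive")
        if len(set(self.titration_levels)) != len(self.titration_levels):
            raise ValidationError("titration_levels must be distinct")
        if self.replicates_per_level < 1 or self.n_negatives < 0 or self.n_samples < 0:
            raise ValidationError("counts must be non-negative (replicates >= 1)")
        if not (0 <= self.leakage_rate < 1):
            raise ValidationError("leakage_rate must lie in [0, 1)")
        if min(self.true_k_half, self.true_h, self.depth_max_median) <= 0:
            raise ValidationError("model parameters must be positive")
        if not (0 < self.true_ymax <= 1):
            raise ValidationError("true_ymax must lie in (0, 1]")
        if self.background_taxa < 1 or self.community_taxa < 1:
            raise ValidationError("need at least one background and community taxon")
        lo, hi = self.sample_biomass_range
        if not (0 < lo <= hi):
            raise ValidationError("sample_biomass_range must be positive and ordered")


def _taxonomy(params: SimulationParams) -> Tuple[Tuple[str, ...], dict]:
    background = tuple(f"bg_{i:04d}" for i in range(params.background_taxa))
    community = tuple(f"env_{i:04d}" for i in range(params.community_taxa))
    taxonomy = {TARGET_FEATURE_ID: TARGET_LINEAGE}
    for i, fid in enumerate(background):
        genus = _BACKGROUND_GENERA[i % len(_BACKGROUND_GENERA)]
        taxonomy[fid] = (
            f"k__Bacteria;p__Proteobacteria;c__;o__;f__;g__{genus};s__strain{i}"
        )
    for i, fid in enumerate(community):
        taxonomy[fid] = f"k__Bacteria;p__Environmental;c__;o__;f__;g__EnvTaxon{i};s__"
    return background + community, taxonomy


def _depth_mean(cells: float, params: SimulationParams) -> float:
    k_depth = params.depth_k_half or params.true_k_half
    top = hill_curve(max(params.titration_levels), 1.0, k_depth, params.depth_h)
    frac = hill_curve(cells, 1.0, k_depth, params.depth_h) / top if cells > 0 else 0.0
    return params.negative_depth + (params.depth_max_median - params.negative_depth) * frac


def _draw_depth(cells: float, params: SimulationParams, rng: np.random.Generator) -> int:
    mean = _depth_mean(cells, params)
    return int(round(mean * float(np.exp(rng.normal(0.0, params.depth_sigma)))))


def _spread_background(
    total: int, n_taxa: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    if total <= 0:
        return np.zeros(n_taxa, dtype=np.int64)
    probs = rng.dirichlet(np.full(n_taxa, concentration))
    return rng.multinomial(total, probs).astype(np.int64)


def _control_column(
    cells: float,
    params: SimulationParams,
    rng: np.random.Generator,
    n_background: int,
    leak: bool,
) -> np.ndarray:
    """One well's counts: [target, background taxa..., community taxa zeros]."""
    depth = _draw_depth(cells, params, rng)
    signal_frac = (
        hill_curve(cells, params.true_ymax, params.true_k_half, params.true_h)
        if cells > 0
        else 0.0
    )
    if leak:
        signal_frac = min(signal_frac + params.leakage_rate, 1.0)
    target = int(rng.binomial(depth, signal_frac)) if depth > 0 else 0
    background = _spread_background(
        depth - target, n_background, params.background_concentration, rng
    )
    column = np.zeros(1 + n_background + params.community_taxa, dtype=np.int64)
    column[0] = target
    column[1 : 1 + n_background] = background
    return column


def generate_titration(
    params: SimulationParams, seed: Optional[int] = None
) -> Tuple[FeatureTable, StudyDesign]:
    """Generate the control arm: positives at each titration level plus
    negatives.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    feature_rest, taxonomy = _taxonomy(params)
    n_background = params.background_taxa

    columns, records = [], {}
    for level in params.titration_levels:
        for rep in range(params.replicates_per_level):
            sid = f"pos_{int(level)}c_{rep:02d}"
            columns.append(
                (sid, _control_column(level, params, rng, n_background, leak=False))
            )
            records[sid] = SampleRecord(
                sample_id=sid,
                control_class="extraction_positive",
                input_cells=float(level),
                target_spec=TARGET_SPEC,
            )
    for rep in range(params.n_negatives):
        sid = f"neg_{rep:02d}"
        columns.append((sid, _control_column(0.0, params, rng, n_background, leak=True)))
        records[sid] = SampleRecord(
            sample_id=sid, control_class="extraction_negative", target_spec=TARGET_SPEC
        )

    table = _build_table(columns, feature_rest, taxonomy)
    return table, StudyDesign(records=records)


def generate_study(
    params: SimulationParams, seed: Optional[int] = None
) -> Tuple[FeatureTable, StudyDesign]:
    """Generate a full study: the control arm plus true samples.

    Sample biomass is log-uniform over ``sample_biomass_range``, so with
    the default range spanning both sides of the background load some
    samples fall below any sensible exclusion threshold.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    feature_rest, taxonomy = _taxonomy(params)
    n_background = params.background_taxa
    n_community = params.community_taxa

    control_table, design = generate_titration(params, seed=int(rng.integers(2**31)))
    columns = [
        (sid, control_table.sample_counts(sid)) for sid in control_table.sample_ids
    ]
    records = dict(design.records)

    lo, hi = params.sample_biomass_range
    for i in range(params.n_samples):
        sid = f"sample_{i:03d}"
        biomass = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        depth = _draw_depth(biomass, params, rng)
        signal_frac = hill_curve(
            biomass, params.true_ymax, params.true_k_half, params.true_h
        )
        signal = int(rng.binomial(depth, signal_frac)) if depth > 0 else 0
        # leakage is a share of total depth, so the observed target fraction
        # in a contaminated sample estimates leakage_rate directly
        leaked = (
            min(int(rng.binomial(depth, params.leakage_rate)), depth - signal)
            if depth - signal > 0
            else 0
        )
        community = _spread_background(
            signal, n_community, params.background_concentration, rng
        )
        background = _spread_background(
            depth - signal - leaked,
            n_background,
            params.background_concentration,
            rng,
        )
        column = np.zeros(1 + n_background + n_community, dtype=np.int64)
        column[0] = leaked
        column[1 : 1 + n_background] = background
        column[1 + n_background :] = community
        columns.append((sid, column))
        records[sid] = SampleRecord(sample_id=sid, control_class="sample")

    table = _build_table(columns, feature_rest, taxonomy)
    return table, StudyDesign(records=records)


def _build_table(columns, feature_rest, taxonomy) -> FeatureTable:
    sample_ids = tuple(sid for sid, _ in columns)
    counts = np.column_stack([col for _, col in columns])
    return FeatureTable(
        feature_ids=(TARGET_FEATURE_ID, *feature_rest),
        sample_ids=sample_ids,
        counts=counts,
        taxonomy=taxonomy,
    )


def params_to_manifest(params: SimulationParams, seed: Optional[int] = None) -> str:
    """JSON manifest of every parameter and the effective seed."""
    payload = asdict(params)
    payload["effective_seed"] = params.seed if seed is None else seed
    return json.dumps(payload, sort_keys=True, indent=2)
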