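import numpy as np
import pytest

from katharoseq import (
    FeatureTable,
    SampleRecord,
    StudyDesign,
    SimulationParams,
    composition_points,
    generate_titration,
)

NEG_CLASSES = {"extraction_negative", "pcr_negative", "blank"}


@pytest.fixture
def toy_table():
    """3 features x 2 samples; B. subtilis target plus two contaminants."""
    return FeatureTable(
        feature_ids=("f_bs", "f_vf", "f_ac"),
        sample_ids=("s1", "s2"),
        counts=np.array([[906, 0], [94, 0], [0, 7]]),
        taxonomy={
            "f_bs": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;"
            "f__Bacillaceae;g__Bacillus;s__subtilis",
            "f_vf": "k__Bacteria;p__Proteobacteria;f__Vibrionaceae;"
            "g__Vibrio;s__fischeri",
            "f_ac": "k__Bacteria;p__Proteobacteria;g__Acinetobacter;s__lwoffii",
        },
    )


@pytest.fixture
def toy_design():
    records = {
        "s1": SampleRecord(
            sample_id="s1",
            control_class="extraction_positive",
            input_cells=500,
            target_spec="g__Bacillus",
        ),
        "s2": SampleRecord(sample_id="s2", control_class="sample"),
    }
    return StudyDesign(records=records)


@pytest.fixture(scope="session")
def default_titration():
    """One default synthetic titration experiment (fixed seed)."""
    return generate_titration(SimulationParams(), seed=1)


@pytest.fixture(scope="session")
def titration_points(default_titration):
    table, design = default_titration
    positives, _ = composition_points(table, design, {"extraction_positive"})
    negatives, _ = composition_points(table, design, NEG_CLASSES)
    return positives, negatives
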