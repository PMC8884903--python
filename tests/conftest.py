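import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metascreen.io import LibraryDesign, SampleSheet

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_library() -> LibraryDesign:
    return LibraryDesign(
        pd.DataFrame(
            {
                "sgrna_id": ["Atp11b_sg1", "Atp11b_sg2", "Trp53_sg1", "Brca1_sg1"],
                "spacer": ["ACGTACGTAC", "TTTTACGGTC", "GGGTTTAACC", "CCAATTGGCC"],
                "gene": ["Atp11b", "Atp11b", "Trp53", "Brca1"],
            }
        )
    )


@pytest.fixture
def five_organ_sheet() -> SampleSheet:
    rows = [
        {"sample_id": "pre", "compartment": "preimplant", "organ": "",
         "subject_id": "library", "week": 0},
        {"sample_id": "p1", "compartment": "primary", "organ": "",
         "subject_id": "m1", "week": 8},
        {"sample_id": "r1", "compartment": "recurrent", "organ": "",
         "subject_id": "m1", "week": 8},
        {"sample_id": "b1", "compartment": "blood", "organ": "",
         "subject_id": "m1", "week": 4},
    ] + [
        {"sample_id": f"met_{o}", "compartment": "metastasis", "organ": o,
         "subject_id": "m1", "week": 8}
        for o in ("lung", "liver", "spleen", "brain", "kidney")
    ]
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
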