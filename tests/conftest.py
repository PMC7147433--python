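"""Shared fixtures: scaled detection settings and annotated test molecules.

All synthetic material is generated at run time; sizes are one order of
magnitude below real plastomes so the full suite stays fast while keeping
the LSC > IR > SSC size ordering and circular structure.
"""

from __future__ import annotations

import pytest
from Bio import SeqIO

from plastcure.ir_detection import DetectionConfig
from plastcure.simulation import (
    SyntheticTruth,
    generate_synthetic_plastome,
    make_annotated_record,
)


@pytest.fixture(scope="session")
def scaled_cfg() -> DetectionConfig:
    """Detection settings matched to the desk-scale synthetic molecules."""
    return DetectionConfig(window_size=250, min_ir_length=250)


@pytest.fixture(scope="session")
def clean_truth() -> SyntheticTruth:
    return generate_synthetic_plastome(seed=7, cut_class=1)


@pytest.fixture()
def annotated_folder(tmp_path, clean_truth):
    """A folder holding one annotated GenBank file of a synthetic plastome."""
    rec = make_annotated_record(clean_truth.plastome.sequence, "synt1", seed=5)
    path = tmp_path / "synt1.gb"
    SeqIO.write(rec, str(path), "genbank")
    return tmp_path
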