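import numpy as np
import pytest

from beatbox import annotate as an
from beatbox import io_formats as iof
from beatbox import synthetic_ecg as se

FS = 360.0


@pytest.fixture(scope="session")
def clean_record():
    """20 noise-free beats cycling through several classes."""
    return se.make_record(
        20, ["N", "L", "V", "A", "j"], fs=FS, seed=11, amp_jitter=0.0
    )


@pytest.fixture(scope="session")
def all_class_record():
    """One noise-free record containing all 12 beat classes."""
    return se.make_record(
        24, list(se.TEMPLATES), fs=FS, seed=5, amp_jitter=0.05
    )


@pytest.fixture(scope="session")
def annotated(clean_record):
    boxes, fids = an.annotate_record(clean_record.record, clean_record.beats())
    return clean_record, boxes, fids


@pytest.fixture()
def wfdb_dir(tmp_path, all_class_record):
    name = se.write_as_wfdb(all_class_record, tmp_path, "s1")
    return tmp_path, name, all_class_record


@pytest.fixture(scope="session")
def class_map():
    return iof.DEFAULT_CLASS_MAP


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
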