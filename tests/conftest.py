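import numpy as np
import pytest

import hoxcomb as hx

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def profile():
    """Profile built once from the bundled seed alignment."""
    return hx.default_profile()


@pytest.fixture(scope="session")
def signatures():
    return hx.builtin_signatures()


def random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AA))[rng.integers(0, 20, size=n)])


def make_segment(hd: str | None = None, cflank: str = "", **forced: str) -> hx.AnalysisSegment:
    """Segment helper: neutral reference homeodomain with residues forced at
    1-based positions given as p3='K' style kwargs."""
    residues = list(hd if hd is not None else hx.reference_homeodomain())
    for key, res in forced.items():
        residues[int(key[1:]) - 1] = res
    return hx.AnalysisSegment(hd="".join(residues), cflank=cflank)
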