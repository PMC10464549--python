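import numpy as np
import pytest

from modsite import ModProfile, SimConfig, make_reference, simulate_reads

TOY_SAM = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:toyref\tLN:4
r1\t0\ttoyref\t1\t60\t4M\t*\t0\t0\tAAAA\t*\tMD:Z:4
r2\t0\ttoyref\t1\t60\t4M\t*\t0\t0\tAACA\t*\tMD:Z:2A1
r3\t0\ttoyref\t1\t60\t2M1D1M\t*\t0\t0\tAAA\t*\tMD:Z:2^A1
"""


def mod_error_vector(mismatch=0.30, deletion=0.02, insertion=0.01):
    """Six-category error vector with the mismatch mass on one alternative base."""
    return np.array([1.0 - mismatch - deletion - insertion, mismatch, 0.0, 0.0, deletion, insertion])


@pytest.fixture
def toy_sam(tmp_path):
    path = tmp_path / "toy.sam"
    path.write_text(TOY_SAM)
    return path


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(200, gc=0.5, seed=123, name="mini18S")


@pytest.fixture(scope="session")
def small_bam_pools(small_ref, tmp_path_factory):
    """One modified (site 100) and one unmodified pool of 600 reads each."""
    out = tmp_path_factory.mktemp("pools")
    prof = ModProfile(site=100, mod_error=mod_error_vector(0.40), class_label="m7G")
    wt = simulate_reads(small_ref, [prof], 1.0, SimConfig(600, 1, seed=11), out, "wt")[0]
    ko = simulate_reads(small_ref, [], 0.0, SimConfig(600, 1, seed=12), out, "ko")[0]
    return {"ref": small_ref, "wt": wt, "ko": ko, "site": 100, "dir": out}
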