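"""Shared fixtures: synthetic references, catalogues, and ReadSet builders."""

import numpy as np
import pytest

import riboslicer as rl


@pytest.fixture(scope="session")
def ref():
    """Synthetic 45SN1-length (13,351 nt) reference."""
    return rl.make_reference()


@pytest.fixture(scope="session")
def templates(ref):
    return rl.default_template_set(ref.length)


@pytest.fixture(scope="session")
def sites(ref):
    return rl.default_processing_sites(ref.length)


@pytest.fixture(scope="session")
def small_ref():
    return rl.make_reference(length=400, seed=3, name="mini_ref")


@pytest.fixture(scope="session")
def make_readset():
    """Factory: build a ReadSet from a list of (start, end) 0-based intervals."""

    def _make(intervals, ref_length, **kwargs):
        records = [
            rl.ReadRecord(read_id=f"r{i}", start=int(s), end=int(e))
            for i, (s, e) in enumerate(intervals)
        ]
        return rl.ReadSet(records=records, ref_length=ref_length, **kwargs)

    return _make


@pytest.fixture(scope="session")
def ref_fasta(ref, tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, 80):
            fh.write(ref.sequence[i : i + 80] + "\n")
    return path
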