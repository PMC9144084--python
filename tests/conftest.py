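import pytest

from mtmosaic import MultipleAlignment, SequenceRecord, paper_mimic_config, simulate


def make_aln(*rows: str, ids=None) -> MultipleAlignment:
    """Small alignment from residue strings."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(
        [SequenceRecord(i, r) for i, r in zip(ids, rows)]
    )


@pytest.fixture(scope="session")
def mimic_dataset():
    """One paper-regime synthetic dataset shared by read-only tests."""
    config = paper_mimic_config(seed=1)
    aln, truth = simulate(config)
    return config, aln, truth


@pytest.fixture(scope="session")
def candidates():
    return [f"A{k}" for k in range(1, 6)]
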