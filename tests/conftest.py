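import numpy as np
import pytest

from sncpipe.refdb import ReferenceRecord, build_index, preprocess_trna
from sncpipe.synthetic import SimConfig, build_feature_panel, generate_references


@pytest.fixture(scope="session")
def toy_refset():
    """Small deterministic reference set (18S embedded in 45S, His tRNA with
    intron, off-genome rescue decoys)."""
    cfg = SimConfig(seed=123)
    rng = np.random.default_rng(cfg.seed)
    return generate_references(cfg, rng)


@pytest.fixture(scope="session")
def toy_index(toy_refset):
    return build_index(toy_refset.records, genome=toy_refset.genome)


@pytest.fixture(scope="session")
def toy_panel(toy_refset):
    cfg = SimConfig(seed=123)
    rng = np.random.default_rng(321)
    return build_feature_panel(cfg, toy_refset, rng)


@pytest.fixture()
def raw_his_trna():
    """75-nt raw histidine tRNA gene with one 10-nt intron (positions 36-45)."""
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 75))
    return ReferenceRecord(
        ref_id="tRNA-His-GTG-9",
        biotype="tRNA",
        sequence=seq,
        amino_acid="His",
        intron_intervals=[(36, 45)],
    )


@pytest.fixture(scope="session")
def processed_trna():
    rng = np.random.default_rng(11)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 72))
    return preprocess_trna(
        ReferenceRecord(
            ref_id="tRNA-Glu-CTC-9", biotype="tRNA", sequence=seq, amino_acid="Glu"
        )
    )
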