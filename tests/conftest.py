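import numpy as np
import pytest

from metaqtl.mqtl_engine import ProjectedQTL
from metaqtl.qtl_catalog import PopulationType, QTLRecord, QTLStudy, TraitClass


def make_pqtl(i: int, x: float, sd: float = 1.0, pve: float = 10.0,
              chrom: int = 1, study: str = "S1") -> ProjectedQTL:
    return ProjectedQTL(
        qtl_id=f"q{i:03d}", chromosome=chrom, x=x, sd=sd,
        pve_percent=pve, trait=TraitClass.YLD, study_id=study,
    )


@pytest.fixture
def ril_study() -> QTLStudy:
    return QTLStudy("S1", PopulationType.RIL, 200, year=2015)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def simple_record() -> QTLRecord:
    return QTLRecord(
        qtl_id="q001", study_id="S1", trait=TraitClass.YLD, chromosome=1,
        peak_cM=12.0, ci_lo_cM=10.0, ci_hi_cM=14.0, ci_width_cM=4.0,
        lod=4.0, pve_percent=10.0,
    )
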