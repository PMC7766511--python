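import datetime as dt

import numpy as np
import pytest

from herdlife.records import CowLifeRecord


def make_record(cow_id, birth=dt.date(1995, 3, 1), herd=1, fca=24.0,
                calv=(24.0, 36.0), cull=5.5, reason="fertility",
                et=False, sire=None):
    calv = list(calv)
    return CowLifeRecord(
        cow_id=cow_id, herd_id=herd, birth_date=birth,
        first_calving_age=fca, calving_ages=calv, culling_age=cull,
        culling_reason=reason, embryo_transfer=et, sire_id=sire,
    )


@pytest.fixture
def toy_records():
    """Ten handwritten records; three violate distinct QC rules."""
    good = [
        make_record(i, cull=4.0 + i, calv=[24.0, 36.0], reason="fertility")
        for i in range(1, 8)
    ]
    bad = [
        make_record(8, fca=18.0, calv=[18.0]),                 # early calving
        make_record(9, birth=dt.date(1985, 5, 1)),             # born pre-1990
        make_record(10, cull=21.0),                            # culled too old
    ]
    return good + bad


@pytest.fixture(scope="session")
def small_gaussian():
    from herdlife.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_founders=60, n_generations=2, mode="gaussian",
                           seed=42)
    ped, tv, data = simulate_dataset(cfg)
    return cfg, ped, tv, data


@pytest.fixture(scope="session")
def small_binary():
    from herdlife.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_founders=60, n_generations=2, mode="binary",
                           seed=42)
    ped, tv, data = simulate_dataset(cfg)
    return cfg, ped, tv, data


def random_pedigree(rng, n, n_founders=None):
    """Random valid pedigree for oracle tests."""
    from herdlife.pedigree import PedigreeTable

    nf = n_founders or max(2, int(rng.integers(2, max(3, n // 4))))
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(nf, n):
        s = int(rng.integers(0, i))
        d = int(rng.integers(0, i))
        sire[i] = s
        dam[i] = d if d != s else -1
        if rng.random() < 0.1:
            sire[i] = -1
    return PedigreeTable(np.arange(1, n + 1), sire, dam,
                         np.zeros(n, dtype=np.int64))
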