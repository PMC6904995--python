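import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ionbind as ib

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_records():
    """Three hand-built chains with annotated SO4 binding residues."""
    def rec(chain_id, seq, positions, resolution=2.0):
        mask = np.zeros(len(seq), dtype=bool)
        mask[[p - 1 for p in positions]] = True
        rng = np.random.default_rng(abs(hash(chain_id)) % 2**31)
        return ib.ProteinRecord(
            chain_id=chain_id,
            sequence=seq,
            binding={"SO4": mask},
            ss_track="".join(rng.choice(list("HEC"), size=len(seq))),
            rsa_track=rng.uniform(0, 1, size=len(seq)),
            resolution=resolution,
        )

    return [
        rec("1abc_A", "ACDEFGHIKLMNPQRSTVWYACDEF", [3, 12]),
        rec("2xyz_B", "MKLVNDERQHST", [2]),
        rec("3foo_C", "GGGGCCCCAAAA", []),
    ]


@pytest.fixture
def small_dataset():
    """Synthetic dataset at default study conditions, small and seeded."""
    cfg = ib.SyntheticConfig(n_chains=20, seed=11)
    records, annotations = ib.generate_synthetic_dataset(cfg)
    return cfg, records, annotations
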