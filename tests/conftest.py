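import pytest
from hypothesis import HealthCheck, settings

import tftargets as tt
from tftargets.records import TargetStatus

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# small planted partition used by the fast end-to-end tests
SMALL_COUNTS = {"conserved": 10, "lost_in_disease": 15, "gained_in_disease": 20}
SMALL_N_DEPENDENT = 12


def small_config(**overrides):
    base = dict(n_genes=400, class_counts=dict(SMALL_COUNTS),
                n_dependent=SMALL_N_DEPENDENT, seed=11)
    base.update(overrides)
    return tt.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    """A 400-gene noise-free dataset with a planted 10/15/20 partition."""
    return tt.simulate_dataset(small_config(epsilon=0.0))


@pytest.fixture(scope="session")
def small_noisy_dataset():
    return tt.simulate_dataset(small_config(epsilon=0.1, seed=13))


def make_status(gene_id: str, condition_id: str, member: bool,
                direction: str = "up", bound: bool = None,
                kd: bool = False, score: float = None) -> TargetStatus:
    """Build a consistent TargetStatus for classification tests."""
    if member:
        cls = tt.F3T_IN_KD if kd else tt.F3T_IN
        return TargetStatus(gene_id=gene_id, condition_id=condition_id,
                            bound=True, direction=direction, kd_regulated=kd,
                            target_class=cls, max_peak_score=score)
    return TargetStatus(gene_id=gene_id, condition_id=condition_id,
                        bound=bool(bound), direction="none",
                        kd_regulated=False, target_class=tt.NON_TARGET,
                        max_peak_score=score)
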