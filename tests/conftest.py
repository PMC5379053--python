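import numpy as np
import pytest

from tecrm import simulate
from tecrm.motifs import PWM


@pytest.fixture(scope="session")
def pwms():
    return simulate.default_pwms()


@pytest.fixture(scope="session")
def short_pwm():
    """Length-4 PWM with distinct column shapes, for exhaustive oracles."""
    probs = np.array(
        [
            [0.70, 0.10, 0.25, 0.40],
            [0.10, 0.60, 0.25, 0.30],
            [0.10, 0.20, 0.25, 0.20],
            [0.10, 0.10, 0.25, 0.10],
        ]
    )
    return PWM(name="toy4", probs=probs)


@pytest.fixture(scope="session")
def small_genome():
    """A compact simulated genome with a planted 3-TF module (seed 7)."""
    cfg = simulate.SimConfig(
        genome_length=400_000,
        n_chromosomes=1,
        subfamily_specs=tuple(
            simulate.SubfamilySpec(
                name=f"Sub{i}",
                consensus=_consensus(300, 100 + i),
                n_copies=40,
                sub_rate=0.05,
            )
            for i in range(3)
        ),
        planted_module_spec=simulate.ModuleSpec(
            subfamily="Sub0", pwm_names=("Esrrb", "Klf4", "Sox2"), carrier_fraction=0.5
        ),
        seed=7,
    )
    return simulate.simulate_genome(cfg)


def _consensus(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture
def consensus_factory():
    return _consensus
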