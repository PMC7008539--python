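import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from passengerscreen.gsmm import Environment
from passengerscreen.synthetic import CommunitySpec, generate_community, generate_environment


CHAIN_MODEL = """\
# minimal chain: import A, grow on it 1:1
EX_A\t0\t1000\t-1 A_e +1 A
GROW\t0\t1000000\t-1 A\tbiomass
"""

TWO_SUBSTRATE_MODEL = """\
# biomass needs 1 A + 2 B
EX_A\t0\t1000\t-1 A_e +1 A
EX_B\t0\t1000\t-1 B_e +1 B
GROW\t0\t1000\t-1 A -2 B\tbiomass
"""

SUBSTITUTABLE_MODEL = """\
# A and B both convert to C; biomass needs only C
EX_A\t0\t1000\t-1 A_e +1 A
EX_B\t0\t1000\t-1 B_e +1 B
CONV_A\t0\t1000\t-1 A +1 C
CONV_B\t0\t1000\t-1 B +1 C
GROW\t0\t1000\t-1 C\tbiomass
"""


def write_model(tmp_path, text, name="toy.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def chain_model(tmp_path):
    from passengerscreen.io import read_tabular_model

    return read_tabular_model(write_model(tmp_path, CHAIN_MODEL))


@pytest.fixture
def two_substrate_model(tmp_path):
    from passengerscreen.io import read_tabular_model

    return read_tabular_model(write_model(tmp_path, TWO_SUBSTRATE_MODEL))


@pytest.fixture
def substitutable_model(tmp_path):
    from passengerscreen.io import read_tabular_model

    return read_tabular_model(write_model(tmp_path, SUBSTITUTABLE_MODEL))


@pytest.fixture
def small_env():
    return Environment("basal", {"A_e": 10.0, "B_e": 10.0, "C_e": 5.0, "D_e": 2.0})


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-model synthetic cohort with its environment and ground truth."""
    spec = CommunitySpec(n_models=60, n_genera=8, seed=11)
    env, disease = generate_environment(spec)
    models, truth = generate_community(spec, env, disease)
    return spec, env, disease, models, truth
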