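import pytest
from hypothesis import HealthCheck, settings

import evoattract as ea
from evoattract.neuralnet import CODE_BITS, NetworkParams, pyramid_hidden_size

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

TEACH_LEN = 60  # residues per teaching sequence in the small fixtures


@pytest.fixture(scope="session")
def table1_matrix():
    return ea.build_semihomology_matrix(ea.get_genetic_code(1))


@pytest.fixture(scope="session")
def table2_matrix():
    return ea.build_semihomology_matrix(ea.get_genetic_code(2))


@pytest.fixture(scope="session")
def teaching_six():
    """Six unrelated random 60-residue proteins (independent codon ancestors)."""
    code = ea.get_genetic_code(1)
    return [
        ea.SequenceRecord(
            id=f"teach{i}",
            residues=code.translate(ea.random_ancestor(TEACH_LEN, code, 100 + i)),
        )
        for i in range(6)
    ]


def _fixture_params(rmse_target: float = 0.01) -> NetworkParams:
    n = CODE_BITS * TEACH_LEN
    return NetworkParams(n=n, m=pyramid_hidden_size(n, 6), k=6, rmse_target=rmse_target)


@pytest.fixture(scope="session")
def single_net_ensemble(teaching_six):
    """One trained network on the six-sequence fixture (convergence check)."""
    return ea.teach_ensemble(teaching_six, _fixture_params(), n_versions=1, master_seed=7)


@pytest.fixture(scope="session")
def five_net_ensemble(teaching_six):
    """Five-member ensemble on the six-sequence fixture (generalization check)."""
    return ea.teach_ensemble(teaching_six, _fixture_params(), n_versions=5, master_seed=11)
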