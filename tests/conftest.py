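import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ideal_helix():
    """12-residue poly-ALA α-helix at ideal dihedrals (φ=−57°, ψ=−47°)."""
    from confdiv.peptide import build_chain

    return build_chain([(-57.0, -47.0)] * 12)


@pytest.fixture(scope="session")
def extended_chain():
    """Fully extended isolated chain (φ=ψ=180°): no H-bond partners."""
    from confdiv.peptide import build_chain

    return build_chain([(180.0, 180.0)] * 12)


@pytest.fixture(scope="session")
def antiparallel_sheet():
    from confdiv.synth import build_antiparallel_sheet

    return build_antiparallel_sheet()


@pytest.fixture(scope="session")
def small_study():
    """One synthetic protein: 2 aqueous + 2 organic-medium conformers."""
    from confdiv.synth import EnsembleSpec, make_study

    spec = EnsembleSpec(target_rmsd={"AA": 1.0, "AO": 1.0, "OO": 0.5}, seed=11)
    return make_study(spec, protein_id="prot")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
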