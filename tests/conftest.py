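import pytest

from httxl.simulate import build_solenoid_bead_model, simulate_crosslinks


@pytest.fixture(scope="session")
def base_model():
    """Default 3144-residue solenoid bead model, seed 1."""
    return build_solenoid_bead_model(seed=1)


@pytest.fixture(scope="session")
def simulated(base_model):
    """One simulated crosslink experiment on the base model."""
    return simulate_crosslinks(base_model, allele_label="Q23", seed=7)
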