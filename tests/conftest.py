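import numpy as np
import pytest

from v1contrast import ssn, synth


@pytest.fixture(scope="session")
def stim_single():
    """One session, 15 reps, 30 blanks (750 trials)."""
    return synth.make_stimulus_table(n_reps=15, n_blanks=30, n_sessions=1, seed=11)


@pytest.fixture(scope="session")
def vip_dataset():
    return synth.generate_dataset("vip", 30, n_reps=15, n_blanks=30, seed=21)


@pytest.fixture(scope="session")
def flat_dataset():
    return synth.generate_dataset("flat", 30, n_reps=15, n_blanks=30, seed=22)


@pytest.fixture(scope="session")
def reduced_config():
    """Small ring for fast SSN tests.

    Interneuron pools of identical units collapse to single units without
    changing the dynamics (weights are normalized per postsynaptic cell).
    The coarser 60-unit E ring shifts the critical VIP->SST coupling by a
    few percent, and the shipped default sits at 0.99 of critical, so the
    fixture backs the coupling off to -0.55 to stay clearly subcritical.
    """
    import dataclasses

    coup = dataclasses.replace(ssn.Couplings(), vip_sst=-0.55)
    return ssn.NetworkConfig(
        n_e_ring=60, n_e_extra=2, n_pv=1, n_sst=1, n_vip=1, couplings=coup
    )


@pytest.fixture(scope="session")
def reduced_net(reduced_config):
    return ssn.SSNetwork(reduced_config)
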