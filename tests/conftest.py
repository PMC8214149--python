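import numpy as np
import pytest

from xlmsn.chem import get_linker
from xlmsn.seqdb import DigestParams, ProteinRecord, random_proteins
from xlmsn.simulate import SimConfig, render_spectra, simulate_crosslinks


@pytest.fixture(scope="session")
def small_db():
    """A dozen synthetic target proteins, enough digest peptides to search."""
    return random_proteins(12, 320, seed=11)


@pytest.fixture(scope="session")
def noiseless_sim(small_db):
    """Noise-free simulated SDASO-M run: truth records + rendered spectra."""
    cfg = SimConfig(linker="SDASO-M", n_interlinks=30, n_deadend_nhs=6,
                    n_deadend_diazirine=6, n_intralinks=6,
                    ppm_sigma=0.0, noise_peaks=0, seed=5)
    truth = simulate_crosslinks(small_db, cfg)
    spectra = render_spectra(truth, cfg)
    return cfg, truth, spectra


@pytest.fixture(scope="session")
def sdaso_m():
    return get_linker("SDASO-M")


@pytest.fixture(scope="session")
def dsso():
    return get_linker("DSSO")
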