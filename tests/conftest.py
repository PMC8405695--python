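import numpy as np
import pytest

import corneamech as cm

#: Default optics of the emulated OCT system.
OPTICS = {"wavelength_nm": 878.0, "asu_um": 4.48, "refractive_index": 1.375,
          "lsu_um": 12.5}


@pytest.fixture(scope="session")
def wt_prony() -> cm.PronyModel:
    return cm.WT_PRONY


@pytest.fixture(scope="session")
def col5a1_prony() -> cm.PronyModel:
    return cm.COL5A1_PRONY


@pytest.fixture(scope="session")
def noiseless_wt_pair() -> cm.OCEScanPair:
    """Canonical noiseless wt phantom: 148 um, -4.93 permil imposed."""
    spec = cm.PhantomSpec(cct_um=148.0, imposed_strain=-4.93e-3, seed=0)
    return cm.gen_oct_pair(spec)


@pytest.fixture(scope="session")
def noiseless_col5a1_pair() -> cm.OCEScanPair:
    """Canonical noiseless Col5a1 phantom: 125 um, -4.84 permil imposed."""
    spec = cm.PhantomSpec(cct_um=125.0, imposed_strain=-4.84e-3, seed=0)
    return cm.gen_oct_pair(spec)


def uniform_phase_pair(phase_per_px: float, nz: int = 64, nx: int = 48,
                       seed: int = 0) -> cm.OCEScanPair:
    """Flat speckle slab whose deformed scan carries a linear depth phase."""
    rng = np.random.default_rng(seed)
    refl = (rng.standard_normal((nz, nx)) + 1j * rng.standard_normal((nz, nx)))
    depth = np.arange(nz)[:, None] * np.ones((1, nx))
    b_def = refl * np.exp(1j * phase_per_px * depth)
    meta = dict(OPTICS, n_ascans=nx, n_z=nz, delta_p_mmhg=-3.0)
    return cm.OCEScanPair(b_ref=refl, b_def=b_def, meta=meta)
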