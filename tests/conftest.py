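import numpy as np
import pytest

import prfgain as pg
from prfgain.fitting import PRFModel, ridge_factor


@pytest.fixture(scope="session")
def seq():
    return pg.build_bar_sequence(seed=1)


@pytest.fixture(scope="session")
def dm101(seq):
    return pg.render_design_matrix(seq, 101)


@pytest.fixture(scope="session")
def dm31(seq):
    return pg.render_design_matrix(seq, 31)


@pytest.fixture(scope="session")
def hrf():
    return pg.hrf_double_gamma(dt_s=1.6)


@pytest.fixture(scope="session")
def prf_model(dm101, hrf):
    return PRFModel(dm101, hrf)


@pytest.fixture(scope="session")
def regressors31(dm31, hrf):
    return pg.convolve_design(dm31, hrf)


@pytest.fixture(scope="session")
def ridge_fac(regressors31):
    return ridge_factor(regressors31)


@pytest.fixture(scope="session")
def tiny_seq():
    """One direction, two positions, no blanks: minimal renderable run."""
    return pg.build_bar_sequence(
        n_passes_per_direction=1,
        directions=(0.0,),
        n_positions_per_pass=2,
        n_blanks=0,
        seed=0,
    )


@pytest.fixture(scope="session")
def fitted_noisy_voxels(dm101, dm31, hrf, prf_model, regressors31, ridge_fac):
    """20 voxels at 20% noise, all three conditions fitted (shared across tests)."""
    af = pg.GenerativeAFSpec()
    voxels = pg.sample_ground_truth_voxels(
        20, ecc_range=(0.3, 3.0), size_intercept=0.5, size_slope=0.1, seed=42
    )
    fits = []
    for i, v in enumerate(voxels):
        ts = {
            c: pg.generate_bold_timeseries(v, dm101, c, af, hrf, 0.2, seed=1000 + 10 * i + k).values
            for k, c in enumerate(("AttendFixation", "AttendColor", "AttendTF"))
        }
        concat = np.concatenate([ts[c] for c in ("AttendFixation", "AttendColor", "AttendTF")])
        init = pg.ridge_init(concat, regressors31, 31, factor=ridge_fac)
        joint = pg.fit_prf_joint(ts, prf_model, init)
        fits.append(pg.fit_prf_per_condition(ts, prf_model, joint))
    return voxels, af, fits
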