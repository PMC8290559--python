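import numpy as np
import pandas as pd
import pytest

from mrexposome.harmonize import RECORD_COLUMNS, HarmonizedSet


def make_harmonized(bx, by, sy, sx=None, snp_ids=None,
                    exposure_id="exposure", outcome_id="outcome"):
    """Build a HarmonizedSet directly from effect arrays."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.broadcast_to(np.asarray(sy, float), bx.shape)
    sx = np.broadcast_to(
        np.asarray(sx if sx is not None else 1e-6, float), bx.shape
    )
    if snp_ids is None:
        snp_ids = [f"rs{i:04d}" for i in range(len(bx))]
    records = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "beta_x": bx,
            "se_x": sx,
            "beta_y": by,
            "se_y": sy,
            "eaf_x": 0.3,
            "eaf_y": 0.3,
        },
        columns=RECORD_COLUMNS,
    )
    actions = pd.DataFrame({"snp_id": snp_ids, "action": "kept_direct"})
    return HarmonizedSet(exposure_id, outcome_id, records, actions)


@pytest.fixture
def proportional_toy():
    """Exactly proportional betas: IVW slope 0.5, SE 1/sqrt(1400), Q = 0."""
    return make_harmonized(
        bx=[0.1, 0.2, 0.3], by=[0.05, 0.10, 0.15], sy=[0.01, 0.01, 0.01]
    )


@pytest.fixture
def affine_toy():
    """Exactly affine betas: Egger slope 0.5, intercept 0.02, zero residual."""
    return make_harmonized(
        bx=[0.1, 0.2, 0.3], by=[0.07, 0.12, 0.17], sy=[0.01, 0.01, 0.01]
    )


def random_harmonized(rng, j, theta=0.5):
    """A generic random harmonized set for oracle-equivalence checks."""
    bx = rng.normal(0.1, 0.05, j)
    bx[np.abs(bx) < 1e-3] = 1e-3
    sy = rng.uniform(0.005, 0.05, j)
    by = theta * bx + rng.normal(0, sy)
    sx = rng.uniform(0.001, 0.01, j)
    return make_harmonized(bx, by, sy, sx=sx)
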