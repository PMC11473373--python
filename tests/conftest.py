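import numpy as np
import pytest

from metamediation import Polarity, load_reference_table, subset_by_polarity
from metamediation.effects import EffectRecord


@pytest.fixture(scope="session")
def ref_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def neg_stratum(ref_table):
    return subset_by_polarity(ref_table, Polarity.NEGATIVE)


@pytest.fixture(scope="session")
def pos_stratum(ref_table):
    return subset_by_polarity(ref_table, Polarity.POSITIVE)


def make_effects(zs, ses):
    """Build effect records from parallel z / se arrays (n back-solved from se)."""
    return [
        EffectRecord(
            study_id=f"s{i}",
            z=float(z),
            v=float(se) ** 2,
            se=float(se),
            n=max(4, int(round(1.0 / float(se) ** 2)) + 3),
        )
        for i, (z, se) in enumerate(zip(zs, ses))
    ]


# A z-symmetric 9-study funnel (effects mirrored about 0.5).  Deleting its
# 3 leftmost studies creates the one-sided suppression pattern that the
# trim-and-fill rank estimator should detect as exactly 3 missing studies
# (hand rank computation at the converged center 0.465: signed-rank sum
# Sr = 19, L0 = (4*19 - 42)/11 = 3.09 -> k0 = 3).
SYMMETRIC9_Z = np.array([-0.21, 0.25, 0.28, 0.43, 0.50, 0.57, 0.72, 0.75, 1.21])
SYMMETRIC9_SE = np.array([0.32, 0.30, 0.33, 0.07, 0.08, 0.25, 0.28, 0.31, 0.25])


@pytest.fixture()
def symmetric9():
    return make_effects(SYMMETRIC9_Z, SYMMETRIC9_SE)


@pytest.fixture()
def symmetric9_deleted():
    return make_effects(SYMMETRIC9_Z[3:], SYMMETRIC9_SE[3:])
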