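import numpy as np
import pandas as pd
import pytest

from caerisk.arms import ArmMap
from caerisk.cohort import CohortParams, cohort_to_frame, generate_cohort
from caerisk.copynumber import ArmEventSet


@pytest.fixture(scope="session")
def arm_map():
    return ArmMap.hg38()


@pytest.fixture(scope="session")
def small_cohort():
    """300 subjects under default study conditions, fixed seed."""
    return generate_cohort(CohortParams(n_subjects=300, seed=11))


@pytest.fixture(scope="session")
def small_cohort_frame(small_cohort):
    return cohort_to_frame(small_cohort)


def make_events(sample_id="s", **status):
    """ArmEventSet from keyword arm statuses, e.g. make_events(q8='gain').

    Keyword names use the arm letter first (q8 -> '8q') because Python
    identifiers cannot start with a digit.
    """
    return ArmEventSet(
        sample_id=sample_id,
        status={k[1:] + k[0]: v for k, v in status.items()},
    )


def enumeration_loglik(beta, X, y, groups):
    """Independent oracle: per set, the probability that the observed case
    is the case among all within-set relabelings, summed in log across sets."""
    total = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        scores = [float(np.exp(X[i] @ beta)) for i in idx]
        case_pos = [i for i in idx if y[i]]
        assert len(case_pos) == 1
        p = scores[list(idx).index(case_pos[0])] / sum(scores)
        total += np.log(p)
    return total


def cmh_statistic(x, y, groups):
    """Cochran-Mantel-Haenszel chi-square without continuity correction,
    computed directly from the per-stratum 2x2 tables."""
    num = var = 0.0
    for g in np.unique(groups):
        idx = groups == g
        xg, yg = x[idx], y[idx]
        T = len(xg)
        n1, m1 = yg.sum(), xg.sum()
        a = float(x[idx][yg].sum())  # exposed cases
        num += a - n1 * m1 / T
        var += n1 * (T - n1) * m1 * (T - m1) / (T**2 * (T - 1))
    return num**2 / var


def random_matched_instance(rng, n_sets=5, set_size=3, p_covs=2):
    """Random small matched-set arrays (X, y, groups) for oracle checks."""
    n = n_sets * set_size
    X = rng.normal(size=(n, p_covs))
    y = np.zeros(n, dtype=bool)
    y[::set_size] = True
    groups = np.repeat(np.arange(n_sets), set_size)
    return X, y, groups
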