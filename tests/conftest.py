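import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pdprog.cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_default():
    """Moderate cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(n_subjects=250, seed=42))


@pytest.fixture(scope="session")
def cohort_longitudinal():
    """Everyone followed up; useful for models needing repeat visits."""
    return generate_cohort(
        GeneratorConfig(n_subjects=250, seed=43, single_visit_fraction=0.0)
    )


def simulate_ordinal_panel(seed, n_subjects=200, n_visits=4, beta=(1.0, -0.5),
                           sigma_b=1.0, alphas=(-0.5, 1.5)):
    """Direct draw from the proportional-odds random-intercept model.

    Independent of the cohort generator: the oracle data-generating
    process for estimator recovery tests.
    """
    rng = np.random.default_rng(seed)
    N = n_subjects * n_visits
    X = rng.normal(size=(N, len(beta)))
    g = np.repeat(np.arange(n_subjects), n_visits)
    b = rng.normal(0.0, sigma_b, n_subjects)[g] if sigma_b > 0 else np.zeros(N)
    eta = X @ np.asarray(beta) + b
    u = rng.random(N)
    p0 = expit(alphas[0] - eta)
    p1 = expit(alphas[1] - eta)
    y = np.where(u < p0, 0, np.where(u < p1, 1, 2))
    cols = {f"x{j+1}": X[:, j] for j in range(len(beta))}
    return pd.DataFrame({"subject_id": g, **cols, "status": y})
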