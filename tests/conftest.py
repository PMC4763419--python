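import dataclasses

import numpy as np
import pytest

import traumarisk as tr


@pytest.fixture(scope="session")
def truth_model():
    return tr.generating_truth_model()


@pytest.fixture(scope="session")
def complete_cohort():
    """A complete (no missing values) full-period cohort, n=4440."""
    return tr.generate_cohort(tr.default_spec("full", seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """n=50 000 single-hospital validation-marginal cohort for asymptotics."""
    spec = tr.default_spec("validation", seed=17)
    spec = dataclasses.replace(spec, n_per_hospital={"AA": 50_000})
    return tr.generate_cohort(spec)


@pytest.fixture(scope="session")
def masked_cohort(complete_cohort):
    """The complete cohort with MAR missingness at the published rates."""
    rates = {"sbp": 0.20, "hr": 0.18, "gcs": 0.20, "delay_h": 0.06}
    return tr.impose_missingness(complete_cohort, rates, "MAR", seed=23)


def brute_force_auroc(p, y):
    """All-pairs concordance oracle: ties between case and non-case count 1/2."""
    p = np.asarray(p, float)
    y = np.asarray(y)
    cases = p[y == 1]
    controls = p[y == 0]
    total = 0.0
    for c in cases:
        total += np.sum(c > controls) + 0.5 * np.sum(c == controls)
    return total / (len(cases) * len(controls))
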