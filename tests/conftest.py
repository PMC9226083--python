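import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def palmyra_cohort():
    """The packaged default synthetic cohort at its default seed."""
    from coralrec.simulate import default_palmyra_spec, generate

    return generate(default_palmyra_spec())


@pytest.fixture()
def constant_cohort_factory():
    """Cohorts simulated under a single constant-survival taxon."""
    from coralrec.models import ConstantSurvival
    from coralrec.simulate import CohortSpec, TaxonSpec, generate

    def make(s_c=0.8, n=1000, seed=7, window_years=4, consolidated_fraction=0.8,
             dead_fraction=0.51):
        spec = CohortSpec(
            taxa=(TaxonSpec("Simtaxon", n, consolidated_fraction, ConstantSurvival(s_c)),),
            window_years=window_years,
            dead_fraction=dead_fraction,
            seed=seed,
        )
        return generate(spec)

    return make


@pytest.fixture()
def logistic_cohort_factory():
    """Cohorts simulated under a single logistic-survival taxon."""
    from coralrec.models import LogisticSurvival
    from coralrec.simulate import CohortSpec, TaxonSpec, generate

    def make(s=0.95, b=1.2, n=5000, seed=7, window_years=4, consolidated_fraction=0.8):
        spec = CohortSpec(
            taxa=(TaxonSpec("Simtaxon", n, consolidated_fraction, LogisticSurvival(s, b)),),
            window_years=window_years,
            seed=seed,
        )
        return generate(spec)

    return make
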