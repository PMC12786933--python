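import pandas as pd
import pytest

from genestrata.ages import build_ladder, call_ages
from genestrata.simulate import simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, fixed seed, shared across the suite."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return cohort.write(out)


@pytest.fixture(scope="session")
def cohort_calls(cohort):
    return call_ages(cohort.genes, cohort.hits, cohort.lineages, cohort.ladder,
                     self_hits=cohort.self_hits)


@pytest.fixture(scope="session")
def calls_truth(cohort, cohort_calls):
    """Age calls joined to the generator's ground truth, one row per gene."""
    called = pd.DataFrame([vars(c) for c in cohort_calls])
    return called.merge(cohort.truth, on="gene_id", validate="1:1")


@pytest.fixture(scope="session")
def new_ranks(cohort):
    K = cohort.ladder.n_strata
    return set(range(K - 3, K + 1))


@pytest.fixture
def small_ladder():
    """Four-stratum ladder with published anchor ages."""
    lineage = ["cellular_organisms", "Eukaryota", "genus", "species"]
    ages = {"cellular_organisms": 4250.0, "Eukaryota": 1598.0,
            "genus": 35.0, "species": 9.0}
    return build_ladder(lineage, ages)
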