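import pytest

import ntsqbd as nq

ALL_CANDIDATES = [f"X{i}" for i in range(1, 11)] + [f"Z{k}" for k in range(1, 7)]

#: Published term sets of the two CQA screening models.
Y1_TERMS = ["X1", "X9", "X10", "Z5", "Z6"]
Y2_TERMS = ["X1", "Z1", "Z2", "Z4"]

#: Material attributes of the four graded example lots (mg/g).
GRADING_Z = {
    "PN17": {"Z1": 6.55, "Z2": 37.1, "Z4": 35.9, "Z5": 7.19, "Z6": 242},
    "PN18": {"Z1": 8.05, "Z2": 38.7, "Z4": 34.0, "Z5": 7.41, "Z6": 241},
    "PN19": {"Z1": 8.67, "Z2": 51.6, "Z4": 46.8, "Z5": 7.42, "Z6": 312},
    "PN20": {"Z1": 9.09, "Z2": 38.7, "Z4": 32.3, "Z5": 6.43, "Z6": 227},
}


@pytest.fixture(scope="session")
def fixtures():
    return nq.load_fixtures()


@pytest.fixture(scope="session")
def dataset(fixtures):
    return nq.joined_dataset(fixtures)


@pytest.fixture(scope="session")
def fitted_models(fixtures, dataset):
    """Stepwise-selected and augmentation-screened models for both CQAs."""
    models = {}
    for cqa in ("rd_purity", "total_saponin_purity"):
        m = nq.stepwise_fit(dataset, cqa, ALL_CANDIDATES,
                            factors=fixtures.factors)
        models[cqa] = nq.augment_and_refit(m, dataset, fixtures.factors)
    return models
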