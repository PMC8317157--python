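import datetime as dt

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from assaycp import (
    CLASSIFICATION,
    REGRESSION,
    Assay,
    CompoundRecord,
    LabeledDataset,
    Qualifier,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    cid="c1",
    ic50=5.0,
    qualifier=Qualifier.EXACT,
    date=dt.date(2016, 1, 1),
    assay=Assay.OLD,
    features=None,
):
    return CompoundRecord(
        compound_id=cid,
        ic50_um=ic50,
        qualifier=qualifier,
        test_date=date,
        assay=assay,
        features={3: 1, 17: 2} if features is None else features,
    )


def make_regression_dataset(n=40, d=8, seed=0, assay="new"):
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(rng.poisson(1.0, size=(n, d)).astype(float))
    w = rng.normal(size=d)
    y = 5.0 + X @ w / np.sqrt(d) + rng.normal(0, 0.3, size=n)
    return LabeledDataset(
        X=X, y=y, assay_tag=np.full(n, assay, dtype=object), task=REGRESSION
    )


def make_classification_dataset(n=60, d=8, seed=0, assay="new", frac=0.5):
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(rng.poisson(1.0, size=(n, d)).astype(float))
    w = rng.normal(size=d)
    score = np.asarray(X @ w / np.sqrt(d)).ravel()
    thr = np.quantile(score, 1 - frac)
    y = np.where(score + rng.normal(0, 0.2, size=n) >= thr, "A", "N").astype(object)
    # guarantee both classes
    y[0], y[1] = "A", "N"
    return LabeledDataset(
        X=X, y=y, assay_tag=np.full(n, assay, dtype=object), task=CLASSIFICATION
    )


@pytest.fixture
def regression_split():
    ds = make_regression_dataset(n=60, seed=1)
    return ds.subset(np.arange(40)), ds.subset(np.arange(40, 60))


@pytest.fixture
def classification_split():
    ds = make_classification_dataset(n=120, seed=2)
    return ds.subset(np.arange(80)), ds.subset(np.arange(80, 120))
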