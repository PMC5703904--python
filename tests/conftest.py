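import numpy as np
import pytest

from gdmcshm.synthetic_cohort import CohortTable, FeatureSpec


def make_table(values, kinds, labels, names=None):
    """Build a CohortTable from raw arrays for tests."""
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    meta = []
    for name, kind in zip(names, kinds):
        if kind == "binary":
            params = {"p": 0.5}
        elif kind == "continuous":
            params = {"mean": 0.0, "sd": 1.0}
        else:
            params = {"probs": (1 / 3, 1 / 3, 1 / 3)}
        meta.append(FeatureSpec(name, kind, params))
    return CohortTable(values=values, feature_meta=meta, labels=np.asarray(labels, dtype=int))


@pytest.fixture
def toy_discrete_table():
    """60 rows, two 3-level features; f0 is predictive, f1 is noise."""
    rng = np.random.default_rng(11)
    f0 = rng.integers(1, 4, size=60).astype(float)
    f1 = rng.integers(1, 4, size=60).astype(float)
    p = np.where(f0 == 3, 0.85, np.where(f0 == 2, 0.4, 0.1))
    labels = np.where(rng.random(60) < p, 1, -1)
    if np.unique(labels).size < 2:  # pragma: no cover
        labels[0] = -labels[0]
    return make_table(np.column_stack([f0, f1]), ["ordinal3", "ordinal3"], labels)


@pytest.fixture(scope="session")
def separable_2d():
    rng = np.random.default_rng(0)
    n = 80
    X = np.vstack(
        [rng.normal([-2, -2], 0.5, size=(n // 2, 2)), rng.normal([2, 2], 0.5, size=(n // 2, 2))]
    )
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    return make_table(X, ["continuous", "continuous"], y)


@pytest.fixture(scope="session")
def big_complete_cohort():
    """A 50,000-subject fully observed default cohort, shared across the
    large-sample checks (coefficient recovery, masking independence)."""
    from gdmcshm.synthetic_cohort import CohortConfig, default_feature_catalog, generate_cohort

    return generate_cohort(
        CohortConfig(
            n_subjects=50_000,
            features=default_feature_catalog(),
            target_prevalence=0.14,
            seed=20_250_101,
            with_missingness=False,
        )
    )
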