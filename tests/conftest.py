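import numpy as np
import pytest

from phenocomplete import MaskedPhenotypeMatrix, PhenotypeSchema


def make_matrix(
    n=50,
    n_cont=6,
    n_bin=4,
    missing_rate=0.2,
    seed=0,
    prefix="S",
):
    """Random mixed-type matrix with MCAR missingness (test helper)."""
    rng = np.random.default_rng(seed)
    p = n_cont + n_bin
    values = np.empty((n, p))
    values[:, :n_cont] = rng.normal(size=(n, n_cont)) * 3 + 1
    values[:, n_cont:] = rng.integers(0, 2, size=(n, n_bin)).astype(float)
    mask = rng.random((n, p)) >= missing_rate
    values = np.where(mask, values, np.nan)
    schema = PhenotypeSchema(
        names=tuple([f"c{i}" for i in range(n_cont)] + [f"b{i}" for i in range(n_bin)]),
        kinds=tuple(["continuous"] * n_cont + ["binary"] * n_bin),
    )
    return MaskedPhenotypeMatrix(
        ids=tuple(f"{prefix}{i:04d}" for i in range(n)),
        values=values,
        mask=mask,
        schema=schema,
    )


@pytest.fixture
def small_matrix():
    return make_matrix()


@pytest.fixture
def block_matrix():
    """Matrix with two questionnaire-block missingness patterns."""
    rng = np.random.default_rng(7)
    n, p = 400, 8
    values = rng.normal(size=(n, p))
    mask = np.ones((n, p), dtype=bool)
    skip_a = rng.random(n) < 0.4
    skip_b = rng.random(n) < 0.3
    mask[np.ix_(skip_a, range(0, 4))] = False
    mask[np.ix_(skip_b, range(4, 8))] = False
    values = np.where(mask, values, np.nan)
    schema = PhenotypeSchema(
        names=tuple(f"p{i}" for i in range(p)), kinds=("continuous",) * p
    )
    return MaskedPhenotypeMatrix(
        ids=tuple(f"B{i:04d}" for i in range(n)), values=values, mask=mask, schema=schema
    )
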