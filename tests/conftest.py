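import numpy as np
import pytest

from mirdirect import MIRNA, MRNA, ExpressionMatrix


def make_expression(values, n_mirna=1, sample_prefix="S"):
    """Wrap a raw array as an ExpressionMatrix with the first rows as miRNAs."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    ids = [f"miR-{i + 1:03d}" for i in range(n_mirna)] + [
        f"gene-{j + 1:04d}" for j in range(p - n_mirna)
    ]
    kinds = [MIRNA] * n_mirna + [MRNA] * (p - n_mirna)
    return ExpressionMatrix(
        values, ids, kinds, [f"{sample_prefix}{k + 1:04d}" for k in range(n)]
    )


def sample_ggm(omega, n, seed, n_mirna=1):
    """Draw n samples from the zero-mean Gaussian with precision omega."""
    omega = np.asarray(omega, dtype=float)
    cov = np.linalg.inv(omega)
    rng = np.random.default_rng(seed)
    values = np.linalg.cholesky(cov) @ rng.standard_normal((omega.shape[0], n))
    return make_expression(values, n_mirna=n_mirna)


def chain_precision(rho12=0.45, rho23=0.45):
    """Precision matrix of the 3-variable chain X1—X2—X3 (partial(1,3)=0)."""
    return np.array(
        [[1.0, -rho12, 0.0], [-rho12, 1.0, -rho23], [0.0, -rho23, 1.0]]
    )


@pytest.fixture
def chain_expression():
    """n=500 draw from the chain GGM; variable 1 is the miRNA."""
    from mirdirect import standardize

    return standardize(sample_ggm(chain_precision(), n=500, seed=7, n_mirna=1))
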