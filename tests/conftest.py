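import numpy as np
import pytest

import hybridgblup as hg


def marker_matrix(values, locus_ids=None, individual_ids=None):
    """Small MarkerMatrix from a plain nested list (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, q = values.shape
    return hg.MarkerMatrix(
        values=values,
        locus_ids=locus_ids if locus_ids is not None else [f"m{j}" for j in range(q)],
        individual_ids=(
            individual_ids if individual_ids is not None else [f"i{k}" for k in range(n)]
        ),
    )


def hwe_column(p: float, n_copies: int = 1) -> np.ndarray:
    """A dosage column with exact Hardy-Weinberg genotype counts.

    Chooses the smallest population with integer counts n*p^2, 2n*p(1-p),
    n*(1-p)^2 (p must be a multiple of 0.1) and repeats it n_copies times.
    """
    from fractions import Fraction

    fp = Fraction(p).limit_denominator(10)
    n = fp.denominator**2
    n11 = int(n * fp**2)
    nhet = int(2 * n * fp * (1 - fp))
    n22 = n - n11 - nhet
    col = np.array([2.0] * n11 + [1.0] * nhet + [0.0] * n22)
    return np.tile(col, n_copies)


@pytest.fixture(scope="session")
def small_study():
    """One shared small simulated hybrid study (64 hybrids, 5 traits)."""
    return hg.simulate_hybrid_study(
        n_lines=40, n_loci=400, n_per_group=(8, 8), divergence=0.25, seed=11
    )
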