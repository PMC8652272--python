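import numpy as np
import pytest

from usptest import ContingencyTable, eye_colour, marital_education


@pytest.fixture(scope="session")
def marital_table() -> ContingencyTable:
    return marital_education()


@pytest.fixture(scope="session")
def eye_table() -> ContingencyTable:
    return eye_colour()


def exact_usp_and_dhat(counts) -> tuple:
    """U-hat and D-hat in exact rational arithmetic (tie-safe rank oracle)."""
    from fractions import Fraction

    o = [[int(v) for v in row] for row in counts]
    I, J = len(o), len(o[0])
    n = sum(map(sum, o))
    R = [sum(row) for row in o]
    C = [sum(o[i][j] for i in range(I)) for j in range(J)]
    sq = Fraction(0)
    cross = Fraction(0)
    t1 = t2 = t3 = Fraction(0)
    for i in range(I):
        for j in range(J):
            oij = o[i][j]
            e = Fraction(R[i] * C[j], n)
            sq += (oij - e) ** 2
            cross += oij * e
            t1 += oij * (oij - 1)
            t2 += oij * R[i] * C[j] - oij * R[i] - oij * C[j] - oij**2 + 2 * oij
            t3 += (
                R[i] * (R[i] - 1) * C[j] * (C[j] - 1)
                - 4 * oij * (R[i] - 1) * (C[j] - 1)
                + 2 * oij * (oij - 1)
            )
    U = sq / (n * (n - 3)) - 4 * cross / (n * (n - 2) * (n - 3))
    D = (
        t1 / (n * (n - 1))
        - 2 * t2 / (n * (n - 1) * (n - 2))
        + t3 / (n * (n - 1) * (n - 2) * (n - 3))
    )
    return U, D


def random_tables(rng: np.random.Generator, count: int, n_range=(4, 8), max_dim=4):
    """Small random tables: dimensions up to max_dim, totals in n_range."""
    out = []
    for _ in range(count):
        I = int(rng.integers(1, max_dim + 1))
        J = int(rng.integers(1, max_dim + 1))
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        p = rng.dirichlet(np.ones(I * J))
        out.append(ContingencyTable(rng.multinomial(n, p).reshape(I, J)))
    return out
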