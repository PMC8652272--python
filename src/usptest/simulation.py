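"""Simulation designs and Monte-Carlo studies for the independence tests.

Two families of alternatives, distinguished by how the departure from
independence is spread over the table:

* **sparse** — a product base distribution whose cell probability halves
  with every step right or down, p_ij ∝ 2^{−(i+j)}, perturbed by ±ε in the
  top-left 2×2 block only ((1,1) and (2,2) up, (1,2) and (2,1) down, 1-based).
  The perturbation cancels within the affected rows and columns, so the
  marginals are untouched and the dependence measure is D = 4ε².
* **dense** — the uniform distribution on an I×J grid (I, J even) with a
  checkerboard perturbation p_ij = 1/(IJ) + (−1)^{i+j} ε, giving D = IJ ε².

On top of these, the module provides multinomial table sampling and four
study drivers: power/size curves over an ε grid, the sampling distribution
of the dependence estimator D̂, and two studies anchored at an observed
table — parametric resampling from its empirical cell probabilities, and
subsampling m of its n observations without replacement.

Study defaults are desk-scale (reps=500, B=99), chosen so Monte-Carlo
standard errors (reported alongside every proportion) stay near 2% while a
full curve runs in seconds; paper-scale runs (reps=10⁴, B=999) are plain
argument changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import JointDistribution, _dhat_closed_values, dependence_D
from .permutation import ALL_TESTS, PERM_TESTS, batch_pvalues
from .tables import ContingencyTable, PairedSample, SampleSizeError, pairs_from_table, table_from_pairs

__all__ = [
    "DesignSpec",
    "PowerCurve",
    "EstimatorStudy",
    "sparse_null_probs",
    "sparse_alt_probs",
    "dense_alt_probs",
    "design_joint",
    "sample_table",
    "power_study",
    "estimator_study",
    "resample_study",
    "subsample_study",
]

#: default ε grids: 11 points for the sparse design; dense capped so the
#: largest perturbation is half the uniform cell probability.
SPARSE_EPS_GRID = tuple(np.round(np.linspace(0.0, 0.10, 11), 3))


def dense_eps_grid(I: int, J: int, points: int = 11) -> tuple[float, ...]:  # noqa: E741
    return tuple(np.linspace(0.0, 1.0 / (2 * I * J), points))


@dataclass(frozen=True)
class DesignSpec:
    """A named simulation design at one perturbation strength ε."""

    name: str  # 'sparse' | 'dense' | 'custom'
    I: int  # noqa: E741
    J: int
    epsilon: float = 0.0
    probs: np.ndarray | None = None  # for 'custom'

    def joint(self) -> JointDistribution:
        return design_joint(self)


def sparse_null_probs(I: int, J: int) -> JointDistribution:  # noqa: E741
    """Product distribution p_ij = 2^{−(i+j)} / ((1−2^{−I})(1−2^{−J})) (1-based i, j)."""
    if I < 1 or J < 1:
        raise ValueError("need I >= 1 and J >= 1")
    q = 2.0 ** -np.arange(1, I + 1) / (1 - 2.0 ** -I)
    r = 2.0 ** -np.arange(1, J + 1) / (1 - 2.0 ** -J)
    return JointDistribution.product(q, r)


def sparse_alt_probs(I: int, J: int, eps: float) -> JointDistribution:  # noqa: E741
    """Sparse alternative: ±ε perturbation of the top-left 2×2 block.

    Cells (1,1), (2,2) gain ε and (1,2), (2,1) lose ε (1-based), so the
    marginals are unchanged and D = 4ε².
    """
    if I < 2 or J < 2:
        raise ValueError("sparse alternative needs I >= 2 and J >= 2")
    if eps < 0:
        raise ValueError("epsilon must be non-negative")
    p = sparse_null_probs(I, J).probs.copy()
    if eps > min(p[0, 1], p[1, 0]):
        raise ValueError(
            f"epsilon={eps} drives a cell probability negative "
            f"(max admissible {min(p[0, 1], p[1, 0]):.6f})"
        )
    p[0, 0] += eps
    p[1, 1] += eps
    p[0, 1] -= eps
    p[1, 0] -= eps
    return JointDistribution(p)


def dense_alt_probs(I: int, J: int, eps: float) -> JointDistribution:  # noqa: E741
    """Dense alternative: checkerboard p_ij = 1/(IJ) + (−1)^{i+j} ε.

    For even I and J the marginals stay uniform and D = IJ ε².
    """
    if I < 1 or J < 1:
        raise ValueError("need I >= 1 and J >= 1")
    if not 0 <= eps <= 1.0 / (I * J):
        raise ValueError(f"epsilon must lie in [0, 1/(IJ)] = [0, {1.0 / (I * J):.6f}]")
    i = np.arange(1, I + 1)[:, None]
    j = np.arange(1, J + 1)[None, :]
    p = 1.0 / (I * J) + (-1.0) ** (i + j) * eps
    return JointDistribution(p)


def design_joint(design: DesignSpec) -> JointDistribution:
    if design.name == "sparse":
        return sparse_alt_probs(design.I, design.J, design.epsilon)
    if design.name == "dense":
        return dense_alt_probs(design.I, design.J, design.epsilon)
    if design.name == "custom":
        if design.probs is None:
            raise ValueError("custom design needs explicit probs")
        return JointDistribution(design.probs)
    raise ValueError(f"unknown design {design.name!r}")


def sample_table(
    joint: JointDistribution, n: int, seed: int | np.random.Generator | None = None
) -> ContingencyTable:
    """One table of n iid pairs from the joint: a multinomial draw over cells."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = rng.multinomial(n, joint.probs.ravel())
    return ContingencyTable(flat.reshape(joint.probs.shape))


@dataclass(frozen=True)
class PowerCurve:
    """Per-ε, per-test rejection proportions with binomial standard errors."""

    design: str
    n: int
    reps: int
    B: int
    alpha: float
    seed: int | None
    data: pd.DataFrame  # columns: design, epsilon, test, power, se, reps, B, n, alpha


def _rejections_to_frame(
    rows: list[dict], reps: int
) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["se"] = np.sqrt(df["power"] * (1 - df["power"]) / reps)
    return df


def power_study(
    design: str = "sparse",
    epsilons: Sequence[float] | None = None,
    I: int = 5,  # noqa: E741
    J: int = 8,
    n: int = 100,
    reps: int = 500,
    B: int = 99,
    alpha: float = 0.05,
    tests: Sequence[str] = PERM_TESTS,
    seed: int | None = None,
) -> PowerCurve:
    """Estimate rejection probability of each test along an ε grid.

    Each replicate draws a fresh multinomial table and runs every requested
    test on one shared set of B permutations.  At ε = 0 the curve is a size
    study: every permutation test's proportion should sit at or below α (up
    to Monte-Carlo error).
    """
    if epsilons is None:
        epsilons = SPARSE_EPS_GRID if design == "sparse" else dense_eps_grid(I, J)
    unknown = set(tests) - set(ALL_TESTS)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    children = np.random.SeedSequence(seed).spawn(len(epsilons))
    rows: list[dict] = []
    for eps, child in zip(epsilons, children):
        rng = np.random.default_rng(child)
        joint = design_joint(DesignSpec(design, I, J, float(eps)))
        reject = {t: 0 for t in tests}
        for _ in range(reps):
            table = sample_table(joint, n, rng)
            pvals = batch_pvalues(table, tests, B=B, seed=rng)
            for t in tests:
                reject[t] += pvals[t] <= alpha
        for t in tests:
            rows.append(
                dict(design=design, epsilon=float(eps), test=t,
                     power=reject[t] / reps, reps=reps, B=B, n=n, alpha=alpha)
            )
    return PowerCurve(design, n, reps, B, alpha, seed, _rejections_to_frame(rows, reps))


@dataclass(frozen=True)
class EstimatorStudy:
    """Sampling distribution of D̂ along an ε grid (violin-plot data)."""

    design: str
    n: int
    reps: int
    epsilons: tuple[float, ...]
    draws: Mapping[float, np.ndarray]  # per-ε vector of D̂ values
    true_D: Mapping[float, float]

    def summary(self) -> pd.DataFrame:
        rows = []
        for eps in self.epsilons:
            d = self.draws[eps]
            rows.append(
                dict(epsilon=eps, mean=d.mean(), var=d.var(ddof=1),
                     se_mean=d.std(ddof=1) / np.sqrt(d.size),
                     true_D=self.true_D[eps], reps=d.size, n=self.n)
            )
        return pd.DataFrame(rows)


def estimator_study(
    design: str = "sparse",
    epsilons: Sequence[float] | None = None,
    I: int = 5,  # noqa: E741
    J: int = 8,
    n: int = 100,
    reps: int = 2000,
    seed: int | None = None,
) -> EstimatorStudy:
    """Draw reps tables per ε and record D̂ on each (closed form, vectorized)."""
    if n < 4:
        raise SampleSizeError("D-hat needs n >= 4")
    if epsilons is None:
        epsilons = SPARSE_EPS_GRID if design == "sparse" else dense_eps_grid(I, J)
    children = np.random.SeedSequence(seed).spawn(len(epsilons))
    draws: dict[float, np.ndarray] = {}
    true_D: dict[float, float] = {}
    for eps, child in zip(epsilons, children):
        rng = np.random.default_rng(child)
        joint = design_joint(DesignSpec(design, I, J, float(eps)))
        counts = rng.multinomial(n, joint.probs.ravel(), size=reps).reshape(reps, I, J)
        draws[float(eps)] = _dhat_closed_values(counts)
        true_D[float(eps)] = dependence_D(joint)
    return EstimatorStudy(design, n, reps, tuple(float(e) for e in epsilons), draws, true_D)


def resample_study(
    table: ContingencyTable,
    reps: int = 500,
    B: int = 99,
    alpha: float = 0.05,
    seed: int | None = None,
    tests: Sequence[str] = PERM_TESTS,
) -> pd.DataFrame:
    """Parametric resampling anchored at an observed table.

    Treats the empirical cell proportions o_ij/n as a joint distribution,
    repeatedly draws multinomial tables of the same n, and reports how often
    each test rejects at level α.
    """
    n = table.n
    if n < 4:
        raise SampleSizeError("resampling study needs n >= 4")
    joint = JointDistribution(table.counts / n)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reject = {t: 0 for t in tests}
    for _ in range(reps):
        t_obs = sample_table(joint, n, rng)
        pvals = batch_pvalues(t_obs, tests, B=B, seed=rng)
        for t in tests:
            reject[t] += pvals[t] <= alpha
    rows = [dict(test=t, power=reject[t] / reps, reps=reps, B=B, n=n, alpha=alpha)
            for t in tests]
    return _rejections_to_frame(rows, reps)


def subsample_study(
    table: ContingencyTable,
    m: int,
    reps: int = 500,
    B: int = 99,
    alpha: float = 0.05,
    seed: int | None = None,
    tests: Sequence[str] = PERM_TESTS,
    replace: bool = True,
) -> pd.DataFrame:
    """Draw m of the table's n observations uniformly at random,
    re-tabulate, and report each test's rejection proportion at level α.

    By default the m observations are drawn with replacement, i.e. iid from
    the empirical cell distribution (equivalently a multinomial table of
    size m on the empirical proportions).  ``replace=False`` draws a true
    without-replacement subsample instead; its tables are hypergeometrically
    concentrated around the scaled-down original, which measurably lowers
    every test's rejection rate relative to the iid reading (see the methods
    note).
    """
    n = table.n
    if not 4 <= m <= n:
        raise ValueError(f"m must lie in [4, n={n}], got {m}")
    sample = pairs_from_table(table)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reject = {t: 0 for t in tests}
    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=replace)
        sub = PairedSample(sample.x[idx], sample.y[idx], sample.I, sample.J)
        pvals = batch_pvalues(table_from_pairs(sub), tests, B=B, seed=rng)
        for t in tests:
            reject[t] += pvals[t] <= alpha
    rows = [dict(test=t, power=reject[t] / reps, reps=reps, B=B, n=m, alpha=alpha)
            for t in tests]
    return _rejections_to_frame(rows, reps)
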