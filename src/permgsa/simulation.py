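"""Synthetic expression/phenotype generator and type-I-error/power harness.

One simulated gene set of size ``p`` is drawn per replicate: per-gene means
from U(0, 10) and variances from U(1, 5), rows of the n x p expression
matrix i.i.d. multivariate normal with a mixed intra-set correlation
structure

    rho_ij = rho          for 1 <= i != j <= p1        (compound symmetry),
    rho_ij = rho^|i-j|    for p1+1 <= i != j <= 2p1     (AR(1)),
    rho_ij = 0            otherwise,

and a continuous phenotype Y = X mu + eps (linear) or Y = exp(X mu) + eps
(nonlinear) with standard normal noise.  Under the null mu = 0.  Under the
alternative, 5 of the first 20 components of mu are drawn from N(nu, |nu|)
and 5 of components 21-40 from N(-nu, |nu|) (mean, standard deviation), the
rest 0 — ten truly associated genes, half up- and half downregulated.

``rejection_rate`` runs replicates of any permutation test callable and
returns the fraction rejecting at the nominal level, which estimates type I
error (nu = 0) or power (nu > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulationScenario",
    "correlation_matrix",
    "simulate_expression",
    "draw_effect_vector",
    "simulate_phenotype",
    "rejection_rate",
    "rf_test_callable",
]


@dataclass
class SimulationScenario:
    """One cell of the simulation design.

    Defaults mirror the study conditions: 1000 replicates x 1000
    permutations x 500 trees at nominal alpha = 0.05.  ``reduced()`` gives
    the 200 x 200 x 100 scale used for routine checks.
    """

    n: int = 10
    p: int = 20
    p1: int = 5
    rho: float = 0.0
    nu: float = 0.0
    link: str = "linear"
    n_reps: int = 1000
    nb_perm: int = 1000
    n_trees: int = 500
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if 2 * self.p1 > self.p:
            raise ValueError("need 2 * p1 <= p for the two correlated blocks")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.link not in ("linear", "nonlinear"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.nu != 0 and self.p < 40:
            raise ValueError("the alternative model places effects in genes 1-40; need p >= 40")

    def reduced(self) -> "SimulationScenario":
        return SimulationScenario(
            n=self.n, p=self.p, p1=self.p1, rho=self.rho, nu=self.nu, link=self.link,
            n_reps=200, nb_perm=200, n_trees=100, alpha=self.alpha, seed=self.seed,
        )


def correlation_matrix(p: int, p1: int, rho: float) -> np.ndarray:
    """Mixed compound-symmetry / AR(1) / independent correlation matrix."""
    if 2 * p1 > p:
        raise ValueError("need 2 * p1 <= p")
    R = np.eye(p)
    # compound symmetry over genes 0..p1-1 (1-based 1..p1)
    R[:p1, :p1] = rho
    # AR(1) over genes p1..2p1-1
    for i in range(p1, 2 * p1):
        for j in range(p1, 2 * p1):
            if i != j:
                R[i, j] = rho ** abs(i - j)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_expression(scenario: SimulationScenario, rng: np.random.Generator | None = None) -> np.ndarray:
    """One n x p expression matrix with U(0,10) means and U(1,5) variances."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    means = rng.uniform(0.0, 10.0, size=scenario.p)
    variances = rng.uniform(1.0, 5.0, size=scenario.p)
    R = correlation_matrix(scenario.p, scenario.p1, scenario.rho)
    sd = np.sqrt(variances)
    cov = R * np.outer(sd, sd)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(scenario.p))
    Z = rng.standard_normal(size=(scenario.n, scenario.p))
    return means + Z @ L.T


def draw_effect_vector(p: int, nu: float, rng_or_seed=None) -> np.ndarray:
    """Effect vector mu: zero under the null; ten nonzero effects otherwise.

    Five positions uniformly chosen among genes 1-20 get N(nu, |nu|) draws
    and five among genes 21-40 get N(-nu, |nu|) (mean, SD parameterisation).
    """
    if nu < 0:
        raise ValueError("nu must be nonnegative")
    mu = np.zeros(p)
    if nu == 0:
        return mu
    if p < 40:
        raise ValueError("effect placement needs p >= 40 when nu != 0")
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) else np.random.default_rng(rng_or_seed)
    up = rng.choice(20, size=5, replace=False)
    down = 20 + rng.choice(20, size=5, replace=False)
    mu[up] = rng.normal(nu, abs(nu), size=5)
    mu[down] = rng.normal(-nu, abs(nu), size=5)
    return mu


def simulate_phenotype(X: np.ndarray, mu: np.ndarray, link: str = "linear",
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Y = X mu + eps (linear) or exp(X mu) + eps (nonlinear), eps ~ N(0, I)."""
    rng = np.random.default_rng() if rng is None else rng
    X = np.asarray(X, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if X.shape[1] != len(mu):
        raise ValueError("effect vector length must match the gene count")
    eta = X @ mu
    if link == "nonlinear":
        with np.errstate(over="raise"):
            try:
                eta = np.exp(eta)
            except FloatingPointError:
                raise ValueError("overflow in exp(X mu); scale the effects down") from None
    elif link != "linear":
        raise ValueError(f"unknown link {link!r}")
    return eta + rng.standard_normal(len(eta))


def rf_test_callable(scenario: SimulationScenario):
    """The default method under evaluation: the continuous-phenotype RF test."""
    from .data_model import Phenotype
    from .rf import RFConfig, rf_permutation_pvalue

    def test(X: np.ndarray, Y: np.ndarray, seed: int) -> float:
        cfg = RFConfig(
            n_trees=scenario.n_trees,
            nb_perm=scenario.nb_perm,
            phenotype_type="continuous",
            seed=seed,
        )
        return rf_permutation_pvalue(X, Phenotype("continuous", Y), cfg).pvalue

    return test


def rejection_rate(method, scenario: SimulationScenario) -> float:
    """Fraction of replicates with permutation P <= alpha.

    ``method`` is either ``"rf"`` (the random-forest regression test) or a
    callable ``(X, Y, seed) -> pvalue``.  Every replicate draws a fresh
    expression matrix, effect vector and phenotype from seed-derived
    substreams, so the estimate is fully reproducible.
    """
    test = rf_test_callable(scenario) if method == "rf" else method
    root = np.random.SeedSequence(0 if scenario.seed is None else scenario.seed)
    rejections = 0
    for rep, child in enumerate(root.spawn(scenario.n_reps)):
        data_ss, test_ss = child.spawn(2)
        rng = np.random.default_rng(data_ss)
        X = simulate_expression(scenario, rng=rng)
        mu = draw_effect_vector(scenario.p, scenario.nu, rng)
        Y = simulate_phenotype(X, mu, scenario.link, rng=rng)
        p = test(X, Y, int(test_ss.generate_state(1)[0] % (2**31)))
        if p <= scenario.alpha:
            rejections += 1
    return rejections / scenario.n_reps
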