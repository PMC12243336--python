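"""Genetic-algorithm wavelength selection for PLS calibration.

Two fitness flavours over binary wavelength-inclusion chromosomes:

* **GA-PLS** — penalized cross-validation error,
  ``RMSECV + lambda * k / p`` with ``lambda = 0.05`` by default, where k
  is the number of selected wavelengths out of p.  The penalty form
  (normalised count) keeps lambda scale-free.  Run with multiple random
  restarts, keeping the restart with the lowest fitness.
* **GA-ICOMP-PLS** — the information-complexity criterion
  ``ICOMP = -2 log L + 2 C(Sigma)`` evaluated on the leave-one-out
  residual covariance of the masked PLS model, so the criterion scores
  generalisation error and penalises non-spherical (collinear) residual
  structure.  ``C`` is Bozdogan's C1 covariance complexity.

The GA itself is generational with size-2 tournament selection, uniform
crossover, per-bit mutation and elitism of 1, so the best-so-far fitness
is non-increasing.  Chromosome bits may address single wavelengths or
contiguous spectral windows (``window_size > 1``).  The initial
population holds random 50%-density masks plus one all-ones chromosome,
guaranteeing the full-spectrum baseline is in the search space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pls import PLSModel, fit_pls, loo_residuals

__all__ = [
    "Chromosome",
    "GAConfig",
    "ICOMPScore",
    "GAHistory",
    "penalized_fitness",
    "icomp_score",
    "run_ga",
    "ga_pls",
    "ga_icomp_pls",
]


@dataclass(frozen=True)
class Chromosome:
    """Binary inclusion mask with its fitness (lower is better)."""

    mask: np.ndarray
    fitness: float


@dataclass(frozen=True)
class GAConfig:
    population: int = 30
    generations: int = 50
    mutation_rate: float = 0.01
    crossover: str = "uniform"
    elitism: int = 1
    penalty_lambda: float = 0.05
    window_size: int = 1
    n_lv: int = 5
    seed: int = 0
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.crossover != "uniform":
            raise ValueError(f"unsupported crossover {self.crossover!r}")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must be in [0, population)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class ICOMPScore:
    """ICOMP = -2 log L + 2 C1(Sigma) on a residual covariance."""

    minus2_loglik: float
    complexity: float
    total: float
    residual_cov: np.ndarray
    ridged: bool = False


@dataclass(frozen=True)
class GAHistory:
    """Per-generation best fitness, mean fitness and mean selected count."""

    best: np.ndarray
    mean: np.ndarray
    mean_selected: np.ndarray


# ---------------------------------------------------------------------------
# Fitness functions
# ---------------------------------------------------------------------------

def penalized_fitness(mask, X, Y, n_lv: int, penalty_lambda: float = 0.05) -> float:
    """Penalized GA-PLS fitness: RMSECV(masked PLS) + lambda * k / p."""
    mask = np.asarray(mask, dtype=bool)
    if penalty_lambda < 0:
        raise ValueError("penalty_lambda must be >= 0")
    if not mask.any():
        raise ValueError("mask selects no wavelengths")
    if int(mask.sum()) < n_lv:
        raise ValueError(
            f"mask selects {int(mask.sum())} wavelengths, fewer than "
            f"{n_lv} latent variables"
        )
    res = loo_residuals(X, Y, n_lv, mask=mask)
    rmsecv = float(np.sqrt(np.mean(res**2)))
    return rmsecv + penalty_lambda * mask.sum() / mask.size


def icomp_score(residuals: np.ndarray, ridge: float = 1e-12) -> ICOMPScore:
    """Information complexity of a residual block (n x q).

    Sigma = E'E/n (profiled Gaussian MLE);
    -2 log L = n q ln(2 pi) + n ln det Sigma + n q;
    C1(Sigma) = (q/2) ln(tr Sigma / q) - (1/2) ln det Sigma, which is zero
    iff Sigma is spherical (arithmetic-geometric mean equality on the
    eigenvalues) and strictly positive otherwise.
    """
    E = np.atleast_2d(np.asarray(residuals, float))
    n, q = E.shape
    if n <= q:
        raise ValueError(f"need more residual rows ({n}) than responses ({q})")
    if not np.all(np.isfinite(E)):
        raise ValueError("residuals contain non-finite entries")
    sigma = E.T @ E / n
    eig = np.linalg.eigvalsh(sigma)
    ridged = False
    if eig.min() <= 0:
        sigma = sigma + ridge * np.eye(q)
        eig = eig + ridge
        ridged = True
        if eig.min() <= 0:
            raise np.linalg.LinAlgError("residual covariance is singular")
    logdet = float(np.sum(np.log(eig)))
    minus2ll = n * q * np.log(2 * np.pi) + n * logdet + n * q
    complexity = (q / 2.0) * np.log(eig.mean()) - 0.5 * logdet
    complexity = max(float(complexity), 0.0)
    total = minus2ll + 2.0 * complexity
    return ICOMPScore(float(minus2ll), complexity, float(total), sigma, ridged)


# ---------------------------------------------------------------------------
# GA engine
# ---------------------------------------------------------------------------

def _expand_mask(bits: np.ndarray, n_vars: int, window: int) -> np.ndarray:
    """Expand window-level bits to a per-wavelength boolean mask."""
    if window == 1:
        return bits.astype(bool)
    return np.repeat(bits.astype(bool), window)[:n_vars]


def run_ga(fitness, n_vars: int, config: GAConfig):
    """Generic binary GA minimising *fitness(mask)*.

    *fitness* receives a boolean mask over the n_vars wavelengths and
    returns a scalar (lower is better).  Returns
    ``(best: Chromosome, history: GAHistory)``.  Reproducible from
    ``config.seed``; with elitism >= 1 the best-so-far fitness is
    monotone non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    window = config.window_size
    n_bits = -(-n_vars // window)  # ceil; last window may truncate
    pop_n = config.population

    def repair(bits: np.ndarray) -> np.ndarray:
        if not bits.any():
            bits = bits.copy()
            bits[rng.integers(n_bits)] = True
        return bits

    cache: dict[bytes, float] = {}

    def score(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = float(fitness(_expand_mask(bits, n_vars, window)))
        return cache[key]

    # initial population: 50%-density random masks + one all-ones chromosome
    pop = [repair(rng.random(n_bits) < 0.5) for _ in range(pop_n - 1)]
    pop.append(np.ones(n_bits, dtype=bool))
    fits = np.array([score(b) for b in pop])

    best_hist = np.empty(config.generations + 1)
    mean_hist = np.empty(config.generations + 1)
    k_hist = np.empty(config.generations + 1)

    def record(g):
        best_hist[g] = fits.min()
        mean_hist[g] = fits.mean()
        k_hist[g] = np.mean(
            [_expand_mask(b, n_vars, window).sum() for b in pop]
        )

    record(0)
    for g in range(1, config.generations + 1):
        order = np.argsort(fits, kind="stable")
        elite = [pop[i].copy() for i in order[: config.elitism]]
        children = list(elite)
        while len(children) < pop_n:
            # size-2 tournament selection for each parent
            picks = rng.integers(pop_n, size=4)
            pa = pop[picks[0]] if fits[picks[0]] <= fits[picks[1]] else pop[picks[1]]
            pb = pop[picks[2]] if fits[picks[2]] <= fits[picks[3]] else pop[picks[3]]
            swap = rng.random(n_bits) < 0.5  # uniform crossover
            child = np.where(swap, pa, pb)
            flip = rng.random(n_bits) < config.mutation_rate
            child = repair(child ^ flip)
            children.append(child)
        pop = children
        fits = np.array([score(b) for b in pop])
        record(g)
    ibest = int(np.argmin(fits))
    best = Chromosome(_expand_mask(pop[ibest], n_vars, window), float(fits[ibest]))
    return best, GAHistory(best_hist, mean_hist, k_hist)


# ---------------------------------------------------------------------------
# Wavelength-selection front ends
# ---------------------------------------------------------------------------

def _n_vars_of(X) -> int:
    arr = X.absorbance if hasattr(X, "absorbance") else np.atleast_2d(X)
    return arr.shape[1]


def ga_pls(X, Y, config: GAConfig = GAConfig(generations=100)):
    """Penalized-RMSECV GA wavelength selection with multiple restarts.

    Returns ``(best: Chromosome, histories: list[GAHistory])`` where the
    best chromosome has the lowest penalized cross-validated fitness over
    all restarts (restart seeds derive from ``config.seed``).
    """
    n_vars = _n_vars_of(X)

    def fitness(mask):
        return penalized_fitness(mask, X, Y, config.n_lv, config.penalty_lambda)

    best = None
    histories = []
    for r in range(config.n_restarts):
        cfg = replace(config, seed=config.seed + r)
        cand, hist = run_ga(fitness, n_vars, cfg)
        histories.append(hist)
        if best is None or cand.fitness < best.fitness:
            best = cand
    return best, histories


def ga_icomp_pls(X, Y, config: GAConfig = GAConfig()):
    """GA variable selection scored by ICOMP on leave-one-out residuals.

    Returns ``(best: Chromosome, score: ICOMPScore, model: PLSModel)``:
    the winning mask, its ICOMP decomposition, and the PLS model refitted
    on the selected wavelengths.  Because the all-ones chromosome seeds
    the population under elitism, the returned ICOMP never exceeds the
    full-spectrum ICOMP on the same data.
    """
    n_vars = _n_vars_of(X)

    def fitness(mask):
        if int(mask.sum()) < config.n_lv:
            return np.inf  # undersized masks cannot support the fixed LV count
        res = loo_residuals(X, Y, config.n_lv, mask=mask)
        return icomp_score(res).total

    best, _history = None, None
    for r in range(config.n_restarts):
        cfg = replace(config, seed=config.seed + r)
        cand, hist = run_ga(fitness, n_vars, cfg)
        if best is None or cand.fitness < best.fitness:
            best, _history = cand, hist
    score = icomp_score(loo_residuals(X, Y, config.n_lv, mask=best.mask))
    model = fit_pls(X, Y, config.n_lv, mask=best.mask)
    return best, score, model
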