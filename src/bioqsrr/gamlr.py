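"""Genetic-algorithm descriptor-subset selection with OLS regression.

Candidate models are encoded as binary inclusion chromosomes over the
descriptor columns ('1' = included).  Each generation the fittest model
is retained (elitism) and the rest of the population is rebuilt by
tournament selection, uniform crossover and per-gene mutation, with a
repair step that keeps the selected-descriptor count at the configured
subset size.  Fitness defaults to the leave-one-out cross-validated
coefficient of determination (Q2_LOO) of the candidate OLS model, which
penalises overfit subsets on small compound sets; plain training R2 is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DescriptorMatrix, GAConfig, QSRRModel
from .validation import loo_q2, regression_metrics

__all__ = ["Chromosome", "fit_mlr", "predict", "ga_select", "crossover", "mutate"]


@dataclass(frozen=True)
class Chromosome:
    """Binary descriptor-inclusion mask."""

    mask: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(g not in (0, 1) for g in self.mask):
            raise ValueError("mask genes must be 0 or 1")

    def __len__(self) -> int:
        return len(self.mask)

    @property
    def n_selected(self) -> int:
        return sum(self.mask)

    @property
    def selected_indices(self) -> tuple[int, ...]:
        return tuple(i for i, g in enumerate(self.mask) if g)


def _as_frame(X, descriptor_names=None) -> pd.DataFrame:
    if isinstance(X, DescriptorMatrix):
        return X.frame
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    names = descriptor_names or [f"x{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=list(names))


def fit_mlr(X_sub, y, endpoint_name: str = "y", descriptor_names=None) -> QSRRModel:
    """Ordinary-least-squares fit of y on the supplied descriptor columns.

    Parameters
    ----------
    X_sub : DescriptorMatrix, DataFrame or 2-D array
        Descriptor values for the selected subset (no intercept column).
    y : array-like
        Response (a chromatographic index) aligned with the rows.
    endpoint_name : str
        Name recorded on the returned model.
    descriptor_names : sequence of str, optional
        Names for array input.

    Raises
    ------
    ValueError
        If n <= p + 1 (under-determined) or the intercept-augmented
        design is rank deficient (singular fit).
    """
    df = _as_frame(X_sub, descriptor_names)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = df.shape
    if yv.size != n:
        raise ValueError(f"response length {yv.size} does not match {n} rows")
    if n <= p + 1:
        raise ValueError(f"under-determined fit: n={n} rows for p={p} descriptors (need n > p+1)")
    design = np.column_stack([np.ones(n), df.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        raise ValueError("singular fit: design matrix (with intercept) is rank deficient")
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    fitted = design @ beta
    return QSRRModel(
        endpoint_name=endpoint_name,
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(df.columns, beta[1:])},
        training_ids=list(df.index) if isinstance(X_sub, (DescriptorMatrix, pd.DataFrame)) else None,
        fitted_values=fitted,
    )


def predict(model: QSRRModel, x):
    """Evaluate a model at descriptor vector(s); see QSRRModel.predict."""
    if isinstance(x, dict):
        return model.predict_one(x)
    return model.predict(x)


def _repair(mask: np.ndarray, subset_size: int, rng: np.random.Generator) -> np.ndarray:
    """Force the number of selected genes to subset_size, choices seeded."""
    mask = mask.copy()
    on = np.flatnonzero(mask)
    if on.size > subset_size:
        off = rng.choice(on, size=on.size - subset_size, replace=False)
        mask[off] = 0
    elif on.size < subset_size:
        zeros = np.flatnonzero(mask == 0)
        add = rng.choice(zeros, size=subset_size - on.size, replace=False)
        mask[add] = 1
    return mask


def crossover(
    parent_a: Chromosome,
    parent_b: Chromosome,
    rng: np.random.Generator,
    subset_size: int | None = None,
) -> Chromosome:
    """Uniform crossover: each gene drawn from one parent at random."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal mask lengths")
    a = np.array(parent_a.mask)
    b = np.array(parent_b.mask)
    take_a = rng.random(a.size) < 0.5
    child = np.where(take_a, a, b)
    if subset_size is not None:
        child = _repair(child, subset_size, rng)
    return Chromosome(tuple(int(g) for g in child))


def mutate(
    c: Chromosome,
    rate: float,
    rng: np.random.Generator,
    subset_size: int | None = None,
) -> Chromosome:
    """Flip each gene independently with probability ``rate``, then repair."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("mutation rate must be in [0, 1]")
    mask = np.array(c.mask)
    flips = rng.random(mask.size) < rate
    mask = np.where(flips, 1 - mask, mask)
    if subset_size is not None:
        mask = _repair(mask, subset_size, rng)
    return Chromosome(tuple(int(g) for g in mask))


def _fitness(df: pd.DataFrame, y: np.ndarray, mask: tuple[int, ...], kind: str) -> float:
    cols = [c for c, g in zip(df.columns, mask) if g]
    Xs = df[cols].to_numpy()
    design = np.column_stack([np.ones(len(y)), Xs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return -np.inf
    if kind == "q2_loo":
        try:
            return loo_q2(Xs, y)[1]
        except (ValueError, np.linalg.LinAlgError):
            return -np.inf
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    r2, _ = regression_metrics(y, design @ beta)
    return r2


def ga_select(
    X, y, config: GAConfig, endpoint_name: str = "y"
) -> tuple[Chromosome, QSRRModel, np.ndarray]:
    """Search descriptor subsets of fixed size by a genetic algorithm.

    Returns the best-ever chromosome, the OLS model refit on that subset
    over all supplied rows, and the best-so-far fitness trace (one entry
    per generation, monotone non-decreasing).  Fully reproducible from
    ``config.seed``.
    """
    df = _as_frame(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = df.shape
    k = config.subset_size
    if p < k:
        raise ValueError(f"{p} descriptors available but subset_size={k}")
    rng = np.random.default_rng(config.seed)

    cache: dict[tuple[int, ...], float] = {}

    def fit_of(mask: tuple[int, ...]) -> float:
        if mask not in cache:
            cache[mask] = _fitness(df, yv, mask, config.fitness_name)
        return cache[mask]

    def random_mask() -> tuple[int, ...]:
        idx = rng.choice(p, size=k, replace=False)
        m = np.zeros(p, dtype=int)
        m[idx] = 1
        return tuple(int(g) for g in m)

    population = [Chromosome(random_mask()) for _ in range(config.population_size)]
    scores = [fit_of(c.mask) for c in population]
    best_i = int(np.argmax(scores))
    best, best_score = population[best_i], scores[best_i]
    trace = np.empty(config.generations, dtype=float)

    if p == k:  # only one possible subset; nothing to evolve
        trace[:] = best_score
    else:
        for gen in range(config.generations):
            order = np.argsort(scores)[::-1]
            elite = [population[i] for i in order[: config.elitism_count]]
            children = list(elite)
            while len(children) < config.population_size:
                # tournament of 2 per parent
                ia, ib = rng.integers(config.population_size, size=2)
                pa = population[ia] if scores[ia] >= scores[ib] else population[ib]
                ia, ib = rng.integers(config.population_size, size=2)
                pb = population[ia] if scores[ia] >= scores[ib] else population[ib]
                child = crossover(pa, pb, rng, subset_size=k)
                child = mutate(child, config.mutation_rate, rng, subset_size=k)
                children.append(child)
            population = children
            scores = [fit_of(c.mask) for c in population]
            gen_best = int(np.argmax(scores))
            if scores[gen_best] > best_score:
                best, best_score = population[gen_best], scores[gen_best]
            trace[gen] = best_score

    selected = [c for c, g in zip(df.columns, best.mask) if g]
    model = fit_mlr(df[selected], yv, endpoint_name=endpoint_name)
    model.fit_meta.update(
        seed=config.seed,
        ga_config_hash=config.config_hash(),
        fitness_name=config.fitness_name,
        best_fitness=float(best_score),
    )
    return best, model, trace
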