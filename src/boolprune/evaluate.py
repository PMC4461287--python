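"""Validation protocols for contextualized networks.

Three protocols quantify what optimization buys over the prior network:

* repeated random sub-sampling cross-validation — optimize on a random
  training subset of the measured genes, then score every network of the
  final population on the full gene profile (prediction of the held-out
  expression values);
* comparison of optimized against random-search populations with Welch's
  unequal-variance t-test;
* sensitivity analyses — re-run the optimization with the phenotype
  information of chosen genes either withheld (missing) or bit-flipped
  (wrong), and score the resulting populations against the original,
  uncorrupted phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .fitness import score_subnetwork
from .network import PhenotypeSet, SignedDigraph
from .optimize import (
    OptimizationConfig,
    OptimizationResult,
    optimize,
    random_search_baseline,
)


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic per-task seed below 2**31 derived from a root seed."""
    ss = np.random.SeedSequence([seed, *key])
    return int(ss.generate_state(1)[0] % (2**31))


def split_genes(
    genes: Iterable[str], train_size: int, rng: np.random.Generator
) -> tuple[frozenset[str], frozenset[str]]:
    """Uniform random training/validation split of the measured genes."""
    ordered = sorted(set(genes))
    if not (1 <= train_size <= len(ordered)):
        raise ValueError(
            f"train_size must be in [1, {len(ordered)}], got {train_size}"
        )
    idx = rng.choice(len(ordered), size=train_size, replace=False)
    training = frozenset(ordered[i] for i in idx)
    validation = frozenset(ordered) - training
    return training, validation


@dataclass
class SplitRecord:
    split: int
    training_genes: frozenset[str]
    validation_genes: frozenset[str]
    scores: list[float]  # final population scored on ALL genes
    training_scores: list[float]  # the fitness seen by the optimizer


@dataclass
class CrossValRun:
    """Pooled prediction scores for one training-set size."""

    train_size: int
    splits: list[SplitRecord]

    @property
    def scores(self) -> list[float]:
        return [s for rec in self.splits for s in rec.scores]

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative frequency curve of the pooled scores."""
        xs = np.sort(np.asarray(self.scores))
        ys = np.arange(1, len(xs) + 1) / len(xs)
        return xs, ys


def _evaluate_population(
    result: OptimizationResult,
    pkn: SignedDigraph,
    phenotypes: PhenotypeSet,
    config: OptimizationConfig,
) -> list[float]:
    """Score every final-population network on the full gene profile."""
    return [
        score_subnetwork(
            pkn,
            net,
            phenotypes,
            init_fill=config.init_fill,
            max_steps=config.max_steps,
            inputs_hold_state=config.inputs_hold_state,
        ).f
        for net, _ in result.final_population
    ]


def cross_validate(
    pkn: SignedDigraph,
    phenotypes: PhenotypeSet,
    train_sizes: Sequence[int],
    n_splits: int = 10,
    config: OptimizationConfig | None = None,
    baseline: bool = False,
) -> list[CrossValRun]:
    """Repeated random sub-sampling cross-validation.

    For each training size, draws ``n_splits`` independent splits, runs one
    optimization per split on the training genes only, and pools the
    full-profile prediction scores of the final populations (so each size
    yields ``population_size * n_splits`` scores).  ``baseline=True`` runs
    the elitist random search instead of the distribution-sampling
    optimizer, for comparison under identical budgets and seeds.
    """
    config = config or OptimizationConfig()
    universe = sorted(phenotypes.genes & pkn.nodes)
    runs: list[CrossValRun] = []
    search = random_search_baseline if baseline else optimize
    for size_idx, size in enumerate(train_sizes):
        records: list[SplitRecord] = []
        for split in range(n_splits):
            split_rng = np.random.default_rng(
                _child_seed(config.seed, 1, size_idx, split)
            )
            training, validation = split_genes(universe, size, split_rng)
            run_config = replace(
                config, seed=_child_seed(config.seed, 2, size_idx, split)
            )
            result = search(pkn, phenotypes, training, run_config)
            full_scores = _evaluate_population(result, pkn, phenotypes, run_config)
            records.append(
                SplitRecord(
                    split=split,
                    training_genes=training,
                    validation_genes=validation,
                    scores=full_scores,
                    training_scores=result.population_scores(),
                )
            )
        runs.append(CrossValRun(train_size=size, splits=records))
    return runs


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def compare_to_baseline(
    optimized_scores: Sequence[float], baseline_scores: Sequence[float]
) -> WelchResult:
    """Two-sided Welch's t-test between two score populations.

    Degenerate inputs (both samples with zero variance) are resolved by the
    limits of the statistic: equal means give p = 1, different means p = 0.
    """
    a = np.asarray(optimized_scores, dtype=float)
    b = np.asarray(baseline_scores, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if math.isclose(a.mean(), b.mean()):
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return WelchResult(
            t=sign * math.inf, df=float(len(a) + len(b) - 2), p=0.0
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def sensitivity_missing(
    pkn: SignedDigraph,
    phenotypes: PhenotypeSet,
    removed: Iterable[str],
    config: OptimizationConfig | None = None,
) -> list[float]:
    """Optimize with chosen genes' phenotype information withheld.

    The removed genes are excluded from the training signal and their
    initial states fall back to the fill policy; the returned distribution
    scores the final population against the complete original phenotypes.
    """
    config = config or OptimizationConfig()
    removed = frozenset(removed)
    universe = phenotypes.genes & pkn.nodes
    if not removed <= phenotypes.genes:
        raise ValueError("removed genes must be phenotype genes")
    kept = universe - removed
    if not kept:
        raise ValueError("cannot withhold every measured gene")
    reduced = phenotypes.restricted(phenotypes.genes - removed)
    result = optimize(pkn, reduced, kept, config)
    return _evaluate_population(result, pkn, phenotypes, config)


def sensitivity_wrong(
    pkn: SignedDigraph,
    phenotypes: PhenotypeSet,
    flipped: Iterable[str],
    config: OptimizationConfig | None = None,
) -> list[float]:
    """Optimize with chosen genes' phenotype states bit-flipped.

    The corrupted states drive both the training signal and the initial
    conditions; the returned distribution scores the final population
    against the original, uncorrupted phenotypes.
    """
    config = config or OptimizationConfig()
    flipped = frozenset(flipped)
    if not flipped <= phenotypes.genes:
        raise ValueError("flipped genes must be phenotype genes")
    corrupted = phenotypes.flipped(flipped)
    universe = phenotypes.genes & pkn.nodes
    result = optimize(pkn, corrupted, universe, config)
    return _evaluate_population(result, pkn, phenotypes, config)
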