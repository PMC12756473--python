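"""Sparrow search over filter-bank configurations.

The sparrow search algorithm (SSA) is a population metaheuristic with
three behavioral roles: *producers* explore globally, *followers* exploit
around the best solution, and *watchers* inject perturbation that guards
against premature convergence. Here each individual encodes a candidate
filter bank as a flat vector of ``2 n_bands`` frequency edges in Hz, and
its fitness is the mean cross-validated accuracy of the full filter-bank
CSP + classifier pipeline under that bank.

Update rules (position ``x``, iteration ``t`` of ``T``):

* producer: ``x * exp(-t / (alpha T))`` while the warning draw ``R2`` is
  below the safety threshold ``ST`` (shrinking step, coarse-to-fine),
  otherwise ``x + Q`` with a scalar standard-normal ``Q`` (escape jump);
* follower (improved): ``x + step * (x_best - x) + Q`` with a
  per-coordinate step ``R exp(-j/dim) + beta_explore (1 - t/T)`` — an
  exponentially decaying pull toward the best individual plus a
  per-coordinate Gaussian perturbation;
* watcher (improved): for a non-best individual,
  ``x_best + beta |x - x_best| + noise`` with standard-normal ``beta`` and
  damped Gaussian ``noise ~ (1 - t/T) N(0, sigma^2)``, ``sigma`` the width
  of the whole search range; the current best individual is instead kicked
  by ``K (x - x_best) / (|f_i - f_w| + eps)``.

The classic follower/watcher rules of the original SSA are available
behind ``use_classic_follower`` / ``use_classic_watcher`` for ablation.

After every update a total *repair* step projects the position back into
the feasible set (ordered edges, clipped to [f_min, f_max], minimum band
width, bands sorted by low edge), so every vector handed to the fitness
evaluator decodes to a valid bank. The best solution ever evaluated is
retained across iterations (elitism), making the fitness history monotone
non-decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .containers import EpochSet
from .csp import _binary_problems, _normalized_mean_cov, _trial_covariances, fit_csp
from .exceptions import ConfigurationError
from .filterbank import (
    FilterBank,
    bank_from_position,
    filter_array,
    make_uniform_bank,
    position_from_bank,
)
from .metrics import accuracy, fit_classifier, predict

__all__ = [
    "SSAConfig",
    "Population",
    "OptimizationResult",
    "FitnessEvaluator",
    "repair",
    "producer_update",
    "follower_update",
    "watcher_update",
    "init_population",
    "evaluate_fitness",
    "optimize",
    "ALL_ROLES",
]

ALL_ROLES = frozenset({"producers", "followers", "watchers"})


@dataclass(frozen=True)
class SSAConfig:
    """Hyperparameters of the band-configuration search.

    Defaults follow the published operating point: 15 sparrows, 30
    iterations, 10 sub-bands, safety threshold 0.8, 20% producers, 30%
    watchers, searching 4-40 Hz.
    """

    pop_size: int = 15
    max_iter: int = 30
    n_bands: int = 10
    st: float = 0.8
    producer_frac: float = 0.2
    watcher_frac: float = 0.3
    beta_explore: float = 0.5
    w_min: float = 0.5
    f_min: float = 4.0
    f_max: float = 40.0
    epsilon: float = 1e-8
    use_classic_follower: bool = False
    use_classic_watcher: bool = False
    cv_folds: int = 5
    classifier_kind: str = "lda"
    m_pairs: int = 2
    scheme: str = "ovr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        if self.n_bands < 1:
            raise ConfigurationError("n_bands must be >= 1")
        if not 0.0 < self.st <= 1.0:
            raise ConfigurationError(f"safety threshold must be in (0, 1], got {self.st}")
        if not 0.0 < self.producer_frac < 1.0:
            raise ConfigurationError("producer_frac must be in (0, 1)")
        if not 0.0 <= self.watcher_frac <= 1.0:
            raise ConfigurationError("watcher_frac must be in [0, 1]")
        if self.w_min <= 0:
            raise ConfigurationError("w_min must be positive")
        if not self.f_min < self.f_max:
            raise ConfigurationError("need f_min < f_max")
        if self.max_iter < 0:
            raise ConfigurationError("max_iter must be >= 0")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")

    @property
    def dim(self) -> int:
        return 2 * self.n_bands

    @property
    def n_producers(self) -> int:
        return math.ceil(self.producer_frac * self.pop_size)

    @property
    def n_watchers(self) -> int:
        return math.ceil(self.watcher_frac * self.pop_size)

    @property
    def sigma(self) -> float:
        """Std of the watcher noise: the full search-range width in Hz."""
        return self.f_max - self.f_min


def repair(position: Sequence[float], cfg: SSAConfig) -> np.ndarray:
    """Project an arbitrary real vector onto the feasible band set.

    Total function: for every (low, high) pair, swap if reversed, clip into
    ``[f_min, f_max]``, widen to the minimum width ``w_min`` (pushing the
    pair down from ``f_max`` if needed), then sort pairs by low edge. The
    result always decodes to a valid :class:`FilterBank`.
    """
    pos = np.asarray(position, dtype=float).copy()
    if pos.ndim != 1 or pos.size != cfg.dim:
        raise ConfigurationError(
            f"position must have {cfg.dim} values, got shape {pos.shape}"
        )
    pairs = pos.reshape(-1, 2)
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    lo = np.clip(lo, cfg.f_min, cfg.f_max)
    hi = np.clip(hi, cfg.f_min, cfg.f_max)
    narrow = hi - lo < cfg.w_min
    hi = np.where(narrow, lo + cfg.w_min, hi)
    over = hi > cfg.f_max
    lo = np.where(over, cfg.f_max - cfg.w_min, lo)
    hi = np.where(over, cfg.f_max, hi)
    order = np.lexsort((hi, lo))
    return np.column_stack([lo[order], hi[order]]).ravel()


def producer_update(
    x: np.ndarray,
    t: int,
    cfg: SSAConfig,
    rng: np.random.Generator,
    *,
    r2: float | None = None,
    alpha: float | None = None,
    q: float | None = None,
) -> np.ndarray:
    """Producer move: multiplicative shrink below the safety threshold,
    additive standard-normal jump otherwise.

    Keyword overrides pin the random draws for closed-form checks.
    """
    x = np.asarray(x, dtype=float)
    if r2 is None:
        r2 = rng.uniform()
    if r2 < cfg.st:
        if alpha is None:
            alpha = 1.0 - rng.random()  # Uniform(0, 1]
        return x * math.exp(-t / (alpha * cfg.max_iter))
    if q is None:
        q = rng.standard_normal()
    return x + q * np.ones_like(x)


def follower_update(
    x: np.ndarray,
    t: int,
    cfg: SSAConfig,
    rng: np.random.Generator,
    x_best: np.ndarray,
    rank: int = 1,
    n_followers: int = 1,
    x_worst: np.ndarray | None = None,
    *,
    r: float | None = None,
    q: np.ndarray | float | None = None,
    step: np.ndarray | float | None = None,
) -> np.ndarray:
    """Follower move toward the best individual.

    Improved rule (default): ``x + step * (x_best - x) + Q`` with
    per-coordinate step ``R exp(-j/dim) + beta_explore (1 - t/T)`` (1-based
    coordinate ``j``), so later band edges decay independently and steps
    shrink over iterations. Classic rule (``use_classic_follower``):
    the worst-ranked half (``rank`` counted from the worst = 1) scatters as
    ``Q exp((x_worst - x) / rank^2)``, the better half moves to
    ``x_best + |x - x_best| . A+ . 1`` with a random sign vector ``A``.
    """
    x = np.asarray(x, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    T = cfg.max_iter

    if cfg.use_classic_follower:
        if rank < n_followers / 2:
            if x_worst is None:
                raise ValueError("classic follower rule needs x_worst")
            if q is None:
                q = rng.standard_normal()
            return q * np.exp(np.clip((x_worst - x) / rank**2, -50.0, 50.0))
        a = rng.choice([-1.0, 1.0], size=x.size)
        # A+ = A^T (A A^T)^-1 = A^T / dim for a +-1 row vector
        s = float(np.abs(x - x_best) @ (a / x.size))
        return x_best + s * np.ones_like(x)

    if step is None:
        if r is None:
            r = rng.uniform()
        j = np.arange(1, x.size + 1)
        decay = 1.0 - t / T if T > 0 else 0.0
        step = r * np.exp(-j / x.size) + cfg.beta_explore * decay
    if q is None:
        q = rng.standard_normal(x.size)
    return x + step * (x_best - x) + q


def watcher_update(
    x: np.ndarray,
    f_i: float,
    t: int,
    cfg: SSAConfig,
    rng: np.random.Generator,
    x_best: np.ndarray,
    f_best: float,
    f_worst: float,
    *,
    beta: float | None = None,
    noise: np.ndarray | float | None = None,
    k: float | None = None,
) -> np.ndarray:
    """Watcher move: anti-stagnation perturbation around the best individual.

    A non-best watcher jumps to ``x_best + beta |x - x_best| (+ noise)``;
    the improved rule adds Gaussian noise with std ``sigma = f_max - f_min``
    damped by ``(1 - t/T)``, so perturbation is wide early and vanishes at
    the final iteration. The current best individual is instead displaced
    along ``(x - x_best)`` scaled by the inverse fitness gap to the worst.
    """
    x = np.asarray(x, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    T = cfg.max_iter

    if f_i != f_best:
        if beta is None:
            beta = rng.standard_normal()
        moved = x_best + beta * np.abs(x - x_best)
        if cfg.use_classic_watcher:
            return moved
        if noise is None:
            damp = 1.0 - t / T if T > 0 else 0.0
            noise = damp * rng.normal(0.0, cfg.sigma, size=x.size)
        return moved + noise
    if k is None:
        k = rng.uniform()
    return x_best + k * (x - x_best) / (abs(f_i - f_worst) + cfg.epsilon)


class FitnessEvaluator:
    """Maps a repaired band-configuration vector to cross-validated accuracy.

    Fitness is the mean accuracy of the filter-bank CSP + classifier
    pipeline over stratified k-fold cross-validation on the training
    epochs. The folds are drawn once from the run seed, independent of the
    candidate, so fitness is a deterministic function of the position.
    Evaluations are cached on the position rounded to 0.01 Hz — band edges
    closer than that produce indistinguishable filters at EEG sampling
    rates.
    """

    def __init__(self, epochs: EpochSet, cfg: SSAConfig):
        counts = [int((epochs.labels == c).sum()) for c in epochs.classes]
        if min(counts) < cfg.cv_folds:
            raise ValueError(
                f"need >= {cfg.cv_folds} trials per class for "
                f"{cfg.cv_folds}-fold CV, got counts {counts}"
            )
        self.epochs = epochs
        self.cfg = cfg
        skf = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True,
            random_state=int(cfg.seed) % (2**31),
        )
        self.folds = [
            (tr.copy(), te.copy())
            for tr, te in skf.split(np.zeros(epochs.n_trials), epochs.labels)
        ]
        self.problems = _binary_problems(epochs.classes, cfg.scheme)
        self._cache: dict[tuple, float] = {}
        self.n_evaluations = 0

    def __call__(self, position: np.ndarray) -> float:
        key = tuple(np.round(np.asarray(position, dtype=float), 2))
        if key in self._cache:
            return self._cache[key]
        value = self._evaluate(np.asarray(position, dtype=float))
        self._cache[key] = value
        self.n_evaluations += 1
        return value

    def _evaluate(self, position: np.ndarray) -> float:
        bank = bank_from_position(position)
        epochs = self.epochs
        labels = epochs.labels
        n_samples = epochs.n_samples
        m = self.cfg.m_pairs

        # Filter and accumulate per-trial scatter matrices once per band;
        # every CV fold then works on covariance subsets only.
        scatters = []
        for band in bank:
            filtered = filter_array(epochs.data, band.low, band.high, epochs.fs)
            scatters.append(_trial_covariances(filtered))

        fold_accs = []
        for train_idx, test_idx in self.folds:
            blocks = []
            for S in scatters:
                for pos_cls, neg_cls in self.problems:
                    pos_mask = np.isin(labels, pos_cls)
                    neg_mask = np.isin(labels, neg_cls)
                    tr_pos = np.intersect1d(train_idx, np.where(pos_mask)[0])
                    tr_neg = np.intersect1d(train_idx, np.where(neg_mask)[0])
                    C1 = _normalized_mean_cov(S[tr_pos])
                    C2 = _normalized_mean_cov(S[tr_neg])
                    sf = fit_csp(C1, C2, m)
                    variances = np.einsum(
                        "tcd,cm,dm->tm", S, sf.W, sf.W
                    ) / n_samples
                    blocks.append(np.log(variances / variances.sum(axis=1,
                                                                   keepdims=True)))
            features = np.concatenate(blocks, axis=1)
            clf = fit_classifier(features[train_idx], labels[train_idx],
                                 self.cfg.classifier_kind)
            y_hat = predict(clf, features[test_idx])
            fold_accs.append(accuracy(labels[test_idx], y_hat))
        return float(np.mean(fold_accs))


def evaluate_fitness(position, epochs: EpochSet, cfg: SSAConfig) -> float:
    """One-off fitness of a repaired position (see :class:`FitnessEvaluator`)."""
    return FitnessEvaluator(epochs, cfg)(position)


@dataclass
class Population:
    """Current sparrow population: positions, fitness, and the incumbent."""

    positions: np.ndarray  # (N, dim)
    fitness: np.ndarray  # (N,)
    best_position: np.ndarray
    best_fitness: float

    def note(self, i: int, position: np.ndarray, fit: float) -> None:
        self.positions[i] = position
        self.fitness[i] = fit
        if fit > self.best_fitness:
            self.best_fitness = float(fit)
            self.best_position = position.copy()


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of a band-configuration search."""

    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    evaluations: int
    config: SSAConfig
    seed: int

    @property
    def best_bank(self) -> FilterBank:
        return bank_from_position(self.best_position)


def init_population(cfg: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial positions: the uniform bank as a warm start, the rest random.

    Individual 0 encodes the uniform ``n_bands`` bank over
    ``[f_min, f_max]``; together with elitism this guarantees the search
    never returns a bank worse (in training fitness) than the fixed
    uniform bank it is meant to improve on. The remaining individuals are
    uniform random in the search range, then repaired.
    """
    positions = np.empty((cfg.pop_size, cfg.dim))
    positions[0] = position_from_bank(make_uniform_bank(cfg.n_bands, cfg.f_min,
                                                        cfg.f_max))
    for i in range(1, cfg.pop_size):
        raw = rng.uniform(cfg.f_min, cfg.f_max, size=cfg.dim)
        positions[i] = repair(raw, cfg)
    return positions


def optimize(
    epochs: EpochSet,
    cfg: SSAConfig,
    role_mask: Iterable[str] | None = None,
    evaluator: FitnessEvaluator | None = None,
) -> OptimizationResult:
    """Run the sparrow search and return the best bank found.

    ``role_mask`` names the enabled roles (subset of
    ``{"producers", "followers", "watchers"}``); a disabled role's
    individuals keep their positions that phase, which implements the
    role-ablation experiments. With an empty mask the search degenerates to
    evaluating the initial population.
    """
    roles = ALL_ROLES if role_mask is None else frozenset(role_mask)
    unknown = roles - ALL_ROLES
    if unknown:
        raise ConfigurationError(f"unknown role(s) {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    if evaluator is None:
        evaluator = FitnessEvaluator(epochs, cfg)

    positions = init_population(cfg, rng)
    fitness = np.array([evaluator(p) for p in positions])
    best = int(np.argmax(fitness))
    pop = Population(
        positions=positions,
        fitness=fitness,
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
    )
    history = [pop.best_fitness]

    for t in range(1, cfg.max_iter + 1):
        order = np.argsort(pop.fitness)[::-1]  # descending fitness
        producers = order[: cfg.n_producers]
        followers = order[cfg.n_producers :]

        if "producers" in roles:
            for i in producers:
                new = repair(producer_update(pop.positions[i], t, cfg, rng), cfg)
                pop.note(i, new, evaluator(new))

        if "followers" in roles:
            x_worst = pop.positions[int(np.argmin(pop.fitness))].copy()
            n_f = len(followers)
            for idx, i in enumerate(followers):
                rank = n_f - idx  # worst-ranked follower has rank 1
                new = follower_update(
                    pop.positions[i], t, cfg, rng, pop.best_position,
                    rank=rank, n_followers=n_f, x_worst=x_worst,
                )
                new = repair(new, cfg)
                pop.note(i, new, evaluator(new))

        if "watchers" in roles and cfg.n_watchers > 0:
            f_worst = float(pop.fitness.min())
            chosen = rng.choice(cfg.pop_size, size=min(cfg.n_watchers, cfg.pop_size),
                                replace=False)
            for i in chosen:
                new = watcher_update(
                    pop.positions[i], float(pop.fitness[i]), t, cfg, rng,
                    pop.best_position, pop.best_fitness, f_worst,
                )
                new = repair(new, cfg)
                pop.note(i, new, evaluator(new))

        history.append(pop.best_fitness)

    return OptimizationResult(
        best_position=pop.best_position,
        best_fitness=pop.best_fitness,
        history=history,
        evaluations=evaluator.n_evaluations,
        config=cfg,
        seed=cfg.seed,
    )
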