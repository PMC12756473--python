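"""Experiment orchestration: hold-out evaluation, ablation, band sweeps.

An *experiment* trains the adaptive decoder on one session and tests it on
another (the cross-session hold-out protocol), repeated ``repeats`` times
under different base-seed offsets to average out the stochastic search.
Ablations re-run the same experiment with optimizer roles disabled; the
sub-band sweep re-runs it across bank sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .containers import EpochSet
from .filterbank import FilterBank
from .metrics import summarize
from .model import SSAFBCSP
from .ssa import ALL_ROLES, SSAConfig

__all__ = [
    "ExperimentConfig",
    "RepeatRecord",
    "ExperimentReport",
    "run_experiment",
    "run_ablation",
    "sweep_n_bands",
    "plot_bands",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """A train/test decoding experiment.

    ``repeats`` independent runs are performed; run ``r`` seeds the search
    and its cross-validation folds with ``base_seed + r`` while the
    train/test split (the two sessions) stays fixed.
    """

    train: EpochSet
    test: EpochSet
    ssa: SSAConfig = field(default_factory=SSAConfig)
    repeats: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.train.n_channels != self.test.n_channels:
            raise ValueError(
                f"channel mismatch: train has {self.train.n_channels}, "
                f"test has {self.test.n_channels}"
            )
        if self.train.fs != self.test.fs:
            raise ValueError(
                f"sampling-rate mismatch: {self.train.fs} vs {self.test.fs} Hz"
            )


@dataclass(frozen=True)
class RepeatRecord:
    """Outcome of one repeat: the fitted bank and its scores."""

    seed: int
    bank: FilterBank
    train_fitness: float
    test_acc: float
    test_kappa: float


@dataclass(frozen=True)
class ExperimentReport:
    """Per-repeat records plus aggregate mean +/- sample std."""

    repeats: tuple[RepeatRecord, ...]
    disabled_roles: tuple[str, ...] = ()

    @property
    def mean_test_acc(self) -> float:
        return summarize([r.test_acc for r in self.repeats])[0]

    @property
    def std_test_acc(self) -> float:
        return summarize([r.test_acc for r in self.repeats])[1]

    @property
    def mean_test_kappa(self) -> float:
        return summarize([r.test_kappa for r in self.repeats])[0]

    @property
    def mean_train_fitness(self) -> float:
        return summarize([r.train_fitness for r in self.repeats])[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": [r.seed for r in self.repeats],
                "train_fitness": [r.train_fitness for r in self.repeats],
                "test_acc": [r.test_acc for r in self.repeats],
                "test_kappa": [r.test_kappa for r in self.repeats],
                "bank": [r.bank.edges() for r in self.repeats],
            }
        )


def run_experiment(
    cfg: ExperimentConfig, roles_to_disable: Iterable[str] = ()
) -> ExperimentReport:
    """Train on the training session, test on the held-out session.

    Per repeat ``r``: seed the search with ``base_seed + r``, optimize the
    bank on the training epochs, refit features + classifier on the full
    training session under the best bank, and score on the test session.
    """
    disabled = tuple(sorted(set(roles_to_disable)))
    role_mask = ALL_ROLES - set(disabled)
    records = []
    for r in range(cfg.repeats):
        seed = cfg.base_seed + r
        ssa_cfg = replace(cfg.ssa, seed=seed)
        result = SSAFBCSP(cfg.train, ssa_cfg).fit(role_mask=role_mask)
        metrics = result.score(cfg.test)
        records.append(
            RepeatRecord(
                seed=seed,
                bank=result.bank,
                train_fitness=result.cv_accuracy,
                test_acc=metrics.acc,
                test_kappa=metrics.kappa,
            )
        )
    return ExperimentReport(repeats=tuple(records), disabled_roles=disabled)


def run_ablation(
    cfg: ExperimentConfig, roles_to_disable: Iterable[str]
) -> ExperimentReport:
    """Identical pipeline with the named optimizer roles skipped."""
    return run_experiment(cfg, roles_to_disable=roles_to_disable)


def sweep_n_bands(cfg: ExperimentConfig, n_range: Sequence[int]) -> pd.DataFrame:
    """Re-run the experiment for each bank size in ``n_range``.

    All runs share the base seed, so rows are directly comparable. Returns
    a table with columns ``n_bands``, ``mean_acc``, ``std_acc``,
    ``mean_kappa``.
    """
    n_range = list(n_range)
    if not n_range:
        raise ValueError("n_range must be non-empty")
    rows = []
    for n in n_range:
        report = run_experiment(replace(cfg, ssa=replace(cfg.ssa, n_bands=int(n))))
        rows.append(
            {
                "n_bands": int(n),
                "mean_acc": report.mean_test_acc,
                "std_acc": report.std_test_acc,
                "mean_kappa": report.mean_test_kappa,
            }
        )
    return pd.DataFrame(rows)


def plot_bands(report: ExperimentReport, out_path: str | Path) -> Path:
    """Visualize the per-repeat banks of a report (see :mod:`plotting`)."""
    from .plotting import plot_report_bands

    return plot_report_bands(report, out_path)
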