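"""Top-level modelling interface: fit an adaptive filter-bank decoder.

:class:`SSAFBCSP` is the package's front door, organized the way
statistical modelling libraries present estimators: the model object is
built from data, ``fit()`` runs the estimation (here, the sparrow search
over band configurations followed by a refit of the filter-bank CSP
features and classifier on the full training set), and the returned
:class:`SSAFBCSPResults` carries the estimates — the individualized band
boundaries — together with their fitness diagnostics, prediction methods,
and a ``summary()`` table.

A fixed (non-optimized) bank can be supplied to fit the classical uniform
filter-bank CSP decoder through the same interface, which is how the
optimized and uniform pipelines are compared like for like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .csp import FBCSPModel, fit_fbcsp, transform
from .filterbank import FilterBank
from .metrics import Metrics, evaluate_predictions, fit_classifier, predict
from .ssa import FitnessEvaluator, OptimizationResult, SSAConfig, optimize

__all__ = ["SSAFBCSP", "SSAFBCSPResults"]


class SSAFBCSP:
    """Adaptive filter-bank CSP decoder for epoched motor-imagery EEG.

    Parameters
    ----------
    epochs : EpochSet
        Training epochs (already preprocessed).
    config : SSAConfig, optional
        Search hyperparameters; defaults to the published operating point
        (15 sparrows, 30 iterations, 10 bands, LDA, 5-fold fitness CV).
    bank : FilterBank, optional
        Skip the search and fit with this fixed bank instead. ``fit()``
        then reports the bank's cross-validated fitness but runs no
        optimization.

    Examples
    --------
    >>> from ssafbcsp import SSAFBCSP, SSAConfig, generate_epochs, SynthConfig
    >>> train = generate_epochs(SynthConfig(seed=1))
    >>> model = SSAFBCSP(train, SSAConfig(pop_size=6, max_iter=5, n_bands=4))
    >>> res = model.fit()
    >>> res.bank.edges()  # doctest: +SKIP
    """

    def __init__(
        self,
        epochs: EpochSet,
        config: SSAConfig | None = None,
        bank: FilterBank | None = None,
    ):
        self.epochs = epochs
        self.config = config if config is not None else SSAConfig()
        self.fixed_bank = bank

    @classmethod
    def from_arrays(
        cls, data: np.ndarray, labels: np.ndarray, fs: float, **kwargs
    ) -> "SSAFBCSP":
        """Build the model from a raw (trials, channels, samples) array."""
        return cls(EpochSet(data=data, labels=labels, fs=fs), **kwargs)

    def fit(self, role_mask=None) -> "SSAFBCSPResults":
        """Estimate the band configuration and fit the final decoder.

        Runs the sparrow search on the training epochs (unless a fixed bank
        was given), then refits the filter-bank CSP features and the
        classifier on the full training set under the best bank.
        ``role_mask`` restricts the enabled optimizer roles (ablation).
        """
        cfg = self.config
        evaluator = FitnessEvaluator(self.epochs, cfg)
        if self.fixed_bank is not None:
            from .filterbank import position_from_bank

            pos = position_from_bank(self.fixed_bank)
            fitness = evaluator(pos)
            opt = OptimizationResult(
                best_position=pos, best_fitness=fitness, history=[fitness],
                evaluations=evaluator.n_evaluations, config=cfg, seed=cfg.seed,
            )
        else:
            opt = optimize(self.epochs, cfg, role_mask=role_mask,
                           evaluator=evaluator)

        bank = opt.best_bank
        fb = fit_fbcsp(self.epochs, bank, m=cfg.m_pairs, scheme=cfg.scheme)
        features = transform(fb, self.epochs)
        fb.classifier = fit_classifier(features, self.epochs.labels,
                                       cfg.classifier_kind)
        return SSAFBCSPResults(model=self, fbcsp=fb, optimization=opt)


@dataclass
class SSAFBCSPResults:
    """Fitted decoder: band estimates, diagnostics, and prediction."""

    model: SSAFBCSP
    fbcsp: FBCSPModel
    optimization: OptimizationResult

    @property
    def bank(self) -> FilterBank:
        """The estimated (or supplied) filter bank."""
        return self.fbcsp.bank

    @property
    def cv_accuracy(self) -> float:
        """Cross-validated training accuracy of the final bank (the fitness)."""
        return self.optimization.best_fitness

    @property
    def fitness_history(self) -> list[float]:
        """Best-so-far fitness per iteration (monotone non-decreasing)."""
        return self.optimization.history

    def predict(self, epochs: EpochSet) -> np.ndarray:
        """Class label per trial of ``epochs``."""
        features = transform(self.fbcsp, epochs)
        return predict(self.fbcsp.classifier, features)

    def score(self, epochs: EpochSet, p_e: float | None = None) -> Metrics:
        """Accuracy and Cohen's kappa on a held-out :class:`EpochSet`."""
        return evaluate_predictions(epochs.labels, self.predict(epochs), p_e=p_e)

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.model.config
        opt = self.optimization
        lines = [
            "Adaptive filter-bank CSP decoder",
            "=" * 48,
            f"classes:             {self.fbcsp.classes}",
            f"trials (train):      {self.model.epochs.n_trials}",
            f"channels:            {self.model.epochs.n_channels}",
            f"classifier:          {cfg.classifier_kind}",
            f"CSP filter pairs m:  {cfg.m_pairs}",
            f"sub-bands:           {len(self.bank)}",
            f"search range:        {cfg.f_min}-{cfg.f_max} Hz",
            f"population / iters:  {cfg.pop_size} / {cfg.max_iter}",
            f"fitness evaluations: {opt.evaluations}",
            f"CV accuracy (train): {self.cv_accuracy:.4f}",
            "-" * 48,
            "band   low (Hz)   high (Hz)   width (Hz)",
        ]
        for i, b in enumerate(self.bank, 1):
            lines.append(f"{i:>4}   {b.low:8.2f}   {b.high:9.2f}   {b.width:10.2f}")
        return "\n".join(lines)

    def plot_bands(self, ax=None):
        """Draw the estimated sub-bands over the mu/beta reference ranges."""
        from .plotting import plot_bank

        return plot_bank(self.bank, ax=ax)
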