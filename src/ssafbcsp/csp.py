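"""Common spatial patterns per sub-band, and filter-bank feature extraction.

CSP finds spatial filters ``W`` that jointly diagonalize the two class
covariance matrices: ``W^T (C1 + C2) W = I`` and ``W^T C1 W = diag(lambda)``,
a symmetric-definite generalized eigenproblem. Filters belonging to the
largest and smallest eigenvalues maximize the variance ratio between the
classes in opposite directions; the ``m`` top and ``m`` bottom eigenvectors
are retained.

Filter-bank CSP (FBCSP) runs this per sub-band of a filter bank and
concatenates the per-band log-variance features. The multi-class extension
is one-vs-rest by default (one binary CSP problem per class), with pairwise
problems available behind ``scheme="pairwise"``.

Log-variance features are normalized by the *sum* of the variances over
the retained components (so ``sum(exp(f)) = 1`` per problem), the usual
FBCSP convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import EpochSet
from .exceptions import ConfigurationError
from .filterbank import FilterBank, filter_array

__all__ = [
    "SpatialFilters",
    "FBCSPModel",
    "class_covariance",
    "fit_csp",
    "project",
    "logvar_features",
    "fit_fbcsp",
    "transform",
]

#: Condition-number threshold above which a ridge is added to C1 + C2.
_COND_LIMIT = 1e10
#: Ridge strength, as a fraction of trace/channels.
_RIDGE_EPS = 1e-6


@dataclass(frozen=True)
class SpatialFilters:
    """Fitted CSP projection for one binary problem in one sub-band.

    ``W`` has one column per retained component: the ``m`` filters with the
    largest variance-ratio eigenvalues first (descending), then the ``m``
    with the smallest (ascending). ``eigvals`` are the corresponding
    generalized eigenvalues, all in [0, 1].
    """

    W: np.ndarray
    eigvals: np.ndarray
    m: int


def _trial_covariances(data: np.ndarray) -> np.ndarray:
    """Per-trial scatter matrices ``X_c X_c^T`` of channel-centered data."""
    centered = data - data.mean(axis=-1, keepdims=True)
    return np.einsum("tcs,tds->tcd", centered, centered)


def _normalized_mean_cov(scatters: np.ndarray) -> np.ndarray:
    """Average of trace-normalized per-trial covariances (unit trace)."""
    traces = np.trace(scatters, axis1=-2, axis2=-1)
    if np.any(traces <= 0):
        raise ValueError("trial with zero variance: cannot normalize covariance")
    return (scatters / traces[:, None, None]).mean(axis=0)


def class_covariance(epochs: EpochSet, class_selector) -> np.ndarray:
    """Normalized spatial covariance of the trials selected by ``class_selector``.

    ``class_selector`` is either an integer label or a boolean/index array
    over trials. Each trial's channel-centered scatter matrix is normalized
    by its trace before averaging, so inter-trial amplitude differences do
    not dominate; the result is symmetric PSD with unit trace.
    """
    if np.isscalar(class_selector):
        mask = epochs.labels == class_selector
    else:
        mask = np.asarray(class_selector)
    data = epochs.data[mask]
    if data.shape[0] == 0:
        raise ValueError(f"no trials selected by {class_selector!r}")
    return _normalized_mean_cov(_trial_covariances(data))


def fit_csp(C1: np.ndarray, C2: np.ndarray, m: int = 2) -> SpatialFilters:
    """Solve ``C1 w = lambda (C1 + C2) w`` and retain 2m extreme filters.

    Eigenvalues of this problem are the class-1 variance fractions and lie
    in [0, 1]; the problem for ``C2`` has eigenvalues ``1 - lambda`` with
    the same eigenvectors, so one decomposition serves both classes. Ties
    are broken by the solver's ascending eigenvalue order, making the fit
    deterministic. If ``C1 + C2`` is near-singular (e.g. after common
    average referencing, which removes one rank), a small ridge
    proportional to ``trace/channels`` is added automatically.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    if C1.shape != C2.shape or C1.ndim != 2 or C1.shape[0] != C1.shape[1]:
        raise ValueError(f"covariance shapes {C1.shape}, {C2.shape} do not match")
    n_ch = C1.shape[0]
    if 2 * m > n_ch:
        raise ConfigurationError(
            f"2m = {2 * m} filters requested but only {n_ch} channels"
        )
    comp = C1 + C2
    if np.linalg.cond(comp) > _COND_LIMIT:
        comp = comp + np.eye(n_ch) * (_RIDGE_EPS * np.trace(comp) / n_ch)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(C1, comp)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "generalized eigendecomposition failed: C1 + C2 is singular; "
            "regularize the covariance estimates (more trials, or a ridge)"
        ) from exc
    # ascending from eigh: take m largest (descending) then m smallest (ascending)
    top = eigvals.argsort()[::-1][:m]
    bottom = eigvals.argsort()[:m]
    sel = np.concatenate([top, bottom])
    return SpatialFilters(W=eigvecs[:, sel], eigvals=eigvals[sel], m=m)


def project(filters: SpatialFilters, epoch: np.ndarray) -> np.ndarray:
    """Spatially filter one epoch: ``Z = W^T X`` (components x samples)."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] != filters.W.shape[0]:
        raise ValueError(
            f"epoch shape {epoch.shape} does not match {filters.W.shape[0]} channels"
        )
    return filters.W.T @ epoch


def logvar_features(Z: np.ndarray) -> np.ndarray:
    """Normalized log-variance per component: ``log(var_i / sum_j var_j)``.

    The reference variance is the sum over the retained components, so the
    features of one problem satisfy ``sum(exp(f)) = 1``.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("need components x samples with at least 2 samples")
    variances = Z.var(axis=1)
    total = variances.sum()
    if total <= 0:
        raise ValueError("all components have zero variance")
    return np.log(variances / total)


def _binary_problems(
    classes: np.ndarray, scheme: str
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    classes = [int(c) for c in classes]
    if len(classes) == 2:
        return [((classes[0],), (classes[1],))]
    if scheme == "ovr":
        return [
            ((c,), tuple(o for o in classes if o != c)) for c in classes
        ]
    if scheme == "pairwise":
        return [
            ((a,), (b,))
            for i, a in enumerate(classes)
            for b in classes[i + 1 :]
        ]
    raise ConfigurationError(f"unknown multi-class scheme {scheme!r}")


@dataclass
class FBCSPModel:
    """Fitted filter-bank CSP feature extractor.

    ``filters[band_index][problem_index]`` holds the :class:`SpatialFilters`
    for each (sub-band, binary problem) pair. ``classifier`` is attached by
    the decoding pipeline after feature extraction; the feature mapping
    itself never depends on it.
    """

    bank: FilterBank
    m: int
    classes: tuple[int, ...]
    problems: list[tuple[tuple[int, ...], tuple[int, ...]]]
    filters: list[list[SpatialFilters]]
    scheme: str = "ovr"
    fs: float | None = None
    n_channels: int | None = None
    classifier: object | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return len(self.bank) * len(self.problems) * 2 * self.m

    def feature_index(self, band: int, problem: int, component: int) -> int:
        """Column of feature (band, problem, component), band-major order."""
        per_band = len(self.problems) * 2 * self.m
        return band * per_band + problem * 2 * self.m + component


def fit_fbcsp(
    epochs: EpochSet, bank: FilterBank, m: int = 2, scheme: str = "ovr"
) -> FBCSPModel:
    """Fit CSP filters for every (sub-band, binary problem) pair.

    For each band the epochs are band-pass filtered once; per binary
    problem the two class covariances are averaged over the problem's
    trials (one-vs-rest uses all trials, pairwise only the pair's).
    """
    classes = epochs.classes
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit CSP")
    counts = [int((epochs.labels == c).sum()) for c in classes]
    if min(counts) < 2:
        raise ValueError(f"every class needs >= 2 trials, got counts {counts}")
    problems = _binary_problems(classes, scheme)

    all_filters: list[list[SpatialFilters]] = []
    for band in bank:
        filtered = filter_array(epochs.data, band.low, band.high, epochs.fs)
        scatters = _trial_covariances(filtered)
        band_filters = []
        for pos, neg in problems:
            pos_mask = np.isin(epochs.labels, pos)
            neg_mask = np.isin(epochs.labels, neg)
            C1 = _normalized_mean_cov(scatters[pos_mask])
            C2 = _normalized_mean_cov(scatters[neg_mask])
            band_filters.append(fit_csp(C1, C2, m))
        all_filters.append(band_filters)

    return FBCSPModel(
        bank=bank,
        m=m,
        classes=tuple(int(c) for c in classes),
        problems=problems,
        filters=all_filters,
        scheme=scheme,
        fs=epochs.fs,
        n_channels=epochs.n_channels,
    )


def transform(model: FBCSPModel, epochs: EpochSet) -> np.ndarray:
    """Extract the concatenated log-variance feature matrix (trials x features).

    Columns are ordered band-major, then problem, then component, matching
    :meth:`FBCSPModel.feature_index`.
    """
    if model.n_channels is not None and epochs.n_channels != model.n_channels:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels, model expects "
            f"{model.n_channels}"
        )
    if model.fs is not None and epochs.fs != model.fs:
        raise ValueError(f"epochs at {epochs.fs} Hz, model fitted at {model.fs} Hz")

    n_samples = epochs.n_samples
    blocks = []
    for band, band_filters in zip(model.bank, model.filters):
        filtered = filter_array(epochs.data, band.low, band.high, epochs.fs)
        scatters = _trial_covariances(filtered)
        for sf in band_filters:
            # variance of W^T X per trial from the scatter matrix
            variances = np.einsum("tcd,cm,dm->tm", scatters, sf.W, sf.W) / n_samples
            totals = variances.sum(axis=1, keepdims=True)
            blocks.append(np.log(variances / totals))
    features = np.concatenate(blocks, axis=1)
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite features: a component has zero variance")
    return features
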