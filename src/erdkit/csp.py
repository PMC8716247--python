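"""Common spatial patterns: supervised spatial filtering for two-class EEG.

CSP finds a filter matrix W that simultaneously diagonalizes the two
class-mean spatial covariance matrices, i.e. solves the generalized
eigenproblem ``S1 w = lambda (S1 + S2) w``. Projected through W
(``X_csp = W.T @ X``), the first filters maximize class-1 variance share and
the last maximize class-2's, so log-variance features of the extreme filter
pairs separate the classes.

Implementation is the whitening route (eigendecompose the composite
covariance, whiten, eigendecompose the whitened class-1 covariance); tests
cross-check it against a dense generalized eigensolver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trials import TrialSet

__all__ = ["CSPModel", "FeatureMatrix", "fit_csp", "csp_features"]


@dataclass
class CSPModel:
    """Fitted CSP filter bank.

    ``filters`` columns are spatial filters sorted by descending class-1
    eigenvalue; ``eigenvalues`` are the class-1 variance shares in [0, 1]
    (the class-2 share of each filter is ``1 - lambda``). The retained set
    is the first and last ``n_pairs`` columns.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    n_pairs: int
    class_order: tuple[str, str]
    channel_labels: list[str]

    @property
    def retained(self) -> np.ndarray:
        """Filter columns actually used for features (2 * n_pairs)."""
        return np.concatenate(
            [self.filters[:, : self.n_pairs], self.filters[:, -self.n_pairs:]],
            axis=1,
        )

    def to_text(self, path) -> None:
        """Serialize filters + eigenvalues as delimited text for audit."""
        n_ch = self.filters.shape[0]
        header = (
            f"csp n_channels={n_ch} n_pairs={self.n_pairs} "
            f"class_order={self.class_order[0]},{self.class_order[1]} "
            f"channels={','.join(self.channel_labels)}"
        )
        body = np.vstack([self.eigenvalues[None, :], self.filters])
        np.savetxt(path, body, delimiter="\t", header=header)

    @classmethod
    def from_text(cls, path) -> "CSPModel":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
        meta = dict(item.split("=", 1) for item in header[1:])
        body = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(
            filters=body[1:],
            eigenvalues=body[0],
            n_pairs=int(meta["n_pairs"]),
            class_order=tuple(meta["class_order"].split(",")),
            channel_labels=meta["channels"].split(","),
        )


@dataclass
class FeatureMatrix:
    """Per-trial log-variance CSP features (trials x 2*n_pairs)."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")


def _class_covariance(data: np.ndarray) -> np.ndarray:
    """Mean of trace-normalized per-trial spatial covariances.

    Trace normalization removes trial-level global amplitude so that the
    spatial *pattern* of variance, not its scale, drives the filters.
    """
    covs = np.einsum("tcs,tds->tcd", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    if (traces <= 0).any():
        raise np.linalg.LinAlgError("a trial has zero total variance")
    return (covs / traces[:, None, None]).mean(axis=0)


def fit_csp(trials: TrialSet, n_pairs: int = 3, reg: float = 1e-10) -> CSPModel:
    """Fit CSP filters on a two-class trial set.

    Parameters
    ----------
    trials : TrialSet
        Band-passed, windowed epochs with exactly two condition labels and
        at least two trials per class.
    n_pairs : int
        Number of extreme filter pairs retained for features (default 3).
    reg : float
        Ridge added to the composite covariance as
        ``reg * trace/n_channels * I`` to stabilize rank-deficient inputs.
    """
    classes = trials.conditions
    if len(classes) != 2:
        raise ValueError(f"CSP needs exactly two classes, got {classes}")
    if trials.n_samples <= trials.n_channels:
        raise ValueError("need more samples than channels per trial")
    n_ch = trials.n_channels
    if not 1 <= n_pairs <= n_ch // 2:
        raise ValueError(f"n_pairs must be in [1, {n_ch // 2}]")
    per_class = []
    for c in classes:
        sub = trials.select_condition(c)
        if sub.n_trials < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
        per_class.append(_class_covariance(sub.data))
    s1, s2 = per_class
    composite = s1 + s2
    composite = composite + reg * (np.trace(composite) / n_ch) * np.eye(n_ch)

    # whitening route: composite = U diag(d) U.T, P = d^-1/2 U.T
    d, u = np.linalg.eigh(composite)
    if d[-1] <= 0 or d[0] < 1e-12 * d[-1]:
        raise np.linalg.LinAlgError(
            "composite covariance is (near-)singular: smallest/largest "
            f"eigenvalue = {d[0]:.3e}/{d[-1]:.3e}; consider a larger reg"
        )
    whitener = (u / np.sqrt(d)).T
    lam, v = np.linalg.eigh(whitener @ s1 @ whitener.T)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, 1.0)
    filters = whitener.T @ v[:, order]
    # sign convention: largest-magnitude coefficient of each filter positive
    signs = np.sign(filters[np.abs(filters).argmax(axis=0), np.arange(n_ch)])
    filters = filters * np.where(signs == 0, 1.0, signs)

    return CSPModel(
        filters=filters,
        eigenvalues=lam,
        n_pairs=n_pairs,
        class_order=(classes[0], classes[1]),
        channel_labels=list(trials.channel_labels),
    )


def csp_features(model: CSPModel, trials: TrialSet) -> FeatureMatrix:
    """Log-variance features of the retained CSP projections.

    Per trial, ``feature_j = log(var_j / sum_j var_j)`` over the
    ``2 * n_pairs`` retained projections — the variance-share form, which is
    invariant to global amplitude scaling of the trial.
    """
    if trials.n_channels != model.filters.shape[0]:
        raise ValueError(
            f"trials have {trials.n_channels} channels, model expects "
            f"{model.filters.shape[0]}"
        )
    w = model.retained
    projected = np.einsum("cj,tcs->tjs", w, trials.data)
    variances = projected.var(axis=-1)
    totals = variances.sum(axis=1, keepdims=True)
    if (variances <= 0).any() or (totals <= 0).any():
        raise np.linalg.LinAlgError(
            "zero-variance CSP projection; trials may be constant"
        )
    return FeatureMatrix(
        features=np.log(variances / totals), labels=trials.condition_labels.copy()
    )
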