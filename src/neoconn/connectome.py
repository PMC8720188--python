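"""Accordance connectomes and weighted-graph nodal strength.

The accordance between two regional BOLD series counts their simultaneous
same-sign excursions. Each series x_i is reduced to two indicator series
against its own within-run quantiles:

    u_i(t) = 1  iff  x_i(t) > Q_{q_high}(x_i)       (positive excursion)
    d_i(t) = 1  iff  x_i(t) < Q_{q_low}(x_i)        (negative excursion)

and, with e_i the concatenation [u_i; d_i],

    accordance(i, j)  = (<u_i, u_j> + <d_i, d_j>) / (||e_i|| ||e_j||)
    discordance(i, j) = (<u_i, d_j> + <d_i, u_j>) / (||e_i|| ||e_j||)

so identical series score accordance 1 and exactly anti-phased zero-median
series score discordance 1. Defaults q_low = 0.158, q_high = 0.842 put the
thresholds at the Gaussian +/-1 SD equivalents. Both matrices are symmetric;
the accordance diagonal is 1 by construction.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import RegionalRun

Q_LOW = 0.158
Q_HIGH = 0.842


def _excursion_indicators(
    signals: np.ndarray, q_low: float, q_high: float
) -> tuple[np.ndarray, np.ndarray]:
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be (n_regions, n_volumes)")
    if signals.shape[1] < 2:
        raise ValueError("need at least 2 retained volumes")
    const = np.ptp(signals, axis=1) == 0
    if np.any(const):
        bad = np.flatnonzero(const)
        raise ValueError(f"constant regional series at index {bad.tolist()}")
    hi = np.quantile(signals, q_high, axis=1, keepdims=True)
    lo = np.quantile(signals, q_low, axis=1, keepdims=True)
    u = (signals > hi).astype(float)
    d = (signals < lo).astype(float)
    return u, d


def _norms(u: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = np.sqrt(u.sum(axis=1) + d.sum(axis=1))
    if np.any(n == 0):
        bad = np.flatnonzero(n == 0)
        raise ValueError(f"no excursions for region index {bad.tolist()}")
    return n


def accordance_matrix(
    series: RegionalRun | np.ndarray, q_low: float = Q_LOW, q_high: float = Q_HIGH
) -> np.ndarray:
    """Accordance connectome of one run; symmetric with unit diagonal."""
    signals = series.signals if isinstance(series, RegionalRun) else series
    u, d = _excursion_indicators(signals, q_low, q_high)
    norms = _norms(u, d)
    acc = (u @ u.T + d @ d.T) / np.outer(norms, norms)
    np.fill_diagonal(acc, 1.0)
    return acc


def discordance_matrix(
    series: RegionalRun | np.ndarray, q_low: float = Q_LOW, q_high: float = Q_HIGH
) -> np.ndarray:
    """Discordance (anti-phased co-excursions); diagnostic companion matrix."""
    signals = series.signals if isinstance(series, RegionalRun) else series
    u, d = _excursion_indicators(signals, q_low, q_high)
    norms = _norms(u, d)
    return (u @ d.T + d @ u.T) / np.outer(norms, norms)


def nodal_strength(weights: np.ndarray) -> np.ndarray:
    """Per-region strength: sum of off-diagonal edge weights of a symmetric matrix."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectome must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("connectome must be symmetric")
    return w.sum(axis=1) - np.diag(w)


def delta_nodal_strength(run1: np.ndarray, run2: np.ndarray) -> np.ndarray:
    """Run-2 minus run-1 nodal strength; positive = stronger after the stimulus."""
    run1, run2 = np.asarray(run1), np.asarray(run2)
    if run1.shape != run2.shape:
        raise ValueError("connectomes must share shape (same region set)")
    return nodal_strength(run2) - nodal_strength(run1)


class AccordanceConnectivity(TransformerMixin, BaseEstimator):
    """Transform regional time series into accordance (or discordance) connectomes.

    Follows the scikit-learn transformer protocol: ``transform`` maps a list of
    per-subject ``(n_regions, n_volumes)`` arrays (or ``RegionalRun``) to a
    ``(n_subjects, n_regions, n_regions)`` stack. Runs may differ in length
    (e.g. after censoring); regions may not.

    Parameters
    ----------
    q_low, q_high : float
        Within-region excursion quantiles; defaults 0.158 / 0.842 (~+/-1 SD).
    kind : {"accordance", "discordance"}
        Which coupling matrix to compute.
    """

    def __init__(
        self, q_low: float = Q_LOW, q_high: float = Q_HIGH, kind: str = "accordance"
    ):
        self.q_low = q_low
        self.q_high = q_high
        self.kind = kind

    def fit(self, X, y=None):
        if not 0 < self.q_low < self.q_high < 1:
            raise ValueError("require 0 < q_low < q_high < 1")
        if self.kind not in ("accordance", "discordance"):
            raise ValueError(f"unknown kind {self.kind!r}")
        first = X[0].signals if isinstance(X[0], RegionalRun) else np.asarray(X[0])
        self.n_regions_ = first.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_regions_"):
            self.fit(X)
        func = accordance_matrix if self.kind == "accordance" else discordance_matrix
        mats = []
        for run in X:
            sig = run.signals if isinstance(run, RegionalRun) else np.asarray(run)
            if sig.shape[0] != self.n_regions_:
                raise ValueError("all runs must share the region set")
            mats.append(func(sig, self.q_low, self.q_high))
        return np.stack(mats)
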