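"""Partial least squares correlation (PLSC) for dose-response brain patterns.

PLSC relates an outcome block Y (here: one column, the number of prior music
sessions) to an imaging block X (here: 90 per-region delta nodal strengths)
through the singular value decomposition of their cross-covariance,

    R = Y_z^T X_z / (n - 1) = U S V^T,

where both blocks are z-scored column-wise across subjects first. Columns of
V are brain saliences, columns of U outcome saliences, and the latent scores
are Lx = X_z V, Ly = Y_z U. With a single outcome there is exactly one
component and a closed form: V is the vector of dose-region Pearson
correlations normalized to unit length, and S is that vector's norm — this
closed form anchors the implementation's correctness tests.

Inference follows the standard PLSC recipe:

* significance of the component by permutation of the outcome rows
  (null statistic: the permuted singular value; +1-smoothed p-value),
* stability of each salience by bootstrap over subjects (resampled refits
  share the sign convention, hence are directly comparable; a salience is
  "robust" when its 5th-95th percentile interval excludes zero;
  bootstrap-ratio thresholding is available as an alternative),
* robustness of the latent scores by leave-one-out cross-validation, applying
  each fold's learnt standardization and saliences to the held-out subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

N_PERMUTATIONS = 5000
N_BOOTSTRAP = 200
BOOT_PERCENTILES = (5.0, 95.0)
BOOT_RATIO_THRESHOLD = 2.0


def _standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    return (a - mean) / sd, mean, sd


def _svd_single_outcome(r: np.ndarray) -> tuple[float, float, np.ndarray]:
    """SVD of a 1 x p cross-covariance: returns (u, s, v).

    Sign convention: the outcome salience u is fixed to +1, which identifies
    the component exactly (v = R / ||R||) and makes each brain salience carry
    the sign of its region's dose association. Refits (permutation, bootstrap,
    LOOCV folds) share the convention, so their saliences are directly
    comparable without a posteriori alignment.
    """
    s = float(np.linalg.norm(r))
    if s == 0:
        return 1.0, 0.0, np.zeros(r.shape[1])
    v = (r / s).ravel()
    return 1.0, s, v


@dataclass
class LoocvScores:
    """Full-model vs leave-one-out latent scores and their correlations."""

    scores: pd.DataFrame  # subject, lx_full, lx_cv, ly_full, ly_cv
    r_brain: float  # corr(lx_full, lx_cv)
    r_outcome: float  # corr(ly_full, ly_cv)


class PLSCorrelation(BaseEstimator):
    """Single-component PLSC with permutation, bootstrap and LOOCV built in.

    Parameters
    ----------
    n_permutations : int
        Outcome-row permutations for the component's p-value (0 disables).
    n_bootstrap : int
        Subject resamples for salience stability (0 disables).
    robust : {"percentile", "ratio"}
        "percentile": a salience is robust when its bootstrap percentile
        interval (``boot_percentiles``) excludes zero. "ratio": when
        |bootstrap mean / bootstrap SD| exceeds ``ratio_threshold``.
    boot_percentiles : (float, float)
        Percentile interval bounds, in percent.
    random_state : int, RandomState or None
        Seeds both resampling schemes.

    Attributes
    ----------
    x_saliences_ : ndarray (n_features,)
        Brain saliences V (unit norm). With the outcome salience fixed to +1
        each entry carries the sign of its region's dose association.
    y_saliences_ : float
        Outcome salience U; +1 by the sign convention.
    singular_value_ : float
        Singular value of the component.
    cross_cov_ : ndarray (1, n_features)
        The z-scored cross-covariance R (1/(n-1) scaling).
    x_scores_, y_scores_ : ndarray (n_subjects,)
        Latent scores Lx, Ly on the training subjects.
    p_value_ : float
        Permutation p-value (+1 smoothing), if permutations were run.
    perm_null_ : ndarray
        Null singular values.
    boot_saliences_ : ndarray (n_bootstrap, n_features)
        Sign-aligned bootstrap brain saliences.
    boot_mean_, boot_low_, boot_high_ : ndarray (n_features,)
        Bootstrap mean and percentile interval per region.
    robust_mask_ : ndarray of bool (n_features,)
        Regions whose salience is judged stable.
    """

    def __init__(
        self,
        n_permutations: int = N_PERMUTATIONS,
        n_bootstrap: int = N_BOOTSTRAP,
        robust: str = "percentile",
        boot_percentiles: tuple[float, float] = BOOT_PERCENTILES,
        ratio_threshold: float = BOOT_RATIO_THRESHOLD,
        random_state=None,
    ):
        self.n_permutations = n_permutations
        self.n_bootstrap = n_bootstrap
        self.robust = robust
        self.boot_percentiles = boot_percentiles
        self.ratio_threshold = ratio_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2:
            raise ValueError("X must be (n_subjects, n_features)")
        if y.size != X.shape[0]:
            raise ValueError("X and y must have the same number of subjects")
        n = X.shape[0]
        if n < 5:
            raise ValueError("need at least 5 subjects")
        if self.robust not in ("percentile", "ratio"):
            raise ValueError(f"unknown robust rule {self.robust!r}")
        if 0 < self.n_permutations < 100:
            warnings.warn("fewer than 100 permutations: p-value is coarse", stacklevel=2)

        xz, self.x_mean_, self.x_std_ = _standardize(X)
        yz, self.y_mean_, self.y_std_ = _standardize(y[:, None])

        self.n_subjects_, self.n_features_in_ = X.shape
        self.cross_cov_ = yz.T @ xz / (n - 1)
        u, s, v = _svd_single_outcome(self.cross_cov_)
        if s == 0:
            warnings.warn("degenerate design: all-zero cross-covariance", stacklevel=2)
        self.y_saliences_ = u
        self.x_saliences_ = v
        self.singular_value_ = s
        self.x_scores_ = xz @ v
        self.y_scores_ = (yz * u).ravel()

        rng = np.random.default_rng(self.random_state)
        if self.n_permutations:
            self._permutation_test(xz, yz, rng)
        if self.n_bootstrap:
            self._bootstrap(X, y, rng)
        return self

    # --------------------------------------------------------- resampling
    def _permutation_test(self, xz: np.ndarray, yz: np.ndarray, rng) -> None:
        n = xz.shape[0]
        null = np.empty(self.n_permutations)
        for b in range(self.n_permutations):
            perm = rng.permutation(n)
            r = yz[perm].T @ xz / (n - 1)
            null[b] = np.linalg.norm(r)
        self.perm_null_ = null
        self.p_value_ = (1 + np.sum(null >= self.singular_value_)) / (
            1 + self.n_permutations
        )

    def _bootstrap(self, X: np.ndarray, y: np.ndarray, rng) -> None:
        n, p = X.shape
        boots = np.empty((self.n_bootstrap, p))
        redraws = 0
        for b in range(self.n_bootstrap):
            while True:
                idx = rng.integers(0, n, size=n)
                xb, yb = X[idx], y[idx]
                if xb.std(axis=0).min() > 0 and yb.std() > 0:
                    break
                redraws += 1
            xzb, _, _ = _standardize(xb)
            yzb, _, _ = _standardize(yb[:, None])
            _, _, vb = _svd_single_outcome(yzb.T @ xzb / (n - 1))
            boots[b] = vb  # u=+1 convention: already sign-consistent with the fit
        if redraws > 0.1 * self.n_bootstrap:
            warnings.warn(
                f"{redraws} bootstrap redraws due to zero-variance columns", stacklevel=2
            )
        self.boot_redraws_ = redraws
        self.boot_saliences_ = boots
        self.boot_mean_ = boots.mean(axis=0)
        self.boot_sd_ = boots.std(axis=0, ddof=1)
        lo, hi = self.boot_percentiles
        self.boot_low_ = np.percentile(boots, lo, axis=0)
        self.boot_high_ = np.percentile(boots, hi, axis=0)
        if self.robust == "percentile":
            self.robust_mask_ = (self.boot_low_ > 0) | (self.boot_high_ < 0)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(self.boot_sd_ > 0, self.boot_mean_ / self.boot_sd_, 0.0)
            self.robust_mask_ = np.abs(ratio) > self.ratio_threshold

    # ---------------------------------------------------------- transform
    def transform(self, X, y=None):
        """Project new subjects with the learnt standardization and saliences.

        Returns Lx, or (Lx, Ly) when ``y`` is given.
        """
        check_is_fitted(self, "x_saliences_")
        X = np.asarray(X, dtype=float)
        lx = ((X - self.x_mean_) / self.x_std_) @ self.x_saliences_
        if y is None:
            return lx
        y = np.asarray(y, dtype=float).reshape(-1)
        ly = (y - self.y_mean_[0]) / self.y_std_[0] * self.y_saliences_
        return lx, ly

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X, y)


def fit_plsc(X, y, **kwargs) -> PLSCorrelation:
    """Convenience wrapper: fit a :class:`PLSCorrelation` on (X, y)."""
    return PLSCorrelation(**kwargs).fit(X, y)


def loocv_scores(X, y, subject_ids=None) -> LoocvScores:
    """Leave-one-out robustness of the PLSC latent scores.

    For each fold the model (standardization + saliences) is learnt on the
    remaining subjects and applied to the held-out one; each fold is
    sign-aligned to the full-sample fit. Reported are the per-subject pairs of
    full-model and cross-validated scores and their Pearson correlations.
    Folds whose training block has a zero-variance column are flagged,
    excluded, and warned about.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects for LOOCV")
    full = PLSCorrelation(n_permutations=0, n_bootstrap=0).fit(X, y)
    lx_full, ly_full = full.transform(X, y)

    lx_cv = np.full(n, np.nan)
    ly_cv = np.full(n, np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fold = PLSCorrelation(n_permutations=0, n_bootstrap=0).fit(X[mask], y[mask])
        except ValueError as exc:
            warnings.warn(f"fold {i} excluded: {exc}", stacklevel=2)
            continue
        lx_cv[i], ly_cv[i] = (s[0] for s in fold.transform(X[i : i + 1], y[i : i + 1]))

    ok = ~np.isnan(lx_cv)
    r_brain = float(stats.pearsonr(lx_full[ok], lx_cv[ok])[0])
    r_outcome = float(stats.pearsonr(ly_full[ok], ly_cv[ok])[0])
    if subject_ids is None:
        subject_ids = np.arange(n)
    scores = pd.DataFrame(
        {
            "subject": subject_ids,
            "lx_full": lx_full,
            "lx_cv": lx_cv,
            "ly_full": ly_full,
            "ly_cv": ly_cv,
        }
    )
    return LoocvScores(scores=scores, r_brain=r_brain, r_outcome=r_outcome)
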