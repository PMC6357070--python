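"""Orthogonal projections to latent structures discriminant analysis (OPLS-DA).

Splits predictor variation into a single class-predictive latent component
and ``n_orth`` class-orthogonal components, following the classical
NIPALS-style deflation for a univariate response: at each orthogonal round
the candidate predictive weight w is computed from the current X, the
loading component orthogonal to w is extracted and removed from X, and the
final one-component PLS model is fitted on the filtered matrix.

The estimator follows the scikit-learn protocol (fit/transform/predict,
fitted attributes with trailing underscores) so it composes with sklearn
pipelines and model selection. X is expected samples x variables; the
binary class membership is encoded -1/+1.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import ValidationError


class OPLSDA(TransformerMixin, BaseEstimator):
    """OPLS-DA with one predictive and ``n_orth`` orthogonal components.

    Parameters
    ----------
    n_orth : int, default 1
        Number of orthogonal (class-uncorrelated) components removed before
        the predictive component is fitted.
    scale : bool, default True
        Autoscale X to unit variance (after centering) before fitting, the
        convention for metabolomics concentration tables.

    Attributes
    ----------
    x_mean_, x_std_ : centering/scaling vectors applied to X
    y_mean_ : response centering scalar
    w_ : (p,) predictive weight (unit norm)
    t_ : (n,) predictive score
    p_ : (p,) predictive X loading
    c_ : float, response loading
    w_orth_, t_orth_, p_orth_ : orthogonal weights (k x p), scores (n x k),
        loadings (k x p)
    r2y_ : fraction of (centered) response variance explained on training data
    """

    def __init__(self, n_orth: int = 1, scale: bool = True):
        self.n_orth = n_orth
        self.scale = scale

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean_) / self.x_std_

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValidationError("X and y sample counts differ")
        if self.n_orth < 0:
            raise ValidationError("n_orth must be >= 0")
        if X.shape[0] <= self.n_orth + 1:
            raise ValidationError("too few samples for the requested component count")

        self.x_mean_ = X.mean(axis=0)
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            if (sd == 0).any():
                j = int(np.argmax(sd == 0))
                raise ValidationError(f"constant column {j} cannot be autoscaled")
            self.x_std_ = sd
        else:
            self.x_std_ = np.ones(X.shape[1])
        self.y_mean_ = y.mean()

        Xc = self._preprocess(X)
        yc = y - self.y_mean_
        if np.allclose(yc, 0):
            raise ValidationError("response has no variance")

        w_orth_list, t_orth_list, p_orth_list = [], [], []
        for _ in range(self.n_orth):
            w = Xc.T @ yc
            w /= np.linalg.norm(w)
            t = Xc @ w
            p = Xc.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:
                break  # no orthogonal variation left
            w_o /= norm
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            w_orth_list.append(w_o)
            t_orth_list.append(t_o)
            p_orth_list.append(p_o)

        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        c = float(yc @ t / (t @ t))

        self.w_ = w
        self.t_ = t
        self.p_ = p
        self.c_ = c
        n_kept = len(w_orth_list)
        self.w_orth_ = (
            np.array(w_orth_list) if n_kept else np.empty((0, X.shape[1]))
        )
        self.t_orth_ = (
            np.array(t_orth_list).T if n_kept else np.empty((X.shape[0], 0))
        )
        self.p_orth_ = (
            np.array(p_orth_list) if n_kept else np.empty((0, X.shape[1]))
        )
        resid = yc - t * c
        self.r2y_ = float(1.0 - (resid @ resid) / (yc @ yc))
        self.n_features_in_ = X.shape[1]
        return self

    def _filter(self, Xc: np.ndarray) -> np.ndarray:
        """Remove the fitted orthogonal components from preprocessed data."""
        for k in range(self.w_orth_.shape[0]):
            t_o = Xc @ self.w_orth_[k]
            Xc = Xc - np.outer(t_o, self.p_orth_[k])
        return Xc

    def transform(self, X):
        """Predictive score of new samples after orthogonal filtering."""
        check_is_fitted(self, "w_")
        Xc = self._filter(self._preprocess(check_array(X, dtype=float)))
        return (Xc @ self.w_).reshape(-1, 1)

    def predict(self, X):
        """Continuous prediction of the -1/+1 response."""
        t = self.transform(X).ravel()
        return t * self.c_ + self.y_mean_

    def decision_function(self, X):
        return self.predict(X)

    def score(self, X, y):
        """R2 of the response prediction (sklearn regression convention)."""
        y = np.asarray(y, dtype=float).ravel()
        resid = y - self.predict(X)
        yc = y - y.mean()
        return float(1.0 - (resid @ resid) / (yc @ yc))


def vip(model: OPLSDA) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt( p * sum_a SS_a (w_aj/||w_a||)^2 / sum_a SS_a ) where p is
    the number of variables and SS_a the response sum of squares explained
    by component a. With a single predictive component this reduces to
    sqrt(p) * |w_j| / ||w||, and the mean of squared VIPs is exactly 1.
    """
    check_is_fitted(model, "w_")
    w = model.w_
    p = w.size
    return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)
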