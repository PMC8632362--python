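"""Multi-output ridge regression with contiguous-block inner CV.

All cross-subject and stimulus models in this package are penalised linear
maps fit per outer fold, with the penalty chosen by inner cross-validation on
contiguous sub-blocks of the training events (shuffled inner splits would
leak through temporal autocorrelation exactly like shuffled outer folds).

Implementation notes
--------------------
Predictors and responses are z-scored per column on training statistics and
predictions are un-scaled afterwards, which absorbs the intercept.  The
penalty path is evaluated through a single eigendecomposition of the
(standardised) Gram matrix ``X'X = V diag(w) V'`` per training set, so adding
penalties to the grid is nearly free:

    W(lam) = V diag(1 / (w + lam)) V' X'Y.

Penalty ties are broken toward the largest penalty (prefer regularisation).
The X-side quantities (statistics, eigendecomposition, projected validation
blocks) depend only on the predictor matrix and split, so they are cached and
shared across every response that reuses the same predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .folds import inner_splits

DEFAULT_LAMBDAS = tuple(10.0 ** np.arange(0, 7))
_STD_FLOOR = 1e-12


def _stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < _STD_FLOOR] = 1.0  # constant columns carry no signal; leave centred zeros
    return mean, std


class RidgeDesign:
    """Reusable X-side quantities for one predictor matrix and one training set.

    Parameters
    ----------
    X
        Full predictor matrix (all events x d).
    train_idx
        Outer-fold training event indices.
    n_inner
        Number of contiguous inner validation blocks for penalty selection.
    inner_edge_drop
        Edge events dropped around inner validation blocks (None = automatic).
    """

    def __init__(
        self,
        X: np.ndarray,
        train_idx: np.ndarray,
        n_inner: int = 3,
        inner_edge_drop: int | None = None,
    ):
        X = np.asarray(X, float)
        self.X = X
        self.train_idx = np.asarray(train_idx)
        if np.isnan(X[self.train_idx]).any():
            raise ValueError("NaNs in predictor matrix on training events")
        self.splits = []
        for tr, val in inner_splits(self.train_idx, n_inner, inner_edge_drop):
            mean, std = _stats(X[tr])
            Xtr = (X[tr] - mean) / std
            w, V = np.linalg.eigh(Xtr.T @ Xtr)
            XvalV = ((X[val] - mean) / std) @ V
            self.splits.append(
                {"tr": tr, "val": val, "mean": mean, "std": std, "w": w, "V": V, "XvalV": XvalV}
            )
        mean, std = _stats(X[self.train_idx])
        Xtr = (X[self.train_idx] - mean) / std
        w, V = np.linalg.eigh(Xtr.T @ Xtr)
        self.final = {"mean": mean, "std": std, "w": w, "V": V}


@dataclass
class FittedRidge:
    """A fitted penalised linear map Y ~ XW + b in original units."""

    W: np.ndarray  # (d_in, d_out) on the standardised scale
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_std
        return Xs @ self.W * self.y_std + self.y_mean


def fit_ridge_cv(design: RidgeDesign, Y: np.ndarray, lambdas=DEFAULT_LAMBDAS) -> FittedRidge:
    """Fit ridge on the design's training set, penalty chosen by inner CV (MSE)."""
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(Y[design.train_idx]).any():
        raise ValueError("NaNs in response matrix on training events")
    lambdas = np.sort(np.asarray(lambdas, float))
    if lambdas.size == 0:
        raise ValueError("empty penalty grid")

    if lambdas.size == 1:
        best = lambdas[0]
    else:
        mse = np.zeros(len(lambdas))
        for sp in design.splits:
            ym, ys = _stats(Y[sp["tr"]])
            Ytr = (Y[sp["tr"]] - ym) / ys
            Xtr = (design.X[sp["tr"]] - sp["mean"]) / sp["std"]
            A = sp["V"].T @ (Xtr.T @ Ytr)
            Yval = (Y[sp["val"]] - ym) / ys
            for li, lam in enumerate(lambdas):
                pred = (sp["XvalV"] / (sp["w"] + lam)) @ A
                mse[li] += ((pred - Yval) ** 2).mean()
        # ties -> largest penalty
        best = lambdas[::-1][np.argmin(mse[::-1])]

    f = design.final
    ym, ys = _stats(Y[design.train_idx])
    Ytr = (Y[design.train_idx] - ym) / ys
    A = f["V"].T @ (((design.X[design.train_idx] - f["mean"]) / f["std"]).T @ Ytr)
    W = f["V"] @ (A / (f["w"] + best)[:, None])
    return FittedRidge(W, f["mean"], f["std"], ym, ys, float(best))
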