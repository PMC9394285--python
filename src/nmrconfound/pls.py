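"""Latent-variable discriminant models: PCA, (sparse) PLS-DA with VIP
scores, Mahalanobis class prediction in score space, and an L1-regularized
logistic alternative.

PLS-DA is fit by NIPALS on mean-centered X against a centered one-column-
per-class dummy Y (Y is not deflated; X is deflated per component).  The
sparse variant caps the number of nonzero weights per component (keepX
semantics: hard truncation of the weight vector to its largest-magnitude
entries, renormalized).  Component signs are fixed by forcing the
largest-|weight| entry positive so fitted models are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "pca",
    "PLSDA",
    "SparsePLSDA",
    "PLSDAResults",
    "vip",
    "predict_mahalanobis",
    "l1_logistic_fit",
    "L1LogisticModel",
]


def pca(X: np.ndarray, ncomp: int | None = None, center: bool = True):
    """Principal component analysis via SVD.

    Returns ``(scores, loadings, explained)`` with orthonormal loading
    columns, ``scores = Xc @ loadings`` and nonincreasing explained-
    variance fractions.  ``ncomp`` beyond the matrix rank is reduced with
    a warning.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0) if center else X
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if ncomp is None:
        ncomp = rank
    elif ncomp > rank:
        warnings.warn(f"ncomp={ncomp} exceeds rank {rank}; reduced", stacklevel=2)
        ncomp = rank
    total = (s**2).sum()
    explained = (s[:ncomp] ** 2) / total if total > 0 else np.zeros(ncomp)
    loadings = Vt[:ncomp].T
    # deterministic orientation: largest-|loading| entry positive
    for a in range(ncomp):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
    scores = Xc @ loadings
    return scores, loadings, explained


def _dummy(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


class PLSDA:
    """Partial least squares discriminant analysis model.

    Parameters
    ----------
    X : (n, p) feature matrix (not scaled; centering is done by the fit).
    y : (n,) class labels; >= 2 classes with >= 2 samples each.
    n_components : number of latent variables to extract.
    """

    sparse = False

    def __init__(self, X, y, n_components: int = 2):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n, p) with one label per row")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("PLSDA requires >= 2 classes")
        if (counts < 2).any():
            raise ValueError("every class needs >= 2 samples")
        max_a = min(X.shape[0] - 1, X.shape[1])
        if n_components > max_a:
            raise ValueError(f"n_components={n_components} exceeds min(n-1, p)={max_a}")
        self.X = X
        self.y = y
        self.classes = classes
        self.n_components = n_components

    # -- weight post-processing hook for the sparse subclass --------------
    def _shrink(self, w: np.ndarray, a: int) -> np.ndarray:
        return w

    def fit(self) -> "PLSDAResults":
        X = self.X
        n, p = X.shape
        A = self.n_components
        x_mean = X.mean(axis=0)
        Y = _dummy(self.y, self.classes)
        y_mean = Y.mean(axis=0)
        Xd = X - x_mean
        Yc = Y - y_mean
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        C = np.zeros((len(self.classes), A))
        T = np.zeros((n, A))
        for a in range(A):
            u = Yc[:, np.argmax(Yc.var(axis=0))].copy()
            t = np.zeros(n)
            for _ in range(500):
                w = Xd.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise ValueError("no remaining X variance to extract")
                w /= nw
                w = self._shrink(w, a)
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise ValueError("all weights truncated to zero")
                w /= nw
                t_new = Xd @ w
                c = Yc.T @ t_new / (t_new @ t_new)
                u = Yc @ c / (c @ c)
                if np.linalg.norm(t_new - t) <= 1e-12 * max(np.linalg.norm(t_new), 1e-300):
                    t = t_new
                    break
                t = t_new
            # fix component sign for reproducibility
            j = np.argmax(np.abs(w))
            if w[j] < 0:
                w, t = -w, -t
            tt = t @ t
            if tt == 0:
                raise ValueError("degenerate component with zero score variance")
            pvec = Xd.T @ t / tt
            c = Yc.T @ t / tt
            Xd = Xd - np.outer(t, pvec)
            W[:, a], P[:, a], C[:, a], T[:, a] = w, pvec, c, t
        ssy = (T**2).sum(axis=0) * (C**2).sum(axis=0)
        return PLSDAResults(self, x_mean, y_mean, W, P, C, T, ssy)


class SparsePLSDA(PLSDA):
    """PLS-DA with a per-component cap on retained variables (keepX).

    ``keep_x`` is an int (same cap for all components) or a sequence with
    one cap per component; each component's weight vector keeps only its
    keepX largest-magnitude entries.
    """

    sparse = True

    def __init__(self, X, y, n_components: int = 2, keep_x=None):
        super().__init__(X, y, n_components)
        p = self.X.shape[1]
        if keep_x is None:
            keep_x = p
        if np.isscalar(keep_x):
            keep_x = [int(keep_x)] * n_components
        keep_x = [int(k) for k in keep_x]
        if len(keep_x) != n_components:
            raise ValueError("keep_x must give one cap per component")
        if any(k < 1 for k in keep_x):
            raise ValueError("keepX must be >= 1")
        if any(k > p for k in keep_x):
            raise ValueError(f"keepX exceeds number of features ({p})")
        self.keep_x = keep_x

    def _shrink(self, w: np.ndarray, a: int) -> np.ndarray:
        k = self.keep_x[a]
        if k >= len(w):
            return w
        out = np.zeros_like(w)
        idx = np.argpartition(np.abs(w), -k)[-k:]
        out[idx] = w[idx]
        return out


@dataclass
class PLSDAResults:
    """Fitted (sparse) PLS-DA model: weights, loadings, scores, class
    score-space statistics, and per-component explained Y-variance."""

    model: PLSDA
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # W, (p, A), unit-norm columns
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # C, (g, A)
    x_scores: np.ndarray  # T, (n, A), mutually orthogonal columns
    ssy: np.ndarray  # explained Y variance per component
    _stats_cache: dict = field(default_factory=dict, repr=False)

    @property
    def classes(self):
        return self.model.classes

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def _ncomp(self, ncomp) -> int:
        a = self.n_components if ncomp is None else int(ncomp)
        if not 1 <= a <= self.n_components:
            raise ValueError(f"ncomp must be in [1, {self.n_components}]")
        return a

    def rotation(self, ncomp=None) -> np.ndarray:
        """R = W (P'W)^-1 : projects centered X onto the score space."""
        a = self._ncomp(ncomp)
        W, P = self.x_weights[:, :a], self.x_loadings[:, :a]
        return W @ np.linalg.inv(P.T @ W)

    def transform(self, Xnew, ncomp=None) -> np.ndarray:
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        return (Xnew - self.x_mean) @ self.rotation(ncomp)

    def class_stats(self, ncomp=None):
        """Per-class score means and the pooled within-class covariance
        (within-class centering, n - g denominator; ridge-regularized on
        singularity)."""
        a = self._ncomp(ncomp)
        if a in self._stats_cache:
            return self._stats_cache[a]
        T = self.x_scores[:, :a]
        y = self.model.y
        g = len(self.classes)
        means = np.vstack([T[y == c].mean(axis=0) for c in self.classes])
        resid = T - means[np.searchsorted(self.classes, y)]
        cov = resid.T @ resid / max(len(y) - g, 1)
        try:
            cov_inv = np.linalg.inv(cov)
            if not np.isfinite(cov_inv).all():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("singular pooled covariance; ridge-regularized", stacklevel=2)
            eps = 1e-8 * np.trace(cov) / a if np.trace(cov) > 0 else 1e-8
            cov = cov + eps * np.eye(a)
            cov_inv = np.linalg.inv(cov)
        self._stats_cache[a] = (means, cov, cov_inv)
        return self._stats_cache[a]

    def mahalanobis(self, Xnew, ncomp=None) -> np.ndarray:
        """Squared Mahalanobis distance of projected samples to each class
        score-mean under the pooled within-class covariance; (n, g)."""
        a = self._ncomp(ncomp)
        t = self.transform(Xnew, a)
        means, _, cov_inv = self.class_stats(a)
        d = np.empty((t.shape[0], len(self.classes)))
        for k, mu in enumerate(means):
            diff = t - mu
            d[:, k] = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
        return d

    def predict(self, Xnew, ncomp=None) -> np.ndarray:
        """Assign each sample to the nearest class by Mahalanobis distance
        in score space (ties break to the first class in sorted order)."""
        d = self.mahalanobis(Xnew, ncomp)
        return self.classes[np.argmin(d, axis=1)]

    def coefficients(self, ncomp=None) -> np.ndarray:
        """Regression coefficients B (p, g) mapping centered X to the
        centered class indicators: Y_hat = (X - x_mean) B + y_mean."""
        a = self._ncomp(ncomp)
        return self.rotation(a) @ self.y_loadings[:, :a].T

    def contrast_coef(self, positive, negative, ncomp=None) -> np.ndarray:
        """Per-feature coefficient for a binary contrast (positive minus
        negative class column)."""
        B = self.coefficients(ncomp)
        i = int(np.where(self.classes == positive)[0][0])
        j = int(np.where(self.classes == negative)[0][0])
        return B[:, i] - B[:, j]

    def vip(self, ncomp=None) -> np.ndarray:
        return vip(self, ncomp)

    def summary(self) -> str:
        a = self.n_components
        frac = self.ssy / self.ssy.sum() if self.ssy.sum() > 0 else self.ssy
        kind = "Sparse PLS-DA" if self.model.sparse else "PLS-DA"
        lines = [
            f"{kind} results",
            f"  samples: {self.x_scores.shape[0]}, features: {self.x_weights.shape[0]}",
            f"  classes: {', '.join(map(str, self.classes))}",
            f"  components: {a}",
            "  explained Y-variance share per component: "
            + ", ".join(f"{f:.3f}" for f in frac),
        ]
        if self.model.sparse:
            lines.append(f"  keepX: {self.model.keep_x}")
        nsel = int((np.abs(self.x_weights).sum(axis=1) > 0).sum())
        lines.append(f"  features with nonzero weight: {nsel}")
        return "\n".join(lines)


def vip(results: PLSDAResults, ncomp=None) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a ssy_a (w_ja / ||w_a||)^2 / sum_a ssy_a );
    the mean of VIP^2 over features is exactly 1.
    """
    a = results._ncomp(ncomp)
    W = results.x_weights[:, :a]
    ssy = results.ssy[:a]
    if not (ssy > 0).any():
        raise ValueError("no explained Y variance; VIP undefined")
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    p = W.shape[0]
    return np.sqrt(p * ((W / norms) ** 2 @ ssy) / ssy.sum())


def predict_mahalanobis(results: PLSDAResults, Xnew, ncomp=None):
    """Labels and score coordinates for new samples (projection followed by
    nearest class mean under the pooled score covariance)."""
    labels = results.predict(Xnew, ncomp)
    return labels, results.transform(Xnew, ncomp)


# ---------------------------------------------------------------------------
# L1-regularized logistic regression (binary)
# ---------------------------------------------------------------------------

@dataclass
class L1LogisticModel:
    """Lasso-penalized logistic model selected on a lambda path."""

    classes: np.ndarray
    lambda_path: np.ndarray
    cv_error: np.ndarray
    coef_path: np.ndarray  # (n_lambda, p)
    chosen_lambda: float
    coef: np.ndarray
    intercept: float
    scaled: bool

    @property
    def nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.coef)

    def summary(self) -> str:
        return (
            "L1 logistic regression\n"
            f"  classes: {self.classes[0]} (0) vs {self.classes[1]} (1)\n"
            f"  chosen lambda: {self.chosen_lambda:.4g} "
            f"(CV misclassification {self.cv_error[np.argmin(self.cv_error)]:.3f})\n"
            f"  nonzero coefficients: {len(self.nonzero)} / {len(self.coef)}"
        )


def l1_logistic_fit(
    X,
    y,
    lambda_grid=None,
    cv_folds: int = 10,
    scale: bool = False,
    seed: int = 0,
) -> L1LogisticModel:
    """Fit an L1-penalized logistic classifier over a decreasing lambda
    grid and keep the grid value minimizing cross-validated
    misclassification ("class" criterion, minimum-lambda rule).

    ``scale=True`` autoscales columns to unit variance (used when mixing
    metabolite intensities with clinical covariates).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("l1_logistic_fit is binary only")
    ybin = (y == classes[1]).astype(int)
    n, p = X.shape
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if lambda_grid is None:
        # glmnet-style: from the smallest lambda zeroing everything down
        lam_max = np.abs(X.T @ (ybin - ybin.mean())).max() / n
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, 30)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) > 0):
        raise ValueError("lambda_grid must be decreasing")

    def _profile_intercept(Xtr, ytr, w, b0):
        # the intercept is unpenalized: polish it by 1-D Newton given w
        eta = Xtr @ w
        b = b0
        for _ in range(50):
            prob = 1.0 / (1.0 + np.exp(-(eta + b)))
            grad = prob.mean() - ytr.mean()
            hess = (prob * (1 - prob)).mean()
            if hess <= 0:
                break
            step = grad / hess
            b -= step
            if abs(step) < 1e-12:
                break
        return b

    def fit_one(Xtr, ytr, lam):
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (lam * len(ytr)),
            solver="saga",
            max_iter=20000,
            tol=1e-8,
        ).fit(Xtr, ytr)
        clf.intercept_[0] = _profile_intercept(
            Xtr, ytr, clf.coef_.ravel(), clf.intercept_[0]
        )
        return clf

    cv_folds = min(cv_folds, np.bincount(ybin).min())
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(lambda_grid))
    for tr, te in skf.split(X, ybin):
        for li, lam in enumerate(lambda_grid):
            clf = fit_one(X[tr], ybin[tr], lam)
            errors[li] += (clf.predict(X[te]) != ybin[te]).sum()
    errors /= n
    best = int(np.argmin(errors))
    coef_path = np.zeros((len(lambda_grid), p))
    for li, lam in enumerate(lambda_grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef_path[li] = fit_one(X, ybin, lam).coef_.ravel()
    final = fit_one(X, ybin, lambda_grid[best])
    return L1LogisticModel(
        classes=classes,
        lambda_path=lambda_grid,
        cv_error=errors,
        coef_path=coef_path,
        chosen_lambda=float(lambda_grid[best]),
        coef=final.coef_.ravel(),
        intercept=float(final.intercept_[0]),
        scaled=scale,
    )
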