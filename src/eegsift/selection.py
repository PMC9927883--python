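"""Feature screening, repeated NCA weighting and step-down optimization.

The three selection stages ahead of classifier evaluation:

1. univariate screen — equal-variance two-sample t-test per feature,
   retaining P < 0.05 (uncorrected);
2. z-scoring and repeated neighbourhood-component-analysis (NCA) feature
   weighting — the diagonal (per-feature-weight) NCA variant fitted many
   times under random initialization and subsampling, mean weights
   thresholded relative to the maximum;
3. greedy step-down elimination of redundant features while monitoring
   SVM cross-validation accuracy.

`TTestScreen` and `NCAFeatureSelector` are scikit-learn selector
transformers and compose with Pipelines; the module-level functions are
thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y


class TTestScreen(SelectorMixin, BaseEstimator):
    """Univariate screen: equal-variance two-sample t-test per feature.

    Features with P < ``alpha`` are retained. Constant features (zero
    variance in both classes, undefined t) are excluded with a warning.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("screening requires exactly two classes")
        a, b = X[y == classes[0]], X[y == classes[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least two subjects per class")
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = np.asarray(t), np.asarray(p)
        bad = ~np.isfinite(p)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} constant feature(s) excluded from screening",
                RuntimeWarning,
            )
            p = np.where(bad, 1.0, p)
        self.tvalues_ = t
        self.pvalues_ = p
        self.support_ = p < self.alpha
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def zscore(X: np.ndarray) -> np.ndarray:
    """Standardize columns to mean 0, SD 1 over all subjects."""
    return StandardScaler().fit_transform(np.asarray(X, dtype=float))


class DiagonalNCA(BaseEstimator):
    """Feature-weight (diagonal) neighbourhood component analysis.

    Learns one non-negative relevance weight per feature by maximizing the
    expected leave-one-out accuracy of a soft nearest-neighbour rule with
    the weighted L1 distance ``d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|``
    and reference-point kernel ``exp(-d / sigma)``, minus an L2 penalty
    ``reg * sum_r w_r^2``. Optimized with L-BFGS from a random positive
    initialization.

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,)
        Learned relevance weights ``w_r^2`` (larger = more discriminative).
    objective_ : float
        Final penalized leave-one-out objective.
    """

    def __init__(self, sigma: float = 1.0, reg: float | None = None,
                 max_iter: int = 100, random_state: int | None = None):
        self.sigma = sigma
        self.reg = reg
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n, p = X.shape
        reg = self.reg if self.reg is not None else 1.0 / n
        rng = np.random.default_rng(self.random_state)
        same = (y[:, None] == y[None, :]).astype(float)
        np.fill_diagonal(same, 0.0)
        # |x_ir - x_jr| tensor; n and p are modest post-screening
        diff = np.abs(X[:, None, :] - X[None, :, :])

        def neg_obj_grad(w):
            w2 = w * w
            d = diff @ w2
            np.fill_diagonal(d, np.inf)
            k = np.exp(-d / self.sigma)
            denom = k.sum(axis=1, keepdims=True)
            denom[denom == 0] = 1.0
            pij = k / denom
            pi = (pij * same).sum(axis=1)
            f = pi.mean() - reg * w2.sum()
            # dF/d(w2_r) = (1/(n sigma)) sum_i sum_j pij (pi_i - same_ij) |diff_ijr| - reg
            coef = pij * (pi[:, None] - same)
            grad_w2 = np.tensordot(coef, diff, axes=([0, 1], [0, 1])) / (n * self.sigma) - reg
            grad_w = 2.0 * w * grad_w2
            return -f, -grad_w

        w0 = rng.uniform(0.5, 1.5, size=p)
        res = optimize.minimize(
            neg_obj_grad, w0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        self.weights_ = res.x**2
        self.objective_ = -float(res.fun)
        self.n_features_in_ = p
        return self


class NCAFeatureSelector(SelectorMixin, BaseEstimator):
    """Repeated diagonal-NCA weighting with relative-to-max retention.

    The NCA is fitted ``n_reps`` times, each on a random ``subsample``
    fraction of subjects (stratified by drawing without replacement) and
    from a fresh random initialization; per-feature weights are averaged.
    Features whose mean weight exceeds ``tau`` times the maximum mean
    weight are retained.
    """

    def __init__(self, n_reps: int = 1000, tau: float = 0.05,
                 subsample: float = 0.8, sigma: float = 1.0,
                 reg: float | None = None, max_iter: int = 100,
                 random_state: int | None = None):
        self.n_reps = n_reps
        self.tau = tau
        self.subsample = subsample
        self.sigma = sigma
        self.reg = reg
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        X, y = check_X_y(X, y)
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        acc = np.zeros(p)
        for _ in range(self.n_reps):
            if self.subsample < 1.0:
                m = max(int(round(self.subsample * n)), 4)
                idx = rng.choice(n, size=m, replace=False)
                if len(np.unique(y[idx])) < 2:  # resample until both classes present
                    continue
            else:
                idx = np.arange(n)
            nca = DiagonalNCA(
                sigma=self.sigma, reg=self.reg, max_iter=self.max_iter,
                random_state=int(rng.integers(2**31 - 1)),
            )
            nca.fit(X[idx], y[idx])
            acc += nca.weights_
        self.weights_ = acc / self.n_reps
        wmax = self.weights_.max()
        self.support_ = self.weights_ > self.tau * wmax if wmax > 0 else \
            np.zeros(p, dtype=bool)
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def make_svm(C: float = 1.0) -> SVC:
    """The linear SVM used throughout (C = 1)."""
    return SVC(kernel="linear", C=C)


def cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    C: float = 1.0,
) -> float:
    """Mean linear-SVM accuracy over repeated stratified k-fold CV.

    Folds are re-randomized every repetition; accuracies are averaged over
    all folds and repetitions.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    # a fold needs at least one subject of each class
    folds = min(folds, int(np.bincount(np.unique(y, return_inverse=True)[1]).min()))
    if folds < 2:
        raise ValueError("need at least two subjects per class for cross-validation")
    accs = []
    for _ in range(reps):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        correct = 0
        for tr, te in skf.split(X, y):
            clf = make_svm(C).fit(X[tr], y[tr])
            correct += (clf.predict(X[te]) == y[te]).sum()
        accs.append(correct / len(y))
    return float(np.mean(accs))


def stepdown(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str],
    folds: int = 5,
    reps: int = 20,
    tolerance: float = 0.005,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], list[float]]:
    """Greedy backward elimination of redundant features.

    At each iteration the feature whose removal yields the highest CV
    accuracy is dropped; elimination stops when the best achievable
    accuracy after a removal falls more than ``tolerance`` below the
    running best. Returns the surviving columns and the accuracy trace
    (starting with the full-set accuracy).
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    keep = list(range(X.shape[1]))
    trace = [cv_accuracy(X, y, folds, reps, rng)]
    best = trace[0]
    while len(keep) > 1:
        cand_accs = []
        for drop in range(len(keep)):
            cols = keep[:drop] + keep[drop + 1 :]
            cand_accs.append(cv_accuracy(X[:, cols], y, folds, reps, rng))
        i_best = int(np.argmax(cand_accs))
        if cand_accs[i_best] < best - tolerance:
            break
        keep.pop(i_best)
        trace.append(cand_accs[i_best])
        best = max(best, cand_accs[i_best])
    return [columns[i] for i in keep], trace


@dataclass
class SelectionResult:
    """Outcome of the three selection stages."""

    screened: list[str]
    screen_pvalues: dict[str, float]
    nca_weights: dict[str, float]
    nca_selected: list[str]
    selected: list[str]
    cv_accuracy_trace: list[float] = field(default_factory=list)
    validation_accuracy: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "screened": self.screened,
            "screen_pvalues": self.screen_pvalues,
            "nca_weights": self.nca_weights,
            "nca_selected": self.nca_selected,
            "selected": self.selected,
            "cv_accuracy_trace": self.cv_accuracy_trace,
            "validation_accuracy": self.validation_accuracy,
        }


def select_features(
    X,
    y,
    columns: list[str] | None = None,
    alpha: float = 0.05,
    nca_reps: int = 1000,
    tau: float = 0.05,
    cv_folds: int = 5,
    cv_reps: int = 1000,
    stepdown_reps: int = 20,
    stepdown_tolerance: float = 0.005,
    seed: int | None = None,
) -> SelectionResult:
    """Run screen -> z-score -> repeated NCA -> CV check -> step-down.

    ``cv_reps`` controls the validation-accuracy estimate of the NCA-chosen
    set; the step-down inner loop uses the cheaper ``stepdown_reps``.
    Z-scoring is fitted on the full sample ahead of selection, mirroring
    the screening-first ordering of the overall procedure (a train-only
    variant belongs to evaluation, not selection).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if columns is None:
        columns = [f"f{i}" for i in range(X.shape[1])]
    rng = np.random.default_rng(seed)

    screen = TTestScreen(alpha=alpha).fit(X, y)
    screened_cols = [c for c, s in zip(columns, screen.support_) if s]
    pvals = {c: float(p) for c, p in zip(columns, screen.pvalues_)}
    if not screened_cols:
        return SelectionResult([], pvals, {}, [], [], [], float("nan"))
    Xs = zscore(X[:, screen.support_])

    nca = NCAFeatureSelector(
        n_reps=nca_reps, tau=tau,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(Xs, y)
    weights = {c: float(w) for c, w in zip(screened_cols, nca.weights_)}
    nca_cols = [c for c, s in zip(screened_cols, nca.support_) if s]
    if not nca_cols:
        return SelectionResult(screened_cols, pvals, weights, [], [], [], float("nan"))
    Xn = Xs[:, nca.support_]

    val_acc = cv_accuracy(Xn, y, cv_folds, cv_reps, rng)
    selected, trace = stepdown(
        Xn, y, nca_cols, folds=cv_folds, reps=stepdown_reps,
        tolerance=stepdown_tolerance, rng=rng,
    )
    return SelectionResult(
        screened=screened_cols,
        screen_pvalues=pvals,
        nca_weights=weights,
        nca_selected=nca_cols,
        selected=selected,
        cv_accuracy_trace=trace,
        validation_accuracy=val_acc,
    )


def screen(X, y, alpha: float = 0.05) -> np.ndarray:
    """Boolean retention mask of the univariate t-test screen."""
    return TTestScreen(alpha=alpha).fit(X, y).support_


def nca_select(X, y, n_reps: int = 1000, tau: float = 0.05,
               rng: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean NCA weights and the retained-feature mask."""
    sel = NCAFeatureSelector(n_reps=n_reps, tau=tau, random_state=rng).fit(X, y)
    return sel.weights_, sel.support_
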