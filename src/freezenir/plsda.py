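"""PLS discriminant analysis with per-class thresholds and a no-match class.

The regression is SIMPLS onto a one-hot class-indicator response. The number
of latent variables is chosen by leave-one-out cross-validation minimizing
the misclassification count (smallest count within 1% of the minimum, for
parsimony). Per-class decision cutoffs on the predicted indicator values are
set where the two Gaussian densities fitted to the in-class and out-of-class
calibration predictions cross (a Bayes threshold with empirical priors);
samples whose predictions clear no cutoff are assigned ``no_match``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from freezenir.preprocess import PreprocessConfig, second_derivative
from freezenir.spectra_io import CLASSES, NO_MATCH, SpectraSet
from freezenir.simca import ClassificationResult

MAX_LATENT = 15


@dataclass
class PlsdaModel:
    x_mean: np.ndarray               # (P,)
    y_mean: np.ndarray               # (C,)
    weights: np.ndarray              # (P, a) SIMPLS weight vectors R
    x_loadings: np.ndarray           # (P, a)
    y_loadings: np.ndarray           # (C, a)
    a: int
    coefficients: np.ndarray         # (P, C) regression matrix B
    class_thresholds: np.ndarray     # (C,)
    classes: list[str] = None        # type: ignore[assignment]
    pretreatment: PreprocessConfig | None = None
    threshold_rule: str = "bayes"
    cv_misclassifications: np.ndarray | None = None  # per candidate a

    def __post_init__(self) -> None:
        if self.a < 1:
            raise ValueError("need at least one latent variable")
        if self.classes is None:
            self.classes = list(CLASSES)

    def predict_indicators(self, X: np.ndarray, pretreat_done: bool = True) -> np.ndarray:
        """Predicted class-indicator values, rows of X already pretreated."""
        return (np.atleast_2d(X) - self.x_mean) @ self.coefficients + self.y_mean


def _simpls(X0: np.ndarray, Y0: np.ndarray, n_components: int):
    """SIMPLS decomposition of centered X0 (n x P) onto centered Y0 (n x C).

    Returns (R, P_load, Q) such that B_a = R[:, :a] @ Q[:, :a].T for any
    truncation a; columns may stop early if the covariance is exhausted.
    """
    n, p = X0.shape
    m = Y0.shape[1]
    S = X0.T @ Y0
    R = np.zeros((p, n_components))
    Pl = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    V = np.zeros((p, n_components))
    ncomp = 0
    for a in range(n_components):
        # dominant right singular vector of S via the small (C x C) eigenproblem
        StS = S.T @ S
        evals, evecs = np.linalg.eigh(StS)
        if evals[-1] < 1e-24:
            break
        q = evecs[:, -1]
        r = S @ q
        t = X0 @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            break
        t /= normt
        r /= normt
        p_a = X0.T @ t
        q_a = Y0.T @ t
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        v /= nv
        S = S - np.outer(v, v @ S)
        R[:, a], Pl[:, a], Q[:, a], V[:, a] = r, p_a, q_a, v
        ncomp = a + 1
    return R[:, :ncomp], Pl[:, :ncomp], Q[:, :ncomp]


def _indicator(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    Y = np.zeros((labels.size, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y


def _loo_predictions(
    X: np.ndarray, Y: np.ndarray, labels_idx: np.ndarray, max_lv: int
) -> tuple[np.ndarray, np.ndarray]:
    """LOO predictions and misclassification counts per candidate a.

    Returns (errors, yhat_loo) with errors[a-1] the argmax misclassification
    count and yhat_loo[i, a-1] the held-out indicator prediction of sample i
    using a latent variables.
    """
    n, C = X.shape[0], Y.shape[1]
    errors = np.zeros(max_lv, dtype=int)
    yhat_loo = np.zeros((n, max_lv, C))
    for i in range(n):
        keep = np.arange(n) != i
        Xt, Yt = X[keep], Y[keep]
        xm, ym = Xt.mean(axis=0), Yt.mean(axis=0)
        R, _, Q = _simpls(Xt - xm, Yt - ym, max_lv)
        x0 = X[i] - xm
        t_all = x0 @ R                              # (ncomp,)
        ncomp = R.shape[1]
        yhat = ym.copy()
        for a in range(max_lv):
            if a < ncomp:
                yhat = yhat + t_all[a] * Q[:, a]
            yhat_loo[i, a] = yhat
            errors[a] += int(np.argmax(yhat) != labels_idx[i])
    return errors, yhat_loo


def _bayes_threshold(inside: np.ndarray, outside: np.ndarray) -> float:
    """Crossing point of two Gaussians fitted to in/out-of-class predictions.

    Falls back to 0.5 when the geometry is degenerate (means inverted or no
    crossing between the two means).
    """
    mu1, mu0 = float(inside.mean()), float(outside.mean())
    s1 = max(float(inside.std(ddof=1)) if inside.size > 1 else 0.0, 1e-6)
    s0 = max(float(outside.std(ddof=1)) if outside.size > 1 else 0.0, 1e-6)
    if mu1 <= mu0:
        return 0.5
    n1, n0 = inside.size, outside.size
    pi1, pi0 = n1 / (n1 + n0), n0 / (n1 + n0)
    a = 1.0 / (2 * s0**2) - 1.0 / (2 * s1**2)
    b = mu1 / s1**2 - mu0 / s0**2
    c = mu0**2 / (2 * s0**2) - mu1**2 / (2 * s1**2) + np.log((pi1 * s0) / (pi0 * s1))
    if abs(a) < 1e-12:
        x = -c / b if abs(b) > 1e-12 else 0.5
        return float(x) if mu0 < x < mu1 else 0.5
    disc = b**2 - 4 * a * c
    if disc < 0:
        return 0.5
    roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
    inside_roots = [r for r in roots if mu0 < r < mu1]
    if not inside_roots:
        return 0.5
    return float(min(inside_roots, key=lambda r: abs(r - (mu0 + mu1) / 2)))


def fit_plsda(
    data: SpectraSet,
    max_lv: int = MAX_LATENT,
    pretreatment: PreprocessConfig | None = None,
    threshold_rule: Literal["bayes", "fixed:0.5"] = "bayes",
    pretreated: bool = False,
) -> PlsdaModel:
    """Fit PLS-DA on labeled calibration spectra.

    Latent-variable count by LOO CV (argmax misclassification, 1% parsimony);
    per-class no-match cutoffs from calibration predictions.
    """
    if data.labels is None:
        raise ValueError("calibration data must be labeled")
    pretreatment = pretreatment or PreprocessConfig()
    work = data if pretreated else second_derivative(data, pretreatment)
    labels = np.asarray(work.labels)
    classes = [c for c in CLASSES if (labels == c).any()]
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if (labels == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 calibration samples")
    X = work.absorbance
    n = X.shape[0]
    max_lv = int(min(max_lv, MAX_LATENT, n - 2, X.shape[1]))
    Y = _indicator(labels, classes)
    labels_idx = np.array([classes.index(l) for l in labels])

    errors, yhat_loo = _loo_predictions(X, Y, labels_idx, max_lv)
    best = int(errors.min())
    a = int(np.flatnonzero(errors <= best * 1.01 + 1e-12)[0]) + 1

    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    R, Pl, Q = _simpls(X - xm, Y - ym, a)
    a = R.shape[1]  # may shrink if covariance exhausted
    B = R @ Q.T

    # Cutoffs from the LOO predictions at the chosen a: fitted calibration
    # predictions are optimistic and would place thresholds too high.
    yhat_cv = yhat_loo[:, a - 1, :]
    thresholds = np.zeros(len(classes))
    for j in range(len(classes)):
        if threshold_rule == "fixed:0.5":
            thresholds[j] = 0.5
        else:
            thresholds[j] = _bayes_threshold(
                yhat_cv[labels_idx == j, j], yhat_cv[labels_idx != j, j]
            )

    return PlsdaModel(
        x_mean=xm,
        y_mean=ym,
        weights=R,
        x_loadings=Pl,
        y_loadings=Q,
        a=a,
        coefficients=B,
        class_thresholds=thresholds,
        classes=classes,
        pretreatment=pretreatment,
        threshold_rule=threshold_rule,
        cv_misclassifications=errors,
    )


def predict_plsda(
    model: PlsdaModel, data: SpectraSet, pretreated: bool = False
) -> ClassificationResult:
    """Predict classes; samples clearing no class cutoff become ``no_match``.

    Among classes whose predicted indicator value reaches the class cutoff,
    the one with the largest prediction wins. Deterministic.
    """
    work = data if pretreated else second_derivative(data, model.pretreatment)
    if work.n_channels != model.x_mean.size:
        raise ValueError("wavelength grid does not match the fitted model")
    yhat = model.predict_indicators(work.absorbance)
    classes = model.classes
    assigned: list[str] = []
    accepted: list[list[str]] = []
    for i in range(yhat.shape[0]):
        acc = [c for j, c in enumerate(classes) if yhat[i, j] >= model.class_thresholds[j]]
        accepted.append(acc)
        if not acc:
            assigned.append(NO_MATCH)
        else:
            j_best = max(
                (j for j, c in enumerate(classes) if c in acc),
                key=lambda j: (yhat[i, j], -j),
            )
            assigned.append(classes[j_best])
    # distance analogue: shortfall of the prediction below 1 (per class)
    dist = 1.0 - yhat
    scores = {"latent": (work.absorbance - model.x_mean) @ model.weights}
    return ClassificationResult(
        sample_ids=list(work.sample_ids),
        classes=classes,
        assigned=assigned,
        accepted=accepted,
        distances=dist,
        scores=scores,
    )
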