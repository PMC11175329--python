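"""Soft Independent Modeling of Class Analogy (SIMCA).

One PCA model per freeze-thaw class. A new sample is accepted by a class
when both of two statistics stay below their critical limits derived from
the membership probability threshold (default 0.95):

* residual F-ratio  s_i^2 / s_0^2 — the sample's mean squared orthogonal
  residual against the pooled calibration residual variance. Its critical
  value defaults to a moment-matched chi-square (Box) limit fitted to the
  calibration residual sums of squares, which stays calibrated when channel
  noise is correlated (as it always is after Savitzky-Golay filtering); the
  textbook F quantile on (P - k, (P - k)(n - k - 1)) degrees of freedom,
  exact only for white residuals, is available as ``residual_limit="f"``;
* Hotelling T^2 of the sample's scores, compared with the new-observation
  limit  k (n - 1)(n + 1) / (n (n - k)) * F(k, n - k).

Each limit uses alpha = 1 - sqrt(threshold) (Sidak split) so that the joint
nominal false-rejection rate of a genuine class member matches 1 - threshold. A
sample accepted by several classes is assigned to the nearest by reduced
distance; a sample accepted by none is assigned ``no_match``.

The number of components per class is chosen by leave-one-out
cross-validated reconstruction PRESS with a 1% parsimony rule (smallest k
whose PRESS is within 1% of the minimum), capped at 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from freezenir.preprocess import PreprocessConfig, second_derivative
from freezenir.spectra_io import CLASSES, NO_MATCH, SpectraSet

MAX_COMPONENTS = 15


@dataclass
class SimcaClassModel:
    """Fitted PCA sub-model of a single class."""

    class_label: str
    mean: np.ndarray                 # (P,) mean pretreated spectrum
    loadings: np.ndarray             # (P, k), orthonormal columns
    k: int
    residual_variance_s0: float      # pooled per-channel residual variance s0^2
    score_variances: np.ndarray      # (k,) calibration score variances (ddof=1)
    n_cal: int
    press: np.ndarray = field(default_factory=lambda: np.empty(0))  # LOO PRESS curve
    resid_sq_mean: float = 0.0       # calibration mean of Q_i = ||residual||^2
    resid_sq_var: float = 0.0        # calibration variance of Q_i (ddof=1)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_COMPONENTS:
            raise ValueError(f"k={self.k} outside 1..{MAX_COMPONENTS}")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        if self.residual_variance_s0 < 0:
            raise ValueError("residual variance must be nonnegative")

    def decompose(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Scores and squared orthogonal residual norms for rows of X."""
        Xc = np.atleast_2d(X) - self.mean
        scores = Xc @ self.loadings
        resid_sq = np.einsum("ij,ij->i", Xc, Xc) - np.einsum(
            "ij,ij->i", scores, scores
        )
        return scores, np.maximum(resid_sq, 0.0)

    def statistics(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(residual F-ratio, Hotelling T^2) per row of X."""
        P = self.mean.size
        scores, resid_sq = self.decompose(X)
        s_i2 = resid_sq / (P - self.k)
        f_ratio = s_i2 / self.residual_variance_s0
        t2 = np.sum(scores**2 / self.score_variances, axis=1)
        return f_ratio, t2

    def critical_limits(
        self,
        threshold: float,
        mode: Literal["augmented", "residual"] = "augmented",
        residual_limit: Literal["moment", "f"] = "moment",
    ) -> tuple[float, float]:
        """(residual F-ratio critical value, T^2 critical value).

        In augmented mode each statistic gets alpha = 1 - sqrt(threshold) so
        the joint nominal false-rejection probability of a genuine member is
        1 - threshold. The residual limit is a Box moment-matched chi-square
        fitted to the calibration residual sums of squares (falls back to
        the nominal F quantile when the calibration spread is degenerate),
        expressed on the F-ratio scale.
        """
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        n, k, P = self.n_cal, self.k, self.mean.size
        # Sidak split in augmented mode: each test accepts with probability
        # sqrt(threshold) so the joint acceptance probability of a genuine
        # member is the stated threshold.
        alpha = (
            1.0 - float(np.sqrt(threshold)) if mode == "augmented" else 1.0 - threshold
        )
        df2 = (P - k) * max(n - k - 1, 1)
        f_crit = float(stats.f.ppf(1.0 - alpha, P - k, df2))
        if residual_limit == "moment" and self.resid_sq_var > 0 and self.resid_sq_mean > 0:
            g = self.resid_sq_var / (2.0 * self.resid_sq_mean)
            h = 2.0 * self.resid_sq_mean**2 / self.resid_sq_var
            q_crit = g * float(stats.chi2.ppf(1.0 - alpha, h))
            # onto the F-ratio scale: F = Q / ((P - k) * s0^2)
            f_crit = q_crit / ((P - k) * self.residual_variance_s0)
        t2_crit = float(
            k * (n - 1) * (n + 1) / (n * (n - k)) * stats.f.ppf(1.0 - alpha, k, n - k)
        )
        return f_crit, t2_crit


@dataclass
class SimcaModel:
    """Per-class PCA models plus the shared acceptance rule."""

    class_models: dict[str, SimcaClassModel]
    probability_threshold: float = 0.95
    pretreatment: PreprocessConfig | None = None
    mode: Literal["augmented", "residual"] = "augmented"
    residual_limit: Literal["moment", "f"] = "moment"

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must lie in (0, 1)")
        sizes = {m.mean.size for m in self.class_models.values()}
        if len(sizes) > 1:
            raise ValueError("class models disagree on the wavelength grid")

    @property
    def classes(self) -> list[str]:
        return [c for c in CLASSES if c in self.class_models] + sorted(
            set(self.class_models) - set(CLASSES)
        )


@dataclass
class ClassificationResult:
    """Per-sample class assignments with the full acceptance record."""

    sample_ids: list[str]
    classes: list[str]
    assigned: list[str]                  # class label or NO_MATCH
    accepted: list[list[str]]            # accepting classes per sample
    distances: np.ndarray                # (n, n_classes) reduced distances
    scores: dict[str, np.ndarray]        # class -> (n, k_class) projections

    def __post_init__(self) -> None:
        for a, acc in zip(self.assigned, self.accepted):
            if a == NO_MATCH:
                if acc:
                    raise ValueError("no_match sample lists accepting classes")
            elif a not in acc:
                raise ValueError("assigned class not among accepting classes")

    def no_match_count(self) -> int:
        return sum(1 for a in self.assigned if a == NO_MATCH)


def _loo_press(X: np.ndarray, max_k: int) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out PRESS and plain held-out residuals for k = 1..max_k.

    Each fold refits the PCA (SVD) on the remaining rows. Two quantities are
    recorded for the held-out row x per component count k:

    * its plain squared orthogonal residual ||x - V_k V_k' x||^2 (used for
      the Box residual limit at the chosen k);
    * its leverage-corrected PRESS  sum_j (e_j / (1 - h_j))^2  with
      h_j = sum_{m<=k} v_jm^2, i.e. exact leave-one-channel-out prediction
      error of the regression of x on the loadings. The naive residual is
      monotone decreasing in k even for pure noise (the held-out row takes
      part in its own scores), so it cannot select k; the leverage-corrected
      form grows again once components stop generalizing.

    Returns (press, resid): press[k-1] = sum_i press_i[k-1], resid[i, k-1].
    """
    n = X.shape[0]
    resid = np.zeros((n, max_k))
    press = np.zeros(max_k)
    for i in range(n):
        train = np.delete(X, i, axis=0)
        mean = train.mean(axis=0)
        _, _, vt = np.linalg.svd(train - mean, full_matrices=False)
        x = X[i] - mean
        kmax_i = min(max_k, vt.shape[0])
        r = x.copy()
        h = np.zeros_like(x)
        for k in range(max_k):
            if k < kmax_i:
                v = vt[k]
                r = r - (v @ x) * v
                h = h + v**2
            resid[i, k] = float(r @ r)
            denom = np.maximum(1.0 - h, 1e-3)
            press[k] += float(np.sum((r / denom) ** 2))
    return press, resid


def select_k_parsimonious(press: np.ndarray, rtol: float = 0.01) -> int:
    """Smallest k (1-based) whose PRESS is within ``rtol`` of the minimum."""
    best = float(press.min())
    within = np.flatnonzero(press <= best * (1.0 + rtol) + 1e-30)
    return int(within[0]) + 1


def fit_class_pca(
    X_class: np.ndarray, max_k: int = MAX_COMPONENTS, class_label: str = ""
) -> SimcaClassModel:
    """Fit one class's PCA sub-model with LOO-CV component selection.

    ``X_class`` holds pretreated spectra of the class (rows = samples).
    """
    X = np.atleast_2d(np.asarray(X_class, dtype=float))
    n, P = X.shape
    if n < 4:
        raise ValueError(f"need at least 4 calibration samples, got {n}")
    max_k = int(min(max_k, MAX_COMPONENTS, n - 2, P))
    if max_k < 1:
        raise ValueError("max_k must allow at least one component")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("zero-variance class matrix")
    press, loo_resid = _loo_press(X, max_k)
    k = select_k_parsimonious(press)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:k].T
    scores = Xc @ loadings
    resid_sq = np.einsum("ij,ij->i", Xc, Xc) - np.einsum("ij,ij->i", scores, scores)
    resid_sq = np.maximum(resid_sq, 0.0)
    df = (P - k) * max(n - k - 1, 1)
    s0_sq = float(resid_sq.sum() / df)
    score_var = np.maximum(s[:k] ** 2 / (n - 1), 1e-30)
    # Box-limit moments of Q from the LOO residuals at the chosen k: a fitted
    # calibration residual underestimates that of a new sample, the held-out
    # residual does not.
    q_loo = loo_resid[:, k - 1]
    return SimcaClassModel(
        class_label=class_label,
        mean=mean,
        loadings=loadings,
        k=k,
        residual_variance_s0=max(s0_sq, 1e-30),
        score_variances=score_var,
        n_cal=n,
        press=press,
        resid_sq_mean=float(q_loo.mean()),
        resid_sq_var=float(q_loo.var(ddof=1)) if n > 1 else 0.0,
    )


def reduced_distance(
    model: SimcaClassModel,
    X: np.ndarray,
    threshold: float = 0.95,
    mode: Literal["augmented", "residual"] = "augmented",
    residual_limit: Literal["moment", "f"] = "moment",
) -> np.ndarray:
    """Reduced (critical-limit-normalized) distance of samples to a class.

    d = sqrt(F_ratio / F_crit + T^2 / T^2_crit) in augmented mode, or
    sqrt(F_ratio / F_crit) in residual-only mode; d = 0 at the class mean
    and d <= sqrt(2) (resp. 1) on the acceptance boundary.
    """
    f_ratio, t2 = model.statistics(np.atleast_2d(X))
    f_crit, t2_crit = model.critical_limits(threshold, mode, residual_limit)
    if mode == "residual":
        return np.sqrt(f_ratio / f_crit)
    return np.sqrt(f_ratio / f_crit + t2 / t2_crit)


def fit_simca(
    data: SpectraSet,
    max_k: int = MAX_COMPONENTS,
    probability_threshold: float = 0.95,
    pretreatment: PreprocessConfig | None = None,
    mode: Literal["augmented", "residual"] = "augmented",
    residual_limit: Literal["moment", "f"] = "moment",
    pretreated: bool = False,
) -> SimcaModel:
    """Fit the full SIMCA model on labeled calibration spectra.

    Unless ``pretreated`` is True, the recorded pretreatment (default
    Savitzky-Golay second derivative) is applied before fitting and is
    re-applied to raw data at prediction time.
    """
    if data.labels is None:
        raise ValueError("calibration data must be labeled")
    pretreatment = pretreatment or PreprocessConfig()
    work = data if pretreated else second_derivative(data, pretreatment)
    models: dict[str, SimcaClassModel] = {}
    for cls in CLASSES:
        idx = work.class_indices(cls)
        if idx.size == 0:
            continue
        models[cls] = fit_class_pca(work.absorbance[idx], max_k, class_label=cls)
    if len(models) < 2:
        raise ValueError("need at least two classes with calibration samples")
    return SimcaModel(
        class_models=models,
        probability_threshold=probability_threshold,
        pretreatment=pretreatment,
        mode=mode,
        residual_limit=residual_limit,
    )


def classify(
    model: SimcaModel, data: SpectraSet, pretreated: bool = False
) -> ClassificationResult:
    """Accept/reject each sample per class; assign nearest accepting class.

    Samples accepted by no class are assigned ``no_match``. Deterministic;
    ties on distance break toward the earlier class in the canonical order.
    """
    any_model = next(iter(model.class_models.values()))
    work = data if pretreated else second_derivative(data, model.pretreatment)
    if work.n_channels != any_model.mean.size:
        raise ValueError("wavelength grid does not match the fitted model")
    classes = model.classes
    n = work.n_samples
    dist = np.zeros((n, len(classes)))
    accepted_mask = np.zeros((n, len(classes)), dtype=bool)
    scores: dict[str, np.ndarray] = {}
    for j, cls in enumerate(classes):
        cm = model.class_models[cls]
        f_ratio, t2 = cm.statistics(work.absorbance)
        f_crit, t2_crit = cm.critical_limits(
            model.probability_threshold, model.mode, model.residual_limit
        )
        if model.mode == "residual":
            accepted_mask[:, j] = f_ratio <= f_crit
            dist[:, j] = np.sqrt(f_ratio / f_crit)
        else:
            accepted_mask[:, j] = (f_ratio <= f_crit) & (t2 <= t2_crit)
            dist[:, j] = np.sqrt(f_ratio / f_crit + t2 / t2_crit)
        scores[cls], _ = cm.decompose(work.absorbance)
    assigned: list[str] = []
    accepted: list[list[str]] = []
    for i in range(n):
        acc = [classes[j] for j in np.flatnonzero(accepted_mask[i])]
        accepted.append(acc)
        if not acc:
            assigned.append(NO_MATCH)
        else:
            j_best = min(
                (j for j in range(len(classes)) if accepted_mask[i, j]),
                key=lambda j: (dist[i, j], j),
            )
            assigned.append(classes[j_best])
    return ClassificationResult(
        sample_ids=list(work.sample_ids),
        classes=classes,
        assigned=assigned,
        accepted=accepted,
        distances=dist,
        scores=scores,
    )
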