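"""Supervised discrimination of dose groups: OSC filtering and PLS-DA.

The per-time-point discrimination engine: an orthogonal signal correction
(OSC) filter removes X-variation orthogonal to class membership (batch,
physiology, instrument), then partial least squares regression onto the
centered class-indicator matrix yields latent components whose quality is
summarized by R2Y (explained class variance), Q2 (1 - PRESS/SS under
stratified k-fold cross-validation) and per-feature VIP scores.  A
label-permutation test regresses (R2, Q2) on the correlation between the
permuted and original class matrices; a negative Q2 intercept marks a
model not explained by chance fit.  Hotelling T2 confidence ellipses
summarize two-component score plots.

PLS component extraction is delegated to scikit-learn's NIPALS
implementation; everything around it (scaling policy, OSC, Q2, VIP,
permutation intercepts, ellipses) lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger("nmrasca")

__all__ = [
    "ScalingSpec",
    "OscModel",
    "PlsdaModel",
    "PermutationValidation",
    "EllipseParams",
    "osc_filter",
    "fit_plsda",
    "cross_validate_q2",
    "permutation_validate",
    "vip",
    "hotelling_ellipse",
    "auto_components",
]


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingSpec:
    """Column preprocessing: mean-centering plus none/unit-variance/Pareto.

    Pareto divides by the square root of the standard deviation,
    attenuating (without equalizing) intensity differences between
    features.  During cross-validation the statistics are computed on the
    training folds only.
    """

    center: bool = True
    scale: str = "uv"   # "none" | "uv" | "pareto"

    def __post_init__(self) -> None:
        if self.scale not in ("none", "uv", "pareto"):
            raise ValueError(f"unknown scaling {self.scale!r}")

    def fit(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = x.mean(axis=0) if self.center else np.zeros(x.shape[1])
        sd = x.std(axis=0, ddof=1)
        zero = sd <= 0
        if zero.any() and self.scale != "none":
            logger.warning("%d constant column(s) after centering left unscaled", int(zero.sum()))
        sd = np.where(zero, 1.0, sd)
        if self.scale == "uv":
            factor = sd
        elif self.scale == "pareto":
            factor = np.sqrt(sd)
        else:
            factor = np.ones_like(sd)
        return mean, factor

    def apply(self, x: np.ndarray, mean: np.ndarray, factor: np.ndarray) -> np.ndarray:
        return (x - mean) / factor


def _one_hot(classes: np.ndarray) -> tuple[np.ndarray, list]:
    labels = np.asarray(classes)
    levels = list(dict.fromkeys(labels.tolist()))
    y = np.zeros((len(labels), len(levels)))
    for j, lv in enumerate(levels):
        y[labels == lv, j] = 1.0
    return y, levels


# ---------------------------------------------------------------------------
# Orthogonal signal correction
# ---------------------------------------------------------------------------

@dataclass
class OscModel:
    """Fitted OSC filter: removal weights/loadings plus the training mean.

    ``apply`` reproduces the filtered training matrix and filters new
    samples; removed scores are orthogonal to the class-indicator matrix.
    """

    mean: np.ndarray
    weights: list[np.ndarray] = field(default_factory=list)
    loadings: list[np.ndarray] = field(default_factory=list)
    variance_removed: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def apply(self, x: np.ndarray) -> np.ndarray:
        xc = np.asarray(x, dtype=float) - self.mean
        for w, p in zip(self.weights, self.loadings):
            t = xc @ w
            xc = xc - np.outer(t, p)
        return xc + self.mean


def osc_filter(
    x: np.ndarray,
    classes: np.ndarray,
    n_osc: int = 1,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, OscModel]:
    """Remove ``n_osc`` components of X-variation orthogonal to the classes.

    Iterative orthogonalization: starting from the leading principal
    component score, alternate (i) projection out of the class-indicator
    column space and (ii) regression back onto X, until the score
    stabilizes; the converged orthogonal score and its loading are
    deflated from X.  If nothing orthogonal to the classes remains, the
    component is skipped with zero removed variance.
    """
    x = np.asarray(x, dtype=float)
    y, levels = _one_hot(classes)
    if len(levels) < 2:
        raise ValueError("need at least 2 classes")
    if n_osc < 1:
        raise ValueError("n_osc must be >= 1")
    mean = x.mean(axis=0)
    xc = x - mean
    rank = np.linalg.matrix_rank(xc)
    if n_osc >= rank:
        raise ValueError(f"n_osc={n_osc} exceeds usable rank {rank}")
    yc = y - y.mean(axis=0)
    total_ssq = float(np.sum(xc**2))

    def deflate_y(t: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(yc, t, rcond=None)
        return t - yc @ coef

    model = OscModel(mean=mean)
    for _ in range(n_osc):
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        t = u[:, 0] * s[0]
        scale0 = np.linalg.norm(t)
        for _ in range(max_iter):
            t_orth = deflate_y(t)
            if np.linalg.norm(t_orth) < 1e-12 * max(scale0, 1.0):
                break
            w, *_ = np.linalg.lstsq(xc, t_orth, rcond=None)
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = xc @ w
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        t_orth = deflate_y(t)
        w, *_ = np.linalg.lstsq(xc, t_orth, rcond=None)
        t_rm = xc @ w
        ssq_rm = float(t_rm @ t_rm)
        if ssq_rm < 1e-12 * max(total_ssq, 1.0):
            logger.info("OSC: no class-orthogonal variation left; component skipped")
            model.variance_removed.append(0.0)
            continue
        p = xc.T @ t_rm / ssq_rm
        xc = xc - np.outer(t_rm, p)
        model.weights.append(w)
        model.loadings.append(p)
        model.variance_removed.append(
            100.0 * (ssq_rm * float(p @ p)) / total_ssq if total_ssq else 0.0
        )
    return xc + mean, model


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    """Fitted PLS-DA model (NIPALS components onto centered one-hot Y)."""

    n_components: int
    class_levels: list
    scaling: ScalingSpec
    x_mean: np.ndarray
    x_factor: np.ndarray
    y_mean: np.ndarray
    x_scores: np.ndarray      # T, samples x A
    x_weights: np.ndarray     # W, features x A
    x_loadings: np.ndarray    # P, features x A
    y_loadings: np.ndarray    # Q, classes x A
    ssy_per_component: np.ndarray
    r2y_cum: float            # fraction of Y variance explained
    _pls: PLSRegression = field(repr=False, default=None)

    @property
    def r2y_percent(self) -> float:
        return 100.0 * self.r2y_cum

    def transform(self, x: np.ndarray) -> np.ndarray:
        xs = self.scaling.apply(np.asarray(x, dtype=float), self.x_mean, self.x_factor)
        return self._pls.transform(xs)

    def predict_y(self, x: np.ndarray) -> np.ndarray:
        xs = self.scaling.apply(np.asarray(x, dtype=float), self.x_mean, self.x_factor)
        return self._pls.predict(xs) + self.y_mean

    def predict_class(self, x: np.ndarray) -> np.ndarray:
        yhat = self.predict_y(x)
        return np.asarray([self.class_levels[j] for j in np.argmax(yhat, axis=1)])


def fit_plsda(
    x: np.ndarray,
    classes: np.ndarray,
    n_components: int,
    scaling: ScalingSpec = ScalingSpec(),
) -> PlsdaModel:
    """Fit a PLS-DA model with ``n_components`` latent variables."""
    x = np.asarray(x, dtype=float)
    y, levels = _one_hot(np.asarray(classes))
    if len(levels) < 2:
        raise ValueError("need at least 2 classes")
    max_a = min(x.shape[0] - 1, x.shape[1])
    if not 1 <= n_components <= max_a:
        raise ValueError(f"n_components must be in [1, {max_a}]")
    mean, factor = scaling.fit(x)
    xs = scaling.apply(x, mean, factor)
    y_mean = y.mean(axis=0)
    yc = y - y_mean

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(xs, yc)
    t = pls.x_scores_
    q = pls.y_loadings_
    # orthogonal scores => per-component explained Y sums of squares add
    ssy = np.array([
        float(np.sum(t[:, a] ** 2) * np.sum(q[:, a] ** 2)) for a in range(n_components)
    ])
    ss_tot = float(np.sum(yc**2))
    resid = yc - t @ q.T
    r2y = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else 0.0
    return PlsdaModel(
        n_components=n_components,
        class_levels=levels,
        scaling=scaling,
        x_mean=mean,
        x_factor=factor,
        y_mean=y_mean,
        x_scores=t,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=q,
        ssy_per_component=ssy,
        r2y_cum=r2y,
        _pls=pls,
    )


def vip(model: PlsdaModel) -> np.ndarray:
    """Variable importance in the projection; mean squared VIP is 1."""
    w = model.x_weights
    ssy = model.ssy_per_component
    wn2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    p = w.shape[0]
    return np.sqrt(p * (wn2 @ ssy) / ssy.sum())


def cross_validate_q2(
    x: np.ndarray,
    classes: np.ndarray,
    n_components: int,
    scaling: ScalingSpec = ScalingSpec(),
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Stratified k-fold Q2 = 1 - PRESS/SS on the centered class matrix.

    Scaling statistics and class means come from the training folds only.
    If a class has fewer members than ``folds`` the fold count is reduced
    (re-stratified) so every class is present in every training fold.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(classes)
    y, _ = _one_hot(labels)
    _, counts = np.unique(labels, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("every class needs at least 2 samples for cross-validation")
    if folds > min_count:
        logger.warning("reducing CV folds from %d to %d (smallest class)", folds, min_count)
        folds = min_count
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    ss = 0.0
    for train, test in skf.split(x, labels):
        spec_mean, spec_factor = scaling.fit(x[train])
        xs_train = scaling.apply(x[train], spec_mean, spec_factor)
        xs_test = scaling.apply(x[test], spec_mean, spec_factor)
        y_mean = y[train].mean(axis=0)
        yc_train = y[train] - y_mean
        yc_test = y[test] - y_mean
        a = min(n_components, len(train) - 1, x.shape[1])
        pls = PLSRegression(n_components=a, scale=False)
        pls.fit(xs_train, yc_train)
        press += float(np.sum((yc_test - pls.predict(xs_test)) ** 2))
        ss += float(np.sum(yc_test**2))
    return 1.0 - press / ss


def auto_components(
    x: np.ndarray,
    classes: np.ndarray,
    max_components: int = 10,
    scaling: ScalingSpec = ScalingSpec(),
    folds: int = 7,
    seed: int = 0,
    min_gain: float = 0.01,
) -> int:
    """Smallest A after which the cross-validated Q2 gain drops below ``min_gain``."""
    x = np.asarray(x, dtype=float)
    limit = min(max_components, x.shape[0] - 1, x.shape[1])
    best_a, prev_q2 = 1, -np.inf
    for a in range(1, limit + 1):
        q2 = cross_validate_q2(x, classes, a, scaling, folds, seed)
        if q2 - prev_q2 < min_gain:
            break
        best_a, prev_q2 = a, q2
    return best_a


# ---------------------------------------------------------------------------
# Permutation validation
# ---------------------------------------------------------------------------

@dataclass
class PermutationValidation:
    """Label-permutation diagnostics for one fitted PLS-DA configuration."""

    n_iterations: int
    correlations: np.ndarray   # per permutation (original model excluded)
    r2_values: np.ndarray
    q2_values: np.ndarray
    r2_original: float
    q2_original: float
    r2_intercept: float
    q2_intercept: float

    @property
    def robust(self) -> bool:
        """True when the Q2 regression intercept at zero label correlation is negative."""
        return self.q2_intercept < 0


def _label_correlation(yc_perm: np.ndarray, yc: np.ndarray) -> float:
    denom = np.linalg.norm(yc_perm) * np.linalg.norm(yc)
    return float(np.sum(yc_perm * yc) / denom) if denom else 0.0


def permutation_validate(
    x: np.ndarray,
    classes: np.ndarray,
    n_components: int,
    scaling: ScalingSpec = ScalingSpec(),
    n: int = 200,
    seed: int = 0,
    folds: int = 7,
    n_osc: int = 0,
) -> PermutationValidation:
    """Permute class labels ``n`` times and extrapolate R2/Q2 to zero correlation.

    Each permutation refits the whole pipeline — including the OSC filter
    when ``n_osc > 0`` — so any overfitting introduced by class-aware
    filtering is exposed rather than hidden.  Intercepts come from a
    least-squares line of the (correlation, R2) and (correlation, Q2)
    clouds including the unpermuted model at correlation 1.
    """
    if n < 20:
        raise ValueError("use at least 20 permutations")
    x = np.asarray(x, dtype=float)
    labels = np.asarray(classes)
    y, _ = _one_hot(labels)
    yc = y - y.mean(axis=0)
    rng = np.random.default_rng(seed)

    def pipeline(lbl: np.ndarray, cv_seed: int) -> tuple[float, float]:
        xf = x
        if n_osc > 0:
            xf, _ = osc_filter(x, lbl, n_osc=n_osc)
        model = fit_plsda(xf, lbl, n_components, scaling)
        q2 = cross_validate_q2(xf, lbl, n_components, scaling, folds, cv_seed)
        return model.r2y_cum, q2

    r2_orig, q2_orig = pipeline(labels, seed)
    corrs = np.empty(n)
    r2s = np.empty(n)
    q2s = np.empty(n)
    for i in range(n):
        perm = rng.permutation(len(labels))
        lbl = labels[perm]
        corrs[i] = _label_correlation(yc[perm], yc)
        r2s[i], q2s[i] = pipeline(lbl, int(rng.integers(2**31)))

    cx = np.concatenate([np.abs(corrs), [1.0]])
    design = np.column_stack([np.ones_like(cx), cx])
    r2_line, *_ = np.linalg.lstsq(design, np.concatenate([r2s, [r2_orig]]), rcond=None)
    q2_line, *_ = np.linalg.lstsq(design, np.concatenate([q2s, [q2_orig]]), rcond=None)
    return PermutationValidation(
        n_iterations=n,
        correlations=corrs,
        r2_values=r2s,
        q2_values=q2s,
        r2_original=r2_orig,
        q2_original=q2_orig,
        r2_intercept=float(r2_line[0]),
        q2_intercept=float(q2_line[0]),
    )


# ---------------------------------------------------------------------------
# Hotelling ellipse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseParams:
    """Hotelling T2 confidence ellipse of a two-component score plot."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float
    alpha: float

    def boundary(self, n_points: int = 200) -> np.ndarray:
        theta = np.linspace(0, 2 * np.pi, n_points)
        circ = np.column_stack(
            [self.semi_axes[0] * np.cos(theta), self.semi_axes[1] * np.sin(theta)]
        )
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return circ @ rot.T + np.asarray(self.center)


def hotelling_ellipse(scores: np.ndarray, alpha: float = 0.05) -> EllipseParams:
    """Confidence ellipse from the F-scaled two-component Hotelling T2.

    The squared semi-axes are the score-covariance eigenvalues times
    ``2 (n-1) / (n-2) * F_{1-alpha}(2, n-2)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be a 2-column matrix")
    n = scores.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] <= 1e-12 * max(eigval[1], 1.0):
        raise ValueError("singular score covariance; ellipse undefined")
    t2_crit = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(1.0 - alpha, 2, n - 2)
    # eigh returns ascending; report major axis first
    order = [1, 0]
    axes = np.sqrt(eigval[order] * t2_crit)
    major = eigvec[:, order[0]]
    return EllipseParams(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(axes[0]), float(axes[1])),
        angle_rad=float(np.arctan2(major[1], major[0])),
        alpha=alpha,
    )


def model_report(
    name: str,
    model: PlsdaModel,
    q2: float,
    validation: PermutationValidation | None = None,
) -> dict:
    """One machine-readable row of per-dataset model diagnostics."""
    row = {
        "dataset": name,
        "N": model.x_scores.shape[0],
        "components": model.n_components,
        "R2_percent": model.r2y_percent,
        "Q2": q2,
    }
    if validation is not None:
        row.update(
            R2_intercept=validation.r2_intercept,
            Q2_intercept=validation.q2_intercept,
            robust=overall_verdict(model.r2y_cum, q2, validation),
        )
    return row


def overall_verdict(
    r2: float, q2: float, validation: PermutationValidation
) -> bool:
    """Full robustness rule: R2 > 50%, Q2 > 0.4 and a negative Q2 intercept.

    The intercept sign alone cannot separate signal from noise — on
    signal-free data the permuted Q2 cloud is centered below zero, so its
    extrapolation is negative about half the time regardless of the
    model.  A model is only called robust when it first meets the
    explained-variance and predictive-ability thresholds.
    """
    return bool(r2 > 0.5 and q2 > 0.4 and validation.q2_intercept < 0)
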