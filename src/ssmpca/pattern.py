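"""Disease-related pattern construction.

Selects the discriminating principal-component subset by stepwise logistic
regression under AIC and combines the selected components, weighted by
their logistic coefficients, into a single unit-norm voxel-weight pattern
with a control-referenced z-score scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .core import Mask, PCAResult, SRPMatrix, run_pca, select_top_variance

__all__ = [
    "PatternModel",
    "ExpressionScore",
    "LogitFit",
    "fit_logistic",
    "stepwise_logistic_aic",
    "combine_pattern",
    "zscore_scores",
    "derive_pattern",
]

RIDGE_PENALTY = 1e-4  # L2 penalty on slopes used only when ML fits separate


@dataclass
class PatternModel:
    """A derived covariance pattern plus everything needed to score new scans.

    ``weights`` live on ``mask`` (unit Euclidean norm, sign fixed so that
    patients express the pattern more than controls).  ``gmp`` is the
    derivation group mean profile subtracted when scoring; ``control_ref``
    is the (mean, SD) of raw control scores defining the z-score scale.
    """

    weights: np.ndarray
    mask: Mask
    gmp: np.ndarray
    selected_components: list[int]
    logistic_coefficients: np.ndarray
    control_ref: tuple[float, float]
    threshold_z: float | None = None
    selection_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sd = self.control_ref[1]
        # NaN marks a degenerate derivation (constant control scores): the
        # pattern itself is well-defined but the z-score scale is not
        if not (sd > 0 or np.isnan(sd)):
            raise ValueError("control reference SD must be positive")

    def weight_volume(self) -> np.ndarray:
        """Weights mapped back onto the 3D grid (zero off-mask)."""
        vol = np.zeros(self.mask.keep.shape)
        vol[self.mask.keep] = self.weights
        return vol


@dataclass
class ExpressionScore:
    subject_id: str
    raw: float
    z: float


@dataclass
class LogitFit:
    llf: float
    aic: float
    params: np.ndarray  # intercept first
    separated: bool


def _ridge_logit(X: np.ndarray, y: np.ndarray, penalty: float = RIDGE_PENALTY) -> np.ndarray:
    """L2-penalized logistic fit (penalty on slopes only); returns params."""

    def negll(beta):
        eta = X @ beta
        # log(1+e^eta) - y*eta, numerically stable
        val = np.sum(np.logaddexp(0.0, eta) - y * eta)
        return val + 0.5 * penalty * np.sum(beta[1:] ** 2)

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        g = X.T @ (p - y)
        g[1:] += penalty * beta[1:]
        return g

    res = minimize(negll, np.zeros(X.shape[1]), jac=grad, method="BFGS")
    return res.x


def fit_logistic(x: np.ndarray, y: np.ndarray) -> LogitFit:
    """Maximum-likelihood logistic fit of labels on columns of ``x``.

    Perfect separation is detected (statsmodels warning or diverging fit);
    such models get the supremum log-likelihood 0 (AIC = 2k) and
    ridge-stabilized coefficients so downstream arithmetic stays finite.
    """
    X = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    k = X.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e3:
                return LogitFit(float(res.llf), float(res.aic), np.asarray(res.params), False)
        except (PerfectSeparationWarning, np.linalg.LinAlgError, Exception):
            pass
    return LogitFit(0.0, 2.0 * k, _ridge_logit(X, y), True)


def stepwise_logistic_aic(
    loadings: np.ndarray, labels: np.ndarray
) -> tuple[list[int], np.ndarray, dict]:
    """Stepwise (forward with backward pruning) logistic selection under AIC.

    Starting from the intercept-only model, at each step the single
    addition or removal that lowers AIC the most is applied; the search
    stops when no move lowers AIC.  AIC = 2k - 2 log L with k counting the
    intercept.

    Returns the selected candidate indices (sorted), the intercept-free
    coefficients of the final fit aligned with those indices, and an info
    dict (final AIC, separation flag, search trace).

    When the final model is perfectly separated, the model falls back to
    the best separating single candidate (AIC over ridge-stabilized single
    fits), flagged in the info dict.
    """
    loadings = np.asarray(loadings, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if loadings.ndim != 2 or loadings.shape[0] != len(labels):
        raise ValueError("loadings must be (n_subjects, n_candidates)")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    n_cand = loadings.shape[1]
    if n_cand < 1:
        raise ValueError("need at least one candidate component")

    cache: dict[tuple[int, ...], LogitFit] = {}

    def fit_subset(subset: tuple[int, ...]) -> LogitFit:
        if subset not in cache:
            cache[subset] = fit_logistic(loadings[:, list(subset)], labels)
        return cache[subset]

    included: tuple[int, ...] = ()
    current = fit_subset(included)
    trace = [(included, current.aic)]
    while True:
        moves: list[tuple[float, tuple[int, ...]]] = []
        for j in range(n_cand):
            if j not in included:
                cand = tuple(sorted(included + (j,)))
                moves.append((fit_subset(cand).aic, cand))
        for j in included:
            cand = tuple(i for i in included if i != j)
            moves.append((fit_subset(cand).aic, cand))
        best_aic, best_subset = min(moves, key=lambda m: (m[0], m[1]))
        if best_aic < current.aic - 1e-10:
            included, current = best_subset, fit_subset(best_subset)
            trace.append((included, current.aic))
        else:
            break

    info = {"aic": current.aic, "separated": current.separated, "trace": trace,
            "fallback": None}
    if current.separated:
        # prefer the single candidate that separates on its own, if any
        singles = [(fit_subset((j,)), j) for j in range(n_cand)]
        sep_singles = [(f, j) for f, j in singles if f.separated]
        if sep_singles:
            fit, j = min(sep_singles, key=lambda fj: (fj[0].aic, fj[1]))
            included, current = (j,), fit
            info["fallback"] = "separating_single_component"
        info["separated"] = True
    coefs = current.params[1:] if included else np.empty(0)
    return list(included), np.asarray(coefs, dtype=float), info


def combine_pattern(
    pca: PCAResult,
    selected: list[int],
    coefficients: np.ndarray,
    srp: SRPMatrix | None = None,
    labels=None,
) -> np.ndarray:
    """Weighted linear combination of selected components, unit-normalized.

    Each component is weighted by its logistic coefficient; the resulting
    map is rescaled to unit Euclidean norm (pattern norm is a free scale
    absorbed by the control-referenced z-scoring).  If an SRP matrix and
    labels are supplied the sign is fixed so that patients score higher
    than controls on average.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if not np.all(np.isfinite(coefficients)):
        raise ValueError("non-finite logistic coefficients")
    if len(selected) != len(coefficients) or not selected:
        raise ValueError("selected components and coefficients must pair up, non-empty")
    w = coefficients @ pca.components[selected]
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("combined pattern is identically zero")
    w = w / norm
    if srp is not None and labels is not None:
        y = np.asarray(labels)
        scores = srp.values @ w
        if scores[y == 1].mean() < scores[y == 0].mean():
            w = -w
    return w


def zscore_scores(
    raw_scores, control_ref: tuple[float, float], subject_ids=None
) -> list[ExpressionScore]:
    """Reference raw projection scores to the derivation controls.

    z = (raw - control mean) / control SD, with the SD computed with the
    n-1 denominator.
    """
    mean, sd = control_ref
    if sd <= 0:
        raise ValueError("control reference SD must be positive")
    raw_scores = np.asarray(raw_scores, dtype=float)
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(len(raw_scores))]
    return [
        ExpressionScore(sid, float(r), float((r - mean) / sd))
        for sid, r in zip(subject_ids, raw_scores)
    ]


def control_reference(raw_scores, labels) -> tuple[float, float]:
    """(mean, SD) of raw scores over control subjects (n-1 denominator)."""
    raw = np.asarray(raw_scores, dtype=float)[np.asarray(labels) == 0]
    if len(raw) < 2:
        raise ValueError("need at least 2 controls for a reference")
    sd = float(raw.std(ddof=1))
    if sd == 0:
        raise ValueError("control scores are constant; z-scale undefined")
    return float(raw.mean()), sd


def derive_pattern(
    srp: SRPMatrix,
    variance_threshold: float = 0.5,
) -> tuple[PatternModel, np.ndarray]:
    """Full pattern derivation from an SRP matrix.

    PCA in voxel space, retention of the top-``variance_threshold``
    components, stepwise-AIC logistic selection on their subject loadings,
    and weighted combination into one pattern.  If stepwise selection
    retains no component (labels carry no signal strong enough to beat the
    AIC penalty) the single candidate with the lowest one-component AIC is
    used so that scoring stays defined; this fallback is flagged.

    Returns the PatternModel and the raw scores of the derivation subjects.
    """
    labels = srp.group_labels
    pca = run_pca(srp, align_labels=labels)
    candidates = select_top_variance(pca, variance_threshold)
    sel_local, coefs, info = stepwise_logistic_aic(pca.subject_loadings[:, candidates], labels)
    if not sel_local:
        singles = [
            (fit_logistic(pca.subject_loadings[:, [candidates[j]]], labels).aic, j)
            for j in range(len(candidates))
        ]
        _, j = min(singles)
        sel_local = [j]
        coefs = fit_logistic(pca.subject_loadings[:, [candidates[j]]], labels).params[1:]
        info["fallback"] = "forced_best_single_component"
    selected = [candidates[j] for j in sel_local]
    weights = combine_pattern(pca, selected, coefs, srp=srp, labels=labels)
    raw = srp.values @ weights
    try:
        ref = control_reference(raw, labels)
    except ValueError:
        ref = (float(raw[labels == 0].mean()), float("nan"))
    model = PatternModel(
        weights=weights,
        mask=srp.mask,
        gmp=srp.group_mean_profile,
        selected_components=selected,
        logistic_coefficients=np.asarray(coefs, dtype=float),
        control_ref=ref,
        selection_info={**info, "n_candidates": len(candidates),
                        "candidate_vaf": pca.vaf[candidates].tolist()},
    )
    return model, raw
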