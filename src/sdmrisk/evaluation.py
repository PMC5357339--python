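"""Model evaluation: background-contrast AUC, jackknife variable importance,
and environmental-similarity (extrapolation) surfaces."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .maxent import (
    ModelSettings,
    build_features,
    fit_maxent,
    predict_raw_design,
)


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC of presences against background
    pseudo-absences: the probability a random presence outscores a random
    background point, ties counting half. Computed via midranks but equal to
    the exhaustive pairwise count."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background score lists must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    return float((r_p - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


def classify_auc(value: float) -> str:
    """Discrimination label: >0.9 'very good', >0.8 'good', >0.7 'useful',
    otherwise 'none' (strict thresholds)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if value > 0.9:
        return "very good"
    if value > 0.8:
        return "good"
    if value > 0.7:
        return "useful"
    return "none"


def training_gain(model, F_presence: np.ndarray) -> float:
    """Average presence log-lift over the uniform background distribution:
    (1/m) sum_i ln(N * raw(x_i))."""
    raw = predict_raw_design(model, F_presence)
    return float(np.mean(np.log(model.n_background * raw)))


def jackknife_importance(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    predictor_names: tuple[str, ...],
    settings: ModelSettings | None = None,
) -> dict:
    """Per-predictor importance from single-variable models.

    For each predictor a model is fit with only that variable's features; its
    training gain (floored at zero) is normalized so the importances sum to
    one. Gains of the all-variable model and of each leave-one-out model are
    recorded alongside for reporting.
    """
    settings = settings or ModelSettings()
    X_pres = np.atleast_2d(np.asarray(X_presence, dtype=float))
    X_bg = np.atleast_2d(np.asarray(X_background, dtype=float))
    names = tuple(predictor_names)
    P = len(names)
    if P < 2:
        raise ValueError("need at least 2 predictors for a jackknife")

    def gain_for(cols: list[int]) -> float:
        fs = build_features(X_bg[:, cols], predictor_names=tuple(names[c] for c in cols),
                            classes=settings.classes, n_hinge_knots=settings.n_hinge_knots)
        model = fit_maxent(fs.transform(X_pres[:, cols]), fs.transform(X_bg[:, cols]),
                           rm=settings.rm, feature_set=fs)
        return training_gain(model, fs.transform(X_pres[:, cols]))

    only = {names[p]: gain_for([p]) for p in range(P)}
    without = {names[p]: gain_for([q for q in range(P) if q != p]) for p in range(P)}
    with_all = gain_for(list(range(P)))

    floored = np.array([max(only[n], 0.0) for n in names])
    total = floored.sum()
    if total <= 0:
        warnings.warn("all single-variable gains non-positive; uniform importances")
        weights = np.full(P, 1.0 / P)
    else:
        weights = floored / total
    return {
        "importance": dict(zip(names, weights.tolist())),
        "gain_only": only,
        "gain_without": without,
        "gain_with_all": with_all,
    }


@dataclass
class MESSResult:
    mess: np.ndarray  # min over predictors of the similarity, per query point
    per_predictor: dict[str, np.ndarray]
    most_dissimilar: np.ndarray  # index into predictor order, per query point
    predictor_names: tuple[str, ...]
    fraction_nonneg: float


def _similarity(reference: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Similarity of each query value to the reference sample, percent-like.

    f is the percent of reference values below the query value (ties counted
    half to each side). f=0 and f=100 branches extrapolate linearly past the
    reference range, going negative outside it.
    """
    ref = np.sort(np.asarray(reference, dtype=float).ravel())
    q = np.asarray(query, dtype=float).ravel()
    n = ref.size
    lo, hi = ref[0], ref[-1]
    span = hi - lo
    below = np.searchsorted(ref, q, side="left")
    at = np.searchsorted(ref, q, side="right") - below
    f = (below + 0.5 * at) / n * 100.0

    s = np.empty_like(q)
    if span == 0:
        # degenerate reference: all values equal
        s[:] = np.where(q == lo, 0.0, -np.inf)
        return s
    branch_lo = f == 0
    branch_hi = f == 100
    s[branch_lo] = (q[branch_lo] - lo) / span * 100.0
    s[branch_hi] = (hi - q[branch_hi]) / span * 100.0
    mid = ~(branch_lo | branch_hi)
    fm = f[mid]
    s[mid] = np.where(fm <= 50.0, 2.0 * fm, 2.0 * (100.0 - fm))
    return s


def mess(
    reference: dict[str, np.ndarray],
    query: dict[str, np.ndarray],
) -> MESSResult:
    """Multivariate environmental similarity of query points to a reference
    sample: per-predictor similarity, with the surface being the minimum over
    predictors. Negative exactly where some predictor leaves its reference
    range. Shapes of the query arrays are preserved."""
    names = tuple(reference.keys())
    if not names:
        raise ValueError("need at least one predictor")
    if set(query.keys()) != set(names):
        raise ValueError("reference and query predictors differ")
    shape = np.asarray(query[names[0]]).shape
    per = {}
    stack = []
    for name in names:
        ref = np.asarray(reference[name], dtype=float).ravel()
        if ref.size == 0:
            raise ValueError(f"empty reference for predictor {name!r}")
        qv = np.asarray(query[name], dtype=float)
        if qv.shape != shape:
            raise ValueError("query layers must share one shape")
        s = _similarity(ref, qv).reshape(shape)
        per[name] = s
        stack.append(s)
    arr = np.stack(stack)
    finite = np.all(np.isfinite(np.stack([np.asarray(query[n], dtype=float) for n in names])), axis=0)
    mess_surface = np.where(finite, arr.min(axis=0), np.nan)
    most = np.where(finite, arr.argmin(axis=0), -1)
    vals = mess_surface[finite]
    frac = float(np.mean(vals >= 0)) if vals.size else float("nan")
    return MESSResult(
        mess=mess_surface,
        per_predictor=per,
        most_dissimilar=most,
        predictor_names=names,
        fraction_nonneg=frac,
    )


@dataclass
class EvaluationReport:
    auc_per_replicate: list[float]
    jackknife_importance: dict[str, float]
    fraction_nonneg_mess: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def auc_median(self) -> float:
        return float(np.median(self.auc_per_replicate))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.auc_per_replicate, ddof=1)) if len(self.auc_per_replicate) > 1 else 0.0

    @property
    def auc_min(self) -> float:
        return float(np.min(self.auc_per_replicate))

    @property
    def auc_max(self) -> float:
        return float(np.max(self.auc_per_replicate))

    @property
    def auc_class(self) -> str:
        return classify_auc(self.auc_median)

    def to_dict(self) -> dict:
        weights = np.array(list(self.jackknife_importance.values()))
        if np.any(weights < 0) or (weights.size and abs(weights.sum() - 1.0) > 1e-9):
            raise ValueError("jackknife importances must be non-negative and sum to 1")
        return {
            "auc_per_replicate": self.auc_per_replicate,
            "auc_median": self.auc_median,
            "auc_sd": self.auc_sd,
            "auc_min": self.auc_min,
            "auc_max": self.auc_max,
            "auc_class": self.auc_class,
            "jackknife_importance": self.jackknife_importance,
            "fraction_nonneg_mess": self.fraction_nonneg_mess,
            **self.extras,
        }
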