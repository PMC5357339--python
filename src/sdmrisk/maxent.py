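"""Presence-only maximum-entropy suitability model.

The model is the Gibbs distribution over background cells that maximizes the
l1-penalized presence log-likelihood

    (1/m) * sum_i  lambda . f(x_i)  -  ln Z(lambda)  -  sum_j beta_j |lambda_j|

with Z(lambda) = sum_background exp(lambda . f(x)). Features are linear,
quadratic, product and hinge transforms of the predictors, min-max scaled to
[0, 1] on the background. Fitting uses FISTA (accelerated proximal gradient
with backtracking and function restarts) on the convex negative objective.

Outputs: "raw" is the normalized relative occurrence rate summing to one over
the background; "logistic" maps raw through the entropy-calibrated bounded
transform used for suitability maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .grid import GridSpec
from .preprocess import BioclimLayers, PREDICTOR_NAMES

CANDIDATE_CLASSES = ("L", "LQ", "LQH", "LQP", "LQPH")
CANDIDATE_RM = (0.5, 1.0, 2.0, 3.0, 4.0)

#: per-class penalty constants (coarse stand-in for sample-size tables)
CLASS_CONSTANTS = {"linear": 1.0, "quadratic": 1.0, "product": 1.0, "hinge": 0.5}

#: floor on beta_j, keeps zero-variance features from escaping penalization
_BETA_FLOOR = 1e-4


class ConvergenceError(RuntimeError):
    """Raised when the solver hits its iteration cap; carries the last objective."""

    def __init__(self, message: str, objective: float):
        super().__init__(message)
        self.objective = objective


@dataclass
class Feature:
    kind: str  # linear | quadratic | product | hinge_fwd | hinge_rev
    predictors: tuple[int, ...]  # column indices into the predictor matrix
    lo: float  # scaling min (transform-space)
    hi: float  # scaling max
    knot: float | None = None

    @property
    def penalty_class(self) -> str:
        return "hinge" if self.kind.startswith("hinge") else self.kind

    def label(self, names: Sequence[str]) -> str:
        ps = "*".join(names[p] for p in self.predictors)
        if self.kind == "linear":
            return ps
        if self.kind == "quadratic":
            return f"{ps}^2"
        if self.kind == "product":
            return ps
        arrow = "'" if self.kind == "hinge_rev" else ""
        return f"hinge{arrow}({ps};{self.knot:.6g})"


@dataclass
class FeatureSet:
    """Feature definitions plus background scaling constants.

    ``clamp_lo``/``clamp_hi`` are the background per-predictor ranges;
    query predictor values are clamped to them before feature evaluation
    (the documented clamp), and feature outputs are clipped to [0, 1].
    """

    predictor_names: tuple[str, ...]
    features: list[Feature]
    clamp_lo: np.ndarray
    clamp_hi: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.predictor_names):
            raise ValueError("predictor matrix has wrong number of columns")
        Xc = np.clip(X, self.clamp_lo, self.clamp_hi)
        out = np.empty((X.shape[0], len(self.features)))
        for j, f in enumerate(self.features):
            if f.kind == "linear":
                v = Xc[:, f.predictors[0]]
            elif f.kind == "quadratic":
                v = Xc[:, f.predictors[0]] ** 2
            elif f.kind == "product":
                v = Xc[:, f.predictors[0]] * Xc[:, f.predictors[1]]
            elif f.kind == "hinge_fwd":
                v = np.maximum(0.0, Xc[:, f.predictors[0]] - f.knot)
            elif f.kind == "hinge_rev":
                v = np.maximum(0.0, f.knot - Xc[:, f.predictors[0]])
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {f.kind}")
            span = f.hi - f.lo
            out[:, j] = (v - f.lo) / span if span > 0 else 0.0
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "predictor_names": list(self.predictor_names),
            "clamp_lo": self.clamp_lo.tolist(),
            "clamp_hi": self.clamp_hi.tolist(),
            "dropped": self.dropped,
            "features": [
                {
                    "kind": f.kind,
                    "predictors": list(f.predictors),
                    "lo": f.lo,
                    "hi": f.hi,
                    "knot": f.knot,
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(
            predictor_names=tuple(d["predictor_names"]),
            features=[
                Feature(
                    kind=f["kind"],
                    predictors=tuple(f["predictors"]),
                    lo=f["lo"],
                    hi=f["hi"],
                    knot=f["knot"],
                )
                for f in d["features"]
            ],
            clamp_lo=np.asarray(d["clamp_lo"], dtype=float),
            clamp_hi=np.asarray(d["clamp_hi"], dtype=float),
            dropped=list(d.get("dropped", [])),
        )


def build_features(
    X_background: np.ndarray,
    predictor_names: Sequence[str] | None = None,
    classes: str = "LQH",
    n_hinge_knots: int = 50,
) -> FeatureSet:
    """Build a feature set scaled to the background predictor distribution.

    ``classes`` is a subset of "LQPH": Linear, Quadratic (squares), Product
    (pairwise), Hinge (forward and reverse, knots at background quantiles
    strictly inside the range). Constant predictors contribute no features
    and are recorded in ``FeatureSet.dropped`` with a warning.
    """
    X = np.atleast_2d(np.asarray(X_background, dtype=float))
    if predictor_names is None:
        predictor_names = (
            PREDICTOR_NAMES if X.shape[1] == len(PREDICTOR_NAMES)
            else tuple(f"p{j}" for j in range(X.shape[1]))
        )
    names = tuple(predictor_names)
    if X.shape[1] != len(names):
        raise ValueError("predictor matrix / names mismatch")
    classes = classes.upper()
    if not classes or any(c not in "LQPH" for c in classes):
        raise ValueError(f"invalid feature classes {classes!r}")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    constant = hi <= lo
    dropped = [names[p] for p in range(len(names)) if constant[p]]
    if dropped:
        warnings.warn(f"constant predictors dropped from features: {dropped}")
    live = [p for p in range(len(names)) if not constant[p]]

    feats: list[Feature] = []
    if "L" in classes:
        for p in live:
            feats.append(Feature("linear", (p,), lo[p], hi[p]))
    if "Q" in classes:
        for p in live:
            sq = X[:, p] ** 2
            feats.append(Feature("quadratic", (p,), float(sq.min()), float(sq.max())))
    if "P" in classes:
        for a_i, a in enumerate(live):
            for b in live[a_i + 1 :]:
                pr = X[:, a] * X[:, b]
                feats.append(Feature("product", (a, b), float(pr.min()), float(pr.max())))
    if "H" in classes:
        for p in live:
            qs = np.quantile(X[:, p], np.arange(1, n_hinge_knots + 1) / (n_hinge_knots + 1))
            knots = np.unique(qs)
            knots = knots[(knots > lo[p]) & (knots < hi[p])]
            for k in knots:
                feats.append(Feature("hinge_fwd", (p,), 0.0, float(hi[p] - k), knot=float(k)))
                feats.append(Feature("hinge_rev", (p,), 0.0, float(k - lo[p]), knot=float(k)))
    return FeatureSet(predictor_names=names, features=feats, clamp_lo=lo, clamp_hi=hi, dropped=dropped)


@dataclass
class MaxentModel:
    feature_set: FeatureSet
    lambdas: np.ndarray  # (J,)
    betas: np.ndarray  # (J,)
    rm: float
    log_z: float  # ln Z over the fit background
    entropy: float  # H of the fitted raw distribution over the background
    n_background: int
    background_X: np.ndarray  # raw predictor matrix used as background
    n_presence: int
    n_iter: int = 0
    converged: bool = True

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.lambdas))

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set.to_dict(),
            "lambdas": self.lambdas.tolist(),
            "betas": self.betas.tolist(),
            "rm": self.rm,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_background": self.n_background,
            "n_presence": self.n_presence,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    def lambdas_text(self) -> str:
        """Plain-text export of nonzero coefficients for human inspection."""
        lines = [f"# rm={self.rm} logZ={self.log_z:.6f} H={self.entropy:.6f}"]
        names = self.feature_set.predictor_names
        for f, lam in zip(self.feature_set.features, self.lambdas):
            if lam != 0:
                lines.append(f"{f.label(names)}\t{lam:.10g}")
        return "\n".join(lines) + "\n"


def _objective(lam, F_bg, mean_pres, betas):
    return float(logsumexp(F_bg @ lam) - mean_pres @ lam + betas @ np.abs(lam))


def fit_maxent(
    F_presence: np.ndarray,
    F_background: np.ndarray,
    rm: float = 1.0,
    feature_set: FeatureSet | None = None,
    background_X: np.ndarray | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model on design matrices.

    ``F_presence`` (m x J) and ``F_background`` (N x J) are feature values in
    [0, 1]. Per-feature penalties are beta_j = rm * c_class * sd_j / sqrt(m)
    with sd_j the presence-sample standard deviation of feature j (floored to
    keep zero-variance features penalized).
    """
    if not rm > 0:
        raise ValueError("regularization multiplier must be positive")
    F_pres = np.atleast_2d(np.asarray(F_presence, dtype=float))
    F_bg = np.atleast_2d(np.asarray(F_background, dtype=float))
    m, J = F_pres.shape
    N = F_bg.shape[0]
    if m < 5:
        raise ValueError(f"need at least 5 presence points, got {m}")
    if N < m:
        raise ValueError("background must be at least as large as the presence set")
    if F_bg.shape[1] != J:
        raise ValueError("presence/background feature count mismatch")
    if not (np.isfinite(F_pres).all() and np.isfinite(F_bg).all()):
        raise ValueError("non-finite feature values")

    if feature_set is not None:
        c_class = np.array([CLASS_CONSTANTS[f.penalty_class] for f in feature_set.features])
    else:
        c_class = np.ones(J)
    sd = F_pres.std(axis=0, ddof=0)
    betas = np.maximum(rm * c_class * sd / np.sqrt(m), _BETA_FLOOR)

    mean_pres = F_pres.mean(axis=0)

    def smooth(lam):
        s = F_bg @ lam
        lse = logsumexp(s)
        p = np.exp(s - lse)
        g = p @ F_bg - mean_pres
        return float(lse - mean_pres @ lam), g

    lam = np.zeros(J)
    y = lam.copy()
    t_mom = 1.0
    L = 1.0
    obj = _objective(lam, F_bg, mean_pres, betas)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gy, grad = smooth(y)
        # backtracking line search on the smooth part
        while True:
            cand = np.sign(y - grad / L) * np.maximum(np.abs(y - grad / L) - betas / L, 0.0)
            diff = cand - y
            s_cand = F_bg @ cand
            g_cand = float(logsumexp(s_cand) - mean_pres @ cand)
            if g_cand <= gy + grad @ diff + 0.5 * L * diff @ diff + 1e-12:
                break
            L *= 2.0
        new_obj = g_cand + betas @ np.abs(cand)
        if new_obj > obj:  # function restart: drop momentum
            y = lam.copy()
            t_mom = 1.0
            continue
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        y = cand + ((t_mom - 1.0) / t_next) * (cand - lam)
        lam, t_mom = cand, t_next
        obj = new_obj
        # subgradient optimality residual at the new point (KKT check)
        p_cand = np.exp(s_cand - logsumexp(s_cand))
        g_at = p_cand @ F_bg - mean_pres
        res = np.where(
            cand != 0.0,
            np.abs(g_at + betas * np.sign(cand)),
            np.maximum(np.abs(g_at) - betas, 0.0),
        )
        if float(res.max()) <= tol:
            break
        L *= 0.95  # allow the step to grow back
    else:
        raise ConvergenceError(
            f"maxent solver did not converge in {max_iter} iterations", objective=obj
        )

    s = F_bg @ lam
    log_z = float(logsumexp(s))
    p = np.exp(s - log_z)
    entropy = float(-np.sum(p * np.log(np.where(p > 0, p, 1.0))))
    return MaxentModel(
        feature_set=feature_set
        if feature_set is not None
        else FeatureSet(
            predictor_names=tuple(f"f{j}" for j in range(J)),
            features=[Feature("linear", (j,), 0.0, 1.0) for j in range(J)],
            clamp_lo=np.zeros(J),
            clamp_hi=np.ones(J),
        ),
        lambdas=lam,
        betas=betas,
        rm=rm,
        log_z=log_z,
        entropy=entropy,
        n_background=N,
        background_X=np.empty((0, J)) if background_X is None else np.asarray(background_X, dtype=float),
        n_presence=m,
        n_iter=n_iter,
        converged=True,
    )


def fit_from_predictors(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    classes: str = "LQH",
    rm: float = 1.0,
    n_hinge_knots: int = 50,
    predictor_names: Sequence[str] | None = None,
    **kwargs,
) -> MaxentModel:
    """Convenience wrapper: build features on the background, then fit."""
    n_pred = np.atleast_2d(X_background).shape[1]
    if predictor_names is None:
        predictor_names = (
            PREDICTOR_NAMES if n_pred == len(PREDICTOR_NAMES)
            else tuple(f"p{j}" for j in range(n_pred))
        )
    fs = build_features(X_background, predictor_names=predictor_names,
                        classes=classes, n_hinge_knots=n_hinge_knots)
    return fit_maxent(
        fs.transform(X_presence),
        fs.transform(X_background),
        rm=rm,
        feature_set=fs,
        background_X=X_background,
        **kwargs,
    )


def predict_raw(model: MaxentModel, X: np.ndarray) -> np.ndarray:
    """Raw relative occurrence rate exp(lambda . f(x)) / Z; sums to one over
    the model's own background."""
    F = model.feature_set.transform(X)
    return np.exp(F @ model.lambdas - model.log_z)


def predict_raw_design(model: MaxentModel, F: np.ndarray) -> np.ndarray:
    return np.exp(np.atleast_2d(F) @ model.lambdas - model.log_z)


def predict_logistic(model: MaxentModel, X: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Entropy-calibrated logistic suitability in (0, 1).

    l(x) = e^H raw(x) r / (1 + e^H raw(x) r) with r = tau / (1 - tau).
    A uniform model (raw = 1/N, H = ln N) gives exactly tau everywhere.
    """
    raw = predict_raw(model, X)
    odds = np.exp(model.entropy) * raw * (tau / (1.0 - tau))
    return odds / (1.0 + odds)


def aicc(model: MaxentModel, raw_presence: np.ndarray, raw_allcells: np.ndarray) -> float:
    """Sample-size-corrected AIC from the presence likelihood.

    Raw values are standardized to sum to one over all cells; k is the count
    of nonzero coefficients. Returns +inf when k >= m - 1 (invalid by
    convention).
    """
    raw_presence = np.asarray(raw_presence, dtype=float)
    raw_allcells = np.asarray(raw_allcells, dtype=float)
    m = raw_presence.size
    k = model.n_nonzero
    if k >= m - 1:
        return float("inf")
    total = raw_allcells.sum()
    lnl = float(np.sum(np.log(raw_presence / total)))
    return 2.0 * k - 2.0 * lnl + 2.0 * k * (k + 1.0) / (m - k - 1.0)


@dataclass
class TuningResult:
    candidates: list[dict]  # {"classes", "rm", "aicc", "k", "loglik"}
    selected: dict

    def __post_init__(self) -> None:
        finite = [c for c in self.candidates if np.isfinite(c["aicc"])]
        if finite and self.selected["aicc"] > min(c["aicc"] for c in finite):
            raise ValueError("selected candidate does not have the minimal AICc")


def tune_settings(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    candidate_classes: Sequence[str] = CANDIDATE_CLASSES,
    candidate_rm: Sequence[float] = CANDIDATE_RM,
    n_hinge_knots: int = 50,
    **fit_kwargs,
) -> TuningResult:
    """Fit every (classes, rm) candidate and select the minimal-AICc one.

    The background doubles as the all-cell set for AICc standardization.
    Ties break deterministically: fewer nonzero coefficients, then lower rm,
    then candidate-class order.
    """
    if not candidate_classes or not len(candidate_rm):
        raise ValueError("need at least one candidate")
    candidates = []
    for ci, classes in enumerate(candidate_classes):
        fs = build_features(X_background, classes=classes, n_hinge_knots=n_hinge_knots)
        F_pres = fs.transform(X_presence)
        F_bg = fs.transform(X_background)
        for rm in candidate_rm:
            model = fit_maxent(F_pres, F_bg, rm=rm, feature_set=fs,
                               background_X=X_background, **fit_kwargs)
            raw_pres = predict_raw_design(model, F_pres)
            raw_all = predict_raw_design(model, F_bg)
            score = aicc(model, raw_pres, raw_all)
            lnl = float(np.sum(np.log(raw_pres / raw_all.sum())))
            candidates.append(
                {
                    "classes": classes,
                    "rm": float(rm),
                    "aicc": float(score),
                    "k": model.n_nonzero,
                    "loglik": lnl,
                    "_order": (ci, rm),
                    "model": model,
                }
            )
    valid = [c for c in candidates if np.isfinite(c["aicc"])]
    if not valid:
        raise ValueError("all tuning candidates are invalid (k >= m - 1)")
    best = min(valid, key=lambda c: (c["aicc"], c["k"], c["rm"], c["_order"]))
    public = [
        {k: v for k, v in c.items() if k not in ("_order", "model")} for c in candidates
    ]
    sel = {k: v for k, v in best.items() if k != "_order"}
    return TuningResult(candidates=public, selected=sel)


@dataclass
class ModelSettings:
    classes: str = "LQH"
    rm: float = 1.0
    n_hinge_knots: int = 50
    tau: float = 0.5


@dataclass
class SuitabilityMap:
    """Cellwise mean logistic suitability over replicate fits."""

    values: np.ndarray  # (R, C), NaN on nodata
    grid: GridSpec
    n_replicates: int
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        self.grid.check_layer(self.values)
        valid = self.values[self.grid.valid_mask]
        valid = valid[np.isfinite(valid)]
        if valid.size and (valid.min() <= 0 or valid.max() >= 1):
            raise ValueError("suitability values must lie strictly in (0, 1)")


def select_background(
    bioclim: BioclimLayers, max_background: int = 10_000, seed=0
) -> tuple[np.ndarray, np.ndarray]:
    """Background predictor matrix: all valid cells, or a seeded uniform
    sample of ``max_background`` of them. Returns (X, flat cell indices)."""
    X, flat = bioclim.values_valid()
    if X.shape[0] > max_background:
        rng = np.random.default_rng(seed)
        pick = rng.choice(X.shape[0], size=max_background, replace=False)
        pick.sort()
        return X[pick], flat[pick]
    return X, flat


def replicate_fit(
    X_presence: np.ndarray,
    bioclim: BioclimLayers,
    settings: ModelSettings | None = None,
    n_replicates: int = 15,
    test_fraction: float = 0.25,
    master_seed: int = 0,
    max_background: int = 10_000,
) -> tuple[SuitabilityMap, list[float], list[MaxentModel]]:
    """Random-subsampling replicates: seeded 75/25 presence splits, one fit
    each, full-grid logistic prediction, held-out AUC vs the background.

    Returns the cellwise mean map, the per-replicate test AUC list, and the
    fitted models.
    """
    from .evaluation import auc as _auc

    settings = settings or ModelSettings()
    X_pres = np.atleast_2d(np.asarray(X_presence, dtype=float))
    m = X_pres.shape[0]
    n_test = int(round(m * test_fraction)) if n_replicates > 1 or test_fraction > 0 else 0
    if m - n_test < 5:
        raise ValueError("too few presences for the requested split")

    X_bg, bg_flat = select_background(bioclim, max_background, seed=[master_seed, 9999])
    fs = build_features(X_bg, classes=settings.classes, n_hinge_knots=settings.n_hinge_knots)
    F_bg = fs.transform(X_bg)

    grid = bioclim.grid
    X_all, all_flat = bioclim.values_valid()

    maps = np.empty((n_replicates, grid.n_rows, grid.n_cols))
    aucs: list[float] = []
    models: list[MaxentModel] = []
    for r in range(n_replicates):
        rng = np.random.default_rng([master_seed, r])
        order = rng.permutation(m)
        test_idx, train_idx = order[:n_test], order[n_test:]
        model = fit_maxent(
            fs.transform(X_pres[train_idx]), F_bg, rm=settings.rm,
            feature_set=fs, background_X=X_bg,
        )
        pred = np.full(grid.shape, np.nan)
        pred.ravel()[all_flat] = predict_logistic(model, X_all, tau=settings.tau)
        maps[r] = pred
        if n_test:
            pres_scores = predict_logistic(model, X_pres[test_idx], tau=settings.tau)
            bg_scores = predict_logistic(model, X_bg, tau=settings.tau)
            aucs.append(_auc(pres_scores, bg_scores))
        models.append(model)
    mean_map = maps.mean(axis=0)
    return SuitabilityMap(values=mean_map, grid=grid, n_replicates=n_replicates), aucs, models


def response_curve(
    model: MaxentModel, predictor: str, n_points: int = 100, tau: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Sweep one predictor across its background range with the others held
    at their background means; returns (grid, logistic suitability)."""
    names = model.feature_set.predictor_names
    if predictor not in names:
        raise KeyError(f"unknown predictor {predictor!r}")
    if model.background_X.size == 0:
        raise ValueError("model carries no background predictor matrix")
    p = names.index(predictor)
    lo, hi = model.feature_set.clamp_lo[p], model.feature_set.clamp_hi[p]
    sweep = np.linspace(lo, hi, n_points)
    X = np.tile(model.background_X.mean(axis=0), (n_points, 1))
    X[:, p] = sweep
    return sweep, predict_logistic(model, X, tau=tau)
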