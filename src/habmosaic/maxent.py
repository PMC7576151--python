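"""Maximum-entropy presence-background suitability model.

The model is the regularized Gibbs distribution over background cells,

    p_lambda(x) = exp(lambda . f(x)) / Z,

fitted by maximizing the presence log-likelihood minus an L1 penalty
``sum_j beta_j |lambda_j|``. Feature classes are linear, quadratic and hinge
(15 knots per direction at training quantiles), all scaled to [0, 1] and
clamped to training bounds on new data. The per-feature penalty weight
follows the published Maxent default table for each feature class,
interpolated on the presence sample size and scaled by the feature's
standard deviation at presences over sqrt(n).

Optimization is a monotone proximal-gradient descent with backtracking, so
the penalized objective is non-increasing across iterations and the fit is
deterministic given its inputs. The default map output is the cloglog
transform ``1 - exp(-exp(H) * raw)`` with H the entropy of the fitted
distribution over the background sample.

Spatial-bias handling for statewide background sampling is provided by a
95% kernel-density (utilization-distribution) region with the reference
bandwidth h_ref; background points are uniform cell-center draws inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .covariates import CovariateStack
from .raster import Raster

FEATURE_CLASSES = ("linear", "quadratic", "hinge")

# Published default regularization values per feature class, as
# (presence sample size, beta) breakpoints with linear interpolation.
_REG_TABLE = {
    "linear": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(0, 1.3), (10, 0.8), (17, 0.5), (30, 0.25), (100, 0.05)],
    "hinge": [(0, 0.5), (100, 0.5)],
}


def _class_default(feature_class: str, n_presence: int) -> float:
    table = _REG_TABLE[feature_class]
    xs = np.array([t[0] for t in table], dtype=float)
    ys = np.array([t[1] for t in table], dtype=float)
    return float(np.interp(n_presence, xs, ys))


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Feature expansion shared by training and prediction.

    Bounds and hinge knots come from the training sample; evaluation on new
    data clamps covariates into the training range first, the standard guard
    against extrapolating feature responses.
    """

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    classes: tuple[str, ...] = FEATURE_CLASSES
    knots: dict[str, np.ndarray] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    feature_class: list[str] = field(default_factory=list)

    @classmethod
    def from_training(
        cls,
        X: np.ndarray,
        names: Sequence[str],
        classes: Sequence[str] = FEATURE_CLASSES,
        n_knots: int = 15,
    ) -> "FeatureSet":
        X = np.asarray(X, dtype=float)
        lower = X.min(axis=0)
        upper = X.max(axis=0)
        fs = cls(names=list(names), lower=lower, upper=upper,
                 classes=tuple(classes))
        if "hinge" in fs.classes:
            qs = np.linspace(0, 1, n_knots + 2)[1:-1]
            for j, name in enumerate(fs.names):
                fs.knots[name] = np.quantile(X[:, j], qs)
        fs._index_features()
        return fs

    def _index_features(self) -> None:
        fn, fc = [], []
        for j, name in enumerate(self.names):
            if "linear" in self.classes:
                fn.append(f"lin:{name}")
                fc.append("linear")
            if "quadratic" in self.classes:
                fn.append(f"quad:{name}")
                fc.append("quadratic")
            if "hinge" in self.classes:
                for i in range(len(self.knots.get(name, []))):
                    fn.append(f"hingef:{name}:{i}")
                    fc.append("hinge")
                for i in range(len(self.knots.get(name, []))):
                    fn.append(f"hinger:{name}:{i}")
                    fc.append("hinge")
        self.feature_names = fn
        self.feature_class = fc

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map covariate rows to the [0, 1]-scaled feature matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite covariate values")
        cols = []
        for j, name in enumerate(self.names):
            lo, hi = self.lower[j], self.upper[j]
            span = hi - lo if hi > lo else 1.0
            x = np.clip(X[:, j], lo, hi)
            if "linear" in self.classes:
                cols.append((x - lo) / span)
            if "quadratic" in self.classes:
                cols.append(((x - lo) / span) ** 2)
            if "hinge" in self.classes:
                for k in self.knots[name]:
                    denom = hi - k if hi > k else 1.0
                    cols.append(np.maximum(0.0, x - k) / denom)
                for k in self.knots[name]:
                    denom = k - lo if k > lo else 1.0
                    cols.append(np.maximum(0.0, k - x) / denom)
        return np.column_stack(cols)

    def column_block(self, name: str) -> slice:
        """Slice of feature columns belonging to one covariate."""
        idx = [i for i, fn in enumerate(self.feature_names)
               if fn.split(":")[1] == name]
        return slice(idx[0], idx[-1] + 1)

    def transform_block(self, name: str, x: np.ndarray) -> np.ndarray:
        """Feature columns of a single covariate for the given values."""
        j = self.names.index(name)
        lo, hi = self.lower[j], self.upper[j]
        span = hi - lo if hi > lo else 1.0
        x = np.clip(np.asarray(x, dtype=float), lo, hi)
        cols = []
        if "linear" in self.classes:
            cols.append((x - lo) / span)
        if "quadratic" in self.classes:
            cols.append(((x - lo) / span) ** 2)
        if "hinge" in self.classes:
            for k in self.knots[name]:
                denom = hi - k if hi > k else 1.0
                cols.append(np.maximum(0.0, x - k) / denom)
            for k in self.knots[name]:
                denom = k - lo if k > lo else 1.0
                cols.append(np.maximum(0.0, k - x) / denom)
        return np.column_stack(cols)

    def linear_scale(self) -> dict[str, float]:
        """Factor mapping each linear-feature coefficient back to covariate scale."""
        return {
            name: 1.0 / (self.upper[j] - self.lower[j]
                         if self.upper[j] > self.lower[j] else 1.0)
            for j, name in enumerate(self.names)
        }


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    feature_set: FeatureSet
    lam: np.ndarray
    beta: np.ndarray
    log_z: float                    # log normalizer over the training background
    entropy: float                  # H of the fitted distribution
    output_transform: str = "cloglog"
    n_iter: int = 0
    objective_path: list[float] = field(default_factory=list)
    converged: bool = True

    def raw(self, X: np.ndarray) -> np.ndarray:
        """Gibbs score exp(lambda.f - log Z); sums to 1 over the training background."""
        F = self.feature_set.transform(X)
        return np.exp(F @ self.lam - self.log_z)

    def transform_output(self, raw: np.ndarray) -> np.ndarray:
        if self.output_transform == "raw":
            return raw
        if self.output_transform == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        if self.output_transform == "logistic":
            r = np.exp(self.entropy) * raw
            return r / (1.0 + r)
        raise ValueError(f"unknown output transform {self.output_transform!r}")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.transform_output(self.raw(X))

    def covariate_coefficients(self) -> dict[str, float]:
        """Linear-feature coefficients mapped back to covariate units."""
        scale = self.feature_set.linear_scale()
        out = {}
        for lam_j, fname in zip(self.lam, self.feature_set.feature_names):
            if fname.startswith("lin:"):
                name = fname[4:]
                out[name] = float(lam_j) * scale[name]
        return out

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        fs = self.feature_set
        payload = {
            "names": fs.names,
            "lower": fs.lower.tolist(),
            "upper": fs.upper.tolist(),
            "classes": list(fs.classes),
            "knots": {k: v.tolist() for k, v in fs.knots.items()},
            "lam": self.lam.tolist(),
            "beta": self.beta.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "output_transform": self.output_transform,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        fs = FeatureSet(
            names=d["names"], lower=np.array(d["lower"]),
            upper=np.array(d["upper"]), classes=tuple(d["classes"]),
            knots={k: np.array(v) for k, v in d["knots"].items()},
        )
        fs._index_features()
        return cls(feature_set=fs, lam=np.array(d["lam"]),
                   beta=np.array(d["beta"]), log_z=d["log_z"],
                   entropy=d["entropy"], output_transform=d["output_transform"])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _penalty_weights(
    F_pres: np.ndarray, fs: FeatureSet, reg_multiplier: float
) -> np.ndarray:
    n = F_pres.shape[0]
    sd = F_pres.std(axis=0)
    sd = np.maximum(sd, 1e-3)       # floor keeps never-varying features penalized
    beta = np.empty(fs.n_features)
    for j, cls_name in enumerate(fs.feature_class):
        beta[j] = _class_default(cls_name, n) * sd[j] / np.sqrt(n)
    return reg_multiplier * beta


def fit_maxent(
    presence: np.ndarray,
    background: np.ndarray,
    reg_multiplier: float = 1.0,
    feature_set: FeatureSet | None = None,
    names: Sequence[str] | None = None,
    classes: Sequence[str] = FEATURE_CLASSES,
    n_knots: int = 15,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> MaxentModel:
    """Fit the L1-penalized Gibbs model.

    ``presence`` and ``background`` are covariate matrices (rows = points).
    The solver is monotone proximal gradient with backtracking; convergence
    is declared when the relative change of the penalized objective drops
    below ``tol``. Raises if the iteration budget is exhausted first.
    """
    presence = np.atleast_2d(np.asarray(presence, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if presence.shape[0] < 2:
        raise ValueError("need at least two presence points")
    if background.shape[0] < 2:
        raise ValueError("need at least two background points")
    if not (np.all(np.isfinite(presence)) and np.all(np.isfinite(background))):
        raise ValueError("non-finite covariate values")
    if names is None:
        names = [f"v{j}" for j in range(presence.shape[1])]
    if feature_set is None:
        both = np.vstack([presence, background])
        feature_set = FeatureSet.from_training(both, names, classes, n_knots)

    F_pres = feature_set.transform(presence)
    F_bg = feature_set.transform(background)
    p_bar = F_pres.mean(axis=0)
    beta = _penalty_weights(F_pres, feature_set, reg_multiplier)

    lam = np.zeros(feature_set.n_features)
    scores = F_bg @ lam

    def smooth_val(scores_: np.ndarray, lam_: np.ndarray) -> float:
        return float(logsumexp(scores_) - np.log(F_bg.shape[0]) - p_bar @ lam_)

    def objective(scores_: np.ndarray, lam_: np.ndarray) -> float:
        return smooth_val(scores_, lam_) + float(beta @ np.abs(lam_))

    obj = objective(scores, lam)
    path = [obj]
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.exp(scores - logsumexp(scores))
        grad = F_bg.T @ w - p_bar
        g_val = smooth_val(scores, lam)
        while True:
            cand = lam - step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * beta, 0.0)
            diff = cand - lam
            cand_scores = F_bg @ cand
            lhs = smooth_val(cand_scores, cand)
            rhs = g_val + grad @ diff + (diff @ diff) / (2.0 * step)
            if lhs <= rhs + 1e-12 or step < 1e-12:
                break
            step *= 0.5
        lam, scores = cand, cand_scores
        new_obj = objective(scores, lam)
        path.append(new_obj)
        rel = abs(obj - new_obj) / max(1.0, abs(obj))
        obj = new_obj
        if rel < tol:
            converged = True
            break
        step *= 1.3
    if not converged:
        raise RuntimeError(
            f"maxent did not converge in {max_iter} iterations "
            f"(last objective {obj:.6g}, last rel change {rel:.3g})"
        )

    log_z = float(logsumexp(scores))
    w = np.exp(scores - log_z)
    entropy = float(-(w * np.where(w > 0, np.log(w), 0.0)).sum())
    return MaxentModel(
        feature_set=feature_set, lam=lam, beta=beta, log_z=log_z,
        entropy=entropy, n_iter=it, objective_path=path, converged=converged,
    )


def training_gain(model: MaxentModel, presence: np.ndarray,
                  background: np.ndarray) -> float:
    """Mean presence log-probability gain over the uniform background model."""
    F_pres = model.feature_set.transform(presence)
    F_bg = model.feature_set.transform(background)
    log_z = logsumexp(F_bg @ model.lam)
    return float((F_pres @ model.lam).mean() - log_z
                 + np.log(F_bg.shape[0]))


# ---------------------------------------------------------------------------
# Prediction over a stack
# ---------------------------------------------------------------------------

def predict_maxent(model: MaxentModel, stack: CovariateStack) -> Raster:
    """Cellwise suitability map (default cloglog, in [0, 1])."""
    missing = set(model.feature_set.names) - set(stack.names)
    if missing:
        raise KeyError(f"stack is missing covariates: {sorted(missing)}")
    mask = stack.valid_mask()
    X = np.column_stack(
        [stack.rasters[n].values[mask] for n in model.feature_set.names])
    out = np.full(stack.grid.shape, np.nan)
    out[mask] = model.predict(X)
    return stack.grid.with_values(out)


# ---------------------------------------------------------------------------
# Background sampling and the KDE region
# ---------------------------------------------------------------------------

@dataclass
class KdePolygon:
    """A kernel-density utilization-distribution superlevel region."""

    bandwidth: float
    density: Raster
    level: float
    mask: Raster                    # {0,1} cells of the superlevel set

    def polygon(self):
        """Shapely boundary polygon(s) of the region (union of cell boxes)."""
        from shapely.geometry import box as _box
        from shapely.ops import unary_union

        g = self.mask
        rows, cols = np.nonzero(g.values)
        boxes = []
        for r, c in zip(rows, cols):
            x0 = g.x_origin + c * g.cell_size
            y1 = g.y_origin + (g.nrows - r) * g.cell_size
            boxes.append(_box(x0, y1 - g.cell_size, x0 + g.cell_size, y1))
        return unary_union(boxes)

    def area_km2(self) -> float:
        return float(self.mask.values.sum()) * self.mask.cell_area_km2()


def kde_polygon(
    points: np.ndarray, grid: Raster, level: float = 0.95
) -> KdePolygon:
    """Utilization distribution with the reference bandwidth h_ref.

    ``h_ref = sqrt((var_x + var_y) / 2) * n^(-1/6)`` (bivariate normal
    kernel). The region is the smallest density superlevel set holding at
    least ``level`` of the total KDE mass on the grid.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 5:
        raise ValueError("need at least five points for a KDE region")
    var = points.var(axis=0, ddof=1)
    h = float(np.sqrt((var[0] + var[1]) / 2.0) * points.shape[0] ** (-1.0 / 6.0))
    if h <= 0:
        raise ValueError("degenerate bandwidth: all points identical")
    cx, cy = grid.cell_centers()
    dens = np.zeros(grid.shape)
    norm = 1.0 / (2.0 * np.pi * h * h * points.shape[0])
    # chunked accumulation keeps memory bounded for large point sets
    for start in range(0, points.shape[0], 512):
        chunk = points[start:start + 512]
        d2 = ((cx[..., None] - chunk[:, 0]) ** 2
              + (cy[..., None] - chunk[:, 1]) ** 2)
        dens += np.exp(-d2 / (2.0 * h * h)).sum(axis=-1)
    dens *= norm
    density = grid.with_values(dens)

    mask_flat = np.zeros(dens.size, dtype=int)
    if level >= 1.0:
        mask_flat[dens.ravel() > 0] = 1
    else:
        order = np.argsort(dens.ravel())[::-1]
        mass = dens.ravel()[order]
        cum = np.cumsum(mass)
        n_in = int(np.searchsorted(cum, level * mass.sum()) + 1)
        mask_flat[order[:n_in]] = 1
    return KdePolygon(bandwidth=h, density=density, level=level,
                      mask=grid.with_values(mask_flat.reshape(grid.shape)))


def sample_background(
    region: Raster | KdePolygon, n: int = 10000, seed: int = 0
) -> np.ndarray:
    """Uniform cell-center draws (with replacement) from a region mask."""
    mask = region.mask if isinstance(region, KdePolygon) else region
    rows, cols = np.nonzero(mask.values.astype(bool) & mask.valid_mask())
    if rows.size == 0:
        raise ValueError("empty background region")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, rows.size, size=n)
    x = mask.x_origin + (cols[pick] + 0.5) * mask.cell_size
    y = mask.y_origin + (mask.nrows - rows[pick] - 0.5) * mask.cell_size
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Variable contribution and selection
# ---------------------------------------------------------------------------

def percent_contribution(
    model: MaxentModel,
    presence: np.ndarray,
    background: np.ndarray,
    seed: int = 0,
    n_permutations: int = 10,
) -> dict[str, float]:
    """Permutation importance normalized to sum to 100.

    For each covariate, its values are shuffled across the pooled
    presence+background points and the drop in training gain (mean of
    ``n_permutations`` shuffles, floored at zero) is recorded.
    """
    rng = np.random.default_rng(seed)
    presence = np.atleast_2d(np.asarray(presence, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    fs = model.feature_set
    n_p = presence.shape[0]
    pool = np.vstack([presence, background])
    F_pool = fs.transform(pool)
    n_bg = background.shape[0]

    def gain(scores_pres: np.ndarray, scores_bg: np.ndarray) -> float:
        return float(scores_pres.mean() - logsumexp(scores_bg) + np.log(n_bg))

    scores = F_pool @ model.lam
    base = gain(scores[:n_p], scores[n_p:])
    drops = np.zeros(len(fs.names))
    for j, name in enumerate(fs.names):
        block = fs.column_block(name)
        lam_b = model.lam[block]
        # scores with this covariate's contribution removed, recomputed per shuffle
        partial = scores - F_pool[:, block] @ lam_b
        tot = 0.0
        for _ in range(n_permutations):
            shuffled = rng.permutation(pool[:, j])
            s = partial + fs.transform_block(name, shuffled) @ lam_b
            tot += base - gain(s[:n_p], s[n_p:])
        drops[j] = max(0.0, tot / n_permutations)
    names = fs.names
    if drops.sum() == 0:
        return {n: 100.0 / len(names) for n in names}
    pct = 100.0 * drops / drops.sum()
    return dict(zip(names, pct.tolist()))


def stepwise_select(
    stack: CovariateStack,
    presence_xy: np.ndarray,
    background_xy: np.ndarray,
    reg_multiplier: float = 1.0,
    contribution_floor: float = 1.0,
    corr_threshold: float = 0.7,
    max_rounds: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[list[str], MaxentModel]:
    """Reverse step-wise variable selection.

    Fit with all variables, drop those contributing <= ``contribution_floor``
    percent, then among flagged correlated pairs keep the higher-contribution
    member; refit and repeat until stable (at most ``max_rounds`` rounds).
    """
    from .covariates import correlation_screen

    if stack.correlation is None:
        correlation_screen(stack, corr_threshold)
    variables = [n for n in stack.names if n not in stack.degenerate]
    flagged = {(a, b) for a, b, _ in stack.flagged_pairs}
    model: MaxentModel | None = None
    for _ in range(max_rounds):
        if not variables:
            raise ValueError("step-wise selection dropped every variable")
        P = stack.values_at(presence_xy[:, 0], presence_xy[:, 1], variables)
        B = stack.values_at(background_xy[:, 0], background_xy[:, 1], variables)
        model = fit_maxent(P, B, reg_multiplier=reg_multiplier,
                           names=variables, **fit_kwargs)
        pc = percent_contribution(model, P, B, seed=seed)
        keep = [v for v in variables if pc[v] > contribution_floor]
        if not keep:
            raise ValueError("step-wise selection dropped every variable")
        for a, b in flagged:
            if a in keep and b in keep:
                keep.remove(a if pc[a] <= pc[b] else b)
        if keep == variables:
            break
        variables = keep
    assert model is not None
    if set(variables) != set(model.feature_set.names):
        P = stack.values_at(presence_xy[:, 0], presence_xy[:, 1], variables)
        B = stack.values_at(background_xy[:, 0], background_xy[:, 1], variables)
        model = fit_maxent(P, B, reg_multiplier=reg_multiplier,
                           names=variables, **fit_kwargs)
    return variables, model


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvFold:
    model: MaxentModel
    train_presence_xy: np.ndarray
    test_presence_xy: np.ndarray
    background_xy: np.ndarray


def cross_validate(
    presence_xy: np.ndarray,
    stack: CovariateStack,
    k: int = 10,
    seed: int = 0,
    n_background: int = 10000,
    region: Raster | KdePolygon | None = None,
    variables: Sequence[str] | None = None,
    reg_multiplier: float = 1.0,
    **fit_kwargs,
) -> list[CvFold]:
    """Seeded random k-fold partition of presences, one model per fold.

    Each fold's background sample is retained on the fold for evaluation
    reuse (AUC/TSS use the same background points as training).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    presence_xy = np.asarray(presence_xy, dtype=float)
    if presence_xy.shape[0] < k:
        raise ValueError("fewer presences than folds")
    variables = list(variables) if variables is not None else stack.names
    rng = np.random.default_rng(seed)
    order = rng.permutation(presence_xy.shape[0])
    fold_ids = np.arange(presence_xy.shape[0]) % k
    assignment = np.empty(presence_xy.shape[0], dtype=int)
    assignment[order] = fold_ids
    if region is None:
        region = stack.grid.with_values(stack.valid_mask().astype(int))
    folds: list[CvFold] = []
    for i in range(k):
        train = presence_xy[assignment != i]
        test = presence_xy[assignment == i]
        bg_xy = sample_background(region, n=n_background,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        P = stack.values_at(train[:, 0], train[:, 1], variables)
        B = stack.values_at(bg_xy[:, 0], bg_xy[:, 1], variables)
        model = fit_maxent(P, B, reg_multiplier=reg_multiplier,
                           names=variables, **fit_kwargs)
        folds.append(CvFold(model=model, train_presence_xy=train,
                            test_presence_xy=test, background_xy=bg_xy))
    return folds
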