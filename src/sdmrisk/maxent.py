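"""Maximum-entropy presence-background model.

The model is the Gibbs density q_λ(x) ∝ exp(λ·f(x)) over a background sample
of landscape cells, fitted by maximizing the L1-penalized presence
log-likelihood

    (1/m) Σ_i λ·f(x_i) − log Z_λ − Σ_j β_j |λ_j|,

the standard convex-dual formulation of maximum-entropy density estimation:
the L1 penalty is equivalent to relaxing the moment-matching constraints by
±β_j. Feature classes are the field's usual basis expansion — linear (L),
quadratic (Q), pairwise product (P), step/threshold (T) and hinge (H)
transforms of the covariates — and the per-feature penalty is

    β_j = rm · c(class_j, m) · s_j / √m,

where m is the presence count, s_j the presence-sample standard deviation of
feature j, rm the user-facing regularization multiplier, and c a per-class
schedule (see ``class_beta_scale``). Fitted densities are reported on the
logistic output scale, suitability in [0, 1], via the training-entropy
transform s = e^H·raw / (1 + e^H·raw).

Projection to new climates supports three extrapolation policies: ``none``
(evaluate features as-is), ``clamp`` (truncate each covariate to its training
range first) and ``fade`` (clamp, then additionally damp the output where the
clamped and unclamped linear predictors disagree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grids import ClimateGrid, GridStack

__all__ = [
    "FeatureConfig", "FeatureSet", "MaxentModel", "SuitabilityGrid",
    "build_features", "fit_maxent", "predict", "predict_scores",
    "variable_importance", "jackknife", "response_curve", "training_gain",
]

VALID_CLASSES = set("LQPTH")


class FitError(RuntimeError):
    """The penalized-likelihood optimization failed."""


@dataclass(frozen=True)
class FeatureConfig:
    """Feature classes and regularization for one candidate model."""

    classes: str = "LQPH"
    rm: float = 1.0
    n_hinge_knots: int = 20
    n_threshold_knots: int = 20

    def __post_init__(self) -> None:
        cls = set(self.classes.upper())
        if not cls or not cls <= VALID_CLASSES:
            raise ValueError(f"classes must be a non-empty subset of LQPTH, got {self.classes!r}")
        if not self.rm > 0:
            raise ValueError(f"rm must be > 0, got {self.rm}")

    @property
    def class_set(self) -> frozenset:
        return frozenset(self.classes.upper())

    @property
    def label(self) -> str:
        return "".join(c for c in "LQPTH" if c in self.class_set)


def class_beta_scale(cls: str, m: int) -> float:
    """Per-class penalty constant c(class, m), interpolated on presence count.

    L/Q: 1.0 at m<=10 down to 0.05 at m>=100; T: 2.0 down to 1.0 on the same
    range; P: 0.2 and H: 0.5, constant. These mirror the defaults of the
    original reference software and are configurable at the fit call.
    """
    t = float(np.clip((m - 10) / 90.0, 0.0, 1.0))
    if cls in ("L", "Q"):
        return 1.0 + t * (0.05 - 1.0)
    if cls == "P":
        return 0.2
    if cls == "T":
        return 2.0 + t * (1.0 - 2.0)
    if cls == "H":
        return 0.5
    raise ValueError(f"unknown feature class {cls!r}")


@dataclass(frozen=True)
class FeatureDef:
    kind: str                    # linear, quadratic, product, threshold, hinge_fwd, hinge_rev
    vars: tuple[str, ...]
    knot: float | None = None

    @property
    def cls(self) -> str:
        return {"linear": "L", "quadratic": "Q", "product": "P",
                "threshold": "T", "hinge_fwd": "H", "hinge_rev": "H"}[self.kind]

    def describe(self) -> str:
        v = "*".join(self.vars)
        return f"{self.kind}({v})" if self.knot is None else f"{self.kind}({v}@{self.knot:.6g})"


class FeatureSet:
    """Feature definitions plus the training bounds needed to re-evaluate them.

    Features are affinely rescaled to [0, 1] using their training min/max, so
    the penalty is scale-free and the fitted suitability surface is invariant
    to affine rescaling of any covariate.
    """

    def __init__(self, defs: list[FeatureDef], var_bounds: dict[str, tuple[float, float]],
                 fmin: np.ndarray, fmax: np.ndarray):
        self.defs = defs
        self.var_bounds = var_bounds
        self.fmin = np.asarray(fmin, dtype=float)
        self.fmax = np.asarray(fmax, dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.defs)

    @property
    def var_names(self) -> list[str]:
        return list(self.var_bounds)

    @property
    def classes(self) -> list[str]:
        return [d.cls for d in self.defs]

    def vars_of(self, j: int) -> tuple[str, ...]:
        return self.defs[j].vars

    def _z(self, name: str, values: dict[str, np.ndarray]) -> np.ndarray:
        # min-max normalized covariate; makes L/Q/P invariant to positive
        # affine rescaling of the raw variable
        lo, hi = self.var_bounds[name]
        span = hi - lo if hi > lo else 1.0
        return (values[name] - lo) / span

    def _raw_column(self, d: FeatureDef, values: dict[str, np.ndarray]) -> np.ndarray:
        z = self._z(d.vars[0], values)
        if d.kind == "linear":
            return z
        if d.kind == "quadratic":
            return z ** 2
        if d.kind == "product":
            return z * self._z(d.vars[1], values)
        x = values[d.vars[0]]
        lo, hi = self.var_bounds[d.vars[0]]
        if d.kind == "threshold":
            return (x > d.knot).astype(float)
        if d.kind == "hinge_fwd":
            denom = hi - d.knot
            return np.maximum(0.0, x - d.knot) / denom
        if d.kind == "hinge_rev":
            denom = d.knot - lo
            return np.maximum(0.0, d.knot - x) / denom
        raise ValueError(d.kind)

    def evaluate(self, values: dict[str, np.ndarray], clamp: bool = False) -> np.ndarray:
        """Feature matrix (n, k) for per-variable covariate vectors.

        With ``clamp=True`` each covariate is truncated to its training range
        before any feature is computed.
        """
        vals = {}
        for name in self.var_bounds:
            if name not in values:
                raise ValueError(f"missing variable {name!r}")
            x = np.asarray(values[name], dtype=float)
            if clamp:
                lo, hi = self.var_bounds[name]
                x = np.clip(x, lo, hi)
            vals[name] = x
        cols = [self._raw_column(d, vals) for d in self.defs]
        X = np.column_stack(cols) if cols else np.empty((len(next(iter(vals.values()))), 0))
        span = np.where(self.fmax > self.fmin, self.fmax - self.fmin, 1.0)
        return (X - self.fmin) / span

    def clamp_counts(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """Per-row count of covariates outside their training range."""
        n = len(np.asarray(values[next(iter(self.var_bounds))]))
        out = np.zeros(n, dtype=int)
        for name, (lo, hi) in self.var_bounds.items():
            x = np.asarray(values[name], dtype=float)
            out += ((x < lo) | (x > hi)).astype(int)
        return out


def build_features(values: dict[str, np.ndarray], config: FeatureConfig,
                   ) -> tuple[np.ndarray, FeatureSet]:
    """Expand covariate vectors into the configured feature basis.

    ``values`` maps variable name to its vector over the *training* rows
    (presences followed by background, or any pooled training sample); the
    recorded bounds come from these rows. Returns the scaled training matrix
    and the reusable :class:`FeatureSet`.
    """
    if not values:
        raise ValueError("at least one variable required")
    names = list(values)
    arrays = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    for k, v in arrays.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"variable {k!r} has non-finite values")
    var_bounds = {k: (float(v.min()), float(v.max())) for k, v in arrays.items()}
    cls = config.class_set
    defs: list[FeatureDef] = []
    for name in names:
        lo, hi = var_bounds[name]
        constant = not hi > lo
        if "L" in cls:
            defs.append(FeatureDef("linear", (name,)))
        if "Q" in cls:
            defs.append(FeatureDef("quadratic", (name,)))
        if ("T" in cls or "H" in cls) and constant:
            warnings.warn(f"variable {name!r} is constant; threshold/hinge features dropped")
            continue
        if "T" in cls:
            for knot in np.linspace(lo, hi, config.n_threshold_knots + 2)[1:-1]:
                defs.append(FeatureDef("threshold", (name,), float(knot)))
        if "H" in cls:
            for knot in np.linspace(lo, hi, config.n_hinge_knots + 2)[1:-1]:
                defs.append(FeatureDef("hinge_fwd", (name,), float(knot)))
                defs.append(FeatureDef("hinge_rev", (name,), float(knot)))
    if "P" in cls:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                defs.append(FeatureDef("product", (names[i], names[j])))
    # raw bounds per feature for [0,1] scaling
    probe = FeatureSet(defs, var_bounds, np.zeros(len(defs)), np.ones(len(defs)))
    raw = np.column_stack([probe._raw_column(d, arrays) for d in defs]) \
        if defs else np.empty((len(arrays[names[0]]), 0))
    fmin = raw.min(axis=0) if defs else np.zeros(0)
    fmax = raw.max(axis=0) if defs else np.zeros(0)
    keep = fmax > fmin
    if defs and not keep.all():
        dropped = [defs[i].describe() for i in np.where(~keep)[0]]
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}")
        defs = [d for d, k in zip(defs, keep) if k]
        raw, fmin, fmax = raw[:, keep], fmin[keep], fmax[keep]
    fs = FeatureSet(defs, var_bounds, fmin, fmax)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    X = (raw - fmin) / span
    return X, fs


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model and everything needed to project it."""

    feature_set: FeatureSet
    lambdas: np.ndarray
    betas: np.ndarray
    rm: float
    log_z: float                 # log partition over the training background
    entropy: float               # H of the fitted raw distribution
    presence_means: dict[str, float]
    n_presence: int
    n_background: int
    transform: str = "logistic"
    objective_path: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def var_names(self) -> list[str]:
        return self.feature_set.var_names

    def linear_predictor(self, values: dict[str, np.ndarray], clamp: bool = False) -> np.ndarray:
        X = self.feature_set.evaluate(values, clamp=clamp)
        return X @ self.lambdas

    def raw(self, values: dict[str, np.ndarray], clamp: bool = False) -> np.ndarray:
        return np.exp(self.linear_predictor(values, clamp=clamp) - self.log_z)

    def output(self, values: dict[str, np.ndarray], clamp: bool = False) -> np.ndarray:
        r = self.raw(values, clamp=clamp)
        if self.transform == "raw":
            return r
        eh = np.exp(self.entropy)
        if self.transform == "logistic":
            return eh * r / (1.0 + eh * r)
        if self.transform == "cloglog":
            return 1.0 - np.exp(-eh * r)
        raise ValueError(f"unknown transform {self.transform!r}")

    def to_lambdas_text(self) -> str:
        """Plain-text serialization: header then one feature per line."""
        lines = [
            f"transform {self.transform}",
            f"rm {self.rm!r}",
            f"log_z {self.log_z!r}",
            f"entropy {self.entropy!r}",
            f"n_presence {self.n_presence}",
            f"n_background {self.n_background}",
        ]
        for name, (lo, hi) in self.feature_set.var_bounds.items():
            lines.append(f"varbound {name} {lo!r} {hi!r} {self.presence_means[name]!r}")
        for d, lam, beta, lo, hi in zip(self.feature_set.defs, self.lambdas, self.betas,
                                        self.feature_set.fmin, self.feature_set.fmax):
            knot = "-" if d.knot is None else repr(float(d.knot))
            lines.append(f"feature {d.kind} {','.join(d.vars)} {knot} "
                         f"{float(lam)!r} {float(beta)!r} {float(lo)!r} {float(hi)!r}")
        return "\n".join(lines) + "\n"


def _penalties(X_pres: np.ndarray, classes: list[str], rm: float) -> np.ndarray:
    m = X_pres.shape[0]
    s = X_pres.std(axis=0, ddof=1) if m > 1 else np.zeros(X_pres.shape[1])
    s = np.maximum(s, 1e-3)  # constant-on-presence features still get a penalty
    c = np.array([class_beta_scale(cl, m) for cl in classes])
    return rm * c * s / np.sqrt(m)


def fit_maxent(X_pres: np.ndarray, X_bg: np.ndarray, feature_set: FeatureSet,
               config: FeatureConfig, seed: int = 0, *,
               transform: str = "logistic", gtol: float = 1e-8,
               max_iter: int = 2000, betas: np.ndarray | None = None) -> MaxentModel:
    """Fit λ by bound-constrained quasi-Newton on the split L1 objective.

    λ is written as a − b with a, b ≥ 0, which turns the non-smooth penalized
    likelihood into a smooth bound-constrained problem solved by L-BFGS-B.
    Deterministic given the inputs (the seed is recorded for provenance only).
    """
    X_pres = np.asarray(X_pres, dtype=float)
    X_bg = np.asarray(X_bg, dtype=float)
    if X_pres.shape[0] < 2 or X_bg.shape[0] < 2:
        raise FitError("need at least 2 presence and 2 background rows")
    if X_pres.shape[1] != X_bg.shape[1] or X_pres.shape[1] != feature_set.n_features:
        raise FitError("feature matrices do not match the feature set")
    k = feature_set.n_features
    if betas is None:
        betas = _penalties(X_pres, feature_set.classes, config.rm)
    betas = np.asarray(betas, dtype=float)
    fbar = X_pres.mean(axis=0)
    n_bg = X_bg.shape[0]

    def objective(z: np.ndarray):
        a, b = z[:k], z[k:]
        lam = a - b
        eta_bg = X_bg @ lam
        lz = logsumexp(eta_bg)
        val = -(fbar @ lam) + lz + betas @ (a + b)
        if not np.isfinite(val):
            raise FitError("non-finite objective encountered")
        w = np.exp(eta_bg - lz)
        ef = X_bg.T @ w
        grad_lam = -fbar + ef
        return val, np.concatenate([grad_lam + betas, -grad_lam + betas])

    path: list[float] = []
    res = minimize(
        objective, np.zeros(2 * k), jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        callback=lambda z: path.append(objective(z)[0]),
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 0.0},
    )
    lam = res.x[:k] - res.x[k:]
    lam[np.abs(lam) < 1e-10] = 0.0
    # judge convergence by the KKT conditions of the unsplit L1 problem, not
    # by the optimizer's status code (a failed final line search at the
    # optimum is harmless)
    eta_chk = X_bg @ lam
    w_chk = np.exp(eta_chk - logsumexp(eta_chk))
    g = fbar - X_bg.T @ w_chk  # gradient of the unpenalized objective
    viol = np.where(lam > 0, np.abs(g - betas),
                    np.where(lam < 0, np.abs(g + betas),
                             np.maximum(np.abs(g) - betas, 0.0)))
    if not res.success and viol.max() > 1e-3:
        raise FitError(
            f"optimization failed: {res.message} (KKT violation {viol.max():.2e})")
    if viol.max() > 1e-3:
        warnings.warn(
            f"fit stopped with KKT violation {viol.max():.2e}; result may be loose")
    eta_bg = X_bg @ lam
    log_z = float(logsumexp(eta_bg))
    p = np.exp(eta_bg - log_z)
    entropy = float(-(p * np.log(np.maximum(p, 1e-300))).sum())
    return MaxentModel(
        feature_set=feature_set, lambdas=lam, betas=betas, rm=config.rm,
        log_z=log_z, entropy=entropy, presence_means={}, n_presence=X_pres.shape[0],
        n_background=n_bg, transform=transform,
        objective_path=-np.asarray(path),  # stored as the maximized objective
    )


def fit_from_values(values_pres: dict[str, np.ndarray], values_bg: dict[str, np.ndarray],
                    config: FeatureConfig, seed: int = 0, *,
                    add_samples_to_background: bool = True, **kw) -> MaxentModel:
    """Convenience wrapper: build features on pooled rows, then fit.

    Training bounds come from the pooled presence+background sample. By
    default the presence rows are added to the background for the partition
    function (the standard presence-background convention): it keeps the
    presence feature mean inside the convex hull of the background features,
    which makes the penalized objective bounded for any penalty.
    """
    names = list(values_bg)
    m = len(np.asarray(values_pres[names[0]]))
    pooled = {n: np.concatenate([np.asarray(values_pres[n], dtype=float),
                                 np.asarray(values_bg[n], dtype=float)]) for n in names}
    X_all, fs = build_features(pooled, config)
    X_bg = X_all if add_samples_to_background else X_all[m:]
    model = fit_maxent(X_all[:m], X_bg, fs, config, seed=seed, **kw)
    model.presence_means = {n: float(np.mean(values_pres[n])) for n in names}
    return model


@dataclass
class SuitabilityGrid:
    """A suitability map in [0, 1] with its transform and clamp diagnostics."""

    grid: ClimateGrid
    transform: str
    clamp_mode: str
    clamp_counts: np.ndarray  # per-cell count of covariates outside training range

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask


def predict(model: MaxentModel, stack: GridStack, clamp: str = "fade") -> SuitabilityGrid:
    """Project a fitted model over a grid stack.

    ``clamp``: ``none`` evaluates features at the projected covariates as-is;
    ``clamp`` truncates covariates to the training range first; ``fade``
    additionally subtracts the clamped/unclamped linear-predictor discrepancy
    (rescaled into [0, 1] over the projection) from the output, floored at 0.
    Cells inside the training envelope are identical under all modes.
    """
    if clamp not in ("none", "clamp", "fade"):
        raise ValueError(f"unknown clamp mode {clamp!r}")
    missing = [v for v in model.var_names if v not in stack.layers]
    if missing:
        raise ValueError(f"stack lacks model variables: {missing}")
    template = stack.template
    keep = ~stack.mask
    values = {v: stack[v].values[keep] for v in model.var_names}
    out = np.zeros(template.shape)
    counts = np.zeros(template.shape, dtype=int)
    counts[keep] = model.feature_set.clamp_counts(values)
    if clamp == "none":
        suit = model.output(values, clamp=False)
    else:
        suit = model.output(values, clamp=True)
        if clamp == "fade":
            gap = np.abs(model.linear_predictor(values, clamp=False)
                         - model.linear_predictor(values, clamp=True))
            top = gap.max()
            if top > 0:
                suit = np.maximum(0.0, suit - gap / top)
    out[keep] = suit
    grid = template.with_values(out, name="suitability", units="index")
    return SuitabilityGrid(grid=grid, transform=model.transform,
                           clamp_mode=clamp, clamp_counts=counts)


def predict_scores(model: MaxentModel, values: dict[str, np.ndarray],
                   clamp: str = "clamp") -> np.ndarray:
    """Suitability scores at arbitrary covariate rows (no fade term)."""
    return model.output(values, clamp=(clamp != "none"))


# ---------------------------------------------------------------------------
# gain, importance, jackknife, response curves


def training_gain(model: MaxentModel, values_pres: dict[str, np.ndarray]) -> float:
    """Unpenalized training gain over the uniform background model.

    gain = (1/m) Σ λ·f(x_i) − log Z + log n_background; zero when λ = 0.
    """
    eta = model.linear_predictor(values_pres, clamp=False)
    return float(eta.mean() - model.log_z + np.log(model.n_background))


def _train_auc(model: MaxentModel, values_pres, values_bg) -> float:
    from .evaluation import auc
    return auc(model.linear_predictor(values_pres, clamp=True),
               model.linear_predictor(values_bg, clamp=True))


def variable_importance(model: MaxentModel, values_pres: dict[str, np.ndarray],
                        values_bg: dict[str, np.ndarray], seed: int = 0,
                        k_permutations: int = 5) -> dict[str, dict[str, float]]:
    """Percent contribution and permutation importance per variable.

    Percent contribution re-traces the fit with cyclic proximal coordinate
    ascent from λ = 0 and credits each objective increase to the variable(s)
    whose feature moved (product features split evenly); credits are
    normalized to sum to 100. It is path-dependent by construction, which is
    why the path-free permutation importance — the drop in training AUC when
    one variable's values are permuted jointly across presences and
    background, averaged over seeded permutations — is reported alongside.
    """
    names = model.var_names
    contrib = _contribution_by_coordinate_path(model, values_pres, values_bg)
    rng = np.random.default_rng(seed)
    base = _train_auc(model, values_pres, values_bg)
    m = len(np.asarray(values_pres[names[0]]))
    drops = {}
    for name in names:
        pooled = np.concatenate([np.asarray(values_pres[name], dtype=float),
                                 np.asarray(values_bg[name], dtype=float)])
        acc = 0.0
        for _ in range(k_permutations):
            perm = rng.permutation(pooled)
            vp = dict(values_pres); vb = dict(values_bg)
            vp[name], vb[name] = perm[:m], perm[m:]
            acc += base - _train_auc(model, vp, vb)
        drops[name] = max(acc / k_permutations, 0.0)
    total = sum(drops.values())
    out = {}
    for name in names:
        out[name] = {
            "percent_contribution": contrib.get(name, 0.0),
            "permutation_importance": 100.0 * drops[name] / total if total > 0
            else 100.0 / len(names),
        }
    return out


def _contribution_by_coordinate_path(model: MaxentModel, values_pres, values_bg,
                                     max_passes: int = 100, tol: float = 1e-8,
                                     ) -> dict[str, float]:
    fs = model.feature_set
    Xp = fs.evaluate(values_pres, clamp=False)
    Xb = fs.evaluate(values_bg, clamp=False)
    betas = model.betas
    fbar = Xp.mean(axis=0)
    k = fs.n_features
    lam = np.zeros(k)
    eta = np.zeros(Xb.shape[0])
    credit: dict[str, float] = {v: 0.0 for v in fs.var_names}

    def gain(lam_, eta_):
        return fbar @ lam_ - logsumexp(eta_) - betas @ np.abs(lam_)

    g_cur = gain(lam, eta)
    for _ in range(max_passes):
        g_start = g_cur
        for j in range(k):
            lz = logsumexp(eta)
            w = np.exp(eta - lz)
            ef = w @ Xb[:, j]
            grad = fbar[j] - ef
            hess = max(w @ (Xb[:, j] - ef) ** 2, 1e-12)
            target = lam[j] + grad / hess
            prop = np.sign(target) * max(abs(target) - betas[j] / hess, 0.0)
            step = prop - lam[j]
            if step == 0.0:
                continue
            for _ in range(30):  # backtrack if the quadratic model overshoots
                new_lam_j = lam[j] + step
                new_eta = eta + step * Xb[:, j]
                new_lam = lam.copy(); new_lam[j] = new_lam_j
                g_new = gain(new_lam, new_eta)
                if g_new >= g_cur - 1e-12:
                    break
                step /= 2.0
            else:
                continue
            delta = g_new - g_cur
            if delta > 0:
                for v in fs.vars_of(j):
                    credit[v] += delta / len(fs.vars_of(j))
            lam, eta, g_cur = new_lam, new_eta, g_new
        if g_cur - g_start < tol:
            break
    total = sum(credit.values())
    if total <= 0:
        return {v: 100.0 / len(credit) for v in credit}
    return {v: 100.0 * c / total for v, c in credit.items()}


def jackknife(values_pres: dict[str, np.ndarray], values_bg: dict[str, np.ndarray],
              config: FeatureConfig, seed: int = 0,
              variables: list[str] | None = None) -> dict:
    """Leave-one-in / leave-one-out training gains, 2k+1 fits for k variables.

    Returns ``{"full_gain": g, "full_auc": a, "per_variable": {name:
    {gain_with_only, gain_without, auc_with_only}}}``.
    """
    variables = variables or list(values_bg)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")

    def fit_on(subset: list[str]):
        vp = {v: values_pres[v] for v in subset}
        vb = {v: values_bg[v] for v in subset}
        model = fit_from_values(vp, vb, config, seed=seed)
        return (training_gain(model, vp), _train_auc(model, vp, vb))

    full_gain, full_auc = fit_on(variables)
    per: dict[str, dict[str, float]] = {}
    for v in variables:
        only_gain, only_auc = fit_on([v])
        rest = [w for w in variables if w != v]
        without_gain, _ = fit_on(rest)
        per[v] = {"gain_with_only": only_gain, "gain_without": without_gain,
                  "auc_with_only": only_auc}
    return {"full_gain": full_gain, "full_auc": full_auc, "per_variable": per}


def response_curve(model: MaxentModel, variable: str, n_points: int = 100,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: sweep one variable, others held at presence means."""
    if variable not in model.var_names:
        raise ValueError(f"model does not use variable {variable!r}")
    if not model.presence_means:
        raise ValueError("model lacks presence means; fit via fit_from_values")
    lo, hi = model.feature_set.var_bounds[variable]
    xs = np.linspace(lo, hi, n_points)
    values = {v: np.full(n_points, model.presence_means[v]) for v in model.var_names}
    values[variable] = xs
    return xs, model.output(values, clamp=False)
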