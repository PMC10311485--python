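"""Full-information maximum likelihood for twin-spouse family tables.

Each family contributes the log-density of the multivariate normal over
whichever quartet roles it has observed (FIML over missing-data patterns);
families are independent and enter the likelihood exactly once.  Estimation
maximizes the likelihood over the raw-scale paths and copaths with multiple
jittered starts; inference uses likelihood-ratio tests against nested
submodels (plain chi-square reference, alpha = 0.05 by convention), Wald
standard errors from the numeric Hessian as diagnostics, and
profile-likelihood confidence intervals.

Numeric derivatives are central differences computed in-house
(:func:`_numdiff_jacobian`, :func:`_numdiff_hessian`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    ROLES,
    FamilyConfiguration,
    ParameterSet,
    Zygosity,
    implied_observed_moments,
)

__all__ = [
    "PARAM_NAMES",
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "ProfileInterval",
    "IdentifiabilityReport",
    "FitError",
    "fiml_loglik",
    "fit_model",
    "lrt",
    "profile_ci",
    "identifiability_check",
    "power_by_simulation",
]

#: Canonical parameter order used throughout the optimizer.
PARAM_NAMES: tuple[str, ...] = ("a", "s", "e", "delta_p", "delta_y", "beta_sex", "mu")

_BOUNDS: Mapping[str, tuple[float, float]] = {
    "a": (0.0, 50.0),
    "s": (0.0, 50.0),
    "e": (1e-6, 50.0),  # a sliver of unique environment keeps V > 0
    "delta_p": (-1.5, 1.5),
    "delta_y": (-5.0, 5.0),
    "beta_sex": (-20.0, 20.0),
    "mu": (-100.0, 100.0),
}

_PENALTY = -1e12


class FitError(RuntimeError):
    """Raised when no optimizer start converges or the data are degenerate."""


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free; the rest are fixed at given values.

    Submodels are nested in the full model by fixing ``delta_p`` and/or
    ``delta_y`` to zero.
    """

    free: tuple[str, ...] = PARAM_NAMES
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        free = tuple(self.free)
        unknown = (set(free) | set(self.fixed)) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        overlap = set(free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        missing = set(PARAM_NAMES) - set(free) - set(self.fixed)
        if missing:
            raise ValueError(f"parameters neither free nor fixed: {sorted(missing)}")
        object.__setattr__(
            self, "free", tuple(p for p in PARAM_NAMES if p in free)
        )
        object.__setattr__(self, "fixed", dict(self.fixed))

    @classmethod
    def full(cls) -> "ModelSpec":
        """All seven parameters free."""
        return cls()

    def drop(self, *names: str) -> "ModelSpec":
        """Nested submodel with the named copaths (or other parameters)
        fixed at zero."""
        free = tuple(p for p in self.free if p not in names)
        fixed = dict(self.fixed)
        for n in names:
            if n not in self.free:
                raise ValueError(f"{n} is not free in this spec")
            fixed[n] = 0.0
        return ModelSpec(free=free, fixed=fixed)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.free) < set(other.free)

    def to_params(self, theta: Sequence[float]) -> ParameterSet:
        values = dict(self.fixed)
        for name, v in zip(self.free, theta, strict=True):
            values[name] = float(v)
        return ParameterSet(**values)

    def from_params(self, params: ParameterSet) -> np.ndarray:
        d = params.as_dict()
        return np.array([d[p] for p in self.free])


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    spec: ModelSpec
    estimates: ParameterSet
    loglik: float
    n_params: int
    converged: bool
    n_families: int
    se: Mapping[str, float]
    ci: Mapping[str, tuple[float, float]]  # Wald 95% intervals (diagnostic)
    vcov: np.ndarray | None = None  # asymptotic covariance of the free params

    def se_of(self, func: Callable[[ParameterSet], float], rel_step: float = 1e-6) -> float:
        """Delta-method standard error of a scalar function of the estimates
        (e.g. a standardized variance proportion)."""
        if self.vcov is None:
            return math.nan
        x0 = self.spec.from_params(self.estimates)
        grad = np.zeros(len(x0))
        for i in range(len(x0)):
            h = rel_step * (1.0 + abs(x0[i]))
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (
                func(self.spec.to_params(xp)) - func(self.spec.to_params(xm))
            ) / (2.0 * h)
        var = float(grad @ self.vcov @ grad)
        return math.sqrt(var) if var > 0 else math.nan

    def summary(self) -> pd.DataFrame:
        rows = []
        d = self.estimates.as_dict()
        for p in PARAM_NAMES:
            lo, hi = self.ci.get(p, (math.nan, math.nan))
            rows.append(
                {
                    "parameter": p,
                    "estimate": d[p],
                    "free": p in self.spec.free,
                    "se": self.se.get(p, math.nan),
                    "ci95_low": lo,
                    "ci95_high": hi,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of two nested fits."""

    statistic: float
    df: int
    p_value: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


@dataclass(frozen=True)
class ProfileInterval:
    """Profile-likelihood confidence interval; a bound is NaN and flagged
    one-sided when the profile never crosses the threshold inside the
    parameter's domain or search range."""

    parameter: str
    level: float
    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Numeric rank analysis of the moment map at a point."""

    parameters: tuple[str, ...]
    singular_values: np.ndarray
    rank: int
    tol: float
    null_directions: np.ndarray  # rows: near-null parameter directions

    @property
    def full_rank(self) -> bool:
        return self.rank == len(self.parameters)


# ---------------------------------------------------------------------------
# data preparation

class GroupedFamilies:
    """Family table grouped by (zygosity, missingness pattern).

    Sexes only shift means, so families sharing a zygosity and an observed-role
    pattern share one implied covariance; their mean differences are captured
    by a per-row female indicator matrix.
    """

    def __init__(self, data: pd.DataFrame):
        if len(data) == 0:
            raise ValueError("empty family table")
        years = np.column_stack(
            [
                pd.to_numeric(
                    data.get(f"{r}_years", pd.Series(np.nan, index=data.index)),
                    errors="coerce",
                ).to_numpy(float)
                for r in ROLES
            ]
        )
        if not np.isfinite(years[:, 0]).all():
            bad = int((~np.isfinite(years[:, 0])).sum())
            raise ValueError(f"{bad} families are missing the twin1 phenotype")
        female = np.zeros_like(years)
        for j, r in enumerate(ROLES):
            col = data.get(f"{r}_sex")
            if col is not None:
                female[:, j] = (
                    col.astype("string").str.upper().isin(["F", "FEMALE", "1", "W"])
                ).to_numpy(float)
        zyg = data["zygosity"].astype(str).to_numpy()
        bad_z = set(np.unique(zyg)) - {z.value for z in Zygosity}
        if bad_z:
            raise ValueError(f"unknown zygosity codes {sorted(bad_z)}")

        obs = np.isfinite(years)
        self.groups: list[dict] = []
        self.n_families = len(data)
        self.n_observations = int(obs.sum())
        for z in sorted({z.value for z in Zygosity} & set(zyg)):
            zsel = zyg == z
            patterns = {tuple(row) for row in obs[zsel]}
            for pat in sorted(patterns):
                mask = np.array(pat, bool)
                sel = zsel & (obs == mask).all(axis=1)
                y = years[np.ix_(sel, mask)]
                f = female[np.ix_(sel, mask)]
                # sufficient statistics: the Gaussian log-likelihood of a
                # pattern group depends on the rows only through these
                # cross-products, making each evaluation O(1) in n
                self.groups.append(
                    {
                        "zygosity": z,
                        "mask": mask,
                        "n": y.shape[0],
                        "k": y.shape[1],
                        "syy": y.T @ y,
                        "syf": y.T @ f,
                        "sff": f.T @ f,
                        "sy": y.sum(axis=0),
                        "sf": f.sum(axis=0),
                    }
                )

        all_years = years[obs]
        self.constant_phenotype = bool(np.ptp(all_years) == 0) and len(all_years) > 1
        self.grand_mean = float(all_years.mean())
        self.grand_var = float(all_years.var())
        fem_obs = female[obs] > 0.5
        self.mean_female = float(all_years[fem_obs].mean()) if fem_obs.any() else self.grand_mean
        self.mean_male = float(all_years[~fem_obs].mean()) if (~fem_obs).any() else self.grand_mean


_LOG2PI = math.log(2.0 * math.pi)


def _grouped_loglik(params: ParameterSet, grouped: GroupedFamilies) -> float:
    """FIML log-likelihood; finite penalty on non-PSD implied covariances so
    optimizers can recover."""
    v = params.variance
    if v <= 0:
        return _PENALTY
    total = 0.0
    mu, beta = params.mu, params.beta_sex
    for g in grouped.groups:
        mask = g["mask"]
        roles = tuple(r for r, m in zip(ROLES, mask) if m)
        config = FamilyConfiguration(roles)
        mom = implied_observed_moments(params, g["zygosity"], config, check=False)
        cov = mom.cov
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            eigmin = float(np.linalg.eigvalsh(cov)[0])
            return _PENALTY * (1.0 + abs(eigmin))
        n, k = g["n"], g["k"]
        sy, sf = g["sy"], g["sf"]
        # scatter of residuals y - mu - beta*f from the cross-products
        ones = np.ones(k)
        m = (
            g["syy"]
            - mu * (np.outer(sy, ones) + np.outer(ones, sy))
            - beta * (g["syf"] + g["syf"].T)
            + mu * mu * n * np.ones((k, k))
            + mu * beta * (np.outer(ones, sf) + np.outer(sf, ones))
            + beta * beta * g["sff"]
        )
        sol = np.linalg.solve(chol, m)
        quad = float(np.trace(np.linalg.solve(chol, sol.T)))
        logdet = 2.0 * float(np.log(np.diag(chol)).sum())
        total += -0.5 * (n * k * _LOG2PI + n * logdet + quad)
    return total


def fiml_loglik(params: ParameterSet, data: pd.DataFrame | GroupedFamilies) -> float:
    """Sum over families of the MVN log-density of the observed roles.

    Families with missing roles contribute the corresponding marginal
    density.  Non-PSD implied covariances yield a large finite penalty
    rather than an exception, so profiling and optimization stay robust.
    """
    grouped = data if isinstance(data, GroupedFamilies) else GroupedFamilies(data)
    return _grouped_loglik(params, grouped)


# ---------------------------------------------------------------------------
# numeric derivatives (central differences)

def _numdiff_jacobian(
    f: Callable[[np.ndarray], np.ndarray], x: np.ndarray, rel_step: float = 1e-6
) -> np.ndarray:
    x = np.asarray(x, float)
    cols = []
    for i in range(len(x)):
        h = rel_step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        cols.append((f(xp) - f(xm)) / (2.0 * h))
    return np.column_stack(cols)


def _numdiff_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4
) -> np.ndarray:
    x = np.asarray(x, float)
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                hess[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                hess[i, j] = hess[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4.0 * h[i] * h[j])
    return hess


# ---------------------------------------------------------------------------
# estimation

def _default_start(spec: ModelSpec, grouped: GroupedFamilies) -> np.ndarray:
    v = max(grouped.grand_var, 1e-6)
    beta0 = grouped.mean_female - grouped.mean_male
    defaults = {
        "a": math.sqrt(0.4 * v),
        "s": math.sqrt(0.2 * v),
        "e": math.sqrt(0.4 * v),
        "delta_p": 0.2,
        "delta_y": 0.3,
        "beta_sex": beta0,
        "mu": grouped.mean_male,
    }
    return np.array([defaults[p] for p in spec.free])


def _jitter(x0: np.ndarray, spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    out = x0.copy()
    for i, name in enumerate(spec.free):
        lo, hi = _BOUNDS[name]
        if name in ("a", "s", "e"):
            out[i] = x0[i] * math.exp(rng.normal(0.0, 0.3))
        elif name in ("delta_p", "delta_y"):
            out[i] = x0[i] + rng.normal(0.0, 0.15)
        else:
            out[i] = x0[i] + rng.normal(0.0, 0.25 * (1.0 + abs(x0[i])))
        out[i] = min(max(out[i], lo), hi)
    return out


def fit_model(
    spec: ModelSpec,
    data: pd.DataFrame | GroupedFamilies,
    starts: int = 5,
    seed: int | None = 0,
    *,
    start_values: ParameterSet | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Maximize the FIML log-likelihood from multiple jittered starts.

    The first start is moment-based (or ``start_values`` if given); the rest
    are seeded jitters of it.  The best converged solution is returned.
    Deterministic given ``seed``.
    """
    grouped = data if isinstance(data, GroupedFamilies) else GroupedFamilies(data)
    if grouped.constant_phenotype:
        raise FitError("degenerate data: phenotype is constant")
    rng = np.random.default_rng(seed)
    x_base = (
        spec.from_params(start_values)
        if start_values is not None
        else _default_start(spec, grouped)
    )
    bounds = [_BOUNDS[p] for p in spec.free]
    x_base = np.clip(x_base, [b[0] for b in bounds], [b[1] for b in bounds])

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def negll(theta: np.ndarray) -> float:
        # clip rather than raise: derivative-free steps may probe just
        # outside the parameter domain
        return -_grouped_loglik(spec.to_params(np.clip(theta, lo, hi)), grouped)

    best: optimize.OptimizeResult | None = None
    any_success = False
    for k in range(max(1, starts)):
        x0 = x_base if k == 0 else _jitter(x_base, spec, rng)
        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    # quasi-Newton runs occasionally stall on a ridge; a derivative-free
    # polish from the best point is cheap and recovers those cases
    polish = optimize.minimize(
        negll,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-5, "maxiter": 1200, "maxfev": 1200},
    )
    if polish.fun < best.fun:
        polish.x = np.clip(polish.x, [b[0] for b in bounds], [b[1] for b in bounds])
        if negll(polish.x) <= best.fun:
            best = polish
            any_success = any_success or bool(polish.success)
    if not any_success and best.fun >= -_PENALTY / 2:
        raise FitError(
            f"no optimizer start converged (best status: {best.message!r})"
        )

    estimates = spec.to_params(best.x)
    loglik = -float(best.fun)
    se: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    vcov: np.ndarray | None = None
    if compute_se:
        try:
            hess = _numdiff_hessian(negll, best.x)
            cov = np.linalg.inv(hess)
            vcov = cov
            diag = np.diag(cov)
            zcrit = stats.norm.ppf(0.975)
            for i, name in enumerate(spec.free):
                if diag[i] > 0:
                    se[name] = math.sqrt(diag[i])
                    ci[name] = (
                        best.x[i] - zcrit * se[name],
                        best.x[i] + zcrit * se[name],
                    )
                else:
                    se[name] = math.nan
                    ci[name] = (math.nan, math.nan)
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        spec=spec,
        estimates=estimates,
        loglik=loglik,
        n_params=spec.n_free,
        converged=bool(any_success) and loglik > _PENALTY / 2,
        n_families=grouped.n_families,
        se=se,
        ci=ci,
        vcov=vcov,
    )


def lrt(full: FitResult, nested: FitResult) -> LRTResult:
    """Likelihood-ratio test: -2 * (loglik_nested - loglik_full) against the
    chi-square with df equal to the difference in free-parameter counts."""
    if not nested.spec.is_nested_in(full.spec):
        raise ValueError(
            "models are not nested: "
            f"{nested.spec.free} is not a strict subset of {full.spec.free}"
        )
    statistic = -2.0 * (nested.loglik - full.loglik)
    df = full.n_params - nested.n_params
    p = float(stats.chi2.sf(max(statistic, 0.0), df))
    return LRTResult(statistic=float(statistic), df=df, p_value=p)


def profile_ci(
    spec: ModelSpec,
    data: pd.DataFrame | GroupedFamilies,
    parameter: str,
    level: float = 0.95,
    *,
    fit: FitResult | None = None,
    seed: int | None = 0,
    max_expand: int = 8,
) -> ProfileInterval:
    """Profile-likelihood confidence interval for one free parameter.

    Each endpoint is where the profile log-likelihood has dropped by
    ``chi2_1(level)/2`` (1.9207 at 95%) from the maximum; the remaining
    parameters are re-optimized at every profiled value.  Domain bounds
    (e.g. non-negative paths) are respected: if the profile never crosses the
    threshold before the bound or search limit, that side is flagged open.
    """
    if parameter not in spec.free:
        raise ValueError(f"{parameter!r} is fixed in this spec; cannot profile")
    grouped = data if isinstance(data, GroupedFamilies) else GroupedFamilies(data)
    if fit is None:
        fit = fit_model(spec, grouped, seed=seed)
    drop = 0.5 * float(stats.chi2.ppf(level, 1))
    target = fit.loglik - drop
    mle = fit.estimates.as_dict()[parameter]
    reduced = ModelSpec(
        free=tuple(p for p in spec.free if p != parameter),
        fixed={**spec.fixed, parameter: mle},
    )

    warm = {"params": fit.estimates}

    def profile_ll(value: float) -> float:
        sub = ModelSpec(free=reduced.free, fixed={**spec.fixed, parameter: value})
        res = fit_model(
            sub, grouped, starts=1, seed=seed,
            start_values=warm["params"].replace(**{parameter: value}),
            compute_se=False,
        )
        warm["params"] = res.estimates
        return res.loglik

    lo_bound, hi_bound = _BOUNDS[parameter]
    scale = fit.se.get(parameter)
    if scale is None or not math.isfinite(scale) or scale <= 0:
        scale = 0.25 * (1.0 + abs(mle))

    def solve_side(direction: int) -> tuple[float, bool]:
        bound = hi_bound if direction > 0 else lo_bound
        step = scale
        prev_x, prev_g = mle, drop  # g = profile_ll - target, g(mle) = drop > 0
        for _ in range(max_expand):
            x = mle + direction * step
            if (direction > 0 and x >= bound) or (direction < 0 and x <= bound):
                x = bound
            g = profile_ll(x) - target
            if g < 0.0:
                root = optimize.brentq(
                    lambda v: profile_ll(v) - target, min(prev_x, x), max(prev_x, x),
                    xtol=1e-5 * (1.0 + abs(mle)),
                )
                return float(root), False
            prev_x, prev_g = x, g
            if x == bound:
                return float(bound), True  # profile stays above threshold: open side
            step *= 2.0
        return math.nan, True

    lower, lower_open = solve_side(-1)
    upper, upper_open = solve_side(+1)
    return ProfileInterval(
        parameter=parameter,
        level=level,
        lower=lower,
        upper=upper,
        lower_open=lower_open,
        upper_open=upper_open,
    )


# ---------------------------------------------------------------------------
# identifiability

def _moment_vector(values: Mapping[str, float], with_c: bool) -> np.ndarray:
    """Stacked unique implied moments over zygosities: means for both sexes
    and the five distinct covariance entries per zygosity group.

    The optional ``c`` parameter adds a classical shared-environment factor
    alongside the social background: twin-twin correlation 1 in both
    zygosities, no homogamy copath.
    """
    a, s, e = values["a"], values["s"], values["e"]
    dp, dy = values["delta_p"], values["delta_y"]
    b, mu = values["beta_sex"], values["mu"]
    c = values.get("c", 0.0) if with_c else 0.0
    v = a * a + c * c + s * s + e * e
    out = [mu, mu + b, v]
    for alpha in (1.0, 0.5 * (1.0 + dp)):
        c_tt = alpha * a * a + c * c + s * s
        c1 = v * dp + s * s * dy
        c2 = dp * c_tt + s * s * dy
        c3 = dp * dp * c_tt + 2.0 * dp * s * s * dy + s * s * dy
        out.extend([c_tt, c1, c2, c3])
    return np.array(out)


def identifiability_check(
    free: Sequence[str] | ModelSpec,
    point: Mapping[str, float] | ParameterSet,
    *,
    tol: float = 1e-6,
) -> IdentifiabilityReport:
    """Numeric rank of the moment-map Jacobian at a parameter point.

    ``free`` lists the parameters to differentiate with respect to; it may
    include ``"c"`` to extend the model with a separate classical
    shared-environment factor next to the social background.  Rank is the
    number of singular values above ``tol`` times the largest; directions
    belonging to smaller singular values are reported as (near-)null.

    The base A+S+E model with both copaths is full rank at generic points.
    Adding ``c`` makes the map structurally rank-deficient: ``c`` and ``s``
    then enter every moment only through ``c**2 + s**2`` and ``s**2 *
    delta_y``-type products, which is the empirical under-identification
    that motivates absorbing the shared environment into the social
    background factor.  Likewise, fixing ``s`` at zero leaves ``delta_y``
    with no pathway into the moments (a structural zero column).
    """
    if isinstance(free, ModelSpec):
        free = free.free
    if isinstance(point, ParameterSet):
        point = point.as_dict()
    free = tuple(free)
    valid = set(PARAM_NAMES) | {"c"}
    unknown = set(free) - valid
    if unknown:
        raise ValueError(f"unknown parameters {sorted(unknown)}")
    with_c = "c" in free or "c" in point
    base = dict(point)
    for p in PARAM_NAMES:
        base.setdefault(p, 0.0)

    x0 = np.array([base[p] for p in free], float)

    def f(x: np.ndarray) -> np.ndarray:
        vals = dict(base)
        for name, v in zip(free, x):
            vals[name] = float(v)
        return _moment_vector(vals, with_c)

    jac = _numdiff_jacobian(f, x0)
    u, sv, vt = np.linalg.svd(jac)
    rank = int((sv > tol * sv[0]).sum()) if sv.size and sv[0] > 0 else 0
    return IdentifiabilityReport(
        parameters=free,
        singular_values=sv,
        rank=rank,
        tol=tol,
        null_directions=vt[rank:],
    )


# ---------------------------------------------------------------------------
# Monte-Carlo power

def power_by_simulation(
    gen: ParameterSet,
    design_counts: Mapping[tuple[str, str], int],
    alpha: float = 0.05,
    reps: int = 200,
    seed: int = 0,
    tests: Sequence[str] = ("delta_p", "delta_y", "both"),
    starts: int = 1,
) -> pd.DataFrame:
    """Monte-Carlo power of the copath likelihood-ratio tests.

    Each replicate simulates a family table at the generating parameters and
    the given design, fits the full model and the requested nested models,
    and rejects when the LRT p-value is at or below ``alpha``.  Returns one
    row per test with the rejection rate and its binomial Monte-Carlo
    standard error.  Reproducible given ``seed``.
    """
    from .simulate import SimulationDesign, simulate_families

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    drops = {"delta_p": ("delta_p",), "delta_y": ("delta_y",), "both": ("delta_p", "delta_y")}
    for t in tests:
        if t not in drops:
            raise ValueError(f"unknown test {t!r}; valid: {sorted(drops)}")

    rng = np.random.default_rng(seed)
    full_spec = ModelSpec.full()
    rejections = {t: 0 for t in tests}
    for _ in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        table = simulate_families(SimulationDesign(dict(design_counts), gen, rep_seed))
        grouped = GroupedFamilies(table)
        full_fit = fit_model(full_spec, grouped, starts=starts, seed=rep_seed,
                             start_values=gen, compute_se=False)
        for t in tests:
            sub = full_spec.drop(*drops[t])
            sub_fit = fit_model(
                sub, grouped, starts=starts, seed=rep_seed,
                start_values=gen.replace(**{d: 0.0 for d in drops[t]}),
                compute_se=False,
            )
            if lrt(full_fit, sub_fit).p_value <= alpha:
                rejections[t] += 1
    rows = []
    for t in tests:
        p_hat = rejections[t] / reps
        rows.append(
            {
                "test": t,
                "power": p_hat,
                "mc_se": math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / reps),
                "reps": reps,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)
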