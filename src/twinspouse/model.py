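"""Structural model of twin-spouse resemblance under assortative mating.

The phenotype (years of education) of each member of a twin-spouse quartet
(twin1, spouse1, twin2, spouse2) is decomposed into three latent standardized
components:

* ``A`` -- additive genetic effects (path ``a``),
* ``S`` -- social background, which absorbs the classical twin shared
  environment C (path ``s``),
* ``E`` -- unique environment (path ``e``).

Twins reared together share their social background exactly (S correlation 1)
and their genetic factors at 1 (MZ) or ``alpha = 0.5*(1 + delta_p)`` (DZ; the
DZ genetic correlation is inflated above 0.5 by phenotypic assortment in
equilibrium).  Two copaths connect the twins' spouses to the family:

* ``delta_p`` -- phenotypic assortment: a direct copath between the
  phenotypes of each twin and their own spouse;
* ``delta_y`` -- social homogamy: the in-marrying spouses' social-background
  strata correlate ``delta_y`` with the twin family's stratum and with each
  other (exchangeable strata).  As a copath, ``delta_y`` is not bounded by 1
  at the observed level.

Sex enters the mean structure only (``mu`` plus ``beta_sex`` for women).

Two independent routes to the implied quartet covariance are provided:
closed-form entries (:func:`implied_observed_moments`) and an explicit 12x12
latent-component covariance propagated through the factor loadings
(:func:`implied_latent_covariance`).  They agree to machine precision on the
latent-admissible region; the closed forms remain valid wherever the observed
matrix is positive semi-definite, which includes social-homogamy copaths
slightly above 1 such as the estimates reported for Finland and the
Netherlands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ROLES",
    "Zygosity",
    "FamilyConfiguration",
    "ParameterSet",
    "ImpliedMoments",
    "DecompositionResult",
    "ModelError",
    "DegenerateModelError",
    "AdmissibilityError",
    "dz_alpha",
    "implied_correlations",
    "implied_latent_covariance",
    "implied_observed_moments",
    "decompose",
]

#: Canonical role order within a family quartet.
ROLES: tuple[str, ...] = ("twin1", "spouse1", "twin2", "spouse2")

_ROLE_INDEX = {r: i for i, r in enumerate(ROLES)}


class Zygosity(str, Enum):
    """Zygosity groups. OSDZ shares the SSDZ covariance structure; only the
    sex composition (and hence the mean vector) differs."""

    MZ = "MZ"
    SSDZ = "SSDZ"
    OSDZ = "OSDZ"

    @property
    def is_mz(self) -> bool:
        return self is Zygosity.MZ


class ModelError(ValueError):
    """Base class for structural-model errors."""


class DegenerateModelError(ModelError):
    """Raised when the total phenotypic variance is zero."""


class AdmissibilityError(ModelError):
    """Raised when a parameter set implies a non-PSD covariance matrix."""


@dataclass(frozen=True)
class FamilyConfiguration:
    """Which of the four quartet roles are observed in a family.

    ``twin1`` is always observed; roles are stored in canonical order.
    """

    roles_observed: tuple[str, ...]

    def __post_init__(self) -> None:
        roles = tuple(self.roles_observed)
        unknown = set(roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles {sorted(unknown)}; valid roles are {ROLES}")
        if "twin1" not in roles:
            raise ValueError("twin1 must always be observed")
        if len(set(roles)) != len(roles):
            raise ValueError("duplicate roles in configuration")
        object.__setattr__(
            self, "roles_observed", tuple(sorted(roles, key=_ROLE_INDEX.__getitem__))
        )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask over :data:`ROLES`."""
        m = np.zeros(len(ROLES), dtype=bool)
        for r in self.roles_observed:
            m[_ROLE_INDEX[r]] = True
        return m

    def __len__(self) -> int:
        return len(self.roles_observed)


# The patterns of the cohort data: single twins with or without their spouse,
# and twin pairs with zero, one or two participating spouses.
SINGLE_TWIN = FamilyConfiguration(("twin1",))
TWIN_SPOUSE = FamilyConfiguration(("twin1", "spouse1"))
TWIN_PAIR = FamilyConfiguration(("twin1", "twin2"))
PAIR_ONE_SPOUSE = FamilyConfiguration(("twin1", "spouse1", "twin2"))
QUARTET = FamilyConfiguration(ROLES)

CONFIGURATIONS: Mapping[str, FamilyConfiguration] = {
    "single_twin": SINGLE_TWIN,
    "twin_spouse": TWIN_SPOUSE,
    "twin_pair": TWIN_PAIR,
    "pair_one_spouse": PAIR_ONE_SPOUSE,
    "quartet": QUARTET,
}


@dataclass(frozen=True)
class ParameterSet:
    """Free parameters of the twin-spouse model on the raw (years) scale.

    Parameters
    ----------
    a, s, e:
        Non-negative path coefficients of the additive-genetic,
        social-background and unique-environment components
        (units: years^0.5 of the standardized latent factors, i.e. the
        implied variances are ``a**2 + s**2 + e**2`` years^2).
    delta_p:
        Phenotypic-assortment copath (dimensionless).
    delta_y:
        Social-homogamy copath (dimensionless; may exceed 1).
    beta_sex:
        Additive mean effect of female sex, in years.
    mu:
        Grand mean (male baseline), in years.
    """

    a: float
    s: float
    e: float
    delta_p: float = 0.0
    delta_y: float = 0.0
    beta_sex: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "s", "e"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"path {name} must be finite and >= 0, got {v}")
        for name in ("delta_p", "delta_y", "beta_sex", "mu"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def variance(self) -> float:
        """Total phenotypic variance V = a^2 + s^2 + e^2 (years^2)."""
        return self.a**2 + self.s**2 + self.e**2

    @property
    def proportions(self) -> tuple[float, float, float]:
        """Standardized variance proportions ``(h2, s2, e2)``; they sum to 1."""
        v = self.variance
        if v <= 0:
            raise DegenerateModelError("total phenotypic variance is zero")
        return (self.a**2 / v, self.s**2 / v, self.e**2 / v)

    @classmethod
    def from_proportions(
        cls,
        h2: float,
        s2: float,
        e2: float,
        *,
        variance: float = 1.0,
        delta_p: float = 0.0,
        delta_y: float = 0.0,
        beta_sex: float = 0.0,
        mu: float = 0.0,
        tol: float = 1e-8,
    ) -> "ParameterSet":
        """Build a parameter set from standardized variance proportions.

        ``h2 + s2 + e2`` must equal 1 (tolerance ``tol``); ``variance`` sets
        the raw scale.
        """
        total = h2 + s2 + e2
        if abs(total - 1.0) > tol:
            raise ValueError(f"proportions must sum to 1, got {total}")
        if min(h2, s2, e2) < 0:
            raise ValueError("proportions must be non-negative")
        if variance <= 0:
            raise DegenerateModelError("variance must be positive")
        return cls(
            a=math.sqrt(h2 * variance),
            s=math.sqrt(s2 * variance),
            e=math.sqrt(e2 * variance),
            delta_p=delta_p,
            delta_y=delta_y,
            beta_sex=beta_sex,
            mu=mu,
        )

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def as_dict(self) -> dict[str, float]:
        return {
            "a": self.a,
            "s": self.s,
            "e": self.e,
            "delta_p": self.delta_p,
            "delta_y": self.delta_y,
            "beta_sex": self.beta_sex,
            "mu": self.mu,
        }


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied mean vector and covariance matrix over observed roles."""

    roles: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        k = len(self.roles)
        if mean.shape != (k,) or cov.shape != (k, k):
            raise ValueError("moment dimensions do not match number of roles")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


@dataclass(frozen=True)
class DecompositionResult:
    """Standardized variance components and the spousal-correlation split.

    ``mu_spouse`` is the implied twin-own-spouse correlation; it decomposes
    exactly into the direct phenotypic-assortment part (``delta_p``) and the
    social-homogamy part (``s2 * delta_y``).
    """

    h2: float
    s2: float
    e2: float
    part_phenotypic: float
    part_social: float

    @property
    def mu_spouse(self) -> float:
        return self.part_phenotypic + self.part_social


def dz_alpha(delta_p: float, zygosity: Zygosity | str = Zygosity.SSDZ) -> float:
    """Genetic correlation of a twin pair under equilibrium assortment.

    Returns 1.0 for MZ pairs and ``0.5 * (1 + delta_p)`` for DZ pairs: with
    phenotypic assortment at equilibrium, the parental genotypes correlate and
    push the DZ genetic correlation above the random-mating value 0.5.
    """
    if not math.isfinite(delta_p):
        raise ValueError("delta_p must be finite")
    if Zygosity(zygosity).is_mz:
        return 1.0
    return 0.5 * (1.0 + delta_p)


def implied_correlations(
    params: ParameterSet, zygosity: Zygosity | str
) -> dict[str, float]:
    """Standardized implied correlations for a quartet.

    Returns the twin-twin (``r_tw``), twin-own-spouse (``r1``), cotwin-spouse
    (``r2``) and spouse-spouse (``r3``) entries:

    * ``r_tw = alpha * h2 + s2``
    * ``r1 = delta_p + s2 * delta_y``
    * ``r2 = delta_p * r_tw + s2 * delta_y``
    * ``r3 = delta_p**2 * r_tw + 2 * delta_p * s2 * delta_y + s2 * delta_y``

    Under pure social homogamy (``delta_p = 0``) all three spousal
    correlations are equal; under pure phenotypic assortment
    (``delta_y = 0``, ``r_tw < 1``) they obey ``r1 > r2 > r3``.
    """
    h2, s2, _ = params.proportions
    alpha = dz_alpha(params.delta_p, zygosity)
    dp, dy = params.delta_p, params.delta_y
    r_tw = alpha * h2 + s2
    r1 = dp + s2 * dy
    r2 = dp * r_tw + s2 * dy
    r3 = dp * dp * r_tw + 2.0 * dp * s2 * dy + s2 * dy
    return {"r_tw": r_tw, "r1": r1, "r2": r2, "r3": r3}


#: latent components per person, canonical order
_COMPONENTS = ("A", "S", "E")


def latent_labels() -> tuple[str, ...]:
    """Labels of the 12 latent components: ``A/S/E`` per quartet role."""
    return tuple(f"{c}_{r}" for r in ROLES for c in _COMPONENTS)


def implied_latent_covariance(
    params: ParameterSet,
    zygosity: Zygosity | str,
    *,
    check: bool = True,
    tol: float = 1e-10,
) -> np.ndarray:
    """Covariance of the 12 latent components (A, S, E per quartet member).

    This is the construction oracle for the closed-form observed moments: all
    spouse-twin and spouse-spouse component covariances are obtained by
    path tracing through the copaths, with each copath traversed at most once
    per chain, and with the social-background strata of the two in-marrying
    spouses equicorrelated at ``delta_y`` with the family stratum and with
    each other.  Propagating it through the factor loadings reproduces
    :func:`implied_observed_moments` entry by entry.

    Only defined on the latent-admissible region (the resulting matrix must
    be PSD, which in particular requires ``|delta_y| <= 1``); outside it an
    :class:`AdmissibilityError` is raised naming the offending copath.
    """
    h2, s2, e2 = params.proportions
    lam = np.sqrt([h2, s2, e2])
    alpha = dz_alpha(params.delta_p, zygosity)
    dp, dy = params.delta_p, params.delta_y
    r_comp = np.array([alpha, 1.0, 0.0])  # twin-twin component correlations
    r_tw = alpha * h2 + s2
    st = lam[1]

    sigma = np.zeros((12, 12))

    def set_block(i: int, j: int, m: np.ndarray) -> None:
        sigma[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = m
        sigma[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = m.T

    for p in range(4):
        sigma[3 * p : 3 * p + 3, 3 * p : 3 * p + 3] = np.eye(3)

    # twin1 (0) - twin2 (2): genetic alpha, stratum 1, E independent
    set_block(0, 2, np.diag(r_comp))

    # each couple: one delta_p chain end to end, plus the stratum copath
    couple = np.outer(lam, lam) * dp
    couple[1, 1] += dy
    set_block(0, 1, couple)
    set_block(2, 3, couple)

    # spouse - cotwin: delta_p chain continued through the twin-twin
    # component correlations, plus the shared stratum
    cross = np.outer(lam, lam * r_comp) * dp
    cross[1, 1] += dy
    set_block(1, 2, cross)
    set_block(3, 0, cross)

    # spouse - spouse: delta_p chains through both couples and the twin pair,
    # mixed delta_p/delta_y chains, and the equicorrelated strata
    ss = np.outer(lam, lam) * dp * dp * r_tw
    ss[1, :] += dy * st * dp * lam
    ss[:, 1] += lam * dp * st * dy
    ss[1, 1] += dy
    set_block(1, 3, ss)

    if check:
        eigmin = float(np.linalg.eigvalsh(sigma)[0])
        if eigmin < -tol:
            # attribute the violation: retry with each copath switched off
            blame = []
            for name in ("delta_y", "delta_p"):
                trial = implied_latent_covariance(
                    params.replace(**{name: 0.0}), zygosity, check=False
                )
                if np.linalg.eigvalsh(trial)[0] >= -tol:
                    blame.append(f"{name}={getattr(params, name)}")
                    break
            detail = blame[0] if blame else (
                f"delta_p={dp}, delta_y={dy} (jointly inadmissible)"
            )
            raise AdmissibilityError(
                f"latent covariance is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3e}); offending copath: {detail}"
            )
    return sigma


def latent_loadings(params: ParameterSet) -> np.ndarray:
    """4x12 loading matrix mapping standardized latent components to the
    standardized quartet phenotypes."""
    h2, s2, e2 = params.proportions
    lam = np.sqrt([h2, s2, e2])
    big = np.zeros((4, 12))
    for p in range(4):
        big[p, 3 * p : 3 * p + 3] = lam
    return big


def _female_indicator(
    sexes: Mapping[str, str] | Sequence[str], roles: Sequence[str]
) -> np.ndarray:
    if isinstance(sexes, Mapping):
        vals = [sexes[r] for r in roles]
    else:
        vals = list(sexes)
        if len(vals) != len(roles):
            raise ValueError(
                f"expected {len(roles)} sexes for roles {tuple(roles)}, got {len(vals)}"
            )
    out = np.zeros(len(roles))
    for i, v in enumerate(vals):
        sv = str(v).upper()
        if sv in ("F", "FEMALE", "1", "W"):
            out[i] = 1.0
        elif sv in ("M", "MALE", "0"):
            out[i] = 0.0
        else:
            raise ValueError(f"unrecognized sex code {v!r} (use 'M'/'F')")
    return out


def implied_observed_moments(
    params: ParameterSet,
    zygosity: Zygosity | str,
    config: FamilyConfiguration = QUARTET,
    sexes: Mapping[str, str] | Sequence[str] | None = None,
    *,
    standardized: bool = False,
    check: bool = True,
    tol: float = 1e-9,
) -> ImpliedMoments:
    """Model-implied means and covariance over a family's observed roles.

    The standardized covariance entries are the closed forms of
    :func:`implied_correlations` (variance 1 on the diagonal); raw moments
    scale the covariance by the total variance ``V`` and add means
    ``mu + beta_sex * I(female)``.  Rows and columns are restricted to
    ``config.roles_observed``.

    Parameters
    ----------
    sexes:
        Sex per observed role ('M'/'F'); mapping or sequence aligned with
        ``config.roles_observed``.  Defaults to all male (mean ``mu``).
    standardized:
        If True, return correlation-scale moments (unit variances, means on
        the same standardized scale: ``0`` plus ``beta_sex/sqrt(V)`` for
        women).
    check:
        Verify that the restricted covariance is PSD; note that only
        *observed*-level admissibility is required here, so social-homogamy
        copaths slightly above 1 (e.g. 1.03 with small s2) pass.
    """
    v = params.variance
    if v <= 0:
        raise DegenerateModelError("total phenotypic variance is zero")
    rr = implied_correlations(params, zygosity)
    r_tw, r1, r2, r3 = rr["r_tw"], rr["r1"], rr["r2"], rr["r3"]
    corr = np.array(
        [
            [1.0, r1, r_tw, r2],
            [r1, 1.0, r2, r3],
            [r_tw, r2, 1.0, r1],
            [r2, r3, r1, 1.0],
        ]
    )
    mask = config.mask
    if sexes is None:
        female = np.zeros(len(config))
    else:
        female = _female_indicator(sexes, config.roles_observed)

    if standardized:
        cov = corr[np.ix_(mask, mask)]
        mean = female * (params.beta_sex / math.sqrt(v))
    else:
        cov = v * corr[np.ix_(mask, mask)]
        mean = params.mu + params.beta_sex * female

    if check:
        eigmin = float(np.linalg.eigvalsh(cov)[0])
        if eigmin < -tol * max(1.0, v):
            raise AdmissibilityError(
                f"implied observed covariance is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3e}) at delta_p={params.delta_p}, "
                f"delta_y={params.delta_y}"
            )
    return ImpliedMoments(roles=config.roles_observed, mean=mean, cov=cov)


def decompose(params: ParameterSet) -> DecompositionResult:
    """Standardize the paths and split the implied spousal correlation.

    The social-homogamy contribution is ``s2 * delta_y`` (the standardized
    social-background variance times the homogamy copath) and the phenotypic
    assortment contribution is ``delta_p`` itself; the implied twin-own-spouse
    correlation is exactly their sum.
    """
    h2, s2, e2 = params.proportions
    return DecompositionResult(
        h2=h2,
        s2=s2,
        e2=e2,
        part_phenotypic=params.delta_p,
        part_social=s2 * params.delta_y,
    )
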