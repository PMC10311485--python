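"""Synthetic twin-spouse family data.

Two generators are provided:

* :func:`simulate_families` -- the primary generator.  It samples family
  quartets directly from the model-implied *observed* multivariate-normal
  moments, per zygosity and family configuration.  Because only observed-level
  admissibility is required, it remains valid for social-homogamy copaths
  slightly above 1 (as estimated in both cohorts).
* :func:`mate_choice_oracle` -- a mechanistic agent-based check.  Individuals
  carry explicit A/S/E components, spouses are matched on a weighted
  similarity score of phenotype and social stratum, and the process can be
  iterated over generations.  It exists to validate the qualitative
  predictions of the structural model (rank order of correlations, the rise
  of the sibling genetic correlation and genetic variance under persistent
  phenotypic assortment) from an independent generative route.

Missingness is MCAR by construction: configurations are assigned
independently of the phenotype values, mirroring the observed cohort
configuration tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CONFIGURATIONS,
    ROLES,
    ParameterSet,
    Zygosity,
    implied_observed_moments,
)

__all__ = [
    "SimulationDesign",
    "simulate_families",
    "apply_missingness",
    "mate_choice_oracle",
    "MateChoiceResult",
    "FAMILY_COLUMNS",
]

#: Column schema of the family table.
FAMILY_COLUMNS: tuple[str, ...] = (
    "family_id",
    "zygosity",
    "twin1_sex",
    "spouse1_sex",
    "twin2_sex",
    "spouse2_sex",
    "twin1_years",
    "spouse1_years",
    "twin2_years",
    "spouse2_years",
)

_SEX_COLS = ("twin1_sex", "spouse1_sex", "twin2_sex", "spouse2_sex")
_YEAR_COLS = ("twin1_years", "spouse1_years", "twin2_years", "spouse2_years")


@dataclass(frozen=True)
class SimulationDesign:
    """A simulation plan: families per (zygosity, configuration) plus the
    generating parameters and the master seed.

    ``counts`` maps ``(zygosity, configuration_name)`` to family counts;
    configuration names are those of :data:`twinspouse.model.CONFIGURATIONS`.
    Twin-pair sexes are assigned 50/50 per family; OSDZ twins are
    opposite-sex by construction, and every spouse is opposite-sex to their
    twin.
    """

    counts: Mapping[tuple[str, str], int]
    params: ParameterSet
    seed: int

    def __post_init__(self) -> None:
        for (zyg, cfg), n in self.counts.items():
            Zygosity(zyg)
            if cfg not in CONFIGURATIONS:
                raise ValueError(
                    f"unknown configuration {cfg!r}; valid: {sorted(CONFIGURATIONS)}"
                )
            if n < 0:
                raise ValueError(f"negative family count for {(zyg, cfg)}")

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, str], int],
        params: ParameterSet,
        seed: int,
        *,
        total: int | None = None,
    ) -> "SimulationDesign":
        """Build a design from a count table, optionally rescaled so the
        counts sum to ``total`` (proportions preserved, largest-remainder
        rounding)."""
        if total is None:
            return cls(dict(counts), params, seed)
        keys = sorted(counts)
        raw = np.array([counts[k] for k in keys], dtype=float)
        if raw.sum() <= 0:
            raise ValueError("count table sums to zero")
        exact = raw / raw.sum() * total
        base = np.floor(exact).astype(int)
        rem = total - base.sum()
        order = np.argsort(-(exact - base))
        base[order[:rem]] += 1
        return cls({k: int(v) for k, v in zip(keys, base)}, params, seed)

    @classmethod
    def quartets(
        cls, n_per_zygosity: int, params: ParameterSet, seed: int
    ) -> "SimulationDesign":
        """Complete-quartet design: ``n_per_zygosity`` families for each of
        MZ, SSDZ and OSDZ, all fully observed."""
        return cls(
            {(z.value, "quartet"): n_per_zygosity for z in Zygosity}, params, seed
        )

    @property
    def n_families(self) -> int:
        return int(sum(self.counts.values()))


def _assign_sexes(
    zygosity: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n x 4 female indicator over ROLES; spouses opposite-sex to their twin."""
    fem = np.zeros((n, 4))
    if zygosity == Zygosity.OSDZ.value:
        t1 = rng.integers(0, 2, size=n).astype(float)
        fem[:, 0] = t1
        fem[:, 2] = 1.0 - t1
    else:
        pair = rng.integers(0, 2, size=n).astype(float)
        fem[:, 0] = pair
        fem[:, 2] = pair
    fem[:, 1] = 1.0 - fem[:, 0]
    fem[:, 3] = 1.0 - fem[:, 2]
    return fem


def simulate_families(design: SimulationDesign) -> pd.DataFrame:
    """Draw a family table from the model-implied observed moments.

    Each family's observed roles are sampled from the multivariate normal
    with the implied covariance of its (zygosity, configuration) cell and
    means ``mu + beta_sex * I(female)``.  Output is a CSV-ready table with
    one row per family and NaN for unobserved roles; same seed, same table.
    """
    rng = np.random.default_rng(design.seed)
    params = design.params
    frames: list[pd.DataFrame] = []
    fid = 0
    for (zyg, cfg_name) in sorted(design.counts):
        n = design.counts[(zyg, cfg_name)]
        if n == 0:
            continue
        config = CONFIGURATIONS[cfg_name]
        mask = config.mask
        # moments with all-male means; sex effects added per family below
        mom = implied_observed_moments(params, zyg, config)
        chol = np.linalg.cholesky(
            mom.cov + 1e-12 * params.variance * np.eye(len(config))
        )
        draws = rng.standard_normal((n, len(config))) @ chol.T
        fem = _assign_sexes(zyg, n, rng)
        years = np.full((n, 4), np.nan)
        years[:, mask] = draws + params.mu + params.beta_sex * fem[:, mask]

        block = pd.DataFrame(
            {
                "family_id": np.arange(fid, fid + n),
                "zygosity": zyg,
            }
        )
        for j, role in enumerate(ROLES):
            sex = np.where(fem[:, j] > 0.5, "F", "M")
            block[f"{role}_sex"] = np.where(mask[j], sex, None)
            block[f"{role}_years"] = years[:, j] if mask[j] else np.nan
        frames.append(block)
        fid += n
    if not frames:
        raise ValueError("simulation design contains no families")
    out = pd.concat(frames, ignore_index=True)
    return out[list(FAMILY_COLUMNS)]


def apply_missingness(
    table: pd.DataFrame,
    frequencies: Mapping[str, Mapping[str, float] | Sequence[float]],
    seed: int,
    *,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Mask spouse phenotypes per sampled configuration (MCAR).

    ``frequencies`` maps each zygosity to probabilities of the three spouse
    patterns ``(none, one, both)``; they must be non-negative and sum to 1
    (tolerance ``tol``).  Twins are never masked.  Families drawn into the
    ``none`` pattern lose both spouses, ``one`` keeps only spouse1.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for zyg, freq in frequencies.items():
        if isinstance(freq, Mapping):
            p = np.array([freq.get("none", 0), freq.get("one", 0), freq.get("both", 0)], float)
        else:
            p = np.asarray(list(freq), dtype=float)
            if p.shape != (3,):
                raise ValueError("expected three frequencies (none, one, both)")
        if (p < 0).any():
            raise ValueError(f"negative configuration frequency for {zyg}: {p}")
        if abs(p.sum() - 1.0) > tol:
            raise ValueError(
                f"configuration frequencies for {zyg} sum to {p.sum()}, expected 1"
            )
        idx = out.index[out["zygosity"] == zyg]
        if len(idx) == 0:
            continue
        pattern = rng.choice(3, size=len(idx), p=p)
        drop_both = idx[pattern == 0]
        drop_sp2 = idx[pattern == 1]
        out.loc[drop_both, ["spouse1_years", "spouse2_years"]] = np.nan
        out.loc[drop_sp2, "spouse2_years"] = np.nan
    return out


@dataclass
class MateChoiceResult:
    """Trajectories and final-state summaries from the mate-choice oracle."""

    spousal_corr: list[float] = field(default_factory=list)
    sib_genetic_corr: list[float] = field(default_factory=list)
    genetic_variance: list[float] = field(default_factory=list)
    r1: float = math.nan
    r2: float = math.nan
    r3: float = math.nan

    @property
    def variance_plateaued(self) -> bool:
        """Relative change of the genetic variance below 1% between the last
        two generations."""
        if len(self.genetic_variance) < 2:
            return False
        a, b = self.genetic_variance[-2], self.genetic_variance[-1]
        return abs(b - a) < 0.01 * max(abs(a), 1e-12)


def _rank_match(
    score_a: np.ndarray, score_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pair two pools by sorting on their matching scores (rank-to-rank)."""
    return np.argsort(score_a, kind="stable"), np.argsort(score_b, kind="stable")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def mate_choice_oracle(
    params: ParameterSet,
    n_couples: int = 2000,
    weights: tuple[float, float] = (1.0, 0.0),
    generations: int = 1,
    seed: int = 0,
    *,
    noise_sd: float = 1.0,
    n_twin_families: int | None = None,
) -> MateChoiceResult:
    """Agent-based mate choice with explicit A/S/E components.

    Each generation, male and female pools are matched on the score
    ``w_p * z(phenotype) + w_s * z(stratum) + noise`` by rank pairing; the
    noise standard deviation (relative to the unit-variance weighted score)
    controls how tight the matching is.  Couples produce two children: full
    sibs share midparent genotype plus independent segregation (variance half
    the base additive variance) and share a family stratum; the stratum pool
    is renormalized each generation so its variance stays at ``s**2``.

    After the last generation, MZ-like twin families are formed (twins share
    A and S exactly) and each twin is matched to a fresh spouse pool with the
    same rule, yielding the twin-own-spouse (r1), cotwin-spouse (r2) and
    spouse-spouse (r3) correlations.

    Phenotype-only matching reproduces ``r1 > r2 > r3``; stratum-only
    matching with tight matching (small ``noise_sd``) gives approximately
    equal correlations; persistent phenotype matching over generations pushes
    the full-sib genetic correlation above 0.5 and the genetic variance to a
    plateau.
    """
    if n_couples < 100:
        raise ValueError("pool size must be at least 100 couples")
    w_p, w_s = float(weights[0]), float(weights[1])
    norm = math.hypot(w_p, w_s)
    if norm == 0:
        raise ValueError("degenerate matching weights: both zero")
    w_p, w_s = w_p / norm, w_s / norm
    if generations < 1:
        raise ValueError("need at least one generation")
    if n_twin_families is None:
        n_twin_families = n_couples

    rng = np.random.default_rng(seed)
    a2, s2, e2 = params.a**2, params.s**2, params.e**2
    res = MateChoiceResult()

    def draw_pool(n: int, var_a: float) -> dict[str, np.ndarray]:
        return {
            "A": rng.normal(0.0, math.sqrt(var_a), n),
            "S": rng.normal(0.0, math.sqrt(s2), n) if s2 > 0 else np.zeros(n),
            "E": rng.normal(0.0, math.sqrt(e2), n) if e2 > 0 else np.zeros(n),
        }

    def score(pool: dict[str, np.ndarray]) -> np.ndarray:
        p = pool["A"] + pool["S"] + pool["E"]
        return (
            w_p * _zscore(p)
            + w_s * _zscore(pool["S"])
            + rng.normal(0.0, noise_sd, len(p))
        )

    males = draw_pool(n_couples, a2)
    females = draw_pool(n_couples, a2)

    for _ in range(generations):
        om, of = _rank_match(score(males), score(females))
        males = {k: v[om] for k, v in males.items()}
        females = {k: v[of] for k, v in females.items()}
        pm = males["A"] + males["S"] + males["E"]
        pf = females["A"] + females["S"] + females["E"]
        res.spousal_corr.append(float(np.corrcoef(pm, pf)[0, 1]))

        # offspring: two full sibs per couple
        mid = 0.5 * (males["A"] + females["A"])
        seg_sd = math.sqrt(0.5 * a2)  # segregation variance, base-population scale
        sib1_a = mid + rng.normal(0.0, seg_sd, n_couples)
        sib2_a = mid + rng.normal(0.0, seg_sd, n_couples)
        res.sib_genetic_corr.append(float(np.corrcoef(sib1_a, sib2_a)[0, 1]))
        res.genetic_variance.append(float(np.concatenate([sib1_a, sib2_a]).var()))

        if s2 > 0:
            fam_s = _zscore(0.5 * (males["S"] + females["S"])) * math.sqrt(s2)
        else:
            fam_s = np.zeros(n_couples)
        # one child of each sex enters the next mating pool; shuffle families
        # so rank-matching cannot exploit residual family ordering
        perm = rng.permutation(n_couples)
        males = {
            "A": sib1_a[perm],
            "S": fam_s[perm],
            "E": rng.normal(0.0, math.sqrt(e2), n_couples) if e2 > 0 else np.zeros(n_couples),
        }
        females = {
            "A": sib2_a[perm],
            "S": fam_s[perm],
            "E": rng.normal(0.0, math.sqrt(e2), n_couples) if e2 > 0 else np.zeros(n_couples),
        }

    # MZ-like twin families from the final population state
    var_a_now = res.genetic_variance[-1]
    nf = n_twin_families
    twin_a = rng.normal(0.0, math.sqrt(var_a_now), nf)
    twin_s = rng.normal(0.0, math.sqrt(s2), nf) if s2 > 0 else np.zeros(nf)
    t1 = twin_a + twin_s + (rng.normal(0.0, math.sqrt(e2), nf) if e2 > 0 else 0.0)
    t2 = twin_a + twin_s + (rng.normal(0.0, math.sqrt(e2), nf) if e2 > 0 else 0.0)

    def match_spouses(t_pheno: np.ndarray) -> np.ndarray:
        cand = draw_pool(nf, var_a_now)
        t_score = (
            w_p * _zscore(t_pheno)
            + w_s * _zscore(twin_s)
            + rng.normal(0.0, noise_sd, nf)
        )
        ot, oc = _rank_match(t_score, score(cand))
        sp_pheno = (cand["A"] + cand["S"] + cand["E"])[oc]
        out = np.empty(nf)
        out[ot] = sp_pheno
        return out

    sp1 = match_spouses(t1)
    sp2 = match_spouses(t2)
    res.r1 = float(np.corrcoef(np.r_[t1, t2], np.r_[sp1, sp2])[0, 1])
    res.r2 = float(np.corrcoef(np.r_[t1, t2], np.r_[sp2, sp1])[0, 1])
    res.r3 = float(np.corrcoef(sp1, sp2)[0, 1])
    return res
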