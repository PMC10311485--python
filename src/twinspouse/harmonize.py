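"""Harmonize country-specific educational levels to years of education.

Both cohorts report highest attained education on a five-category scale; the
Dutch data additionally arrive on a seven-category scale which is first
merged down to the common five categories (lower vocational with lower
secondary general into category 2; intermediate vocational with
intermediate/higher secondary general into category 3).  Each five-category
level maps to a fixed number of years; respondents still enrolled at survey
time receive one year less than the completed-level value.

The default mapping ships as an editable YAML file
(``twinspouse/data/education_years.yaml``).

Order-of-operations convention: for Dutch records the "did not complete the
highest level" step-down happens on the seven-category scale *before*
merging, and the enrolled-minus-one rule applies after merging, on the final
years value (the rule is stated for the Finnish survey; applying it to both
countries keeps the scales symmetric and is recorded in output metadata).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "MappingError",
    "load_mapping",
    "years_from_level",
    "merge_nl_categories",
    "harmonize_table",
    "HARMONIZATION_METADATA",
]

#: Conventions a consumer of harmonized output should know about.
HARMONIZATION_METADATA: Mapping[str, str] = {
    "enrolled_rule": "enrolled-minus-1 applied to both countries, after the NL merge",
    "nl_not_completed": "step down one 7-level category before merging",
}


class MappingError(KeyError):
    """Unknown country or educational level."""


@lru_cache(maxsize=None)
def _default_mapping() -> dict:
    text = resources.files("twinspouse").joinpath("data/education_years.yaml").read_text()
    return yaml.safe_load(text)


def load_mapping(path: str | None = None) -> dict:
    """Load the level-to-years mapping (the shipped default, or a YAML file
    of the same shape)."""
    if path is None:
        return _default_mapping()
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _resolve_level(country: str, level, mapping: dict) -> int:
    cmap = mapping.get(str(country).upper())
    if cmap is None:
        raise MappingError(
            f"unknown country {country!r}; valid countries: "
            f"{sorted(k for k in mapping if isinstance(k, str))}"
        )
    if isinstance(level, str) and not level.strip().isdigit():
        code = cmap.get("aliases", {}).get(level.strip().lower())
        if code is None:
            valid = sorted(cmap.get("aliases", {}))
            raise MappingError(
                f"unknown level {level!r} for {country}; valid labels: {valid}"
            )
        return int(code)
    code = int(level)
    if code not in cmap:
        valid = sorted(k for k in cmap if isinstance(k, int))
        raise MappingError(
            f"unknown level code {level!r} for {country}; valid codes: {valid}"
        )
    return code


def years_from_level(
    country: str,
    level,
    enrolled: bool = False,
    *,
    mapping: dict | None = None,
) -> int:
    """Years of education for a five-category level code or label.

    ``enrolled=True`` (still engaged in education) gives the completed-level
    years minus one.
    """
    mapping = mapping or _default_mapping()
    code = _resolve_level(country, level, mapping)
    years = int(mapping[str(country).upper()][code]["years"])
    return years - 1 if enrolled else years


# seven-category -> five-category merge for the Dutch coding
_NL_MERGE = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 4, 7: 5}


def merge_nl_categories(seven_cat: int, completed_highest: bool = True) -> int:
    """Collapse the Dutch seven-category coding to the common five categories.

    If the highest reported level was not completed, the next lower
    seven-category level is used first (floored at category 1), then merged:
    {1}->1, {2,3}->2, {4,5}->3, {6}->4, {7}->5.
    """
    code = int(seven_cat)
    if code not in _NL_MERGE:
        raise MappingError(f"NL seven-category code must be 1..7, got {seven_cat!r}")
    if not completed_highest:
        code = max(code - 1, 1)
    return _NL_MERGE[code]


def harmonize_table(
    data: pd.DataFrame,
    *,
    country_col: str = "country",
    roles: tuple[str, ...] = ("twin1", "spouse1", "twin2", "spouse2"),
    mapping: dict | None = None,
) -> pd.DataFrame:
    """Fill ``<role>_years`` columns from ``<role>_level`` codes.

    Recognized per-role columns: ``<role>_level`` (5-category code or label;
    for NL rows a ``<role>_level7`` column is merged down first),
    ``<role>_enrolled`` and ``<role>_completed`` flags.  Existing years
    values are preserved where no level is given.
    """
    mapping = mapping or _default_mapping()
    out = data.copy()
    if country_col not in out.columns:
        raise MappingError(f"harmonization needs a {country_col!r} column")
    for role in roles:
        lvl7 = f"{role}_level7"
        lvl = f"{role}_level"
        if lvl7 in out.columns:
            compl = out.get(f"{role}_completed", pd.Series(True, index=out.index))
            merged = [
                merge_nl_categories(int(v), bool(c)) if pd.notna(v) else pd.NA
                for v, c in zip(out[lvl7], compl.fillna(True))
            ]
            if lvl in out.columns:
                out[lvl] = out[lvl].where(out[lvl].notna(), pd.Series(merged, index=out.index))
            else:
                out[lvl] = pd.Series(merged, index=out.index)
        if lvl not in out.columns:
            continue
        enrolled = out.get(f"{role}_enrolled", pd.Series(False, index=out.index))
        years_col = f"{role}_years"
        if years_col not in out.columns:
            out[years_col] = pd.NA
        new_years = []
        for v, country, enr, existing in zip(
            out[lvl], out[country_col], enrolled.fillna(False), out[years_col]
        ):
            if pd.isna(v):
                new_years.append(existing)
            else:
                new_years.append(
                    years_from_level(str(country), v, bool(enr), mapping=mapping)
                )
        out[years_col] = pd.to_numeric(pd.Series(new_years, index=out.index), errors="coerce")
    return out
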