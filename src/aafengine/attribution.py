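"""Death attribution: ICD-10 mapping, AAF application, rates.

Deaths are keyed by (year, sex, age_group, cause category); the underlying
cause code is matched to the cause catalog by longest ICD-10 prefix (single
codes, prefixes and ranges like ``I20-I25`` are supported).  Attributable
deaths are AAF x count per cell; rates are crude and directly
age-standardized per 100,000 against a configurable standard population
(default: WHO World Standard collapsed to the analysis age groups).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    AGE_GROUPS,
    MIN_ATTRIBUTION_AGE,
    age_to_group,
    validate_weights,
    who_standard_weights,
)
from .rr import FULLY, RRRegistry

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9X]?$")
_RANGE_RE = re.compile(r"^([A-Z])([0-9]{2})-([A-Z])([0-9]{2})$")


def normalize_code(code: str) -> str:
    """Uppercase an ICD-10 code and strip the decimal point (K70.3 -> K703)."""
    return str(code).strip().upper().replace(".", "")


def expand_code_patterns(patterns) -> list[str]:
    """Expand catalog entries (codes, prefixes, ranges) to a prefix list.

    A range like ``I20-I25`` expands to the 3-character prefixes I20..I25;
    single 3- or 4-character codes act as prefixes of themselves.
    """
    out: list[str] = []
    for pat in patterns:
        pat = str(pat).strip().upper().replace(".", "")
        m = _RANGE_RE.match(pat)
        if m:
            lo_letter, lo, hi_letter, hi = m.groups()
            if lo_letter != hi_letter:
                raise ValueError(f"ICD-10 range {pat!r} spans letters")
            lo_i, hi_i = int(lo), int(hi)
            if hi_i < lo_i:
                raise ValueError(f"ICD-10 range {pat!r} is reversed")
            out.extend(f"{lo_letter}{i:02d}" for i in range(lo_i, hi_i + 1))
        elif _CODE_RE.match(pat):
            out.append(pat)
        else:
            raise ValueError(f"malformed ICD-10 catalog entry {pat!r}")
    return out


def build_code_index(registry: RRRegistry) -> dict[str, str]:
    """prefix -> cause name index for the registry's catalog."""
    index: dict[str, str] = {}
    for cause in registry.causes.values():
        for prefix in expand_code_patterns(cause.icd10):
            index[prefix] = cause.name
    return index


def map_icd10(code: str, code_index: dict[str, str]) -> str | None:
    """Map one death record's ICD-10 code to a cause category.

    Longest-prefix match; returns None (unmapped) for codes outside the
    catalog.  Malformed codes are warned about and treated as unmapped.
    """
    if not code or not str(code).strip():
        raise ValueError("empty ICD-10 code")
    norm = normalize_code(code)
    if not re.match(r"^[A-Z][0-9]{2}", norm):
        logger.warning("malformed ICD-10 code %r treated as unmapped", code)
        return None
    for length in range(len(norm), 2, -1):
        cause = code_index.get(norm[:length])
        if cause is not None:
            return cause
    return None


@dataclass
class DeathTable:
    """Death counts by (year, sex, age_group, cause) plus stratum totals.

    ``counts`` has columns year/sex/age_group/cause/deaths; ``totals`` has
    year/sex/age_group/deaths (all deaths in the attribution frame, mapped
    or not); ``unmapped`` is the unmapped-record count per year.
    """

    counts: pd.DataFrame
    totals: pd.DataFrame
    unmapped: pd.DataFrame


def build_death_table(records: pd.DataFrame, registry: RRRegistry,
                      min_age: int = MIN_ATTRIBUTION_AGE,
                      include_under_min_in_totals: bool = False) -> DeathTable:
    """Aggregate individual death records (year, sex, age, icd10).

    Deaths below ``min_age`` are excluded from attribution; by default they
    are excluded from totals as well (set ``include_under_min_in_totals``
    to count them in proportion denominators).
    """
    index = build_code_index(registry)
    df = records.copy()
    df["age_group"] = df["age"].map(age_to_group)
    under = df["age"] < min_age
    frame = df.loc[~under].copy()
    frame["cause"] = [map_icd10(c, index) for c in frame["icd10"]]
    mapped = frame.dropna(subset=["cause"])
    counts = (mapped.groupby(["year", "sex", "age_group", "cause"],
                             observed=True)
              .size().rename("deaths").reset_index())
    if include_under_min_in_totals:
        totals_frame = df.copy()
        totals_frame.loc[under, "age_group"] = "<15"
    else:
        totals_frame = frame
    totals = (totals_frame.groupby(["year", "sex", "age_group"],
                                   observed=True)
              .size().rename("deaths").reset_index())
    unmapped = (frame[frame["cause"].isna()].groupby("year")
                .size().rename("unmapped").reset_index())
    return DeathTable(counts=counts, totals=totals, unmapped=unmapped)


def attributable_deaths(death_table: DeathTable | pd.DataFrame,
                        aaf_table: pd.DataFrame,
                        registry: RRRegistry) -> pd.DataFrame:
    """Attributable = AAF x deaths per (year, sex, age_group, cause) cell.

    Fully attributable causes contribute their full count; every non-empty
    cell of a partially attributable cause must have an AAF.  Negative
    (protective) AAFs yield negative attributable cells and are retained.
    """
    counts = death_table.counts if isinstance(death_table, DeathTable) else death_table
    keys = ["year", "sex", "age_group", "cause"]
    merged = counts.merge(aaf_table[keys + ["aaf"]], on=keys, how="left")
    fully = {c.name for c in registry.causes.values()
             if c.attribution == FULLY}
    is_fully = merged["cause"].isin(fully)
    merged.loc[is_fully & merged["aaf"].isna(), "aaf"] = 1.0
    missing = merged[merged["aaf"].isna() & (merged["deaths"] > 0)]
    if len(missing):
        cells = missing[keys].to_records(index=False).tolist()
        raise ValueError(f"missing AAF for non-empty cells: {cells}")
    merged["attributable"] = merged["aaf"] * merged["deaths"]
    return merged


def proportion_of_total(attributable: pd.DataFrame, totals: pd.DataFrame,
                        by=("year", "sex")) -> pd.DataFrame:
    """Percent of total deaths attributable to alcohol, per group.

    Groups with zero total deaths are reported as missing (NaN).
    """
    by = list(by)
    att = attributable.groupby(by, observed=True)["attributable"].sum()
    tot = totals.groupby(by, observed=True)["deaths"].sum()
    out = pd.concat([att, tot], axis=1).reset_index()
    out["attributable"] = out["attributable"].fillna(0.0)
    out["percent"] = np.where(out["deaths"] > 0,
                              100.0 * out["attributable"] / out["deaths"],
                              np.nan)
    return out


def age_standardize(stratum_deaths: dict[str, float],
                    populations: dict[str, float],
                    weights: dict[str, float] | None = None,
                    age_groups=AGE_GROUPS) -> float:
    """Directly age-standardized rate per 100,000.

    sum_g w_g * (deaths_g / population_g) * 100,000 with standard weights
    w_g summing to one.
    """
    if weights is None:
        weights = who_standard_weights(age_groups)
    validate_weights(weights, age_groups)
    missing = [g for g in age_groups
               if g not in populations or populations[g] <= 0]
    if missing:
        raise ValueError(f"missing population for age groups: {missing}")
    return float(sum(
        weights[g] * stratum_deaths.get(g, 0.0) / populations[g] * 1e5
        for g in age_groups
    ))


def rate_table(attributable: pd.DataFrame, totals: pd.DataFrame,
               populations: pd.DataFrame,
               weights: dict[str, float] | None = None,
               age_groups=AGE_GROUPS) -> pd.DataFrame:
    """Crude and age-standardized attributable rates per sex/year + overall.

    ``populations`` columns: year, sex, age_group, population.  The overall
    rows pool both sexes.  Proportion of total deaths (%) is included.
    """
    if weights is None:
        weights = who_standard_weights(age_groups)
    rows = []
    years = sorted(attributable["year"].unique())
    for year in years:
        att_y = attributable[attributable["year"] == year]
        tot_y = totals[totals["year"] == year]
        pop_y = populations[populations["year"] == year]
        sexes = sorted(att_y["sex"].unique())
        for sex in sexes + ["all"]:
            if sex == "all":
                att_s, tot_s, pop_s = att_y, tot_y, pop_y
            else:
                att_s = att_y[att_y["sex"] == sex]
                tot_s = tot_y[tot_y["sex"] == sex]
                pop_s = pop_y[pop_y["sex"] == sex]
            deaths_g = att_s.groupby("age_group", observed=True)[
                "attributable"].sum().to_dict()
            pops_g = pop_s.groupby("age_group", observed=True)[
                "population"].sum().to_dict()
            population = sum(pops_g.values())
            attributable_total = float(att_s["attributable"].sum())
            total_deaths = float(tot_s["deaths"].sum())
            rows.append({
                "year": year, "sex": sex,
                "attributable_deaths": attributable_total,
                "total_deaths": total_deaths,
                "population": population,
                "crude_rate": attributable_total / population * 1e5,
                "age_standardized_rate": age_standardize(
                    deaths_g, pops_g, weights, age_groups),
                "percent_of_total": (100.0 * attributable_total / total_deaths
                                     if total_deaths > 0 else np.nan),
            })
    return pd.DataFrame(rows)
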