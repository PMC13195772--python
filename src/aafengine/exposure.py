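"""Survey microdata -> per-stratum alcohol exposure distributions.

The exposure model follows the indirect-estimation convention used in
comparative risk assessment: survey respondents are classified as lifetime
abstainers, former drinkers (drank in the past year but not the past month)
or current drinkers; categorical frequency/quantity items are converted to
grams of pure alcohol per day; per-drinker consumption is rescaled so that
population per-capita consumption matches an external benchmark (litres of
pure alcohol per person 15+ per year); and the rescaled values are smoothed
with a gamma distribution per sex-age stratum, capped at 150 g/day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .constants import (
    AGE_GROUPS,
    CONSUMPTION_CAP_G_PER_DAY,
    FREQUENCY_OCCASIONS_PER_DAY,
    GRAMS_PER_DRINK,
    HED_DRINK_THRESHOLD,
    HED_FREQUENCY_PAST_MONTH,
    QUANTITY_DRINKS_PER_OCCASION,
    age_to_group,
    litres_per_year_to_grams_per_day,
)

logger = logging.getLogger(__name__)

ABSTAINER = "abstainer"
FORMER = "former"
CURRENT = "current"


@dataclass
class ExposureDistribution:
    """Exposure parameters for one sex x age-group (x year) stratum.

    ``shape``/``scale`` parameterize the gamma consumption model in grams of
    pure alcohol per day among current drinkers, truncated and renormalized
    on (0, cap].  ``p_hed`` is the probability of heavy-episodic-drinking
    status among current drinkers.
    """

    sex: str
    age_group: str
    p_abstainer: float
    p_former: float
    p_current: float
    shape: float
    scale: float
    p_hed: float = 0.0
    year: int | None = None
    cap: float = CONSUMPTION_CAP_G_PER_DAY
    calibration_factor: float = 1.0
    imputed: bool = False
    n_respondents: int | None = None
    n_drinkers: int | None = None

    def __post_init__(self) -> None:
        total = self.p_abstainer + self.p_former + self.p_current
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"status probabilities sum to {total!r} (stratum "
                f"{self.sex}/{self.age_group}), expected 1"
            )
        for name in ("p_abstainer", "p_former", "p_current", "p_hed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        for name in ("shape", "scale", "cap"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name}={v!r} must be strictly positive")

    @property
    def key(self) -> tuple:
        return (self.sex, self.age_group, self.year)

    def mean_consumption(self) -> float:
        """Mean grams/day among current drinkers under the truncated gamma."""
        k, th, cap = self.shape, self.scale, self.cap
        z = stats.gamma.cdf(cap, k, scale=th)
        return k * th * stats.gamma.cdf(cap, k + 1, scale=th) / z


# --- respondent-level classification ----------------------------------------


def _as_bool(indicator) -> bool | None:
    if isinstance(indicator, str):
        s = indicator.strip().lower()
        if s in ("yes", "y", "true", "1"):
            return True
        if s in ("no", "n", "false", "0"):
            return False
        return None
    if indicator is None or (isinstance(indicator, float) and math.isnan(indicator)):
        return None
    return bool(indicator)


def classify_status(past_year, past_month) -> str:
    """Drinker status from past-year / past-month drinking indicators.

    No past-year drinking -> abstainer; past-year but not past-month ->
    former drinker; both -> current drinker.
    """
    py, pm = _as_bool(past_year), _as_bool(past_month)
    if py is None or pm is None:
        raise ValueError("missing drinking indicator")
    if not py:
        return ABSTAINER
    return CURRENT if pm else FORMER


def grams_per_day(frequency: str, quantity: str,
                  grams_per_drink: float = GRAMS_PER_DRINK) -> float:
    """Average grams of pure alcohol per day implied by the two items.

    Category midpoints: occasions/day from the frequency item times
    drinks/occasion from the quantity item times grams per standard drink.
    """
    try:
        occ = FREQUENCY_OCCASIONS_PER_DAY[frequency]
    except KeyError:
        raise ValueError(f"unknown frequency category {frequency!r}") from None
    if occ == 0.0:
        return 0.0
    try:
        drinks = QUANTITY_DRINKS_PER_OCCASION[quantity]
    except KeyError:
        raise ValueError(f"unknown quantity category {quantity!r}") from None
    return occ * drinks * grams_per_drink


def hed_status(sex: str, quantity, hed_frequency: str | None) -> bool:
    """Heavy-episodic-drinking status for a current drinker.

    True when the dedicated HED-frequency item reports at least one episode
    in the past month, or when a numeric typical drinks-per-occasion meets
    the sex-specific threshold (5+ men, 4+ women).  When the quantity is a
    survey category the dedicated item is authoritative (categories pool
    episodic and steady patterns, so their midpoints are not compared to
    the threshold).
    """
    if hed_frequency is not None:
        try:
            if HED_FREQUENCY_PAST_MONTH[hed_frequency]:
                return True
        except KeyError:
            raise ValueError(f"unknown HED frequency category {hed_frequency!r}") from None
    if quantity is None or isinstance(quantity, str):
        if isinstance(quantity, str) and quantity not in QUANTITY_DRINKS_PER_OCCASION:
            raise ValueError(f"unknown quantity category {quantity!r}")
        return False
    return float(quantity) >= HED_DRINK_THRESHOLD[sex]


def classify_survey(survey: pd.DataFrame,
                    grams_per_drink: float = GRAMS_PER_DRINK) -> pd.DataFrame:
    """Add status / grams-per-day / HED columns to a survey table.

    Rows with missing drinking indicators are dropped with a logged count.
    Expected columns: sex, age, weight, past_year, past_month, frequency,
    quantity, hed_frequency.
    """
    df = survey.copy()
    py = df["past_year"].map(_as_bool)
    pm = df["past_month"].map(_as_bool)
    bad = py.isna() | pm.isna()
    if bad.any():
        logger.warning("excluding %d rows with missing drinking indicators",
                       int(bad.sum()))
        df = df.loc[~bad].copy()
        py, pm = py[~bad], pm[~bad]
    status = np.where(~py.astype(bool), ABSTAINER,
                      np.where(pm.astype(bool), CURRENT, FORMER))
    df["status"] = status
    df["age_group"] = df["age"].map(age_to_group)
    gpd = np.zeros(len(df))
    hed = np.zeros(len(df), dtype=bool)
    cur = df["status"].to_numpy() == CURRENT
    if cur.any():
        sub = df.loc[cur]
        gpd[cur] = [
            grams_per_day(f, q, grams_per_drink)
            for f, q in zip(sub["frequency"], sub["quantity"])
        ]
        hed[cur] = [
            hed_status(s, q, h)
            for s, q, h in zip(sub["sex"], sub["quantity"], sub["hed_frequency"])
        ]
    df["grams_per_day"] = gpd
    df["hed"] = hed
    return df


# --- stratum-level estimation ------------------------------------------------


def weighted_prevalence(survey: pd.DataFrame, sex: str, age_group: str
                        ) -> tuple[float, float, float, float]:
    """Survey-weighted (p_abstainer, p_former, p_current, p_hed) for a stratum.

    p_hed is the weighted share of HED status among current drinkers.
    Requires the columns added by :func:`classify_survey`.
    """
    sub = survey[(survey["sex"] == sex) & (survey["age_group"] == age_group)]
    sub = sub[sub["weight"] > 0]
    if len(sub) == 0:
        raise ValueError(f"no respondents with positive weight in stratum "
                         f"({sex}, {age_group})")
    w = sub["weight"].to_numpy(float)
    total = w.sum()
    shares = {
        s: float(w[(sub["status"] == s).to_numpy()].sum() / total)
        for s in (ABSTAINER, FORMER, CURRENT)
    }
    cur = (sub["status"] == CURRENT).to_numpy()
    if cur.any():
        wc = w[cur]
        p_hed = float(wc[sub.loc[cur, "hed"].to_numpy(bool)].sum() / wc.sum())
    else:
        p_hed = 0.0
    return shares[ABSTAINER], shares[FORMER], shares[CURRENT], p_hed


def calibrate(grams: np.ndarray, weights: np.ndarray, frame_weight_total: float,
              benchmark_litres: float, coverage: float = 1.0
              ) -> tuple[np.ndarray, float]:
    """Rescale per-drinker grams/day to match a per-capita benchmark.

    ``frame_weight_total`` is the weight sum over the whole population frame
    (drinkers and non-drinkers), so that sum(w*g)/frame_weight_total is the
    survey-implied per-capita grams/day.  The multiplicative factor

        f = coverage * benchmark (as grams/day per capita) / survey per-capita

    is applied to every drinker; calibration is therefore exactly
    multiplicative and ratio-preserving.  Returns (calibrated values, f).
    """
    if benchmark_litres <= 0:
        raise ValueError("benchmark must be positive")
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage={coverage!r} outside (0, 1]")
    grams = np.asarray(grams, float)
    weights = np.asarray(weights, float)
    implied = float((weights * grams).sum() / frame_weight_total)
    if implied <= 0:
        raise ValueError("survey-implied per-capita consumption is zero; "
                         "cannot calibrate against a positive benchmark")
    target = coverage * litres_per_year_to_grams_per_day(benchmark_litres)
    factor = target / implied
    return grams * factor, factor


# --- gamma smoothing ---------------------------------------------------------

MIN_POSITIVE_OBS = 10


def _fit_gamma_from_stats(mean, meanlog):
    """Gamma MLE from (weighted) sufficient statistics; vectorized.

    Solves log(k) - digamma(k) = log(mean) - meanlog by Newton's method,
    then scale = mean / k.  Inputs may be scalars or arrays.
    """
    mean = np.asarray(mean, float)
    meanlog = np.asarray(meanlog, float)
    s = np.log(mean) - meanlog
    with np.errstate(all="ignore"):
        k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        for _ in range(40):
            g = np.log(k) - special.digamma(k) - s
            gp = 1.0 / k - special.polygamma(1, k)
            step = g / gp
            k_new = k - step
            k = np.where(k_new > 0, k_new, k / 2.0)
    ok = np.isfinite(k) & (k > 0) & (s > 0)
    return k, mean / np.where(ok, k, 1.0), ok


def fit_gamma(values, weights=None, cap: float | None = None
              ) -> tuple[float, float]:
    """Weighted maximum-likelihood gamma fit, (shape, scale) in grams/day.

    With ``cap`` set, the likelihood is that of the gamma truncated and
    renormalized on (0, cap] — the consumption model used downstream — so
    parameters remain consistent when the data themselves are capped.  The
    untruncated profile likelihood (solved by Newton iteration) provides
    the plain fit and the truncated fit's starting point; if fitting fails
    (or the data are degenerate) a weighted method-of-moments fit is used
    with a logged warning.  Requires at least 10 strictly positive
    observations.
    """
    values = np.asarray(values, float)
    w = np.ones_like(values) if weights is None else np.asarray(weights, float)
    finite = np.isfinite(values)
    values, w = values[finite], w[finite]
    pos = values > 0
    if int(pos.sum()) < MIN_POSITIVE_OBS:
        raise ValueError(
            f"need at least {MIN_POSITIVE_OBS} strictly positive values to "
            f"fit a gamma distribution, got {int(pos.sum())}"
        )
    x, w = values[pos], w[pos]
    w = w / w.sum()
    mean = float((w * x).sum())
    meanlog = float((w * np.log(x)).sum())
    k, th, ok = _fit_gamma_from_stats(mean, meanlog)
    if not bool(ok):
        var = float((w * (x - mean) ** 2).sum())
        if var <= 0:
            logger.warning("degenerate (zero-variance) consumption values; "
                           "method-of-moments scale collapses to 0")
            return float("inf"), 0.0
        logger.warning("gamma MLE failed; falling back to method of moments")
        return mean * mean / var, var / mean
    if cap is None:
        return float(k), float(th)

    from scipy import optimize, stats as _st

    def nll(params):
        lk, lth = params
        kk, tt = math.exp(lk), math.exp(lth)
        logz = _st.gamma.logcdf(cap, kk, scale=tt)
        return -((kk - 1.0) * meanlog - mean / tt
                 - special.gammaln(kk) - kk * lth - logz)

    res = optimize.minimize(nll, [math.log(k), math.log(th)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12})
    if not res.success:
        logger.warning("truncated-gamma MLE did not converge; using the "
                       "untruncated fit")
        return float(k), float(th)
    return float(math.exp(res.x[0])), float(math.exp(res.x[1]))


def estimate_exposures(survey: pd.DataFrame, benchmark_litres: float,
                       coverage: float = 1.0,
                       grams_per_drink: float = GRAMS_PER_DRINK,
                       cap: float = CONSUMPTION_CAP_G_PER_DAY,
                       year: int | None = None,
                       age_groups=AGE_GROUPS) -> list[ExposureDistribution]:
    """Full exposure estimation for one survey wave.

    Classifies respondents, converts items to grams/day, applies the
    per-capita benchmark calibration across the whole wave, then fits one
    gamma per sex-age stratum.  Strata with too few positive observations
    borrow the same-sex adjacent age group's gamma (logged warning).
    """
    df = classify_survey(survey, grams_per_drink)
    cur = df["status"] == CURRENT
    grams = df.loc[cur, "grams_per_day"].to_numpy(float)
    wts = df.loc[cur, "weight"].to_numpy(float)
    frame_total = float(df["weight"].sum())
    calibrated, factor = calibrate(grams, wts, frame_total,
                                   benchmark_litres, coverage)
    df.loc[cur, "grams_per_day"] = calibrated

    fits: dict[tuple, tuple[float, float] | None] = {}
    meta: dict[tuple, dict] = {}
    for sex in sorted(df["sex"].unique()):
        for group in age_groups:
            sub = df[(df["sex"] == sex) & (df["age_group"] == group)]
            if len(sub) == 0:
                fits[(sex, group)] = None
                continue
            p_abs, p_form, p_cur, p_hed = weighted_prevalence(df, sex, group)
            d = sub[(sub["status"] == CURRENT) & (sub["grams_per_day"] > 0)]
            try:
                shape, scale = fit_gamma(d["grams_per_day"], d["weight"],
                                         cap=cap)
            except ValueError:
                logger.warning("stratum (%s, %s): too few positive values; "
                               "borrowing adjacent age group", sex, group)
                shape = scale = None
            fits[(sex, group)] = (shape, scale)
            meta[(sex, group)] = dict(
                p_abstainer=p_abs, p_former=p_form, p_current=p_cur,
                p_hed=p_hed, n_respondents=len(sub), n_drinkers=len(d),
            )

    out: list[ExposureDistribution] = []
    for sex in sorted(df["sex"].unique()):
        for gi, group in enumerate(age_groups):
            entry = fits.get((sex, group))
            if entry is None:
                continue
            shape, scale = entry
            if shape is None:
                # borrow the nearest same-sex age group with a successful fit
                for other in sorted(range(len(age_groups)),
                                    key=lambda j: abs(j - gi)):
                    alt = fits.get((sex, age_groups[other]))
                    if alt is not None and alt[0] is not None:
                        shape, scale = alt
                        break
                else:
                    raise ValueError(f"no stratum with enough positive "
                                     f"consumption values for sex {sex!r}")
            m = meta[(sex, group)]
            out.append(ExposureDistribution(
                sex=sex, age_group=group, year=year, cap=cap,
                shape=shape, scale=scale, calibration_factor=factor, **m,
            ))
    return out


def carry_forward_oldest(exposures: list[ExposureDistribution],
                         age_groups=AGE_GROUPS) -> list[ExposureDistribution]:
    """Fill age groups above the survey ceiling from the oldest surveyed group.

    For each (sex, year), any analysis age group missing from ``exposures``
    that is older than the oldest surveyed group receives a copy of that
    group's distribution with ``imputed=True``.  Present strata pass through
    unchanged.
    """
    order = {g: i for i, g in enumerate(age_groups)}
    by_sy: dict[tuple, dict[str, ExposureDistribution]] = {}
    for e in exposures:
        by_sy.setdefault((e.sex, e.year), {})[e.age_group] = e
    out = list(exposures)
    for (sex, yr), groups in by_sy.items():
        oldest = max(groups, key=lambda g: order[g])
        for g in age_groups:
            if g not in groups and order[g] > order[oldest]:
                src = groups[oldest]
                out.append(replace(src, age_group=g, imputed=True))
    return out


def exposures_to_frame(exposures: list[ExposureDistribution]) -> pd.DataFrame:
    """Serialize exposures to a flat table (inverse of frame_to_exposures)."""
    return pd.DataFrame([{
        "year": e.year, "sex": e.sex, "age_group": e.age_group,
        "p_abstainer": e.p_abstainer, "p_former": e.p_former,
        "p_current": e.p_current, "p_hed": e.p_hed,
        "shape": e.shape, "scale": e.scale, "cap": e.cap,
        "calibration_factor": e.calibration_factor, "imputed": e.imputed,
        "n_respondents": e.n_respondents, "n_drinkers": e.n_drinkers,
    } for e in exposures])


def frame_to_exposures(df: pd.DataFrame) -> list[ExposureDistribution]:
    out = []
    for _, r in df.iterrows():
        year = r.get("year")
        out.append(ExposureDistribution(
            sex=r["sex"], age_group=r["age_group"],
            year=None if pd.isna(year) else int(year),
            p_abstainer=float(r["p_abstainer"]), p_former=float(r["p_former"]),
            p_current=float(r["p_current"]), p_hed=float(r["p_hed"]),
            shape=float(r["shape"]), scale=float(r["scale"]),
            cap=float(r["cap"]),
            calibration_factor=float(r["calibration_factor"]),
            imputed=bool(r["imputed"]),
            n_respondents=None if pd.isna(r.get("n_respondents")) else int(r["n_respondents"]),
            n_drinkers=None if pd.isna(r.get("n_drinkers")) else int(r["n_drinkers"]),
        ))
    return out
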