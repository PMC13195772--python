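"""Monte Carlo propagation of exposure and relative-risk uncertainty.

Each iteration jointly redraws (i) drinker-status shares from a multinomial
with the stratum's effective sample size (binomial marginals for the former
and current proportions), (ii) the gamma consumption parameters by
parametric bootstrap — simulate an effective-sample of consumption values
from the fitted gamma and refit — and (iii) relative-risk coefficients from
a (multivariate) normal on the log-RR scale, then recomputes the AAF.
Percentile intervals (2.5/97.5 by default) summarize the draws.  Coefficient
draws are shared across strata within an iteration (one coherent risk curve
per function per iteration), and all derived quantities (attributable
counts, rates) are transformed per-iteration from the same draw matrix
before percentiles are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aaf import compute_aaf_for_cause, make_grid
from .constants import HED_INTEGRATION_THRESHOLD_G
from .exposure import ExposureDistribution, _fit_gamma_from_stats
from .rr import FULLY, RRFunction, RRRegistry

DEFAULT_ITERATIONS = 10_000


@dataclass
class SimulationSpec:
    """Controls for the Monte Carlo simulation."""

    n_iterations: int = DEFAULT_ITERATIONS
    seed: int = 0
    perturb_prevalence: bool = True
    perturb_consumption: bool = True
    perturb_rr: bool = True
    #: fallback effective sample size when an exposure lacks respondent counts
    default_effective_n: int = 1000
    grid_size: int = 1501

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def effective_n(self, exposure: ExposureDistribution) -> int:
        return int(exposure.n_respondents or self.default_effective_n)

    def effective_n_drinkers(self, exposure: ExposureDistribution) -> int:
        if exposure.n_drinkers:
            return int(exposure.n_drinkers)
        return max(2, int(round(self.effective_n(exposure)
                                * exposure.p_current)))


def draw_prevalence(p: float, n: int, rng: np.random.Generator,
                    size: int | None = None):
    """Binomial(n, p)/n draw(s) of a proportion."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p!r} outside [0, 1]")
    if n < 1:
        raise ValueError("effective sample size must be >= 1")
    out = rng.binomial(n, p, size=size) / n
    return float(out) if size is None else out


def draw_consumption(shape: float, scale: float, n: int,
                     rng: np.random.Generator, size: int | None = None,
                     max_retries: int = 5):
    """Parametric-bootstrap draw(s) of gamma (shape, scale).

    Simulates ``n`` consumption values from gamma(shape, scale), refits by
    MLE, and returns the refitted parameters; vectorized over ``size``
    iterations.  Refit failures are retried on fresh draws a bounded number
    of times.
    """
    m = 1 if size is None else size
    k_out = np.empty(m)
    th_out = np.empty(m)
    todo = np.arange(m)
    for _ in range(max_retries + 1):
        draws = rng.gamma(shape, scale, size=(todo.size, n))
        mean = draws.mean(axis=1)
        meanlog = np.log(draws).mean(axis=1)
        k, th, ok = _fit_gamma_from_stats(mean, meanlog)
        k, th, ok = np.atleast_1d(k), np.atleast_1d(th), np.atleast_1d(ok)
        k_out[todo[ok]] = k[ok]
        th_out[todo[ok]] = th[ok]
        todo = todo[~ok]
        if todo.size == 0:
            break
    else:
        raise RuntimeError(f"gamma refit failed for {todo.size} bootstrap "
                           f"iterations after {max_retries} retries")
    if size is None:
        return float(k_out[0]), float(th_out[0])
    return k_out, th_out


def percentile_ci(draws, lower: float = 2.5,
                  upper: float = 97.5) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation."""
    draws = np.asarray(draws, float)
    if draws.size == 0:
        raise ValueError("cannot take percentiles of zero draws")
    lo, hi = np.percentile(draws, [lower, upper], method="linear")
    return float(lo), float(hi)


def _rr_matrix(fn: RRFunction, coefs: np.ndarray, x: np.ndarray) -> np.ndarray:
    """RR(x) for every coefficient draw: (n_iter, len(beta)) -> (n_iter, m)."""
    if fn.form == "constant":
        return np.exp(coefs[:, :1]) * np.ones_like(x)[None, :]
    if fn.form == "log-linear":
        return np.exp(coefs[:, :1] * x[None, :])
    return np.exp(coefs[:, :1] * x[None, :] + coefs[:, 1:2] * x[None, :] ** 2)


def _trapz_matrix(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.trapezoid(y, x, axis=-1)


def simulate_aafs(exposures: list[ExposureDistribution],
                  registry: RRRegistry,
                  spec: SimulationSpec) -> dict[tuple, np.ndarray]:
    """Joint AAF draws for every stratum x cause.

    Returns {(sex, age_group, year, cause): array of n_iterations draws}.
    Independent substreams are derived per RR function and per stratum from
    the master seed; fully attributable causes have constant draws of 1.
    """
    n_it = spec.n_iterations
    master = np.random.SeedSequence(spec.seed)
    ss_fn, ss_strata = master.spawn(2)

    fn_keys = sorted((f.cause, f.sex, f.age_group, f.group)
                     for f in registry.functions)
    coef_draws: dict[tuple, np.ndarray] = {}
    for key, child in zip(fn_keys, ss_fn.spawn(len(fn_keys))):
        fn = registry._index[key]
        if spec.perturb_rr:
            coef_draws[key] = fn.draw_coefficients(
                np.random.default_rng(child), size=n_it)
        else:
            coef_draws[key] = np.tile(np.asarray(fn.beta, float), (n_it, 1))

    def draws_for(fn: RRFunction) -> np.ndarray:
        return coef_draws[(fn.cause, fn.sex, fn.age_group, fn.group)]

    x = make_grid(exposures[0].cap if exposures else 150.0, spec.grid_size)
    idx = int(np.searchsorted(x, HED_INTEGRATION_THRESHOLD_G))
    results: dict[tuple, np.ndarray] = {}
    exp_sorted = sorted(exposures, key=lambda e: (str(e.sex), str(e.age_group),
                                                  str(e.year)))
    for e, child in zip(exp_sorted, ss_strata.spawn(len(exp_sorted))):
        rng = np.random.default_rng(child)
        n_eff = spec.effective_n(e)
        if spec.perturb_prevalence:
            counts = rng.multinomial(
                n_eff, [e.p_abstainer, e.p_former, e.p_current], size=n_it)
            shares = counts / n_eff
            p_form_d, p_cur_d = shares[:, 1], shares[:, 2]
            n_hed = spec.effective_n_drinkers(e)
            p_hed_d = rng.binomial(n_hed, e.p_hed, size=n_it) / n_hed
        else:
            p_form_d = np.full(n_it, e.p_former)
            p_cur_d = np.full(n_it, e.p_current)
            p_hed_d = np.full(n_it, e.p_hed)
        if spec.perturb_consumption:
            k_d, th_d = draw_consumption(e.shape, e.scale,
                                         spec.effective_n_drinkers(e),
                                         rng, size=n_it)
        else:
            k_d = np.full(n_it, e.shape)
            th_d = np.full(n_it, e.scale)

        # truncated-gamma density matrix (n_iter, grid)
        z = stats.gamma.cdf(e.cap, k_d, scale=th_d)
        with np.errstate(divide="ignore", invalid="ignore"):
            pdf = stats.gamma.pdf(x[None, :], k_d[:, None],
                                  scale=th_d[:, None]) / z[:, None]
        pdf = np.where(np.isfinite(pdf), pdf, 0.0)
        pos = x > 0
        mass_lo = stats.gamma.cdf(HED_INTEGRATION_THRESHOLD_G, k_d,
                                  scale=th_d) / z
        mass_hi = 1.0 - mass_lo

        def seg_integral(fn, mass, seg):
            """pdf * (RR - 1) over a segment; constant RR uses the mass."""
            coefs = draws_for(fn)
            if fn.form == "constant":
                return (np.exp(coefs[:, 0]) - 1.0) * mass
            ex = np.where(pos[None, seg],
                          _rr_matrix(fn, coefs, x[seg]) - 1.0, 0.0)
            return _trapz_matrix(pdf[:, seg] * ex, x[seg])

        for cause, entry in registry.causes.items():
            if entry.attribution == FULLY:
                results[(e.sex, e.age_group, e.year, cause)] = np.ones(n_it)
                continue
            fns = registry.functions_for(cause, e.sex, e.age_group)
            former_fn = fns["former"]
            rr_form = np.exp(draws_for(former_fn)[:, 0])
            former = p_form_d * (rr_form - 1.0)
            if entry.hed_stratified:
                lo = slice(0, idx + 1)
                hi = slice(idx, None)
                cur = p_cur_d * (
                    (1.0 - p_hed_d) * seg_integral(fns["current_non_hed"],
                                                   mass_lo, lo)
                    + p_hed_d * seg_integral(fns["current_hed"], mass_lo, lo)
                    + seg_integral(fns["current_hed"], mass_hi, hi)
                )
            else:
                cur = p_cur_d * seg_integral(fns["current"], 1.0,
                                             slice(None))
            n = former + cur
            results[(e.sex, e.age_group, e.year, cause)] = n / (n + 1.0)
    return results


def summarize_aaf_draws(draws: dict[tuple, np.ndarray],
                        exposures: list[ExposureDistribution],
                        registry: RRRegistry,
                        spec: SimulationSpec) -> pd.DataFrame:
    """Point AAFs (deterministic recomputation) with percentile CIs."""
    by_key = {(e.sex, e.age_group, e.year): e for e in exposures}
    rows = []
    for (sex, ag, year, cause), d in draws.items():
        est = compute_aaf_for_cause(by_key[(sex, ag, year)], cause, registry,
                                    spec.grid_size)
        lo, hi = percentile_ci(d)
        rows.append({"year": year, "sex": sex, "age_group": ag,
                     "cause": cause, "aaf": est.aaf, "aaf_lo95": lo,
                     "aaf_hi95": hi, "n_iter": spec.n_iterations,
                     "seed": spec.seed})
    return pd.DataFrame(rows)


def attributable_draws(draws: dict[tuple, np.ndarray],
                       counts: pd.DataFrame,
                       registry: RRRegistry) -> dict[tuple, np.ndarray]:
    """Per-iteration attributable-death draws per (year, sex, age_group).

    Reuses the AAF draw matrix so dependence is preserved; sums across
    causes within each iteration.  Fully attributable causes contribute
    their full count.
    """
    n_it = len(next(iter(draws.values())))
    out: dict[tuple, np.ndarray] = {}
    for _, row in counts.iterrows():
        key = (row["sex"], row["age_group"], row["year"])
        cell = draws.get((row["sex"], row["age_group"], row["year"],
                          row["cause"]))
        if cell is None:
            entry = registry.causes.get(row["cause"])
            if entry is not None and entry.attribution == FULLY:
                cell = np.ones(n_it)
            else:
                raise ValueError(f"no AAF draws for cell "
                                 f"{tuple(row[k] for k in ('year', 'sex', 'age_group', 'cause'))}")
        out.setdefault(key, np.zeros(n_it))
        out[key] = out[key] + cell * float(row["deaths"])
    return out
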