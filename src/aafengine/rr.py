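"""Parametric relative-risk registry.

Relative-risk (RR) curves map daily pure-alcohol intake (grams/day) to
mortality risk relative to lifetime abstention, per cause of death, sex,
age group and drinker group.  Coefficients live on the log-RR scale and
carry a covariance matrix so Monte Carlo draws can propagate meta-analytic
uncertainty.  Curves are loaded from a YAML/JSON configuration; the package
ships an ILLUSTRATIVE parameter set (``data/illustrative_rr.yaml``) whose
magnitudes are plausible for the comparative-risk literature but are not a
published meta-analysis — substitute published coefficient tables for any
substantive use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

FORMS = {"constant": 1, "log-linear": 1, "log-quadratic": 2}
DRINKER_GROUPS = ("former", "current", "current_non_hed", "current_hed")
FULLY = "fully_attributable"
PARTIALLY = "partially_attributable"


@dataclass(frozen=True)
class RRFunction:
    """One relative-risk curve for a cause/sex/age-group/drinker-group cell.

    ``sex`` and ``age_group`` may be the wildcard ``"all"``.
    """

    cause: str
    sex: str
    age_group: str
    group: str
    form: str
    beta: tuple[float, ...]
    cov: tuple[tuple[float, ...], ...]
    max_dose: float = 150.0

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown RR functional form {self.form!r}")
        if self.group not in DRINKER_GROUPS:
            raise ValueError(f"unknown drinker group {self.group!r}")
        if len(self.beta) != FORMS[self.form]:
            raise ValueError(
                f"form {self.form!r} needs {FORMS[self.form]} coefficient(s), "
                f"got {len(self.beta)} ({self.cause}/{self.group})"
            )
        c = np.asarray(self.cov, float)
        if c.shape != (len(self.beta), len(self.beta)):
            raise ValueError(f"covariance shape {c.shape} does not match "
                             f"{len(self.beta)} coefficient(s)")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError(f"covariance not symmetric for {self.cause}/"
                             f"{self.group}")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError(f"covariance not positive semi-definite for "
                             f"{self.cause}/{self.group}")

    def evaluate(self, x) -> np.ndarray | float:
        """RR at grams/day ``x`` (scalar or array); RR(0)=1 for current forms."""
        x = np.asarray(x, float)
        if np.any(x < 0):
            raise ValueError("consumption must be non-negative")
        b = self.beta
        if self.form == "constant":
            out = np.full_like(x, np.exp(b[0]))
        elif self.form == "log-linear":
            out = np.exp(b[0] * x)
        else:
            out = np.exp(b[0] * x + b[1] * x * x)
        return float(out) if out.ndim == 0 else out

    def draw_coefficients(self, rng: np.random.Generator,
                          size: int | None = None) -> np.ndarray:
        """Draw coefficient vectors from N(beta, cov) on the log-RR scale.

        A zero covariance returns the point coefficients exactly.  Shape is
        (len(beta),) for size=None, else (size, len(beta)).
        """
        beta = np.asarray(self.beta, float)
        cov = np.asarray(self.cov, float)
        n = 1 if size is None else size
        if np.all(cov == 0):
            draws = np.tile(beta, (n, 1))
        else:
            draws = rng.multivariate_normal(beta, cov, size=n,
                                            method="svd")
        return draws[0] if size is None else draws


@dataclass(frozen=True)
class CauseEntry:
    """A cause-of-death category in the catalog."""

    name: str
    icd10: tuple[str, ...]
    attribution: str  # fully_attributable | partially_attributable
    hed_stratified: bool = False

    def __post_init__(self) -> None:
        if self.attribution not in (FULLY, PARTIALLY):
            raise ValueError(f"unknown attribution type {self.attribution!r} "
                             f"for cause {self.name!r}")


class RRRegistry:
    """Cause catalog plus the RR functions covering it."""

    def __init__(self, causes: list[CauseEntry], functions: list[RRFunction],
                 sexes=("male", "female"), age_groups=None):
        from .constants import AGE_GROUPS
        self.causes = {c.name: c for c in causes}
        self.functions = list(functions)
        self._index: dict[tuple, RRFunction] = {}
        for f in functions:
            key = (f.cause, f.sex, f.age_group, f.group)
            if key in self._index:
                raise ValueError(f"duplicate RR function for {key}")
            self._index[key] = f
        self.sexes = tuple(sexes)
        self.age_groups = tuple(age_groups or AGE_GROUPS)
        self._validate()

    # -- validation ----------------------------------------------------------

    def _validate(self) -> None:
        self._check_code_overlap()
        missing = []
        for c in self.causes.values():
            if c.attribution == FULLY:
                if any(f.cause == c.name for f in self.functions):
                    raise ValueError(f"fully attributable cause {c.name!r} "
                                     f"must not define RR functions")
                continue
            needed = ["former"]
            needed += (["current_non_hed", "current_hed"] if c.hed_stratified
                       else ["current"])
            for sex in self.sexes:
                for ag in self.age_groups:
                    for grp in needed:
                        if self.get_function(c.name, sex, ag, grp) is None:
                            missing.append((c.name, sex, ag, grp))
        if missing:
            raise ValueError(f"registry missing RR functions for: {missing}")

    def _check_code_overlap(self) -> None:
        from .attribution import expand_code_patterns
        prefixes: dict[str, str] = {}
        clashes = []
        for c in self.causes.values():
            for p in expand_code_patterns(c.icd10):
                for q, owner in prefixes.items():
                    if owner != c.name and (p.startswith(q) or q.startswith(p)):
                        clashes.append((p, c.name, q, owner))
                prefixes[p] = c.name
        if clashes:
            raise ValueError(f"overlapping ICD-10 codes across causes: {clashes}")

    # -- lookup --------------------------------------------------------------

    def get_function(self, cause: str, sex: str, age_group: str,
                     group: str) -> RRFunction | None:
        """Resolve a function, preferring exact sex/age over the 'all' wildcard."""
        for s in (sex, "all"):
            for a in (age_group, "all"):
                f = self._index.get((cause, s, a, group))
                if f is not None:
                    return f
        return None

    def functions_for(self, cause: str, sex: str, age_group: str
                      ) -> dict[str, RRFunction]:
        entry = self.causes[cause]
        if entry.attribution == FULLY:
            return {}
        groups = ["former"] + (["current_non_hed", "current_hed"]
                               if entry.hed_stratified else ["current"])
        out = {}
        for g in groups:
            f = self.get_function(cause, sex, age_group, g)
            if f is None:
                raise KeyError(f"no RR function for {cause}/{sex}/"
                               f"{age_group}/{g}")
            out[g] = f
        return out

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"causes": {}}
        for c in self.causes.values():
            entry: dict = {
                "icd10": list(c.icd10),
                "attribution": c.attribution,
                "hed_stratified": c.hed_stratified,
                "functions": [],
            }
            for f in self.functions:
                if f.cause != c.name:
                    continue
                entry["functions"].append({
                    "sex": f.sex, "age_group": f.age_group, "group": f.group,
                    "form": f.form, "beta": list(f.beta),
                    "cov": [list(r) for r in f.cov], "max_dose": f.max_dose,
                })
            d["causes"][c.name] = entry
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RRRegistry":
        causes, functions = [], []
        for name, entry in d["causes"].items():
            causes.append(CauseEntry(
                name=name, icd10=tuple(entry["icd10"]),
                attribution=entry["attribution"],
                hed_stratified=bool(entry.get("hed_stratified", False)),
            ))
            for f in entry.get("functions", []):
                functions.append(RRFunction(
                    cause=name, sex=f["sex"], age_group=f["age_group"],
                    group=f["group"], form=f["form"],
                    beta=tuple(float(b) for b in f["beta"]),
                    cov=tuple(tuple(float(v) for v in row) for row in f["cov"]),
                    max_dose=float(f.get("max_dose", 150.0)),
                ))
        return cls(causes, functions)


def load_registry(path) -> RRRegistry:
    """Load and validate an RR registry from a YAML or JSON config file."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return RRRegistry.from_dict(d)


def illustrative_registry() -> RRRegistry:
    """The shipped illustrative (non-canonical) registry."""
    with resources.files("aafengine.data").joinpath(
            "illustrative_rr.yaml").open() as fh:
        return RRRegistry.from_dict(yaml.safe_load(fh))
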