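import numpy as np
import pytest

from aafengine.exposure import ExposureDistribution
from aafengine.rr import CauseEntry, RRFunction, RRRegistry, illustrative_registry


@pytest.fixture(scope="session")
def registry():
    return illustrative_registry()


def make_fn(cause="x", sex="all", age_group="all", group="current",
            form="log-linear", beta=(0.01,), cov=None):
    """Shorthand RRFunction constructor with zero covariance by default."""
    if cov is None:
        p = len(beta)
        cov = tuple(tuple(0.0 for _ in range(p)) for _ in range(p))
    return RRFunction(cause=cause, sex=sex, age_group=age_group, group=group,
                      form=form, beta=tuple(beta), cov=cov)


def make_exposure(p_former=0.0, p_current=0.5, shape=2.0, scale=10.0,
                  p_hed=0.3, **kw):
    return ExposureDistribution(
        sex=kw.pop("sex", "male"), age_group=kw.pop("age_group", "30-44"),
        p_abstainer=1.0 - p_former - p_current, p_former=p_former,
        p_current=p_current, shape=shape, scale=scale, p_hed=p_hed, **kw)


def constant_registry(rr_current=1.0, rr_former=1.0, hed=False,
                      icd10=("K74",), cause="testcause"):
    """One-cause registry with constant (possibly unit) relative risks."""
    fns = [make_fn(cause=cause, group="former", form="constant",
                   beta=(np.log(rr_former),))]
    if hed:
        for grp in ("current_non_hed", "current_hed"):
            fns.append(make_fn(cause=cause, group=grp, form="log-linear",
                               beta=(np.log(rr_current) / 100.0,)))
    else:
        fns.append(make_fn(cause=cause, group="current", form="constant",
                           beta=(np.log(rr_current),)))
    return RRRegistry(
        [CauseEntry(name=cause, icd10=icd10,
                    attribution="partially_attributable", hed_stratified=hed)],
        fns)
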