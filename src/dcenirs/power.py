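"""Noncentral-F power analysis for the within-between interaction.

Post-hoc power and a-priori sample size for the time x group interaction of a
repeated-measures design with ``g`` groups and ``m`` repeated measurements,
given an effect size as partial eta-squared.  Two noncentrality conventions
in common use by G*Power-style calculators are implemented and always
reported side by side, because published analyses rarely state which options
were active:

* ``gpower_default``: the effect size lives on the total-variance metric and
  the noncentrality absorbs the assumed correlation rho among repeated
  measures, lambda = f^2 * N * m / (1 + (m-1) rho) * eps;
* ``spss_etasq``: partial eta-squared is taken as already error-scaled
  (as SPSS defines it), lambda = f^2 * N * eps;

with f^2 = eta_p^2 / (1 - eta_p^2), df1 = (g-1)(m-1) eps and
df2 = (N-g)(m-1) eps, where eps is a nonsphericity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .dtof import InputError

CONVENTIONS = ("gpower_default", "spss_etasq")


@dataclass
class PowerSpec:
    partial_eta_sq: float
    n_total: int
    n_groups: int = 2
    n_measurements: int = 6
    alpha: float = 0.05
    corr_rep_measures: float = 0.5
    nonsphericity_eps: float = 1.0
    convention: str = "gpower_default"

    def __post_init__(self):
        if not 0 <= self.partial_eta_sq < 1:
            raise InputError("partial eta-squared must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")
        if self.n_total <= self.n_groups:
            raise InputError("total N must exceed the number of groups")
        if not 0 <= self.corr_rep_measures < 1:
            raise InputError("repeated-measures correlation must lie in [0, 1)")
        if self.convention not in CONVENTIONS:
            raise InputError(f"convention must be one of {CONVENTIONS}")


@dataclass
class PowerResult:
    power: float
    noncentrality: float
    df1: float
    df2: float
    f_crit: float
    f_squared: float
    convention: str


def _noncentrality(spec: PowerSpec) -> tuple[float, float, float, float]:
    f2 = spec.partial_eta_sq / (1.0 - spec.partial_eta_sq)
    g, m, N = spec.n_groups, spec.n_measurements, spec.n_total
    eps = spec.nonsphericity_eps
    df1 = (g - 1) * (m - 1) * eps
    df2 = (N - g) * (m - 1) * eps
    if spec.convention == "gpower_default":
        lam = f2 * N * m / (1.0 + (m - 1) * spec.corr_rep_measures) * eps
    else:
        lam = f2 * N * eps
    return f2, lam, df1, df2


def interaction_power(spec: PowerSpec) -> PowerResult:
    """Power of the within-between interaction F test for one convention."""
    f2, lam, df1, df2 = _noncentrality(spec)
    f_crit = float(stats.f.isf(spec.alpha, df1, df2))
    power = float(stats.ncf.sf(f_crit, df1, df2, lam)) if lam > 0 else spec.alpha
    return PowerResult(power, lam, df1, df2, f_crit, f2, spec.convention)


def interaction_power_both(spec: PowerSpec) -> dict:
    """Power under both conventions (always report both)."""
    return {c: interaction_power(replace(spec, convention=c)) for c in CONVENTIONS}


def required_n(spec: PowerSpec, target_power: float, n_max: int = 100000) -> dict:
    """Smallest total N reaching ``target_power``, per convention.

    ``spec.n_total`` is ignored (any valid placeholder works).  Raises if the
    target is not reachable below ``n_max``.
    """
    if not spec.alpha < target_power < 1:
        raise InputError("target power must lie in (alpha, 1)")
    out = {}
    for conv in CONVENTIONS:
        found = None
        for N in range(spec.n_groups + 1, n_max + 1):
            s = replace(spec, n_total=N, convention=conv)
            if interaction_power(s).power >= target_power:
                found = N
                break
        if found is None:
            raise InputError(
                f"target power {target_power} unreachable below N={n_max} under "
                f"{conv}: the effect size may be too small"
            )
        out[conv] = found
    return out
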