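"""Regimen metrics derived from the fractionated two-population model.

Given a Hill viability curve and growth rates for sensitive/resistant
populations, this module computes:

* exhaustive dose sweeps with the "Gain" of an n-dose regimen relative to a
  single dose at the same cumulative dose (for total cells and for the
  resistant fraction);
* the crossover dose x* solving V(x/n)^n = V(x), below which fractionation
  spares more sensitive cells than one bolus and above which it kills more;
* the critical concentration at which the treated colony ends up half
  resistant, half sensitive;
* the collateral trade-off of fractionation on a healthy cell line with its
  own (much lower) EC50.

Root-finding is by bisection: sensitive survival is monotone in dose, so a
bracket with a sign change guarantees the root.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .dose_response import HillParams, viability
from .dynamics import (
    DosingRegimen,
    GrowthParams,
    PopulationState,
    fraction_resistant,
    simulate_regimen,
)

__all__ = [
    "NoCrossoverError",
    "UnreachableCriticalDoseError",
    "dose_sweep",
    "crossover_dose",
    "critical_concentration",
    "collateral_tradeoff",
]

#: Bisection bracket relative to ec50 and relative tolerance on the root.
BRACKET = (1e-6, 1e3)
ROOT_RTOL = 1e-9


class NoCrossoverError(RuntimeError):
    """No sign change of V(x/n)^n - V(x) on the search bracket."""


class UnreachableCriticalDoseError(RuntimeError):
    """No dose drives the final resistant fraction to one half."""


def dose_sweep(
    initial_states: Sequence[PopulationState],
    doses: Sequence[float],
    n_list: Sequence[int],
    growth: GrowthParams,
    curve: HillParams,
    gains: bool = True,
) -> pd.DataFrame:
    """Simulate every (initial state, dose, n) combination.

    Returns a long-format table with one row per combination: final
    sensitive/resistant counts, total, resistant fraction, and (when
    ``gains``) gain_total and gain_frac relative to the n = 1 row at the
    same dose and initial state.  Gains at n = 1 are exactly 1.
    """
    doses = np.asarray(doses, dtype=float)
    n_list = [int(n) for n in n_list]
    if doses.size == 0 or not n_list or not initial_states:
        raise ValueError("initial_states, doses and n_list must be non-empty")
    if gains and 1 not in n_list:
        raise ValueError("gains are relative to n=1; include 1 in n_list")

    rows = []
    for state in initial_states:
        for dose in doses:
            for n in n_list:
                final = simulate_regimen(
                    state, DosingRegimen(dose, n), growth, curve
                )
                rows.append(
                    {
                        "dose_uM": dose,
                        "n_doses": n,
                        "ns0": state.n_sensitive,
                        "nr0": state.n_resistant,
                        "ns_final": final.n_sensitive,
                        "nr_final": final.n_resistant,
                        "total": final.total,
                        "frac_resistant": fraction_resistant(final)
                        if final.total > 0
                        else np.nan,
                    }
                )
    df = pd.DataFrame(rows)
    if gains:
        key = ["ns0", "nr0", "dose_uM"]
        base = (
            df[df["n_doses"] == 1]
            .set_index(key)[["total", "frac_resistant"]]
            .rename(columns={"total": "_t1", "frac_resistant": "_f1"})
        )
        df = df.join(base, on=key)
        df["gain_total"] = df["total"] / df["_t1"]
        df["gain_frac"] = df["frac_resistant"] / df["_f1"]
        df = df.drop(columns=["_t1", "_f1"])
    return df


def crossover_dose(
    n: int,
    curve: HillParams,
    bracket: tuple = BRACKET,
    rtol: float = ROOT_RTOL,
) -> float:
    """Dose x* at which n fractions and one bolus kill equally: V(x/n)^n = V(x).

    Below x*, fractionation leaves more sensitive cells (gain_total > 1);
    above, fewer.  The resistant term e^{a_r} N_r is identical under both
    regimens, so x* is independent of the resistant population and its
    growth rate.  For h = 2, top = 1, bottom = 0, n = 2 the root is
    ec50 * sqrt(8) analytically.

    Raises :class:`NoCrossoverError` when the survival difference does not
    change sign on the bracket (e.g. h <= 1, where fractionation is never
    more lethal).
    """
    n = int(n)
    if n < 2:
        raise ValueError("crossover is defined for n >= 2")

    def log_survival_diff(x: float) -> float:
        return n * math.log(viability(x / n, curve)) - math.log(viability(x, curve))

    lo, hi = bracket[0] * curve.ec50, bracket[1] * curve.ec50
    f_lo, f_hi = log_survival_diff(lo), log_survival_diff(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise NoCrossoverError(
            f"V(x/{n})^{n} - V(x) has no sign change on "
            f"[{lo:.3g}, {hi:.3g}] uM (h={curve.hill_coeff})"
        )
    return float(bisect(log_survival_diff, lo, hi, rtol=rtol))


def critical_concentration(
    initial: PopulationState,
    growth: GrowthParams,
    curve: HillParams,
    n: int = 1,
    rtol: float = ROOT_RTOL,
) -> float:
    """Dose at which the treated population ends exactly half resistant.

    The final resistant fraction is monotone non-decreasing in dose, so the
    root is found by bisection.  If the population is already at least half
    resistant after an untreated interval, the critical dose is 0.  With no
    resistant cells, or a bottom plateau that keeps the sensitive majority
    at any dose, the fraction never reaches one half and
    :class:`UnreachableCriticalDoseError` is raised.

    For top = 1, bottom = 0, n = 1 the closed form is
    ec50 * ((Ns/Nr) * e^{a_s - a_r} - 1)^(1/h).
    """
    if initial.total <= 0:
        raise UnreachableCriticalDoseError("empty population")

    def excess(x: float) -> float:
        final = simulate_regimen(initial, DosingRegimen(x, int(n)), growth, curve)
        return fraction_resistant(final) - 0.5

    if initial.n_resistant == 0:
        raise UnreachableCriticalDoseError(
            "no resistant cells: fraction can never reach 0.5"
        )
    if excess(0.0) >= 0:
        return 0.0
    hi = curve.ec50
    for _ in range(60):
        if excess(hi) > 0:
            break
        hi *= 2.0
    else:
        raise UnreachableCriticalDoseError(
            "resistant fraction stays below 0.5 at all doses "
            f"(bottom plateau {curve.bottom} preserves sensitive cells)"
        )
    return float(bisect(excess, 0.0, hi, rtol=rtol, xtol=1e-12 * curve.ec50))


def collateral_tradeoff(
    tumor: PopulationState,
    tumor_growth: GrowthParams,
    tumor_curve: HillParams,
    healthy_curve: HillParams,
    healthy_growth: GrowthParams,
    regimen_list: Iterable[DosingRegimen],
    healthy_initial: float = 1.0,
) -> pd.DataFrame:
    """Tumor burden versus healthy-cell survival across regimens.

    Healthy tissue is modelled as a purely drug-sensitive population with
    its own Hill curve (e.g. EC50 ~60-fold below the tumor line's).  For
    each regimen the table reports the tumor totals, the healthy cell count
    and drug-only surviving fraction V_h(x/n)^n, and the signed relative
    difference (value(n) - value(1)) / value(1) against the single-dose
    regimen at the same cumulative dose.
    """
    regimens = list(regimen_list)
    if not regimens:
        raise ValueError("regimen list is empty")
    rows = []
    for reg in regimens:
        tum = simulate_regimen(tumor, reg, tumor_growth, tumor_curve)
        healthy_surv = viability(reg.per_dose, healthy_curve) ** reg.n_doses
        rows.append(
            {
                "cumulative_dose_uM": reg.cumulative_dose,
                "n_doses": reg.n_doses,
                "tumor_sensitive": tum.n_sensitive,
                "tumor_resistant": tum.n_resistant,
                "tumor_total": tum.total,
                "healthy_surviving_fraction": healthy_surv,
                "healthy_count": healthy_surv
                * math.exp(healthy_growth.a_sensitive)
                * healthy_initial,
            }
        )
    df = pd.DataFrame(rows)
    base = df[df["n_doses"] == 1].set_index("cumulative_dose_uM")
    missing = set(df["cumulative_dose_uM"]) - set(base.index)
    if missing:
        raise ValueError(
            f"no n=1 baseline regimen for cumulative dose(s) {sorted(missing)}"
        )
    for col, out in [
        ("tumor_total", "tumor_total_rel_diff"),
        ("healthy_count", "healthy_rel_diff"),
    ]:
        ref = df["cumulative_dose_uM"].map(base[col])
        df[out] = (df[col] - ref) / ref
    return df
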