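"""Hill dose-response model for chemosensitive cell viability.

Viability of drug-sensitive cells as a function of drug concentration is
modelled with a decreasing four-parameter Hill (logistic) curve

    V(x) = bottom + (top - bottom) / (1 + (x / ec50)**h)

where ``x`` is the concentration (uM), ``ec50`` the half-effect
concentration, ``h`` the Hill coefficient (steepness), and ``top`` /
``bottom`` the viability plateaus at zero and saturating dose.  The module
also normalises raw MTT plate readings (OD 570 nm signal minus OD 690 nm
background, scaled by untreated control wells) into viability fractions and
fits the Hill curve to replicate viability tables by nonlinear least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HillParams",
    "ViabilityTable",
    "HillFit",
    "InvalidPlateError",
    "FitConvergenceError",
    "UndefinedIC50Error",
    "viability",
    "normalize_mtt",
    "fit_hill",
    "ic50",
]


class InvalidPlateError(ValueError):
    """Raised when an MTT plate cannot be normalised (e.g. dead controls)."""


class FitConvergenceError(RuntimeError):
    """Raised when the Hill fit fails to converge; carries diagnostics."""


class UndefinedIC50Error(ValueError):
    """Raised when absolute 50% viability lies outside the curve plateaus."""


@dataclass(frozen=True)
class HillParams:
    """Parameters of a decreasing Hill viability curve.

    Parameters
    ----------
    ec50 : float
        Half-effect concentration (uM), strictly positive.
    hill_coeff : float
        Hill coefficient (dimensionless steepness), strictly positive.
    top : float
        Viability at zero dose, in (bottom, 1].  Default 1.
    bottom : float
        Viability asymptote at infinite dose, in [0, top).  Default 0.
    """

    ec50: float
    hill_coeff: float
    top: float = 1.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ec50) or self.ec50 <= 0:
            raise ValueError(f"ec50 must be finite and > 0, got {self.ec50}")
        if not np.isfinite(self.hill_coeff) or self.hill_coeff <= 0:
            raise ValueError(
                f"hill_coeff must be finite and > 0, got {self.hill_coeff}"
            )
        if not (0.0 <= self.bottom < self.top <= 1.0):
            raise ValueError(
                "plateaus must satisfy 0 <= bottom < top <= 1, got "
                f"bottom={self.bottom}, top={self.top}"
            )

    def __call__(self, x):
        return viability(x, self)

    def to_dict(self) -> dict:
        return {
            "ec50_uM": self.ec50,
            "hill_coeff": self.hill_coeff,
            "top": self.top,
            "bottom": self.bottom,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        return cls(
            ec50=float(d.get("ec50_uM", d.get("ec50"))),
            hill_coeff=float(d["hill_coeff"]),
            top=float(d.get("top", 1.0)),
            bottom=float(d.get("bottom", 0.0)),
        )


def viability(x, params: HillParams):
    """Evaluate the Hill viability curve V(x) at dose(s) ``x`` (uM).

    Returns a value in [bottom, top]; V(0) = top and V -> bottom as
    x -> infinity.  Negative doses are a domain error.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / params.ec50) ** params.hill_coeff, 0.0)
    v = params.bottom + (params.top - params.bottom) / (1.0 + ratio)
    # guard against 1-ulp excursions outside the plateaus
    v = np.clip(v, params.bottom, params.top)
    return float(v) if v.ndim == 0 else v


@dataclass
class ViabilityTable:
    """Long-format viability measurements: one (dose, viability) pair per well.

    Replicates appear as repeated doses.  Values are fractions, nominally in
    [0, ~1.2] to tolerate measurement noise above the untreated plateau.
    """

    dose: np.ndarray
    viability: np.ndarray
    od570: Optional[np.ndarray] = None
    od690: Optional[np.ndarray] = None
    is_control: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float).ravel()
        self.viability = np.asarray(self.viability, dtype=float).ravel()
        if self.dose.shape != self.viability.shape:
            raise ValueError("dose and viability must have equal length")
        if self.dose.size == 0:
            raise ValueError("empty viability table")
        if np.any(self.dose < 0):
            raise ValueError("doses must be >= 0")

    @property
    def distinct_doses(self) -> np.ndarray:
        return np.unique(self.dose)

    @classmethod
    def from_replicates(
        cls, doses: Sequence[float], replicate_matrix
    ) -> "ViabilityTable":
        """Build from a (n_doses, n_replicates) matrix of viability fractions."""
        doses = np.asarray(doses, dtype=float)
        mat = np.atleast_2d(np.asarray(replicate_matrix, dtype=float))
        if mat.shape[0] != doses.size:
            raise ValueError("replicate matrix rows must match doses")
        dose_col = np.repeat(doses, mat.shape[1])
        return cls(dose=dose_col, viability=mat.ravel())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"dose_uM": self.dose, "viability": self.viability})
        df["replicate"] = df.groupby("dose_uM").cumcount() + 1
        return df

    def to_csv(self, path) -> None:
        """Write the wide CSV dialect ``dose_uM, rep1, rep2, ...``."""
        wide = (
            self.to_frame()
            .pivot(index="dose_uM", columns="replicate", values="viability")
            .rename(columns=lambda k: f"rep{k}")
            .reset_index()
        )
        wide.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ViabilityTable":
        """Read either CSV dialect.

        Wide: columns ``dose_uM, rep1, rep2, ...`` of viability fractions.
        Raw: columns ``well, dose_uM, od570, od690, is_control`` of plate
        readings, normalised here via :func:`normalize_mtt`.
        """
        df = pd.read_csv(path_or_buf)
        cols = set(df.columns)
        if {"od570", "od690", "is_control"} <= cols:
            controls = np.flatnonzero(df["is_control"].astype(bool).to_numpy())
            return normalize_mtt(
                df["od570"].to_numpy(),
                df["od690"].to_numpy(),
                controls,
                doses=df["dose_uM"].to_numpy(),
            )
        rep_cols = [c for c in df.columns if c.startswith("rep")]
        if "dose_uM" not in cols or not rep_cols:
            raise ValueError(
                "CSV must have columns 'dose_uM, rep1, ...' or "
                "'well, dose_uM, od570, od690, is_control'"
            )
        long = df.melt(
            id_vars="dose_uM", value_vars=rep_cols, value_name="viability"
        ).dropna(subset=["viability"])
        return cls(
            dose=long["dose_uM"].to_numpy(), viability=long["viability"].to_numpy()
        )


def normalize_mtt(
    od570,
    od690,
    control_wells,
    doses=None,
) -> ViabilityTable:
    """Normalise raw MTT optical densities into viability fractions.

    Per-well signal is OD570 minus the OD690 background; viability is the
    signal divided by the mean signal of the (untreated) control wells, so
    control wells average to exactly 1.

    Parameters
    ----------
    od570, od690 : array-like
        Per-well readings at 570 nm (formazan) and 690 nm (background).
    control_wells : sequence of int
        Indices of the control wells (non-empty).
    doses : array-like, optional
        Per-well doses (uM).  Control wells default to dose 0 when omitted;
        other wells then get NaN doses, which blocks downstream fitting.
    """
    od570 = np.asarray(od570, dtype=float).ravel()
    od690 = np.asarray(od690, dtype=float).ravel()
    if od570.shape != od690.shape:
        raise ValueError("od570 and od690 must have equal length")
    control_wells = np.asarray(list(control_wells), dtype=int)
    if control_wells.size == 0:
        raise InvalidPlateError("control well set is empty")
    signal = od570 - od690
    control_mean = float(signal[control_wells].mean())
    if control_mean <= 0:
        raise InvalidPlateError(
            f"mean control signal {control_mean:.4g} <= 0; plate unusable"
        )
    viab = signal / control_mean
    if doses is None:
        doses = np.full(od570.shape, np.nan)
        doses[control_wells] = 0.0
    doses = np.asarray(doses, dtype=float).ravel()
    is_control = np.zeros(od570.shape, dtype=bool)
    is_control[control_wells] = True
    return ViabilityTable(
        dose=doses, viability=viab, od570=od570, od690=od690, is_control=is_control
    )


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill-curve fit: parameters plus goodness-of-fit."""

    params: HillParams
    rss: float
    n_points: int

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d["rss"] = self.rss
        return d


def _n_free(fixed_hill: Optional[float], fixed_plateaus: bool) -> int:
    n = 4
    if fixed_hill is not None:
        n -= 1
    if fixed_plateaus:
        n -= 2
    return n


def fit_hill(
    table: ViabilityTable,
    fixed_hill: Optional[float] = None,
    fixed_plateaus: bool = False,
    clip_negative: bool = False,
) -> HillFit:
    """Fit the Hill viability curve to a plate table by least squares.

    Unweighted nonlinear least squares on the viability scale.
    Initialisation: top = max(v), bottom = min(v), ec50 = dose whose mean
    viability is nearest the half-range, h = 1.  Bounds: h in (0, 10],
    ec50 in (0, 10 * max dose], plateaus in [0, 1].

    Parameters
    ----------
    fixed_hill : float, optional
        Fix the Hill coefficient at this value (e.g. 2).
    fixed_plateaus : bool
        Fix top = 1 and bottom = 0.
    clip_negative : bool
        Clip viability values to >= 0 before fitting.  Off by default:
        values above 1 or below 0 are noise and inform plateau estimates.
    """
    x = table.dose
    y = table.viability
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("doses and viability values must be finite")
    if clip_negative:
        y = np.clip(y, 0.0, None)
    n_free = _n_free(fixed_hill, fixed_plateaus)
    n_distinct = table.distinct_doses.size
    if n_distinct < n_free:
        raise ValueError(
            f"{n_distinct} distinct doses cannot determine {n_free} free "
            "parameters; provide more dose levels"
        )

    top0 = float(np.clip(y.max(), 1e-3, 1.0))
    bot0 = float(np.clip(y.min(), 0.0, top0 - 1e-3))
    half = 0.5 * (top0 + bot0)
    mean_by_dose = pd.Series(y).groupby(pd.Series(x)).mean()
    positive = mean_by_dose.index[mean_by_dose.index > 0]
    if positive.size:
        ec0 = float(
            positive[np.argmin(np.abs(mean_by_dose.loc[positive].to_numpy() - half))]
        )
    else:
        ec0 = 1.0
    ec_hi = 10.0 * max(x.max(), ec0)

    if fixed_plateaus:
        def model(xx, ec50, h=None):
            hh = fixed_hill if fixed_hill is not None else h
            return viability(xx, HillParams(ec50, hh))

        p0 = [ec0] if fixed_hill is not None else [ec0, 1.0]
        lo = [1e-12] if fixed_hill is not None else [1e-12, 1e-6]
        hi = [ec_hi] if fixed_hill is not None else [ec_hi, 10.0]
    else:
        def model(xx, ec50, top, bottom, h=None):
            hh = fixed_hill if fixed_hill is not None else h
            xx = np.asarray(xx, dtype=float)
            ratio = np.where(xx > 0, (xx / ec50) ** hh, 0.0)
            return bottom + (top - bottom) / (1.0 + ratio)

        p0 = [ec0, top0, bot0] if fixed_hill is not None else [ec0, top0, bot0, 1.0]
        lo = [1e-12, 0.0, 0.0] if fixed_hill is not None else [1e-12, 0.0, 0.0, 1e-6]
        hi = [ec_hi, 1.0, 1.0] if fixed_hill is not None else [ec_hi, 1.0, 1.0, 10.0]

    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as err:
        raise FitConvergenceError(
            f"Hill fit did not converge (p0={p0}): {err}"
        ) from err

    if fixed_plateaus:
        ec50_hat = popt[0]
        h_hat = fixed_hill if fixed_hill is not None else popt[1]
        top_hat, bot_hat = 1.0, 0.0
    else:
        ec50_hat, top_hat, bot_hat = popt[0], popt[1], popt[2]
        h_hat = fixed_hill if fixed_hill is not None else popt[3]
    if bot_hat >= top_hat:
        raise FitConvergenceError(
            f"degenerate fit: bottom={bot_hat:.4g} >= top={top_hat:.4g}"
        )
    params = HillParams(
        ec50=float(ec50_hat),
        hill_coeff=float(h_hat),
        top=float(top_hat),
        bottom=float(bot_hat),
    )
    rss = float(np.sum((viability(x, params) - y) ** 2))
    return HillFit(params=params, rss=rss, n_points=int(y.size))


def ic50(params: HillParams) -> float:
    """Dose at which absolute viability equals 0.5.

    Distinct from ``ec50`` when the plateaus are shifted:
    solving bottom + (top-bottom)/(1+(x/ec50)^h) = 0.5 gives

        ic50 = ec50 * ((top - 0.5) / (0.5 - bottom)) ** (1/h)

    which reduces to ec50 for top=1, bottom=0.  Undefined (raises) when 0.5
    is outside (bottom, top).
    """
    if not (params.bottom < 0.5 < params.top):
        raise UndefinedIC50Error(
            "absolute 50% viability is outside the curve plateaus "
            f"[{params.bottom}, {params.top}]"
        )
    return params.ec50 * (
        (params.top - 0.5) / (0.5 - params.bottom)
    ) ** (1.0 / params.hill_coeff)
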