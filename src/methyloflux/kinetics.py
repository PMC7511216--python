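"""Michaelis-Menten kinetics for arabitol phosphate dehydrogenase assays.

Fits v = Vmax * S / (Km + S) to initial-rate data (rates in U/mg, substrate
in mM), reports standard errors and the catalytic efficiency Vmax/Km, and
screens assay series for significant activity (strictly above the
0.05 U/mg detection threshold used for the AtlD/AtlF substrate panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "AssayDataset",
    "KineticsResult",
    "ACTIVITY_THRESHOLD",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "screen_activities",
]

ACTIVITY_THRESHOLD = 0.05  # U / mg


@dataclass
class AssayDataset:
    enzyme: str
    substrate: str
    cofactor: str
    data: pd.DataFrame  # columns: S_mM, C_mM, rate_U_per_mg, optional sd

    def __post_init__(self):
        d = self.data
        if np.any(d["S_mM"] <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(d["rate_U_per_mg"] < 0):
            raise ValueError("rates must be nonnegative")


@dataclass
class KineticsResult:
    enzyme: str
    substrate: str
    cofactor: str
    km: float  # mM
    km_se: float
    vmax: float  # U / mg
    vmax_se: float
    active: bool
    identifiable: bool
    efficiency: float = field(init=False)

    def __post_init__(self):
        self.efficiency = catalytic_efficiency(self.km, self.vmax)


def _mm(S, vmax, km):
    return vmax * S / (km + S)


def fit_michaelis_menten(assay: AssayDataset) -> KineticsResult:
    """Nonlinear least-squares fit of the Michaelis-Menten rate law.

    Requires at least 4 distinct substrate concentrations.  The fit is
    flagged non-identifiable when the estimated Km falls outside the range
    probed by the assay (all S >> Km or all S << Km) or when its standard
    error exceeds the estimate itself.
    """
    d = assay.data
    S = d["S_mM"].to_numpy(dtype=float)
    v = d["rate_U_per_mg"].to_numpy(dtype=float)
    if len(np.unique(S)) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    sd = d["sd"].to_numpy(dtype=float) if "sd" in d.columns and d["sd"].notna().all() else None
    p0 = (float(v.max()), float(np.median(S)))
    popt, pcov = curve_fit(
        _mm,
        S,
        v,
        p0=p0,
        sigma=sd,
        absolute_sigma=sd is not None,
        bounds=([0.0, 1e-9], [np.inf, np.inf]),
        maxfev=20000,
    )
    vmax, km = popt
    vmax_se, km_se = np.sqrt(np.diag(pcov))
    identifiable = bool(S.min() / 10 <= km <= S.max() * 10) and np.isfinite(km_se) and km_se < km
    return KineticsResult(
        assay.enzyme,
        assay.substrate,
        assay.cofactor,
        km=float(km),
        km_se=float(km_se),
        vmax=float(vmax),
        vmax_se=float(vmax_se),
        active=bool(v.max() > ACTIVITY_THRESHOLD),
        identifiable=identifiable,
    )


def catalytic_efficiency(km: float, vmax: float, sig: int | None = None) -> float:
    """Vmax / Km; pass ``sig`` to round to the reporting precision."""
    if km <= 0:
        raise ValueError("Km must be positive")
    eff = vmax / km
    if sig is not None:
        if eff == 0:
            return 0.0
        from math import floor, log10

        eff = round(eff, -int(floor(log10(abs(eff)))) + (sig - 1))
    return eff


def screen_activities(
    assays: list[AssayDataset], threshold: float = ACTIVITY_THRESHOLD
) -> pd.DataFrame:
    """Activity table: one row per assay; active iff max rate > threshold."""
    rows = []
    for a in assays:
        vmax_obs = float(a.data["rate_U_per_mg"].max())
        active = vmax_obs > threshold
        rows.append(
            (a.enzyme, a.substrate, a.cofactor, vmax_obs, active,
             "" if active else "no significant activity")
        )
    return pd.DataFrame(
        rows, columns=["enzyme", "substrate", "cofactor", "max_rate", "active", "note"]
    )
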