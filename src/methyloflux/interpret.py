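"""Post-fit analyses.

Flux normalization to C-mmol per C-mmol of substrate, cofactor balance
accounting (NADPH / NADH / FADH2 / ATP with oxidative-phosphorylation
transfer at fixed P/O ratios), arabitol route discrimination, subnetwork
flux estimation from label dynamics, physiology rates from growth curves,
and elemental-balance data reconciliation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .fit import FitConfig, FitResult, MeasurementSet, fit_fluxes, goodness_of_fit
from .model import FluxVector, LabelInput, Network

__all__ = [
    "CofactorConfig",
    "CofactorBalance",
    "PhysiologyResult",
    "ReconciliationConfig",
    "normalize_fluxes",
    "cofactor_balance",
    "discriminate_arabitol_route",
    "scalaflux_subnetwork_fit",
    "compute_physiology",
    "reconcile_rates",
    "load_default_cofactor_config",
]


# ---------------------------------------------------------------------------
# flux normalization
# ---------------------------------------------------------------------------


def normalize_fluxes(
    flux: FluxVector, net: Network, uptake_C: float
) -> dict[str, float]:
    """Convert absolute fluxes to C-mmol per C-mmol of substrate carbon.

    Each net flux is multiplied by the total carbon count of its reactants
    and divided by the substrate uptake rate in C-mmol/gDCW/h, so the
    substrate uptake itself normalizes to 1 and conditions with different
    carbon sources become directly comparable.
    """
    if uptake_C <= 0:
        raise ValueError("substrate uptake must be positive")
    out = {}
    for rid, v in flux.net.items():
        r = net.reactions[rid]
        carbons = sum(t.coef * net.n_carbons(t.met) for t in r.reactants)
        out[rid] = v * carbons / uptake_C
    return out


# ---------------------------------------------------------------------------
# cofactor balance
# ---------------------------------------------------------------------------


@dataclass
class CofactorConfig:
    """Reaction-to-cofactor stoichiometry and energy parameters.

    ``cofactors`` maps cofactor -> {reaction: stoichiometry} with producers
    positive and consumers negative per unit net flux.  NADH and FADH2
    surpluses are routed to the respiratory chain, producing ATP at the
    P/O ratios.  ``biomass_requirements`` are mmol per gDCW, multiplied by
    the growth rate.
    """

    cofactors: dict[str, dict[str, float]]
    po_nadh: float = 1.5
    po_fadh2: float = 1.0
    biomass_requirements: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.po_nadh <= 0 or self.po_fadh2 <= 0:
            raise ValueError("P/O ratios must be positive")


def load_default_cofactor_config() -> CofactorConfig:
    text = resources.files("methyloflux.data").joinpath("cofactors.json").read_text()
    obj = json.loads(text)
    return CofactorConfig(
        cofactors=obj["cofactors"],
        po_nadh=obj["po_nadh"],
        po_fadh2=obj["po_fadh2"],
        biomass_requirements=obj.get("biomass_requirements", {}),
    )


@dataclass
class CofactorBalance:
    """Per-cofactor accounting, mmol/gDCW/h.

    ``unknown`` closes each balance exactly:
    production - consumption - biomass - transfer - unknown = 0.
    For NADH/FADH2 the transfer term is the full surplus handed to
    oxidative phosphorylation; the matching ATP production is recorded as
    a (negative) transfer on the ATP row.
    """

    table: pd.DataFrame  # index cofactor; columns production, consumption, biomass, transfer, unknown

    def closure_residual(self) -> float:
        t = self.table
        return float(
            np.max(
                np.abs(
                    t["production"] - t["consumption"] - t["biomass"] - t["transfer"] - t["unknown"]
                )
            )
        )


def cofactor_balance(
    flux: FluxVector, cfg: CofactorConfig, growth_rate: float = 0.0
) -> CofactorBalance:
    """Sum cofactor production/consumption over the flux map and close the
    balances with oxidative phosphorylation and an 'unknown' remainder."""
    rows = {}
    for cof, stoich in cfg.cofactors.items():
        prod = cons = 0.0
        for rid, coef in stoich.items():
            if rid not in flux.net:
                continue  # mapping covers all three condition models
            term = coef * flux.net[rid]
            if term >= 0:
                prod += term
            else:
                cons += -term
        rows[cof] = {"production": prod, "consumption": cons}

    for cof in ("NADPH", "NADH", "FADH2", "ATP"):
        rows.setdefault(cof, {"production": 0.0, "consumption": 0.0})

    biomass = {c: cfg.biomass_requirements.get(c, 0.0) * growth_rate for c in rows}

    transfer = {c: 0.0 for c in rows}
    for c in ("NADH", "FADH2"):
        transfer[c] = rows[c]["production"] - rows[c]["consumption"] - biomass[c]
    oxphos_atp = cfg.po_nadh * transfer["NADH"] + cfg.po_fadh2 * transfer["FADH2"]
    transfer["ATP"] = -oxphos_atp  # ATP received from the respiratory chain

    unknown = {}
    for c in rows:
        unknown[c] = (
            rows[c]["production"] - rows[c]["consumption"] - biomass[c] - transfer[c]
        )

    table = pd.DataFrame(
        {
            "production": {c: rows[c]["production"] for c in rows},
            "consumption": {c: rows[c]["consumption"] for c in rows},
            "biomass": biomass,
            "transfer": transfer,
            "unknown": unknown,
        }
    )
    return CofactorBalance(table)


# ---------------------------------------------------------------------------
# arabitol route discrimination
# ---------------------------------------------------------------------------


def discriminate_arabitol_route(
    net: Network,
    measurements: MeasurementSet | list[MeasurementSet],
    inp: LabelInput | list[LabelInput],
    cfg: FitConfig | None = None,
    uptake: tuple[str, float] | None = None,
    extra_constraints: list | None = None,
    exchange: dict[str, float] | None = None,
    route1: str = "araupt1",
    route5: str = "araupt5",
) -> pd.DataFrame:
    """Fit the PTS1-only, PTS5-only and both-free entry variants.

    Each variant forces the excluded entry flux to zero and is judged by
    the chi-square test; the both-free variant also reports the fitted
    fraction of uptake through the C1 route.  Errors in one variant do not
    abort the others.
    """
    cfg = cfg or FitConfig()
    base = list(extra_constraints or [])
    if uptake is not None:
        target, value = uptake
        base.append(({route1: 1.0, route5: 1.0} if target == "total" else target, value))
    variants = {
        "PTS1-only": base + [(route5, 0.0)],
        "PTS5-only": base + [(route1, 0.0)],
        "both": base,
    }
    rows = []
    for name, cons in variants.items():
        try:
            fr = fit_fluxes(net, measurements, inp, cfg, constraints=cons, exchange=exchange)
            ssr, p, ok = goodness_of_fit(fr, cfg.alpha)
            v1, v5 = fr.flux.net[route1], fr.flux.net[route5]
            split = v1 / (v1 + v5) if (v1 + v5) > 0 else np.nan
            rows.append((name, ssr, fr.dof, p, ok, split, None))
        except Exception as exc:
            rows.append((name, np.nan, 0, np.nan, False, np.nan, str(exc)))
    return pd.DataFrame(
        rows, columns=["variant", "ssr", "dof", "p_value", "passes", "route1_fraction", "error"]
    )


# ---------------------------------------------------------------------------
# subnetwork (precursor -> product) flux from label dynamics
# ---------------------------------------------------------------------------


def scalaflux_subnetwork_fit(
    times: np.ndarray,
    precursor_m0: np.ndarray,
    target_m0: np.ndarray,
    target_pool: float,
    target_sd: float | np.ndarray = 0.01,
    mc_n: int = 200,
    seed: int | None = None,
    v0: float | None = None,
    normalize_precursor: bool = True,
    target_ss: float | None = None,
) -> dict:
    """Estimate the flux through a two-reaction subnetwork from M+0 dynamics.

    Model: d M0_t / dt = (v / pool) * (M0_p(t) - M0_t(t)), i.e. one reaction
    converts the precursor into the target and one sink balances the target
    pool at the same rate.  The precursor M+0 profile is normalized to its
    isotopic steady state (its last value) before fitting, which absorbs an
    unlabeled extracellular contribution.  Units must be consistent
    (e.g. pool in umol/gDCW, flux in umol/gDCW per time unit of `times`).

    Monte Carlo (n = ``mc_n``) resampling of the target profile gives the
    flux sd.  Returns a dict with v, sd, ssr and the fitted curve.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if target_pool <= 0:
        raise ValueError("target pool must be positive")
    prec = np.asarray(precursor_m0, dtype=float)
    targ = np.asarray(target_m0, dtype=float)

    if np.ptp(prec) < 1e-9 and abs(prec[0] - targ[0]) < 1e-9:
        raise ValueError("precursor never labels: subnetwork flux unidentifiable")
    if normalize_precursor and prec[-1] > 1e-9:
        # unlabeled extracellular contribution: rescale the precursor
        # plateau onto the target's isotopic steady state
        target_ss = targ[-1] if target_ss is None else target_ss
        prec = prec * (target_ss / prec[-1])

    sd = np.broadcast_to(np.asarray(target_sd, dtype=float), targ.shape)

    def curve(v):
        # integrate dy/dt = k (p(t) - y), y(0) = target_m0[0]
        k = v / target_pool
        y = np.empty_like(times)
        y[0] = targ[0]
        # exact exponential propagation per interval with p(t) linear
        for i in range(1, len(times)):
            t0, t1 = times[i - 1], times[i]
            dt = t1 - t0
            p0, p1 = prec[i - 1], prec[i]
            slope = (p1 - p0) / dt
            if k * dt < 1e-12:
                y[i] = y[i - 1] + k * dt * (p0 - y[i - 1])
                continue
            e = np.exp(-k * dt)
            # solution of y' = k(p0 + slope (t-t0) - y)
            y[i] = p1 - slope / k + (y[i - 1] - p0 + slope / k) * e
        return y

    def resid(theta, data):
        return (curve(theta[0]) - data) / sd

    v_start = v0 if v0 is not None else target_pool / max(times[-1] - times[0], 1e-9)
    sol = least_squares(resid, [v_start], args=(targ,), bounds=(0.0, np.inf), xtol=1e-14, ftol=1e-14)
    v_hat = float(sol.x[0])
    fitted = curve(v_hat)
    ssr = float(np.sum(((fitted - targ) / sd) ** 2))

    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(mc_n):
        data = fitted + rng.normal(0.0, sd)
        s = least_squares(resid, [v_hat], args=(data,), bounds=(0.0, np.inf))
        draws.append(float(s.x[0]))
    draws = np.array(draws)
    return {
        "v": v_hat,
        "sd": float(draws.std(ddof=1)) if mc_n > 1 else 0.0,
        "mc_mean": float(draws.mean()),
        "ssr": ssr,
        "fitted": fitted,
        "n_mc": mc_n,
    }


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------


@dataclass
class PhysiologyResult:
    growth_rate: float  # 1/h
    growth_rate_se: float
    biomass_yield: float | None  # g dry weight / g substrate
    uptake: float | None  # mmol/gDCW/h
    uptake_C: float | None  # C-mmol/gDCW/h
    product_rates: dict[str, float]
    conversion_factor: float  # gDCW/L per OD600


def compute_physiology(
    od_series: pd.DataFrame,
    substrate_series: pd.DataFrame | None,
    conversion_factor: float,
    substrate_molar_mass: float | None = None,
    substrate_carbons: int | None = None,
    product_series: dict[str, pd.DataFrame] | None = None,
) -> PhysiologyResult:
    """Growth and exchange rates from exponential-phase time series.

    ``od_series``: columns time_h, od.  The growth rate comes from the
    log-linear regression of OD; uptake and production rates q come from
    the slope of concentration (mM) against biomass (g/L, = od x
    conversion factor), using ds/dX = -q/mu during balanced exponential
    growth.  The biomass yield needs the substrate molar mass (g/mol).
    """
    od = od_series["od"].to_numpy(dtype=float)
    t = od_series["time_h"].to_numpy(dtype=float)
    if len(od) < 3:
        raise ValueError("need at least 3 exponential-phase points")
    if np.any(od <= 0):
        raise ValueError("non-positive OD values")
    reg = stats.linregress(t, np.log(od))
    mu, mu_se = float(reg.slope), float(reg.stderr)

    uptake = uptake_C = byield = None
    if substrate_series is not None:
        s = substrate_series["conc_mM"].to_numpy(dtype=float)
        ts = substrate_series["time_h"].to_numpy(dtype=float)
        X = conversion_factor * np.exp(reg.intercept + mu * ts)
        sreg = stats.linregress(X, s)
        uptake = -float(sreg.slope) * mu  # mmol/gDCW/h
        if substrate_carbons:
            uptake_C = uptake * substrate_carbons
        if substrate_molar_mass:
            # ds/dX = -q/mu (mM per g/L); grams substrate per gram biomass
            byield = 1000.0 / (-float(sreg.slope) * substrate_molar_mass)

    products = {}
    for name, series in (product_series or {}).items():
        p = series["conc_mM"].to_numpy(dtype=float)
        tp = series["time_h"].to_numpy(dtype=float)
        X = conversion_factor * np.exp(reg.intercept + mu * tp)
        preg = stats.linregress(X, p)
        products[name] = float(preg.slope) * mu

    return PhysiologyResult(mu, mu_se, byield, uptake, uptake_C, products, conversion_factor)


# ---------------------------------------------------------------------------
# elemental-balance data reconciliation
# ---------------------------------------------------------------------------


@dataclass
class ReconciliationConfig:
    """Elemental composition context for rate reconciliation.

    The default biomass formula CH1.646 N0.219 O0.410 S0.005 with 6% ash is
    the Bacillus subtilis composition used for gram-to-carbon conversion.
    """

    biomass_formula: dict[str, float] = field(
        default_factory=lambda: {"C": 1.0, "H": 1.646, "N": 0.219, "O": 0.410, "S": 0.005}
    )
    ash_fraction: float = 0.06

    def __post_init__(self):
        if not 0.0 <= self.ash_fraction < 1.0:
            raise ValueError("ash fraction must be in [0, 1)")

    def biomass_carbon_content(self) -> float:
        """mmol carbon per g dry cell weight."""
        masses = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
        cmol_mass = sum(masses[e] * n for e, n in self.biomass_formula.items())
        return 1000.0 * (1.0 - self.ash_fraction) / cmol_mass


def reconcile_rates(
    rates: pd.DataFrame,
    constraint: np.ndarray | list[float],
    cfg: ReconciliationConfig | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, float, bool]:
    """Project measured rates onto a conservation subspace.

    ``rates``: columns name, value, sd.  ``constraint``: one or more rows
    of carbon (or elemental) coefficients c with the balance c . r = 0.
    Returns (reconciled rates, chi-square statistic, p-value, consistent).

    The weighted least-squares projection is the classical data
    reconciliation estimator r* = r - S E' (E S E')^-1 E r with S the
    measurement covariance; the statistic follows chi2 with as many dof as
    independent constraints.
    """
    E = np.atleast_2d(np.asarray(constraint, dtype=float))
    r = rates["value"].to_numpy(dtype=float)
    sd = rates["sd"].to_numpy(dtype=float)
    if np.any(sd <= 0):
        raise ValueError("rate sds must be positive")
    S = np.diag(sd**2)
    G = E @ S @ E.T
    if np.linalg.matrix_rank(G) < G.shape[0]:
        raise ValueError("structurally infeasible or redundant constraints")
    adj = S @ E.T @ np.linalg.solve(G, E @ r)
    r_star = r - adj
    chi2_stat = float((E @ r) @ np.linalg.solve(G, E @ r))
    dof = E.shape[0]
    p = float(stats.chi2.sf(chi2_stat, dof))
    out = rates.copy()
    out["reconciled"] = r_star
    return out, chi2_stat, p, bool(p >= alpha)
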