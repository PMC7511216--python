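"""Flux estimation from isotope labeling measurements.

Free net fluxes (a deterministic basis of the constrained stoichiometric
nullspace) and, optionally, exchange fluxes of reversible reactions are
estimated by variance-weighted least squares against CIDs, positional
enrichments, coupling fractions and measured rates.  Multi-start bounded
optimization guards against local minima; goodness of fit is assessed by a
chi-square test on the weighted SSR, and flux precision by Monte Carlo
resampling of the measurements.

Exchange fluxes are parameterized as x / (1 - x) with x in [0, 1), the
usual device to tame their unbounded range.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .model import (
    FluxParameterization,
    FluxVector,
    LabelInput,
    Network,
    apply_flux_parameters,
    free_flux_basis,
)
from .simulate import (
    EMUSystem,
    LabelingState,
    SingularLabelingError,
    _solve_stationary,
    emu_decompose,
    required_emus,
    simulate_instationary,
)

__all__ = [
    "FitConfig",
    "MeasurementSet",
    "FitResult",
    "PrecisionReport",
    "fit_fluxes",
    "goodness_of_fit",
    "monte_carlo_precision",
    "minimize_unresolved_fluxes",
    "score_label_design",
]


@dataclass
class FitConfig:
    n_starts: int = 10
    flux_bound: float = 50.0  # |net flux| upper bound, mmol/gDCW/h
    exchange_bound: float = 0.9  # bound on the [0,1) exchange coordinate
    alpha: float = 0.05
    mc_n: int = 100
    seed: int | None = None
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mc_n < 1:
            raise ValueError("mc_n must be >= 1")


@dataclass
class MeasurementSet:
    """Labeling and rate measurements with uncertainties and masks.

    ``table`` columns: species, kind (cid|enrichment|coupling), index,
    value, sd, use (bool mask; False = excluded, e.g. the contaminated
    Gnt6P M+2/M+3 isotopologues).  ``rates`` columns: target (reaction id
    or 'a+b' sum), value, sd.
    """

    table: pd.DataFrame
    rates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["target", "value", "sd"])
    )
    pools: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["species", "value", "sd"])
    )
    # instationary data: columns time_min, species, isotopologue, fraction, sd
    timecourse: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["time_min", "species", "isotopologue", "fraction", "sd"]
        )
    )

    def __post_init__(self):
        if "use" not in self.table.columns:
            self.table = self.table.assign(use=True)
        if len(self.table) and np.any(self.table.loc[self.table["use"], "sd"] <= 0):
            raise ValueError("measurement sds must be positive")

    @property
    def used(self) -> pd.DataFrame:
        return self.table[self.table["use"]]

    @property
    def n_measurements(self) -> int:
        return len(self.used) + len(self.rates) + len(self.timecourse)

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.table.to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, rates: pd.DataFrame | None = None) -> "MeasurementSet":
        tbl = pd.read_csv(io.StringIO(text))
        if "mask" in tbl.columns and "use" not in tbl.columns:
            tbl["use"] = ~tbl["mask"].astype(bool)
            tbl = tbl.drop(columns=["mask"])
        return cls(tbl, rates if rates is not None else pd.DataFrame(columns=["target", "value", "sd"]))


def _rate_coefs(target: str) -> dict[str, float]:
    return {t.strip(): 1.0 for t in target.split("+")}


@dataclass
class FitResult:
    params: np.ndarray
    param_names: list[str]
    flux: FluxVector
    ssr: float
    dof: int
    residuals: pd.DataFrame
    covariance: np.ndarray | None
    converged: bool
    starts: list[dict]
    mc: "PrecisionReport | None" = None
    # context for downstream operations
    net: Network | None = None
    parameterization: FluxParameterization | None = None
    config: FitConfig | None = None
    _problem: "object | None" = None


@dataclass
class PrecisionReport:
    """Per-reaction Monte Carlo flux statistics (mean, sd, central 95% CI)."""

    fluxes: pd.DataFrame  # index: reaction, columns mean, sd, lo, hi
    params: pd.DataFrame  # same for free parameters
    n: int
    n_failed: int
    warning: str | None = None

    def interval(self, rxn: str) -> tuple[float, float]:
        row = self.fluxes.loc[rxn]
        return float(row["lo"]), float(row["hi"])


@dataclass
class _Dataset:
    ms: MeasurementSet
    tbl: pd.DataFrame
    system: "EMUSystem | None"
    inp: LabelInput
    tc: pd.DataFrame
    tc_system: "EMUSystem | None"
    times_h: np.ndarray
    tc_rows: list  # (species, time index, isotopologue)


class _FitProblem:
    """Residual machinery shared by fitting, MC and design scoring."""

    def __init__(
        self,
        net: Network,
        measurements: list[MeasurementSet],
        inputs: list[LabelInput],
        par: FluxParameterization,
        exchange_fixed: dict[str, float],
        fit_exchange: bool,
        cfg: FitConfig,
        inp_before: LabelInput | None = None,
    ):
        self.net = net
        self.par = par
        self.cfg = cfg
        self.fit_exchange = fit_exchange
        self.exchange_fixed = dict(exchange_fixed)
        self.inp_before = inp_before or LabelInput(
            {s: [("0" * net.n_carbons(s), 1.0)] for s in net.substrates}
        )
        self.datasets: list[_Dataset] = []
        for ms, inp in zip(measurements, inputs):
            tbl = ms.used.reset_index(drop=True)
            system = emu_decompose(net, required_emus(net, tbl)) if len(tbl) else None
            tc = ms.timecourse.reset_index(drop=True)
            tc_system, times_h, tc_rows = None, np.array([]), []
            if len(tc):
                tc_system = emu_decompose(net, sorted(tc["species"].unique()))
                times_min = np.sort(tc["time_min"].unique())
                t_index = {t: i for i, t in enumerate(times_min)}
                times_h = times_min / 60.0
                tc_rows = [
                    (r["species"], t_index[r["time_min"]], int(r["isotopologue"]))
                    for _, r in tc.iterrows()
                ]
            self.datasets.append(
                _Dataset(ms, tbl, system, inp, tc, tc_system, times_h, tc_rows)
            )
        self.param_names = [f"net:{r}" for r in par.free]
        if fit_exchange:
            self.param_names += [f"exch:{r}" for r in par.free_exchange]
        self.n_free_net = len(par.free)
        self.irreversible = [
            (i, rid)
            for i, rid in enumerate(par.order)
            if not net.reactions[rid].reversible
        ]
        self.n_data = sum(len(d.tbl) + len(d.tc) + len(d.ms.rates) for d in self.datasets)

    # -- parameter handling -------------------------------------------------

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for rid in self.par.free:
            if self.net.reactions[rid].reversible:
                lo.append(-self.cfg.flux_bound)
            else:
                lo.append(0.0)
            hi.append(self.cfg.flux_bound)
        if self.fit_exchange:
            lo += [0.0] * len(self.par.free_exchange)
            hi += [self.cfg.exchange_bound] * len(self.par.free_exchange)
        return np.array(lo), np.array(hi)

    def fluxvec(self, theta: np.ndarray) -> FluxVector:
        exch = dict(self.exchange_fixed)
        if self.fit_exchange:
            for name, t in zip(self.par.free_exchange, theta[self.n_free_net :]):
                exch[name] = t / (1.0 - t)
        return apply_flux_parameters(self.par, theta[: self.n_free_net], exch)

    # -- residuals ----------------------------------------------------------

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        fv = self.fluxvec(theta)
        out = []
        for d in self.datasets:
            if d.system is not None:
                try:
                    state = LabelingState(self.net, d.inp, _solve_stationary(d.system, fv, d.inp))
                    sims = np.empty(len(d.tbl))
                    for i, row in d.tbl.iterrows():
                        sims[i] = _simulate_row(state, row)
                    out.append((sims - d.tbl["value"].to_numpy()) / d.tbl["sd"].to_numpy())
                except SingularLabelingError:
                    out.append(np.full(len(d.tbl), 1e6))
            if d.tc_system is not None:
                try:
                    sims = self._tc_sims(d, fv)
                    out.append((sims - d.tc["fraction"].to_numpy()) / d.tc["sd"].to_numpy())
                except (SingularLabelingError, ValueError):
                    out.append(np.full(len(d.tc), 1e6))
            for _, row in d.ms.rates.iterrows():
                v = sum(c * fv.net[r] for r, c in _rate_coefs(row["target"]).items())
                out.append(np.array([(v - row["value"]) / row["sd"]]))
        # smooth hinge penalty for irreversible reactions driven negative
        pen = np.array([1e3 * min(fv.net[rid], 0.0) for _, rid in self.irreversible])
        out.append(pen)
        return np.concatenate(out)

    def _tc_sims(self, d: _Dataset, fv) -> np.ndarray:
        course = simulate_instationary(
            self.net,
            fv,
            None,
            self.inp_before,
            d.inp,
            d.times_h,
            system=d.tc_system,
            rtol=1e-6,
            atol=1e-8,
        )
        cids = {sp: course.cid(sp) for sp in {r[0] for r in d.tc_rows}}
        return np.array([cids[sp][ti][iso] for sp, ti, iso in d.tc_rows])

    def ssr(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)[: self.n_data]
        return float(r @ r)


def _simulate_row(state: LabelingState, row: pd.Series) -> float:
    kind = row["kind"]
    if kind == "cid":
        return float(state.cid(row["species"])[int(row["index"])])
    if kind == "enrichment":
        return state.enrichment(row["species"], int(row["index"]))
    if kind == "coupling":
        anchor_s, pattern = str(row["index"]).split(":")
        return state.coupling_fractions(row["species"], int(anchor_s))[pattern]
    raise ValueError(f"unknown measurement kind {kind!r}")


def _as_lists(measurements, inputs):
    if isinstance(measurements, MeasurementSet):
        measurements = [measurements]
    if isinstance(inputs, LabelInput):
        inputs = [inputs] * len(measurements)
    if len(measurements) != len(inputs):
        raise ValueError("need one label input per measurement dataset")
    return measurements, inputs


def fit_fluxes(
    net: Network,
    measurements: MeasurementSet | list[MeasurementSet],
    inp: LabelInput | list[LabelInput],
    cfg: FitConfig | None = None,
    constraints: list | None = None,
    exchange: dict[str, float] | None = None,
    fit_exchange: bool = False,
    x0: np.ndarray | None = None,
    inp_before: LabelInput | None = None,
) -> FitResult:
    """Estimate fluxes from one or several (parallel) labeling datasets.

    ``constraints`` fixes measured fluxes exactly (e.g. the substrate
    uptake, biomass drains); ``exchange`` supplies fixed exchange-flux
    values for reversible reactions not being fitted.  Multi-start bounded
    least squares, deterministic given ``cfg.seed``.
    """
    cfg = cfg or FitConfig()
    measurements, inputs = _as_lists(measurements, inp)
    par = free_flux_basis(net, constraints or [])
    prob = _FitProblem(
        net, measurements, inputs, par, exchange or {}, fit_exchange, cfg, inp_before
    )
    lo, hi = prob.bounds()
    nparam = len(lo)
    if nparam == 0:
        raise ValueError("parameterization has no free parameters")

    rng = np.random.default_rng(cfg.seed)
    starts = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), lo, hi))
    if cfg.n_starts > len(starts):
        # prefer starts inside the irreversibility cone, where the labeling
        # residuals carry gradient information
        sampler = qmc.LatinHypercube(d=nparam, seed=rng)
        feasible, fallback = [], []
        for p in sampler.random(200 * cfg.n_starts):
            s = lo + p * (hi - lo)
            if len(feasible) >= cfg.n_starts:
                break
            if prob.fluxvec(s).violations:
                fallback.append(s)
            else:
                feasible.append(s)
        starts += feasible[: cfg.n_starts - len(starts)]
        k = cfg.n_starts - len(starts)
        if k > 0:
            starts += fallback[:k]

    outcomes = []
    best = None
    for s in starts:
        try:
            res = least_squares(
                prob.residuals,
                s,
                bounds=(lo, hi),
                method="trf",
                xtol=cfg.xtol,
                ftol=cfg.ftol,
                gtol=cfg.gtol,
            )
            ssr = prob.ssr(res.x)
            outcomes.append({"x0": s, "x": res.x, "ssr": ssr, "success": res.success})
            if res.success and (best is None or ssr < best[0]):
                best = (ssr, res)
        except Exception as exc:  # keep best converged start
            outcomes.append({"x0": s, "error": str(exc), "success": False})
    if best is None:
        raise RuntimeError("no optimization start converged")

    ssr, res = best
    fv = prob.fluxvec(res.x)
    dof = prob.n_data - nparam
    jac = res.jac[: prob.n_data]
    try:
        cov = np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov = None

    resid_rows = []
    for d in prob.datasets:
        if d.system is not None:
            state = LabelingState(net, d.inp, _solve_stationary(d.system, fv, d.inp))
            for _, row in d.tbl.iterrows():
                sim = _simulate_row(state, row)
                resid_rows.append(
                    (row["species"], row["kind"], row["index"], row["value"], sim, row["sd"])
                )
        if d.tc_system is not None:
            sims = prob._tc_sims(d, fv)
            for (sp, ti, iso), sim, (_, row) in zip(d.tc_rows, sims, d.tc.iterrows()):
                resid_rows.append(
                    (sp, "tc", f"{row['time_min']}:{iso}", row["fraction"], sim, row["sd"])
                )
        for _, row in d.ms.rates.iterrows():
            v = sum(c * fv.net[r] for r, c in _rate_coefs(row["target"]).items())
            resid_rows.append((row["target"], "rate", "", row["value"], v, row["sd"]))
    residuals = pd.DataFrame(
        resid_rows, columns=["species", "kind", "index", "measured", "simulated", "sd"]
    )

    return FitResult(
        params=res.x,
        param_names=prob.param_names,
        flux=fv,
        ssr=ssr,
        dof=dof,
        residuals=residuals,
        covariance=cov,
        converged=True,
        starts=outcomes,
        net=net,
        parameterization=par,
        config=cfg,
        _problem=prob,
    )


def goodness_of_fit(fr: FitResult, alpha: float | None = None) -> tuple[float, float, bool]:
    """Chi-square test of the weighted SSR against chi2(dof).

    Returns (statistic, p-value, pass).  Pass iff SSR does not exceed the
    upper alpha quantile.
    """
    if fr.dof < 1:
        raise ValueError("chi-square test requires dof >= 1")
    alpha = alpha if alpha is not None else (fr.config.alpha if fr.config else 0.05)
    p = float(stats.chi2.sf(fr.ssr, fr.dof))
    passed = fr.ssr <= stats.chi2.ppf(1 - alpha, fr.dof)
    return fr.ssr, p, bool(passed)


def monte_carlo_precision(fr: FitResult, cfg: FitConfig | None = None) -> PrecisionReport:
    """Monte Carlo flux precision: resample measurements around the best
    simulation, refit, aggregate per-reaction statistics."""
    cfg = cfg or fr.config or FitConfig()
    prob: _FitProblem = fr._problem
    rng = np.random.default_rng(cfg.seed)
    sim_col = fr.residuals["simulated"].to_numpy()
    sd_col = fr.residuals["sd"].to_numpy()

    flux_samples, param_samples = [], []
    n_failed = 0
    for _ in range(cfg.mc_n):
        noisy = sim_col + rng.normal(0.0, sd_col)
        k = 0
        saved = [(d.tbl, d.tc, d.ms) for d in prob.datasets]
        for d in prob.datasets:
            t = d.tbl.copy()
            if len(t):
                t["value"] = noisy[k : k + len(t)]
                k += len(t)
            tc = d.tc.copy()
            if len(tc):
                tc["fraction"] = noisy[k : k + len(tc)]
                k += len(tc)
            r = d.ms.rates.copy()
            if len(r):
                r["value"] = noisy[k : k + len(r)]
                k += len(r)
            d.tbl, d.tc = t, tc
            d.ms = MeasurementSet(t.assign(use=True), r, d.ms.pools, tc)
        try:
            lo, hi = prob.bounds()
            res = least_squares(
                prob.residuals,
                np.clip(fr.params, lo, hi),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
            )
            if not res.success:
                raise RuntimeError(res.message)
            fv = prob.fluxvec(res.x)
            flux_samples.append([fv.net[r_] for r_ in prob.par.order])
            param_samples.append(res.x)
        except Exception:
            n_failed += 1
        finally:
            for d, (tbl, tc, ms) in zip(prob.datasets, saved):
                d.tbl, d.tc, d.ms = tbl, tc, ms

    warning = None
    if n_failed > 0.2 * cfg.mc_n:
        warning = f"{n_failed}/{cfg.mc_n} Monte Carlo refits failed"

    def summarize(arr: np.ndarray, names: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": arr.mean(axis=0),
                "sd": arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1]),
                "lo": np.percentile(arr, 2.5, axis=0),
                "hi": np.percentile(arr, 97.5, axis=0),
            },
            index=names,
        )

    fl = np.array(flux_samples) if flux_samples else np.zeros((0, len(prob.par.order)))
    ps = np.array(param_samples) if param_samples else np.zeros((0, len(fr.params)))
    report = PrecisionReport(
        fluxes=summarize(fl, prob.par.order),
        params=summarize(ps, prob.param_names),
        n=len(flux_samples),
        n_failed=n_failed,
        warning=warning,
    )
    fr.mc = report
    return report


def minimize_unresolved_fluxes(
    fr: FitResult, flux_subset: list[str], cfg: FitConfig | None = None
) -> dict[str, float]:
    """Lower-bound |flux| for poorly resolved reactions.

    For each reaction in ``flux_subset``, minimizes |net flux| over the
    free parameters subject to the fit staying chi-square acceptable
    (SSR <= upper alpha quantile of chi2(dof)).
    """
    if not flux_subset:
        return {}
    cfg = cfg or fr.config or FitConfig()
    prob: _FitProblem = fr._problem
    par = prob.par
    bound = float(stats.chi2.ppf(1 - cfg.alpha, max(fr.dof, 1)))
    if prob.ssr(fr.params) > bound:
        raise ValueError("best fit already exceeds the chi-square bound")
    lo, hi = prob.bounds()
    out = {}
    eps = 1e-9
    for rid in flux_subset:
        if rid not in par.order:
            raise KeyError(f"unknown reaction {rid!r}")
        j = par.order.index(rid)

        def objective(theta, j=j):
            v = par.offset[j] + par.basis[j] @ theta[: prob.n_free_net]
            return float(np.sqrt(v * v + eps))

        res = minimize(
            objective,
            fr.params,
            method="SLSQP",
            bounds=list(zip(lo, hi)),
            constraints=[{"type": "ineq", "fun": lambda th: bound - prob.ssr(th)}],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        theta = res.x if res.success else fr.params
        v = par.offset[j] + par.basis[j] @ theta[: prob.n_free_net]
        out[rid] = abs(float(v))
    return out


def score_label_design(
    net: Network,
    candidate_inputs: list[LabelInput],
    reference_flux: FluxVector,
    measured_table: pd.DataFrame,
    fluxes_of_interest: list[str],
    constraints: list | None = None,
    cfg: FitConfig | None = None,
) -> pd.DataFrame:
    """Expected flux precision per candidate label input.

    Linearized design evaluation: simulate the measurements at the
    reference fluxes, form the weighted Jacobian with respect to the free
    net fluxes, and propagate its (pseudo)inverse covariance onto the
    fluxes of interest.  The score is the mean relative sd over those
    fluxes; candidates leaving a flux of interest unidentifiable score
    infinity and are flagged.
    """
    cfg = cfg or FitConfig()
    par = free_flux_basis(net, constraints or [])
    theta_ref = np.array([reference_flux.net[r] for r in par.free])
    system = emu_decompose(net, required_emus(net, measured_table))
    tbl = measured_table.reset_index(drop=True)
    sds = tbl["sd"].to_numpy(dtype=float)
    exch_ref = dict(reference_flux.exch)

    def simvec(theta, inp):
        fv = apply_flux_parameters(par, theta, exch_ref)
        state = LabelingState(net, inp, _solve_stationary(system, fv, inp))
        return np.array([_simulate_row(state, row) for _, row in tbl.iterrows()])

    rows = []
    for ci, inp in enumerate(candidate_inputs):
        f0 = simvec(theta_ref, inp)
        h = 1e-6 * np.maximum(1.0, np.abs(theta_ref))
        J = np.empty((len(tbl), len(theta_ref)))
        for k in range(len(theta_ref)):
            tp = theta_ref.copy()
            tp[k] += h[k]
            J[:, k] = (simvec(tp, inp) - f0) / h[k]
        Jw = J / sds[:, None]
        H = Jw.T @ Jw
        lam, V = np.linalg.eigh(H)
        lam_max = max(float(lam[-1]), 0.0)
        cut = max(lam_max * 1e-10, 1e-14)
        rel_sds = {}
        flagged = False
        for rid in fluxes_of_interest:
            jx = par.order.index(rid)
            g = par.basis[jx]
            var = 0.0
            for li, vi in zip(lam, V.T):
                gi = float(g @ vi)
                if li < cut:
                    if abs(gi) > 1e-8:
                        var = np.inf
                        break
                else:
                    var += gi * gi / li
            vref = reference_flux.net[rid]
            denom = abs(vref) if abs(vref) > 1e-12 else 1.0
            rel = np.sqrt(var) / denom
            rel_sds[rid] = rel
            if not np.isfinite(rel):
                flagged = True
        score = float(np.mean(list(rel_sds.values())))
        rows.append({"candidate": ci, "score": score, "unidentifiable": flagged, **{f"sd:{k}": v for k, v in rel_sds.items()}})
    return pd.DataFrame(rows)
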