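"""Synthetic datasets with known ground truth.

Every input the analysis chain consumes can be generated here: stationary
CIDs of amino-acid reporter metabolites (mannitol/arabitol conditions),
instationary CID time courses with pool sizes (methanol condition), NMR
positional enrichments and coupling patterns, Michaelis-Menten assay
curves, and growth/consumption series.  All noise models are explicit and
all draws are seeded, so regeneration is bit-identical.

Amino-acid labeling is represented by the CIDs of the corresponding
precursor pools (proteinogenic amino acids inherit their carbon skeleton
from these precursors; the hydrolysis/derivatization layer is not
modeled).

The module also defines the reference flux state for each bundled
condition (`reference_condition`): substrate uptake and growth rates match
the measured physiology of the corresponding culture, the remaining
degrees of freedom are set to round values consistent with the published
flux maps, and biomass drains are precursor demand x growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import AssayDataset
from .fit import MeasurementSet
from .model import (
    FluxVector,
    LabelInput,
    Network,
    apply_flux_parameters,
    free_flux_basis,
    load_bundled_network,
)
from .simulate import (
    TimeCourse,
    required_emus,
    simulate_instationary,
    simulate_steady_labeling,
)

__all__ = [
    "GeneratorSpec",
    "steady_flux",
    "reference_condition",
    "generate_steady_dataset",
    "generate_instationary_dataset",
    "generate_assay_dataset",
    "generate_growth_series",
]


# ---------------------------------------------------------------------------
# reference flux states
# ---------------------------------------------------------------------------


def steady_flux(
    net: Network,
    hard: list,
    targets: dict[str, float] | None = None,
    exchange: dict[str, float] | None = None,
) -> FluxVector:
    """Steady-state flux vector honoring `hard` equality constraints and
    least-squares matching the soft `targets` with the remaining freedom."""
    par = free_flux_basis(net, hard)
    if par.n_free and targets:
        rows = [par.order.index(r) for r in targets]
        A = par.basis[rows]
        b = np.array([targets[par.order[j]] for j in rows]) - par.offset[rows]
        f, *_ = np.linalg.lstsq(A, b, rcond=None)
    else:
        f = np.zeros(par.n_free)
    return apply_flux_parameters(par, f, exchange or {})


@dataclass
class Condition:
    name: str
    net: Network
    truth: FluxVector
    label_input: LabelInput
    growth_rate: float
    uptake: float  # mmol/gDCW/h
    uptake_C: float  # C-mmol/gDCW/h
    fit_constraints: list  # hard constraints used when re-estimating fluxes
    free_fluxes_of_interest: list[str]
    measured_species: list[str]
    exchange: dict[str, float] = field(default_factory=dict)


_EXCH_COMMON = {
    "pgi": 0.5,
    "rpe": 0.5,
    "rpi": 0.5,
    "tkt1": 0.2,
    "ta": 0.2,
    "tkt2": 0.2,
    "fba": 0.1,
    "pgk": 1.0,
    "sdh": 0.1,
    "fuma": 0.5,
    "maldh": 0.5,
}

_MEASURED_LUMPED = [
    "Glc6P",
    "Gnt6P",
    "Fru6P",
    "Rib5P",
    "E4P",
    "GA3P",
    "PEP",
    "Pyr",
    "AcCoA",
    "OAA",
    "AKG",
    "Suc",
    "Mal",
]


def _drain_constraints(net: Network, mu: float) -> list:
    return [(f"bm_{met.lower()}", coef * mu) for met, coef in net.biomass.items()]


def reference_condition(name: str, route1_fraction: float = 1.0) -> Condition:
    """Reference state for 'methanol', 'mannitol' or 'arabitol'.

    For arabitol, ``route1_fraction`` sets the true share of uptake through
    the arabitol 1-phosphate (Xyl5P) entry; the fitted share in the study
    was 1.0.
    """
    net = load_bundled_network(name)
    if name == "mannitol":
        mu, uptake = 0.36, 6.0  # 36 C-mmol/gDCW/h
        hard = [("manupt", uptake), ("out_Ac", 1.75)] + _drain_constraints(net, mu)
        truth = steady_flux(
            net,
            hard,
            targets={"zwf": 1.8, "pyc": 0.9, "mae": 1.3},
            exchange={k: v for k, v in _EXCH_COMMON.items() if k in net.reactions},
        )
        return Condition(
            name,
            net,
            truth,
            LabelInput({"Mntl": [("100000", 1.0)]}),
            mu,
            uptake,
            uptake * 6,
            hard,
            ["zwf", "pyc", "mae"],
            _MEASURED_LUMPED,
            truth.exch,
        )
    if name == "arabitol":
        mu, uptake = 0.14, 4.9  # 24.5 C-mmol/gDCW/h ([5-13C] culture)
        v1 = route1_fraction * uptake
        hard = [("araupt1", v1), ("araupt5", uptake - v1)] + _drain_constraints(net, mu)
        truth = steady_flux(
            net,
            hard,
            targets={"zwf": 0.5, "pyc": 0.9, "mae": 1.6, "idh": 4.7},
            exchange={k: v for k, v in _EXCH_COMMON.items() if k in net.reactions},
        )
        return Condition(
            name,
            net,
            truth,
            LabelInput({"Abt": [("00001", 1.0)]}),
            mu,
            uptake,
            uptake * 5,
            hard,
            ["araupt1", "araupt5", "zwf"],
            _MEASURED_LUMPED,
            truth.exch,
        )
    if name == "methanol":
        mu, uptake = 0.46, 30.6
        hard = [("mdh", uptake)] + _drain_constraints(net, mu)
        exch = {k: v for k, v in _EXCH_COMMON.items() if k in net.reactions}
        exch.update({"tpi": 0.5, "eno": 1.0, "acn1": 0.2, "acn2": 0.2, "sba": 0.1})
        truth = steady_flux(
            net,
            hard,
            targets={"detox": 4.0, "zwf": 2.3, "idh": 0.62, "mae": 5.05, "akgdh": 0.05, "ta": 1.0},
            exchange=exch,
        )
        return Condition(
            name,
            net,
            truth,
            LabelInput({"MeOH": [("1", 1.0)]}),
            mu,
            uptake,
            uptake,
            hard,
            ["detox", "zwf", "mae"],
            ["Glc6P", "Fru6P", "Gnt6P", "Rib5P", "PEP", "Mal", "Cit"],
            exch,
        )
    raise KeyError(f"unknown condition {name!r}")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


@dataclass
class GeneratorSpec:
    """Study conditions for synthetic measurement generation.

    Default noise levels: absolute sd 0.005 on CID entries, 0.01 on
    positional enrichments and coupling fractions, 5% CV on rates.
    """

    condition: str = "mannitol"
    route1_fraction: float = 1.0
    cid_sd: float = 0.005
    enrichment_sd: float = 0.01
    coupling_sd: float = 0.01
    rate_cv: float = 0.05
    seed: int | None = None
    nmr_enrichments: list[tuple[str, int]] = field(default_factory=list)
    nmr_couplings: list[tuple[str, int]] = field(default_factory=list)
    masks: list[tuple[str, str, object]] = field(default_factory=list)

    def __post_init__(self):
        if min(self.cid_sd, self.enrichment_sd, self.coupling_sd, self.rate_cv) <= 0:
            raise ValueError("noise levels must be positive")


def _noisy_simplex(rng, cid: np.ndarray, sd: float) -> np.ndarray:
    noisy = np.clip(cid + rng.normal(0.0, sd, size=cid.shape), 0.0, None)
    s = noisy.sum()
    return noisy / s if s > 0 else np.eye(len(cid))[0]


def generate_steady_dataset(
    spec: GeneratorSpec, condition: Condition | None = None
) -> tuple[MeasurementSet, Condition]:
    """Stationary labeling dataset (MS CIDs + optional NMR rows).

    Noise: truncated Gaussian per CID entry followed by renormalization to
    the simplex; masked rows keep their value but are excluded (use=False).
    """
    cond = condition or reference_condition(spec.condition, spec.route1_fraction)
    rng = np.random.default_rng(spec.seed)
    targets = list(cond.measured_species)
    probe = pd.DataFrame(
        [(sp, "enrichment", c, 0, 1, True) for sp, c in spec.nmr_enrichments]
        + [(sp, "coupling", f"{a}:s", 0, 1, True) for sp, a in spec.nmr_couplings],
        columns=["species", "kind", "index", "value", "sd", "use"],
    )
    emus = required_emus(cond.net, probe) if len(probe) else []
    state = simulate_steady_labeling(
        cond.net, cond.truth, cond.label_input, targets=targets + emus
    )

    rows = []
    for sp in targets:
        cid = _noisy_simplex(rng, state.cid(sp), spec.cid_sd)
        for k, v in enumerate(cid):
            rows.append((sp, "cid", k, float(v), spec.cid_sd, True))
    for sp, c in spec.nmr_enrichments:
        v = np.clip(state.enrichment(sp, c) + rng.normal(0.0, spec.enrichment_sd), 0.0, 1.0)
        rows.append((sp, "enrichment", c, float(v), spec.enrichment_sd, True))
    for sp, anchor in spec.nmr_couplings:
        fr = state.coupling_fractions(sp, anchor)
        vals = _noisy_simplex(rng, np.array(list(fr.values())), spec.coupling_sd)
        for pat, v in zip(fr, vals):
            rows.append((sp, "coupling", f"{anchor}:{pat}", float(v), spec.coupling_sd, True))
    table = pd.DataFrame(rows, columns=["species", "kind", "index", "value", "sd", "use"])
    for sp, kind, index in spec.masks:
        sel = (table["species"] == sp) & (table["kind"] == kind) & (table["index"] == index)
        table.loc[sel, "use"] = False

    uptake_noisy = cond.uptake * (1.0 + rng.normal(0.0, spec.rate_cv))
    uptake_target = "+".join(
        r for r in ("manupt", "araupt1", "araupt5", "mdh") if r in cond.net.reactions
    )
    rates = pd.DataFrame(
        [(uptake_target, uptake_noisy, cond.uptake * spec.rate_cv)],
        columns=["target", "value", "sd"],
    )
    return MeasurementSet(table, rates), cond


def generate_instationary_dataset(
    spec: GeneratorSpec,
    times_min: np.ndarray | None = None,
    condition: Condition | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TimeCourse, Condition]:
    """Instationary CID time courses after a tracer pulse at t = 0.

    Defaults to the methanol condition sampled on a 13-point grid over
    3.5 min.  Returns (noisy long-format table, pool table, clean course,
    condition); masked (species, 'cid', iso) entries are dropped from the
    table, mirroring cross-contaminated isotopologues.
    """
    cond = condition or reference_condition(spec.condition)
    rng = np.random.default_rng(spec.seed)
    if times_min is None:
        times_min = np.linspace(0.0, 3.5, 13)
    times_h = np.asarray(times_min, dtype=float) / 60.0
    unlabeled = LabelInput({s: [("0" * cond.net.n_carbons(s), 1.0)] for s in cond.net.substrates})
    course = simulate_instationary(
        cond.net,
        cond.truth,
        None,
        unlabeled,
        cond.label_input,
        times_h,
        targets=cond.measured_species,
    )
    masked = {(sp, int(i)) for sp, kind, i in spec.masks if kind == "cid"}
    rows = []
    for sp in cond.measured_species:
        arr = course.cid(sp)
        for ti, tmin in enumerate(times_min):
            cid = _noisy_simplex(rng, arr[ti], spec.cid_sd)
            for k, v in enumerate(cid):
                if (sp, k) in masked:
                    continue
                rows.append((float(tmin), sp, k, float(v), spec.cid_sd))
    table = pd.DataFrame(rows, columns=["time_min", "species", "isotopologue", "fraction", "sd"])
    pools = pd.DataFrame(
        [
            (m.id, m.pool_size)
            for m in cond.net.metabolites.values()
            if m.role == "internal" and m.pool_size is not None
        ],
        columns=["species", "pool_umol_gDCW"],
    )
    return table, pools, course, cond


def generate_assay_dataset(
    enzyme: str,
    substrate: str,
    cofactor: str,
    km: float,
    vmax: float,
    s_grid: np.ndarray,
    cofactor_mM: float = 0.3,
    noise_cv: float = 0.05,
    seed: int | None = None,
) -> AssayDataset:
    """Michaelis-Menten initial rates with multiplicative Gaussian noise.

    Negative draws are clipped to zero and flagged in a 'clipped' column.
    """
    rng = np.random.default_rng(seed)
    S = np.asarray(s_grid, dtype=float)
    if np.any(S <= 0):
        raise ValueError("substrate grid must be positive")
    v_true = vmax * S / (km + S)
    noise = rng.normal(0.0, noise_cv, size=S.shape) if noise_cv > 0 else np.zeros_like(S)
    v = v_true * (1.0 + noise)
    clipped = v < 0
    v = np.clip(v, 0.0, None)
    data = pd.DataFrame(
        {
            "S_mM": S,
            "C_mM": cofactor_mM,
            "rate_U_per_mg": v,
            "sd": np.maximum(v_true * noise_cv, 1e-6),
            "clipped": clipped,
        }
    )
    return AssayDataset(enzyme, substrate, cofactor, data)


def generate_growth_series(
    mu: float,
    conversion_factor: float,
    times_h: np.ndarray,
    od0: float = 0.1,
    substrate0_mM: float = 15.0,
    uptake: float = 6.0,
    product_rates: dict[str, float] | None = None,
    od_cv: float = 0.0,
    conc_sd: float = 0.0,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Exponential growth curve with coupled substrate/product series.

    ``uptake`` (mmol/gDCW/h) drives substrate depletion through
    ds/dt = -q X(t); products accumulate analogously.
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, dtype=float)
    X = conversion_factor * od0 * np.exp(mu * t)  # g/L
    od = od0 * np.exp(mu * t)
    if od_cv > 0:
        od = od * (1.0 + rng.normal(0.0, od_cv, size=t.shape))
    growth = (X - X[0]) / mu  # integral of X dt
    s = substrate0_mM - uptake * growth
    if conc_sd > 0:
        s = s + rng.normal(0.0, conc_sd, size=t.shape)
    out = {
        "od": pd.DataFrame({"time_h": t, "od": od}),
        "substrate": pd.DataFrame({"time_h": t, "conc_mM": s}),
    }
    for name, q in (product_rates or {}).items():
        p = q * growth
        if conc_sd > 0:
            p = p + rng.normal(0.0, conc_sd, size=t.shape)
        out[name] = pd.DataFrame({"time_h": t, "conc_mM": p})
    return out
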