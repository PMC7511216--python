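"""Natural-abundance and tracer-purity correction of MS isotopologue data.

Raw mass-shift intensity vectors mix the biological tracer signal with
natural heavy isotopes (13C on unlabeled positions and, at low resolution,
2H/15N/18O/33S/34S...) and with incomplete tracer enrichment.  The
correction builds the linear operator mapping tracer-space isotopologue
fractions to observed mass-shift fractions and inverts it by non-negative
least squares, so noisy data never yield negative fractions.

The default is high-resolution mode (Orbitrap-class acquisition), where
isotopes of elements other than carbon are resolved away and only 13C
interferes with the tracer signal.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from math import comb

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "ElementalFormula",
    "CorrectionMatrix",
    "default_abundances",
    "build_correction_matrix",
    "correct_measurement",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def default_abundances() -> dict[str, np.ndarray]:
    """Natural isotope abundances by mass shift (bundled IUPAC table)."""
    text = resources.files("methyloflux.data").joinpath("isotopes.json").read_text()
    obj = json.loads(text)
    return {el: np.asarray(v, dtype=float) for el, v in obj.items() if el != "comment"}


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts plus the number of carbon tracer positions."""

    counts: dict[str, int]
    n_tracer: int

    @classmethod
    def parse(cls, formula: str, n_tracer: int | None = None) -> "ElementalFormula":
        counts: dict[str, int] = {}
        for el, num in _FORMULA_RE.findall(formula):
            if el:
                counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        nc = counts.get("C", 0)
        nt = nc if n_tracer is None else n_tracer
        if nt > nc:
            raise ValueError(f"{nt} tracer positions exceed {nc} carbons in {formula!r}")
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative element count")
        return cls(counts, nt)


@dataclass
class CorrectionMatrix:
    """Maps tracer-isotopologue fractions (columns) to mass-shift fractions."""

    matrix: np.ndarray
    formula: ElementalFormula
    purity: float
    resolution_mode: str = "high"
    meta: dict = field(default_factory=dict)


def _shift_distribution(abund: np.ndarray, count: int, width: int) -> np.ndarray:
    """Mass-shift distribution of `count` atoms of one element, truncated."""
    out = np.zeros(width)
    out[0] = 1.0
    for _ in range(count):
        out = np.convolve(out, abund)[:width]
    return out


def build_correction_matrix(
    formula: ElementalFormula | str,
    purity: float = 1.0,
    abundances: dict[str, np.ndarray] | None = None,
    resolution_mode: str = "high",
) -> CorrectionMatrix:
    """Correction matrix for one metabolite (or fragment) formula.

    Column ``j`` is the observed mass-shift distribution of molecules with
    exactly ``j`` tracer-labeled positions: a binomial over the ``j``
    nominally labeled carbons (tracer purity), convolved with the natural
    13C distribution of the remaining carbons and, in ``low`` resolution
    mode, with the natural mass-shift distributions of all other elements.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    if not 0.0 < purity <= 1.0:
        raise ValueError("tracer purity must be in (0, 1]")
    abund = abundances or default_abundances()
    for el in formula.counts:
        if el not in abund:
            raise KeyError(f"no abundance data for element {el!r}")
        s = float(np.sum(abund[el]))
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"abundances for {el} sum to {s}, not 1")

    n = formula.n_tracer
    width = n + 1
    a13 = abund["C"][1] if len(abund["C"]) > 1 else 0.0
    cols = []
    for j in range(n + 1):
        # tracer impurity: each labeled position is 13C with prob `purity`
        col = np.array([comb(j, k) * purity**k * (1 - purity) ** (j - k) for k in range(j + 1)])
        col = np.pad(col, (0, width - len(col)))[:width]
        # natural 13C on the n - j unlabeled tracer positions
        col = np.convolve(col, _shift_distribution(np.array([1 - a13, a13]), n - j, width))[:width]
        # non-tracer carbons
        extra_c = formula.counts.get("C", 0) - n
        if extra_c:
            col = np.convolve(col, _shift_distribution(abund["C"], extra_c, width))[:width]
        if resolution_mode == "low":
            for el, count in formula.counts.items():
                if el == "C" or count == 0:
                    continue
                col = np.convolve(col, _shift_distribution(abund[el], count, width))[:width]
        cols.append(col)
    M = np.column_stack(cols)
    return CorrectionMatrix(M, formula, purity, resolution_mode)


def correct_measurement(raw: np.ndarray, cm: CorrectionMatrix) -> tuple[np.ndarray, float]:
    """Recover the tracer-space CID from raw mass-shift intensities.

    Solves ``min ||M x - raw/sum(raw)||`` subject to ``x >= 0`` and
    renormalizes ``x`` to the simplex.  Returns ``(cid, residual_norm)``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (cm.matrix.shape[0],):
        raise ValueError(f"raw vector length {raw.shape} does not match matrix rows {cm.matrix.shape[0]}")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero raw intensity vector")
    x, resid = nnls(cm.matrix, raw / total)
    s = x.sum()
    if s <= 0:
        raise ValueError("correction produced an all-zero CID")
    return x / s, float(resid)
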