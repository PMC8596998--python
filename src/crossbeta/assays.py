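"""Solution-phase assay arithmetic for peptide hydrogel characterisation.

Covers the quantitative bookkeeping around a gelation study: the critical
aggregation concentration (CAC) read as the break point of a dye-fluorescence
titration, average masses from chemical formulas and ESI adduct m/z, molar vs
mass concentration conversions, Beer-Lambert quantitation (peptide content,
Ellman's free-thiol assay), the hydrogel swelling ratio, and storage/loss
modulus ratios from oscillatory rheology.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .constants import ADDUCT_MASSES, ATOMIC_WEIGHTS

__all__ = [
    "TitrationSeries", "BreakpointFit", "RheoPoint", "ModulusRatios",
    "parse_formula", "formula_mass", "adduct_mz",
    "molar_to_mass", "mass_to_molar",
    "beer_lambert_conc", "swelling_ratio", "modulus_ratio", "gel_state",
    "fit_breakpoint",
]

ChemicalFormula = Dict[str, int]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


# ---------------------------------------------------------------------------
# formulas, masses, concentrations
# ---------------------------------------------------------------------------

def parse_formula(formula: Union[str, ChemicalFormula]) -> ChemicalFormula:
    """Parse a Hill-notation formula string ("C57H62N8O9S") into counts."""
    if isinstance(formula, dict):
        out = dict(formula)
    else:
        out = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            pos = m.end()
            el, count = m.group(1), int(m.group(2) or 1)
            out[el] = out.get(el, 0) + count
        if pos != len(formula) or not out:
            raise ValueError(f"cannot parse formula {formula!r}")
    for el, count in out.items():
        if not (isinstance(count, (int, np.integer)) and count > 0):
            raise ValueError(f"element count must be a positive integer: {el}={count}")
    return out


def formula_mass(formula: Union[str, ChemicalFormula]) -> float:
    """Average molecular mass (g/mol) from frozen standard atomic weights."""
    counts = parse_formula(formula)
    mass = 0.0
    for el, count in counts.items():
        if el not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {el!r}")
        mass += count * ATOMIC_WEIGHTS[el]
    return mass


def adduct_mz(mass: float, adduct: str = "+Na", z: int = 1) -> float:
    """m/z of an ESI adduct ion: (M + adduct masses) / z."""
    if z < 1:
        raise ValueError("charge z must be >= 1")
    if adduct not in ADDUCT_MASSES:
        raise ValueError(f"unsupported adduct {adduct!r}; "
                         f"choose from {sorted(ADDUCT_MASSES)}")
    return (mass + ADDUCT_MASSES[adduct]) / z


def molar_to_mass(conc_mol_per_l: float,
                  formula: Union[str, ChemicalFormula]) -> float:
    """mol/L -> mass concentration in ug/mL."""
    if conc_mol_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return conc_mol_per_l * formula_mass(formula) * 1.0e3


def mass_to_molar(conc_ug_per_ml: float,
                  formula: Union[str, ChemicalFormula]) -> float:
    """ug/mL -> mol/L."""
    if conc_ug_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ug_per_ml / (formula_mass(formula) * 1.0e3)


def beer_lambert_conc(absorbance: float, epsilon: float, path_cm: float = 1.0,
                      dilution: float = 1.0) -> float:
    """Concentration (mol/L) from absorbance: c = A / (eps * l) * dilution."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    return absorbance / (epsilon * path_cm) * dilution


def swelling_ratio(w_swollen_g: float, w_dry_g: float) -> float:
    """Hydrogel swelling ratio q = (Ws - Wd) / Wd * 100 (percent)."""
    if w_dry_g <= 0:
        raise ValueError("dry weight must be positive")
    if w_swollen_g < 0:
        raise ValueError("swollen weight must be non-negative")
    return (w_swollen_g - w_dry_g) / w_dry_g * 100.0


@dataclass(frozen=True)
class ModulusRatios:
    """Both conventions for the storage/loss modulus ratio.

    ``loss_tangent`` is the standard tan(delta) = G''/G'.  Some hydrogel
    reports print "tan delta" for the inverse ratio G'/G'' (a rigidity
    ratio); that value is returned as ``rigidity_ratio`` rather than being
    silently renamed.
    """
    loss_tangent: float      # G'' / G'
    rigidity_ratio: float    # G'  / G''


def modulus_ratio(g_prime_pa: float, g_double_prime_pa: float) -> ModulusRatios:
    if g_prime_pa <= 0 or g_double_prime_pa <= 0:
        raise ValueError("both moduli must be positive")
    return ModulusRatios(loss_tangent=g_double_prime_pa / g_prime_pa,
                         rigidity_ratio=g_prime_pa / g_double_prime_pa)


@dataclass(frozen=True)
class RheoPoint:
    g_prime_pa: float
    g_double_prime_pa: float
    time_s: float = 0.0

    def __post_init__(self):
        if self.g_prime_pa <= 0 or self.g_double_prime_pa <= 0:
            raise ValueError("moduli must be positive")


def gel_state(points: Sequence[RheoPoint]) -> bool:
    """True iff G' exceeds G'' at every point of the series (gel criterion)."""
    points = list(points)
    if not points:
        raise ValueError("need at least one rheology point")
    return all(p.g_prime_pa > p.g_double_prime_pa for p in points)


# ---------------------------------------------------------------------------
# CAC break-point fitting
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """Dye-fluorescence titration: intensity at fixed emission wavelength
    versus (strictly increasing) peptide concentration."""

    concentrations: np.ndarray
    intensities: np.ndarray
    unit: str = "mol/L"
    emission_nm: float = 475.0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        self.intensities = np.asarray(self.intensities, float)
        if len(self.concentrations) != len(self.intensities):
            raise ValueError("concentration and intensity lengths differ")
        if len(self.concentrations) < 5:
            raise ValueError("need at least 5 titration points")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class BreakpointFit:
    """Continuous two-segment linear fit of a titration curve."""

    cac: Optional[float]
    slope_left: float
    intercept_left: float
    slope_right: float
    intercept_right: float
    rss: float
    has_breakpoint: bool
    p_value: float
    unit: str = "mol/L"
    ci: Optional[Tuple[float, float]] = None


def _hinge_fit(x: np.ndarray, y: np.ndarray, c: float):
    """Least squares for y = b0 + b1*x + b2*max(0, x - c); returns (rss, beta)."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def fit_breakpoint(series: TitrationSeries, log_x: bool = False,
                   alpha: float = 0.05, n_boot: int = 0,
                   seed: Optional[int] = None) -> BreakpointFit:
    """Fit a continuous two-segment line and return the knot as the CAC.

    The knot is found by exhaustive search over interior grid concentrations
    (at least 3 points on each side) followed by golden-section refinement
    between the neighbouring grid points of the best knot.  If the two-segment
    model does not improve on a single straight line (F-test at ``alpha``),
    the result is flagged ``has_breakpoint=False`` and ``cac=None`` -- a
    signalled outcome, not an exception.

    With ``n_boot`` > 0, a residual bootstrap gives a percentile confidence
    interval for the CAC.
    """
    x_raw = np.log10(series.concentrations) if log_x else series.concentrations.copy()
    y_raw = series.intensities
    # normalise internally: makes the fit well-conditioned and exactly
    # equivariant under rescaling of either axis
    xscale = float(np.max(np.abs(x_raw))) or 1.0
    yscale = float(np.max(np.abs(y_raw))) or 1.0
    x = x_raw / xscale
    y = y_raw / yscale
    n = len(x)
    lo_i, hi_i = 2, n - 3       # knot candidates with >= 3 points on each side
    if hi_i < lo_i:
        raise ValueError("too few points for a break-point search")

    def best_knot(xv, yv):
        cands = xv[lo_i:hi_i + 1]
        rss = [(_hinge_fit(xv, yv, c)[0], c) for c in cands]
        best_rss, best_c = min(rss, key=lambda t: t[0])
        i = int(np.argmin([r for r, _ in rss]))
        # golden-section refinement between the neighbouring candidates
        a = cands[max(i - 1, 0)]
        b = cands[min(i + 1, len(cands) - 1)]
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        c1 = b - gr * (b - a)
        c2 = a + gr * (b - a)
        f1 = _hinge_fit(xv, yv, c1)[0]
        f2 = _hinge_fit(xv, yv, c2)[0]
        for _ in range(60):
            if f1 <= f2:
                b, c2, f2 = c2, c1, f1
                c1 = b - gr * (b - a)
                f1 = _hinge_fit(xv, yv, c1)[0]
            else:
                a, c1, f1 = c1, c2, f2
                c2 = a + gr * (b - a)
                f2 = _hinge_fit(xv, yv, c2)[0]
        c_ref = 0.5 * (a + b)
        rss_ref, beta = _hinge_fit(xv, yv, c_ref)
        if rss_ref > best_rss:
            c_ref = best_c
            rss_ref, beta = _hinge_fit(xv, yv, best_c)
        return c_ref, rss_ref, beta

    c_hat, rss1, beta = best_knot(x, y)

    # single-line null model
    X0 = np.column_stack([np.ones_like(x), x])
    b0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
    r0 = y - X0 @ b0
    rss0 = float(r0 @ r0)

    dof = n - 4
    scale = float(y @ y) or 1.0
    if rss1 <= 1e-12 * scale:
        # the two-segment model is exact; a break exists unless the single
        # line is exact too
        has_break = rss0 > 1e-12 * scale
        p_value = 0.0 if has_break else 1.0
    else:
        F = ((rss0 - rss1) / 2.0) / (rss1 / dof)
        p_value = float(stats.f.sf(max(F, 0.0), 2, dof))
        has_break = p_value < alpha

    b0_, b1_, b2_ = beta
    sl = b1_ * yscale / xscale
    il = b0_ * yscale
    sr = (b1_ + b2_) * yscale / xscale
    ir = (b0_ - b2_ * c_hat) * yscale

    def to_conc(c_norm):
        c_orig = c_norm * xscale
        return 10 ** c_orig if log_x else c_orig

    cac = to_conc(c_hat)

    ci = None
    if has_break and n_boot > 0:
        rng = np.random.default_rng(seed)
        yhat = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c_hat)]) @ beta
        resid = y - yhat
        boots = []
        for _ in range(n_boot):
            yb = yhat + rng.choice(resid, size=n, replace=True)
            cb, _, _ = best_knot(x, yb)
            boots.append(to_conc(cb))
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return BreakpointFit(
        cac=float(cac) if has_break else None,
        slope_left=float(sl), intercept_left=float(il),
        slope_right=float(sr), intercept_right=float(ir),
        rss=float(rss1 * yscale ** 2), has_breakpoint=bool(has_break),
        p_value=float(p_value), unit=series.unit, ci=ci)
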