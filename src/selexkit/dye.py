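"""Cy7-displacement colorimetric assay analytics.

The cyanine dye Cy7 equilibrates between a monomer (absorbing near
775 nm when aptamer-bound) and a dimer (670 nm).  Aptamer binding
sequesters the monomer; target molecules displace it within seconds,
shifting absorbance from 775 to 670 nm.  The assay readout is the
ratio R = A670/A775, and

    signal gain G = 100% * (R_sample - R_blank) / R_blank

with the blank measured in the same matrix (buffer, 50% urine, 50%
saliva — blanks are never shared across matrices).  Cross-reactivity of
a ligand is its gain as a percentage of the reference target's gain.
Calibration is ordinary least squares of G against concentration inside
the linear range, and the detection limit is the concentration whose
predicted gain first exceeds blank mean + 3 blank SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .itc import solve_equilibrium_one_site

__all__ = [
    "DyeTitration",
    "CalibrationFit",
    "DyeAffinityFit",
    "signal_gain",
    "cross_reactivity",
    "fit_dye_affinity",
    "fit_calibration",
]


@dataclass
class DyeTitration:
    """One analyte titration series of two-wavelength absorbances."""

    concs: np.ndarray  # uM, strictly increasing
    a670: np.ndarray
    a775: np.ndarray
    dye_conc: float = 2.0  # uM
    aptamer_conc: float = 3.0  # uM
    matrix: str = "buffer"

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        self.a670 = np.asarray(self.a670, dtype=float)
        self.a775 = np.asarray(self.a775, dtype=float)
        if not (len(self.concs) == len(self.a670) == len(self.a775)):
            raise ValueError("series lengths must match")
        if np.any(self.concs < 0) or np.any(self.a670 < 0) or np.any(self.a775 < 0):
            raise ValueError("concentrations and absorbances must be >= 0")
        if np.any(np.diff(self.concs) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def ratios(self) -> np.ndarray:
        if np.any(self.a775 == 0):
            raise ValueError("A775 = 0: ratio undefined")
        return self.a670 / self.a775


@dataclass(frozen=True)
class CalibrationFit:
    """Linear calibration of signal gain vs concentration, with LOD."""

    slope: float  # percent gain per uM
    intercept: float  # percent
    linear_range: tuple[float, float]  # uM
    lod: float  # uM
    blank_mean: float
    blank_sd: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class DyeAffinityFit:
    """Exact 1:1 (ligand-depletion) fit of dye-aptamer binding."""

    kd: float  # uM
    signal_free: float  # readout at zero aptamer
    signal_bound: float  # readout at full dye saturation
    residual_sse: float
    se_kd: float


def signal_gain(sample: tuple[float, float], blank: tuple[float, float],
                relative: bool = True) -> float:
    """Percent signal gain of a sample over the matrix blank.

    ``sample`` and ``blank`` are (A670, A775) pairs.  The default is the
    relative change of R = A670/A775 versus the blank, which is zero at
    no target; ``relative=False`` returns the absolute ratio difference
    R_sample - R_blank scaled by 100 instead.
    """
    a670_s, a775_s = sample
    a670_b, a775_b = blank
    if a775_s <= 0 or a775_b <= 0:
        raise ValueError("A775 must be positive in both sample and blank")
    r_s, r_b = a670_s / a775_s, a670_b / a775_b
    if relative:
        return 100.0 * (r_s - r_b) / r_b
    return 100.0 * (r_s - r_b)


def cross_reactivity(gains: dict[str, float], reference: str) -> pd.DataFrame:
    """Signal gains of a ligand panel as percentages of a reference ligand.

    Returns a table with columns ligand, signal_gain_pct and
    cross_reactivity_pct; the reference row is exactly 100%.
    """
    if reference not in gains:
        raise ValueError(f"reference ligand {reference!r} not in table")
    g_ref = gains[reference]
    if g_ref <= 0:
        raise ValueError("reference signal gain must be positive")
    rows = [
        {"ligand": lig, "signal_gain_pct": g,
         "cross_reactivity_pct": 100.0 * g / g_ref}
        for lig, g in gains.items()
    ]
    return pd.DataFrame(rows)


def dye_binding_signal(
    aptamer_concs: np.ndarray,
    dye_conc: float,
    kd: float,
    signal_free: float,
    signal_bound: float,
) -> np.ndarray:
    """Exact 1:1 binding readout vs titrated aptamer at fixed dye.

    Because the dye concentration is comparable to K_D, the
    ligand-depletion (quadratic) isotherm is used: the bound-dye
    fraction comes from the exact mass balance, not the hyperbolic
    free-ligand approximation.
    """
    a = np.asarray(aptamer_concs, dtype=float)
    bound = np.array(
        [solve_equilibrium_one_site(ai, dye_conc, kd) for ai in a]
    )
    frac = bound / dye_conc
    return signal_free + (signal_bound - signal_free) * frac


def fit_dye_affinity(
    aptamer_concs: np.ndarray | list[float],
    signals: np.ndarray | list[float],
    dye_conc: float,
) -> DyeAffinityFit:
    """Fit dye-aptamer K_D from an aptamer-into-dye titration.

    ``signals`` is the 775 nm readout at each aptamer concentration.
    Fits (K_D, signal_free, signal_bound) by least squares on the exact
    quadratic isotherm with deterministic multi-start over K_D.  A fit
    whose K_D standard error exceeds 50% of the estimate is flagged
    low-confidence (affinity outside the titrated range).
    """
    a = np.asarray(aptamer_concs, dtype=float)
    y = np.asarray(signals, dtype=float)
    if a.shape != y.shape or a.ndim != 1:
        raise ValueError("aptamer_concs and signals must match")
    if len(a) < 5:
        raise ValueError("need >= 5 aptamer concentrations")
    if dye_conc <= 0:
        raise ValueError("dye concentration must be positive")
    if np.ptp(y) == 0:
        raise ValueError("unidentifiable: flat response")

    s0_0, s1_0 = float(y[np.argmin(a)]), float(y[np.argmax(a)])
    span = max(abs(s1_0 - s0_0), 1e-12)
    mid = float(np.median(a[a > 0])) if np.any(a > 0) else 1.0

    def resid(p: np.ndarray) -> np.ndarray:
        kd, s0, s1 = p
        return dye_binding_signal(a, dye_conc, kd, s0, s1) - y

    best = None
    for kd0 in (0.1 * mid, mid, 10.0 * mid):
        sol = least_squares(
            resid, [kd0, s0_0, s1_0 + 0.05 * span],
            bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        sse = float(2 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
    sse, sol = best
    kd, s0, s1 = sol.x

    dof = max(len(a) - 3, 1)
    try:
        cov = (sse / dof) * np.linalg.inv(sol.jac.T @ sol.jac)
        se_kd = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_kd = float("nan")
    fit = DyeAffinityFit(kd=float(kd), signal_free=float(s0),
                         signal_bound=float(s1), residual_sse=sse,
                         se_kd=se_kd)
    if sse > 0 and se_kd > 0.5 * kd:
        import warnings

        warnings.warn(
            "low-confidence dye-affinity fit: K_D standard error exceeds "
            "50% of the estimate (K_D likely outside the titrated range)",
            stacklevel=2,
        )
    return fit


def fit_calibration(
    concs: np.ndarray | list[float],
    gains: np.ndarray | list[float],
    blank_gains: np.ndarray | list[float],
    linear_range: tuple[float, float] | None = None,
    lod_rule: str = "blank+3sd",
) -> CalibrationFit:
    """Linear calibration of signal gain vs analyte concentration.

    ``blank_gains`` are >= 3 replicate gains of the no-target blank (0
    by construction on average, but with measurement scatter that sets
    the detection limit).  Points outside ``linear_range`` are excluded
    from the ordinary-least-squares line.  The LOD solves
    predicted G(c) = blank_mean + 3 * blank_sd from the fitted line;
    ``lod_rule='lowest-tested'`` instead reports the smallest measured
    concentration whose gain exceeds that threshold.
    """
    c = np.asarray(concs, dtype=float)
    g = np.asarray(gains, dtype=float)
    b = np.asarray(blank_gains, dtype=float)
    if c.shape != g.shape or c.ndim != 1:
        raise ValueError("concs and gains must be 1-D and the same length")
    if len(b) < 3:
        raise ValueError("cannot estimate blank SD: need >= 3 blank replicates")
    if linear_range is None:
        linear_range = (float(c.min()), float(c.max()))
    lo, hi = linear_range
    if not lo < hi:
        raise ValueError("linear_range lower bound must be below upper")
    mask = (c >= lo) & (c <= hi)
    if mask.sum() < 3:
        raise ValueError("need >= 3 points inside the linear range")

    blank_mean = float(np.mean(b))
    blank_sd = float(np.std(b, ddof=1))

    slope, intercept = np.polyfit(c[mask], g[mask], 1)
    pred = slope * c[mask] + intercept
    ss_res = float(np.sum((g[mask] - pred) ** 2))
    ss_tot = float(np.sum((g[mask] - g[mask].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    threshold = blank_mean + 3.0 * blank_sd
    if lod_rule == "blank+3sd":
        if slope <= 0:
            raise ValueError("non-positive slope: cannot solve for LOD")
        lod = (threshold - intercept) / slope
    elif lod_rule == "lowest-tested":
        above = c[(g > threshold) & (c > 0)]
        if above.size == 0:
            raise ValueError("no tested concentration exceeds the threshold")
        lod = float(above.min())
    else:
        raise ValueError(f"unknown lod_rule {lod_rule!r}")

    return CalibrationFit(
        slope=float(slope), intercept=float(intercept),
        linear_range=(lo, hi), lod=float(lod),
        blank_mean=blank_mean, blank_sd=blank_sd,
        r_squared=r2, n_points=int(mask.sum()),
    )
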