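"""Gel-elution binding statistics and Langmuir affinity estimation.

In the gel-elution assay the library is immobilized on beads via a
complementary capture strand; target binding releases strands into the
supernatant, and a formamide wash then strips everything left on the
beads.  Band concentrations of the two gel fractions give the eluted
fraction

    theta = 100% * V1*c_s / (V2*c_s + V3*c_b)

where c_s / c_b are the strand concentrations of the supernatant and
formamide fractions and V1, V2, V3 are the solution volumes before
supernatant collection, of the collected supernatant, and after
formamide addition.  Plotting theta against target concentration and
fitting the Langmuir isotherm

    theta(c) = theta_max * c / (K_D + c)

yields the pool's apparent dissociation constant.  theta_max is free
because partially enriched pools saturate well below 100% elution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ElutionObservation",
    "LangmuirFit",
    "elution_fraction",
    "fit_langmuir",
    "elution_profile",
    "DEFAULT_VOLUMES",
]

#: (V1, V2, V3) in microlitres: pre-collection volume (with ~8 ul of the
#: nominal 70 ul occupied by agarose beads), collected supernatant, and
#: volume after formamide addition.
DEFAULT_VOLUMES = (62.0, 40.0, 80.0)


@dataclass(frozen=True)
class ElutionObservation:
    """One gel-quantified elution measurement at a target concentration.

    c_s and c_b are band concentrations (any common unit) of the
    target-eluted supernatant and the formamide fraction.
    """

    target_conc: float  # uM
    c_s: float
    c_b: float
    v1: float = DEFAULT_VOLUMES[0]
    v2: float = DEFAULT_VOLUMES[1]
    v3: float = DEFAULT_VOLUMES[2]

    def __post_init__(self) -> None:
        if min(self.v1, self.v2, self.v3) <= 0:
            raise ValueError("volumes must be positive")
        if self.c_s < 0 or self.c_b < 0:
            raise ValueError("band concentrations must be >= 0")


@dataclass(frozen=True)
class LangmuirFit:
    """Langmuir isotherm fit result (concentrations in uM)."""

    kd: float
    theta_max: float
    residual_sse: float
    se_kd: float
    se_theta_max: float
    n_points: int


def elution_fraction(obs: ElutionObservation) -> float:
    """Percent of library eluted by target, from the two gel fractions.

    Returns theta in percent.  theta > 100% is physically impossible and
    indicates a volume-model mismatch; it is returned but flagged with a
    warning.
    """
    denom = obs.v2 * obs.c_s + obs.v3 * obs.c_b
    if denom == 0:
        raise ValueError("no signal in either gel fraction (c_s = c_b = 0)")
    theta = 100.0 * obs.v1 * obs.c_s / denom
    if theta > 100.0:
        warnings.warn(
            f"elution fraction {theta:.1f}% exceeds 100%: the volume model "
            "does not account for all strands (check V1/V2/V3)",
            stacklevel=2,
        )
    return theta


def _langmuir(c: np.ndarray, kd: float, theta_max: float) -> np.ndarray:
    return theta_max * c / (kd + c)


def fit_langmuir(
    concs: np.ndarray | list[float],
    thetas: np.ndarray | list[float],
    fix_theta_max: float | None = None,
) -> LangmuirFit:
    """Least-squares Langmuir fit of eluted fraction vs concentration.

    ``thetas`` are fractions (0-1 scale), ``concs`` in uM.  K_D is
    initialized at 0.1x, 1x and 10x the median nonzero concentration
    (deterministic multi-start; best SSE wins).  ``fix_theta_max`` pins
    the plateau instead of fitting it.  Asymptotic standard errors come
    from the Jacobian at the optimum.
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(thetas, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("concs and thetas must be 1-D and the same length")
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if np.all(y == y[0]):
        raise ValueError("unidentifiable: no curvature (all theta equal)")
    if np.any(y < 0) or np.any(y > 1.6):
        raise ValueError("thetas must be fractions in [0, 1.6]")

    mid = float(np.median(c[c > 0]))
    free_tm = fix_theta_max is None

    def resid(p: np.ndarray) -> np.ndarray:
        kd = p[0]
        tm = p[1] if free_tm else fix_theta_max
        return _langmuir(c, kd, tm) - y

    best = None
    tm0 = float(np.clip(y.max() * 1.05, 1e-3, 1.6))
    for kd0 in (0.1 * mid, mid, 10.0 * mid):
        x0 = [kd0, tm0] if free_tm else [kd0]
        lo = [1e-12, 1e-12] if free_tm else [1e-12]
        hi = [np.inf, 1.6] if free_tm else [np.inf]
        sol = least_squares(resid, x0, bounds=(lo, hi),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        sse = float(2 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
    sse, sol = best

    kd = float(sol.x[0])
    tm = float(sol.x[1]) if free_tm else float(fix_theta_max)
    se = _asymptotic_se(sol.jac, sse, len(c))
    return LangmuirFit(
        kd=kd,
        theta_max=tm,
        residual_sse=sse,
        se_kd=se[0],
        se_theta_max=se[1] if free_tm else 0.0,
        n_points=len(c),
    )


def _asymptotic_se(jac: np.ndarray, sse: float, n: int) -> np.ndarray:
    """Standard errors from the Gauss-Newton approximation at the optimum."""
    p = jac.shape[1]
    dof = max(n - p, 1)
    s2 = sse / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def elution_profile(
    ligands: list[str],
    thetas: list[float],
    buffer_label: str = "buffer",
) -> pd.DataFrame:
    """Ranked single-concentration elution table for a ligand panel.

    One theta (percent) per ligand; a buffer-only row, when present,
    serves as the no-target reference.  Input order is preserved.
    """
    if len(ligands) != len(set(ligands)):
        dupes = sorted({l for l in ligands if ligands.count(l) > 1})
        raise ValueError(f"duplicate ligand labels: {dupes}")
    if len(ligands) != len(thetas):
        raise ValueError("need one theta per ligand")
    df = pd.DataFrame({"ligand": ligands, "theta_pct": thetas})
    df["is_reference"] = df["ligand"] == buffer_label
    return df
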