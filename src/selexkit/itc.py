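"""Isothermal titration calorimetry: one-site and racemic competitive models.

A titrant at syringe concentration X_t is injected stepwise into a cell
of volume V0 containing the aptamer at concentration M_t.  Each
injection releases heat proportional to the change in bound complex in
the cell:

    q_i = V0 * sum_j dH_j * ( [ML_j]_i - d_i * [ML_j]_{i-1} ) + baseline

where d_i = V0 / (V0 + v_i) is the perfusion (overflow) dilution factor
of injection i: a fixed-volume cell overflows, so every pre-existing
species concentration is scaled by d_i and the fresh titrant adds
X_t * v_i / (V0 + v_i).  Heats are in microjoules, concentrations in uM,
volumes in ul, enthalpies in kJ/mol.

The one-site model has a single dissociation constant; chiral targets
titrated as a racemate require the competitive (two-sets-of-sites)
variant: both enantiomers, present at mole fractions phi and 1-phi of
the total titrant, compete for the same N*M_t sites with their own K_D
and dH.  Strongly unequal enantiomer affinities make the racemic
isotherm non-sigmoidal, which a single-site fit cannot reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "ITCExperiment",
    "OneSiteParams",
    "RacemicParams",
    "Isotherm",
    "solve_equilibrium_one_site",
    "solve_equilibrium_racemic",
    "simulate_isotherm",
    "correct_dilution",
    "fit_one_site",
    "fit_racemic",
]

R_GAS = 8.314462618e-3  # kJ/(mol*K)

# unit bridge: V0 [ul] * conc [uM] * dH [kJ/mol] -> heat [uJ] needs 1e-3
_UJ = 1e-3


@dataclass(frozen=True)
class ITCExperiment:
    """Titration geometry: cell volume/concentration, syringe, schedule."""

    cell_volume: float  # ul (V0)
    cell_conc: float  # uM aptamer (M_t at start)
    syringe_conc: float  # uM total titrant (X_t)
    injection_volumes: tuple[float, ...]  # ul per injection
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_conc, self.syringe_conc,
               self.temperature) <= 0:
            raise ValueError("experiment quantities must be positive")
        if len(self.injection_volumes) < 5:
            raise ValueError("need >= 5 injections")
        if min(self.injection_volumes) <= 0:
            raise ValueError("injection volumes must be positive")


@dataclass(frozen=True)
class OneSiteParams:
    """Single-site binding parameters.

    N: sites per aptamer; kd in uM; dh in kJ/mol of ligand bound;
    baseline: constant dilution-heat offset per injection, uJ.
    """

    n: float
    kd: float
    dh: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.kd <= 0:
            raise ValueError("N and K_D must be positive")


@dataclass(frozen=True)
class RacemicParams:
    """Competitive two-ligand (enantiomer) binding parameters.

    phi is the mole fraction of the 'minus' enantiomer in the syringe
    (0.5 for a racemate); both species compete for one class of N*M_t
    sites.
    """

    n: float
    kd_minus: float
    kd_plus: float
    dh_minus: float
    dh_plus: float
    fraction_minus: float = 0.5
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.kd_minus <= 0 or self.kd_plus <= 0:
            raise ValueError("N and both K_D must be positive")
        if not 0.0 < self.fraction_minus < 1.0:
            raise ValueError("fraction_minus must be in (0, 1)")


@dataclass
class Isotherm:
    """Per-injection heats and the running cell composition."""

    heats: np.ndarray  # uJ per injection
    titrant_total: np.ndarray  # cumulative titrant in cell, uM
    macromolecule: np.ndarray  # aptamer concentration in cell, uM
    injection_volumes: np.ndarray  # ul
    moles_injected: np.ndarray | None = None  # mol of injectant per injection
    dilution_method: str | None = None

    def __post_init__(self) -> None:
        n = len(self.heats)
        if not (len(self.titrant_total) == len(self.macromolecule)
                == len(self.injection_volumes) == n):
            raise ValueError("isotherm arrays must share the injection count")

    def __len__(self) -> int:
        return len(self.heats)

    @property
    def normalized(self) -> np.ndarray:
        """Heat per mole of injectant delivered, kJ/mol."""
        if self.moles_injected is None:
            raise ValueError("moles_injected unknown for this isotherm")
        return self.heats * 1e-9 / self.moles_injected


def solve_equilibrium_one_site(m_t: float, l_t: float, kd: float,
                               n: float = 1.0) -> float:
    """Bound complex [ML] for one ligand and N*M_t identical sites.

    Mass balance gives a quadratic in [ML]; the physical (smaller) root
    is returned via the numerically stable product form, so
    0 <= [ML] <= min(N*M_t, L_t) always holds.
    """
    if min(m_t, l_t, kd) < 0 or n < 0:
        raise ValueError("inputs must be non-negative")
    s_t = n * m_t
    if s_t == 0 or l_t == 0:
        return 0.0
    b = s_t + l_t + kd
    disc = b * b - 4.0 * s_t * l_t
    ml = 2.0 * s_t * l_t / (b + np.sqrt(max(disc, 0.0)))
    return float(min(ml, s_t, l_t))


def solve_equilibrium_racemic(
    m_t: float,
    l1_t: float,
    l2_t: float,
    kd1: float,
    kd2: float,
    n: float = 1.0,
) -> tuple[float, float]:
    """Bound complexes ([ML1], [ML2]) for two ligands competing for one
    class of N*M_t sites.

    Reduced to a 1-D root find on the free-site concentration S:
    with free ligand L_j = L_j_t * K_j / (K_j + S), site conservation
    reads  S * (1 + sum_j L_j_t / (K_j + S)) = N*M_t, which is strictly
    increasing in S, so a bracketed Brent solve on [0, N*M_t] is robust.
    Mass conservation of the returned solution holds to 1e-9 relative.
    """
    if min(m_t, l1_t, l2_t) < 0 or n < 0 or kd1 <= 0 or kd2 <= 0:
        raise ValueError("concentrations must be >= 0 and K_D > 0")
    s_t = n * m_t
    if s_t == 0:
        return 0.0, 0.0
    if l1_t == 0 and l2_t == 0:
        return 0.0, 0.0

    def site_balance(s: float) -> float:
        return s * (1.0 + l1_t / (kd1 + s) + l2_t / (kd2 + s)) - s_t

    if site_balance(s_t) < 0:  # numerically exact-saturation guard
        s = s_t
    else:
        s = brentq(site_balance, 0.0, s_t, xtol=1e-300, rtol=8.9e-16,
                   maxiter=200)
    ml1 = s * l1_t / (kd1 + s)
    ml2 = s * l2_t / (kd2 + s)
    return float(ml1), float(ml2)


def _injection_series(exp: ITCExperiment) -> tuple[np.ndarray, np.ndarray]:
    """Cell concentrations after each injection under perfusion dilution:
    (total titrant X_i, aptamer M_i), both uM."""
    v0 = exp.cell_volume
    x = np.empty(len(exp.injection_volumes))
    m = np.empty_like(x)
    xi, mi = 0.0, exp.cell_conc
    for i, v in enumerate(exp.injection_volumes):
        d = v0 / (v0 + v)
        xi = xi * d + exp.syringe_conc * v / (v0 + v)
        mi = mi * d
        x[i], m[i] = xi, mi
    return x, m


def _model_heats(params: OneSiteParams | RacemicParams,
                 exp: ITCExperiment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free per-injection heats plus the (X_i, M_i) series."""
    x, m = _injection_series(exp)
    v0 = exp.cell_volume
    dil = v0 / (v0 + np.asarray(exp.injection_volumes))
    q = np.empty(len(x))
    if isinstance(params, OneSiteParams):
        prev = 0.0
        for i in range(len(x)):
            ml = solve_equilibrium_one_site(m[i], x[i], params.kd, params.n)
            q[i] = v0 * params.dh * (ml - dil[i] * prev) * _UJ + params.baseline
            prev = ml
    else:
        phi = params.fraction_minus
        prev1 = prev2 = 0.0
        for i in range(len(x)):
            ml1, ml2 = solve_equilibrium_racemic(
                m[i], phi * x[i], (1.0 - phi) * x[i],
                params.kd_minus, params.kd_plus, params.n,
            )
            q[i] = (
                v0 * (params.dh_minus * (ml1 - dil[i] * prev1)
                      + params.dh_plus * (ml2 - dil[i] * prev2)) * _UJ
                + params.baseline
            )
            prev1, prev2 = ml1, ml2
    return q, x, m


def simulate_isotherm(
    params: OneSiteParams | RacemicParams,
    exp: ITCExperiment,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    """Forward-simulate per-injection heats, optionally with Gaussian noise.

    noise_sd is in uJ; seed is required whenever noise_sd > 0 so runs
    are reproducible.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    q, x, m = _model_heats(params, exp)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd, size=len(q))
    vols = np.asarray(exp.injection_volumes, dtype=float)
    moles = exp.syringe_conc * vols * 1e-12  # uM * ul -> mol
    return Isotherm(heats=q, titrant_total=x, macromolecule=m,
                    injection_volumes=vols, moles_injected=moles)


def correct_dilution(
    iso: Isotherm,
    method: str = "trailing-mean",
    k: int = 3,
    exp: ITCExperiment | None = None,
) -> Isotherm:
    """Subtract the titrant's dilution heat from every injection.

    'trailing-mean' subtracts the mean of the last k injections (the
    post-saturation plateau, where binding heat is negligible) and is
    idempotent.  'fit-baseline' refits the one-site model (requires
    ``exp``) and subtracts its fitted constant baseline, which separates
    dilution heat from residual binding heat even when the schedule
    barely saturates.
    """
    n = len(iso)
    if method == "trailing-mean":
        if k >= n:
            raise ValueError(f"k={k} must be < number of injections ({n})")
        offset = float(np.mean(iso.heats[-k:]))
    elif method == "fit-baseline":
        if exp is None:
            raise ValueError("method 'fit-baseline' needs the ITCExperiment")
        offset = fit_one_site(iso, exp).params.baseline
    else:
        raise ValueError(f"unknown dilution-correction method {method!r}")
    return Isotherm(
        heats=iso.heats - offset,
        titrant_total=iso.titrant_total.copy(),
        macromolecule=iso.macromolecule.copy(),
        injection_volumes=iso.injection_volumes.copy(),
        moles_injected=None if iso.moles_injected is None
        else iso.moles_injected.copy(),
        dilution_method=method,
    )


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with asymptotic standard errors and fit SSE."""

    params: OneSiteParams | RacemicParams
    se: dict[str, float]
    sse: float
    dg: dict[str, float] = field(default_factory=dict)  # kJ/mol, from RT ln K_D


def _se_from_jac(jac: np.ndarray, sse: float, n: int) -> np.ndarray:
    p = jac.shape[1]
    s2 = sse / max(n - p, 1)
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _delta_g(kd_um: float, temperature: float) -> float:
    """Binding free energy RT ln K_D (kJ/mol), K_D converted to molar."""
    return R_GAS * temperature * np.log(kd_um * 1e-6)


def fit_one_site(
    iso: Isotherm,
    exp: ITCExperiment,
    weights: np.ndarray | None = None,
    drop_first: bool = False,
) -> FitResult:
    """Least-squares one-site fit of (N, K_D, dH, baseline) to heats.

    Multi-start over K_D decades (deterministic order, best SSE wins);
    K_D is optimized on a log scale.  ``drop_first`` excludes injection 1
    (a common ITC practice for syringe-tip diffusion artifacts); default
    keeps all injections.
    """
    q = np.asarray(iso.heats, dtype=float)
    n_inj = len(q)
    if n_inj < 5:
        raise ValueError("need >= 5 injections")
    if np.ptp(q) == 0:
        raise ValueError("unidentifiable: flat isotherm")
    w = np.ones(n_inj) if weights is None else np.asarray(weights, float)
    if drop_first:
        w = w.copy()
        w[0] = 0.0
    sw = np.sqrt(w)

    # rough dH from total evolved heat against full-saturation bound
    qsum = float(np.sum(q - np.median(q[-3:])))
    x_series, m_series = _injection_series(exp)
    bound_guess = min(m_series[-1], x_series[-1])
    dh0 = qsum / (exp.cell_volume * bound_guess * _UJ) if bound_guess > 0 else -40.0
    if dh0 == 0:
        dh0 = -40.0

    def resid(p: np.ndarray) -> np.ndarray:
        n_, logkd, dh, base = p
        model, _, _ = _model_heats(
            OneSiteParams(n=n_, kd=10.0 ** logkd, dh=dh, baseline=base), exp)
        return sw * (model - q)

    best = None
    for logkd0 in (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0):
        sol = least_squares(
            resid, [1.0, logkd0, dh0, 0.0],
            bounds=([1e-6, -9.0, -np.inf, -np.inf],
                    [100.0, 6.0, np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        sse = float(2 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
    sse, sol = best
    n_, logkd, dh, base = sol.x
    kd = 10.0 ** logkd
    se_raw = _se_from_jac(sol.jac, sse, int(np.sum(w > 0)))
    # delta-method back-transform for K_D (fitted on log10 scale)
    se = {
        "n": float(se_raw[0]),
        "kd": float(se_raw[1] * kd * np.log(10.0)),
        "dh": float(se_raw[2]),
        "baseline": float(se_raw[3]),
    }
    params = OneSiteParams(n=float(n_), kd=float(kd), dh=float(dh),
                           baseline=float(base))
    return FitResult(params=params, se=se, sse=sse,
                     dg={"dg": _delta_g(kd, exp.temperature)})


def fit_racemic(
    iso: Isotherm,
    exp: ITCExperiment,
    fraction_minus: float = 0.5,
    weights: np.ndarray | None = None,
    drop_first: bool = False,
) -> FitResult:
    """Competitive two-ligand fit with the enantiomer mole fraction fixed.

    Initialization comes from a one-site pre-fit, with the two K_D seeded
    +/- 1.5 decades around the pre-fit value (plus a degenerate equal-K_D
    start).  A warning field is set when the fitted affinities are within
    a factor of 5, where the two enantiomers are barely distinguishable.
    """
    q = np.asarray(iso.heats, dtype=float)
    n_inj = len(q)
    if n_inj < 5:
        raise ValueError("need >= 5 injections")
    if np.ptp(q) == 0:
        raise ValueError("unidentifiable: flat isotherm")
    w = np.ones(n_inj) if weights is None else np.asarray(weights, float)
    if drop_first:
        w = w.copy()
        w[0] = 0.0
    sw = np.sqrt(w)
    phi = fraction_minus
    if not 0.0 < phi < 1.0:
        raise ValueError("fraction_minus must be in (0, 1)")

    pre = fit_one_site(iso, exp, weights=weights, drop_first=drop_first)
    logkd0 = np.log10(pre.params.kd)
    dh0 = pre.params.dh

    def resid(p: np.ndarray) -> np.ndarray:
        n_, lk1, lk2, dh1, dh2, base = p
        model, _, _ = _model_heats(
            RacemicParams(n=n_, kd_minus=10.0 ** lk1, kd_plus=10.0 ** lk2,
                          dh_minus=dh1, dh_plus=dh2,
                          fraction_minus=phi, baseline=base),
            exp,
        )
        return sw * (model - q)

    starts = [
        (logkd0 - 1.5, logkd0 + 1.5),
        (logkd0 - 0.75, logkd0 + 0.75),
        (logkd0, logkd0),
    ]
    best = None
    for lk1, lk2 in starts:
        sol = least_squares(
            resid, [pre.params.n, lk1, lk2, dh0, dh0, pre.params.baseline],
            bounds=([1e-6, -9.0, -9.0, -np.inf, -np.inf, -np.inf],
                    [100.0, 6.0, 6.0, np.inf, np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        sse = float(2 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
    sse, sol = best
    n_, lk1, lk2, dh1, dh2, base = sol.x
    # convention: the tighter-binding species is reported as 'minus'
    if lk1 > lk2:
        lk1, lk2 = lk2, lk1
        dh1, dh2 = dh2, dh1
    kd1, kd2 = 10.0 ** lk1, 10.0 ** lk2
    if kd2 / kd1 < 5.0:
        import warnings

        warnings.warn(
            "enantiomer affinities differ by < 5-fold and may be "
            "unidentifiable from a racemic titration",
            stacklevel=2,
        )
    se_raw = _se_from_jac(sol.jac, sse, int(np.sum(w > 0)))
    se = {
        "n": float(se_raw[0]),
        "kd_minus": float(se_raw[1] * kd1 * np.log(10.0)),
        "kd_plus": float(se_raw[2] * kd2 * np.log(10.0)),
        "dh_minus": float(se_raw[3]),
        "dh_plus": float(se_raw[4]),
        "baseline": float(se_raw[5]),
    }
    params = RacemicParams(
        n=float(n_), kd_minus=float(kd1), kd_plus=float(kd2),
        dh_minus=float(dh1), dh_plus=float(dh2),
        fraction_minus=phi, baseline=float(base),
    )
    return FitResult(
        params=params, se=se, sse=sse,
        dg={"dg_minus": _delta_g(kd1, exp.temperature),
            "dg_plus": _delta_g(kd2, exp.temperature)},
    )
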