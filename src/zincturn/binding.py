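"""Self-assembly and competition metal-binding equilibria and their fits.

The model: n peptide chains P and one metal M assemble into MP_n with a
dissociation constant defined on the scale

    K_D = [M]_f^(1/n) [P]_f / [MP_n]^(1/n)

so that K_D has molar units and, for n = 2, [MP2] = [M]_f [P]_f^2 / K_D^2.
Competition between two metals for the same site is governed by the exchange
constant K_ex = [M2P2][M1]_f / ([M1P2][M2]_f), which ties the two
dissociation constants together as K_D2 = K_D1 / sqrt(K_ex).

The observable throughout is the saturation fraction Y = n[MP_n]/P_t, the
fraction of peptide chains bound in complex.  Converting raw absorbance to Y
(molar-absorptivity scaling) is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "BindingSystem",
    "SpeciationResult",
    "TitrationDataset",
    "BindingFit",
    "solve_single",
    "solve_competition",
    "simulate_titration",
    "fit_direct",
    "fit_competition",
    "fit_ph_midpoint",
]

_REL_TOL = 1e-12


@dataclass
class BindingSystem:
    """Totals and constants of a (possibly two-metal) binding system."""

    p_total: float  # total peptide, monomer units, M
    metal_totals: dict[str, float]
    k_d: dict[str, float]  # per metal, on the K_D = Mf^(1/n) Pf / C^(1/n) scale
    n: int = 2

    def __post_init__(self) -> None:
        if self.p_total < 0 or any(v < 0 for v in self.metal_totals.values()):
            raise ValueError("concentrations must be non-negative")
        if any(k <= 0 for k in self.k_d.values()):
            raise ValueError("dissociation constants must be positive")
        if self.n < 1:
            raise ValueError("stoichiometry n must be >= 1")


@dataclass
class SpeciationResult:
    """Equilibrium concentrations and saturation fractions."""

    p_free: float
    m_free: dict[str, float]
    complexes: dict[str, float]
    p_total: float
    n: float

    def saturation(self, metal: str) -> float:
        return self.n * self.complexes[metal] / self.p_total if self.p_total > 0 else 0.0


def _speciate(p_total: float, metal_totals: dict[str, float],
              k_d: dict[str, float], n: float) -> SpeciationResult:
    """Root-find the free-peptide concentration satisfying both balances."""
    if p_total <= 0:
        return SpeciationResult(0.0, dict(metal_totals), {m: 0.0 for m in metal_totals},
                                p_total, n)

    def complexes(p):
        return {
            m: metal_totals[m] * p**n / (k_d[m] ** n + p**n)
            for m in metal_totals
        }

    def resid(p):
        return p + n * sum(complexes(p).values()) - p_total

    lo = p_total * 1e-16
    if resid(lo) > 0:  # no metal: all peptide free
        p = p_total
    else:
        p = brentq(resid, lo, p_total, xtol=p_total * 1e-18, rtol=8.9e-16,
                   maxiter=300)
    comp = complexes(p)
    m_free = {m: metal_totals[m] - comp[m] for m in metal_totals}
    res = SpeciationResult(p_free=float(p), m_free=m_free, complexes=comp,
                           p_total=p_total, n=n)
    # mass-balance audit
    p_rec = res.p_free + n * sum(comp.values())
    if p_total > 0 and abs(p_rec - p_total) > 1e-9 * p_total:
        raise RuntimeError(f"peptide mass balance violated: {p_rec} vs {p_total}")
    return res


def solve_single(p_total: float, m_total: float, k_d: float, n: float = 2) -> SpeciationResult:
    """Equilibrium of one metal binding n peptides, by bracketed root finding
    on the free peptide concentration."""
    if min(p_total, m_total, k_d) <= 0:
        raise ValueError("p_total, m_total and k_d must be positive")
    return _speciate(p_total, {"M": m_total}, {"M": k_d}, n)


def solve_competition(
    p_total: float,
    m1_total: float,
    m2_total: float,
    k_d1: float,
    k_ex: float,
    n: float = 2,
) -> SpeciationResult:
    """Two metals competing for the same 2:1 site.

    Metal 2's dissociation constant is derived from the exchange constant:
    K_D2 = K_D1 / sqrt(K_ex).
    """
    if min(p_total, m1_total, k_d1, k_ex) <= 0 or m2_total < 0:
        raise ValueError("inputs must be positive (m2_total may be zero)")
    k_d2 = k_d1 / np.sqrt(k_ex)
    res = _speciate(p_total, {"M1": m1_total, "M2": m2_total},
                    {"M1": k_d1, "M2": k_d2}, n)
    # K_ex consistency audit (skipped in degenerate corners)
    if (res.complexes["M1"] > 1e-12 * p_total
            and res.m_free["M2"] > 1e-6 * m2_total and m2_total > 0):
        k_ex_obs = (res.complexes["M2"] * res.m_free["M1"]) / (
            res.complexes["M1"] * res.m_free["M2"]
        )
        if abs(k_ex_obs - k_ex) > 1e-9 * k_ex:
            raise RuntimeError("exchange-constant identity violated by solver")
    return res


@dataclass
class TitrationDataset:
    """A titration series: increasing titrant totals with observed Y."""

    p_total: float
    titrant_totals: np.ndarray
    observed: np.ndarray
    kind: str = "direct"  # direct | competition | ph
    noise_sd: float = 0.0
    seed: int | None = None
    #: competition runs carry the fixed companion-metal total here
    companion_total: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.titrant_totals = np.asarray(self.titrant_totals, float)
        self.observed = np.asarray(self.observed, float)
        if self.kind != "ph" and np.any(np.diff(self.titrant_totals) <= 0):
            raise ValueError("titrant totals must be strictly increasing")


def direct_curve(p_total: float, m_grid: np.ndarray, k_d: float, n: float = 2) -> np.ndarray:
    """Saturation fraction along a direct-titration grid."""
    return np.array([
        solve_single(p_total, m, k_d, n).saturation("M") if m > 0 else 0.0
        for m in m_grid
    ])


def competition_curve(
    p_total: float, m1_total: float, m2_grid: np.ndarray, k_d1: float, k_ex: float,
    n: float = 2,
) -> np.ndarray:
    """Remaining metal-1 saturation as metal 2 is titrated in."""
    out = []
    for m2 in m2_grid:
        if m2 <= 0:
            res = solve_single(p_total, m1_total, k_d1, n)
            out.append(res.saturation("M"))
        else:
            res = solve_competition(p_total, m1_total, m2, k_d1, k_ex, n)
            out.append(res.saturation("M1"))
    return np.array(out)


def simulate_titration(
    system: BindingSystem,
    titrant_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    titrant: str | None = None,
) -> TitrationDataset:
    """Solver curve plus i.i.d. Gaussian noise, reproducible per seed.

    For a one-metal system the titrant is that metal (direct titration);
    for a two-metal system the named ``titrant`` is varied and the other
    metal's saturation is observed (competition).
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    grid = np.asarray(titrant_grid, float)
    metals = list(system.metal_totals)
    if len(metals) == 1:
        kind = "direct"
        y = direct_curve(system.p_total, grid, system.k_d[metals[0]], system.n)
        companion = 0.0
    else:
        kind = "competition"
        if titrant is None or titrant not in metals:
            raise ValueError("competition simulation needs the titrated metal name")
        held = next(m for m in metals if m != titrant)
        k_ex = (system.k_d[held] / system.k_d[titrant]) ** 2
        y = competition_curve(system.p_total, system.metal_totals[held], grid,
                              system.k_d[held], k_ex, system.n)
        companion = system.metal_totals[held]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return TitrationDataset(
        p_total=system.p_total, titrant_totals=grid, observed=y, kind=kind,
        noise_sd=noise_sd, seed=seed, companion_total=companion,
    )


@dataclass
class BindingFit:
    k_d: float
    k_d_se: float
    n: float
    rss: float
    k_ex: float | None = None
    k_ex_se: float | None = None
    k_d_derived: float | None = None
    k_d_derived_se: float | None = None


def _se_from_jacobian(result, n_points: int) -> np.ndarray:
    """Asymptotic standard errors of least-squares parameters."""
    _, s, vt = np.linalg.svd(result.jac, full_matrices=False)
    s = np.where(s > 1e-12 * s[0], s, np.inf)
    cov = (vt.T / s**2) @ vt
    dof = max(n_points - result.x.size, 1)
    sigma2 = 2 * result.cost / dof
    return np.sqrt(np.diag(cov) * sigma2)


def fit_direct(data: TitrationDataset, fit_n: bool = True,
               k_d0: float = 1e-4, n0: float = 2.0) -> BindingFit:
    """Least-squares fit of K_D (log-parameterized) and optionally n to a
    direct titration."""
    import warnings

    y = data.observed
    if len(y) < 6 or y.min() > 0.2 or y.max() < 0.8:
        warnings.warn("titration poorly conditioned: fewer than 6 points or "
                      "saturation range not spanning 0.2-0.8", stacklevel=2)

    grid = data.titrant_totals

    def model(log10_kd, n):
        return direct_curve(data.p_total, grid, 10.0**log10_kd, n)

    if fit_n:
        res = least_squares(
            lambda th: model(th[0], th[1]) - y,
            x0=[np.log10(k_d0), n0], bounds=([-12, 1.0], [0, 6.0]),
        )
        log_kd, n_hat = res.x
    else:
        res = least_squares(
            lambda th: model(th[0], n0) - y, x0=[np.log10(k_d0)],
            bounds=([-12], [0]),
        )
        log_kd, n_hat = res.x[0], n0
    if not res.success:
        raise RuntimeError(f"direct fit failed: {res.message}")
    se = _se_from_jacobian(res, len(y))
    k_d = 10.0**log_kd
    k_d_se = k_d * np.log(10) * se[0]
    return BindingFit(k_d=float(k_d), k_d_se=float(k_d_se), n=float(n_hat),
                      rss=float(np.sum((res.fun) ** 2)))


def fit_competition(data: TitrationDataset, k_d1: float, n: float = 2,
                    k_ex0: float = 100.0) -> BindingFit:
    """Fit the exchange constant on a displacement curve, with the direct-fit
    K_D of the first metal held fixed; reports K_ex and the derived
    K_D2 = K_D1 / sqrt(K_ex) with propagated SE."""
    y = data.observed
    grid = data.titrant_totals
    m1 = data.companion_total
    if m1 <= 0:
        raise ValueError("competition dataset lacks the held metal total")

    def model(log10_kex):
        return competition_curve(data.p_total, m1, grid, k_d1, 10.0**log10_kex, n)

    res = least_squares(lambda th: model(th[0]) - y, x0=[np.log10(k_ex0)],
                        bounds=([-8], [12]))
    if not res.success:
        raise RuntimeError(f"competition fit failed: {res.message}")
    se = _se_from_jacobian(res, len(y))
    k_ex = 10.0 ** res.x[0]
    k_ex_se = k_ex * np.log(10) * se[0]
    k_d2 = k_d1 / np.sqrt(k_ex)
    # delta method: dK2/dKex = -K2 / (2 Kex)
    k_d2_se = k_d2 * k_ex_se / (2 * k_ex)
    return BindingFit(k_d=float(k_d1), k_d_se=0.0, n=float(n),
                      rss=float(np.sum(res.fun**2)),
                      k_ex=float(k_ex), k_ex_se=float(k_ex_se),
                      k_d_derived=float(k_d2), k_d_derived_se=float(k_d2_se))


def fit_ph_midpoint(ph: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    """Two-state sigmoid fit: signal = lo + (hi-lo)/(1 + 10^(h (pH_mid - pH))).

    Returns (midpoint, SE).  Sign-agnostic: rising and falling transitions
    both work.  Requires points bracketing the transition.
    """
    ph = np.asarray(ph, float)
    signal = np.asarray(signal, float)
    if len(ph) < 5:
        raise ValueError("need at least 5 points bracketing the transition")

    lo0, hi0 = float(signal[0]), float(signal[-1])
    mid0 = float(ph[np.argmin(np.abs(signal - (lo0 + hi0) / 2))])

    def model(th):
        lo, hi, mid, hill = th
        return lo + (hi - lo) / (1.0 + 10.0 ** (hill * (mid - ph)))

    res = least_squares(lambda th: model(th) - signal,
                        x0=[lo0, hi0, mid0, 1.0],
                        bounds=([-np.inf, -np.inf, ph.min(), 0.05],
                                [np.inf, np.inf, ph.max(), 50.0]))
    if not res.success:
        raise RuntimeError(f"pH fit failed: {res.message}")
    mid = float(res.x[2])
    if not ph.min() < mid < ph.max():
        raise RuntimeError("fitted midpoint outside the measured pH range")
    se = _se_from_jacobian(res, len(ph))
    return mid, float(se[2])
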