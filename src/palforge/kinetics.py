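"""Initial-rate estimation, Michaelis-Menten fitting, product quantification
and pH/temperature optimum profiling."""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

PRODUCT_KINDS = ("substrate", "hydrolysis", "cyclic")


class KineticsError(ValueError):
    pass


class FitConvergenceError(KineticsError):
    """Nonlinear fit failed; carries the final residuals for inspection."""

    def __init__(self, message: str, residuals: np.ndarray):
        super().__init__(f"{message}; final residuals: {np.asarray(residuals)}")
        self.residuals = np.asarray(residuals)


@dataclass(frozen=True)
class TimeCourse:
    """A quenched-aliquot product time course at one substrate concentration.

    ``samples`` are (time in seconds, product quantity in the same
    concentration unit as ``substrate_conc``, i.e. micromolar).
    """

    substrate_conc: float  # uM
    enzyme_conc: float  # M
    samples: tuple[tuple[float, float], ...]
    condition: tuple[float, float, str] | None = None  # (pH, temp C, E:S)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise KineticsError("sample times must be strictly increasing")
        if any(q < 0 for _, q in self.samples):
            raise KineticsError("product quantities must be non-negative")
        if self.substrate_conc <= 0:
            raise KineticsError("substrate concentration must be positive")


@dataclass(frozen=True)
class InitialRate:
    rate: float  # uM/s
    intercept: float
    r_squared: float
    points_used: tuple[tuple[float, float], ...]
    n_points: int


def estimate_initial_rate(
    tc: TimeCourse, max_conversion: float = 0.15
) -> InitialRate:
    """Slope of the least-squares line through the early, pre-saturation
    samples (conversion <= ``max_conversion``); intercept left free.

    Requires at least three eligible points; otherwise the rejection
    message lists the conversion reached at every sample.
    """
    conversions = [(t, q, q / tc.substrate_conc) for t, q in tc.samples]
    eligible = [(t, q) for t, q, c in conversions if c <= max_conversion]
    if len(eligible) < 3:
        detail = ", ".join(f"t={t:g}s: {c:.1%}" for t, _, c in conversions)
        raise KineticsError(
            f"need >=3 samples at conversion <= {max_conversion:.0%}, "
            f"have {len(eligible)} ({detail})"
        )
    t = np.array([p[0] for p in eligible])
    q = np.array([p[1] for p in eligible])
    slope, intercept = np.polyfit(t, q, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((q - pred) ** 2))
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return InitialRate(float(slope), float(intercept), r2, tuple(eligible), len(eligible))


@dataclass(frozen=True)
class KineticFit:
    kcat: float  # s^-1
    km: float  # uM
    kcat_over_km: float  # M^-1 s^-1
    vmax: float  # uM/s
    standard_errors: dict[str, float]
    residuals: tuple[float, ...]
    n_points: int
    r_squared: float


def catalytic_efficiency(kcat: float, km_uM: float) -> float:
    """kcat/KM in M^-1 s^-1 from kcat in s^-1 and KM in micromolar."""
    return kcat / (km_uM * 1e-6)


def fit_michaelis_menten(
    substrate_uM: Iterable[float],
    rates_uM_per_s: Iterable[float],
    enzyme_conc: float,
) -> KineticFit:
    """Nonlinear least squares of v = Vmax*S/(KM+S).

    Initialization: Vmax0 = 1.1 x max rate, KM0 = median substrate
    concentration; residual-norm tolerance 1e-10. kcat = Vmax/E0 with the
    enzyme concentration in molar. Degenerate designs (KM driven to a
    bound, or solver failure) raise :class:`FitConvergenceError` with the
    final residuals — never a silent bad fit.
    """
    s = np.asarray(list(substrate_uM), dtype=float)
    v = np.asarray(list(rates_uM_per_s), dtype=float)
    if s.shape != v.shape or s.size == 0:
        raise KineticsError("substrate and rate arrays must be equal-length and non-empty")
    if len(np.unique(s)) < 4:
        raise KineticsError("need >=4 distinct substrate concentrations")
    if enzyme_conc <= 0:
        raise KineticsError("enzyme concentration must be positive")

    def resid(theta: np.ndarray) -> np.ndarray:
        vmax, km = theta
        return vmax * s / (km + s) - v

    x0 = np.array([1.1 * float(v.max()), float(np.median(s))])
    sol = least_squares(
        resid, x0, bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=1e-12, ftol=1e-10, gtol=1e-12,
    )
    if not sol.success:
        raise FitConvergenceError("Michaelis-Menten fit did not converge", sol.fun)
    vmax, km = sol.x
    # a KM far outside the measured substrate range means the design carried
    # no curvature information; report it as a failed fit, not an estimate
    if km < 1e-3 * float(s.min()) or km > 1e3 * float(s.max()):
        raise FitConvergenceError(
            f"KM estimate {km:.3g} uM outside the identifiable range "
            f"[{1e-3 * s.min():.3g}, {1e3 * s.max():.3g}] (degenerate design)",
            sol.fun,
        )
    if vmax <= 0 or km <= 0:
        raise FitConvergenceError("non-positive parameter estimate", sol.fun)

    n, p = s.size, 2
    dof = max(n - p, 1)
    ss_res = float(np.sum(sol.fun**2))
    jac = sol.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * ss_res / dof
        se = {"vmax": math.sqrt(cov[0, 0]), "km": math.sqrt(cov[1, 1])}
    except np.linalg.LinAlgError:
        se = {"vmax": float("nan"), "km": float("nan")}
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    e0_uM = enzyme_conc * 1e6
    kcat = vmax / e0_uM
    se["kcat"] = se["vmax"] / e0_uM
    return KineticFit(
        kcat=float(kcat),
        km=float(km),
        kcat_over_km=catalytic_efficiency(float(kcat), float(km)),
        vmax=float(vmax),
        standard_errors=se,
        residuals=tuple(float(r) for r in sol.fun),
        n_points=n,
        r_squared=r2,
    )


@dataclass(frozen=True)
class ProductQuantification:
    percent_hydrolyzed: float
    percent_cyclized: float
    percent_remaining: float
    ch_ratio: float | None  # None when percent_hydrolyzed == 0 and cyclized > 0
    condition: tuple | None = None


def quantify_products(
    areas: Mapping[str, float],
    kinds: Mapping[str, str],
    calibration: Mapping[str, float] | None = None,
    condition: tuple | None = None,
) -> ProductQuantification:
    """Percent shares per species class from peak signals.

    ``kinds`` labels each species as substrate / hydrolysis / cyclic;
    ``calibration`` holds optional per-species response factors (signal
    divided by factor; default 1). C/H = cyclized share over hydrolyzed
    share; 0 when nothing cyclized, undefined (None) when cyclized but
    nothing hydrolyzed.
    """
    if not areas:
        raise KineticsError("no species signals supplied")
    corrected: dict[str, float] = {}
    for species, signal in areas.items():
        kind = kinds.get(species)
        if kind not in PRODUCT_KINDS:
            raise KineticsError(
                f"species {species!r} has kind {kind!r}; expected one of {PRODUCT_KINDS}"
            )
        rf = 1.0 if calibration is None else calibration.get(species, 1.0)
        corrected[species] = signal / rf
    total = sum(corrected.values())
    if total <= 0:
        raise KineticsError("all species signals are zero")
    share = {k: 0.0 for k in PRODUCT_KINDS}
    for species, signal in corrected.items():
        share[kinds[species]] += 100.0 * signal / total
    h, c = share["hydrolysis"], share["cyclic"]
    if h > 0:
        ch: float | None = c / h
    elif c == 0:
        ch = 0.0
    else:
        ch = None
    return ProductQuantification(h, c, share["substrate"], ch, condition)


def cyclization_yield_from_ch(ch_ratio: float) -> float:
    """Percent of reacted substrate that cyclized, C/(C+H)*100, from C/H."""
    if ch_ratio < 0:
        raise KineticsError("C/H ratio must be non-negative")
    return 100.0 * ch_ratio / (1.0 + ch_ratio)


@dataclass(frozen=True)
class OptimumProfile:
    grid: tuple[tuple[float, float, float], ...]  # (pH, temperature, mean rate)
    optima: tuple[tuple[float, float], ...]

    @property
    def optimum(self) -> tuple[float, float]:
        return self.optima[0]


def profile_optimum(
    measurements: Iterable[tuple[float, float, float]]
) -> OptimumProfile:
    """Argmax of the mean rate over a measured (pH, temperature) grid.

    Replicates at the same condition are averaged; exact ties are all
    reported. No interpolation beyond the grid.
    """
    buckets: dict[tuple[float, float], list[float]] = {}
    for ph, temp, rate in measurements:
        buckets.setdefault((ph, temp), []).append(rate)
    if not buckets:
        raise KineticsError("no grid measurements supplied")
    grid = tuple(
        (ph, temp, float(np.mean(rates))) for (ph, temp), rates in sorted(buckets.items())
    )
    best = max(r for _, _, r in grid)
    optima = tuple((ph, temp) for ph, temp, r in grid if r == best)
    return OptimumProfile(grid, optima)
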