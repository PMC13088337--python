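"""Enzyme-efficiency metrics and correlation statistics.

Conversion, total turnover number (TTN), coupling efficiency, nonlinear
Michaelis–Menten fitting, and Pearson correlation with a two-sided
t-distribution p-value — the quantitative glue between assay tables and
the mechanistic analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "AssayRecord",
    "KineticsDataset",
    "MichaelisFit",
    "CorrelationResult",
    "conversion_percent",
    "ttn",
    "coupling_percent",
    "fit_michaelis_menten",
    "pearson",
]


@dataclass(frozen=True)
class AssayRecord:
    """End-point assay amounts: product / substrate / NADH in mM, enzyme in µM."""

    product_amount: float = 0.0
    substrate_amount: float = 0.0
    nadh_consumed: float = 0.0
    enzyme_conc: float = 0.0

    def __post_init__(self):
        for f in ("product_amount", "substrate_amount", "nadh_consumed", "enzyme_conc"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class KineticsDataset:
    """Substrate–velocity pairs; velocities as per-enzyme turnover (s^-1) by
    default, or concentration rate with ``enzyme_conc`` supplied to the fit."""

    substrate_concs: np.ndarray  # mM
    velocities: np.ndarray

    def __post_init__(self):
        self.substrate_concs = np.asarray(self.substrate_concs, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.substrate_concs.size != self.velocities.size:
            raise ValueError("substrate and velocity arrays must be the same length")
        if self.substrate_concs.size < 3:
            raise ValueError("need at least 3 substrate concentrations")
        if np.any(self.substrate_concs <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.unique(self.substrate_concs).size != self.substrate_concs.size:
            raise ValueError("substrate concentrations must be distinct")


@dataclass
class MichaelisFit:
    Km: float  # mM
    Vmax: float  # velocity units
    kcat: float | None  # s^-1, when normalizable
    catalytic_efficiency: float  # kcat/Km (or Vmax/Km), mM^-1 s^-1
    residual_sse: float
    km_at_lower_bound: bool = False
    km_at_upper_bound: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation out of [-1, 1]")


def conversion_percent(record: AssayRecord) -> float:
    """Conversion (%) = 100 * product / (product + substrate)."""
    total = record.product_amount + record.substrate_amount
    if total <= 0:
        raise ValueError("product + substrate must be positive")
    return 100.0 * record.product_amount / total


def ttn(record: AssayRecord) -> float:
    """Total turnover number = product (mM) / enzyme (µM), unit-consistent
    (×1000 for the mM→µM mismatch)."""
    if record.enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    return 1000.0 * record.product_amount / record.enzyme_conc


def coupling_percent(record: AssayRecord) -> float:
    """Coupling efficiency (%) = 100 * product / NADH consumed."""
    if record.nadh_consumed <= 0:
        raise ValueError("NADH consumption must be positive")
    return 100.0 * record.product_amount / record.nadh_consumed


def michaelis_menten(S, Vmax, Km):
    return Vmax * S / (Km + S)


def fit_michaelis_menten(
    data: KineticsDataset,
    enzyme_conc: float | None = None,
    weighted: bool = False,
) -> MichaelisFit:
    """Nonlinear least-squares fit of v = Vmax S / (Km + S).

    Log-parameterized to keep both parameters positive; initialized at
    Vmax = max(v), Km = median(S).  ``enzyme_conc`` (µM) converts a
    concentration-rate Vmax (mM/s) to kcat; with turnover-velocity input
    leave it None and kcat = Vmax.  Optional 1/v^2 weighting.
    """
    S, v = data.substrate_concs, data.velocities
    km_lo = 1e-4 * float(S.min())
    km_hi = 1e4 * float(S.max())

    def model_log(S_, lnV, lnK):
        return michaelis_menten(S_, np.exp(lnV), np.exp(lnK))

    p0 = [np.log(max(v.max(), 1e-12)), np.log(np.median(S))]
    bounds = (
        [p0[0] + np.log(1e-6), np.log(km_lo)],
        [p0[0] + np.log(1e6), np.log(km_hi)],
    )
    sigma = np.abs(v) if weighted else None
    try:
        popt, _ = curve_fit(
            model_log, S, v, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Michaelis–Menten fit failed to converge: {exc}; "
            f"S range {S.min()}–{S.max()}, v range {v.min()}–{v.max()}"
        ) from None
    Vmax, Km = float(np.exp(popt[0])), float(np.exp(popt[1]))
    resid = v - michaelis_menten(S, Vmax, Km)
    kcat = Vmax if enzyme_conc is None else 1000.0 * Vmax / enzyme_conc
    # Km outside the probed substrate range means the dataset cannot
    # identify it (saturated or linear regime); flag rather than fail
    return MichaelisFit(
        Km=Km,
        Vmax=Vmax,
        kcat=kcat,
        catalytic_efficiency=kcat / Km,
        residual_sse=float((resid**2).sum()),
        km_at_lower_bound=Km < 0.1 * float(S.min()),
        km_at_upper_bound=Km > 10.0 * float(S.max()),
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value from the t-distribution
    with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_two_sided=float(res.pvalue), n=n)
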