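"""Umbrella-sampling free energies: MBAR reweighting, PMF projection,
dihedral PCA, barrier extraction, and conformer classification.

The estimator is the multistate Bennett acceptance ratio (MBAR): given K
biased windows with N_k samples each, the per-window free energies f_k
satisfy

    exp(-f_k / kBT) = sum_n exp(-U_k(x_n)/kBT) / D_n,
    D_n = sum_j N_j exp((f_j - U_j(x_n))/kBT),

with f_1 = 0.  Unbiased weights w_n ∝ 1/D_n reweight the pooled samples to
the unbiased ensemble; the PMF along any collective variable s is
F(s) = -kBT ln P(s) over a weighted histogram.  The solver iterates the
self-consistent update with log-sum-exp stabilization, accelerated by
damped Newton steps on the convex MBAR objective, until the stated
tolerance on max |Δf| is met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KB_KCAL

__all__ = [
    "UmbrellaWindow",
    "BiasModel",
    "MBARResult",
    "CollectiveVariable",
    "DihedralPCAModel",
    "FreeEnergyProfile",
    "generate_window_centers",
    "apply_burn_in",
    "solve_mbar",
    "fit_dihedral_pca",
    "project_pmf",
    "extract_barrier",
    "classify_conformation",
]


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic restraint and its reaction-coordinate samples."""

    window_id: int
    bias_center: float  # Å or CV units
    force_constant: float  # kcal/mol/Å^2; 0 denotes an unbiased window
    rc_samples: np.ndarray
    feature_samples: np.ndarray | None = None  # (n, m) dihedrals, radians
    n_discarded: int = 0

    def __post_init__(self):
        self.rc_samples = np.asarray(self.rc_samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.rc_samples.size < 1:
            raise ValueError(f"window {self.window_id}: needs at least one sample")
        if self.feature_samples is not None:
            self.feature_samples = np.atleast_2d(
                np.asarray(self.feature_samples, dtype=float)
            )
            if self.feature_samples.shape[0] != self.rc_samples.size:
                raise ValueError(
                    f"window {self.window_id}: feature_samples not aligned with rc_samples"
                )


@dataclass(frozen=True)
class BiasModel:
    """Harmonic-bias convention and thermodynamic state.

    ``k_full`` means U = k (ξ-ξ0)^2 (no 1/2), ``k_half`` U = k/2 (ξ-ξ0)^2.
    """

    convention: str = "k_full"
    temperature: float = 300.0  # K
    kB: float = KB_KCAL

    def __post_init__(self):
        if self.convention not in ("k_full", "k_half"):
            raise ValueError(f"unknown bias convention {self.convention!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        return self.kB * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kBT

    def bias_energy(self, window: UmbrellaWindow, x: np.ndarray) -> np.ndarray:
        """Restraint energy of ``window`` at positions ``x``, kcal/mol."""
        pref = window.force_constant if self.convention == "k_full" else 0.5 * window.force_constant
        return pref * (np.asarray(x, float) - window.bias_center) ** 2


@dataclass
class MBARResult:
    free_energies: np.ndarray  # per window, kcal/mol, f[0] == 0
    log_weights: np.ndarray  # per retained sample, normalized
    n_retained_per_window: np.ndarray
    converged: bool
    final_residual: float  # max |Δf| at termination, kcal/mol
    bias: BiasModel = field(default_factory=BiasModel)
    free_energy_cov: np.ndarray | None = None  # asymptotic, kcal^2

    @property
    def sample_weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def free_energy_se(self, reference: int = 0) -> np.ndarray:
        """Asymptotic standard error of f_k - f_reference, kcal/mol."""
        if self.free_energy_cov is None:
            raise ValueError("covariance was not computed")
        T = self.free_energy_cov
        var = np.diag(T) + T[reference, reference] - 2 * T[reference]
        return np.sqrt(np.clip(var, 0.0, None))


@dataclass
class CollectiveVariable:
    """A named scalar function of a sample (rc value and/or feature vector)."""

    name: str
    evaluator: Callable


@dataclass
class DihedralPCAModel:
    """PCA over sin/cos-embedded backbone dihedrals."""

    feature_mean: np.ndarray
    components: np.ndarray  # orthonormal rows, decreasing variance
    explained_variance: np.ndarray

    def embed(self, dihedrals: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(dihedrals, float))
        return np.concatenate([np.cos(x), np.sin(x)], axis=1)

    def pc1_score(self, dihedrals: np.ndarray) -> np.ndarray:
        z = self.embed(dihedrals) - self.feature_mean
        score = z @ self.components[0]
        return score if score.size > 1 else float(score[0])


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    F: np.ndarray  # kcal/mol, min-shifted to 0, NaN where empty
    bin_counts: np.ndarray  # effective weight per bin
    empty_bin_mask: np.ndarray
    single_bin_warning: bool = False


def generate_window_centers(rc_min: float, rc_max: float, spacing: float) -> np.ndarray:
    """Inclusive arithmetic window-center sequence rc_min, ..., rc_max."""
    if rc_max <= rc_min:
        raise ValueError("rc_max must exceed rc_min")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n_float = (rc_max - rc_min) / spacing
    n = round(n_float)
    if abs(n_float - n) > 1e-6:
        raise ValueError(
            f"range ({rc_min}, {rc_max}) is not commensurate with spacing {spacing}"
        )
    return rc_min + spacing * np.arange(n + 1)


def apply_burn_in(
    windows: Sequence[UmbrellaWindow], fraction: float = 0.15
) -> list[UmbrellaWindow]:
    """Discard the first ceil(fraction*n) samples of each window."""
    if not (0 <= fraction < 1):
        raise ValueError("burn-in fraction must lie in [0, 1)")
    out = []
    for w in windows:
        n = w.rc_samples.size
        drop = math.ceil(fraction * n)
        if drop >= n:
            raise ValueError(f"burn-in empties window {w.window_id}")
        out.append(
            UmbrellaWindow(
                window_id=w.window_id,
                bias_center=w.bias_center,
                force_constant=w.force_constant,
                rc_samples=w.rc_samples[drop:],
                feature_samples=(
                    None if w.feature_samples is None else w.feature_samples[drop:]
                ),
                n_discarded=drop,
            )
        )
    return out


def _reduced_bias_matrix(windows, bias: BiasModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.concatenate([w.rc_samples for w in windows])
    N_k = np.array([w.rc_samples.size for w in windows])
    u_kn = np.empty((len(windows), x.size))
    for k, w in enumerate(windows):
        u_kn[k] = bias.beta * bias.bias_energy(w, x)
    return x, N_k, u_kn


def solve_mbar(
    windows: Sequence[UmbrellaWindow],
    bias: BiasModel = BiasModel(),
    tolerance: float = 1e-8,
    max_iter: int = 100_000,
) -> MBARResult:
    """Solve the MBAR self-consistent equations for the window free energies.

    Returns per-window free energies (kcal/mol, first window fixed at 0) and
    normalized unbiased per-sample log-weights.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    x, N_k, u_kn = _reduced_bias_matrix(windows, bias)
    if not np.all(np.isfinite(u_kn)):
        raise ValueError("non-finite bias energies encountered")
    K, N = u_kn.shape
    logN_k = np.log(N_k)

    def log_denom(f_hat: np.ndarray) -> np.ndarray:
        # log D_n = logsumexp_k [ log N_k + f_k - u_kn ]
        return logsumexp(logN_k[:, None] + f_hat[:, None] - u_kn, axis=0)

    def sc_update(f_hat: np.ndarray) -> np.ndarray:
        ld = log_denom(f_hat)
        f_new = -logsumexp(-u_kn - ld[None, :], axis=1)
        return f_new - f_new[0]

    def newton_step(f_hat: np.ndarray) -> np.ndarray | None:
        # mixture responsibilities p_kn = N_k e^{f_k - u_kn} / D_n sum to 1
        # over k; gradient and Hessian of the convex MBAR objective follow.
        ld = log_denom(f_hat)
        P = np.exp(logN_k[:, None] + f_hat[:, None] - u_kn - ld[None, :])
        rowsum = P.sum(axis=1)
        g = rowsum - N_k
        H = np.diag(rowsum) - P @ P.T
        try:
            delta = np.linalg.solve(H[1:, 1:], -g[1:])
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(delta)):
            return None
        # damp very large steps to stay in the convergence basin
        scale = np.max(np.abs(delta))
        if scale > 20.0:
            delta = delta * (20.0 / scale)
        f_new = f_hat.copy()
        f_new[1:] += delta
        return f_new - f_new[0]

    kBT = bias.kBT
    residual = np.inf
    converged = False
    f_hat = np.zeros(K)
    for it in range(max_iter):
        f_sc = sc_update(f_hat)
        residual = float(np.max(np.abs(f_sc - f_hat)) * kBT)
        if residual <= tolerance:
            f_hat = f_sc
            converged = True
            break
        f_next = newton_step(f_sc) if K > 1 else f_sc
        f_hat = f_sc if f_next is None else f_next

    ld = log_denom(f_hat)
    log_w = -ld  # U0 == 0
    log_w = log_w - logsumexp(log_w)

    # asymptotic covariance of the reduced free energies (normalized-weight
    # matrix W_nk, Theta = V S (I - S V' N V S)^+ S V' via thin SVD)
    W = np.exp(f_hat[None, :] - u_kn.T - ld[:, None])
    cov = None
    try:
        _, S, Vt = np.linalg.svd(W, full_matrices=False)
        inner = np.eye(K) - (S[:, None] * Vt) @ (N_k[:, None] * Vt.T) * S[None, :]
        theta = Vt.T @ (S[:, None] * np.linalg.pinv(inner, rcond=1e-10) * S[None, :]) @ Vt
        cov = theta * kBT**2
    except np.linalg.LinAlgError:
        pass

    return MBARResult(
        free_energies=f_hat * kBT,
        log_weights=log_w,
        n_retained_per_window=N_k,
        converged=converged,
        final_residual=residual,
        bias=bias,
        free_energy_cov=cov,
    )


def fit_dihedral_pca(feature_samples: np.ndarray) -> DihedralPCAModel:
    """PCA on (cos, sin)-embedded dihedral samples, components by decreasing
    variance; each component's sign fixed so its largest-|loading| entry is
    positive."""
    X = np.atleast_2d(np.asarray(feature_samples, dtype=float))
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 dihedral")
    Z = np.concatenate([np.cos(X), np.sin(X)], axis=1)
    mean = Z.mean(axis=0)
    Zc = Z - mean
    cov = Zc.T @ Zc / Zc.shape[0]
    total_var = float(np.trace(cov))
    if total_var < 1e-14:
        raise ValueError("zero total variance: all samples identical")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T
    for r in range(comps.shape[0]):
        lead = np.argmax(np.abs(comps[r]))
        if comps[r, lead] < 0:
            comps[r] = -comps[r]
    return DihedralPCAModel(
        feature_mean=mean, components=comps, explained_variance=evals
    )


def _weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    return float(np.interp(q / 100.0, cdf, v))


def project_pmf(
    mbar: MBARResult,
    cv: CollectiveVariable | None,
    samples,
    n_bins: int = 50,
    bin_edges: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """Project the unbiased ensemble onto a collective variable.

    ``samples`` is passed to ``cv.evaluator`` (or used directly as scalars
    when ``cv`` is None); the per-sample MBAR weights form a weighted
    histogram, and F(s) = -kBT ln P(s), min-shifted to zero with empty bins
    masked as NaN.
    """
    if not mbar.converged:
        raise ValueError("MBAR result is not converged; refusing to project")
    if cv is None:
        s = np.asarray(samples, dtype=float)
    else:
        s = np.asarray(cv.evaluator(samples), dtype=float)
    w = mbar.sample_weights
    if s.shape != w.shape:
        raise ValueError("collective-variable values not aligned with weights")
    single_bin = False
    if bin_edges is None:
        lo = _weighted_percentile(s, w, 0.5)
        hi = _weighted_percentile(s, w, 99.5)
        if hi <= lo:
            lo, hi = s.min(), s.max()
        if hi <= lo:  # all samples at one value
            single_bin = True
            lo, hi = lo - 0.5, hi + 0.5
            n_bins = 1
        bin_edges = np.linspace(lo, hi, n_bins + 1)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
    hist, edges = np.histogram(s, bins=bin_edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    empty = hist <= 0
    if np.count_nonzero(~empty) == 1:
        single_bin = True
    kBT = mbar.bias.kBT
    with np.errstate(divide="ignore"):
        F = -kBT * np.log(hist / total)
    F[empty] = np.nan
    F = F - np.nanmin(F)
    return FreeEnergyProfile(
        bin_centers=centers,
        F=F,
        bin_counts=hist,
        empty_bin_mask=empty,
        single_bin_warning=single_bin,
    )


def extract_barrier(
    profile: FreeEnergyProfile,
    basin_A_range: tuple[float, float],
    basin_B_range: tuple[float, float],
) -> tuple[float, float]:
    """Barrier and basin free-energy difference from a 1-D profile.

    Returns (ΔF_barrier, ΔF_AB): the maximum F on the span between the two
    basin minima relative to the basin-A minimum, and F(B minimum) - F(A
    minimum), both kcal/mol.
    """
    aLo, aHi = sorted(basin_A_range)
    bLo, bHi = sorted(basin_B_range)
    if max(aLo, bLo) < min(aHi, bHi):
        raise ValueError("basin ranges must not overlap")
    c, F = profile.bin_centers, profile.F
    inA = (c >= aLo) & (c <= aHi) & ~np.isnan(F)
    inB = (c >= bLo) & (c <= bHi) & ~np.isnan(F)
    if not inA.any() or not inB.any():
        raise ValueError("each basin range must contain a non-empty bin")
    iA = int(np.flatnonzero(inA)[np.nanargmin(F[inA])])
    iB = int(np.flatnonzero(inB)[np.nanargmin(F[inB])])
    lo, hi = sorted((iA, iB))
    span = F[lo : hi + 1]
    barrier = float(np.nanmax(span) - F[iA])
    dF_AB = float(F[iB] - F[iA])
    return barrier, dF_AB


def classify_conformation(d_fes_heme: float) -> str:
    """Classify a [2Fe-2S]-to-heme iron distance as distal (>22 Å),
    proximal (<20 Å), or intermediate."""
    if d_fes_heme < 0:
        raise ValueError("distance must be non-negative")
    if d_fes_heme > 22.0:
        return "distal"
    if d_fes_heme < 20.0:
        return "proximal"
    return "intermediate"
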