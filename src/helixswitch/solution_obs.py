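"""Solution observables that discriminate the short and long states.

SAXS side: Debye-formula model profiles from CA coordinates, Guinier fits,
normalized Kratky curves (peak position/height report compactness vs
elongation), and two-state profile fitting where the better-fitting state is
taken as dominant in solution.  NMR side: combined chemical-shift deviations
for methyl (1H/13C) and amide (1H/15N) groups.

Profiles use the common 3-column SAXS dialect (q in Å⁻¹, intensity,
optional uncertainty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist

from . import constants as C
from .errors import FitError, ParameterError

__all__ = [
    "ScatteringProfile",
    "CSDRecord",
    "debye_profile",
    "radius_of_gyration",
    "guinier_fit",
    "normalized_kratky",
    "fit_states",
    "csd_methyl",
    "csd_amide",
]


@dataclass
class ScatteringProfile:
    """A scattering curve on a strictly increasing q grid (q >= 0 allowed)."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ParameterError("q and I must be 1-D arrays of equal length")
        if np.any(self.q < 0):
            raise ParameterError("q values must be non-negative")
        if np.any(np.diff(self.q) <= 0):
            raise ParameterError("q grid must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ParameterError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape or np.any(self.sigma <= 0):
                raise ParameterError("sigma must be positive and match q")

    def effective_sigma(self) -> np.ndarray:
        """Supplied uncertainties, or 1% of I floored at a small epsilon."""
        if self.sigma is not None:
            return self.sigma
        return np.maximum(C.SIGMA_DEFAULT_FRACTION * np.abs(self.I), C.SIGMA_FLOOR)

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class CSDRecord:
    """Per-site chemical-shift differences and their combined deviation (ppm)."""

    delta_H: float
    delta_C: float
    delta_N: float
    csd: float


def debye_profile(coords: np.ndarray, q_grid: np.ndarray | None = None,
                  form_factor: float | np.ndarray = 1.0) -> ScatteringProfile:
    """Isotropic scattering intensity of a point model via the Debye formula.

    I(q) = sum_ij f_i f_j sin(q r_ij) / (q r_ij), with the q -> 0 limit
    handled analytically, so I(0) = (sum_i f_i)^2.  Rotation/translation
    invariant since only pairwise distances enter.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(pts) < 1:
        raise ParameterError("debye_profile requires at least one scatterer")
    q = C.DEFAULT_Q_GRID.copy() if q_grid is None else np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ParameterError("negative q is not allowed")
    f = np.broadcast_to(np.asarray(form_factor, dtype=float), (len(pts),))

    self_term = float(np.sum(f**2))
    intensity = np.full(len(q), self_term)
    if len(pts) > 1:
        d = pdist(pts)
        ff = f[:, None] * f[None, :]
        iu = np.triu_indices(len(pts), k=1)
        w = ff[iu]
        # sinc(x/pi) = sin(x)/x with the x=0 limit equal to 1
        cross = 2.0 * np.array([np.sum(w * np.sinc(qk * d / np.pi)) for qk in q])
        intensity = intensity + cross
    return ScatteringProfile(q=q, I=intensity)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted root-mean-square distance from the centroid (Å)."""
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(pts) < 1:
        raise ParameterError("radius_of_gyration requires at least one point")
    m = np.ones(len(pts)) if masses is None else np.asarray(masses, dtype=float)
    center = np.average(pts, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((pts - center) ** 2, axis=1), weights=m)))


def guinier_fit(profile: ScatteringProfile,
                qmax_rg: float = C.GUINIER_QMAX_RG) -> tuple[float, float, tuple[float, float]]:
    """Guinier analysis: linear fit of ln I vs q² on the low-q window.

    The window is iterated until q_max * Rg <= ``qmax_rg`` is self-consistent.
    Returns (Rg, I0, (q_min, q_max)) of the final window.  Raises
    :class:`FitError` when fewer than five usable points remain.
    """
    pos = (profile.q > 0) & (profile.I > 0)
    q = profile.q[pos]
    I = profile.I[pos]
    if len(q) < 5:
        raise FitError("Guinier fit window too small (< 5 points)")

    rg = None
    for _ in range(50):
        if rg is None:
            # seed the iteration with a fit over the whole usable curve
            window = slice(0, len(q))
        else:
            qmax = qmax_rg / rg
            count = int(np.searchsorted(q, qmax, side="right"))
            if count < 5:
                raise FitError(f"Guinier fit window too small (< 5 points) "
                               f"for Rg={rg:.2f}")
            window = slice(0, count)
        slope, intercept = np.polyfit(q[window] ** 2, np.log(I[window]), 1)
        if slope >= 0:
            raise FitError("Guinier fit produced non-negative slope")
        new_rg = float(np.sqrt(-3.0 * slope))
        if rg is not None and abs(new_rg - rg) < 1e-9:
            rg = new_rg
            break
        rg = new_rg
    qw = q[window]
    return rg, float(np.exp(intercept)), (float(qw[0]), float(qw[-1]))


@dataclass(frozen=True)
class KratkyCurve:
    """Dimensionless Kratky curve y = (qRg)² I(q)/I(0) vs x = qRg."""

    x: np.ndarray
    y: np.ndarray
    peak_x: float
    peak_y: float


def normalized_kratky(profile: ScatteringProfile, rg: float, i0: float) -> KratkyCurve:
    """Dimensionless Kratky transform with an interpolated peak estimate.

    For an ideal globule (Guinier curve) the peak sits at x = sqrt(3) with
    height 3/e; elongation shifts the peak to larger x.  Scaling I by any
    constant leaves the curve unchanged (I0 scales along).
    """
    if rg <= 0 or i0 <= 0:
        raise ParameterError("normalized_kratky requires Rg > 0 and I0 > 0")
    x = profile.q * rg
    y = x**2 * profile.I / i0
    # locate the peak by cubic-spline refinement around the grid maximum
    k = int(np.argmax(y))
    lo, hi = max(0, k - 4), min(len(x), k + 5)
    if hi - lo >= 4 and 0 < k < len(x) - 1:
        spline = CubicSpline(x[lo:hi], y[lo:hi])
        crit = spline.derivative().roots(extrapolate=False)
        if len(crit):
            vals = spline(crit)
            j = int(np.argmax(vals))
            peak_x, peak_y = float(crit[j]), float(vals[j])
        else:
            peak_x, peak_y = float(x[k]), float(y[k])
    else:
        peak_x, peak_y = float(x[k]), float(y[k])
    return KratkyCurve(x=x, y=y, peak_x=peak_x, peak_y=peak_y)


def _common_grid(exp: ScatteringProfile, model: ScatteringProfile) -> tuple[np.ndarray, np.ndarray]:
    """Model intensity resampled onto the experimental grid (overlap only)."""
    lo = max(exp.q[0], model.q[0])
    hi = min(exp.q[-1], model.q[-1])
    if lo >= hi:
        raise ParameterError("experimental and model q ranges do not overlap")
    mask = (exp.q >= lo) & (exp.q <= hi)
    return mask, np.interp(exp.q[mask], model.q, model.I)


def fit_states(exp_profile: ScatteringProfile,
               short_profile: ScatteringProfile,
               long_profile: ScatteringProfile) -> dict:
    """Fit the data to each state separately; the better fit is dominant.

    For each model profile the optimal scale c minimizing
    chi² = sum[(I_exp - c I_model)² / sigma²] / (N - 1) has the closed form
    c = sum(I_exp I_model / sigma²) / sum(I_model² / sigma²).  Returns the
    per-state chi values, scales, and the dominant label.  Scale-invariant
    in the experimental intensities when sigma is defaulted proportionally.
    """
    results = {}
    for label, model in (("short", short_profile), ("long", long_profile)):
        mask, I_model = _common_grid(exp_profile, model)
        I_exp = exp_profile.I[mask]
        sigma = exp_profile.effective_sigma()[mask]
        n = int(mask.sum())
        if n < 2:
            raise ParameterError("too few overlapping points to fit")
        c = float(np.sum(I_exp * I_model / sigma**2) / np.sum(I_model**2 / sigma**2))
        chi2 = float(np.sum(((I_exp - c * I_model) / sigma) ** 2) / (n - 1))
        results[label] = {"chi": float(np.sqrt(chi2)), "scale": c, "n_points": n}
    results["dominant"] = min(("short", "long"), key=lambda s: results[s]["chi"])
    return results


def csd_methyl(delta_H: float, delta_C: float) -> float:
    """Combined methyl chemical-shift deviation (ppm):
    [1/2 (ΔδH² + ΔδC²/4)]^(1/2)."""
    if not (np.isfinite(delta_H) and np.isfinite(delta_C)):
        raise ParameterError("shift differences must be finite")
    return float(np.sqrt(0.5 * (delta_H**2 + delta_C**2 / 4.0)))


def csd_amide(delta_H: float, delta_N: float) -> float:
    """Combined amide chemical-shift deviation (ppm):
    [1/2 (ΔδH² + ΔδN²/25)]^(1/2)."""
    if not (np.isfinite(delta_H) and np.isfinite(delta_N)):
        raise ParameterError("shift differences must be finite")
    return float(np.sqrt(0.5 * (delta_H**2 + delta_N**2 / 25.0)))
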