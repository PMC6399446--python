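"""Lorentz-oscillator dielectric models for single crystal axes.

The permittivity of one principal axis of a molecular crystal is modelled as a
DC dielectric constant plus a sum of damped Lorentz oscillators,

    eps(w) = eps_dc + sum_n (A_n / 2) / (w_n**2 - w**2 - i * w * gamma_n),

with all frequencies in wavenumbers (cm^-1) and amplitudes ``A_n`` in cm^-2 so
that ``A_n / w**2`` is dimensionless.  The complex refractive index is the
principal square root with non-negative imaginary part, so that a plane wave
``exp(i * sqrt(eps) * 2*pi*w*d)`` decays through an absorbing medium, and the
power absorption coefficient is ``alpha = 4*pi*w*Im(n)`` (field magnitude
through thickness ``d`` scales by ``exp(-alpha*d/2)``).

The module also fits such models to measured absorption spectra (sum of
Lorentzian lines plus a polynomial baseline), which is how axis models are
obtained from 0deg / 90deg polarized far-field measurements in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "LorentzianOscillator",
    "DielectricAxisModel",
    "AbsorbanceFitResult",
    "FitConvergenceError",
    "fit_lorentzians",
]

# 1 THz = 33.356 cm^-1; THz accepted only at I/O boundaries.
CM1_PER_THZ = 33.356


@dataclass(frozen=True)
class LorentzianOscillator:
    """One damped oscillator: amplitude ``A`` (cm^-2), center and FWHM-like
    damping rate ``gamma`` (both cm^-1)."""

    amplitude: float
    center: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.center > 0:
            raise ValueError(f"oscillator center must be > 0, got {self.center}")
        if not self.gamma > 0:
            raise ValueError(f"oscillator linewidth must be > 0, got {self.gamma}")
        if self.amplitude < 0:
            raise ValueError(f"oscillator amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class DielectricAxisModel:
    """Permittivity model of one crystal axis.

    ``eps(0)`` is purely real and equals ``eps_dc + sum A_n / (2 w_n**2)``.
    """

    eps_dc: float
    oscillators: tuple[LorentzianOscillator, ...] = ()
    axis: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "oscillators", tuple(self.oscillators))

    # -- derived optical quantities -------------------------------------------------

    def permittivity(self, omega):
        """Complex permittivity at wavenumber ``omega`` (cm^-1, scalar or array)."""
        w = np.asarray(omega, dtype=float)
        if np.any(w < 0):
            raise ValueError("wavenumber must be >= 0")
        eps = np.full(w.shape, complex(self.eps_dc), dtype=complex)
        for osc in self.oscillators:
            eps = eps + (0.5 * osc.amplitude) / (
                osc.center**2 - w**2 - 1j * w * osc.gamma
            )
        return eps if eps.shape else complex(eps)

    def refractive_index(self, omega):
        """Principal square root of the permittivity with Im(n) >= 0."""
        n = np.sqrt(np.asarray(self.permittivity(omega), dtype=complex))
        n = np.where(n.imag < 0, -n, n)
        return n if n.shape else complex(n)

    def absorption_coefficient(self, omega):
        """Power absorption coefficient alpha(omega) in cm^-1."""
        w = np.asarray(omega, dtype=float)
        alpha = 4.0 * np.pi * w * np.imag(np.asarray(self.refractive_index(w)))
        return alpha if alpha.shape else float(alpha)

    @property
    def static_oscillator_strength(self) -> float:
        """Real oscillator contribution to eps(0): sum A_n / (2 w_n**2)."""
        return sum(o.amplitude / (2.0 * o.center**2) for o in self.oscillators)

    def normalize_dc(self, target_index: float) -> "DielectricAxisModel":
        """Copy with ``eps_dc`` set so that ``Re(sqrt(eps(0))) == target_index``.

        Accounts for the oscillators' static contribution; a target requiring a
        negative DC dielectric constant is rejected as unphysical.
        """
        if target_index < 1:
            raise ValueError("target refractive index must be >= 1")
        eps_dc = target_index**2 - self.static_oscillator_strength
        if eps_dc < 0:
            raise ValueError(
                f"target index {target_index} requires eps_dc = {eps_dc:.4g} < 0"
            )
        return replace(self, eps_dc=eps_dc)


@dataclass
class AbsorbanceFitResult:
    """Result of a multi-Lorentzian absorption fit."""

    model: DielectricAxisModel
    baseline: np.ndarray  # polynomial coefficients, ascending order
    residual_norm: float
    lmfit_result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)

    def baseline_values(self, omega):
        return np.polynomial.polynomial.polyval(np.asarray(omega, float), self.baseline)


class FitConvergenceError(RuntimeError):
    """Raised when the Lorentzian fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


def _alpha_physical(omega, params, n_peaks, eps_dc):
    osc = tuple(
        LorentzianOscillator(
            amplitude=params[f"A{i}"], center=params[f"w{i}"], gamma=params[f"g{i}"]
        )
        for i in range(n_peaks)
    )
    return DielectricAxisModel(eps_dc, osc).absorption_coefficient(omega)


def _alpha_additive(omega, params, n_peaks, eps_dc):
    # Fast path: additive Lorentzian lines with the same (A, w, g) parameterization,
    # peak height ~ pi*A/(n0*g) as implied by the permittivity model at weak damping.
    n0 = np.sqrt(eps_dc)
    out = np.zeros_like(np.asarray(omega, float))
    for i in range(n_peaks):
        a, w0, g = params[f"A{i}"], params[f"w{i}"], params[f"g{i}"]
        height = np.pi * a / (n0 * g)
        half = 0.5 * g
        out = out + height * half**2 / ((omega - w0) ** 2 + half**2)
    return out


def fit_lorentzians(
    omega,
    spectrum,
    n_peaks: int,
    baseline_order: int = 2,
    initial_centers=None,
    eps_dc: float = 3.24,
    lineshape: str = "physical",
) -> AbsorbanceFitResult:
    """Fit ``n_peaks`` Lorentzian absorption lines plus a polynomial baseline.

    Parameters
    ----------
    omega, spectrum
        Absorption-coefficient spectrum alpha(omega) in cm^-1 vs wavenumber.
        (Absorbance data, alpha*d, may be fitted directly; amplitudes then
        absorb the thickness scale.)
    n_peaks
        Number of lines to fit (>= 1).
    baseline_order
        Polynomial baseline order (default 2; smooth background).
    initial_centers
        Optional starting peak positions; auto-seeded from local maxima otherwise.
    eps_dc
        Background DC permittivity held fixed (default 3.24, i.e. n0 = 1.8); a DC
        offset is unobservable in an absorption-only fit.
    lineshape
        "physical" (default) evaluates alpha through the permittivity model, so
        fitted parameters feed the forward simulation directly; "additive" is a
        fast sum-of-Lorentzians approximation.

    Returns parameters ordered by center frequency.
    """
    omega = np.asarray(omega, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if lineshape not in ("physical", "additive"):
        raise ValueError(f"unknown lineshape {lineshape!r}")

    centers = _seed_centers(omega, spectrum, n_peaks, initial_centers)
    if len(centers) < n_peaks:
        warnings.warn(
            f"requested {n_peaks} peaks but only {len(centers)} resolvable features "
            "were found; extra peaks seeded on the spectrum interior",
            stacklevel=2,
        )
        filler = np.linspace(omega[0], omega[-1], n_peaks + 2)[1:-1]
        centers = np.sort(np.concatenate([centers, filler[: n_peaks - len(centers)]]))

    span = omega[-1] - omega[0]
    step = np.median(np.diff(omega))
    scale = max(float(np.max(np.abs(spectrum))), 1e-30)
    n0 = np.sqrt(eps_dc)

    params = lmfit.Parameters()
    for i, c in enumerate(centers):
        height0 = max(float(np.interp(c, omega, spectrum)), 0.05 * scale)
        g0 = 2.0 * step if 2.0 * step > 0.2 else 1.0
        params.add(f"w{i}", value=float(c), min=omega[0], max=omega[-1])
        params.add(f"g{i}", value=g0, min=0.2 * step, max=span)
        params.add(f"A{i}", value=height0 * n0 * g0 / np.pi, min=0.0)
    for k in range(baseline_order + 1):
        params.add(f"c{k}", value=0.0)

    shape_fn = _alpha_physical if lineshape == "physical" else _alpha_additive

    def residual(p):
        vals = {name: p[name].value for name in p}
        model = shape_fn(omega, vals, n_peaks, eps_dc)
        base = np.polynomial.polynomial.polyval(
            omega, [vals[f"c{k}"] for k in range(baseline_order + 1)]
        )
        return model + base - spectrum

    result = lmfit.minimize(residual, params, method="least_squares")
    resid_norm = float(np.linalg.norm(result.residual))
    if not result.success:
        raise FitConvergenceError(
            f"Lorentzian fit did not converge: {result.message} "
            f"(residual norm {resid_norm:.4g})",
            residual_norm=resid_norm,
        )

    v = result.params.valuesdict()
    order = np.argsort([v[f"w{i}"] for i in range(n_peaks)])
    oscillators = tuple(
        LorentzianOscillator(
            amplitude=v[f"A{i}"],
            center=v[f"w{i}"],
            gamma=max(v[f"g{i}"], 1e-12),
        )
        for i in order
    )
    baseline = np.array([v[f"c{k}"] for k in range(baseline_order + 1)])
    return AbsorbanceFitResult(
        model=DielectricAxisModel(eps_dc=eps_dc, oscillators=oscillators),
        baseline=baseline,
        residual_norm=resid_norm,
        lmfit_result=result,
    )


def _seed_centers(omega, spectrum, n_peaks, initial_centers):
    if initial_centers is not None:
        centers = np.sort(np.asarray(initial_centers, dtype=float))
        if centers.size != n_peaks:
            raise ValueError("initial_centers length must equal n_peaks")
        if centers[0] < omega[0] or centers[-1] > omega[-1]:
            raise ValueError("initial_centers must lie inside the spectrum range")
        return centers
    prominence = 0.02 * max(float(np.ptp(spectrum)), 1e-30)
    idx, _ = find_peaks(spectrum, prominence=prominence)
    if idx.size == 0:
        return np.array([])
    heights = spectrum[idx]
    keep = idx[np.argsort(heights)[::-1][:n_peaks]]
    return np.sort(omega[keep])
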