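"""Electro-optic detection response and detection-geometry fitting.

A (110)-cut EO crystal converts the THz field into a balanced-detector signal
that depends on both the THz polarization angle ``phi`` and the NIR probe
polarization angle ``varphi`` (both measured from the crystal's [001] axis):

    dI = |E| * [cos(phi + phi0) * sin(2*varphi) + 2 * sin(phi + phi0) * cos(2*varphi)],

with ``phi0`` the initial THz polarization offset.  Because the EO effect is
linear in the field, the default implementation forms the complex superposition
``s = e_x' * sin(2*varphi) + 2 * e_y' * cos(2*varphi)`` of the field rotated by
``phi0`` into the EO frame and reports ``|s|``; for linearly polarized light
this reduces exactly to the scalar expression above, and it remains
well-defined for elliptical fields.  An alternative "azimuth" mode applies the
scalar expression at the polarization-ellipse azimuth for sensitivity studies.

The geometry fit recovers (phi0, varphi) from an empty-aperture signal-vs-
polarizer-angle curve.  The model has an exact two-fold degeneracy
(varphi, phi0) <-> (90deg - varphi, phi0 - 2*delta) with
delta = atan2(2*cos(2*varphi), sin(2*varphi)); both branches reproduce the
curve exactly, so the fit canonicalizes phi0 to (-90deg, 90deg] and varphi to
[0deg, 90deg) and returns the branch with the smaller |phi0| (a nominally
aligned source), exposing the alternate on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .jones import JonesField, PolarizerSpec

__all__ = [
    "EODetectionConfig",
    "DetectionFitResult",
    "detected_signal",
    "transmission_ratio",
    "reference_signal_curve",
    "fit_detection_geometry",
]


@dataclass(frozen=True)
class EODetectionConfig:
    """EO detection geometry: THz offset ``phi0`` and NIR probe angle
    ``phi_nir`` (degrees, relative to the EO crystal's [001] axis)."""

    phi0_deg: float = 0.0
    phi_nir_deg: float = 45.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.phi0_deg) and np.isfinite(self.phi_nir_deg)):
            raise ValueError("detection angles must be finite")


def _detect_components(ex, ey, config: EODetectionConfig):
    """|s| for (arrays of) lab-frame field components."""
    p0 = np.deg2rad(config.phi0_deg)
    two_phi = 2.0 * np.deg2rad(config.phi_nir_deg)
    exp_ = np.cos(p0) * ex - np.sin(p0) * ey
    eyp = np.sin(p0) * ex + np.cos(p0) * ey
    return np.abs(exp_ * np.sin(two_phi) + 2.0 * eyp * np.cos(two_phi))


def detected_signal(
    field: JonesField, config: EODetectionConfig, mode: str = "superposition"
) -> float:
    """Detected EO signal magnitude dI for one field (arbitrary units)."""
    if mode == "superposition":
        return float(_detect_components(field.e[0], field.e[1], config))
    if mode == "azimuth":
        # Scalar expression at the polarization-ellipse major-axis azimuth.
        ex, ey = field.e
        azimuth = 0.5 * np.angle((ex + 1j * ey) * np.conj(ex - 1j * ey))
        mag = field.magnitude
        phi = azimuth + np.deg2rad(config.phi0_deg)
        two_phi = 2.0 * np.deg2rad(config.phi_nir_deg)
        return float(
            mag * np.abs(np.cos(phi) * np.sin(two_phi) + 2 * np.sin(phi) * np.cos(two_phi))
        )
    raise ValueError(f"unknown detection mode {mode!r}")


def transmission_ratio(di_sample, di_ref, floor: float = 0.0):
    """|T| = dI_sample / dI_ref; reference values at or below ``floor`` yield
    NaN (missing), never infinities."""
    s = np.asarray(di_sample, dtype=float)
    r = np.asarray(di_ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(r > floor, s / np.where(r > floor, r, 1.0), np.nan)
    return t if t.shape else float(t)


def reference_signal_curve(
    theta_deg,
    config: EODetectionConfig,
    polarizer: PolarizerSpec | None = None,
) -> np.ndarray:
    """Empty-aperture dI_ref vs polarizer angle (the chain source -> polarizer
    -> EO detection, x-polarized unit source).  Frequency-independent in this
    model, so valid at any wavenumber (the fit convention uses 33 cm^-1)."""
    if polarizer is None:
        polarizer = PolarizerSpec()
    th = np.deg2rad(np.atleast_1d(np.asarray(theta_deg, dtype=float)))
    # Closed-form polarizer action on the x-polarized source (same operator as
    # polarizer_matrix, expanded for speed over dense angle grids).
    c, s = np.cos(th), np.sin(th)
    e_x = polarizer.t_par * c**2 + polarizer.t_perp * s**2
    e_y = (polarizer.t_par - polarizer.t_perp) * s * c
    return _detect_components(e_x, e_y, config)


@dataclass
class DetectionFitResult:
    """Fitted EO geometry with the degenerate alternate branch."""

    config: EODetectionConfig
    residual_norm: float
    alternates: list = field(default_factory=list)  # [(EODetectionConfig, resid), ...]


def _canonicalize(phi0: float, phi_nir: float) -> tuple[float, float]:
    # phi_nir + 90 and phi0 + 180 each flip the sign of s only.
    phi_nir = phi_nir % 90.0
    phi0 = (phi0 + 90.0) % 180.0 - 90.0
    if phi0 == -90.0:
        phi0 = 90.0
    return phi0, phi_nir


def _mirror_branch(phi0: float, phi_nir: float) -> tuple[float, float]:
    two = np.deg2rad(2.0 * phi_nir)
    delta = np.rad2deg(np.arctan2(2.0 * np.cos(two), np.sin(two)))
    return _canonicalize(phi0 - 2.0 * delta, 90.0 - phi_nir)


def fit_detection_geometry(
    theta_deg,
    signal,
    polarizer: PolarizerSpec | None = None,
    phi_nir_starts=(0.0, 30.0, 60.0),
) -> DetectionFitResult:
    """Least-squares estimate of (phi0, phi_nir) from an empty-aperture
    dI_ref(theta) curve covering at least one full polarizer revolution.

    Multi-start over ``phi_nir_starts`` avoids the trigonometric mirror
    symmetries of the objective; see the module docstring for the branch
    convention used to report a unique answer.
    """
    theta = np.asarray(theta_deg, dtype=float)
    data = np.asarray(signal, dtype=float)
    if theta.shape != data.shape or theta.ndim != 1:
        raise ValueError("theta_deg and signal must be matching 1-D arrays")
    if np.ptp(theta) < 360.0 - 1e-9:
        raise ValueError("signal curve must cover a full polarizer revolution")
    if np.ptp(data) <= 1e-12 * max(np.max(np.abs(data)), 1e-300):
        raise ValueError("degenerate flat signal curve; geometry unidentifiable")
    if polarizer is None:
        polarizer = PolarizerSpec()

    def residual(p):
        cfg = EODetectionConfig(phi0_deg=p[0], phi_nir_deg=p[1])
        return reference_signal_curve(theta, cfg, polarizer) - data

    fits = []
    for phi_start in phi_nir_starts:
        for phi0_start in (0.0, 45.0):
            res = least_squares(residual, x0=[phi0_start, phi_start], method="lm")
            fits.append((float(np.linalg.norm(res.fun)), res.x))
    best_norm = min(f[0] for f in fits)

    # Collect canonical candidates that fit (essentially) as well as the best,
    # fold in each one's exact mirror branch, and deduplicate.
    tol = best_norm * 1.001 + 1e-12 * max(float(np.max(np.abs(data))), 1e-300)
    candidates: dict[tuple[float, float], float] = {}
    for norm, x in fits:
        if norm > tol:
            continue
        for branch in (_canonicalize(x[0], x[1]), _mirror_branch(x[0], x[1])):
            key = (round(branch[0], 6), round(branch[1], 6))
            resid = float(
                np.linalg.norm(residual([branch[0], branch[1]]))
            )
            if resid <= tol and (key not in candidates or resid < candidates[key]):
                candidates[key] = resid

    ranked = sorted(candidates.items(), key=lambda kv: (abs(kv[0][0]), kv[1]))
    (phi0, phi_nir), resid = ranked[0]
    return DetectionFitResult(
        config=EODetectionConfig(phi0_deg=phi0, phi_nir_deg=phi_nir),
        residual_norm=resid,
        alternates=[
            (EODetectionConfig(phi0_deg=p0, phi_nir_deg=pn), r)
            for (p0, pn), r in ranked[1:]
        ],
    )
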