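"""Relative-absorbance surfaces over (wavenumber, angle) grids.

The central quantity is the anisotropic absorbance

    dabs(w, theta) = -2 * ln(|E_t(w, theta)| / |E_t(w, theta_ref)|),

zero by construction at the reference angle.  Two constructors build such
surfaces from the forward optical model: ``farfield_surface`` rotates the
incident linear polarization through a birefringent sample (orientation-
dependent far-field absorbance), and ``pvatm_surface`` runs the full
polarization-varying chain — rotating wire-grid polarizer, sample, and
polarization-sensitive EO detection — with each polarizer angle referenced to
an empty aperture and the resulting transmission normalized at theta = 0.

Missing cells (e.g. vanishing reference transmission) are stored as NaN and
propagate as missing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .detection import EODetectionConfig, _detect_components
from .jones import AnisotropicSample, PolarizerSpec, polarizer_matrix, sample_matrix

__all__ = [
    "AnisoSurface",
    "farfield_surface",
    "pvatm_surface",
    "delta_abs_from_fields",
    "default_omega_grid",
    "default_theta_grid",
]


def default_omega_grid() -> np.ndarray:
    """0 .. 200 cm^-1 in 0.1 cm^-1 steps."""
    return np.round(np.arange(0, 2001) * 0.1, 10)


def default_theta_grid() -> np.ndarray:
    """0 .. 360 deg in 15 deg steps."""
    return np.arange(0.0, 361.0, 15.0)


@dataclass
class AnisoSurface:
    """dabs(w, theta) on a rectangular grid, with reference-angle metadata.

    values has shape (len(omega), len(theta)); NaN marks missing cells.
    provenance is one of "far-field", "pvatm", "measured", "synthetic".
    """

    omega: np.ndarray
    theta: np.ndarray
    values: np.ndarray
    theta_ref: float
    provenance: str = "synthetic"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.omega.size, self.theta.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grids "
                f"({self.omega.size}, {self.theta.size})"
            )
        if np.any(np.diff(self.omega) <= 0) or np.any(np.diff(self.theta) <= 0):
            raise ValueError("omega and theta grids must be strictly ascending")
        ref = self.ref_index
        col = self.values[:, ref]
        if not np.all(col[np.isfinite(col)] == 0.0):
            raise ValueError("dabs must be exactly 0 at the reference angle")

    @property
    def ref_index(self) -> int:
        idx = np.nonzero(np.isclose(self.theta, self.theta_ref, rtol=0, atol=1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"theta_ref = {self.theta_ref} not on the theta grid")
        return int(idx[0])


def _delta_abs(magnitudes: np.ndarray, ref_index: int) -> np.ndarray:
    """-2 ln(|E|/|E_ref|) columnwise, masking nonpositive magnitudes."""
    mags = np.asarray(magnitudes, dtype=float)
    ref = mags[:, ref_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -2.0 * np.log(mags / ref[:, None])
    out[~np.isfinite(out)] = np.nan
    bad = ~(mags > 0)
    out[bad] = np.nan
    out[~(ref > 0), :] = np.nan
    out[:, ref_index] = np.where(ref > 0, 0.0, np.nan)  # exact zero at reference
    return out


def farfield_surface(
    sample: AnisotropicSample,
    omega_grid,
    theta_grid,
    theta_ref: float = 0.0,
    mode: str = "total",
) -> AnisoSurface:
    """Orientation-dependent far-field absorbance surface.

    A unit linear field at each angle theta is transmitted through the sample;
    by default the total transmitted magnitude is detected ("total"), or the
    component along the incident polarization for analyzer-equipped rigs
    ("copolarized").
    """
    if mode not in ("total", "copolarized"):
        raise ValueError(f"unknown far-field mode {mode!r}")
    omega = np.asarray(omega_grid, dtype=float)
    theta = np.asarray(theta_grid, dtype=float)
    m = sample_matrix(sample, omega)  # (Nw, 2, 2)
    th = np.deg2rad(theta)
    e_in = np.stack([np.cos(th), np.sin(th)])  # (2, Nt)
    e_t = np.einsum("wij,jt->wit", m, e_in)  # (Nw, 2, Nt)
    if mode == "total":
        mags = np.sqrt(np.abs(e_t[:, 0, :]) ** 2 + np.abs(e_t[:, 1, :]) ** 2)
    else:
        mags = np.abs(np.einsum("wit,it->wt", e_t, e_in.astype(complex)))
    surf = AnisoSurface(
        omega=omega,
        theta=theta,
        values=np.zeros((omega.size, theta.size)),
        theta_ref=theta_ref,
        provenance="far-field",
        meta={"mode": mode, "beta_deg": sample.beta_deg},
    )
    surf.values = _delta_abs(mags, surf.ref_index)
    return surf


def pvatm_surface(
    sample: AnisotropicSample,
    polarizer: PolarizerSpec | None = None,
    detection: EODetectionConfig | None = None,
    omega_grid=None,
    theta_grid=None,
    theta_ref: float = 0.0,
    source=(1.0, 0.0),
    signal_floor: float = 1e-12,
) -> AnisoSurface:
    """Polarization-varying surface through the full simulation chain.

    For each (w, theta) the reference chain is source -> polarizer(theta) ->
    EO detection, and the sample chain inserts the sample operator before
    detection.  |T| = dI_sample / dI_ref is normalized at theta_ref (0 deg by
    convention) and converted to dabs = -2 ln(|T|/|T(theta_ref)|).  Reference
    signals at or below ``signal_floor`` mask the cell.

    ``source`` allows a complex Jones vector, e.g. a slightly elliptical
    source; the default is pure linear x polarization.
    """
    polarizer = polarizer if polarizer is not None else PolarizerSpec()
    detection = detection if detection is not None else EODetectionConfig()
    omega = np.asarray(
        omega_grid if omega_grid is not None else default_omega_grid(), dtype=float
    )
    theta = np.asarray(
        theta_grid if theta_grid is not None else default_theta_grid(), dtype=float
    )
    if omega.size == 0 or theta.size == 0:
        raise ValueError("grids must be non-empty")
    src = np.asarray(source, dtype=complex).reshape(2)

    m = sample_matrix(sample, omega)  # (Nw, 2, 2)
    tmag = np.empty((omega.size, theta.size))
    for j, th in enumerate(theta):
        e_ref = polarizer_matrix(polarizer.at(th)) @ src
        di_ref = float(_detect_components(e_ref[0], e_ref[1], detection))
        if di_ref <= signal_floor:
            tmag[:, j] = np.nan
            continue
        e_s = m @ e_ref  # (Nw, 2)
        di_s = _detect_components(e_s[:, 0], e_s[:, 1], detection)
        tmag[:, j] = di_s / di_ref

    surf = AnisoSurface(
        omega=omega,
        theta=theta,
        values=np.zeros((omega.size, theta.size)),
        theta_ref=theta_ref,
        provenance="pvatm",
        meta={
            "beta_deg": sample.beta_deg,
            "phi0_deg": detection.phi0_deg,
            "phi_nir_deg": detection.phi_nir_deg,
            "t_perp": polarizer.t_perp,
        },
    )
    surf.values = _delta_abs(tmag, surf.ref_index)
    return surf


def delta_abs_from_fields(
    omega_grid, theta_grid, magnitudes, theta_ref: float = 0.0
) -> AnisoSurface:
    """Build a surface from measured transmitted-field magnitudes |E_t(w, theta)|
    (e.g. Fourier-transformed TDS data); nonpositive magnitudes are masked."""
    omega = np.asarray(omega_grid, dtype=float)
    theta = np.asarray(theta_grid, dtype=float)
    surf = AnisoSurface(
        omega=omega,
        theta=theta,
        values=np.zeros((omega.size, theta.size)),
        theta_ref=theta_ref,
        provenance="measured",
    )
    surf.values = _delta_abs(np.asarray(magnitudes, dtype=float), surf.ref_index)
    return surf
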