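"""Jones-calculus propagation through a rotating polarizer and a birefringent sample.

Convention: lab-frame column vectors (e_x, e_y); a positive rotation angle turns
the lab x axis toward the lab y axis (counter-clockwise viewed along the
propagation direction).  Every angle in this package (polarizer pass axis theta,
sample orientation beta, detection angles) is interpreted under this single
convention and is stored in degrees.

An element oriented at angle ``a`` is built as R(a) @ D @ R(-a) with ``D`` the
element's diagonal transmission in its own frame: the field is rotated into the
element frame, transmitted, and rotated back to the lab frame.  The sample's
diagonal transmission is pure propagation phase, ``t_jj = exp(i*n_j*2*pi*w*d)``
with ``w`` in cm^-1 and ``d`` in cm; no interface (Fresnel) losses and no
internal-reflection etalon terms are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dielectric import DielectricAxisModel

__all__ = [
    "JonesField",
    "PolarizerSpec",
    "AnisotropicSample",
    "rotation",
    "polarizer_matrix",
    "sample_matrix",
    "propagate",
    "linear_field",
]

# Field transmission across the wire grid (t_perp/t_par ~ 1/20, power 1/400).
DEFAULT_T_PERP = 1.0 / 20.0


@dataclass(frozen=True)
class JonesField:
    """Complex two-component electric field at one wavenumber, lab frame."""

    e: np.ndarray  # shape (2,), complex
    omega: float  # cm^-1

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=complex).reshape(2)
        if not np.all(np.isfinite(e.view(float))):
            raise ValueError("field components must be finite")
        object.__setattr__(self, "e", e)

    @property
    def magnitude(self) -> float:
        return float(np.sqrt(np.abs(self.e[0]) ** 2 + np.abs(self.e[1]) ** 2))


def linear_field(angle_deg: float, omega: float, amplitude: float = 1.0) -> JonesField:
    """Unit-amplitude linearly polarized field at ``angle_deg`` from lab x."""
    a = np.deg2rad(angle_deg)
    return JonesField(e=amplitude * np.array([np.cos(a), np.sin(a)]), omega=omega)


@dataclass(frozen=True)
class PolarizerSpec:
    """Wire-grid polarizer: pass axis angle and field transmissions.

    ``t_perp`` defaults to 1/20 (field extinction 20:1, power 400:1); set 0 for
    an ideal polarizer.
    """

    theta_deg: float = 0.0
    t_par: float = 1.0
    t_perp: float = DEFAULT_T_PERP

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_perp <= self.t_par <= 1.0):
            raise ValueError(
                f"need 0 <= t_perp <= t_par <= 1, got {self.t_perp}, {self.t_par}"
            )

    def at(self, theta_deg: float) -> "PolarizerSpec":
        """Same polarizer rotated to a new pass-axis angle."""
        return PolarizerSpec(theta_deg, self.t_par, self.t_perp)


@dataclass(frozen=True)
class AnisotropicSample:
    """Uniaxial-in-plane sample: ordinary (crystal a) and extraordinary
    (crystal b) axis dielectric models, thickness ``d`` (cm) and in-plane
    orientation ``beta`` (degrees; rotation of the a axis from lab x)."""

    ordinary: DielectricAxisModel
    extraordinary: DielectricAxisModel
    thickness_cm: float
    beta_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.thickness_cm > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness_cm}")


def rotation(angle_deg: float) -> np.ndarray:
    """Active 2x2 rotation by ``angle_deg`` (positive: x toward y)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def polarizer_matrix(spec: PolarizerSpec) -> np.ndarray:
    """Lab-frame polarizer operator R(theta) @ diag(t_par, t_perp) @ R(-theta)."""
    r = rotation(spec.theta_deg)
    return r @ np.diag([spec.t_par, spec.t_perp]) @ r.T


def sample_matrix(sample: AnisotropicSample, omega) -> np.ndarray:
    """Lab-frame sample operator R(beta) @ diag(t_xx, t_yy) @ R(-beta).

    ``omega`` may be a scalar (returns (2, 2)) or an array (returns
    (..., 2, 2) with the grid leading).
    """
    w = np.asarray(omega, dtype=float)
    phase = 2j * np.pi * w * sample.thickness_cm
    t_xx = np.exp(phase * np.asarray(sample.ordinary.refractive_index(w)))
    t_yy = np.exp(phase * np.asarray(sample.extraordinary.refractive_index(w)))
    r = rotation(sample.beta_deg)
    diag = np.zeros(w.shape + (2, 2), dtype=complex)
    diag[..., 0, 0] = t_xx
    diag[..., 1, 1] = t_yy
    out = np.einsum("ij,...jk,kl->...il", r, diag, r.T)
    return out if w.shape else out.reshape(2, 2)


def propagate(field: JonesField, operators) -> JonesField:
    """Apply a chain of 2x2 operators to the field, in the order given.

    Each operator is a 2x2 array, or a ``(matrix, omega)`` pair whose wavenumber
    must match the field's (mismatch raises ``ValueError``).
    """
    e = field.e
    for op in operators:
        if isinstance(op, tuple):
            matrix, op_omega = op
            if not np.isclose(op_omega, field.omega, rtol=0, atol=1e-9):
                raise ValueError(
                    f"operator at {op_omega} cm^-1 applied to field at "
                    f"{field.omega} cm^-1"
                )
        else:
            matrix = op
        matrix = np.asarray(matrix)
        if matrix.shape != (2, 2):
            raise ValueError(f"operators must be 2x2, got shape {matrix.shape}")
        e = matrix @ e
    return JonesField(e=e, omega=field.omega)
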