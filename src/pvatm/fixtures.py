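"""Synthetic inputs: crystal presets, peak-parameterized surfaces, noise, and
time-domain-spectroscopy emulation.

Everything downstream of the forward model is testable from here without any
external data: a sucrose crystal preset (the standard molecular-crystal
benchmark, with published phonon frequencies per axis), free and inhibitor-
bound lysozyme (CEWL / CEWL-3NAG) fingerprint presets, a generator that
renders any fingerprint into a dabs surface with exact round-trip properties,
seeded Gaussian noise injection, and a single-cycle-pulse TDS emulator whose
scan length sets the spectral resolution.

Sucrose oscillator amplitudes and linewidths are fixture choices, not
published values: only the center frequencies (b axis 49, 59, 62 cm^-1; a/c
55, 66, 75 cm^-1) are established.  Defaults use 2 cm^-1 linewidths (typical
for molecular crystals at room temperature) and amplitudes giving far-field
dabs peaks of order 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .dielectric import DielectricAxisModel, LorentzianOscillator
from .jones import AnisotropicSample, sample_matrix
from .peaks import PeakRecord
from .surfaces import AnisoSurface

__all__ = [
    "TDSWaveform",
    "sucrose_preset",
    "cewl_presets",
    "surface_from_peaks",
    "add_noise",
    "tds_emulate",
]

C_CM_PER_PS = 0.0299792458  # speed of light, cm/ps: converts cm^-1 <-> THz

SUCROSE_B_CENTERS = (49.0, 59.0, 62.0)  # extraordinary (b) axis, cm^-1
SUCROSE_A_CENTERS = (55.0, 66.0, 75.0)  # ordinary (a, with c projection) axis

# Table-style fingerprints for free and tri-acetyl-glucosamine-bound lysozyme:
# (nu cm^-1, FWHM cm^-1, theta deg, dabs amplitude).  Bound amplitudes are
# (crystal 1, crystal 2); the 97 cm^-1 line was reported for one crystal.
_CEWL_FREE = (
    (26.0, 3.0, 40.0, 2.78),
    (46.0, 4.0, 20.0, 1.50),
    (53.0, 4.0, 40.0, 2.36),
    (68.0, 4.0, 40.0, 2.54),
    (85.0, 6.0, 40.0, 2.84),
    (92.0, 3.0, 40.0, 3.44),
)
_CEWL_BOUND = (
    (16.0, 4.0, 40.0, (4.77, 5.39)),
    (24.0, 2.0, 60.0, (1.07, 1.08)),
    (31.0, 3.0, 40.0, (1.61, 1.28)),
    (41.0, 6.0, 60.0, (1.65, 1.22)),
    (51.0, 3.0, 20.0, (0.42, 1.27)),
    (97.0, 3.0, 40.0, (3.63, 3.63)),
)


def sucrose_preset(
    beta_deg: float = -75.0,
    thickness_cm: float = 0.0275,
    linewidth: float = 2.0,
    a_amplitudes=(120.0, 130.0, 110.0),
    b_amplitudes=(140.0, 120.0, 100.0),
    target_index: float = 1.8,
) -> AnisotropicSample:
    """c-cut sucrose crystal sample for the forward model.

    Ordinary (a) axis lines at 55, 66, 75 cm^-1; extraordinary (b) axis lines
    at 49, 59, 62 cm^-1; both axes DC-normalized to refractive index 1.8;
    thickness 0.0275 cm; default in-plane orientation beta = -75 deg (the
    polarization-varying measurement geometry; use beta=0 to put the a axis
    along the 0-degree reference, the far-field geometry).
    """
    def axis(label, centers, amps):
        osc = tuple(
            LorentzianOscillator(amplitude=a, center=c, gamma=linewidth)
            for c, a in zip(centers, amps)
        )
        return DielectricAxisModel(eps_dc=0.0, oscillators=osc, axis=label).normalize_dc(
            target_index
        )

    return AnisotropicSample(
        ordinary=axis("a", SUCROSE_A_CENTERS, a_amplitudes),
        extraordinary=axis("b", SUCROSE_B_CENTERS, b_amplitudes),
        thickness_cm=thickness_cm,
        beta_deg=beta_deg,
    )


def cewl_presets(crystal: int = 1):
    """(free, bound) fingerprint lists for lysozyme with/without 3NAG.

    ``crystal`` selects which bound crystal's amplitudes to use (1 or 2; the
    source reports two bound crystals and designates neither as canonical).
    """
    if crystal not in (1, 2):
        raise ValueError("crystal must be 1 or 2")
    free = [PeakRecord(*row) for row in _CEWL_FREE]
    bound = [
        PeakRecord(nu, fwhm, theta, amps[crystal - 1])
        for nu, fwhm, theta, amps in _CEWL_BOUND
    ]
    return free, bound


def _angular_profile(theta, theta_n, theta_ref, profile, kappa):
    """180-degree-periodic angular weight with g(theta_n)=1, g(theta_ref)=0."""
    t = np.deg2rad(np.asarray(theta, dtype=float) - theta_n)
    t_ref = np.deg2rad(theta_ref - theta_n)
    if profile == "vonmises":
        e = np.exp(kappa * np.cos(2.0 * t))
        e_ref = np.exp(kappa * np.cos(2.0 * t_ref))
        denom = np.exp(kappa) - e_ref
    elif profile == "cos2":
        e = np.cos(t) ** 2
        e_ref = np.cos(t_ref) ** 2
        denom = 1.0 - e_ref
    else:
        raise ValueError(f"unknown angular profile {profile!r}")
    if abs(denom) < 1e-12:
        raise ValueError("record angle coincides with the reference angle")
    return (e - e_ref) / denom


def surface_from_peaks(
    records,
    omega_grid,
    theta_grid,
    theta_ref: float = 0.0,
    profile: str = "vonmises",
    kappa: float = 4.0,
) -> AnisoSurface:
    """Render a fingerprint into a noiseless dabs surface.

    Each record contributes amplitude * L(omega; nu, fwhm) * g(theta), with L a
    unit-peak Lorentzian and g a 180-degree-periodic angular weight that is
    exactly 1 at the record angle and exactly 0 at the reference angle.  The
    default "vonmises" profile, (exp(k*cos2(t-tn)) - exp(k*cos2(tref-tn))) /
    (exp(k) - exp(k*cos2(tref-tn))), keeps the record's lobe globally dominant
    so peak extraction round-trips exactly on noiseless output; the "cos2"
    profile (cos-squared difference, the form a single absorption dipole
    projects) is available but its opposite-sign lobe exceeds the record
    amplitude whenever |theta_ref - theta_n| < 45 deg.

    A record whose angle coincides with theta_ref (mod 180) has no valid
    normalization and is rejected (unless its amplitude is 0).
    """
    omega = np.asarray(omega_grid, dtype=float)
    theta = np.asarray(theta_grid, dtype=float)
    values = np.zeros((omega.size, theta.size))
    for rec in records:
        if rec.amplitude == 0.0:
            continue
        if abs((rec.theta_deg - theta_ref) % 180.0) < 1e-9 or (
            abs((rec.theta_deg - theta_ref) % 180.0 - 180.0) < 1e-9
        ):
            raise ValueError(
                f"record at nu={rec.nu} has theta={rec.theta_deg} congruent to "
                f"theta_ref={theta_ref} (mod 180); amplitude not representable"
            )
        half = 0.5 * rec.fwhm
        lorentz = half**2 / ((omega - rec.nu) ** 2 + half**2)
        g = _angular_profile(theta, rec.theta_deg, theta_ref, profile, kappa)
        values += rec.amplitude * np.outer(lorentz, g)
    surf = AnisoSurface(
        omega=omega,
        theta=theta,
        values=np.zeros_like(values),
        theta_ref=theta_ref,
        provenance="synthetic",
        meta={"profile": profile, "kappa": kappa},
    )
    ref = surf.ref_index
    values[:, ref] = 0.0  # exact, not merely round-off-level
    surf.values = values
    return surf


def add_noise(surface: AnisoSurface, sigma: float, seed: int) -> AnisoSurface:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma`` to
    every cell except the reference-angle column (kept exactly 0 so the
    self-referencing invariant survives).  Deterministic given ``seed``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = surface.values + sigma * rng.standard_normal(surface.values.shape)
    noisy[:, surface.ref_index] = surface.values[:, surface.ref_index]
    return replace(
        surface,
        values=noisy,
        meta={**surface.meta, "noise_sigma": sigma, "noise_seed": seed},
    )


@dataclass(frozen=True)
class TDSWaveform:
    """Time-domain scan: uniform time grid (ps), field values, and the spectral
    resolution implied by the scan span (cm^-1)."""

    time_ps: np.ndarray
    field: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ps, dtype=float)
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-9, atol=0):
            raise ValueError("time grid must be uniform")
        span = t[-1] - t[0] + dt[0]
        implied = 1.0 / (C_CM_PER_PS * span)
        if not np.isclose(implied, self.resolution, rtol=1e-6):
            raise ValueError(
                f"declared resolution {self.resolution} cm^-1 inconsistent with "
                f"scan span ({implied:.4g} cm^-1)"
            )
        object.__setattr__(self, "time_ps", t)
        object.__setattr__(self, "field", np.asarray(self.field, dtype=float))


def _reference_pulse(t, center_cm1, t0):
    """Derivative-of-Gaussian single-cycle pulse with spectral peak near
    ``center_cm1`` (standard photoconductive-emitter shape)."""
    f_thz = center_cm1 * C_CM_PER_PS
    tau = 1.0 / (2.0 * np.pi * f_thz)
    x = (t - t0) / tau
    return -x * np.exp(-0.5 * x**2)


def tds_emulate(
    sample: AnisotropicSample | None,
    polarization_deg: float = 0.0,
    resolution: float = 0.68,
    center_cm1: float = 33.0,
    dt_ps: float = 0.02,
):
    """Emulate a TDS measurement of ``sample`` at one linear polarization.

    Synthesizes a broadband single-cycle reference pulse, applies the sample's
    co-polarized frequency-domain transfer function (``sample=None`` is the
    empty reference), truncates the scan to the span implied by ``resolution``
    (frequency-bin spacing <= the requested resolution), and Fourier-transforms
    to a magnitude spectrum.

    Returns ``(waveform, omega_cm1, magnitude)``.
    """
    if not resolution > 0:
        raise ValueError("resolution must be > 0")
    span_ps = 1.0 / (C_CM_PER_PS * resolution)
    n = int(np.ceil(span_ps / dt_ps))  # span >= required, so bin spacing <= resolution
    t = np.arange(n) * dt_ps
    actual_span = n * dt_ps
    actual_res = 1.0 / (C_CM_PER_PS * actual_span)

    pulse = _reference_pulse(t, center_cm1, t0=0.15 * actual_span)
    freqs_thz = np.fft.rfftfreq(n, d=dt_ps)
    omega = freqs_thz / C_CM_PER_PS  # cm^-1
    spec = np.fft.rfft(pulse)

    if sample is not None:
        narrowest = min(
            (o.gamma for ax in (sample.ordinary, sample.extraordinary)
             for o in ax.oscillators),
            default=np.inf,
        )
        if resolution > narrowest:
            warnings.warn(
                f"requested resolution {resolution} cm^-1 is coarser than the "
                f"narrowest oscillator linewidth ({narrowest} cm^-1)",
                stacklevel=2,
            )
        u = np.array(
            [np.cos(np.deg2rad(polarization_deg)), np.sin(np.deg2rad(polarization_deg))]
        )
        m = sample_matrix(sample, omega)
        transfer = np.einsum("i,wij,j->w", u, m, u.astype(complex))
        spec = spec * transfer

    field_t = np.fft.irfft(spec, n)  # transmitted time-domain scan
    waveform = TDSWaveform(time_ps=t, field=field_t, resolution=actual_res)
    return waveform, omega, np.abs(spec)
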