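"""File formats and validated simulation configuration.

Surfaces travel as long-format CSV (``wavenumber_cm1,theta_deg,delta_abs``)
with ``# key = value`` metadata header lines, or as an equivalent HDF5
container.  Peak tables are CSV, fingerprint diffs JSON, and configurations
YAML or JSON validated by pydantic models (unknown keys are rejected with
location-bearing messages).  Angles are degrees in every file.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .detection import EODetectionConfig
from .dielectric import DielectricAxisModel, LorentzianOscillator
from .jones import AnisotropicSample, PolarizerSpec
from .peaks import FingerprintDiff, PeakRecord
from .surfaces import AnisoSurface

__all__ = [
    "SimulationConfig",
    "load_config",
    "read_surface",
    "write_surface",
    "read_peaks",
    "write_peaks",
    "write_diff",
]

SURFACE_COLUMNS = ["wavenumber_cm1", "theta_deg", "delta_abs"]
PEAK_COLUMNS = ["nu_cm1", "fwhm_cm1", "theta_deg", "delta_abs", "sign"]


# -- configuration ---------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OscillatorConfig(_Strict):
    A: float = Field(ge=0)
    omega_n: float = Field(gt=0)
    gamma_n: float = Field(gt=0)


class AxisConfig(_Strict):
    eps_dc: float = 0.0
    oscillators: list[OscillatorConfig] = []
    axis: str = ""
    # When set, eps_dc is recomputed so Re(sqrt(eps(0))) equals this index.
    target_index: float | None = None

    def build(self) -> DielectricAxisModel:
        model = DielectricAxisModel(
            eps_dc=self.eps_dc,
            oscillators=tuple(
                LorentzianOscillator(o.A, o.omega_n, o.gamma_n)
                for o in self.oscillators
            ),
            axis=self.axis,
        )
        if self.target_index is not None:
            model = model.normalize_dc(self.target_index)
        return model


class SampleConfig(_Strict):
    ordinary: AxisConfig
    extraordinary: AxisConfig
    thickness_cm: float = Field(gt=0)
    beta_deg: float = -75.0

    def build(self) -> AnisotropicSample:
        return AnisotropicSample(
            ordinary=self.ordinary.build(),
            extraordinary=self.extraordinary.build(),
            thickness_cm=self.thickness_cm,
            beta_deg=self.beta_deg,
        )


class PolarizerConfig(_Strict):
    t_par: float = 1.0
    t_perp: float = 1.0 / 20.0

    def build(self) -> PolarizerSpec:
        return PolarizerSpec(t_par=self.t_par, t_perp=self.t_perp)


class DetectionBlock(_Strict):
    phi0_deg: float = -5.12
    phi_nir_deg: float = 48.45

    def build(self) -> EODetectionConfig:
        return EODetectionConfig(self.phi0_deg, self.phi_nir_deg)


class GridConfig(_Strict):
    omega_start: float = 0.0
    omega_stop: float = 200.0
    omega_step: float = Field(default=0.1, gt=0)
    theta_start: float = 0.0
    theta_stop: float = 360.0
    theta_step: float = Field(default=15.0, gt=0)
    theta_ref: float = 0.0

    def omega(self) -> np.ndarray:
        n = int(round((self.omega_stop - self.omega_start) / self.omega_step)) + 1
        return np.round(self.omega_start + np.arange(n) * self.omega_step, 10)

    def theta(self) -> np.ndarray:
        n = int(round((self.theta_stop - self.theta_start) / self.theta_step)) + 1
        return self.theta_start + np.arange(n) * self.theta_step


class SimulationConfig(_Strict):
    sample: SampleConfig
    polarizer: PolarizerConfig = PolarizerConfig()
    detection: DetectionBlock = DetectionBlock()
    grid: GridConfig = GridConfig()
    seed: int = 0


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML or JSON simulation config."""
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text)
        if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    return SimulationConfig.model_validate(data)


# -- surfaces --------------------------------------------------------------------


def write_surface(surface: AnisoSurface, path) -> None:
    """Write a surface as long-format CSV (or HDF5 for .h5/.hdf5 paths)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("omega_cm1", data=surface.omega)
            f.create_dataset("theta_deg", data=surface.theta)
            f.create_dataset("delta_abs", data=surface.values)
            f.attrs["theta_ref_deg"] = surface.theta_ref
            f.attrs["provenance"] = surface.provenance
        return
    ww, tt = np.meshgrid(surface.omega, surface.theta, indexing="ij")
    frame = pd.DataFrame(
        {
            "wavenumber_cm1": ww.ravel(),
            "theta_deg": tt.ravel(),
            "delta_abs": surface.values.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# theta_ref_deg = {surface.theta_ref:.17g}\n")
        fh.write(f"# provenance = {surface.provenance}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_surface(path) -> AnisoSurface:
    """Read a surface written by :func:`write_surface`; lossless round trip,
    with missing cells preserved as NaN."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return AnisoSurface(
                omega=f["omega_cm1"][:],
                theta=f["theta_deg"][:],
                values=f["delta_abs"][:],
                theta_ref=float(f.attrs["theta_ref_deg"]),
                provenance=str(f.attrs.get("provenance", "measured")),
            )
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        frame = pd.read_csv(fh, float_precision="round_trip")
    if list(frame.columns) != SURFACE_COLUMNS:
        raise ValueError(
            f"{path}: malformed header {list(frame.columns)}; "
            f"expected {SURFACE_COLUMNS}"
        )
    omega = np.unique(frame["wavenumber_cm1"].to_numpy())
    theta = np.unique(frame["theta_deg"].to_numpy())
    if len(frame) != omega.size * theta.size:
        raise ValueError(
            f"{path}: ragged grid — {len(frame)} rows for "
            f"{omega.size} x {theta.size} grid"
        )
    pivot = frame.pivot(
        index="wavenumber_cm1", columns="theta_deg", values="delta_abs"
    )
    theta_ref = float(meta["theta_ref_deg"]) if "theta_ref_deg" in meta else 0.0
    return AnisoSurface(
        omega=pivot.index.to_numpy(float),
        theta=pivot.columns.to_numpy(float),
        values=pivot.to_numpy(float),
        theta_ref=theta_ref,
        provenance=meta.get("provenance", "measured"),
    )


# -- peak tables and diffs -------------------------------------------------------


def write_peaks(records, path) -> None:
    """Peak-table CSV: magnitude amplitudes with an explicit sign column."""
    frame = pd.DataFrame(
        {
            "nu_cm1": [r.nu for r in records],
            "fwhm_cm1": [r.fwhm for r in records],
            "theta_deg": [r.theta_deg for r in records],
            "delta_abs": [abs(r.amplitude) for r in records],
            "sign": [1 if r.amplitude >= 0 else -1 for r in records],
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_peaks(path) -> list[PeakRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns) != PEAK_COLUMNS:
        raise ValueError(
            f"{path}: malformed header {list(frame.columns)}; expected {PEAK_COLUMNS}"
        )
    return [
        PeakRecord(
            nu=row.nu_cm1,
            fwhm=row.fwhm_cm1,
            theta_deg=row.theta_deg,
            amplitude=row.sign * row.delta_abs,
        )
        for row in frame.itertuples()
    ]


def write_diff(diff: FingerprintDiff, path) -> None:
    """Fingerprint diff as JSON with disappeared/appeared/matched arrays."""
    payload = {
        "disappeared": [asdict(r) for r in diff.disappeared],
        "appeared": [asdict(r) for r in diff.appeared],
        "matched": [
            {
                "a": asdict(m.a),
                "b": asdict(m.b),
                "delta_nu": m.delta_nu,
                "delta_theta": m.delta_theta,
            }
            for m in diff.matched
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
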