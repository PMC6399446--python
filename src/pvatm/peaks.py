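"""Resonance fingerprints: peak extraction, 180-degree folding, free-vs-bound
comparison, and the lattice-phonon frequency scaling estimate.

A fingerprint is a short table of records (nu, dnu, theta, amplitude): line
center and FWHM in cm^-1, the polarizer/orientation angle of the extremal
|dabs| folded into [0, 180) (molecular crystals give every feature 180-degree
periodicity), and the signed dabs amplitude there.  Comparing fingerprints of
a free and a ligand-bound crystal yields the peaks that disappear, appear, or
shift on binding — the binding diagnostic the technique is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, peak_widths

from .surfaces import AnisoSurface

__all__ = [
    "PeakRecord",
    "MatchedPair",
    "FingerprintDiff",
    "extract_peaks",
    "fold_periodicity",
    "fingerprint_diff",
    "lattice_phonon_estimate",
]


@dataclass(frozen=True)
class PeakRecord:
    """One resonance: center ``nu`` and FWHM ``fwhm`` (cm^-1), angle of extremal
    |dabs| in canonical [0, 180) degrees, and signed amplitude there."""

    nu: float
    fwhm: float
    theta_deg: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"peak center must be > 0, got {self.nu}")
        if not self.fwhm > 0:
            raise ValueError(f"peak FWHM must be > 0, got {self.fwhm}")


@dataclass(frozen=True)
class MatchedPair:
    a: PeakRecord
    b: PeakRecord

    @property
    def delta_nu(self) -> float:
        return self.b.nu - self.a.nu

    @property
    def delta_theta(self) -> float:
        d = (self.b.theta_deg - self.a.theta_deg) % 180.0
        return d if d <= 90.0 else d - 180.0


@dataclass
class FingerprintDiff:
    """Peaks present only in A (disappeared), only in B (appeared), and pairs
    matched within tolerance."""

    disappeared: list
    appeared: list
    matched: list


def _fold(theta: float) -> float:
    r = float(theta) % 180.0
    return 0.0 if r >= 180.0 else r  # float mod of tiny negatives yields 180.0


def fold_periodicity(records):
    """Map every record's angle into [0, 180); idempotent."""
    return [replace(r, theta_deg=_fold(r.theta_deg)) for r in records]


def _lorentz(omega, nu, fwhm):
    half = 0.5 * fwhm
    return half**2 / ((omega - nu) ** 2 + half**2)


def _fit_row(omega, row, centers0, widths0, amps0, nu_slack, width_factor=None):
    """Joint fit of Lorentzians (unit-peak parameterization) + constant
    baseline to one angle row; centers may move at most ``nu_slack[i]`` from
    their seed, and widths at most by ``width_factor`` (both ways) when given.
    Returns a list of (nu, fwhm, amplitude)."""
    n = len(centers0)
    step = float(np.median(np.diff(omega)))
    x0, lo, hi = [], [], []
    for c0, w0, a0, slack in zip(centers0, widths0, amps0, nu_slack):
        w0 = max(float(w0), step)
        x0 += [float(c0), w0, float(a0)]
        w_lo = w0 / width_factor if width_factor else 0.5 * step
        w_hi = w0 * width_factor if width_factor else float(omega[-1] - omega[0])
        lo += [float(c0) - slack, w_lo, -np.inf]
        hi += [float(c0) + slack, w_hi, np.inf]
    x0.append(0.0)
    lo.append(-np.inf)
    hi.append(np.inf)

    def model(x):
        out = np.full_like(row, x[-1])
        for i in range(n):
            nu, fw, amp = x[3 * i : 3 * i + 3]
            out = out + amp * _lorentz(omega, nu, fw)
        return out

    res = least_squares(lambda x: model(x) - row, x0=x0, bounds=(lo, hi))
    return [tuple(res.x[3 * i : 3 * i + 3]) for i in range(n)]


def extract_peaks(
    surface: AnisoSurface,
    amplitude_floor: float = 0.2,
    min_separation: float = 2.0,
):
    """Extract peak records from a dabs surface.

    Two-stage algorithm.  Stage 1: per angle row, local extrema of either sign
    above ``amplitude_floor`` are seeded with :func:`scipy.signal.find_peaks`
    (minimum spacing ``min_separation``) and refined by a joint Lorentzian
    least-squares fit; the refined detections are clustered across angles by
    center frequency (tolerance max(grid step, FWHM/4), using the narrower of
    adjacent linewidths so a blended fit from a weak row cannot bridge two
    resolved lines) into a consensus line list.  Stage 2: every row is refit
    against the full consensus list, so weak lines below the seeding threshold
    in a given row still have their tails modelled and amplitudes stay
    unbiased.  Each line reports the row of maximal |amplitude|, angle folded
    to [0, 180), sorted by center.  An empty or featureless surface returns an
    empty list.
    """
    omega = surface.omega
    if omega.size < 5:
        return []
    step = float(np.median(np.diff(omega)))
    min_dist = max(int(round(min_separation / step)), 1)

    rows = []  # (theta, finite-filled row)
    for j, th in enumerate(surface.theta):
        row = surface.values[:, j]
        finite = np.isfinite(row)
        if finite.sum() < 5:
            continue
        rows.append((float(th), np.where(finite, row, 0.0)))

    # Stage 1: rough per-row detection and clustering into consensus lines.
    detections = []  # (nu, fwhm, amplitude, theta)
    span = float(omega[-1] - omega[0])
    for th, work in rows:
        seeds = []
        for sign in (1.0, -1.0):
            idx, _ = find_peaks(
                sign * work, height=amplitude_floor, distance=min_dist,
                prominence=0.5 * amplitude_floor,
            )
            seeds += [int(i) for i in idx]
        if not seeds:
            continue
        seeds.sort()
        widths0 = [
            float(peak_widths(np.sign(work[i]) * work, [i], rel_height=0.5)[0][0])
            * step
            for i in seeds
        ]
        fitted = _fit_row(
            omega, work,
            centers0=[omega[i] for i in seeds],
            widths0=widths0,
            amps0=[work[i] for i in seeds],
            nu_slack=[span] * len(seeds),
        )
        for nu, fw, amp in fitted:
            if omega[0] < nu < omega[-1] and abs(amp) >= 0.5 * amplitude_floor:
                detections.append((float(nu), float(fw), float(amp), th))
    if not detections:
        return []

    detections.sort()
    clusters = [[detections[0]]]
    for det in detections[1:]:
        prev = clusters[-1][-1]
        tol = max(step, 0.25 * min(det[1], prev[1]))
        if det[0] - prev[0] <= tol:
            clusters[-1].append(det)
        else:
            clusters.append([det])
    lines = []  # consensus (nu, fwhm, strength) from each cluster's strongest row
    for cluster in clusters:
        nu, fw, amp, _th = max(cluster, key=lambda d: abs(d[2]))
        lines.append((nu, fw, abs(amp)))
    # Prune blended composites before refitting: a weak broad line overlapping
    # a stronger one within half its own width is a stage-1 artifact from rows
    # where neighbours were unresolved, and would make the joint refit
    # degenerate.
    lines = [
        (nu, fw)
        for nu, fw, s in lines
        if not any(
            s2 > s and 0 < abs(nu - nu2) < 0.5 * fw for nu2, _fw2, s2 in lines
        )
    ]

    # Stage 2: constrained refit of every row against the consensus list.
    best: list[tuple[float, float, float, float] | None] = [None] * len(lines)
    for th, work in rows:
        fitted = _fit_row(
            omega, work,
            centers0=[nu for nu, _ in lines],
            widths0=[fw for _, fw in lines],
            amps0=[float(np.interp(nu, omega, work)) for nu, _ in lines],
            nu_slack=[max(step, 0.5 * fw) for _, fw in lines],
            width_factor=3.0,
        )
        for i, (nu, fw, amp) in enumerate(fitted):
            if best[i] is None or abs(amp) > abs(best[i][2]):
                best[i] = (float(nu), float(fw), float(amp), th)

    records = [
        PeakRecord(nu=nu, fwhm=max(fw, 1e-12), theta_deg=_fold(th), amplitude=amp)
        for nu, fw, amp, th in (b for b in best if b is not None)
        if abs(amp) >= amplitude_floor
    ]

    # Drop blend artifacts: a record sitting within half its own FWHM of a
    # strictly stronger record is an unresolved composite of its neighbours.
    records = [
        r
        for r in records
        if not any(
            s is not r
            and abs(s.amplitude) > abs(r.amplitude)
            and abs(r.nu - s.nu) < 0.5 * r.fwhm
            for s in records
        )
    ]
    records.sort(key=lambda r: r.nu)
    return records


def _angle_distance(a: float, b: float) -> float:
    """Distance on the 180-degree-periodic angle circle."""
    d = abs(_fold(a) - _fold(b))
    return min(d, 180.0 - d)


def fingerprint_diff(
    a, b, nu_tol: float = 2.0, theta_tol: float = 15.0
) -> FingerprintDiff:
    """Greedy nearest-frequency matching of two folded fingerprints.

    Pairs within both tolerances are matched in order of increasing |delta nu|
    (ties broken by smaller FWHM difference); everything unmatched in ``a`` is
    reported as disappeared, in ``b`` as appeared.
    """
    a = fold_periodicity(a)
    b = fold_periodicity(b)
    pairs = []
    for i, ra in enumerate(a):
        for j, rb in enumerate(b):
            if abs(ra.nu - rb.nu) <= nu_tol and _angle_distance(
                ra.theta_deg, rb.theta_deg
            ) <= theta_tol:
                pairs.append((abs(ra.nu - rb.nu), abs(ra.fwhm - rb.fwhm), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _dnu, _dfw, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append(MatchedPair(a=a[i], b=b[j]))
    return FingerprintDiff(
        disappeared=[r for i, r in enumerate(a) if i not in used_a],
        appeared=[r for j, r in enumerate(b) if j not in used_b],
        matched=matched,
    )


def lattice_phonon_estimate(
    reference_frequency: float, mass_ratio: float, force_constant_ratio: float
) -> float:
    """Scale a lattice-phonon frequency by sqrt(k/m) ratios.

    A lattice phonon scales as sqrt(k/m) with the intermolecular force constant
    ``k`` and molecular mass ``m``; given a reference crystal's phonon frequency
    and the target/reference ratios of mass and force constant, returns the
    estimated target-crystal phonon frequency (cm^-1).  E.g. a protein ~1000x
    the mass of sucrose with less than half its contact stiffness puts protein
    lattice phonons near 1 cm^-1 — far below the 10-100 cm^-1 intramolecular
    fingerprint region.
    """
    if not (
        reference_frequency > 0 and mass_ratio > 0 and force_constant_ratio > 0
    ):
        raise ValueError("all arguments must be > 0")
    return reference_frequency * float(np.sqrt(force_constant_ratio / mass_ratio))
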