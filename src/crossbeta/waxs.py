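"""Wide-angle X-ray scattering: 2D pattern reduction and peak assignment.

A fiber diffraction pattern from a cross-beta assembly shows rings (or arcs)
whose d-spacings report the two packing periodicities of the zipper: the
inter-sheet separation (~10-11 A) and the inter-strand hydrogen-bonding
repeat (~4.7-4.8 A).  This module folds a detector image into a 1D radial
profile I(q), extracts an azimuthal profile on a chosen ring, detects peaks,
and assigns them to model distances.

The momentum transfer is computed with the exact wide-angle geometry
``q = (4 pi / lambda) sin(theta / 2)`` with ``theta = atan(r / D)`` the full
scattering angle of a pixel at radial distance r from the beam centre --
no small-angle approximation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import find_peaks

from .builder import Assembly

__all__ = [
    "Pattern2D", "RadialProfile", "PeakAssignment",
    "q_to_d", "d_to_q", "q_map", "radial_fold", "azimuthal_profile",
    "detect_peaks", "assign_peaks",
]

DEFAULT_Q_BIN = 0.005       # Angstrom^-1
DEFAULT_AZ_BIN = 2.0        # degrees


@dataclass
class Pattern2D:
    """Detector image with the geometry needed for q calibration."""

    intensity: np.ndarray        # (rows, cols), counts >= 0
    pixel_size_um: float         # square pixels
    distance_mm: float           # sample-detector distance
    wavelength_nm: float         # e.g. Cu K-alpha 0.15405
    beam_center: Tuple[float, float]   # (col, row) pixel coordinates

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D array")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        for val, name in ((self.pixel_size_um, "pixel_size_um"),
                          (self.distance_mm, "distance_mm"),
                          (self.wavelength_nm, "wavelength_nm")):
            if val is None or val <= 0:
                raise ValueError(f"{name} must be positive")
        cx, cy = self.beam_center
        rows, cols = self.intensity.shape
        if not (0 <= cx < cols and 0 <= cy < rows):
            raise ValueError("beam center outside the detector grid")


@dataclass
class RadialProfile:
    """Azimuthally averaged 1D profile I(q); empty q bins are dropped."""

    q: np.ndarray            # bin centers, strictly increasing, A^-1
    intensity: np.ndarray    # mean intensity per bin
    counts: np.ndarray       # pixels per bin

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.intensity = np.asarray(self.intensity, float)
        self.counts = np.asarray(self.counts, int)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class PeakAssignment:
    q_peak: float
    d: float
    label: str          # inter_sheet | inter_strand | other

    def __post_init__(self):
        if abs(self.d - q_to_d(self.q_peak)) > 1e-9 * max(1.0, self.d):
            raise ValueError("d must equal 2*pi/q_peak")


def q_to_d(q: float) -> float:
    """Real-space periodicity d = 2 pi / q (q in A^-1, d in A)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    return 2.0 * np.pi / q if q.ndim else float(2.0 * np.pi / q)


def d_to_q(d: float) -> float:
    """Inverse of :func:`q_to_d`."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be positive")
    return 2.0 * np.pi / d if d.ndim else float(2.0 * np.pi / d)


def q_map(pattern: Pattern2D) -> np.ndarray:
    """Momentum transfer magnitude (A^-1) of every pixel."""
    rows, cols = pattern.intensity.shape
    cx, cy = pattern.beam_center
    y, x = np.mgrid[0:rows, 0:cols]
    pix_mm = pattern.pixel_size_um / 1000.0
    r_mm = np.hypot((x - cx) * pix_mm, (y - cy) * pix_mm)
    theta = np.arctan2(r_mm, pattern.distance_mm)       # full scattering angle
    lam_A = pattern.wavelength_nm * 10.0
    return (4.0 * np.pi / lam_A) * np.sin(theta / 2.0)


def azimuth_map(pattern: Pattern2D) -> np.ndarray:
    """Pixel azimuth in degrees [0, 360), 0 along the detector +x axis."""
    rows, cols = pattern.intensity.shape
    cx, cy = pattern.beam_center
    y, x = np.mgrid[0:rows, 0:cols]
    return np.degrees(np.arctan2(y - cy, x - cx)) % 360.0


def radial_fold(pattern: Pattern2D, q_bins: Optional[np.ndarray] = None,
                bin_width: float = DEFAULT_Q_BIN) -> RadialProfile:
    """Azimuthally average the pattern into I(q).

    ``q_bins`` are bin edges; by default a uniform grid of ``bin_width``
    covering the detector's q range.  Bins containing no pixels are absent
    from the returned profile.
    """
    q = q_map(pattern)
    if q_bins is None:
        q_bins = np.arange(0.0, q.max() + bin_width, bin_width)
    q_bins = np.asarray(q_bins, float)
    idx = np.digitize(q.ravel(), q_bins) - 1
    nbin = len(q_bins) - 1
    valid = (idx >= 0) & (idx < nbin)
    counts = np.bincount(idx[valid], minlength=nbin)
    sums = np.bincount(idx[valid], weights=pattern.intensity.ravel()[valid],
                       minlength=nbin)
    present = counts > 0
    centers = 0.5 * (q_bins[:-1] + q_bins[1:])
    with np.errstate(invalid="ignore"):
        means = np.where(present, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(q=centers[present], intensity=means[present],
                         counts=counts[present])


def azimuthal_profile(pattern: Pattern2D, q0: float, dq: float,
                      bin_width_deg: float = DEFAULT_AZ_BIN):
    """Mean intensity versus azimuth inside the annulus q0 +/- dq.

    Returns (azimuth bin centers in degrees [0, 360), mean intensity).
    """
    q = q_map(pattern)
    ring = np.abs(q - q0) <= dq
    if not ring.any():
        raise ValueError(f"annulus q={q0}+/-{dq} does not intersect the detector")
    az = azimuth_map(pattern)[ring]
    inten = pattern.intensity[ring]
    edges = np.arange(0.0, 360.0 + bin_width_deg, bin_width_deg)
    idx = np.digitize(az, edges) - 1
    nbin = len(edges) - 1
    idx = np.clip(idx, 0, nbin - 1)
    counts = np.bincount(idx, minlength=nbin)
    sums = np.bincount(idx, weights=inten, minlength=nbin)
    present = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers[present], sums[present] / counts[present]


def detect_peaks(profile: RadialProfile, min_prominence: float = 0.05) -> List[float]:
    """Local maxima of the radial profile, refined by 3-point parabolic
    interpolation.

    ``min_prominence`` is a fraction of the profile's dynamic range; peaks
    whose prominence falls below it are discarded.  May return an empty list.
    """
    y = profile.intensity
    if len(y) < 5:
        raise ValueError("need at least 5 bins to detect peaks")
    span = float(y.max() - y.min())
    if span == 0.0:
        return []
    idx, _ = find_peaks(y, prominence=min_prominence * span)
    out = []
    for i in idx:
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            delta = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            q_ref = profile.q[i] + delta * (profile.q[min(i + 1, len(y) - 1)]
                                            - profile.q[max(i - 1, 0)]) / 2.0
        else:
            q_ref = profile.q[i]
        out.append(float(q_ref))
    return out


def _model_spacings(model: Union[Assembly, Tuple[float, float]]):
    if isinstance(model, tuple):
        return model
    if model.provenance is not None:
        return (model.provenance.inter_sheet_spacing,
                model.provenance.inter_strand_spacing)
    # measure from geometry
    inter_sheet = None
    if model.n_sheets >= 2:
        inter_sheet = abs(model.mean_ca_plane_z(1) - model.mean_ca_plane_z(0))
    ca0 = model.ca_xyz(sheet=0, strand=0)
    ca1 = model.ca_xyz(sheet=0, strand=1)
    inter_strand = None
    if len(ca0) and len(ca1):
        d = np.linalg.norm(ca0[:, None, :] - ca1[None, :, :], axis=2)
        inter_strand = float(d.min())
    return inter_sheet, inter_strand


def assign_peaks(peaks: Sequence[float],
                 model: Union[Assembly, Tuple[float, float]],
                 rel_tol: float = 0.10) -> List[PeakAssignment]:
    """Label peaks whose d-spacing matches a model packing distance.

    ``model`` is either a built assembly (spacings taken from its spec or
    measured from its geometry) or an explicit (inter_sheet, inter_strand)
    tuple in Angstrom.  A peak within ``rel_tol`` relative deviation of a
    model distance gets that label; everything else is "other".
    """
    inter_sheet, inter_strand = _model_spacings(model)
    out = []
    for qp in peaks:
        d = q_to_d(qp)
        label = "other"
        if inter_sheet and abs(d - inter_sheet) / inter_sheet <= rel_tol:
            label = "inter_sheet"
        elif inter_strand and abs(d - inter_strand) / inter_strand <= rel_tol:
            label = "inter_strand"
        out.append(PeakAssignment(q_peak=float(qp), d=float(d), label=label))
    return out
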