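"""Ground-truth synthetic data generators for every analysis input.

Each generator is a pure function of (recipe, seed): identical inputs yield
bit-identical outputs, and the generating parameters are returned alongside
the data as a machine-readable ground-truth record so tests never have to
re-derive them.

The three generators emulate, with known ground truth, the phenomenology of
the corresponding experiments: (i) assembly trajectories with ramped twist,
breathing of the inter-sheet separation and Gaussian positional noise;
(ii) powder-like 2D diffraction patterns built from radially Gaussian rings
with optional azimuthal arcs; (iii) two-regime dye-titration curves with a
known break point and multiplicative noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assays import TitrationSeries
from .builder import Assembly, AssemblySpec, build_assembly, spec_st10_sh4
from .traj_analysis import Trajectory
from .waxs import Pattern2D, q_map, azimuth_map

__all__ = [
    "TrajectoryRecipe", "RingSpec", "PatternRecipe", "TitrationRecipe",
    "make_trajectory", "make_pattern", "make_titration",
]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryRecipe:
    """Perturbed-assembly trajectory with known geometric ground truth.

    Frame 0 is always the unperturbed built model.  Subsequent frames apply,
    in order: breathing of the inter-sheet separation (sinusoidal, amplitude
    in A, period in frames), a twist ramp (degrees per strand at the final
    frame, rotating each strand about the fibril axis), and i.i.d. Gaussian
    positional noise.  Noise comes last so the ground-truth distances refer
    to the noiseless geometry.
    """

    spec: AssemblySpec = field(default_factory=spec_st10_sh4)
    n_frames: int = 100
    noise_sigma: float = 0.3            # A, RMS displacement per atom
    twist_rate: float = 0.0             # degrees per strand, at the last frame
    breathing_amplitude: float = 0.0    # A
    breathing_period: int = 20          # frames
    dt_ns: float = 1.0
    seed: int = 0

    def validate(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.breathing_period < 1:
            raise ValueError("breathing_period must be >= 1")
        self.spec.validate()


def make_trajectory(recipe: TrajectoryRecipe):
    """Generate (Trajectory, topology Assembly, ground-truth dict).

    The ground truth maps frame index to the true (noiseless) inter-sheet
    separation and the applied twist in degrees per strand.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    topo = build_assembly(recipe.spec)
    base = topo.xyz.copy()
    spec = recipe.spec

    # per-atom sheet offsets and strand column index for the perturbations
    sheet = topo.sheet_index
    z_planes = np.array([topo.mean_ca_plane_z(k) for k in range(spec.n_sheets)])
    # global strand column (for the twist ramp): strands ordered by y
    strand_col = topo.strand_index.astype(float)

    yc = base[:, 1].mean()
    zc = base[:, 2].mean()

    frames = np.empty((recipe.n_frames, topo.n_atoms, 3))
    truth = {
        "time_ns": np.arange(recipe.n_frames) * recipe.dt_ns,
        "inter_sheet": np.empty(recipe.n_frames),
        "twist_deg_per_strand": np.empty(recipe.n_frames),
    }
    denom = max(recipe.n_frames - 1, 1)
    for f in range(recipe.n_frames):
        xyz = base.copy()
        if f == 0:
            sep = spec.inter_sheet_spacing
            twist = 0.0
        else:
            # breathing: displace whole sheets so adjacent separations are
            # spacing + A sin(2 pi f / period)
            delta = recipe.breathing_amplitude * np.sin(
                2.0 * np.pi * f / recipe.breathing_period)
            sep = spec.inter_sheet_spacing + delta
            xyz[:, 2] += sheet * delta
            # twist ramp about the fibril (x) axis, angle per strand column
            twist = recipe.twist_rate * f / denom
            if twist != 0.0:
                ang = np.radians(twist) * strand_col
                y = xyz[:, 1] - yc
                z = xyz[:, 2] - zc
                ca, sa = np.cos(ang), np.sin(ang)
                xyz[:, 1] = yc + ca * y - sa * z
                xyz[:, 2] = zc + sa * y + ca * z
            if recipe.noise_sigma > 0:
                # sigma is the RMS displacement per atom: sigma/sqrt(3) per axis
                xyz += rng.normal(0.0, recipe.noise_sigma / np.sqrt(3.0),
                                  size=xyz.shape)
        frames[f] = xyz
        truth["inter_sheet"][f] = sep
        truth["twist_deg_per_strand"][f] = twist

    traj = Trajectory(frames=frames, times=truth["time_ns"].astype(float))
    return traj, topo, truth


# ---------------------------------------------------------------------------
# 2D diffraction patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingSpec:
    """One Debye-Scherrer ring: radially Gaussian at q0, optionally
    concentrated into azimuthal arcs."""

    q: float                       # A^-1
    intensity: float = 1.0         # peak height above background
    width: float = 0.02            # radial Gaussian sigma, A^-1
    # arcs: (center azimuth deg, Gaussian width deg, weight); None = isotropic
    arcs: Optional[Tuple[Tuple[float, float, float], ...]] = None

    def validate(self):
        if self.q <= 0 or self.width <= 0 or self.intensity < 0:
            raise ValueError("ring q/width must be positive, intensity >= 0")


@dataclass(frozen=True)
class PatternRecipe:
    """Synthetic detector image with known ring positions.

    Default geometry: 512x512 pixels of 100 um at 60 mm with Cu K-alpha
    radiation, which covers the wide-angle q range (to ~1.6 A^-1 on the
    detector edge) where cross-beta reflections live.
    """

    rings: Tuple[RingSpec, ...] = ()
    shape: Tuple[int, int] = (512, 512)
    pixel_size_um: float = 100.0
    distance_mm: float = 60.0
    wavelength_nm: float = 0.15405
    beam_center: Optional[Tuple[float, float]] = None   # default: grid centre
    background: float = 1.0
    poisson: bool = False
    seed: int = 0

    def center(self) -> Tuple[float, float]:
        if self.beam_center is not None:
            return self.beam_center
        rows, cols = self.shape
        return ((cols - 1) / 2.0, (rows - 1) / 2.0)


def make_pattern(recipe: PatternRecipe):
    """Generate (Pattern2D, ground-truth dict).

    Rings must fall inside the detector's usable q range (up to the edge
    closest to the beam centre); a ring outside it is rejected.
    """
    rows, cols = recipe.shape
    center = recipe.center()
    blank = Pattern2D(intensity=np.zeros(recipe.shape),
                      pixel_size_um=recipe.pixel_size_um,
                      distance_mm=recipe.distance_mm,
                      wavelength_nm=recipe.wavelength_nm,
                      beam_center=center)
    q = q_map(blank)
    # usable radius: nearest detector edge from the beam centre
    cx, cy = center
    edge_px = min(cx, cy, cols - 1 - cx, rows - 1 - cy)
    pix_mm = recipe.pixel_size_um / 1000.0
    theta_max = np.arctan2(edge_px * pix_mm, recipe.distance_mm)
    q_edge = (4.0 * np.pi / (recipe.wavelength_nm * 10.0)) * np.sin(theta_max / 2.0)

    az = azimuth_map(blank)
    inten = np.full(recipe.shape, float(recipe.background))
    for ring in recipe.rings:
        ring.validate()
        if ring.q >= q_edge:
            raise ValueError(
                f"ring q={ring.q} beyond detector edge q={q_edge:.3f}")
        radial = np.exp(-0.5 * ((q - ring.q) / ring.width) ** 2)
        if ring.arcs is None:
            angular = 1.0
        else:
            angular = np.zeros(recipe.shape)
            for c_deg, w_deg, weight in ring.arcs:
                dd = (az - c_deg + 180.0) % 360.0 - 180.0
                angular += weight * np.exp(-0.5 * (dd / w_deg) ** 2)
        inten += ring.intensity * radial * angular

    if recipe.poisson:
        rng = np.random.default_rng(recipe.seed)
        inten = rng.poisson(inten).astype(float)

    pattern = Pattern2D(intensity=inten, pixel_size_um=recipe.pixel_size_um,
                        distance_mm=recipe.distance_mm,
                        wavelength_nm=recipe.wavelength_nm, beam_center=center)
    truth = {
        "ring_q": np.array([r.q for r in recipe.rings]),
        "q_edge": float(q_edge),
        "background": float(recipe.background),
    }
    return pattern, truth


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationRecipe:
    """Two-regime titration with a known break point.

    Defaults place the break at the measured CAC of the unPEGylated
    heptapeptide (9.09e-5 mol/L) inside a concentration grid spanning the
    decade around it, with a shallow pre-break and steep post-break slope as
    seen in dye-uptake fluorescence titrations.
    """

    cac: float = 9.09e-5                      # mol/L
    conc_grid: Tuple[float, ...] = tuple(np.geomspace(1e-5, 1e-3, 20))
    intercept: float = 20.0                   # fluorescence a.u. at c=0
    slope_pre: float = 2.0e4                  # a.u. per (mol/L)
    slope_post: float = 2.0e6
    noise_rel: float = 0.0                    # multiplicative Gaussian sigma
    seed: int = 0

    def validate(self):
        grid = np.asarray(self.conc_grid, float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("conc_grid must be strictly increasing")
        if self.cac is not None and not (grid[0] < self.cac < grid[-1]):
            raise ValueError("cac must lie strictly inside the grid")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")


def make_titration(recipe: TitrationRecipe):
    """Generate (TitrationSeries, ground-truth dict).

    With ``cac=None`` the curve is a single straight line of slope
    ``slope_pre`` (degenerate, no break).
    """
    grid = np.asarray(recipe.conc_grid, float)
    if recipe.cac is not None:
        recipe.validate()
        y = recipe.intercept + recipe.slope_pre * np.minimum(grid, recipe.cac)
        y = y + recipe.slope_post * np.maximum(0.0, grid - recipe.cac)
    else:
        if np.any(np.diff(grid) <= 0):
            raise ValueError("conc_grid must be strictly increasing")
        y = recipe.intercept + recipe.slope_pre * grid
    if recipe.noise_rel > 0:
        rng = np.random.default_rng(recipe.seed)
        y = y * (1.0 + rng.normal(0.0, recipe.noise_rel, size=y.shape))
    series = TitrationSeries(concentrations=grid, intensities=y, unit="mol/L")
    truth = {"cac": recipe.cac, "slope_pre": recipe.slope_pre,
             "slope_post": recipe.slope_post}
    return series, truth
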