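"""Structural metrics for multi-frame coordinate sets of zipper assemblies.

The functions here reproduce the standard stability diagnostics used for
cross-beta aggregate simulations: gyration radius, RMSD against a reference,
inter-sheet separation traces, chi1 rotamer states, a dihedral+contact
beta-structure assignment, minimal S-S approach across a wet interface, the
average structure over a trajectory window, and the RMSIP essential-subspace
overlap used as a convergence check between trajectory halves.

All single-frame functions take a plain ``(N, 3)`` coordinate array plus the
:class:`~crossbeta.builder.Assembly` that provides the topology (atom names,
strand/sheet labels, masses via elements).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._geom import dihedral_deg, kabsch, lsq_plane, superpose
from .builder import Assembly
from .constants import ATOMIC_WEIGHTS

__all__ = [
    "Trajectory", "DistanceSeries", "RotamerSeries", "ConvergenceReport",
    "radius_of_gyration", "rmsd", "inter_sheet_distance", "chi1_states",
    "beta_content", "ss_min_approach", "rmsip", "average_structure",
    "classify_chi1", "distance_series",
]

# chi1 state bins on [0, 360): field convention
_CHI1_BINS = (("gauche+", 0.0, 120.0), ("trans", 120.0, 240.0),
              ("gauche-", 240.0, 360.0))

# dihedral basin used by the beta assignment (phi in degrees, psi mod 360)
_BETA_PHI = (-180.0, -45.0)
_BETA_PSI = (45.0, 225.0)
_BETA_CONTACT_CUTOFF = 5.5  # Angstrom, cross-strand CA-CA

# gamma heavy atom defining chi1, per residue type
_GAMMA_ATOM = {"CYS": "SG", "SER": "OG", "THR": "OG1", "ILE": "CG1",
               "VAL": "CG1"}


@dataclass
class Trajectory:
    """Ordered coordinate frames congruent with a reference topology."""

    frames: np.ndarray          # (F, N, 3)
    times: np.ndarray           # (F,) in ns

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be a (F, N, 3) array")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def window(self, start: int, stop: int) -> "Trajectory":
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(f"window [{start}, {stop}) outside trajectory")
        return Trajectory(self.frames[start:stop], self.times[start:stop])


@dataclass
class DistanceSeries:
    times: np.ndarray
    values: np.ndarray
    label: str

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values lengths differ")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class RotamerSeries:
    """Per-frame, per-residue chi1 states ('trans', 'gauche+', 'gauche-')."""
    times: np.ndarray
    residues: List[Tuple[int, int, int]]      # (sheet, strand, resid)
    states: np.ndarray                        # (F, R) object array, None if n/a


@dataclass
class ConvergenceReport:
    rmsip: float
    k: int
    window_a: Tuple[float, float]
    window_b: Tuple[float, float]

    def __post_init__(self):
        if not (0.0 <= self.rmsip <= 1.0 + 1e-9):
            raise ValueError(f"rmsip {self.rmsip} outside [0, 1]")


# ---------------------------------------------------------------------------

def _masses(topology: Assembly, sel: np.ndarray) -> np.ndarray:
    return np.array([ATOMIC_WEIGHTS[e] for e in topology.elements[sel]])


def _selection(topology: Assembly, selection) -> np.ndarray:
    if selection is None:
        return np.arange(topology.n_atoms)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.nonzero(sel)[0]
    if sel.size == 0:
        raise ValueError("empty selection")
    return sel


def radius_of_gyration(frame: np.ndarray, topology: Assembly,
                       selection=None) -> float:
    """Mass-weighted root-mean-square distance from the centre of mass (A)."""
    sel = _selection(topology, selection)
    x = np.asarray(frame, float)[sel]
    m = _masses(topology, sel)
    com = np.average(x, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((x - com) ** 2, axis=1), weights=m)))


def rmsd(frame: np.ndarray, reference: np.ndarray, selection=None,
         superpose_first: bool = True, topology: Optional[Assembly] = None) -> float:
    """RMSD between two congruent frames, optionally after optimal rigid
    superposition (Kabsch)."""
    x = np.asarray(frame, float)
    r = np.asarray(reference, float)
    if selection is not None:
        sel = np.asarray(selection)
        if sel.dtype == bool:
            sel = np.nonzero(sel)[0]
        x = x[sel]
        r = r[sel]
    if x.shape != r.shape:
        raise ValueError(f"frame shape {x.shape} != reference shape {r.shape}")
    if superpose_first:
        x = superpose(x, r)
    return float(np.sqrt(np.mean(np.sum((x - r) ** 2, axis=1))))


def _central_ca_index(topology: Assembly, sheet: int) -> int:
    """Atom index of the central C-alpha of the central strand of a sheet
    (ties broken toward the lower index)."""
    n_strands = topology.n_strands(sheet)
    if n_strands == 0:
        raise ValueError(f"sheet {sheet} not present in topology")
    strand = (n_strands - 1) // 2
    m = topology.mask(name="CA", sheet=sheet, strand=strand)
    idx = np.nonzero(m)[0]
    resids = topology.resids[idx]
    order = np.argsort(resids)
    return int(idx[order[(len(idx) - 1) // 2]])


def inter_sheet_distance(frame: np.ndarray, topology: Assembly,
                         sheet_a: int, sheet_b: int,
                         mode: str = "mean_planes") -> float:
    """Separation of two sheets in a frame.

    ``representative_pair``: distance between the central C-alpha atoms of
    the central strands.  ``mean_planes``: distance between the least-squares
    C-alpha planes of the two sheets, measured along their mean normal.
    """
    frame = np.asarray(frame, float)
    for s in (sheet_a, sheet_b):
        if not topology.mask(sheet=s).any():
            raise ValueError(f"sheet {s} not present in topology")
    if mode == "representative_pair":
        i = _central_ca_index(topology, sheet_a)
        j = _central_ca_index(topology, sheet_b)
        return float(np.linalg.norm(frame[i] - frame[j]))
    if mode == "mean_planes":
        pa = frame[topology.mask(name="CA", sheet=sheet_a)]
        pb = frame[topology.mask(name="CA", sheet=sheet_b)]
        ca_, na = lsq_plane(pa)
        cb_, nb = lsq_plane(pb)
        if np.dot(na, nb) < 0:
            nb = -nb
        n = na + nb
        n /= np.linalg.norm(n)
        return float(abs(np.dot(cb_ - ca_, n)))
    raise ValueError(f"unknown mode {mode!r}")


def classify_chi1(angle_deg: float) -> str:
    """Map a chi1 angle (degrees) to its rotamer state.

    States partition the circle: gauche+ [0, 120), trans [120, 240),
    gauche- [240, 360).
    """
    a = float(angle_deg) % 360.0
    for state, lo, hi in _CHI1_BINS:
        if lo <= a < hi:
            return state
    return "gauche-"   # a == 360.0 after rounding


def chi1_states(frame: np.ndarray, topology: Assembly):
    """chi1 rotamer state per residue; residues lacking a C-beta or gamma
    heavy atom are reported as None.

    Returns (residue refs, states) with refs (sheet, strand, resid).
    """
    frame = np.asarray(frame, float)
    refs, states = [], []
    key = np.stack([topology.sheet_index, topology.strand_index,
                    topology.resids], axis=1)
    uniq = np.unique(key, axis=0)
    for sheet, strand, resid in uniq:
        m = topology.mask(sheet=sheet, strand=strand, resid=resid)
        names = topology.names[m]
        pos = {n: frame[m][i] for i, n in enumerate(names)}
        resname = topology.resnames[m][0]
        gamma = _GAMMA_ATOM.get(resname, "CG")
        refs.append((int(sheet), int(strand), int(resid)))
        if not {"N", "CA", "CB", gamma} <= set(names):
            states.append(None)
            continue
        chi1 = dihedral_deg(pos["N"], pos["CA"], pos["CB"], pos[gamma])
        states.append(classify_chi1(chi1))
    return refs, states


def beta_content(frame: np.ndarray, topology: Assembly):
    """Fraction of eligible residues in extended beta conformation.

    A residue is labeled beta when its (phi, psi) fall in the extended basin
    (phi in [-180, -45], psi mod 360 in [45, 225]) and its C-alpha has a
    cross-strand C-alpha neighbour within 5.5 A.  Eligible residues are the
    ones whose phi and psi are both defined (interior residues, plus the
    C-terminal residue when an amide cap provides the next amide nitrogen).
    Returns (fraction, labels) with labels a dict ref -> bool.
    """
    frame = np.asarray(frame, float)
    labels = {}
    ca_idx = np.nonzero(topology.names == "CA")[0]
    strand_key = (topology.sheet_index[ca_idx].astype(np.int64) << 20) \
        | topology.strand_index[ca_idx]
    ca_pos = frame[ca_idx]

    strands = {}
    key_all = np.stack([topology.sheet_index, topology.strand_index], axis=1)
    for sheet, strand in np.unique(key_all, axis=0):
        m = topology.mask(sheet=sheet, strand=strand)
        resids = np.unique(topology.resids[m])
        if len(resids) < 3:
            continue
        pos = {}
        for i in np.nonzero(m)[0]:
            pos[(topology.resids[i], topology.names[i])] = frame[i]
        for r in sorted(resids):
            prev_c = pos.get((r - 1, "C"))
            nxt_n = pos.get((r + 1, "N"))
            if nxt_n is None:
                nxt_n = pos.get((r, "NT"))   # amide cap
            need = (prev_c, pos.get((r, "N")), pos.get((r, "CA")),
                    pos.get((r, "C")), nxt_n)
            if any(p is None for p in need):
                continue
            phi = dihedral_deg(prev_c, pos[(r, "N")], pos[(r, "CA")], pos[(r, "C")])
            psi = dihedral_deg(pos[(r, "N")], pos[(r, "CA")], pos[(r, "C")], nxt_n)
            in_basin = (_BETA_PHI[0] <= phi <= _BETA_PHI[1]
                        and _BETA_PSI[0] <= psi % 360.0 <= _BETA_PSI[1])
            # cross-strand contact
            my_key = (int(sheet) << 20) | int(strand)
            me = pos[(r, "CA")]
            other = ca_pos[strand_key != my_key]
            contact = (len(other) > 0 and
                       float(np.min(np.linalg.norm(other - me, axis=1)))
                       <= _BETA_CONTACT_CUTOFF)
            labels[(int(sheet), int(strand), int(r))] = bool(in_basin and contact)
    if not labels:
        return 0.0, labels
    frac = sum(labels.values()) / len(labels)
    return float(frac), labels


def ss_min_approach(frame: np.ndarray, topology: Assembly,
                    interface: int) -> Optional[float]:
    """Minimum S-gamma to S-gamma distance across interface ``interface``
    (between sheets interface and interface+1); None when either face has
    no cysteine sulfur."""
    frame = np.asarray(frame, float)
    a = frame[topology.mask(name="SG", sheet=interface, resname="CYS")]
    b = frame[topology.mask(name="SG", sheet=interface + 1, resname="CYS")]
    if len(a) == 0 or len(b) == 0:
        return None
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.min())


def average_structure(traj: Trajectory, window: Tuple[int, int]) -> np.ndarray:
    """Per-atom mean over a frame window after superposing every frame onto
    the first frame of the window."""
    start, stop = window
    w = traj.window(start, stop)
    ref = w.frames[0]
    acc = np.zeros_like(ref)
    for f in w.frames:
        acc += superpose(f.reshape(-1, 3), ref.reshape(-1, 3))
    return acc / w.n_frames


def rmsip(window_a: Trajectory, window_b: Trajectory, k: int = 10,
          selection=None, superpose_frames: bool = True) -> ConvergenceReport:
    """Root mean square inner product between the top-k covariance
    eigenvector subspaces of two trajectory windows.

    Frames of both windows are superposed onto a common reference (the
    earliest frame across the two windows, making the measure symmetric)
    before the per-window coordinate covariance is diagonalised.

    RMSIP = sqrt( (1/k) sum_ij (u_i . v_j)^2 ), between 0 (orthogonal
    essential subspaces) and 1 (identical subspaces).
    """
    if window_a.frames.shape[1:] != window_b.frames.shape[1:]:
        raise ValueError("windows have incongruent atom sets")
    for w in (window_a, window_b):
        if w.n_frames < k + 1:
            raise ValueError(f"window with {w.n_frames} frames cannot support k={k}")

    if selection is None:
        sel = np.arange(window_a.frames.shape[1])
    else:
        sel = np.asarray(selection)
        if sel.dtype == bool:
            sel = np.nonzero(sel)[0]
    n3 = 3 * len(sel)
    if k > n3:
        raise ValueError(f"k={k} exceeds the {n3} available modes")

    # common reference: earliest frame overall (content tie-break keeps the
    # measure exactly symmetric when both windows start at the same time)
    fa = window_a.frames[0][sel]
    fb = window_b.frames[0][sel]
    if window_a.times[0] < window_b.times[0]:
        ref = fa
    elif window_b.times[0] < window_a.times[0]:
        ref = fb
    else:
        ref = fa if tuple(fa.ravel()) <= tuple(fb.ravel()) else fb

    def top_modes(w: Trajectory) -> np.ndarray:
        X = np.empty((w.n_frames, n3))
        for i, f in enumerate(w.frames):
            x = f[sel]
            if superpose_frames:
                x = superpose(x, ref)
            X[i] = x.ravel()
        X -= X.mean(axis=0)
        C = (X.T @ X) / max(w.n_frames - 1, 1)
        vals, vecs = np.linalg.eigh(C)
        return vecs[:, ::-1][:, :k]          # columns: top-k eigenvectors

    U = top_modes(window_a)
    V = top_modes(window_b)
    overlap = U.T @ V
    val = float(np.sqrt(np.sum(overlap ** 2) / k))
    return ConvergenceReport(
        rmsip=min(val, 1.0), k=k,
        window_a=(float(window_a.times[0]), float(window_a.times[-1])),
        window_b=(float(window_b.times[0]), float(window_b.times[-1])))


def distance_series(traj: Trajectory, topology: Assembly, sheet_a: int,
                    sheet_b: int, mode: str = "mean_planes",
                    label: Optional[str] = None) -> DistanceSeries:
    """Inter-sheet distance evaluated over every frame of a trajectory."""
    vals = np.array([inter_sheet_distance(f, topology, sheet_a, sheet_b, mode)
                     for f in traj.frames])
    return DistanceSeries(times=traj.times.copy(), values=vals,
                          label=label or f"sheet{sheet_a}-sheet{sheet_b}:{mode}")
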