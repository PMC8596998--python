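"""Construction of idealized cross-beta steric-zipper assemblies.

The model family built here is the classic amyloid cross-beta motif: flat
antiparallel beta-sheets of short peptide strands, stacked so that pairs of
sheets meet either through a "dry" interface (tightly packed apolar side
chains, here Phe) or a "wet", solvent-exposed interface (polar side chains,
here Tyr/Cys).  For the heptapeptide FYFCFYF the strict alternation of Phe
with Tyr/Cys along the sequence places all Phe side chains on one face of a
sheet and all Tyr/Cys on the other, which is what makes both interface types
realisable with a single sheet geometry.

Geometry is idealized rather than borrowed from any crystal template: each
strand is an exact two-fold screw repeat (flat, untwisted sheet) whose
consecutive C-alpha distance equals the template rise exactly, so the
by-construction metrics (inter-strand spacing, inter-sheet separation,
interface purity) are reproduced to machine precision and make sharp test
oracles.

Coordinate frame convention (right-handed): strand axis = x, in-sheet
stacking of strands = y, sheet normal = z.  Residue numbering is 1-based
within each strand.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from ._geom import dihedral_deg, nerf_place, unit
from .constants import THREE_LETTER

__all__ = [
    "StrandTemplate", "AssemblySpec", "Assembly", "ResidueRef",
    "build_strand", "build_sheet", "build_assembly", "add_disulfides",
    "BuilderError",
]

# Ideal backbone bond lengths (Angstrom) and the N-CA-C angle (deg).
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_TAU = 111.0
_B_C_O = 1.231
_B_CA_CB = 1.53
_ANG_N_CA_CB = 110.5

# Side-chain internal coordinates: (atom, frame atoms, bond, angle, torsion)
# where torsion "chi1" is substituted with the per-strand chi1 assignment.
_SIDECHAINS = {
    "PHE": [
        ("CG",  ("N", "CA", "CB"), 1.51, 113.8, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, "chi2+180"),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ",  ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "TYR": [
        ("CG",  ("N", "CA", "CB"), 1.51, 113.8, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, "chi2+180"),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ",  ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
        ("OH",  ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0),
    ],
    "CYS": [
        ("SG", ("N", "CA", "CB"), 1.81, 114.0, "chi1"),
        ("HG", ("CA", "CB", "SG"), 1.34, 96.0, 180.0),
    ],
}

_CHI1 = {"trans": 180.0, "gauche+": 60.0, "gauche-": -60.0}

# Default ring torsion chi2 for PHE/TYR (near the modal perpendicular rotamer;
# the exact value maximises the steric clearance of the packed rings).
_CHI2_DEFAULT = 95.0

# Sign of the out-of-plane C-beta component giving L-amino-acid chirality
# (improper dihedral N-C-CA-CB around -122 deg, matching the CCD convention).
_CB_SIGN = -1.0


class BuilderError(ValueError):
    """Raised for invalid assembly specifications or geometry requests."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrandTemplate:
    """Idealized antiparallel-beta strand geometry.

    The strand is generated as an exact two-fold screw: residue i+1 is
    residue i rotated 180 degrees about the strand axis and translated along
    it.  That symmetry requires ``psi = -phi`` (with equal backbone angles at
    C and N), which is why the default basin point is (-143, +143) rather
    than the textbook (-139, +135): it is the nearest point of the beta basin
    on the exactly-flat diagonal.  ``rise`` is the consecutive C-alpha
    distance, reproduced exactly by construction.
    """

    phi: float = -143.0
    psi: float = 143.0
    rise: float = 3.45
    chi1_rule: Tuple[str, ...] = ("trans",)

    def validate(self) -> None:
        if not (-180.0 <= self.phi <= -90.0):
            raise BuilderError(f"phi={self.phi} outside the beta basin [-180, -90]")
        if not (90.0 <= self.psi <= 180.0):
            raise BuilderError(f"psi={self.psi} outside the beta basin [90, 180]")
        if not (3.2 <= self.rise <= 3.6):
            raise BuilderError(f"rise={self.rise} outside [3.2, 3.6] Angstrom")
        if abs(self.psi + self.phi) > 1e-9:
            raise BuilderError(
                "flat-strand template requires psi = -phi (exact two-fold screw)")
        for state in self.chi1_rule:
            if state not in _CHI1:
                raise BuilderError(f"unknown chi1 state {state!r}")

    def chi1_for_strand(self, strand_index: int) -> float:
        return _CHI1[self.chi1_rule[strand_index % len(self.chi1_rule)]]


@dataclass(frozen=True)
class AssemblySpec:
    """Declarative description of a steric-zipper system."""

    sequence: str
    n_strands_per_sheet: int
    n_sheets: int
    inter_strand_spacing: float = 4.75
    inter_sheet_spacing: float = 10.8
    interface_layout: Tuple[str, ...] = ()
    disulfide: bool = False
    c_terminal_amide: bool = True
    template: StrandTemplate = field(default_factory=StrandTemplate)

    def validate(self) -> None:
        if not self.sequence:
            raise BuilderError("sequence must be non-empty")
        for code in self.sequence:
            if code not in THREE_LETTER:
                raise BuilderError(f"unsupported residue code {code!r} in sequence")
        if self.n_strands_per_sheet < 1:
            raise BuilderError("n_strands_per_sheet must be >= 1")
        if self.n_sheets < 1:
            raise BuilderError("n_sheets must be >= 1")
        if self.inter_strand_spacing <= 0 or self.inter_sheet_spacing <= 0:
            raise BuilderError("spacings must be positive")
        if len(self.interface_layout) != self.n_sheets - 1:
            raise BuilderError(
                f"interface_layout has {len(self.interface_layout)} entries; "
                f"{self.n_sheets - 1} required (one per adjacent sheet pair)")
        for lab in self.interface_layout:
            if lab not in ("dry", "wet"):
                raise BuilderError(f"interface label {lab!r} not in {{dry, wet}}")
        for a, b in zip(self.interface_layout, self.interface_layout[1:]):
            if a == b:
                raise BuilderError(
                    f"interface layout {self.interface_layout} is incompatible with "
                    "single-sheet face alternation: each sheet has one apolar and one "
                    "polar face, so successive interfaces must alternate dry/wet")
        if self.disulfide:
            if "C" not in self.sequence:
                raise BuilderError("disulfide=True requires at least one Cys in the sequence")
            if "wet" not in self.interface_layout:
                raise BuilderError("disulfide=True requires at least one wet interface")
        self.template.validate()


ResidueRef = Tuple[int, int, int]  # (sheet, strand-within-sheet, resid)


@dataclass
class Assembly:
    """Labeled atomic coordinate set for a (partial) steric-zipper model."""

    names: np.ndarray            # atom names, e.g. "CA"
    elements: np.ndarray         # element symbols
    resids: np.ndarray           # 1-based residue number within the strand
    resnames: np.ndarray         # 3-letter residue names
    strand_index: np.ndarray     # strand within its sheet, 0-based
    sheet_index: np.ndarray      # sheet, 0-based
    xyz: np.ndarray              # (N, 3) Angstrom
    provenance: Optional[AssemblySpec] = None
    disulfide_pairs: List[Tuple[ResidueRef, ResidueRef]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_sheets(self) -> int:
        return int(self.sheet_index.max()) + 1 if self.n_atoms else 0

    def n_strands(self, sheet: int) -> int:
        m = self.sheet_index == sheet
        return int(self.strand_index[m].max()) + 1 if m.any() else 0

    def copy(self) -> "Assembly":
        return Assembly(
            names=self.names.copy(), elements=self.elements.copy(),
            resids=self.resids.copy(), resnames=self.resnames.copy(),
            strand_index=self.strand_index.copy(), sheet_index=self.sheet_index.copy(),
            xyz=self.xyz.copy(), provenance=self.provenance,
            disulfide_pairs=list(self.disulfide_pairs))

    # -- selections ---------------------------------------------------------
    def mask(self, name=None, sheet=None, strand=None, resname=None, resid=None):
        m = np.ones(self.n_atoms, dtype=bool)
        if name is not None:
            m &= self.names == name
        if sheet is not None:
            m &= self.sheet_index == sheet
        if strand is not None:
            m &= self.strand_index == strand
        if resname is not None:
            m &= self.resnames == resname
        if resid is not None:
            m &= self.resids == resid
        return m

    def ca_xyz(self, sheet=None, strand=None) -> np.ndarray:
        return self.xyz[self.mask(name="CA", sheet=sheet, strand=strand)]

    def sidechain_mask(self) -> np.ndarray:
        """Atoms beyond the backbone (and beyond the amide cap)."""
        backbone = np.isin(self.names, ("N", "CA", "C", "O", "NT", "OXT"))
        return ~backbone

    def mean_ca_plane_z(self, sheet: int) -> float:
        return float(self.ca_xyz(sheet=sheet)[:, 2].mean())


# ---------------------------------------------------------------------------
# screw-frame derivation
# ---------------------------------------------------------------------------

def _nerf_chain(phi: float, psi: float, theta_c: float, n_res: int) -> list:
    """Regular poly-backbone with torsions (phi, psi, 180) and peptide-unit
    angles theta_c at both C and N."""
    N = np.zeros(3)
    CA = np.array([_B_N_CA, 0.0, 0.0])
    C = nerf_place(np.array([0.0, 1.0, 0.0]), N, CA, _B_CA_C, _TAU, 0.0)
    res = [(N, CA, C)]
    for _ in range(1, n_res):
        Np = nerf_place(res[-1][0], res[-1][1], res[-1][2], _B_C_N, theta_c, psi)
        CAp = nerf_place(res[-1][1], res[-1][2], Np, _B_N_CA, theta_c, 180.0)
        Cp = nerf_place(res[-1][2], Np, CAp, _B_CA_C, _TAU, phi)
        res.append((Np, CAp, Cp))
    return res


@lru_cache(maxsize=32)
def _screw_frame(phi: float, rise: float):
    """Canonical residue frame of the exact two-fold screw strand.

    Returns (t_axial, N0, CA0, C0): the screw translation along x and the
    residue-0 backbone positions; residue i is obtained by
    (x, y, z) -> (x + i * t, (-1)**i * y, (-1)**i * z).
    """
    psi = -phi

    def ca_ca(theta):
        ch = _nerf_chain(phi, psi, theta, 6)
        return float(np.linalg.norm(ch[3][1] - ch[2][1]))

    lo, hi = 75.0, 135.0
    if (ca_ca(lo) - rise) * (ca_ca(hi) - rise) > 0:
        raise BuilderError(
            f"no peptide-unit angle realises a {rise} A C-alpha repeat at phi={phi}")
    theta_c = brentq(lambda th: ca_ca(th) - rise, lo, hi, xtol=1e-13)

    chain = _nerf_chain(phi, psi, theta_c, 14)
    cas = np.array([r[1] for r in chain])
    mids = 0.5 * (cas[:-1] + cas[1:])
    c0 = mids.mean(axis=0)
    _, svals, vt = np.linalg.svd(mids - c0)
    if svals[1] > 1e-8:
        raise BuilderError("strand repeat is not an exact two-fold screw")
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    t_ax = float(np.dot(cas[1] - cas[0], axis))

    i0 = 6  # interior residue, away from chain ends
    p = cas[i0] - c0
    perp = p - np.dot(p, axis) * axis
    z0 = float(np.linalg.norm(perp))
    ez = perp / z0
    ex = axis
    ey = np.cross(ez, ex)
    R = np.vstack([ex, ey, ez])
    origin = c0 + np.dot(p, axis) * axis

    def canon(q):
        return R @ (q - origin)

    N0, CA0, C0 = (canon(chain[i0][j]) for j in range(3))
    # kill numerical drift: CA exactly on (0, 0, z0) with the exact repeat
    CA0 = np.array([0.0, 0.0, z0])
    t_ax = float(np.sqrt(rise ** 2 - 4.0 * z0 ** 2))
    return t_ax, N0, CA0, C0


def _screw(q: np.ndarray, i: int, t_ax: float) -> np.ndarray:
    s = 1.0 if i % 2 == 0 else -1.0
    out = np.array(q, dtype=float)
    out[0] += i * t_ax
    out[1] *= s
    out[2] *= s
    return out


def _place_cb(N, CA, C, sign: float = _CB_SIGN) -> np.ndarray:
    u1 = unit(N - CA)
    u2 = unit(C - CA)
    bis = -unit(u1 + u2)
    perp = unit(np.cross(u2, u1)) * sign
    cos_xi = np.cos(np.radians(_ANG_N_CA_CB)) / np.dot(u1, bis)
    xi = np.arccos(np.clip(cos_xi, -1.0, 1.0))
    return CA + _B_CA_CB * (np.cos(xi) * bis + np.sin(xi) * perp)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_strand(sequence: str,
                 template: Optional[StrandTemplate] = None,
                 chi1: float = 180.0,
                 c_terminal_amide: bool = True) -> Assembly:
    """Build a single idealized beta-strand along +x.

    Full side chains are constructed for Phe, Tyr and Cys; every other
    residue is reduced to its C-beta (none for Gly).  Consecutive side
    chains point to alternating faces (+z / -z) of the strand plane.
    """
    if template is None:
        template = StrandTemplate()
    template.validate()
    if not sequence:
        raise BuilderError("sequence must be non-empty")
    for code in sequence:
        if code not in THREE_LETTER:
            raise BuilderError(f"unsupported residue code {code!r}")

    t_ax, N0, CA0, C0 = _screw_frame(template.phi, template.rise)
    L = len(sequence)

    names, elements, resids, resnames, xyz = [], [], [], [], []

    def add(name, pos, resid, resname):
        names.append(name)
        resids.append(resid)
        resnames.append(resname)
        xyz.append(np.asarray(pos, float))

    for i, code in enumerate(sequence):
        res3 = THREE_LETTER[code]
        N = _screw(N0, i, t_ax)
        CA = _screw(CA0, i, t_ax)
        C = _screw(C0, i, t_ax)
        N_next = _screw(N0, i + 1, t_ax)  # real or virtual next amide N
        O = C + _B_C_O * (-unit(unit(CA - C) + unit(N_next - C)))
        add("N", N, i + 1, res3)
        add("CA", CA, i + 1, res3)
        add("C", C, i + 1, res3)
        add("O", O, i + 1, res3)
        if code != "G":
            CB = _place_cb(N, CA, C)
            add("CB", CB, i + 1, res3)
            if res3 in _SIDECHAINS:
                pos = {"N": N, "CA": CA, "CB": CB}
                for name, frame, bond, ang, tors in _SIDECHAINS[res3]:
                    if tors == "chi1":
                        tval = chi1
                    elif tors == "chi2":
                        tval = _CHI2_DEFAULT
                    elif tors == "chi2+180":
                        tval = _CHI2_DEFAULT + 180.0
                    else:
                        tval = float(tors)
                    a, b, c = (pos[f] for f in frame)
                    pos[name] = nerf_place(a, b, c, bond, ang, tval)
                    add(name, pos[name], i + 1, res3)
    if c_terminal_amide:
        add("NT", _screw(N0, L, t_ax), L, THREE_LETTER[sequence[-1]])

    elements = [("S" if n.startswith("S") else "H" if n.startswith("H") else
                 "O" if n.startswith("O") else "N" if n.startswith("N") else "C")
                for n in names]
    n = len(names)
    return Assembly(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        strand_index=np.zeros(n, dtype=int),
        sheet_index=np.zeros(n, dtype=int),
        xyz=np.vstack(xyz),
    )


def build_sheet(strand: Assembly, n_strands: int, spacing: float = 4.75,
                antiparallel: bool = True) -> Assembly:
    """Stack copies of a strand along y into a flat beta-sheet.

    Odd strands are flipped head-to-tail (180-degree rotation about the
    sheet normal through the strand midpoint) when ``antiparallel`` is set,
    which keeps the in-register column structure and the face identity of
    the side chains.
    """
    if n_strands < 1:
        raise BuilderError("n_strands must be >= 1")
    if spacing <= 0:
        raise BuilderError("spacing must be positive")
    if n_strands == 1:
        return strand.copy()

    ca = strand.ca_xyz()
    x_mid = float(ca[:, 0].mean())

    parts = []
    for j in range(n_strands):
        s = strand.copy()
        if antiparallel and j % 2 == 1:
            s.xyz[:, 0] = 2.0 * x_mid - s.xyz[:, 0]
            s.xyz[:, 1] = -s.xyz[:, 1]
        s.xyz[:, 1] += j * spacing
        s.strand_index[:] = j
        parts.append(s)
    return _concat(parts, provenance=None)


def build_assembly(spec: AssemblySpec) -> Assembly:
    """Build the full multi-sheet steric-zipper assembly described by spec.

    Sheets are stacked along z with the requested separation between mean
    C-alpha planes; each sheet is flipped about the strand axis as needed so
    that the face demanded by each interface label (apolar/Phe for dry,
    polar for wet) points into that interface.
    """
    spec.validate()
    strand = build_strand(spec.sequence, spec.template,
                          chi1=spec.template.chi1_for_strand(0),
                          c_terminal_amide=spec.c_terminal_amide)
    sheet0 = build_sheet(strand, spec.n_strands_per_sheet, spec.inter_strand_spacing)
    if len(spec.template.chi1_rule) > 1:
        # rebuild strands whose chi1 assignment differs
        sheet0 = _apply_chi1_rule(spec, sheet0)

    # which face (z sign) of the base sheet carries the apolar (Phe) surface?
    apolar_up = _apolar_face_sign(sheet0) > 0

    y_c = (spec.n_strands_per_sheet - 1) * spec.inter_strand_spacing / 2.0

    sheets = []
    for k in range(spec.n_sheets):
        sh = sheet0.copy()
        sh.sheet_index[:] = k
        want_up = _wanted_face_up(k, spec.interface_layout)
        if want_up is not None:
            flip = (want_up == "dry") != apolar_up
        else:
            flip = False
        if flip:
            sh.xyz[:, 1] = 2.0 * y_c - sh.xyz[:, 1]
            sh.xyz[:, 2] = -sh.xyz[:, 2]
            # strand j maps onto the y column of strand n-1-j
            sh.strand_index = (spec.n_strands_per_sheet - 1) - sh.strand_index
        z_now = float(sh.xyz[sh.mask(name="CA"), 2].mean())
        sh.xyz[:, 2] += k * spec.inter_sheet_spacing - z_now
        sheets.append(sh)

    asm = _concat(sheets, provenance=spec)
    if spec.disulfide:
        for k, lab in enumerate(spec.interface_layout):
            if lab == "wet":
                asm = add_disulfides(asm, interface=k)
    return asm


def _wanted_face_up(k: int, layout: Sequence[str]):
    """Face type that sheet k must present upward (toward sheet k+1)."""
    if k < len(layout):
        return layout[k]            # upper interface dictates the top face
    if layout:
        # topmost sheet: bottom face fixed by the last interface
        return "wet" if layout[-1] == "dry" else "dry"
    return None


def _apolar_face_sign(sheet: Assembly) -> float:
    """+1 if Phe side chains sit above the mean C-alpha plane, else -1."""
    z0 = float(sheet.ca_xyz()[:, 2].mean())
    m = (sheet.resnames == "PHE") & sheet.sidechain_mask()
    if not m.any():
        # no Phe: fall back to apolar = non-(Tyr/Cys/Ser/Thr/...) -- undefined
        raise BuilderError("cannot locate an apolar face: no Phe side chains")
    return 1.0 if float(sheet.xyz[m, 2].mean()) > z0 else -1.0


def _apply_chi1_rule(spec: AssemblySpec, sheet: Assembly) -> Assembly:
    """Rebuild the sheet with the per-strand chi1 assignment of the template."""
    base = {}
    parts = []
    for j in range(spec.n_strands_per_sheet):
        chi1 = spec.template.chi1_for_strand(j)
        if chi1 not in base:
            base[chi1] = build_strand(spec.sequence, spec.template, chi1=chi1,
                                      c_terminal_amide=spec.c_terminal_amide)
        s = base[chi1].copy()
        ca = s.ca_xyz()
        x_mid = float(ca[:, 0].mean())
        if j % 2 == 1:
            s.xyz[:, 0] = 2.0 * x_mid - s.xyz[:, 0]
            s.xyz[:, 1] = -s.xyz[:, 1]
        s.xyz[:, 1] += j * spec.inter_strand_spacing
        s.strand_index[:] = j
        parts.append(s)
    return _concat(parts, provenance=None)


def add_disulfides(assembly: Assembly, interface: Optional[int] = None) -> Assembly:
    """Cross-link facing Cys pairs across a wet interface.

    Each Cys thiol S-gamma is paired greedily with its nearest unpaired
    partner on the facing sheet (ties broken by sheet then strand index);
    both sulfurs are moved symmetrically along the S-S axis to a 2.05 A
    bond, and the thiol hydrogens are removed.  Applying the operation twice
    is a no-op for already-paired residues.
    """
    if interface is None:
        if assembly.provenance is None:
            raise BuilderError(
                "interface index required for assemblies without a build spec")
        wet = [k for k, lab in enumerate(assembly.provenance.interface_layout)
               if lab == "wet"]
        out = assembly
        for k in wet:
            out = add_disulfides(out, interface=k)
        return out

    k = int(interface)
    if k < 0 or k >= assembly.n_sheets - 1:
        raise BuilderError(f"interface {k} does not exist")

    asm = assembly.copy()
    paired = {ref for pair in asm.disulfide_pairs for ref in pair}

    def sg_atoms(sheet: int):
        m = asm.mask(name="SG", sheet=sheet, resname="CYS")
        idx = np.nonzero(m)[0]
        out = []
        for i in idx:
            ref = (int(asm.sheet_index[i]), int(asm.strand_index[i]), int(asm.resids[i]))
            if ref not in paired:
                out.append((ref, i))
        return out

    lower = sg_atoms(k)
    upper = sg_atoms(k + 1)
    # keep only thiols whose S points into this interface
    z_lo = asm.mean_ca_plane_z(k)
    z_hi = asm.mean_ca_plane_z(k + 1)
    lower = [(r, i) for r, i in lower if asm.xyz[i, 2] > z_lo]
    upper = [(r, i) for r, i in upper if asm.xyz[i, 2] < z_hi]

    if not lower or not upper:
        already = any({r1[0], r2[0]} == {k, k + 1}
                      for r1, r2 in asm.disulfide_pairs)
        if not already:   # silent no-op when the interface is already paired
            warnings.warn(
                f"no unpaired facing Cys at interface {k}; assembly unchanged")
        return asm

    cand = []
    for r1, i1 in lower:
        for r2, i2 in upper:
            d = float(np.linalg.norm(asm.xyz[i1] - asm.xyz[i2]))
            cand.append((d, r1, r2, i1, i2))
    cand.sort(key=lambda c: (c[0], c[1], c[2]))

    used = set()
    new_pairs = []
    for d, r1, r2, i1, i2 in cand:
        if r1 in used or r2 in used:
            continue
        used.add(r1)
        used.add(r2)
        mid = 0.5 * (asm.xyz[i1] + asm.xyz[i2])
        axis = unit(asm.xyz[i2] - asm.xyz[i1])
        asm.xyz[i1] = mid - 1.025 * axis
        asm.xyz[i2] = mid + 1.025 * axis
        new_pairs.append((r1, r2))

    if not new_pairs:
        warnings.warn(f"no unpaired facing Cys at interface {k}; assembly unchanged")
        return asm

    # drop thiol hydrogens of the residues just paired
    drop = np.zeros(asm.n_atoms, dtype=bool)
    for r1, r2 in new_pairs:
        for sheet, strand, resid in (r1, r2):
            drop |= (asm.names == "HG") & asm.mask(sheet=sheet, strand=strand,
                                                   resid=resid, resname="CYS")
    if drop.any():
        keep = ~drop
        asm = Assembly(
            names=asm.names[keep], elements=asm.elements[keep],
            resids=asm.resids[keep], resnames=asm.resnames[keep],
            strand_index=asm.strand_index[keep], sheet_index=asm.sheet_index[keep],
            xyz=asm.xyz[keep], provenance=asm.provenance,
            disulfide_pairs=list(asm.disulfide_pairs))
    asm.disulfide_pairs.extend(new_pairs)
    return asm


def _concat(parts: List[Assembly], provenance=None) -> Assembly:
    return Assembly(
        names=np.concatenate([p.names for p in parts]),
        elements=np.concatenate([p.elements for p in parts]),
        resids=np.concatenate([p.resids for p in parts]),
        resnames=np.concatenate([p.resnames for p in parts]),
        strand_index=np.concatenate([p.strand_index for p in parts]),
        sheet_index=np.concatenate([p.sheet_index for p in parts]),
        xyz=np.vstack([p.xyz for p in parts]),
        provenance=provenance,
        disulfide_pairs=[pr for p in parts for pr in p.disulfide_pairs],
    )


# convenience constructors for the three model systems -----------------------

def spec_st50_sh2(**kw) -> AssemblySpec:
    """Two fifty-stranded sheets joined by a dry (Phe) steric zipper."""
    return AssemblySpec("FYFCFYF", 50, 2, interface_layout=("dry",), **kw)


def spec_st10_sh4(disulfide: bool = False, **kw) -> AssemblySpec:
    """Four ten-stranded sheets: dry, wet, dry interfaces; optionally with
    the wet-interface Cys pairs oxidised to disulfides."""
    return AssemblySpec("FYFCFYF", 10, 4, interface_layout=("dry", "wet", "dry"),
                        disulfide=disulfide, **kw)
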