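"""PDB input/output for assemblies and multi-frame coordinate sets.

Atom records are written and parsed through MDAnalysis.  Strand and sheet
identity are encoded twice: the single-character chain ID recycles
A-Z, a-z, 0-9 (so assemblies above 62 strands reuse letters), and the PDB
segment-identifier columns carry a lossless 4-character code
``<sheet hex><strand %03d>`` which the reader prefers.  Disulfide pairs are
emitted as standard SSBOND records plus ``REMARK  99 SSPAIR`` lines keyed by
segment ID, which survive chain-ID recycling.
"""
from __future__ import annotations

import warnings
from typing import List, Optional, Tuple

import numpy as np

from .builder import Assembly, ResidueRef

__all__ = ["write_coordinates", "read_coordinates", "write_trajectory",
           "read_trajectory", "ParseError"]

_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


def _segid(sheet: int, strand: int) -> str:
    if sheet > 15 or strand > 999:
        raise ValueError("segment-ID scheme supports at most 16 sheets and 1000 strands")
    return f"{sheet:X}{strand:03d}"


def _strand_order(assembly: Assembly) -> List[Tuple[int, int]]:
    pairs = sorted({(int(s), int(t))
                    for s, t in zip(assembly.sheet_index, assembly.strand_index)})
    return pairs


def _universe(assembly: Assembly):
    import MDAnalysis as mda

    strands = _strand_order(assembly)
    strand_of = {p: i for i, p in enumerate(strands)}

    atom_strand = np.array([strand_of[(int(s), int(t))]
                            for s, t in zip(assembly.sheet_index, assembly.strand_index)])
    # residues: unique (strand, resid) in atom order
    res_key = atom_strand.astype(np.int64) * 100000 + assembly.resids
    uniq, atom_residx = np.unique(res_key, return_inverse=True)
    res_strand = (uniq // 100000).astype(int)
    res_resid = (uniq % 100000).astype(int)

    n_res = len(uniq)
    n_seg = len(strands)
    u = mda.Universe.empty(assembly.n_atoms, n_residues=n_res, n_segments=n_seg,
                           atom_resindex=atom_residx, residue_segindex=res_strand,
                           trajectory=True)
    u.add_TopologyAttr("names", list(assembly.names))
    u.add_TopologyAttr("elements", list(assembly.elements))
    resname_of = {}
    for k, (rn, rid) in enumerate(zip(assembly.resnames, res_key)):
        resname_of.setdefault(rid, rn)
    u.add_TopologyAttr("resnames", [resname_of[k] for k in uniq])
    u.add_TopologyAttr("resids", list(res_resid))
    u.add_TopologyAttr("segids", [_segid(sh, st) for sh, st in strands])
    u.add_TopologyAttr("chainIDs",
                       [_CHAIN_ALPHABET[atom_strand[i] % 62]
                        for i in range(assembly.n_atoms)])
    u.add_TopologyAttr("occupancies", np.ones(assembly.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(assembly.n_atoms))
    u.atoms.positions = assembly.xyz
    return u, strands


def _ss_lines(assembly: Assembly, strands) -> List[str]:
    lines = []
    strand_of = {p: i for i, p in enumerate(strands)}
    for n, (r1, r2) in enumerate(assembly.disulfide_pairs, start=1):
        ch1 = _CHAIN_ALPHABET[strand_of[(r1[0], r1[1])] % 62]
        ch2 = _CHAIN_ALPHABET[strand_of[(r2[0], r2[1])] % 62]
        lines.append(
            f"SSBOND{n:4d} CYS {ch1} {r1[2]:4d}    CYS {ch2} {r2[2]:4d}"
            f"{'':23s}1555   1555  2.05")
        lines.append(
            f"REMARK  99 SSPAIR {_segid(r1[0], r1[1])} {r1[2]:d} "
            f"{_segid(r2[0], r2[1])} {r2[2]:d}")
    return lines


def write_coordinates(assembly: Assembly, path: str) -> None:
    """Write an assembly as a single-model PDB file."""
    if assembly.n_atoms == 0:
        raise ValueError("refusing to write an empty assembly")
    u, strands = _universe(assembly)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)
    _insert_header_lines(path, _ss_lines(assembly, strands))


def write_trajectory(frames: np.ndarray, topology: Assembly, path: str) -> None:
    """Write a stack of frames congruent with ``topology`` as multi-MODEL PDB."""
    import MDAnalysis as mda
    if len(frames) == 0:
        raise ValueError("no frames to write")
    u, strands = _universe(topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, multiframe=True, n_atoms=topology.n_atoms) as w:
            for f in frames:
                u.atoms.positions = f
                w.write(u.atoms)
    _insert_header_lines(path, _ss_lines(topology, strands))


def _insert_header_lines(path: str, lines: List[str]) -> None:
    if not lines:
        return
    with open(path) as fh:
        content = fh.readlines()
    insert_at = 0
    for i, line in enumerate(content):
        if line.startswith(("ATOM", "HETATM", "MODEL")):
            insert_at = i
            break
    content[insert_at:insert_at] = [l + "\n" for l in lines]
    with open(path, "w") as fh:
        fh.writelines(content)


def _parse_segid(segid: str) -> Optional[Tuple[int, int]]:
    segid = segid.strip()
    if len(segid) == 4 and segid[1:].isdigit():
        try:
            return int(segid[0], 16), int(segid[1:])
        except ValueError:
            return None
    return None


def read_coordinates(path: str) -> Assembly:
    """Read a PDB file back into an :class:`~crossbeta.builder.Assembly`.

    Strand/sheet identity is recovered from segment IDs when present (the
    writer's scheme), falling back to chain IDs in file order.
    """
    import MDAnalysis as mda
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
        positions = u.atoms.positions.copy()
    except Exception as exc:  # annotate with the offending file
        raise ParseError(f"{path}: cannot parse coordinate file ({exc})") from exc

    n = len(u.atoms)
    if n == 0:
        raise ParseError(f"{path}: file contains no atoms")
    names = np.array([a.name for a in u.atoms], dtype=object)
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    resids = np.array([a.resid for a in u.atoms], dtype=int)

    segids = [getattr(a, "segid", "") for a in u.atoms]
    parsed = [_parse_segid(s) for s in segids]
    if all(p is not None for p in parsed):
        sheet = np.array([p[0] for p in parsed], dtype=int)
        strand = np.array([p[1] for p in parsed], dtype=int)
    else:
        # fall back: consecutive chain-ID runs are strands of a single sheet
        try:
            chains = [a.chainID for a in u.atoms]
        except Exception:
            chains = ["A"] * n
        strand = np.zeros(n, dtype=int)
        cur = 0
        for i in range(1, n):
            if chains[i] != chains[i - 1]:
                cur += 1
            strand[i] = cur
        sheet = np.zeros(n, dtype=int)

    elements = np.array(
        [("S" if nm.startswith("S") else "H" if nm.startswith("H") else
          "O" if nm.startswith("O") else "N" if nm.startswith("N") else "C")
         for nm in names], dtype=object)

    pairs = _read_ss_pairs(path, sheet, strand, resids, names)
    return Assembly(names=names, elements=elements, resids=resids,
                    resnames=resnames, strand_index=strand, sheet_index=sheet,
                    xyz=positions.astype(float), provenance=None,
                    disulfide_pairs=pairs)


def _read_ss_pairs(path, sheet, strand, resids, names) -> List[Tuple[ResidueRef, ResidueRef]]:
    pairs: List[Tuple[ResidueRef, ResidueRef]] = []
    sspair_lines = []
    ssbond_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK  99 SSPAIR"):
                sspair_lines.append(line.split()[3:])
            elif line.startswith("SSBOND"):
                ssbond_lines.append(line)
            elif line.startswith(("ATOM", "MODEL")):
                break
    if sspair_lines:
        for seg1, rid1, seg2, rid2 in sspair_lines:
            p1 = _parse_segid(seg1)
            p2 = _parse_segid(seg2)
            if p1 is None or p2 is None:
                raise ParseError(f"{path}: malformed SSPAIR remark")
            pairs.append(((p1[0], p1[1], int(rid1)), (p2[0], p2[1], int(rid2))))
        return pairs
    for line in ssbond_lines:
        try:
            ch1, rid1 = line[15], int(line[17:21])
            ch2, rid2 = line[29], int(line[31:35])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: malformed SSBOND record: {line.rstrip()}") from exc
        idx1 = _CHAIN_ALPHABET.index(ch1)
        idx2 = _CHAIN_ALPHABET.index(ch2)
        order = sorted({(int(s), int(t)) for s, t in zip(sheet, strand)})
        if idx1 < len(order) and idx2 < len(order):
            s1, t1 = order[idx1]
            s2, t2 = order[idx2]
            pairs.append(((s1, t1, rid1), (s2, t2, rid2)))
    return pairs


def read_trajectory(path: str, dt_ns: float = 1.0):
    """Read a multi-MODEL PDB; returns (frames (F,N,3), times (F,), topology)."""
    import MDAnalysis as mda
    topology = read_coordinates(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse trajectory ({exc})") from exc
    times = np.arange(len(frames), dtype=float) * dt_ns
    return frames, times, topology
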