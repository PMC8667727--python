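"""Reading and writing Cα traces and assignment tables.

Structure files are read through gemmi (PDB and mmCIF, altLoc and
insertion-code aware); Cα-only PDB output is written directly with
fixed-width records so that identical input always yields identical
bytes.  A parser for classic fixed-column DSSP output (also produced by
``mkdssp --output-format dssp``) supports validation against the
hydrogen-bond-based reference assignment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .core import SSEAssignment
from .trace import CaTrace, detect_breaks

__all__ = [
    "DsspRecord",
    "read_ca_trace",
    "read_multimodel",
    "read_xyz_trajectory",
    "write_pdb",
    "parse_dssp",
    "write_assignment",
    "read_assignment",
]

_DSSP_ALPHABET = set("HGIEBTS-")

#: three-letter → one-letter residue codes (nonstandard → X)
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class DsspRecord:
    """One residue line of a DSSP file; blank structure column maps to '-'."""

    residue_id: int
    chain_id: str
    code: str
    icode: str = ""

    def __post_init__(self) -> None:
        if self.code not in _DSSP_ALPHABET:
            raise ValueError(f"invalid DSSP code {self.code!r}")


def _structure(path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    return st


def _trace_from_chain(chain: gemmi.Chain, chain_id: str, model_index: int) -> CaTrace:
    coords, resids, names, icodes = [], [], [], []
    for residue in chain:
        best = None
        for atom in residue:
            if atom.name != "CA":
                continue
            # altLoc: keep highest occupancy, ties broken by file order
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            continue
        coords.append([best.pos.x, best.pos.y, best.pos.z])
        resids.append(residue.seqid.num)
        icodes.append(residue.seqid.icode.strip())
        names.append(_THREE_TO_ONE.get(residue.name.upper(), "X"))
    if not coords:
        raise ValueError(f"no CA atoms found in chain {chain_id!r}")
    coords = np.asarray(coords, dtype=float)
    return CaTrace(
        coords, chain_id=chain_id, model_index=model_index,
        residue_ids=tuple(resids), residue_names=tuple(names),
        icodes=tuple(icodes),
        breaks=frozenset(detect_breaks(coords, resids)),
    )


def read_ca_trace(path, chain: str | None = None, model: int = 1) -> CaTrace:
    """Read the Cα trace of one chain of one model from a structure file.

    altLoc conformers are resolved to the highest occupancy (ties → first
    in file); chain breaks (numbering gaps or unphysical Cα–Cα distances)
    are flagged on the returned trace.
    """
    st = _structure(path)
    if not 1 <= model <= len(st):
        raise ValueError(f"model {model} not in file (has {len(st)} models)")
    gmodel = st[model - 1]
    if chain is None:
        if len(gmodel) == 0:
            raise ValueError(f"model {model} has no chains")
        gchain = gmodel[0]
        chain = gchain.name
    else:
        gchain = gmodel.find_chain(chain)
        if gchain is None:
            available = [c.name for c in gmodel]
            raise ValueError(f"chain {chain!r} not found; available: {available}")
    return _trace_from_chain(gchain, chain, model)


def read_multimodel(path, chain: str | None = None) -> list[CaTrace]:
    """One CaTrace per model, same chain, model_index increasing.

    All models must carry an identical residue set; the first model that
    differs is named in the error.
    """
    st = _structure(path)
    traces = [read_ca_trace(path, chain=chain, model=m) for m in range(1, len(st) + 1)]
    ref = traces[0].residue_ids
    for t in traces[1:]:
        if t.residue_ids != ref:
            raise ValueError(
                f"model {t.model_index} has a different residue set than model 1")
    return traces


def read_xyz_trajectory(path, chain_id: str = "A") -> list[CaTrace]:
    """Plain xyz-style Cα trajectory: per frame a count line, a comment,
    then ``count`` lines of ``x y z`` (an element label, if present, is
    ignored)."""
    traces: list[CaTrace] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"expected atom count at line {pos + 1}") from exc
        block = lines[pos + 2:pos + 2 + count]
        if len(block) < count:
            raise ValueError(f"truncated frame starting at line {pos + 1}")
        coords = []
        for ln in block:
            parts = ln.split()
            coords.append([float(v) for v in parts[-3:]])
        coords = np.asarray(coords)
        traces.append(CaTrace(coords, chain_id=chain_id, model_index=len(traces) + 1,
                              breaks=frozenset(detect_breaks(coords))))
        pos += 2 + count
    if not traces:
        raise ValueError(f"no frames found in {path}")
    return traces


def write_pdb(traces: CaTrace | list[CaTrace], path) -> None:
    """Write Cα-only PDB, one MODEL per trace; byte-deterministic."""
    if isinstance(traces, CaTrace):
        traces = [traces]
    multi = len(traces) > 1
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    with open(path, "w") as fh:
        for m, trace in enumerate(traces, start=1):
            if multi:
                fh.write(f"MODEL {m:>8d}\n")
            serial = 1
            for j in range(len(trace)):
                name = "GLY"
                if trace.residue_names is not None:
                    name = one_to_three.get(trace.residue_names[j], "UNK")
                icode = trace.icodes[j] if trace.icodes else ""
                x, y, z = trace.coords[j]
                fh.write(
                    f"ATOM  {serial:>5d}  CA  {name:<3s} {trace.chain_id[:1]}"
                    f"{trace.residue_ids[j]:>4d}{icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {'C':>2s}\n")
                serial += 1
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def parse_dssp(path) -> list[DsspRecord]:
    """Parse classic fixed-column DSSP output into per-residue records.

    Chain-break lines ('!' in the amino-acid column) are skipped; a blank
    structure column becomes '-'.  Raises on a missing residue-table header
    or on truncated residue lines (reported with their line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DSSP file not found: {path}")
    records: list[DsspRecord] = []
    in_table = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not in_table:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_table = True
                continue
            if not line.strip():
                continue
            if len(line.rstrip("\n")) < 17:
                raise ValueError(f"truncated DSSP residue line at line {lineno}")
            aa = line[13]
            if aa == "!":  # chain break marker
                continue
            resnum = line[5:10].strip()
            if not resnum:
                raise ValueError(f"missing residue number at line {lineno}")
            icode = line[10].strip()
            chain = line[11].strip()
            code = line[16]
            records.append(DsspRecord(residue_id=int(resnum), chain_id=chain,
                                      code="-" if code == " " else code,
                                      icode=icode))
    if not in_table:
        raise ValueError(f"{path} has no DSSP residue table header")
    return records


def write_assignment(assignment: SSEAssignment, trace: CaTrace, path) -> None:
    """Tab-separated assignment table: residue_id, code, segment_id, pairing.

    ``segment_id`` numbers helix and strand segments in order of their
    start position; E rows carry the partner residue range and orientation.
    """
    if len(assignment) != len(trace):
        raise ValueError(
            f"assignment length {len(assignment)} != trace length {len(trace)}")
    segments: list[tuple[int, int, str, str]] = []
    for (s, e) in assignment.helix_segments:
        segments.append((s, e, "", ""))
    for seg in assignment.strand_segments:
        segments.append((seg.start, seg.end,
                         f"{seg.partner[0]}-{seg.partner[1]}", seg.orientation))
    segments.sort()
    seg_of = {}
    for sid, (s, e, partner, orient) in enumerate(segments, start=1):
        for p in range(s, e + 1):
            seg_of[p] = (sid, partner, orient)
    with open(path, "w") as fh:
        fh.write("residue_id\tcode\tsegment_id\tpairing\n")
        for pos in range(1, len(trace) + 1):
            code = assignment.code(pos)
            sid, partner, orient = seg_of.get(pos, ("", "", ""))
            pairing = f"{partner} {orient}".strip() if code == "E" else ""
            fh.write(f"{trace.residue_ids[pos - 1]}\t{code}\t{sid}\t{pairing}\n")


def read_assignment(path) -> list[tuple[int, str]]:
    """Read back a written assignment table as (residue_id, code) rows."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("residue_id"):
            raise ValueError(f"not an assignment table: {path}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append((int(parts[0]), parts[1]))
    return rows
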