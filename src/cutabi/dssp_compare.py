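"""Benchmarking Cα-only assignments against DSSP reference labels.

DSSP's eight-letter alphabet is collapsed to three classes: helix
(H + G + I), sheet (E), other (everything else, including the isolated
β-bridge B, which the Cα-only algorithm deliberately does not emit).

The per-structure discrepancy metric is the fraction of residues whose
membership in one class differs between the two assignments, normalised
by the full sequence length — so "35% helix difference" means 35% of all
residues, not of helix residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CutabiParams, assign
from .geometry import AngleProfile
from .trace import CaTrace
from .trace_io import DsspRecord, parse_dssp, read_ca_trace

__all__ = [
    "ClassMap",
    "map_dssp_codes",
    "percent_difference",
    "overall_agreement",
    "difference_histogram",
    "gamma_theta_histogram",
    "compare_structure",
    "ComparisonReport",
]

#: default discrepancy histogram edges; 5% and 15% are the anchored
#: reporting thresholds, finer divisions are configurable
DEFAULT_EDGES = (0.0, 5.0, 15.0, 35.0, 100.0)


@dataclass(frozen=True)
class ClassMap:
    """Partition of the DSSP alphabet into helix / sheet / other."""

    helix_codes: frozenset[str] = frozenset({"H", "G", "I"})
    sheet_codes: frozenset[str] = frozenset({"E"})

    def __post_init__(self) -> None:
        if self.helix_codes & self.sheet_codes:
            raise ValueError("helix and sheet code sets overlap")

    def collapse(self, code: str) -> str:
        """Map one DSSP code to the three-class alphabet H/E/C."""
        if code in self.helix_codes:
            return "H"
        if code in self.sheet_codes:
            return "E"
        return "C"


def map_dssp_codes(records: list[DsspRecord] | str,
                   class_map: ClassMap | None = None) -> str:
    """Collapse DSSP records (or a raw code string) to three-class codes."""
    cm = class_map or ClassMap()
    codes = [r.code for r in records] if not isinstance(records, str) else records
    return "".join(cm.collapse(c) for c in codes)


_CLS_LETTER = {"helix": "H", "sheet": "E", "H": "H", "E": "E"}


def percent_difference(a: str, b: str, cls: str) -> float:
    """Percent of residues whose membership in class ``cls`` differs.

    ``a`` and ``b`` are equal-length three-class code strings;
    100 × |{n : [a_n = cls] ≠ [b_n = cls]}| / N.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    letter = _CLS_LETTER[cls]
    diff = sum((ca == letter) != (cb == letter) for ca, cb in zip(a, b))
    return 100.0 * diff / len(a)


def overall_agreement(a: str, b: str) -> float:
    """Three-class per-residue agreement, percent."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    same = sum(ca == cb for ca, cb in zip(a, b))
    return 100.0 * same / len(a)


def difference_histogram(values, edges=DEFAULT_EDGES) -> np.ndarray:
    """Counts of per-structure percentages in half-open bins [lo, hi),
    last bin closed; total equals the number of structures."""
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    values = np.asarray(list(values), dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    return counts


def gamma_theta_histogram(profiles: list[AngleProfile], labels: list[str],
                          cls: str, bin_width: float = 10.0):
    """2-D occupancy of (γ, θ) for residues of one class.

    ``labels`` are three-class code strings aligned to each profile's
    positions; only residues with both angles defined contribute.  Returns
    ``(counts, gamma_edges, theta_edges)`` with γ covering (−180, 180] and
    θ covering (0, 180].
    """
    letter = _CLS_LETTER[cls]
    gammas, thetas = [], []
    for profile, lab in zip(profiles, labels):
        for n in range(1, profile.n_residues + 1):
            if lab[n - 1] != letter:
                continue
            g, t = profile.gamma[n], profile.theta[n]
            if np.isnan(g) or np.isnan(t):
                continue
            gammas.append(g)
            thetas.append(t)
    g_edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    t_edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _, _ = np.histogram2d(gammas, thetas, bins=[g_edges, t_edges])
    return counts, g_edges, t_edges


@dataclass(frozen=True)
class ComparisonReport:
    helix_percent_difference: float
    sheet_percent_difference: float
    overall_agreement: float
    n_residues: int
    cutabi_codes: str
    reference_codes: str


def align_reference(trace: CaTrace, records: list[DsspRecord],
                    class_map: ClassMap | None = None) -> str:
    """Three-class reference string aligned to trace positions.

    Alignment is by (chain, author residue number, insertion code); the
    first trace residue without a matching DSSP record is reported.
    """
    cm = class_map or ClassMap()
    table = {(r.chain_id, r.residue_id, r.icode): r.code for r in records}
    codes = []
    for pos in range(len(trace)):
        icode = trace.icodes[pos] if trace.icodes else ""
        key = (trace.chain_id, trace.residue_ids[pos], icode)
        if key not in table:
            raise ValueError(
                f"no DSSP record for chain {trace.chain_id!r} residue "
                f"{trace.residue_ids[pos]}{icode} (position {pos + 1})")
        codes.append(cm.collapse(table[key]))
    return "".join(codes)


def compare_structure(pdb_path, dssp_path, chain: str | None = None, model: int = 1,
                      params: CutabiParams | None = None,
                      class_map: ClassMap | None = None) -> ComparisonReport:
    """Assign a structure from its Cα trace and benchmark against its DSSP file."""
    trace = read_ca_trace(pdb_path, chain=chain, model=model)
    reference = align_reference(trace, parse_dssp(dssp_path), class_map)
    ours = assign(trace, params).codes
    return ComparisonReport(
        helix_percent_difference=percent_difference(ours, reference, "helix"),
        sheet_percent_difference=percent_difference(ours, reference, "sheet"),
        overall_agreement=overall_agreement(ours, reference),
        n_residues=len(trace),
        cutabi_codes=ours,
        reference_codes=reference,
    )
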