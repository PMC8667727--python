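"""CUTABI: CUrvature and Torsion based Alpha-helix and Beta-sheet Identification.

Assigns per-residue secondary structure (H = helix, E = sheet, C = coil)
from Cα coordinates alone, using windows on the pseudo-bond curvature θ
and torsion γ plus inter-strand distance tests.

Helix rule: residues k..k+3 are helical if θ_k..θ_{k+3} all fall in
[80°, 105°] and γ_{k+1}, γ_{k+2} fall in [30°, 80°]; the 4-residue window
is slid along the sequence with stride 1 and hits are unioned, so every
helix is at least 4 residues long.

Sheet rule: duplets (k, k+1) and (i, i+1), at least ``min_seq_separation``
apart in sequence, form a sheet pair if θ at all four residues lies in
[100°, 155°], |γ_k| > 80° and |γ_i| > 80°, and the inter-strand distances
satisfy (parallel) d(k,i) < 5.5 Å, d(k+1,i+1) < 5.5 Å, d(k+1,i+2) < 6.8 Å
or (antiparallel, mirrored register) d(k,i+1) < 5.5 Å, d(k+1,i) < 5.5 Å,
d(k,i+2) < 6.8 Å.  A sheet therefore always comprises ≥ 4 residues;
single-residue β-bridges (DSSP code B) are never emitted.

All interval bounds are inclusive except the γ magnitude test (strict) and
the distance tests (strict), matching the stated "between" / "smaller than"
wording.  Helix takes precedence: sheet detection runs with helix residues
excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AngleProfile, compute_angles
from .trace import CaTrace

__all__ = [
    "CutabiParams",
    "SheetPair",
    "StrandSegment",
    "SSEAssignment",
    "detect_helices",
    "detect_sheet_pairs",
    "assemble",
    "assign",
    "count_sse",
]


@dataclass(frozen=True)
class CutabiParams:
    """Thresholds of the assignment rules (degrees, Å, residues)."""

    helix_theta: tuple[float, float] = (80.0, 105.0)
    helix_gamma: tuple[float, float] = (30.0, 80.0)
    sheet_theta: tuple[float, float] = (100.0, 155.0)
    sheet_gamma_abs_min: float = 80.0
    d_pair_max: float = 5.5
    d_diag_max: float = 6.8
    min_helix_len: int = 4
    min_strand_len: int = 2
    min_seq_separation: int = 4

    def __post_init__(self) -> None:
        for name in ("helix_theta", "helix_gamma", "sheet_theta"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval is empty: ({lo}, {hi})")
        if self.d_pair_max <= 0 or self.d_diag_max <= 0:
            raise ValueError("distance thresholds must be positive")
        if self.min_helix_len < 1 or self.min_strand_len < 1:
            raise ValueError("minimal segment sizes must be >= 1")

    def replace(self, **kwargs) -> "CutabiParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SheetPair:
    """Accepted duplet pair: duplets start at positions ``k`` and ``i`` (k < i)."""

    k: int
    i: int
    orientation: str  # "parallel" | "antiparallel"

    @property
    def residues(self) -> tuple[int, int, int, int]:
        return (self.k, self.k + 1, self.i, self.i + 1)


@dataclass(frozen=True)
class StrandSegment:
    start: int
    end: int
    partner: tuple[int, int]
    orientation: str


@dataclass(frozen=True)
class SSEAssignment:
    """Per-residue codes plus segment bookkeeping for one trace."""

    codes: str  # length N, codes[n-1] is the code of position n
    helix_segments: tuple[tuple[int, int], ...] = ()
    strand_segments: tuple[StrandSegment, ...] = ()
    pairs: tuple[SheetPair, ...] = ()

    def __len__(self) -> int:
        return len(self.codes)

    def code(self, position: int) -> str:
        return self.codes[position - 1]


def _in(value: float, interval: tuple[float, float]) -> bool:
    return not np.isnan(value) and interval[0] <= value <= interval[1]


def detect_helices(profile: AngleProfile, params: CutabiParams | None = None) -> np.ndarray:
    """Boolean mask (length N+1, 1-based) of residues in accepted helix windows."""
    params = params or CutabiParams()
    n = profile.n_residues
    mask = np.zeros(n + 1, dtype=bool)
    # window start k needs θ_k..θ_{k+3} (so 2 <= k <= N−4) and γ_{k+1}, γ_{k+2}
    for k in range(2, n - 3):
        if all(_in(profile.theta[k + j], params.helix_theta) for j in range(4)) and \
           all(_in(profile.gamma[k + j], params.helix_gamma) for j in (1, 2)):
            mask[k:k + 4] = True
    return mask


def _duplet_angles_ok(profile: AngleProfile, start: int, params: CutabiParams) -> bool:
    g = profile.gamma[start]
    return (_in(profile.theta[start], params.sheet_theta)
            and _in(profile.theta[start + 1], params.sheet_theta)
            and not np.isnan(g) and abs(g) > params.sheet_gamma_abs_min)


def _pair_orientation(coords: np.ndarray, k: int, i: int, n: int,
                      params: CutabiParams) -> str | None:
    """Orientation of an accepted (k, i) duplet pair, or None if rejected.

    Both registrations need position i+2, so duplets ending at the chain
    terminus cannot pair.  If both registers pass (contrived geometry),
    the one with the smaller summed pair distance wins.
    """
    if i + 2 > n:
        return None

    def d(a: int, b: int) -> float:
        return float(np.linalg.norm(coords[a - 1] - coords[b - 1]))

    results = []
    dp1, dp2 = d(k, i), d(k + 1, i + 1)
    if dp1 < params.d_pair_max and dp2 < params.d_pair_max and \
            d(k + 1, i + 2) < params.d_diag_max:
        results.append((dp1 + dp2, "parallel"))
    da1, da2 = d(k, i + 1), d(k + 1, i)
    if da1 < params.d_pair_max and da2 < params.d_pair_max and \
            d(k, i + 2) < params.d_diag_max:
        results.append((da1 + da2, "antiparallel"))
    if not results:
        return None
    return min(results)[1]


def detect_sheet_pairs(trace: CaTrace, profile: AngleProfile,
                       params: CutabiParams | None = None,
                       exclude: np.ndarray | None = None) -> list[SheetPair]:
    """All accepted duplet pairs (k < i), helix residues excluded.

    ``exclude`` is a 1-based boolean mask of residues unavailable for
    sheets (normally the helix mask).
    """
    params = params or CutabiParams()
    n = len(trace)
    if exclude is None:
        exclude = np.zeros(n + 1, dtype=bool)
    coords = trace.coords

    # duplet start k needs γ_k (2 <= k <= N−2) and an intact bond k..k+1
    candidates = [k for k in range(2, n - 1)
                  if not trace.has_break(k)
                  and not exclude[k] and not exclude[k + 1]
                  and _duplet_angles_ok(profile, k, params)]
    pairs: list[SheetPair] = []
    for k, i in itertools.combinations(candidates, 2):
        if i - k < params.min_seq_separation:
            continue
        orientation = _pair_orientation(coords, k, i, n, params)
        if orientation is not None:
            pairs.append(SheetPair(k=k, i=i, orientation=orientation))
    return pairs


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers as inclusive (start, end)."""
    runs: list[tuple[int, int]] = []
    for pos in sorted(positions):
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    return runs


def assemble(helix_mask: np.ndarray, pairs: list[SheetPair], n: int,
             params: CutabiParams | None = None) -> SSEAssignment:
    """Merge helix windows and sheet pairs into a per-residue assignment.

    H runs are the maximal unions of accepted helix windows (≥ 4 residues
    by construction); E residues are the union of duplets over accepted
    pairs, merged into maximal contiguous strand segments.  Helix wins any
    conflict.  Everything else is coil.
    """
    params = params or CutabiParams()
    codes = np.full(n + 1, "C", dtype="<U1")
    codes[np.asarray(helix_mask[:n + 1], dtype=bool)] = "H"
    sheet_residues: set[int] = set()
    for p in pairs:
        sheet_residues.update(p.residues)
    for pos in sheet_residues:
        if codes[pos] != "H":
            codes[pos] = "E"

    helix_segments = tuple(_runs([p for p in range(1, n + 1) if codes[p] == "H"]))
    strand_runs = _runs([p for p in range(1, n + 1) if codes[p] == "E"])

    def run_of(pos: int) -> tuple[int, int]:
        for run in strand_runs:
            if run[0] <= pos <= run[1]:
                return run
        raise AssertionError(f"position {pos} not in any strand run")

    strand_segments = []
    for run in strand_runs:
        partner, orientation = run, "antiparallel"
        for p in pairs:
            if run[0] <= p.k <= run[1]:
                partner, orientation = run_of(p.i), p.orientation
                break
            if run[0] <= p.i <= run[1]:
                partner, orientation = run_of(p.k), p.orientation
                break
        strand_segments.append(StrandSegment(run[0], run[1], partner, orientation))

    return SSEAssignment(codes="".join(codes[1:]),
                         helix_segments=helix_segments,
                         strand_segments=tuple(strand_segments),
                         pairs=tuple(pairs))


def assign(trace: CaTrace, params: CutabiParams | None = None) -> SSEAssignment:
    """Full assignment: angles → helix windows → sheet pairs → merge."""
    params = params or CutabiParams()
    profile = compute_angles(trace)
    helix_mask = detect_helices(profile, params)
    pairs = detect_sheet_pairs(trace, profile, params, exclude=helix_mask)
    return assemble(helix_mask, pairs, len(trace), params)


def count_sse(assignment: SSEAssignment, region: tuple[int, int] | None = None) -> tuple[int, int]:
    """(α, β): number of H and E residues inside an inclusive positional range."""
    n = len(assignment)
    if region is None:
        region = (1, n)
    lo, hi = region
    lo, hi = max(lo, 1), min(hi, n)
    if lo > hi:
        return (0, 0)
    window = assignment.codes[lo - 1:hi]
    return (window.count("H"), window.count("E"))
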