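"""Conformational-ensemble analytics over per-frame secondary-structure counts.

Each frame of an ensemble is reduced to (α, β): the number of helix and
sheet residues inside an analysis region (default: positions 1–95, the
N-terminal plus NAC regions of α-synuclein, always overridable) together
with the radius of gyration of the full chain.  Frames with α = 0 form
the B (β-only / no-helix) state; the rest the HB (helix + β mixture)
state.

On the integer (α, β) grid the normalised count map P(α, β) yields a
free-energy scale ΔF = ln(P_max/P) in kT units, with P_max the maximum of
P over the α = 0 column (the most probable B-state cell).  The cumulative
fraction of conformations within a cutoff c, F(c) = Σ{P : ΔF ≤ c}, is
nondecreasing and reaches 1; its numerical derivative is the density of
conformational micro-states (DOS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CutabiParams, assign, count_sse
from .geometry import min_interchain_distance, radius_of_gyration
from .trace import CaTrace

__all__ = [
    "ConformationSummary",
    "DensityMap",
    "FractionCurve",
    "PropensityProfile",
    "summarize",
    "summaries_frame",
    "density_map",
    "cumulative_fraction_curve",
    "per_residue_propensity",
    "rg_by_state",
    "filter_monomers",
]

#: default analysis region: N-terminal (1–60) + NAC (61–95) of α-synuclein
DEFAULT_REGION = (1, 95)


@dataclass(frozen=True)
class ConformationSummary:
    """(α, β, Rg, state) record for one ensemble member."""

    frame: int
    alpha: int
    beta: int
    rg: float
    state: str  # "B" (alpha == 0) | "HB"

    def __post_init__(self) -> None:
        expected = "B" if self.alpha == 0 else "HB"
        if self.state != expected:
            raise ValueError(f"state {self.state!r} inconsistent with alpha={self.alpha}")


def summarize(ensemble: list[CaTrace], params: CutabiParams | None = None,
              region: tuple[int, int] | None = None) -> list[ConformationSummary]:
    """Assign every frame and reduce it to a ConformationSummary.

    α and β are counted inside ``region``; Rg is over the full chain.
    All frames must share one chain length.
    """
    if not ensemble:
        return []
    lengths = {len(t) for t in ensemble}
    if len(lengths) != 1:
        raise ValueError(f"heterogeneous chain lengths in ensemble: {sorted(lengths)}")
    region = region or DEFAULT_REGION
    out = []
    for frame, trace in enumerate(ensemble):
        a, b = count_sse(assign(trace, params), region)
        out.append(ConformationSummary(
            frame=frame, alpha=a, beta=b, rg=radius_of_gyration(trace),
            state="B" if a == 0 else "HB"))
    return out


def summaries_frame(summaries: list[ConformationSummary]) -> pd.DataFrame:
    return pd.DataFrame([{"frame": s.frame, "alpha": s.alpha, "beta": s.beta,
                          "rg": s.rg, "state": s.state} for s in summaries])


@dataclass(frozen=True)
class DensityMap:
    """Normalised probability over the integer (α, β) grid.

    ``P[a, b]`` is the fraction of frames at α = a, β = b (1-residue
    cells, no smoothing); ``P_max_B`` is the maximum over the α = 0
    column — the most probable cell of the B state.
    """

    P: np.ndarray
    P_max_B: float

    @property
    def b_marginal(self) -> np.ndarray:
        """P(0, β): the B-state probability profile over β."""
        return self.P[0]

    @property
    def hb_block(self) -> np.ndarray:
        """The α ≥ 1 block of the map (the HB state)."""
        return self.P[1:]

    @property
    def b_fraction(self) -> float:
        return float(self.P[0].sum())


def density_map(summaries: list[ConformationSummary]) -> DensityMap:
    """Count-based P(α, β); sums to 1 by construction."""
    if not summaries:
        raise ValueError("cannot build a density map from zero summaries")
    amax = max(s.alpha for s in summaries)
    bmax = max(s.beta for s in summaries)
    counts = np.zeros((amax + 1, bmax + 1))
    for s in summaries:
        counts[s.alpha, s.beta] += 1
    p = counts / counts.sum()
    return DensityMap(P=p, P_max_B=float(p[0].max()))


@dataclass(frozen=True)
class FractionCurve:
    """Cumulative fraction of conformations vs free-energy cutoff (kT)."""

    cutoffs: np.ndarray
    fraction: np.ndarray

    def dos(self) -> tuple[np.ndarray, np.ndarray]:
        """Density of micro-states: midpoints and dF/dc by central differences."""
        mid = 0.5 * (self.cutoffs[1:] + self.cutoffs[:-1])
        return mid, np.diff(self.fraction) / np.diff(self.cutoffs)


def cumulative_fraction_curve(dmap: DensityMap,
                              cutoffs: np.ndarray | None = None) -> FractionCurve:
    """F(c) = Σ{P(α, β) : ln(P_max_B / P(α, β)) ≤ c} over occupied cells.

    Cells with P = 0 carry infinite ΔF and never contribute.  An HB cell
    more probable than the B maximum has ΔF < 0 and is included at every
    cutoff above its (negative) ΔF; when that happens and no explicit grid
    is given, the default grid extends below zero to cover it.
    """
    p = dmap.P[dmap.P > 0]
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("density map is not normalised")
    delta_f = np.log(dmap.P_max_B / p)
    if cutoffs is None:
        lo = min(0.0, float(delta_f.min()))
        hi = float(delta_f.max())
        cutoffs = np.linspace(lo, hi + 0.5, 201)
    cutoffs = np.asarray(cutoffs, dtype=float)
    fraction = np.array([p[delta_f <= c].sum() for c in cutoffs])
    return FractionCurve(cutoffs=cutoffs, fraction=fraction)


@dataclass(frozen=True)
class PropensityProfile:
    """Per-residue probability of helix and sheet membership across frames."""

    helix: np.ndarray
    sheet: np.ndarray
    n_frames: int


def per_residue_propensity(ensemble: list[CaTrace],
                           params: CutabiParams | None = None,
                           subset: str = "all",
                           region: tuple[int, int] | None = None) -> PropensityProfile:
    """Fraction of frames in which each residue is H (resp. E).

    ``subset`` restricts to B-state or HB-state frames, with the state
    decided by α inside ``region`` (default: the full analysis region).
    Results are invariant under frame permutation.
    """
    if subset not in ("all", "B", "HB"):
        raise ValueError(f"unknown subset {subset!r}")
    if not ensemble:
        raise ValueError("empty ensemble")
    n = len(ensemble[0])
    region = region or DEFAULT_REGION
    h_counts = np.zeros(n)
    e_counts = np.zeros(n)
    kept = 0
    for trace in ensemble:
        assignment = assign(trace, params)
        if subset != "all":
            a, _ = count_sse(assignment, region)
            state = "B" if a == 0 else "HB"
            if state != subset:
                continue
        kept += 1
        for pos, code in enumerate(assignment.codes):
            if code == "H":
                h_counts[pos] += 1
            elif code == "E":
                e_counts[pos] += 1
    if kept == 0:
        raise ValueError(f"no frames in subset {subset!r}")
    return PropensityProfile(helix=h_counts / kept, sheet=e_counts / kept,
                             n_frames=kept)


def rg_by_state(summaries: list[ConformationSummary], bins=30) -> dict[str, tuple]:
    """Normalised Rg probability densities for all / B / HB frames.

    Returns ``{"all"|"B"|"HB": (density, bin_edges)}`` with shared edges so
    the B and HB counts add up binwise to the full-ensemble counts.  A
    subset with no frames yields an all-zero density.
    """
    if not summaries:
        raise ValueError("cannot histogram zero summaries")
    rg = np.array([s.rg for s in summaries])
    states = np.array([s.state for s in summaries])
    _, edges = np.histogram(rg, bins=bins)
    out: dict[str, tuple] = {}
    for key, mask in (("all", np.ones(len(rg), bool)),
                      ("B", states == "B"), ("HB", states == "HB")):
        if mask.any():
            dens, _ = np.histogram(rg[mask], bins=edges, density=True)
        else:
            dens = np.zeros(len(edges) - 1)
        out[key] = (dens, edges)
    return out


def filter_monomers(frames: list[tuple[CaTrace, CaTrace]],
                    cutoff: float = 20.0) -> tuple[list[tuple[CaTrace, CaTrace]], float]:
    """Keep two-chain frames whose chains never approach within ``cutoff`` Å.

    A frame is an isolated-monomer observation iff no residue of one chain
    lies closer than ``cutoff`` to any residue of the other.  Returns the
    retained frames and the retained fraction.
    """
    if not frames:
        raise ValueError("no frames given")
    for idx, frame in enumerate(frames):
        if len(frame) != 2:
            raise ValueError(f"frame {idx} holds {len(frame)} chains, expected 2")
    retained = [f for f in frames if min_interchain_distance(f[0], f[1]) >= cutoff]
    return retained, len(retained) / len(frames)
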