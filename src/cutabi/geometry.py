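"""Discrete differential geometry of a Cα trace.

For a chain of N residues with positions Cα_1..Cα_N and constant virtual
bond length, the conformation is characterised by

* N−2 pseudo-bond angles θ_n (n = 2..N−1): the interior angle at Cα_n
  formed by Cα_{n−1}, Cα_n, Cα_{n+1} — the discrete local curvature;
* N−3 pseudo-torsions γ_n (n = 2..N−2): the signed dihedral defined by
  Cα_{n−1}, Cα_n, Cα_{n+1}, Cα_{n+2} — the discrete local torsion.

Angles are in degrees throughout; γ follows the right-handed (IUPAC) sign
convention, so a canonical right-handed α-helix has γ ≈ +50°.

The module also provides the global shape descriptors used by the
ensemble analytics: radius of gyration, the Flory random-coil reference
Rg = 0.367·b·N^ν, inter-region contact counts and inter-chain distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import CaTrace

__all__ = [
    "AngleProfile",
    "FloryParams",
    "compute_angles",
    "radius_of_gyration",
    "flory_rg",
    "interregion_contact_count",
    "min_interchain_distance",
]

# below this, two "consecutive" points are treated as coincident and the
# angle is reported as undefined rather than a numerical artefact
_DEGENERACY_EPS = 1e-8


@dataclass(frozen=True)
class AngleProfile:
    """Per-residue curvature (θ) and torsion (γ) profiles.

    ``theta`` and ``gamma`` are arrays of length N+1 indexed by 1-based
    residue position; entries outside each angle's domain, or at positions
    listed in ``undefined``, hold NaN.  θ_n is defined for n = 2..N−1 and
    lies in (0, 180]; γ_n is defined for n = 2..N−2 and lies in (−180, 180].
    """

    theta: np.ndarray
    gamma: np.ndarray
    undefined: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_residues(self) -> int:
        return len(self.theta) - 1

    def theta_at(self, n: int) -> float:
        return float(self.theta[n])

    def gamma_at(self, n: int) -> float:
        return float(self.gamma[n])


def _bond_angles(coords: np.ndarray) -> np.ndarray:
    """Interior angles at each middle point, degrees; NaN where degenerate."""
    b1 = coords[:-2] - coords[1:-1]
    b2 = coords[2:] - coords[1:-1]
    n1 = np.linalg.norm(b1, axis=1)
    n2 = np.linalg.norm(b2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", b1, b2) / (n1 * n2)
    cosang = np.clip(cosang, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang[(n1 < _DEGENERACY_EPS) | (n2 < _DEGENERACY_EPS)] = np.nan
    return ang


def _dihedrals(coords: np.ndarray) -> np.ndarray:
    """Signed dihedrals for each consecutive quadruple, degrees, IUPAC sign.

    Result in (−180, 180]; NaN where three consecutive points are collinear
    (torsion undefined).
    """
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    # sign such that a right-handed helix has positive torsion
    ang = -np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=1) < _DEGENERACY_EPS) | (
        np.linalg.norm(n2, axis=1) < _DEGENERACY_EPS)
    ang[bad] = np.nan
    # map −180 to +180 so the range is the half-open (−180, 180]
    ang[ang == -180.0] = 180.0
    return ang


def compute_angles(trace: CaTrace) -> AngleProfile:
    """Curvature/torsion profile of a trace.

    θ_n needs positions n−1..n+1 and γ_n positions n−1..n+2; any angle
    whose atom span crosses a chain break, or that is geometrically
    degenerate, is NaN and its position is listed in ``undefined``.
    Traces shorter than 3 residues yield an all-NaN profile.
    """
    n = len(trace)
    theta = np.full(n + 1, np.nan)
    gamma = np.full(n + 1, np.nan)
    undefined: set[int] = set()
    if n >= 3:
        theta[2:n] = _bond_angles(trace.coords)
    if n >= 4:
        gamma[2:n - 1] = _dihedrals(trace.coords)
    for pos in range(2, n):
        # θ_pos spans bonds (pos−1, pos)
        if any(trace.has_break(b) for b in (pos - 1, pos)):
            theta[pos] = np.nan
            undefined.add(pos)
        elif np.isnan(theta[pos]):
            undefined.add(pos)
    for pos in range(2, n - 1):
        # γ_pos spans bonds (pos−1, pos, pos+1)
        if any(trace.has_break(b) for b in (pos - 1, pos, pos + 1)):
            gamma[pos] = np.nan
            undefined.add(pos)
        elif np.isnan(gamma[pos]):
            undefined.add(pos)
    return AngleProfile(theta=theta, gamma=gamma, undefined=frozenset(undefined))


def radius_of_gyration(trace: CaTrace) -> float:
    """Root-mean-square distance of the Cα points to their centroid, Å.

    Unit masses: every residue is represented by its Cα bead alone.
    """
    coords = trace.coords
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


@dataclass(frozen=True)
class FloryParams:
    """Parameters of the self-avoiding random-coil reference Rg = 0.367·b·N^ν.

    ``b`` is the statistical segment length in Å (7.6 Å ≈ twice the
    Cα–Cα distance is the conventional protein value); ``nu`` is the
    Flory exponent, 3/5 in a good solvent.
    """

    b: float = 7.6
    nu: float = 3.0 / 5.0
    prefactor: float = 0.367

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("statistical segment length b must be positive")
        if not 0 < self.nu < 1:
            raise ValueError("Flory exponent nu must lie in (0, 1)")


def flory_rg(n_residues: int, params: FloryParams | None = None) -> float:
    """Random-coil (good-solvent) radius of gyration reference, Å."""
    if n_residues < 1:
        raise ValueError(f"chain length must be >= 1, got {n_residues}")
    p = params or FloryParams()
    return p.prefactor * p.b * n_residues**p.nu


def interregion_contact_count(trace: CaTrace, region_a: tuple[int, int],
                              region_b: tuple[int, int], cutoff: float = 8.0) -> int:
    """Number of Cα–Cα pairs closer than ``cutoff`` between two disjoint regions.

    Regions are inclusive 1-based positional ranges ``(start, end)``.
    """
    a0, a1 = region_a
    b0, b1 = region_b
    n = len(trace)
    for lo, hi in ((a0, a1), (b0, b1)):
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"region ({lo}, {hi}) out of bounds for trace of length {n}")
    if not (a1 < b0 or b1 < a0):
        raise ValueError(f"regions {region_a} and {region_b} overlap")
    ca = trace.coords[a0 - 1:a1]
    cb = trace.coords[b0 - 1:b1]
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    return int(np.count_nonzero(d < cutoff))


def min_interchain_distance(a: CaTrace, b: CaTrace) -> float:
    """Minimum Cα–Cα distance between two chains, Å."""
    d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
    return float(d.min())
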