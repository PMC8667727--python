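"""Cα traces: the sole structural input the assignment algorithm needs.

A trace is an ordered list of Cα positions for one chain of one model.
Algorithmic residue indexing is positional, 1..N; author residue numbers
and insertion codes are carried only as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: physically plausible range for a virtual Cα–Cα bond, Å
CA_CA_MIN = 2.8
CA_CA_MAX = 4.2


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates of one chain in one model.

    Parameters
    ----------
    coords
        ``(N, 3)`` Cartesian coordinates in Å.
    chain_id
        Chain label from the source file.
    model_index
        1-based model number.
    residue_ids
        Author residue numbers, one per position (metadata only).
    residue_names
        Optional one-letter residue codes.
    icodes
        Optional insertion codes, aligned with ``residue_ids``.
    breaks
        Positions ``i`` (1-based) such that the virtual bond between
        residues ``i`` and ``i+1`` is a chain break; no angle or
        detection window is evaluated across a break.
    """

    coords: np.ndarray
    chain_id: str = "A"
    model_index: int = 1
    residue_ids: tuple[int, ...] | None = None
    residue_names: tuple[str, ...] | None = None
    icodes: tuple[str, ...] | None = None
    breaks: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError(f"coords must be (N, 3) with N >= 1, got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        object.__setattr__(self, "coords", coords)
        if self.residue_ids is None:
            object.__setattr__(self, "residue_ids", tuple(range(1, len(coords) + 1)))
        elif len(self.residue_ids) != len(coords):
            raise ValueError("residue_ids length does not match coords")
        if self.model_index < 1:
            raise ValueError("model_index must be >= 1")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def bond_lengths(self) -> np.ndarray:
        """Consecutive Cα–Cα distances, Å; entry ``i`` spans positions i+1, i+2."""
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def has_break(self, position: int) -> bool:
        """True if a break separates positions ``position`` and ``position + 1``."""
        return position in self.breaks

    def with_breaks_detected(self) -> "CaTrace":
        """Return a copy with breaks inferred from geometry and numbering.

        A break is flagged wherever the virtual bond length falls outside
        [2.8, 4.2] Å or the author residue numbering jumps by more than 1.
        """
        return CaTrace(
            self.coords,
            chain_id=self.chain_id,
            model_index=self.model_index,
            residue_ids=self.residue_ids,
            residue_names=self.residue_names,
            icodes=self.icodes,
            breaks=frozenset(detect_breaks(self.coords, self.residue_ids)),
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "CaTrace":
        """Apply a rigid motion ``x -> R x + t`` to the coordinates."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return CaTrace(coords, chain_id=self.chain_id, model_index=self.model_index,
                       residue_ids=self.residue_ids, residue_names=self.residue_names,
                       icodes=self.icodes, breaks=self.breaks)


def detect_breaks(coords: np.ndarray, residue_ids=None) -> set[int]:
    """Positions (1-based) whose bond to the next residue is a chain break."""
    coords = np.asarray(coords, dtype=float)
    breaks: set[int] = set()
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    for i, dist in enumerate(d, start=1):
        if not (CA_CA_MIN <= dist <= CA_CA_MAX):
            breaks.add(i)
    if residue_ids is not None:
        for i in range(1, len(coords)):
            if residue_ids[i] - residue_ids[i - 1] > 1:
                breaks.add(i)
    return breaks


def concatenate_traces(a: CaTrace, b: CaTrace, chain_id: str | None = None) -> CaTrace:
    """Join two traces into one with an explicit chain break at the junction.

    Useful for analysing a two-chain system (e.g. a parallel strand pair)
    with single-trace algorithms: no window is evaluated across the break,
    but inter-residue distances remain available.
    """
    na = len(a)
    coords = np.vstack([a.coords, b.coords])
    names = None
    if a.residue_names is not None and b.residue_names is not None:
        names = tuple(a.residue_names) + tuple(b.residue_names)
    return CaTrace(
        coords,
        chain_id=chain_id or a.chain_id,
        model_index=a.model_index,
        residue_ids=tuple(a.residue_ids) + tuple(r + a.residue_ids[-1] + 1 for r in b.residue_ids),
        residue_names=names,
        breaks=frozenset(a.breaks) | {na} | frozenset(br + na for br in b.breaks),
    )
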