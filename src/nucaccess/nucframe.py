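"""Coordinate conventions for the 147-bp nucleosome core particle frame.

Positions along the wrapped DNA are expressed either as 0-based base-pair
indices or as superhelical locations (SHL): helical turns from the dyad
(SHL 0), spanning -7 at the entry to +7 at the exit under the canonical
147-bp wrap. The SHL assigned to a motif refers to the centroid of the
motif, so a 6-bp core centred on the dyad sits at SHL 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["NucFrame", "pos_to_shl", "shl_to_pos", "rotational_phase"]


@dataclass(frozen=True)
class NucFrame:
    """Geometry of the nucleosomal DNA wrap.

    Parameters
    ----------
    length_bp:
        Number of wrapped base pairs (odd, default 147).
    dyad_index:
        0-based index of the dyad base pair (default 73, the centre).
    bp_per_shl:
        Base pairs per superhelical turn. The default 73/7 makes the
        147-bp frame span SHL -7..+7 exactly at its edges.
    """

    length_bp: int = 147
    dyad_index: int = 73
    bp_per_shl: float = 73.0 / 7.0

    def __post_init__(self) -> None:
        if self.length_bp < 1 or self.length_bp % 2 == 0:
            raise ValueError(f"length_bp must be odd and >= 1, got {self.length_bp}")
        if not 0 <= self.dyad_index < self.length_bp:
            raise ValueError(f"dyad_index {self.dyad_index} outside [0, {self.length_bp})")
        if self.bp_per_shl <= 0:
            raise ValueError("bp_per_shl must be positive")

    @property
    def shl_min(self) -> float:
        return (0 - self.dyad_index) / self.bp_per_shl

    @property
    def shl_max(self) -> float:
        return (self.length_bp - 1 - self.dyad_index) / self.bp_per_shl


def pos_to_shl(frame: NucFrame, motif_start: int, motif_len: int = 1) -> float:
    """SHL of the centroid of a motif starting at ``motif_start``.

    The centroid of a ``motif_len``-bp motif starting at 0-based index s is
    s + (motif_len - 1)/2; its SHL is the signed distance from the dyad in
    units of ``bp_per_shl``.
    """
    if motif_len < 1:
        raise ValueError("motif_len must be >= 1")
    if motif_start < 0 or motif_start + motif_len > frame.length_bp:
        raise ValueError(
            f"motif [{motif_start}, {motif_start + motif_len}) outside frame "
            f"of length {frame.length_bp}"
        )
    centroid = motif_start + (motif_len - 1) / 2.0
    return (centroid - frame.dyad_index) / frame.bp_per_shl


def shl_to_pos(frame: NucFrame, shl: float, motif_len: int = 1) -> int:
    """Integer motif start whose centroid SHL is nearest to ``shl``.

    Ties between two equally near starts are broken away from the dyad.
    Raises if the nearest valid start would place the motif outside the frame.
    """
    if motif_len < 1:
        raise ValueError("motif_len must be >= 1")
    # Exact (real) start for this SHL, then choose between its floor/ceil.
    target = shl * frame.bp_per_shl + frame.dyad_index - (motif_len - 1) / 2.0
    lo, hi = math.floor(target), math.ceil(target)
    if lo == hi:
        start = lo
    else:
        d_lo, d_hi = target - lo, hi - target
        if math.isclose(d_lo, d_hi):
            # round half away from the dyad
            start = hi if shl >= 0 else lo
        else:
            start = lo if d_lo < d_hi else hi
    if start < 0 or start + motif_len > frame.length_bp:
        raise ValueError(
            f"SHL {shl} with motif_len {motif_len} falls outside the "
            f"{frame.length_bp}-bp frame"
        )
    return start


def rotational_phase(frame: NucFrame, shl: float) -> float:
    """Rotational phase angle in degrees [0, 360) at a given SHL.

    360 * frac(|shl|): 0 deg at every integral SHL (where the major groove
    faces the histone octamer). This is an annotation only; no
    solvent/histone-facing classification is applied.
    """
    if abs(shl) > 7:
        raise ValueError(f"|shl| must be <= 7, got {shl}")
    return (360.0 * (abs(shl) % 1.0)) % 360.0
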