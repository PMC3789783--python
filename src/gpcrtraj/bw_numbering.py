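"""Ballesteros-Weinstein (BW) generic numbering for GPCR TM residues.

Each transmembrane helix H contributes indices ``H.PP`` where the most
conserved residue of the helix sits at position 50 (e.g. the conserved
TM2 aspartate is 2.50).  An anchor residue with a known position fixes
the whole helix: position(residue) = anchor_position + (residue - anchor).
Indices are stored as integer pairs and rendered as "H.PP" only at I/O,
so 2.50 never degrades to the float 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["HelixDefinition", "BWIndex", "BWDefinitionError", "BWLookupError",
           "assign_bw", "lookup_bw"]


class BWDefinitionError(ValueError):
    """Invalid or mutually inconsistent helix definitions."""


class BWLookupError(KeyError):
    """BW index not covered by the helix definitions."""


@dataclass(frozen=True)
class BWIndex:
    helix_id: int
    position: int

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 99:
            raise BWDefinitionError(
                f"BW position {self.position} outside 1-99 (helix {self.helix_id})"
            )

    def __str__(self) -> str:
        return f"{self.helix_id}.{self.position:02d}"

    @classmethod
    def parse(cls, text: str) -> "BWIndex":
        try:
            helix, pos = text.split(".")
            return cls(int(helix), int(pos))
        except (ValueError, TypeError) as exc:
            raise BWLookupError(f"malformed BW index {text!r}") from exc


@dataclass(frozen=True)
class HelixDefinition:
    """A TM helix: inclusive residue range, BW anchor, membrane topology.

    ``intracellular_end`` records which end of the residue range faces the
    cytoplasm ("start" or "end"); geometry code uses it to pick helix ends.
    The anchor need not sit at position 50 (a helix may be anchored at any
    residue whose generic position is known).
    """

    helix_id: int
    start_seq: int
    end_seq: int
    anchor_seq: int
    anchor_position: int = 50
    intracellular_end: str = "end"

    def __post_init__(self) -> None:
        if not 1 <= self.helix_id <= 8:
            raise BWDefinitionError(f"helix_id {self.helix_id} outside 1-8")
        if not self.start_seq <= self.anchor_seq <= self.end_seq:
            raise BWDefinitionError(
                f"anchor {self.anchor_seq} outside range "
                f"{self.start_seq}-{self.end_seq} of helix {self.helix_id}"
            )
        if self.intracellular_end not in ("start", "end"):
            raise BWDefinitionError("intracellular_end must be 'start' or 'end'")
        for seq in (self.start_seq, self.end_seq):
            pos = self.anchor_position + (seq - self.anchor_seq)
            if not 1 <= pos <= 99:
                raise BWDefinitionError(
                    f"helix {self.helix_id}: residue {seq} maps to BW position "
                    f"{pos} outside 1-99"
                )

    @property
    def residues(self) -> range:
        return range(self.start_seq, self.end_seq + 1)

    def position_of(self, residue_seq: int) -> int:
        return self.anchor_position + (residue_seq - self.anchor_seq)

    def intracellular_residues(self, n: int) -> list[int]:
        """The n most intracellular residue numbers, innermost last."""
        if n > len(self.residues):
            raise BWDefinitionError(
                f"helix {self.helix_id}: requested {n} end residues, has "
                f"{len(self.residues)}"
            )
        if self.intracellular_end == "end":
            return list(range(self.end_seq - n + 1, self.end_seq + 1))
        return list(range(self.start_seq + n - 1, self.start_seq - 1, -1))


def assign_bw(helices: Iterable[HelixDefinition]) -> dict[int, BWIndex]:
    """Map every TM residue number to its BW index.

    Raises :class:`BWDefinitionError` on overlapping helix ranges or
    positions escaping 1-99 (checked in HelixDefinition).
    """
    helices = list(helices)
    seen: dict[int, int] = {}
    mapping: dict[int, BWIndex] = {}
    for h in helices:
        for seq in h.residues:
            if seq in seen:
                raise BWDefinitionError(
                    f"residue {seq} claimed by helices {seen[seq]} and {h.helix_id}"
                )
            seen[seq] = h.helix_id
            mapping[seq] = BWIndex(h.helix_id, h.position_of(seq))
    return mapping


def lookup_bw(bw_map: dict[int, BWIndex], index: str | BWIndex) -> int:
    """Inverse lookup: BW index ("7.50" or BWIndex) -> residue number."""
    target = BWIndex.parse(index) if isinstance(index, str) else index
    for seq, bw in bw_map.items():
        if bw == target:
            return seq
    raise BWLookupError(f"BW index {target} not covered by helix definitions")
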