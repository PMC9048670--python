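"""IMGT position algebra for antibody variable domains.

The IMGT unique numbering assigns every variable-domain residue a slot in
1..128; loop-length variation is absorbed by scheme gaps and, for long loops,
by lettered insertion codes hanging off fixed anchor positions (111A, 112B,
...).  Within CDR3 the insertion ladder is asymmetric: insertions at 111
ascend after 111 (111 < 111A < 111B) while insertions at 112 descend before
112 (111B < 112B < 112A < 112).  Everything downstream — profile positions,
alignment columns, CDR extraction — relies on this ordering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ImgtPosition",
    "Region",
    "REGIONS",
    "parse_position",
    "compare_positions",
    "region_of",
    "extract_cdrs",
    "cdr3_ladder",
]

#: Anchor positions at which the scheme permits lettered insertions
#: (CDR3: 111/112; CDR1 and CDR2 length variants: 32/33, 60/61).
INSERTION_ANCHORS = frozenset({32, 33, 60, 61, 111, 112})

_LABEL_RE = re.compile(r"^(\d+)([A-Z]*)$")


def _letters_to_index(letters: str) -> int:
    """'A' -> 1, 'Z' -> 26, 'AA' -> 27 (bijective base 26)."""
    idx = 0
    for ch in letters:
        idx = idx * 26 + (ord(ch) - ord("A") + 1)
    return idx


def _index_to_letters(idx: int) -> str:
    out = []
    while idx > 0:
        idx, rem = divmod(idx - 1, 26)
        out.append(chr(ord("A") + rem))
    return "".join(reversed(out))


@dataclass(frozen=True, order=False)
class ImgtPosition:
    """One IMGT numbering slot: base number in 1..128 plus insertion index.

    Insertion indices are stored as integers (0 = no insertion) and rendered
    as letters (1 -> ``A``), which keeps ordering arithmetic unambiguous past
    ``Z`` (27 -> ``AA``).
    """

    number: int
    insertion: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.number <= 128:
            raise ValueError(f"IMGT position number out of range [1, 128]: {self.number}")
        if self.insertion < 0:
            raise ValueError(f"negative insertion index: {self.insertion}")
        if self.insertion and self.number not in INSERTION_ANCHORS:
            raise ValueError(
                f"insertion code not permitted at IMGT position {self.number} "
                f"(anchors: {sorted(INSERTION_ANCHORS)})"
            )

    @property
    def label(self) -> str:
        return f"{self.number}{_index_to_letters(self.insertion)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    def sort_key(self) -> tuple[int, int]:
        # 112 insertions descend (112B < 112A < 112); all other anchors ascend.
        if self.number == 112:
            return (self.number, -self.insertion)
        return (self.number, self.insertion)

    def __lt__(self, other: "ImgtPosition") -> bool:
        return self.sort_key() < other.sort_key()

    def __le__(self, other: "ImgtPosition") -> bool:
        return self.sort_key() <= other.sort_key()

    def __gt__(self, other: "ImgtPosition") -> bool:
        return self.sort_key() > other.sort_key()

    def __ge__(self, other: "ImgtPosition") -> bool:
        return self.sort_key() >= other.sort_key()


@dataclass(frozen=True)
class Region:
    """A framework or CDR segment as a closed interval of IMGT base numbers."""

    name: str
    start: int
    end: int

    def __contains__(self, number: int) -> bool:
        return self.start <= number <= self.end


#: IMGT-standard region spans; disjoint and covering 1..128 exactly.
REGIONS: tuple[Region, ...] = (
    Region("FR1", 1, 26),
    Region("CDR1", 27, 38),
    Region("FR2", 39, 55),
    Region("CDR2", 56, 65),
    Region("FR3", 66, 104),
    Region("CDR3", 105, 117),
    Region("FR4", 118, 128),
)


class PositionParseError(ValueError):
    pass


def parse_position(label: str) -> ImgtPosition:
    """Parse a position label like ``"105"`` or ``"111A"``.

    Also accepts the dotted IMGT insertion style (``"111.1"``) seen in some
    numbering outputs.
    """
    label = str(label).strip()
    if "." in label:
        num_s, _, ins_s = label.partition(".")
        if num_s.isdigit() and ins_s.isdigit() and int(ins_s) > 0:
            num, ins = int(num_s), int(ins_s)
        else:
            raise PositionParseError(f"malformed IMGT position label: {label!r}")
    else:
        m = _LABEL_RE.match(label)
        if not m:
            raise PositionParseError(f"malformed IMGT position label: {label!r}")
        num = int(m.group(1))
        ins = _letters_to_index(m.group(2)) if m.group(2) else 0
    if not 1 <= num <= 128:
        raise PositionParseError(f"IMGT position out of range [1, 128]: {label!r}")
    try:
        return ImgtPosition(num, ins)
    except ValueError as exc:
        raise PositionParseError(str(exc)) from exc


def compare_positions(a: ImgtPosition, b: ImgtPosition) -> int:
    """Return -1, 0 or 1 for a < b, a == b, a > b in IMGT order."""
    ka, kb = a.sort_key(), b.sort_key()
    return (ka > kb) - (ka < kb)


def region_of(p: ImgtPosition) -> str:
    """Name of the unique region whose span contains ``p``."""
    for region in REGIONS:
        if p.number in region:
            return region.name
    raise ValueError(f"position {p} outside 1..128")  # unreachable for valid positions


def sort_positions(positions: Iterable[ImgtPosition]) -> list[ImgtPosition]:
    return sorted(positions, key=ImgtPosition.sort_key)


def extract_cdrs(residues: Mapping[ImgtPosition, str]) -> tuple[str, str, str]:
    """CDR1/CDR2/CDR3 strings from a position->residue map, in IMGT order.

    Accepts the map directly or any object with a ``residues`` attribute.
    Empty string when no positions fall in a span.
    """
    if hasattr(residues, "residues"):
        residues = residues.residues  # type: ignore[union-attr]
    buckets: dict[str, list[ImgtPosition]] = {"CDR1": [], "CDR2": [], "CDR3": []}
    for pos in residues:
        name = region_of(pos)
        if name in buckets:
            buckets[name].append(pos)
    out = []
    for name in ("CDR1", "CDR2", "CDR3"):
        out.append("".join(residues[p] for p in sort_positions(buckets[name])))
    return tuple(out)  # type: ignore[return-value]


def cdr3_ladder(length: int) -> list[ImgtPosition]:
    """IMGT CDR3 position list, in order, for a junction of ``length`` residues.

    Positions 105..117 are filled symmetrically (the left arm takes the extra
    slot for odd lengths); junctions longer than 13 add insertion codes at the
    loop apex, alternating between the 112 side and the 111 side starting with
    112 (length 14 adds 112A; 15 adds 112A and 111A; ...).
    """
    if length < 1:
        raise ValueError("CDR3 length must be >= 1")
    if length <= 13:
        n_left = (length + 1) // 2
        n_right = length // 2
        left = [ImgtPosition(105 + i) for i in range(n_left)]
        right = [ImgtPosition(117 - n_right + 1 + i) for i in range(n_right)]
        return left + right
    extra = length - 13
    n112 = (extra + 1) // 2
    n111 = extra // 2
    left = [ImgtPosition(n) for n in range(105, 112)]
    left += [ImgtPosition(111, i) for i in range(1, n111 + 1)]
    right = [ImgtPosition(112, i) for i in range(n112, 0, -1)]
    right += [ImgtPosition(n) for n in range(112, 118)]
    return left + right
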