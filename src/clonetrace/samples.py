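"""Sample identity and the experimental design grid.

Every measurement in a barcoding experiment is indexed by a *sample*: one
sorted blood population from one mouse at one bleed.  Four populations are
sorted (granulocytes as the myeloid readout, B cells, CD4 T and CD8 T cells)
at four post-transplantation time points (2.5, 3.5, 5.5 and 6.5 months), in
two experimental groups (HSC-only recipients and HSC + MPP co-transplanted
recipients).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class CellType(str, enum.Enum):
    """Sorted peripheral-blood populations."""

    GR = "Gr"
    B = "B"
    CD4T = "CD4T"
    CD8T = "CD8T"


class Group(str, enum.Enum):
    """Experimental arm: HSC-only vs HSC co-transplanted with MPPs."""

    HSC = "HSC"
    HSC_PLUS_MPP = "HSC+MPP"


#: Canonical cell-type order used for all matrix columns.
CELL_TYPES: tuple[str, ...] = tuple(ct.value for ct in CellType)

#: Myeloid readout: granulocytes are the only sorted myeloid population.
MYELOID: tuple[str, ...] = (CellType.GR.value,)

#: Lymphoid readout: B plus both T-cell populations.
LYMPHOID: tuple[str, ...] = (CellType.B.value, CellType.CD4T.value, CellType.CD8T.value)

#: T-cell populations, merged into "T" for cell-type-combination labels.
T_CELLS: tuple[str, ...] = (CellType.CD4T.value, CellType.CD8T.value)

#: Months post-transplantation at which blood was collected.
DEFAULT_TIMEPOINTS: tuple[float, ...] = (2.5, 3.5, 5.5, 6.5)

_GROUP_ALIASES = {
    "HSC": Group.HSC,
    "HSC+MPP": Group.HSC_PLUS_MPP,
    "HSC_plus_MPP": Group.HSC_PLUS_MPP,
    "HSC(+MPP)": Group.HSC_PLUS_MPP,
}


def parse_group(token: str) -> Group:
    try:
        return _GROUP_ALIASES[token]
    except KeyError:
        raise ValueError(f"unknown group token {token!r}; expected one of {sorted(_GROUP_ALIASES)}") from None


def parse_cell_type(token: str) -> CellType:
    try:
        return CellType(token)
    except ValueError:
        raise ValueError(f"unknown cell-type token {token!r}; expected one of {CELL_TYPES}") from None


def format_timepoint(timepoint: float) -> str:
    return f"{timepoint:g}"


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one sorted sample: mouse, group, population, time point."""

    mouse: str
    group: Group
    cell_type: CellType
    timepoint: float

    def __post_init__(self) -> None:
        if self.timepoint <= 0:
            raise ValueError(f"timepoint must be positive, got {self.timepoint}")

    def token(self) -> str:
        """Serialize as the ``mouse:group:celltype:timepoint`` column header."""
        return ":".join(
            (self.mouse, self.group.value, self.cell_type.value, format_timepoint(self.timepoint))
        )

    @classmethod
    def parse(cls, token: str) -> "SampleKey":
        parts = token.split(":")
        if len(parts) != 4:
            raise ValueError(
                f"malformed sample header {token!r}: expected 'mouse:group:celltype:timepoint'"
            )
        mouse, group, cell_type, timepoint = parts
        if not mouse:
            raise ValueError(f"malformed sample header {token!r}: empty mouse id")
        try:
            tp = float(timepoint)
        except ValueError:
            raise ValueError(f"malformed sample header {token!r}: bad timepoint {timepoint!r}") from None
        return cls(mouse=mouse, group=parse_group(group), cell_type=parse_cell_type(cell_type), timepoint=tp)
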