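"""In-memory containers for barcode counts, flow fractions and clonal abundance.

A *clone* is the set of blood cells descended from one barcoded HSC and is
identified by the pair ``(barcode, mouse)``: barcodes mark independent
transduction events, so the same sequence observed in two mice is two clones.

``ClonalAbundanceMatrix`` is the pipeline's central object: per-clone blood
contribution in percent of all white blood cells (%WBC), laid out as clones ×
(cell type, time point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .samples import CELL_TYPES, SampleKey, parse_cell_type, parse_group

logger = logging.getLogger(__name__)

#: Column-level names of a sample axis (count tables).
SAMPLE_LEVELS = ("mouse", "group", "cell_type", "timepoint")

#: Column-level names of a per-clone profile (abundance matrices).
PROFILE_LEVELS = ("cell_type", "timepoint")


def _canonical_profile_columns(columns: pd.MultiIndex) -> pd.MultiIndex:
    cts = [ct for ct in CELL_TYPES if ct in columns.get_level_values("cell_type")]
    tps = sorted(set(columns.get_level_values("timepoint")))
    return pd.MultiIndex.from_product([cts, tps], names=PROFILE_LEVELS)


@dataclass
class BarcodeCountTable:
    """Integer read counts per barcode per sorted sample.

    ``counts``: DataFrame indexed by barcode sequence, columns a MultiIndex
    with levels (mouse, group, cell_type, timepoint).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.counts.columns
        if not isinstance(cols, pd.MultiIndex) or tuple(cols.names) != SAMPLE_LEVELS:
            raise ValueError(f"count columns must be a MultiIndex with levels {SAMPLE_LEVELS}")
        if len(cols) == 0:
            raise ValueError("no samples")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate barcode(s): {dupes}")
        if cols.duplicated().any():
            raise ValueError("duplicate sample columns")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    def sample_keys(self) -> list[SampleKey]:
        return [
            SampleKey(m, parse_group(g), parse_cell_type(ct), float(tp))
            for m, g, ct, tp in self.counts.columns
        ]

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class FlowSummary:
    """Per-sample flow-cytometry fractions feeding the abundance formula.

    ``table``: DataFrame indexed by (mouse, cell_type, timepoint) with columns
    ``group``, ``pop_frac_wbc`` (population share of WBCs), ``donor_frac``
    (donor chimerism of the population) and ``gfp_frac`` (GFP+ share of donor
    cells); all three fractions in [0, 1].
    """

    FRACTIONS = ("pop_frac_wbc", "donor_frac", "gfp_frac")

    table: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.table.index
        if not isinstance(idx, pd.MultiIndex) or tuple(idx.names) != ("mouse", "cell_type", "timepoint"):
            raise ValueError("flow table must be indexed by (mouse, cell_type, timepoint)")
        missing = [c for c in ("group", *self.FRACTIONS) if c not in self.table.columns]
        if missing:
            raise ValueError(f"flow table missing required column(s): {missing}")
        frac = self.table[list(self.FRACTIONS)].to_numpy(dtype=float)
        if (frac < 0).any() or (frac > 1).any():
            raise ValueError("flow fractions must lie in [0, 1]")
        if idx.duplicated().any():
            raise ValueError("duplicate flow rows")

    def fraction_product(self, mouse: str, cell_type: str, timepoint: float) -> float:
        """pop_frac_wbc x donor_frac x gfp_frac for one sample."""
        try:
            row = self.table.loc[(mouse, cell_type, timepoint)]
        except KeyError:
            raise KeyError(
                f"no flow-cytometry row for sample {mouse}:{cell_type}:{timepoint:g}"
            ) from None
        return float(row["pop_frac_wbc"] * row["donor_frac"] * row["gfp_frac"])


@dataclass
class ClonalAbundanceMatrix:
    """Per-clone %WBC abundance across all (cell type, time point) cells.

    ``abundance``: DataFrame indexed by (barcode, mouse), columns a MultiIndex
    with levels (cell_type, timepoint), values in percent of white blood
    cells.  ``groups`` maps each mouse to its experimental-group label.  Every
    mouse carries the full (cell type x time point) grid; an unmeasured or
    empty sample is all zeros.
    """

    abundance: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = self.abundance.columns
        if not isinstance(cols, pd.MultiIndex) or tuple(cols.names) != PROFILE_LEVELS:
            raise ValueError(f"abundance columns must be a MultiIndex with levels {PROFILE_LEVELS}")
        idx = self.abundance.index
        if not isinstance(idx, pd.MultiIndex) or tuple(idx.names) != ("barcode", "mouse"):
            raise ValueError("abundance must be indexed by (barcode, mouse)")
        if idx.duplicated().any():
            raise ValueError("duplicate (barcode, mouse) clones")
        values = self.abundance.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("abundance must be non-negative")
        if not np.isfinite(values).all():
            raise ValueError("abundance must be finite")
        # fix a canonical column order so serialization is deterministic
        self.abundance = self.abundance.reindex(columns=_canonical_profile_columns(cols), fill_value=0.0)
        missing = set(self.mice) - set(self.groups)
        if missing:
            raise ValueError(f"no group recorded for mice: {sorted(missing)}")

    # -- views ---------------------------------------------------------------

    @property
    def mice(self) -> list[str]:
        return sorted(set(self.abundance.index.get_level_values("mouse")))

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.abundance.columns.get_level_values("cell_type")))

    @property
    def timepoints(self) -> list[float]:
        return sorted(set(self.abundance.columns.get_level_values("timepoint")))

    @property
    def n_clones(self) -> int:
        return len(self.abundance)

    def for_mouse(self, mouse: str) -> pd.DataFrame:
        """Barcode x (cell_type, timepoint) block of one mouse."""
        return self.abundance.xs(mouse, level="mouse")

    def at_timepoint(self, timepoint: float) -> pd.DataFrame:
        """Clone x cell_type slice at one time point."""
        return self.abundance.xs(timepoint, level="timepoint", axis=1)

    def sample_totals(self) -> pd.Series:
        """Summed abundance per (mouse, cell_type, timepoint) sample."""
        total = self.abundance.groupby(level="mouse").sum()
        return total.stack(list(PROFILE_LEVELS), future_stack=True)

    def drop_clones(self, clones: Iterable[tuple[str, str]]) -> "ClonalAbundanceMatrix":
        keep = ~self.abundance.index.isin(list(clones))
        return ClonalAbundanceMatrix(self.abundance.loc[keep].copy(), dict(self.groups))

    # -- long-format conversion ----------------------------------------------

    def to_long(self) -> pd.DataFrame:
        long = (
            self.abundance.stack(list(PROFILE_LEVELS), future_stack=True)
            .rename("abundance_pct_wbc")
            .reset_index()
        )
        long["group"] = long["mouse"].map(self.groups)
        return long[["barcode", "mouse", "group", "cell_type", "timepoint", "abundance_pct_wbc"]]

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "ClonalAbundanceMatrix":
        required = {"barcode", "mouse", "group", "cell_type", "timepoint", "abundance_pct_wbc"}
        missing = required - set(long.columns)
        if missing:
            raise ValueError(f"long-format abundance missing column(s): {sorted(missing)}")
        groups = (
            long.drop_duplicates("mouse").set_index("mouse")["group"].astype(str).to_dict()
        )
        wide = long.pivot_table(
            index=["barcode", "mouse"],
            columns=["cell_type", "timepoint"],
            values="abundance_pct_wbc",
            fill_value=0.0,
            aggfunc="sum",
        )
        wide.columns.names = PROFILE_LEVELS
        return cls(wide, groups)


def assemble_abundance(
    per_sample: Mapping[tuple[str, str, str, float], pd.Series],
    groups: Mapping[str, str],
    membership: Mapping[str, pd.Series] | None = None,
) -> ClonalAbundanceMatrix:
    """Build a clone-major matrix from per-sample abundance vectors.

    ``per_sample`` maps (mouse, group, cell_type, timepoint) to a Series of
    %WBC abundance indexed by barcode.  ``membership`` optionally gives a
    boolean Series per mouse saying which barcodes are that mouse's clones;
    by default a clone belongs to a mouse iff it has positive abundance in at
    least one of that mouse's samples.
    """
    by_mouse: dict[str, dict[tuple[str, float], pd.Series]] = {}
    for (mouse, _group, cell_type, timepoint), series in per_sample.items():
        by_mouse.setdefault(mouse, {})[(cell_type, float(timepoint))] = series

    blocks = []
    for mouse in sorted(by_mouse):
        block = pd.DataFrame(by_mouse[mouse])
        block.columns.names = PROFILE_LEVELS
        if membership is not None:
            member = membership[mouse].reindex(block.index, fill_value=False)
        else:
            member = block.sum(axis=1) > 0
        block = block.loc[member]
        block.index = pd.MultiIndex.from_arrays(
            [block.index, [mouse] * len(block)], names=("barcode", "mouse")
        )
        blocks.append(block)
    if not blocks:
        raise ValueError("no samples to assemble")
    wide = pd.concat(blocks).fillna(0.0)
    return ClonalAbundanceMatrix(wide, dict(groups))
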