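"""Clonal abundance quantification and artifact filtering.

The clonal abundance of a barcode in one sorted sample, in percent of all
white blood cells, is

    abundance = 100% x pop_frac_wbc x donor_frac x gfp_frac x reads / total_reads

i.e. the sample's GFP+ donor share of WBCs partitioned among barcodes by
their read fractions.  Because read fractions sum to one, per-sample
abundance totals equal ``100 x pop_frac_wbc x donor_frac x gfp_frac``
exactly — the conservation law the tests assert.

A clone that exceeds 0.5 %WBC in exactly one (cell type, time point) cell of
a mouse while being absent everywhere else in that mouse is treated as a
single-cell sampling/PCR artifact and removed.  "Absent" is below the
measurability floor (0.01 %WBC by default, the same floor the classifiers
use).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    BarcodeCountTable,
    ClonalAbundanceMatrix,
    FlowSummary,
    assemble_abundance,
)

logger = logging.getLogger(__name__)

#: Spike-artifact removal threshold, %WBC.
DEFAULT_SPIKE_THRESHOLD = 0.5
#: Measurability floor, %WBC; abundance below this counts as "absent".
DEFAULT_ABSENCE_THRESHOLD = 0.01

__all__ = [
    "compute_clonal_abundance",
    "filter_spurious_clones",
    "DEFAULT_SPIKE_THRESHOLD",
    "DEFAULT_ABSENCE_THRESHOLD",
]


def compute_clonal_abundance(counts: BarcodeCountTable, flow: FlowSummary) -> ClonalAbundanceMatrix:
    """Combine barcode read counts with flow fractions into %WBC abundance.

    Every count column must have a matching flow row (KeyError names the
    offending sample otherwise).  A sample with zero total reads yields
    all-zero abundance and a logged warning.  A clone belongs to a mouse iff
    it has at least one read in that mouse.
    """
    per_sample: dict[tuple[str, str, str, float], pd.Series] = {}
    groups: dict[str, str] = {}
    for (mouse, group, cell_type, timepoint), column in counts.counts.items():
        timepoint = float(timepoint)
        factor = 100.0 * flow.fraction_product(mouse, cell_type, timepoint)
        total = int(column.sum())
        if total == 0:
            logger.warning(
                "sample %s:%s:%g has zero total reads; abundance set to zero", mouse, cell_type, timepoint
            )
            abundance = pd.Series(0.0, index=column.index)
        else:
            abundance = factor * column.astype(float) / total
        per_sample[(mouse, group, cell_type, timepoint)] = abundance
        groups[mouse] = group

    # membership: a clone belongs to a mouse iff it has >= 1 read there (not
    # >= 1 abundance: a zero flow fraction must not silently drop clones)
    membership = {
        mouse: counts.counts.xs(mouse, level="mouse", axis=1).sum(axis=1) > 0
        for mouse in {m for m, *_ in per_sample}
    }
    return assemble_abundance(per_sample, groups, membership=membership)


def filter_spurious_clones(
    matrix: ClonalAbundanceMatrix,
    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD,
    absence_threshold: float = DEFAULT_ABSENCE_THRESHOLD,
) -> tuple[ClonalAbundanceMatrix, list[tuple[str, str]]]:
    """Remove single-cell spike artifacts; return (filtered matrix, removed clones).

    A clone is removed iff, within its mouse, its abundance exceeds
    ``spike_threshold`` in exactly one (cell type, time point) cell and is at
    or below ``absence_threshold`` in every other cell.  Evaluated per clone
    independently, so the filter is idempotent.
    """
    if spike_threshold < 0 or absence_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    values = matrix.abundance.to_numpy(dtype=float)
    if values.size == 0:
        return matrix, []
    above = values > spike_threshold
    n_above = above.sum(axis=1)
    elsewhere = np.where(above, -np.inf, values)
    elsewhere_max = elsewhere.max(axis=1)
    removed_mask = (n_above == 1) & (elsewhere_max <= absence_threshold)
    removed = [tuple(idx) for idx in matrix.abundance.index[removed_mask]]
    if removed:
        logger.info("spike filter removed %d clone(s)", len(removed))
    return matrix.drop_clones(removed), removed
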