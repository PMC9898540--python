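"""On-disk formats: count-table TSV, flow-summary CSV, abundance TSV, toy FASTQ.

Count tables are flat TSVs: first column the barcode sequence, remaining
columns one sample each, headed by the colon-delimited token
``mouse:group:celltype:timepoint`` (e.g. ``m1:HSC:Gr:2.5``).  Flow summaries
are CSVs with one row per sample.  Abundance matrices round-trip through a
long-format TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import SAMPLE_LEVELS, BarcodeCountTable, ClonalAbundanceMatrix, FlowSummary
from .samples import SampleKey, parse_cell_type, parse_group

logger = logging.getLogger(__name__)

__all__ = [
    "read_barcode_counts",
    "write_barcode_counts",
    "read_flow_summary",
    "write_flow_summary",
    "read_abundance",
    "write_abundance",
    "count_barcodes_from_reads",
]


# --------------------------------------------------------------------------
# barcode count tables
# --------------------------------------------------------------------------

def read_barcode_counts(path: str | Path) -> BarcodeCountTable:
    """Read a barcode x sample count TSV into a validated table.

    Raises ``ValueError`` on duplicate barcodes, malformed sample headers,
    negative or non-integer counts, or a file with no sample columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("no samples")
    df = df.set_index(df.columns[0])
    df.index.name = "barcode"
    keys = [SampleKey.parse(str(col)) for col in df.columns]
    df.columns = pd.MultiIndex.from_tuples(
        [(k.mouse, k.group.value, k.cell_type.value, k.timepoint) for k in keys],
        names=SAMPLE_LEVELS,
    )
    return BarcodeCountTable(df)


def write_barcode_counts(table: BarcodeCountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.columns = [key.token() for key in table.sample_keys()]
    out.to_csv(path, sep="\t", index_label="barcode")


# --------------------------------------------------------------------------
# flow-cytometry summaries
# --------------------------------------------------------------------------

_FLOW_COLUMNS = ("mouse", "group", "cell_type", "timepoint", "pop_frac_wbc", "donor_frac", "gfp_frac")


def read_flow_summary(path: str | Path) -> FlowSummary:
    """Read the per-sample flow-fraction CSV.

    Each fraction column may be given either as a fraction in [0, 1] or as a
    percentage in (1, 100]; the percent dialect is detected per column and
    divided by 100 with a logged warning.  Values outside [0, 100] are
    rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in _FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"flow summary missing required column(s): {missing}")
    for col in FlowSummary.FRACTIONS:
        values = df[col].astype(float)
        if (values < 0).any() or (values > 100).any():
            raise ValueError(f"column {col!r} has values outside [0, 100]")
        if (values > 1).any():
            logger.warning("column %r looks like percentages; dividing by 100", col)
            values = values / 100.0
        df[col] = values
    df["cell_type"] = [parse_cell_type(ct).value for ct in df["cell_type"].astype(str)]
    df["group"] = [parse_group(g).value for g in df["group"].astype(str)]
    df["timepoint"] = df["timepoint"].astype(float)
    table = df.set_index(["mouse", "cell_type", "timepoint"])[["group", *FlowSummary.FRACTIONS]]
    return FlowSummary(table)


def write_flow_summary(flow: FlowSummary, path: str | Path) -> None:
    flow.table.reset_index()[list(_FLOW_COLUMNS)].to_csv(path, index=False)


# --------------------------------------------------------------------------
# abundance matrices
# --------------------------------------------------------------------------

def write_abundance(matrix: ClonalAbundanceMatrix, path: str | Path) -> None:
    """Write a long-format abundance TSV (12 significant digits)."""
    matrix.to_long().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_abundance(path: str | Path) -> ClonalAbundanceMatrix:
    long = pd.read_csv(path, sep="\t", dtype={"barcode": str, "mouse": str})
    return ClonalAbundanceMatrix.from_long(long)


# --------------------------------------------------------------------------
# toy-FASTQ barcode counting
# --------------------------------------------------------------------------

def _hamming_matrix(window: str, whitelist_u8: np.ndarray) -> np.ndarray:
    query = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    return (whitelist_u8 != query).sum(axis=1)


def count_barcodes_from_reads(
    reads: str | Path | Iterable,
    whitelist: Sequence[str],
    flank: str,
    max_mismatch: int = 1,
) -> tuple[pd.Series, int]:
    """Assign reads to whitelist barcodes by Hamming match after a flank anchor.

    The barcode window starts immediately after the first occurrence of
    ``flank`` in the read.  A read is assigned to the unique whitelist entry
    within Hamming distance <= ``max_mismatch``; reads with no anchor, a
    truncated window, no match, or a tie at the minimal distance are
    discarded.  Matching is substitution-only: the barcodes are fixed-length
    lentiviral library inserts, so indels are not modelled.

    Returns ``(counts, n_discarded)`` where ``counts`` is indexed by the
    whitelist in its given order; assigned + discarded equals the number of
    input reads.
    """
    if len(whitelist) == 0:
        raise ValueError("empty whitelist")
    lengths = {len(b) for b in whitelist}
    if len(lengths) != 1:
        raise ValueError(f"whitelist barcodes have mixed lengths: {sorted(lengths)}")
    if len(set(whitelist)) != len(whitelist):
        raise ValueError("duplicate whitelist barcodes")
    bc_len = lengths.pop()
    whitelist_u8 = np.array(
        [np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8) for b in whitelist]
    )

    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        records: Iterable = SeqIO.parse(str(reads), "fastq")
    else:
        records = reads

    counts = pd.Series(0, index=pd.Index(list(whitelist), name="barcode"), dtype=np.int64)
    discarded = 0
    flank = flank.upper()
    for record in records:
        seq = str(getattr(record, "seq", record)).upper()
        start = seq.find(flank)
        if start < 0:
            discarded += 1
            continue
        window = seq[start + len(flank) : start + len(flank) + bc_len]
        if len(window) < bc_len:
            discarded += 1
            continue
        dists = _hamming_matrix(window, whitelist_u8)
        best = int(dists.min())
        if best > max_mismatch or int((dists == best).sum()) != 1:
            discarded += 1  # no match, or ambiguous tie between whitelist entries
            continue
        counts.iloc[int(dists.argmin())] += 1
    return counts, discarded


def counts_to_table(counts: pd.Series, sample: SampleKey) -> BarcodeCountTable:
    """Wrap a single-sample barcode count vector as a one-column count table."""
    df = counts.to_frame()
    df.columns = pd.MultiIndex.from_tuples(
        [(sample.mouse, sample.group.value, sample.cell_type.value, sample.timepoint)],
        names=SAMPLE_LEVELS,
    )
    return BarcodeCountTable(df)
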