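"""Categorical clone labels: lineage bias, temporal class, expansion dynamics.

All labels derive from a small set of thresholds:

* a clone *produces* a cell type at a time point when its abundance reaches
  the measurability floor (>= 0.01 %WBC, inclusive);
* a clone is *high-abundance* in a cell when its abundance is strictly above
  0.05 %WBC;
* a clone is *lineage-biased* toward myeloid (Gr) or lymphoid (B + CD4 T +
  CD8 T) when its relative copy number in one lineage exceeds
  cot(22.5 deg) = 1 + sqrt(2) ~ 2.4142 times the other's, and
  *lineage-specialized* when it is measurable in only one lineage;
* a clone is *early* / *late* / *persisted* according to production at the
  2.5- and/or 6.5-month reference time points, and a persisted T-cell clone
  is *expanded* or *shrunken* by whether its 6.5:2.5 production ratio is
  above or below one.

"Relative copy number" in a lineage is the clone's summed abundance over the
lineage's cell types divided by the total of all clones over those cell
types in the same mouse, which makes the fold rule invariant to the absolute
sizes of the myeloid and lymphoid compartments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ClonalAbundanceMatrix
from .samples import LYMPHOID, MYELOID, T_CELLS, CellType

logger = logging.getLogger(__name__)

#: Fold threshold of the bias rule: cotangent of 22.5 degrees = 1 + sqrt(2).
COT_22_5 = 1.0 + math.sqrt(2.0)

LINEAGE_BIAS_LABELS = (
    "myeloid_specialized",
    "myeloid_biased",
    "balanced",
    "lymphoid_biased",
    "lymphoid_specialized",
    "undetected",
)
BT_BIAS_LABELS = (
    "B_specialized",
    "B_biased",
    "BT_balanced",
    "T_biased",
    "T_specialized",
    "not_applicable",
)
TEMPORAL_LABELS = ("early", "late", "persisted", "neither")
DYNAMICS_LABELS = ("expanded", "shrunken", "tie", "not_applicable")
OVERLAP_CATEGORIES = ("multilineage", "myeloid_specialized", "lymphoid_specialized", "undetected")


@dataclass(frozen=True)
class BiasParameters:
    """Thresholds and reference time points of the classification scheme.

    fold_threshold
        Bias fold rule; defaults to cot(22.5 deg) (printed as 2.4142).
    detect_floor
        Measurability floor in %WBC (inclusive), shared by production,
        specialization and the temporal classes.
    high_abundance_floor
        High-abundance threshold in %WBC (exclusive: strictly above).
    early_timepoint / late_timepoint
        Reference months for temporal and dynamics classes; 2.5 and 6.5
        because blood production was similar at 5.5 and 6.5 months.
    relative
        If True (default), bias compares lineage-normalized relative copy
        numbers; if False, raw summed %WBC abundances.
    """

    fold_threshold: float = COT_22_5
    detect_floor: float = 0.01
    high_abundance_floor: float = 0.05
    early_timepoint: float = 2.5
    late_timepoint: float = 6.5
    relative: bool = True

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.detect_floor < 0 or self.high_abundance_floor < 0:
            raise ValueError("floors must be non-negative")


def detect_produced_types(matrix: ClonalAbundanceMatrix, params: BiasParameters) -> pd.DataFrame:
    """Boolean clone x (cell_type, timepoint) presence: abundance >= detect_floor."""
    return matrix.abundance >= params.detect_floor


def combination_label(presence: pd.DataFrame, timepoint: float) -> pd.Series:
    """Cell-type-combination label at one time point, CD4 T / CD8 T merged as T.

    Returns one of the seven non-empty subsets of {Gr, B, T}, rendered as
    e.g. ``"Gr+T"``; clones producing nothing at the time point are dropped.
    """
    at_tp = presence.xs(timepoint, level="timepoint", axis=1)
    merged = pd.DataFrame(
        {
            "Gr": at_tp[CellType.GR.value],
            "B": at_tp[CellType.B.value],
            "T": at_tp[list(T_CELLS)].any(axis=1),
        }
    )
    labels = merged.apply(lambda row: "+".join(t for t in ("Gr", "B", "T") if row[t]), axis=1)
    return labels[labels != ""]


def relative_copy_number(
    matrix: ClonalAbundanceMatrix, lineage: Sequence[str], timepoint: float
) -> pd.Series:
    """Clone's share of its mouse's total abundance summed over a lineage.

    Returns zero for every clone of a mouse whose lineage total is zero.
    """
    if len(lineage) == 0:
        raise ValueError("lineage must be non-empty")
    at_tp = matrix.at_timepoint(timepoint)
    summed = at_tp[list(lineage)].sum(axis=1)
    totals = summed.groupby(level="mouse").transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        rcn = summed / totals
    return rcn.fillna(0.0)


def _lineage_sums(matrix: ClonalAbundanceMatrix, lineage: Sequence[str], timepoint: float) -> pd.Series:
    return matrix.at_timepoint(timepoint)[list(lineage)].sum(axis=1)


def _bias_labels(
    matrix: ClonalAbundanceMatrix,
    params: BiasParameters,
    timepoint: float,
    lineage_a: Sequence[str],
    lineage_b: Sequence[str],
    labels: tuple[str, str, str, str, str, str],
) -> pd.Series:
    """Shared specialization-then-fold logic for both bias axes.

    ``labels`` = (a_specialized, a_biased, balanced, b_biased, b_specialized,
    undetected).  Specialization takes precedence: a clone measurable in only
    one of the two lineages is that lineage's specialized class regardless of
    copy numbers.
    """
    at_tp = matrix.at_timepoint(timepoint)
    meas_a = (at_tp[list(lineage_a)] >= params.detect_floor).any(axis=1)
    meas_b = (at_tp[list(lineage_b)] >= params.detect_floor).any(axis=1)
    if params.relative:
        a = relative_copy_number(matrix, lineage_a, timepoint)
        b = relative_copy_number(matrix, lineage_b, timepoint)
    else:
        a = _lineage_sums(matrix, lineage_a, timepoint)
        b = _lineage_sums(matrix, lineage_b, timepoint)

    a_spec, a_biased, balanced, b_biased, b_spec, undetected = labels
    out = pd.Series(undetected, index=at_tp.index, dtype=object)
    out[meas_a & ~meas_b] = a_spec
    out[meas_b & ~meas_a] = b_spec
    both = meas_a & meas_b
    f = params.fold_threshold
    out[both & (a > f * b)] = a_biased
    out[both & (b > f * a)] = b_biased
    out[both & ~(a > f * b) & ~(b > f * a)] = balanced
    return out


def classify_lineage_bias(
    matrix: ClonalAbundanceMatrix, params: BiasParameters, timepoint: float
) -> pd.Series:
    """Myeloid-vs-lymphoid bias label per clone at one time point."""
    return _bias_labels(
        matrix,
        params,
        timepoint,
        MYELOID,
        LYMPHOID,
        (
            "myeloid_specialized",
            "myeloid_biased",
            "balanced",
            "lymphoid_biased",
            "lymphoid_specialized",
            "undetected",
        ),
    )


def classify_bt_bias(
    matrix: ClonalAbundanceMatrix, params: BiasParameters, timepoint: float
) -> pd.Series:
    """B-vs-T bias label per clone at one time point (T = CD4 T + CD8 T).

    Clones measurable in neither B nor T are ``not_applicable``.
    """
    return _bias_labels(
        matrix,
        params,
        timepoint,
        (CellType.B.value,),
        T_CELLS,
        ("B_specialized", "B_biased", "BT_balanced", "T_biased", "T_specialized", "not_applicable"),
    )


def flag_high_abundance(matrix: ClonalAbundanceMatrix, params: BiasParameters) -> pd.DataFrame:
    """Boolean clone x (cell_type, timepoint): abundance strictly above the floor."""
    return matrix.abundance > params.high_abundance_floor


def classify_temporal(
    presence: pd.DataFrame, params: BiasParameters, cell_type: str | None = None
) -> pd.Series:
    """Early / late / persisted / neither per clone.

    With ``cell_type`` given, presence of that population alone is used; with
    ``cell_type=None``, a clone counts as producing blood when any of the
    four populations is present (the overall reading of "produced blood
    cells").
    """
    if cell_type is None:
        early = presence.xs(params.early_timepoint, level="timepoint", axis=1).any(axis=1)
        late = presence.xs(params.late_timepoint, level="timepoint", axis=1).any(axis=1)
    else:
        early = presence[(cell_type, params.early_timepoint)]
        late = presence[(cell_type, params.late_timepoint)]
    out = pd.Series("neither", index=presence.index, dtype=object)
    out[early & ~late] = "early"
    out[late & ~early] = "late"
    out[early & late] = "persisted"
    return out


def classify_dynamics(
    matrix: ClonalAbundanceMatrix, params: BiasParameters, cell_type: str
) -> pd.Series:
    """Expanded / shrunken call for clones persisted in one T-cell population.

    The ratio of late to early production classifies a persisted clone as
    expanded (ratio > 1) or shrunken (ratio < 1); a ratio of exactly one is
    reported as ``tie``.  Clones not persisted in the population are
    ``not_applicable``; a persisted clone with zero early abundance has an
    undefined ratio and is excluded with a warning (possible only when the
    detection floor is zero).
    """
    if cell_type not in T_CELLS:
        raise ValueError(f"dynamics are defined for T-cell populations {T_CELLS}, got {cell_type!r}")
    early = matrix.abundance[(cell_type, params.early_timepoint)]
    late = matrix.abundance[(cell_type, params.late_timepoint)]
    persisted = (early >= params.detect_floor) & (late >= params.detect_floor)
    out = pd.Series("not_applicable", index=matrix.abundance.index, dtype=object)
    undefined = persisted & (early == 0)
    if undefined.any():
        logger.warning(
            "%d persisted clone(s) with zero early %s abundance excluded from dynamics",
            int(undefined.sum()),
            cell_type,
        )
    valid = persisted & ~undefined
    ratio = late[valid] / early[valid]
    out[valid & (ratio > 1).reindex(out.index, fill_value=False)] = "expanded"
    out[valid & (ratio < 1).reindex(out.index, fill_value=False)] = "shrunken"
    out[valid & (ratio == 1).reindex(out.index, fill_value=False)] = "tie"
    return out


def early_late_overlap(
    matrix: ClonalAbundanceMatrix, params: BiasParameters
) -> pd.DataFrame:
    """Late-time-point fate of clones detected at the early reference point.

    For every clone producing any blood at 2.5 months, tally its 6.5-month
    category: ``multilineage`` (measurable in both lineages),
    ``myeloid_specialized``, ``lymphoid_specialized``, or ``undetected``.
    Returns per-mouse counts and fractions; fractions sum to one per mouse.
    """
    presence = detect_produced_types(matrix, params)
    early_detected = presence.xs(params.early_timepoint, level="timepoint", axis=1).any(axis=1)
    late = matrix.at_timepoint(params.late_timepoint)
    meas_m = (late[list(MYELOID)] >= params.detect_floor).any(axis=1)
    meas_l = (late[list(LYMPHOID)] >= params.detect_floor).any(axis=1)

    category = pd.Series("undetected", index=matrix.abundance.index, dtype=object)
    category[meas_m & meas_l] = "multilineage"
    category[meas_m & ~meas_l] = "myeloid_specialized"
    category[meas_l & ~meas_m] = "lymphoid_specialized"
    category = category[early_detected]

    rows = []
    for mouse, labels in category.groupby(level="mouse"):
        counts = labels.value_counts()
        n = int(counts.sum())
        for cat in OVERLAP_CATEGORIES:
            c = int(counts.get(cat, 0))
            rows.append(
                {"mouse": mouse, "category": cat, "count": c, "fraction": c / n if n else 0.0}
            )
    return pd.DataFrame(rows, columns=["mouse", "category", "count", "fraction"])


@dataclass
class CloneLabels:
    """Bundle of every per-clone categorical call plus a long-format view."""

    presence: pd.DataFrame
    high_abundance: pd.DataFrame
    combination: dict[float, pd.Series]
    lineage_bias: dict[float, pd.Series]
    bt_bias: dict[float, pd.Series]
    temporal: dict[str, pd.Series]          # keyed by cell type, "any" = overall
    dynamics: dict[str, pd.Series]          # keyed by T-cell type
    params: BiasParameters = field(default_factory=BiasParameters)

    def to_long(self) -> pd.DataFrame:
        rows = []

        def emit(axis: str, key, series: pd.Series) -> None:
            for (barcode, mouse), label in series.items():
                rows.append((barcode, mouse, axis, key, str(label)))

        for tp, series in self.combination.items():
            emit("combination", f"{tp:g}", series)
        for tp, series in self.lineage_bias.items():
            emit("lineage_bias", f"{tp:g}", series)
        for tp, series in self.bt_bias.items():
            emit("bt_bias", f"{tp:g}", series)
        for ct, series in self.temporal.items():
            emit("temporal", ct, series)
        for ct, series in self.dynamics.items():
            emit("dynamics", ct, series)
        ha = self.high_abundance
        for (barcode, mouse), row in ha.iterrows():
            for (ct, tp), flag in row.items():
                rows.append((barcode, mouse, "high_abundance", f"{ct}:{tp:g}", str(bool(flag))))
        return pd.DataFrame(rows, columns=["barcode", "mouse", "axis", "key", "label"])


def classify_all(
    matrix: ClonalAbundanceMatrix, params: BiasParameters | None = None
) -> CloneLabels:
    """Run every classifier at both reference time points."""
    params = params or BiasParameters()
    presence = detect_produced_types(matrix, params)
    ref_tps = (params.early_timepoint, params.late_timepoint)
    return CloneLabels(
        presence=presence,
        high_abundance=flag_high_abundance(matrix, params),
        combination={tp: combination_label(presence, tp) for tp in ref_tps},
        lineage_bias={tp: classify_lineage_bias(matrix, params, tp) for tp in ref_tps},
        bt_bias={tp: classify_bt_bias(matrix, params, tp) for tp in ref_tps},
        temporal={
            "any": classify_temporal(presence, params, None),
            **{ct.value: classify_temporal(presence, params, ct.value) for ct in CellType},
        },
        dynamics={ct: classify_dynamics(matrix, params, ct) for ct in T_CELLS},
        params=params,
    )
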