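"""Independent brute-force re-implementations used as test oracles.

Everything here loops over the definitions literally, clone by clone and
cell by cell, sharing no code with the package implementation.
"""

from clonetrace.samples import CELL_TYPES, LYMPHOID, MYELOID, T_CELLS


def filter_decision(clone_cells, spike_threshold, absence_threshold):
    """Literal two-clause spike rule for one clone: True = remove.

    ``clone_cells``: {(cell_type, timepoint): abundance} within one mouse.
    """
    above = [cell for cell, v in clone_cells.items() if v > spike_threshold]
    if len(above) != 1:
        return False
    for cell, v in clone_cells.items():
        if cell == above[0]:
            continue
        if v > absence_threshold:
            return False
    return True


def _measurable(clone_cells, lineage, timepoint, floor):
    return any(clone_cells[(ct, timepoint)] >= floor for ct in lineage)


def _rcn(block, barcode, lineage, timepoint):
    mine = sum(block[barcode][(ct, timepoint)] for ct in lineage)
    total = sum(sum(cells[(ct, timepoint)] for ct in lineage) for cells in block.values())
    return mine / total if total > 0 else 0.0


def bias_label(block, barcode, timepoint, params, lineage_a, lineage_b, names):
    """Literal specialization-then-fold rule for one clone.

    ``block``: {barcode: {(ct, tp): abundance}} for one mouse.  ``names`` =
    (a_spec, a_biased, balanced, b_biased, b_spec, undetected).
    """
    cells = block[barcode]
    a_meas = _measurable(cells, lineage_a, timepoint, params.detect_floor)
    b_meas = _measurable(cells, lineage_b, timepoint, params.detect_floor)
    if not a_meas and not b_meas:
        return names[5]
    if a_meas and not b_meas:
        return names[0]
    if b_meas and not a_meas:
        return names[4]
    if params.relative:
        a = _rcn(block, barcode, lineage_a, timepoint)
        b = _rcn(block, barcode, lineage_b, timepoint)
    else:
        a = sum(cells[(ct, timepoint)] for ct in lineage_a)
        b = sum(cells[(ct, timepoint)] for ct in lineage_b)
    if a > params.fold_threshold * b:
        return names[1]
    if b > params.fold_threshold * a:
        return names[3]
    return names[2]


def lineage_bias_label(block, barcode, timepoint, params):
    return bias_label(
        block,
        barcode,
        timepoint,
        params,
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


def bt_bias_label(block, barcode, timepoint, params):
    return bias_label(
        block,
        barcode,
        timepoint,
        params,
        ("B",),
        T_CELLS,
        ("B_specialized", "B_biased", "BT_balanced", "T_biased", "T_specialized", "not_applicable"),
    )


def combination(cells, timepoint, floor):
    present = []
    if cells[("Gr", timepoint)] >= floor:
        present.append("Gr")
    if cells[("B", timepoint)] >= floor:
        present.append("B")
    if cells[("CD4T", timepoint)] >= floor or cells[("CD8T", timepoint)] >= floor:
        present.append("T")
    return "+".join(present) if present else None


def temporal(cells, params, cell_type=None):
    cts = CELL_TYPES if cell_type is None else (cell_type,)
    early = any(cells[(ct, params.early_timepoint)] >= params.detect_floor for ct in cts)
    late = any(cells[(ct, params.late_timepoint)] >= params.detect_floor for ct in cts)
    if early and late:
        return "persisted"
    if early:
        return "early"
    if late:
        return "late"
    return "neither"


def dynamics(cells, params, cell_type):
    early = cells[(cell_type, params.early_timepoint)]
    late = cells[(cell_type, params.late_timepoint)]
    if early < params.detect_floor or late < params.detect_floor:
        return "not_applicable"
    ratio = late / early
    if ratio > 1:
        return "expanded"
    if ratio < 1:
        return "shrunken"
    return "tie"


def matrix_to_blocks(matrix):
    """{mouse: {barcode: {(ct, tp): value}}} from a ClonalAbundanceMatrix."""
    blocks = {}
    for (barcode, mouse), row in matrix.abundance.iterrows():
        blocks.setdefault(mouse, {})[barcode] = {
            (ct, tp): float(v) for (ct, tp), v in row.items()
        }
    return blocks


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration, for n <= 8)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, part in enumerate(partition):
            yield partition[:i] + [part + [first]] + partition[i + 1 :]
        yield partition + [[first]]


def modularity(graph, partition, resolution=1.0):
    """Textbook weighted modularity of a node partition."""
    m2 = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True)) * 2.0
    if m2 == 0:
        return 0.0
    degree = {
        n: sum(d.get("weight", 1.0) for _, _, d in graph.edges(n, data=True)) for n in graph
    }
    q = 0.0
    for part in partition:
        for i in part:
            for j in part:
                w = graph.get_edge_data(i, j, {}).get("weight", 0.0) if i != j else 0.0
                q += w - resolution * degree[i] * degree[j] / m2
    return q / m2


def term_category(detected_fracs, timepoints):
    """Literal majority rule for one cluster; fracs keyed by timepoint."""
    if detected_fracs.get(6.5, 0.0) >= 0.5:
        return "long_term"
    if detected_fracs.get(2.5, 0.0) >= 0.5:
        return "short_term"
    if detected_fracs.get(5.5, 0.0) >= 0.5:
        return "middle_term"
    best = max(timepoints, key=lambda tp: (detected_fracs[tp], tp))
    return {2.5: "short_term", 5.5: "middle_term", 6.5: "long_term"}[best]
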