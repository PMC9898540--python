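"""In-silico barcoding experiments with known ground truth.

The generator emulates the measurement chain of a lentiviral-barcoding
transplantation study.  Each mouse carries a mixture of clone *archetypes*
(short-/middle-/long-term output, myeloid/lymphoid specialization, T-cell
bias, expanding T production).  A clone's true %WBC trajectory is its
archetype's mean profile perturbed by multiplicative lognormal clone noise;
sequencing then draws reads multinomially from the clones' relative
abundances at a fixed depth, and flow-cytometry fractions are emitted so
that the abundance formula reconstructs the planted trajectories (the three
fractions are jointly consistent with each sample's true clonal total).

The HSC+MPP group differs from the HSC-only group in two planted ways:
CD4 T / CD8 T mean production is multiplied by ``mpp_effect`` from 5.5
months on, and mixture weight shifts from short-term toward middle/long-term
archetypes.  Spike artifacts — clones above 0.5 %WBC in exactly one cell and
absent everywhere else — are injected at a configurable rate and flagged in
the ground truth, giving the artifact filter a sharp recall test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import BiasParameters, classify_all
from .containers import (
    PROFILE_LEVELS,
    SAMPLE_LEVELS,
    BarcodeCountTable,
    ClonalAbundanceMatrix,
    FlowSummary,
)
from .samples import CELL_TYPES, DEFAULT_TIMEPOINTS, T_CELLS, Group

logger = logging.getLogger(__name__)

__all__ = [
    "ArchetypeSpec",
    "SimulationConfig",
    "SyntheticGroundTruth",
    "default_archetypes",
    "recovery_archetypes",
    "generate_dataset",
    "generate_toy_reads",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """One clone phenotype: mean %WBC trajectory plus its nominal classes.

    ``means`` maps cell type -> tuple of mean abundances on the time grid.
    The class annotations (``lineage_bias`` at the early reference point,
    ``temporal`` overall, ``dynamics`` for the T-cell populations) are what a
    noise-free simulation classifies the archetype as under the default
    mixture; recovery tests use per-clone truth trajectories instead.
    ``weights`` gives the mixture weight per experimental group.
    """

    name: str
    means: Mapping[str, tuple[float, ...]]
    lineage_bias: str
    temporal: str
    dynamics: str
    weights: Mapping[str, float]

    def mean_array(self, timepoints: Sequence[float]) -> np.ndarray:
        """(cell_type x timepoint) mean matrix in canonical order."""
        arr = np.zeros((len(CELL_TYPES), len(timepoints)))
        for i, ct in enumerate(CELL_TYPES):
            values = self.means.get(ct)
            if values is None:
                continue
            if len(values) != len(timepoints):
                raise ValueError(
                    f"archetype {self.name!r}: {len(values)} means for {len(timepoints)} timepoints"
                )
            arr[i] = values
        if (arr < 0).any():
            raise ValueError(f"archetype {self.name!r} has negative means")
        return arr


def default_archetypes() -> list[ArchetypeSpec]:
    """Seven archetypes spanning the phenotypes the classifiers distinguish.

    Means are %WBC on the (2.5, 3.5, 5.5, 6.5)-month grid, sized so that a
    200-clone mouse yields realistic per-sample totals (a few %WBC) while
    every intentionally produced cell stays at least twice the 0.01 %WBC
    measurability floor.  Intentionally absent cells are exactly zero.  The
    HSC+MPP weights shift mass from the short-term archetype toward
    middle/long-term and expanding-T phenotypes.
    """
    H, M = Group.HSC.value, Group.HSC_PLUS_MPP.value
    return [
        ArchetypeSpec(
            "short_term_multilineage",
            {
                "Gr": (0.07, 0.05, 0.0, 0.0),
                "B": (0.07, 0.05, 0.0, 0.0),
                "CD4T": (0.035, 0.025, 0.0, 0.0),
                "CD8T": (0.035, 0.025, 0.0, 0.0),
            },
            lineage_bias="balanced",
            temporal="early",
            dynamics="not_applicable",
            weights={H: 0.25, M: 0.15},
        ),
        ArchetypeSpec(
            "middle_term",
            {
                "Gr": (0.0, 0.0, 0.05, 0.0),
                "B": (0.0, 0.0, 0.05, 0.0),
                "CD4T": (0.0, 0.0, 0.025, 0.0),
                "CD8T": (0.0, 0.0, 0.025, 0.0),
            },
            lineage_bias="undetected",
            temporal="neither",
            dynamics="not_applicable",
            weights={H: 0.10, M: 0.12},
        ),
        ArchetypeSpec(
            "long_term_balanced",
            {
                "Gr": (0.08, 0.075, 0.07, 0.065),
                "B": (0.035, 0.045, 0.055, 0.06),
                "CD4T": (0.08, 0.06, 0.03, 0.02),
                "CD8T": (0.08, 0.06, 0.03, 0.02),
            },
            lineage_bias="balanced",
            temporal="persisted",
            dynamics="shrunken",
            weights={H: 0.25, M: 0.25},
        ),
        ArchetypeSpec(
            "long_term_myeloid_specialized",
            {"Gr": (0.11, 0.11, 0.10, 0.09)},
            lineage_bias="myeloid_specialized",
            temporal="persisted",
            dynamics="not_applicable",
            weights={H: 0.15, M: 0.13},
        ),
        ArchetypeSpec(
            "long_term_lymphoid_specialized",
            {
                "B": (0.07, 0.07, 0.07, 0.07),
                "CD4T": (0.02, 0.025, 0.045, 0.06),
                "CD8T": (0.02, 0.025, 0.045, 0.06),
            },
            lineage_bias="lymphoid_specialized",
            temporal="persisted",
            dynamics="expanded",
            weights={H: 0.10, M: 0.10},
        ),
        ArchetypeSpec(
            "long_term_T_biased",
            {
                "Gr": (0.02, 0.02, 0.02, 0.02),
                "B": (0.02, 0.02, 0.02, 0.02),
                "CD4T": (0.09, 0.08, 0.05, 0.034),
                "CD8T": (0.09, 0.08, 0.05, 0.034),
            },
            lineage_bias="lymphoid_biased",
            temporal="persisted",
            dynamics="shrunken",
            weights={H: 0.05, M: 0.07},
        ),
        ArchetypeSpec(
            "persisted_expanding_T",
            {
                "Gr": (0.06, 0.06, 0.05, 0.05),
                "B": (0.05, 0.05, 0.05, 0.05),
                "CD4T": (0.02, 0.03, 0.08, 0.12),
                "CD8T": (0.02, 0.03, 0.08, 0.12),
            },
            lineage_bias="balanced",
            temporal="persisted",
            dynamics="expanded",
            weights={H: 0.10, M: 0.18},
        ),
    ]


def recovery_archetypes(abundance: float = 0.15) -> list[ArchetypeSpec]:
    """Three well-separated archetypes for cluster-recovery experiments:
    short-only, middle-only and long-term multilineage output (present cells
    at ``abundance`` %WBC, absent cells zero — unbounded contrast)."""
    H, M = Group.HSC.value, Group.HSC_PLUS_MPP.value
    w = {H: 1 / 3, M: 1 / 3}
    flat = (abundance,) * 4
    off = (0.0,) * 4
    short = (abundance, abundance, 0.0, 0.0)
    middle = (0.0, 0.0, abundance, 0.0)
    return [
        ArchetypeSpec("short_only", {ct: short for ct in CELL_TYPES}, "balanced", "early", "not_applicable", w),
        ArchetypeSpec("middle_only", {ct: middle for ct in CELL_TYPES}, "undetected", "neither", "not_applicable", w),
        ArchetypeSpec("long_multilineage", {ct: flat for ct in CELL_TYPES}, "balanced", "persisted", "tie", w),
    ]


@dataclass
class SimulationConfig:
    """Study conditions of an in-silico experiment.

    Defaults mirror the study design: 5 HSC-only and 7 HSC+MPP mice, four
    sorted populations at 2.5/3.5/5.5/6.5 months, hundreds of clones per
    mouse, and a planted two-fold increase of late T-cell output in the
    HSC+MPP group.
    """

    n_mice: dict[str, int] = field(
        default_factory=lambda: {Group.HSC.value: 5, Group.HSC_PLUS_MPP.value: 7}
    )
    clones_per_mouse: int = 200
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    sigma: float = 0.5                 # lognormal clone-noise scale (log-e)
    depth: int = 100_000               # sequencing reads per sample
    flow_concentration: float = 500.0  # Beta concentration of flow-fraction noise
    mpp_effect: float = 2.0            # late T-cell mean multiplier, HSC+MPP group
    spike_artifact_rate: float = 0.02  # expected spike clones per real clone
    spike_abundance: tuple[float, float] = (0.6, 1.5)  # uniform range, %WBC
    barcode_length: int = 27
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    nominal_pop_frac: dict[str, float] = field(
        default_factory=lambda: {"Gr": 0.25, "B": 0.45, "CD4T": 0.20, "CD8T": 0.13}
    )
    nominal_donor_frac: float = 0.85
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 <= self.spike_artifact_rate <= 1:
            raise ValueError("spike_artifact_rate must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.mpp_effect <= 0:
            raise ValueError("mpp_effect must be positive")

    def null_variant(self) -> "SimulationConfig":
        """Both groups drawn from identical conditions (no planted effect):
        HSC mixture weights everywhere and ``mpp_effect`` = 1."""
        H = Group.HSC.value
        archetypes = [
            replace(a, weights={g: a.weights[H] for g in self.n_mice}) for a in self.archetypes
        ]
        return replace(self, archetypes=archetypes, mpp_effect=1.0)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        if "archetypes" in raw:
            raw["archetypes"] = [
                ArchetypeSpec(
                    name=a["name"],
                    means={ct: tuple(v) for ct, v in a["means"].items()},
                    lineage_bias=a.get("lineage_bias", "balanced"),
                    temporal=a.get("temporal", "persisted"),
                    dynamics=a.get("dynamics", "not_applicable"),
                    weights=a["weights"],
                )
                for a in raw["archetypes"]
            ]
        for key in ("timepoints", "spike_abundance"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticGroundTruth:
    """Per-clone truth: archetype, spike flag and pre-sequencing trajectory.

    ``info`` is indexed by (barcode, mouse) and carries the archetype name,
    its nominal class annotations and ``is_spike_artifact``.  ``labels`` are
    the reference classification labels obtained by running the classifiers
    on the noise-free (pre-sequencing) trajectories of the non-spike clones.
    ``true_abundance`` holds those trajectories for all clones.
    """

    info: pd.DataFrame
    true_abundance: ClonalAbundanceMatrix
    labels: pd.DataFrame

    def non_spike(self) -> pd.Index:
        return self.info.index[~self.info["is_spike_artifact"]]


def _truth_labels(truth_matrix: ClonalAbundanceMatrix, params: BiasParameters) -> pd.DataFrame:
    bundle = classify_all(truth_matrix, params)
    early, late = params.early_timepoint, params.late_timepoint
    out = pd.DataFrame(index=truth_matrix.abundance.index)
    out["lineage_bias_early"] = bundle.lineage_bias[early]
    out["lineage_bias_late"] = bundle.lineage_bias[late]
    out["bt_bias_early"] = bundle.bt_bias[early]
    out["bt_bias_late"] = bundle.bt_bias[late]
    out["combination_early"] = bundle.combination[early].reindex(out.index, fill_value="none")
    out["combination_late"] = bundle.combination[late].reindex(out.index, fill_value="none")
    out["temporal"] = bundle.temporal["any"]
    for ct in T_CELLS:
        out[f"dynamics_{ct}"] = bundle.dynamics[ct]
    return out


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in alphabet[draw]:
            bc = row.tobytes().decode("ascii")
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def generate_dataset(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    params: BiasParameters | None = None,
) -> tuple[BarcodeCountTable, FlowSummary, SyntheticGroundTruth]:
    """Simulate a complete experiment; fully reproducible from the seed.

    Returns the read-count table, the consistent flow summary, and the
    ground truth.  Per-sample count totals equal ``config.depth`` exactly
    (multinomial conservation), and per-sample true-abundance totals equal
    ``100 x pop_frac x donor_frac x gfp_frac`` exactly by construction.
    """
    config = config or SimulationConfig()
    params = params or BiasParameters()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    timepoints = tuple(float(t) for t in config.timepoints)
    n_tp = len(timepoints)

    mean_stack = np.stack([a.mean_array(timepoints) for a in config.archetypes])
    if mean_stack.sum() == 0:
        raise ValueError("archetype means are all zero")
    if config.depth < config.clones_per_mouse:
        warnings.warn("sequencing depth below the number of clones; counts will be sparse")

    t_rows = [CELL_TYPES.index(ct) for ct in T_CELLS]
    late_cols = [j for j, tp in enumerate(timepoints) if tp >= 5.5]

    mice: list[tuple[str, str]] = []
    for group, n in config.n_mice.items():
        prefix = "H" if group == Group.HSC.value else "M"
        mice += [(f"{prefix}{i + 1}", group) for i in range(n)]

    profile_cols = pd.MultiIndex.from_product([CELL_TYPES, timepoints], names=PROFILE_LEVELS)
    count_blocks: list[pd.DataFrame] = []
    truth_blocks: list[pd.DataFrame] = []
    flow_rows: list[dict] = []
    info_rows: list[dict] = []
    groups: dict[str, str] = {}

    for mouse, group in mice:
        groups[mouse] = group
        weights = np.array([a.weights[group] for a in config.archetypes], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights for group {group!r} sum to {weights.sum():g}, not 1")

        arch_idx = rng.choice(len(config.archetypes), size=config.clones_per_mouse, p=weights)
        means = mean_stack[arch_idx].copy()  # clone x cell_type x timepoint
        if group == Group.HSC_PLUS_MPP.value and config.mpp_effect != 1.0:
            means[np.ix_(range(len(means)), t_rows, late_cols)] *= config.mpp_effect
        noise = np.exp(rng.normal(0.0, config.sigma, size=means.shape))
        true = means * noise  # zero means stay exactly zero

        n_spike = int(rng.binomial(config.clones_per_mouse, config.spike_artifact_rate))
        spikes = np.zeros((n_spike, len(CELL_TYPES), n_tp))
        for s in range(n_spike):
            cell = int(rng.integers(len(CELL_TYPES) * n_tp))
            spikes[s, cell // n_tp, cell % n_tp] = rng.uniform(*config.spike_abundance)

        all_true = np.concatenate([true, spikes], axis=0)
        barcodes = _random_barcodes(rng, len(all_true), config.barcode_length)
        index = pd.MultiIndex.from_arrays(
            [barcodes, [mouse] * len(barcodes)], names=("barcode", "mouse")
        )
        flat = all_true.reshape(len(all_true), -1)
        truth_blocks.append(pd.DataFrame(flat, index=index, columns=profile_cols))

        for i, barcode in enumerate(barcodes):
            is_spike = i >= config.clones_per_mouse
            arch = None if is_spike else config.archetypes[arch_idx[i]]
            info_rows.append(
                {
                    "barcode": barcode,
                    "mouse": mouse,
                    "group": group,
                    "archetype": "spike_artifact" if is_spike else arch.name,
                    "nominal_lineage_bias": "" if is_spike else arch.lineage_bias,
                    "nominal_temporal": "" if is_spike else arch.temporal,
                    "nominal_dynamics": "" if is_spike else arch.dynamics,
                    "is_spike_artifact": is_spike,
                }
            )

        # sequencing + flow, one sample per (cell type, timepoint)
        sample_counts: dict[tuple, np.ndarray] = {}
        for ci, cell_type in enumerate(CELL_TYPES):
            for ti, tp in enumerate(timepoints):
                true_col = all_true[:, ci, ti]
                total = float(true_col.sum())
                pop_nom = config.nominal_pop_frac[cell_type]
                c = config.flow_concentration
                pop = float(rng.beta(c * pop_nom, c * (1 - pop_nom)))
                donor = float(
                    rng.beta(c * config.nominal_donor_frac, c * (1 - config.nominal_donor_frac))
                )
                if total == 0:
                    gfp = 0.0
                    counts_col = np.zeros(len(true_col), dtype=np.int64)
                else:
                    gfp = total / (100.0 * pop * donor)
                    if gfp > 0.95:
                        # keep fractions plausible while staying exactly
                        # consistent with the planted clonal total
                        gfp = 0.95
                        pop = total / (100.0 * donor * gfp)
                        if pop > 0.98:
                            pop = 0.98
                            donor = total / (100.0 * pop * gfp)
                            if donor > 1.0:
                                raise ValueError(
                                    f"planted abundance total {total:.2f} %WBC in sample "
                                    f"{mouse}:{cell_type}:{tp:g} exceeds 100%: archetype means too large"
                                )
                    counts_col = rng.multinomial(config.depth, true_col / total)
                sample_counts[(mouse, group, cell_type, tp)] = counts_col
                flow_rows.append(
                    {
                        "mouse": mouse,
                        "group": group,
                        "cell_type": cell_type,
                        "timepoint": tp,
                        "pop_frac_wbc": pop,
                        "donor_frac": donor,
                        "gfp_frac": gfp,
                    }
                )

        block = pd.DataFrame(sample_counts, index=pd.Index(barcodes, name="barcode"))
        block.columns = pd.MultiIndex.from_tuples(block.columns, names=SAMPLE_LEVELS)
        count_blocks.append(block)

    counts_df = pd.concat(count_blocks, axis=1).fillna(0).astype(np.int64)
    counts = BarcodeCountTable(counts_df)

    flow_df = pd.DataFrame(flow_rows).set_index(["mouse", "cell_type", "timepoint"])
    flow = FlowSummary(flow_df[["group", "pop_frac_wbc", "donor_frac", "gfp_frac"]])

    truth_matrix = ClonalAbundanceMatrix(pd.concat(truth_blocks), groups)
    info = pd.DataFrame(info_rows).set_index(["barcode", "mouse"])
    non_spike_matrix = truth_matrix.drop_clones(info.index[info["is_spike_artifact"]])
    labels = _truth_labels(non_spike_matrix, params)
    truth = SyntheticGroundTruth(info=info, true_abundance=truth_matrix, labels=labels)
    return counts, flow, truth


def generate_toy_reads(
    counts: pd.Series,
    flank: str = "GTAC",
    error_rate: float = 0.0,
    seed: int = 17,
    pad: int = 8,
):
    """Emit FASTQ records for one sample's barcode counts, plus the whitelist.

    Each barcode yields ``counts[barcode]`` reads of the form
    ``flank + barcode + 'A' * pad`` with independent per-base substitutions
    at ``error_rate``.  At ``error_rate=0`` the reads round-trip exactly
    through :func:`clonetrace.io.count_barcodes_from_reads`.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    i = 0
    for barcode, n in counts.items():
        template = np.array(list(flank + str(barcode) + "A" * pad))
        for _ in range(int(n)):
            read = template.copy()
            errs = np.nonzero(rng.random(len(read)) < error_rate)[0]
            for pos in errs:
                choices = bases[bases != read[pos]]
                read[pos] = choices[rng.integers(len(choices))]
            record = SeqRecord(Seq("".join(read)), id=f"read_{i}", description="")
            record.letter_annotations["phred_quality"] = [40] * len(read)
            records.append(record)
            i += 1
    whitelist = [str(b) for b in counts.index]
    return records, whitelist
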