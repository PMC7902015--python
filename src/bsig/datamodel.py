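"""Core in-memory containers for B-cell subset expression studies.

The study design this package targets is three sorted B-cell subsets
(naive, memory, plasmablast) from two donor groups (healthy controls, HC,
and SLE patients), profiled on log2-scale expression arrays, plus per-cell
flow-cytometry event tables from dye-dilution proliferation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConsistencyError, FormatError

GROUPS = ("HC", "SLE")
SUBSETS = ("naive", "memory", "plasmablast")

ANNOTATION_COLUMNS = ("sample_id", "donor_id", "group", "subset")
FLOW_COLUMNS = ("cell_id", "dye_intensity", "annexin", "viability")


class ExpressionMatrix:
    """Genes x samples matrix of log2 expression intensities.

    Backed by a pandas DataFrame whose index holds gene identifiers and
    whose columns hold sample identifiers. Gene identifiers are opaque,
    case-sensitive strings; no identifier mapping is attempted.

    Invariants enforced at construction: unique gene ids, unique sample
    ids, all values finite.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise AnalysisError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def select_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise AnalysisError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class SampleSheet:
    """Sample annotations: one record per sample.

    Columns: sample_id, donor_id, group (HC/SLE), subset
    (naive/memory/plasmablast). (donor_id, subset) pairs must be unique —
    each donor contributes at most one sample per subset.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        table = table.loc[:, list(ANNOTATION_COLUMNS)].astype(str).reset_index(drop=True)
        if table["sample_id"].duplicated().any():
            dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dups[:5]}")
        bad_group = sorted(set(table["group"]) - set(GROUPS))
        if bad_group:
            raise FormatError(f"unknown group labels: {bad_group} (expected {GROUPS})")
        bad_subset = sorted(set(table["subset"]) - set(SUBSETS))
        if bad_subset:
            raise FormatError(f"unknown subset labels: {bad_subset} (expected {SUBSETS})")
        pair_dup = table.duplicated(subset=["donor_id", "subset"])
        if pair_dup.any():
            pairs = table.loc[pair_dup, ["donor_id", "subset"]].values.tolist()
            raise FormatError(f"duplicate (donor_id, subset) pairs: {pairs[:5]}")
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples(self, subset: str | None = None, group: str | None = None) -> list[str]:
        """Sample ids in the given subset and/or group, in sheet order."""
        mask = pd.Series(True, index=self.table.index)
        if subset is not None:
            if subset not in SUBSETS:
                raise AnalysisError(f"unknown subset {subset!r} (expected one of {SUBSETS})")
            mask &= self.table["subset"] == subset
        if group is not None:
            if group not in GROUPS:
                raise AnalysisError(f"unknown group {group!r} (expected one of {GROUPS})")
            mask &= self.table["group"] == group
        return self.table.loc[mask, "sample_id"].tolist()

    def aligned_to(self, matrix: ExpressionMatrix) -> "SampleSheet":
        """Restrict to the matrix's samples, in matrix column order.

        Raises ConsistencyError naming the first sample the metadata lacks.
        """
        known = set(self.sample_ids)
        for s in matrix.sample_ids:
            if s not in known:
                raise ConsistencyError(f"metadata has no record for sample {s!r}")
        indexed = self.table.set_index("sample_id")
        return SampleSheet(indexed.loc[matrix.sample_ids].reset_index())

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line). Members are unique and non-empty."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) == 0:
            raise FormatError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.name!r} has duplicate members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


class FlowEventTable:
    """Per-cell flow-cytometry events.

    Required channels: dye_intensity (proliferation dye, linear scale,
    strictly positive — each division halves it), annexin (apoptosis
    marker), viability (dead-cell stain). Simulated tables additionally
    carry true_generation, the planted division count.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in FLOW_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"flow event table missing columns: {missing}")
        table = table.reset_index(drop=True)
        for col in ("dye_intensity", "annexin", "viability"):
            vals = table[col].to_numpy(dtype=float)
            if vals.size and not np.isfinite(vals).all():
                raise FormatError(f"non-finite value in channel {col!r}")
            table[col] = vals
        if (table["dye_intensity"].to_numpy() <= 0).any():
            raise FormatError("dye_intensity must be strictly positive")
        if "true_generation" in table.columns:
            gen = table["true_generation"].to_numpy(dtype=int)
            if (gen < 0).any():
                raise FormatError("true_generation must be >= 0")
            table["true_generation"] = gen
        self.table = table

    @property
    def has_truth(self) -> bool:
        return "true_generation" in self.table.columns

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DEGResult:
    """Differentially expressed genes for one subset contrast (SLE vs HC).

    `stats` holds one row per gene (means, signed fold change, moderated t,
    p-value and call); up/down lists are exactly reproducible from the
    stored statistics and thresholds.
    """

    contrast: str
    stats: pd.DataFrame
    p_thresh: float
    fc_thresh: float
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)

    @property
    def deg_genes(self) -> list[str]:
        return self.up_genes + self.down_genes
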