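"""Core containers shared by every pipeline stage.

The package works on repeated-measures expression studies: each individual is
profiled at T time points, individuals belong to exactly one group (e.g. two
diet arms), and all values are log2 intensities. Containers are thin wrappers
around pandas/numpy objects that enforce the structural invariants the
downstream stages rely on (unique identifiers, complete time series, symmetric
correlation matrices, canonical undirected edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLESHEET_COLUMNS = ("sample_id", "individual_id", "group", "timepoint", "sex")
SEXES = ("female", "male")

EDGE_COLUMNS = ("source", "target", "weight", "support", "sign")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) bound to sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``individual_id``,
        ``group``, ``timepoint`` (1-based integer) and ``sex``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups)[:5]}")
        vals = self.values.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if vals.size and np.isnan(vals.astype(float)).any():
            raise ValueError("missing (NaN) expression values are not allowed")

        missing = [c for c in ("individual_id", "group", "timepoint", "sex") if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet misses columns: {missing}")
        unannotated = set(self.values.columns) - set(self.samples.index)
        if unannotated:
            raise ValueError(f"unannotated sample(s): {sorted(unannotated)}")
        extra = set(self.samples.index) - set(self.values.columns)
        if extra:
            raise ValueError(f"annotated sample(s) absent from matrix: {sorted(extra)}")
        # align annotation order to matrix column order
        self.samples = self.samples.loc[self.values.columns]

        tp = self.samples["timepoint"]
        if not np.issubdtype(tp.dtype, np.integer):
            try:
                as_int = tp.astype(int)
            except (TypeError, ValueError) as exc:
                raise ValueError("timepoint must be a positive integer") from exc
            if not (as_int == tp.astype(float)).all():
                raise ValueError("timepoint must be a positive integer")
            self.samples = self.samples.assign(timepoint=as_int)
            tp = self.samples["timepoint"]
        if (tp < 1).any():
            raise ValueError("timepoint must be a positive integer (1-based)")

        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex label(s): {sorted(bad_sex)}; expected {SEXES}")

        pair = self.samples[["individual_id", "timepoint"]]
        if pair.duplicated().any():
            dup = pair[pair.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate time point: individual {dup['individual_id']!r} "
                f"has several samples at timepoint {dup['timepoint']}"
            )
        groups_per_ind = self.samples.groupby("individual_id")["group"].nunique()
        if (groups_per_ind > 1).any():
            bad = groups_per_ind[groups_per_ind > 1].index[0]
            raise ValueError(f"individual {bad!r} is assigned to more than one group")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list[str]:
        return sorted(self.samples["group"].unique())

    def individuals(self, group: str | None = None) -> list[str]:
        ann = self.samples if group is None else self.samples[self.samples["group"] == group]
        return sorted(ann["individual_id"].unique())

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[genes], self.samples.copy())

    def timepoints(self) -> list[int]:
        return sorted(self.samples["timepoint"].unique())

    def individual_series(self, individual_id: str) -> pd.DataFrame:
        """Genes x timepoints values for one individual, time-ordered columns."""
        ann = self.samples[self.samples["individual_id"] == individual_id]
        if ann.empty:
            raise ValueError(f"unknown individual {individual_id!r}")
        ordered = ann.sort_values("timepoint")
        out = self.values[ordered.index]
        out.columns = ordered["timepoint"].to_numpy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.samples.equals(
            other.samples.loc[self.samples.index, self.samples.columns]
        )


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix; NaN marks undefined."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids in correlation matrix")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} genes")
        if not np.array_equal(self.values, self.values.T, equal_nan=True):
            raise ValueError("correlation matrix is not symmetric")
        defined = ~np.isnan(self.values)
        v = self.values[defined]
        if v.size and (np.abs(v) > 1 + 1e-9).any():
            raise ValueError("correlation values outside [-1, 1]")
        diag = np.diag(self.values)
        ddef = diag[~np.isnan(diag)]
        if ddef.size and not np.allclose(ddef, 1.0):
            raise ValueError("defined diagonal entries must equal 1")


@dataclass
class IndividualCorrelationStack:
    """Per-individual correlation matrices over a shared gene panel.

    Each matrix is the Pearson correlation of gene pairs across one
    individual's T time points; entries are NaN where a gene has zero
    variance over those time points.
    """

    gene_ids: list[str]
    matrices: dict[str, np.ndarray]  # individual_id -> (G, G)

    def __post_init__(self) -> None:
        g = len(self.gene_ids)
        for ind, mat in self.matrices.items():
            if mat.shape != (g, g):
                raise ValueError(f"matrix for individual {ind!r} has shape {mat.shape}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.matrices)

    @property
    def n_individuals(self) -> int:
        return len(self.matrices)

    def as_array(self) -> np.ndarray:
        """Stack as (n_individuals, G, G), in individual_ids order."""
        return np.stack([self.matrices[i] for i in self.individual_ids])

    def matrix_for(self, individual_id: str) -> CorrelationMatrix:
        return CorrelationMatrix(self.gene_ids, self.matrices[individual_id])


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Order an undirected gene pair lexicographically; reject self-edges."""
    if a == b:
        raise ValueError(f"self-edge on {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class CoexpressionNetwork:
    """Undirected signed weighted gene graph with per-edge support fraction.

    Edges are stored canonically (source < target). ``weight`` is the mean
    correlation over the qualifying individuals, ``support`` the fraction of
    the group's individuals that qualified, ``sign`` '+' or '-' matching the
    weight. The same type serves per-group networks and overlap networks.
    """

    edges: pd.DataFrame
    provenance: str = ""
    extra_nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.edges is None or len(self.edges) == 0:
            self.edges = pd.DataFrame(columns=list(EDGE_COLUMNS))
        self.edges = self.edges.reset_index(drop=True)[list(EDGE_COLUMNS)]
        if len(self.edges):
            src = self.edges["source"].astype(str)
            tgt = self.edges["target"].astype(str)
            if (src >= tgt).any():
                raise ValueError("edges must be canonical: source < target, no self-edges")
            w = self.edges["weight"].astype(float)
            s = self.edges["support"].astype(float)
            if (w == 0).any() or (np.abs(w) > 1 + 1e-9).any():
                raise ValueError("edge weights must lie in [-1, 1] and be non-zero")
            if (s <= 0).any() or (s > 1 + 1e-9).any():
                raise ValueError("edge support must lie in (0, 1]")
            expect = np.where(w > 0, "+", "-")
            if (self.edges["sign"].to_numpy() != expect).any():
                raise ValueError("edge sign must match the sign of the weight")
            pairs = self.edges[["source", "target"]].apply(tuple, axis=1)
            if pairs.duplicated().any():
                raise ValueError("duplicate edges")
            self.edges = self.edges.sort_values(["source", "target"]).reset_index(drop=True)

    @property
    def nodes(self) -> list[str]:
        incident = set(self.edges["source"]) | set(self.edges["target"])
        return sorted(incident | set(self.extra_nodes))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_negative_edges(self) -> int:
        return int((self.edges["sign"] == "-").sum()) if len(self.edges) else 0

    def edge_set(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.edges[["source", "target"]].to_numpy()))

    def signed_edge_set(self) -> set[tuple[str, str, str]]:
        return set(map(tuple, self.edges[["source", "target", "sign"]].to_numpy()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoexpressionNetwork):
            return NotImplemented
        if set(self.nodes) != set(other.nodes):
            return False
        a = self.edges.sort_values(["source", "target"]).reset_index(drop=True)
        b = other.edges.sort_values(["source", "target"]).reset_index(drop=True)
        return a.equals(b)


@dataclass(frozen=True)
class NetworkParams:
    """Edge-retention rule: |r| >= corr_cutoff in >= support_fraction of individuals."""

    corr_cutoff: float = 0.6
    support_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.corr_cutoff <= 1:
            raise ValueError("corr_cutoff must be in (0, 1]")
        if not 0 < self.support_fraction <= 1:
            raise ValueError("support_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DEParams:
    """Differential-expression gate: |FC| >= fc_threshold and p < p_threshold."""

    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    test: str = "moderated_paired_t"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold is a linear fold change and must exceed 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.test not in ("moderated_paired_t", "paired_t"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set name -> description + member genes."""

    sets: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, entry in self.sets.items():
            genes = entry.get("genes", set())
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            entry["genes"] = set(genes)
            entry.setdefault("description", "")

    def add(self, name: str, description: str, genes) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        genes = set(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = {"description": description, "genes": genes}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets
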