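"""Readers and writers for every external representation the pipeline touches.

Formats are deliberately plain text: expression matrices and sample designs
as delimited tables, gene sets as GMT, networks as TSV edge lists or
GraphML.  Loaders validate and reject malformed input — they never silently
repair duplicate identifiers, missing values or unassigned samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from coexscreen.network import GroupNetwork

CONTROL = "control"
CASE = "case"

#: Recognised per-gene biotype labels.
BIOTYPES = ("protein_coding", "lncRNA", "other")


class LoadError(ValueError):
    """Raised when an input file violates a format or content invariant."""


@dataclass
class ExpressionMatrix:
    """Normalized gene-by-sample expression values.

    Values are assumed already normalized and on a log-like scale; the
    pipeline performs no normalization of its own.

    Parameters
    ----------
    gene_ids:
        Ordered, unique gene identifiers (row labels).
    sample_ids:
        Ordered, unique sample identifiers (column labels).
    values:
        ``(n_genes, n_samples)`` array of finite floats.
    gene_biotype:
        Optional map gene_id -> biotype label (``protein_coding``,
        ``lncRNA`` or ``other``); genes absent from the map are treated
        as ``other``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    gene_biotype: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise LoadError(
                f"value array shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise LoadError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.gene_biotype is not None:
            unknown = set(self.gene_biotype.values()) - set(BIOTYPES)
            if unknown:
                raise LoadError(f"unknown biotype labels: {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``gene_ids`` (order preserved)."""
        idx = self.gene_index()
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        biotype = None
        if self.gene_biotype is not None:
            biotype = {g: self.gene_biotype[g] for g in gene_ids if g in self.gene_biotype}
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            gene_biotype=biotype,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def uppercase_ids(self) -> "ExpressionMatrix":
        """Return a copy with all gene ids upper-cased (opt-in preprocessing)."""
        biotype = None
        if self.gene_biotype is not None:
            biotype = {g.upper(): b for g, b in self.gene_biotype.items()}
        return ExpressionMatrix(
            gene_ids=[g.upper() for g in self.gene_ids],
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            gene_biotype=biotype,
        )


@dataclass
class SampleDesign:
    """Assignment of every sample to exactly one of two groups."""

    assignments: dict[str, str]
    control_label: str = CONTROL
    case_label: str = CASE

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        allowed = {self.control_label, self.case_label}
        extra = labels - allowed
        if extra:
            raise LoadError(
                f"unknown group labels {sorted(extra)}; expected "
                f"{self.control_label!r} / {self.case_label!r}"
            )

    @property
    def n_control(self) -> int:
        return sum(1 for v in self.assignments.values() if v == self.control_label)

    @property
    def n_case(self) -> int:
        return sum(1 for v in self.assignments.values() if v == self.case_label)

    def samples_in(self, group: str) -> list[str]:
        if group not in (self.control_label, self.case_label):
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.assignments.items() if g == group]

    def validate_against(self, matrix: ExpressionMatrix, min_per_group: int = 3) -> None:
        """Check every matrix sample is assigned and groups are large enough.

        Correlation p-values need df = n - 2 >= 1, hence at least 3 samples
        per group.
        """
        unassigned = [s for s in matrix.sample_ids if s not in self.assignments]
        if unassigned:
            raise LoadError(f"samples without group assignment: {unassigned}")
        stray = [s for s in self.assignments if s not in matrix.sample_index()]
        if stray:
            raise LoadError(f"design samples not present in matrix: {stray}")
        for group, n in ((self.control_label, self.n_control), (self.case_label, self.n_case)):
            if n < min_per_group:
                raise LoadError(
                    f"group {group!r} has {n} samples; at least {min_per_group} required"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. GO terms or pathways supplied as GMT."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    namespace: str = ""

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if len(members) == 0:
                raise LoadError(f"gene set {term!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term_id: str) -> tuple[str, ...]:
        return self.sets[term_id][1]

    def term_name(self, term_id: str) -> str:
        return self.sets[term_id][0]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise LoadError(f"duplicate {kind} id {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    biotype_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes-in-rows delimited matrix (header row = sample ids).

    ``biotype_path`` optionally points at a two-column table
    (gene_id, biotype) attaching biotype labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise LoadError(
                    f"non-numeric cell at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}: {raw!r}"
                ) from None
            if not math.isfinite(v):
                raise LoadError(
                    f"non-finite cell at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            values[i, j] = v
    biotype = None
    if biotype_path is not None:
        bt = pd.read_csv(biotype_path, sep="\t", header=None, names=["gene", "biotype"], dtype=str)
        biotype = dict(zip(bt["gene"], bt["biotype"]))
    return ExpressionMatrix(gene_ids, sample_ids, values, gene_biotype=biotype)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="gene_id", float_format="%.10g")


def write_biotypes(matrix: ExpressionMatrix, path: str | Path) -> None:
    if matrix.gene_biotype is None:
        raise ValueError("matrix carries no biotype annotation")
    with open(path, "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{matrix.gene_biotype.get(g, 'other')}\n")


# ---------------------------------------------------------------------------
# sample designs


def read_design(path: str | Path, control_label: str = CONTROL, case_label: str = CASE) -> SampleDesign:
    """Read a two-column TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise LoadError(f"{path}: expected two columns (sample_id, group)")
    _check_unique(list(df[0]), "sample")
    assignments = dict(zip(df[0], df[1]))
    return SampleDesign(assignments, control_label=control_label, case_label=case_label)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in design.assignments.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, namespace: str = "") -> GeneSetCollection:
    """Read a GMT file: term, description, then tab-separated member ids."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            term, desc = fields[0], fields[1]
            members = tuple(m for m in fields[2:] if m)
            if not members:
                raise LoadError(f"{path}:{lineno}: gene set {term!r} has no members")
            if term in sets:
                raise LoadError(f"{path}:{lineno}: duplicate term id {term!r}")
            sets[term] = (desc, members)
    return GeneSetCollection(sets, namespace=namespace)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# networks

#: edge_tsv column order; r printed to 7 decimals, p/fdr to 6 significant digits.
EDGE_COLUMNS = ("gene_a", "gene_b", "pearson_r", "p_value", "fdr", "style")


def write_group_network(network: "GroupNetwork", path: str | Path, format: str = "edge_tsv") -> None:
    """Serialize a group network as a TSV edge list or GraphML.

    Each undirected pair is written once with ``gene_a < gene_b``
    lexicographically.  GraphML output carries node attributes ``degree``
    and ``core_number`` plus edge attributes ``r``, ``p``, ``fdr``,
    ``style``.
    """
    if format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(EDGE_COLUMNS) + "\n")
            for e in sorted(network.edges, key=lambda e: (e.gene_a, e.gene_b)):
                fh.write(
                    f"{e.gene_a}\t{e.gene_b}\t{e.r:.7f}\t{e.p_value:.6g}\t{e.fdr:.6g}\t{e.style}\n"
                )
    elif format == "graphml":
        import networkx as nx

        from coexscreen.topology import core_numbers, degrees

        g = network.to_graph()
        deg = degrees(network)
        core = core_numbers(network)
        for node in g.nodes:
            g.nodes[node]["degree"] = deg[node]
            g.nodes[node]["core_number"] = core[node]
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_group_network(path: str | Path, group: str = "", n_samples: int = 0) -> "GroupNetwork":
    """Read an edge_tsv file written by :func:`write_group_network`.

    Node list is reconstructed from edge endpoints; degree-0 nodes present
    in the original network are not recoverable from the edge list alone
    and may be supplied afterwards via ``network.nodes``.
    """
    from coexscreen.network import CorrelationEdge, GroupNetwork

    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing edge columns {sorted(missing)}")
    edges = [
        CorrelationEdge(
            gene_a=row.gene_a,
            gene_b=row.gene_b,
            r=float(row.pearson_r),
            n=n_samples,
            p_value=float(row.p_value),
            fdr=float(row.fdr),
        )
        for row in df.itertuples()
    ]
    nodes = sorted({g for e in edges for g in (e.gene_a, e.gene_b)})
    return GroupNetwork(group=group, nodes=nodes, edges=edges, n_samples=n_samples)


# ---------------------------------------------------------------------------
# tabular stage outputs


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_list(path: str | Path) -> list[str]:
    genes = [line.strip() for line in open(path) if line.strip()]
    _check_unique(genes, "gene")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
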