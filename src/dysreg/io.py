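"""Domain types and file I/O for the dysregulation pipeline.

The pipeline works on four kinds of objects: paired tumor/normal expression
cohorts, named gene sets over a shared universe, an undirected protein-protein
interaction (PPI) network, and per-cohort molecular matrices (copy-number or
DNA-methylation values for tumor samples).  All on-disk formats are plain
text: TSV matrices, GMT gene sets and a two-column edge list.

Gene identity is the bare symbol string, matched case-sensitively; no alias
resolution is attempted.  The analysis universe of every downstream statistic
is the set of genes measured in a cohort's expression matrix —
``intersect_universe`` restricts catalogs, networks and molecular matrices to
that universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SET_KINDS = ("category", "tissue", "pathway")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


def _check_gene_symbol(symbol: str) -> None:
    if not isinstance(symbol, str) or symbol == "":
        raise FormatError(f"invalid gene symbol: {symbol!r}")
    if any(ch.isspace() for ch in symbol):
        raise FormatError(f"gene symbol contains whitespace: {symbol!r}")


@dataclass
class PairedCohort:
    """One cancer type's expression matrix with tumor/normal pairing.

    ``expr`` is genes x samples (non-negative, already-normalized
    abundances); ``pairs`` lists (patient_id, tumor_column, normal_column)
    with both columns present in ``samples``.
    """

    cohort_id: str
    genes: list[str]
    samples: list[str]
    expr: np.ndarray
    pairs: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        if self.expr.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"expression shape {self.expr.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        seen: set[str] = set()
        for g in self.genes:
            _check_gene_symbol(g)
            if g in seen:
                raise FormatError(f"duplicate gene symbol: {g!r}")
            seen.add(g)
        if np.any(self.expr < 0):
            bad = self.genes[int(np.argwhere(self.expr < 0)[0][0])]
            raise FormatError(f"negative expression value for gene {bad!r}")
        if len(self.pairs) < 2:
            raise FormatError("a paired cohort needs at least 2 sample pairs")
        col_index = {s: i for i, s in enumerate(self.samples)}
        for patient, tcol, ncol in self.pairs:
            if tcol not in col_index:
                raise FormatError(f"pairing references missing column {tcol!r}")
            if ncol not in col_index:
                raise FormatError(f"pairing references missing column {ncol!r}")
            if tcol == ncol:
                raise FormatError(
                    f"pair for patient {patient!r} uses the same column twice"
                )
        self._col_index = col_index

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def tumor_columns(self) -> list[str]:
        return [t for _, t, _ in self.pairs]

    @property
    def normal_columns(self) -> list[str]:
        return [n for _, _, n in self.pairs]

    def tumor_matrix(self) -> np.ndarray:
        idx = [self._col_index[t] for t in self.tumor_columns]
        return self.expr[:, idx]

    def normal_matrix(self) -> np.ndarray:
        idx = [self._col_index[n] for n in self.normal_columns]
        return self.expr[:, idx]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class GeneCatalog:
    """Named gene sets (categories, tissue-specific sets, pathways).

    ``tissue_to_cohort`` maps each tissue-kind set name to the cohort whose
    cancer arises from that tissue.
    """

    universe: set[str] = field(default_factory=set)
    sets: dict[str, set[str]] = field(default_factory=dict)
    set_kind: dict[str, str] = field(default_factory=dict)
    tissue_to_cohort: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, members in self.sets.items():
            if name not in self.set_kind:
                raise FormatError(f"set {name!r} has no kind")
            if self.set_kind[name] not in SET_KINDS:
                raise FormatError(f"set {name!r} has unknown kind {self.set_kind[name]!r}")
            extra = members - self.universe
            if extra:
                raise FormatError(
                    f"set {name!r} contains genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )
        tissue_sets = {n for n, k in self.set_kind.items() if k == "tissue"}
        if set(self.tissue_to_cohort) != tissue_sets:
            raise FormatError(
                "tissue_to_cohort keys must be exactly the tissue-kind sets"
            )

    def merge(self, other: "GeneCatalog") -> "GeneCatalog":
        """Union of two catalogs; set names must not collide."""
        clash = set(self.sets) & set(other.sets)
        if clash:
            raise FormatError(f"duplicate set names on merge: {sorted(clash)}")
        return GeneCatalog(
            universe=self.universe | other.universe,
            sets={**self.sets, **other.sets},
            set_kind={**self.set_kind, **other.set_kind},
            tissue_to_cohort={**self.tissue_to_cohort, **other.tissue_to_cohort},
        )

    def sets_of_kind(self, kind: str) -> list[str]:
        return [n for n, k in self.set_kind.items() if k == kind]

    def tissue_set_for(self, cohort_id: str) -> str | None:
        hits = [n for n, c in self.tissue_to_cohort.items() if c == cohort_id]
        if len(hits) > 1:
            raise FormatError(f"multiple tissue sets mapped to cohort {cohort_id!r}")
        return hits[0] if hits else None

    def restricted(self, genes: set[str]) -> tuple["GeneCatalog", dict[str, int]]:
        """Restrict every set to ``genes``; returns (catalog, retained counts)."""
        new_sets = {n: m & genes for n, m in self.sets.items()}
        counts = {n: len(m) for n, m in new_sets.items()}
        for n, m in new_sets.items():
            if not m and self.sets[n]:
                logger.warning("set %r is empty after universe restriction", n)
        cat = GeneCatalog(
            universe=self.universe & genes,
            sets=new_sets,
            set_kind=dict(self.set_kind),
            tissue_to_cohort=dict(self.tissue_to_cohort),
        )
        return cat, counts


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network without self-loops."""

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise FormatError(f"edge ({a!r}, {b!r}) references missing node")
            canon.add((a, b) if a <= b else (b, a))
        self.edges = canon
        self._adj: dict[str, set[str]] | None = None

    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            self._adj = adj
        return self._adj

    def neighbors(self, gene: str) -> set[str]:
        return set(self.adjacency().get(gene, set()))

    def restricted(self, genes: set[str]) -> "PPINetwork":
        keep = self.nodes & genes
        edges = {(a, b) for a, b in self.edges if a in keep and b in keep}
        return PPINetwork(nodes=keep, edges=edges)


@dataclass
class MolecularMatrix:
    """Gene x tumor-sample matrix of CNV (log2 copy-ratio) or methylation
    (beta-like value in [0, 1])."""

    assay: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.assay not in ("cnv", "methylation"):
            raise FormatError(f"unknown assay {self.assay!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError("molecular matrix shape mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene in molecular matrix")
        if self.assay == "methylation" and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise FormatError("methylation values must lie in [0, 1]")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def restricted(self, genes: set[str]) -> "MolecularMatrix":
        keep = [i for i, g in enumerate(self.genes) if g in genes]
        return MolecularMatrix(
            assay=self.assay,
            genes=[self.genes[i] for i in keep],
            samples=list(self.samples),
            values=self.values[keep, :],
        )


@dataclass
class RestrictedViews:
    """Result of restricting all inputs to a cohort's measured genes."""

    cohort: PairedCohort
    catalog: GeneCatalog | None
    network: PPINetwork | None
    mats: list[MolecularMatrix]
    retained_counts: dict[str, int]


# ---------------------------------------------------------------------------
# Readers / writers.  TSV dialect: tab separator, UTF-8, '.' decimal, no
# quoting; the header cell (0,0) of matrix files is ignored on read.
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path: str) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    genes = [str(g) for g in df.index]
    if len(set(genes)) != len(genes):
        seen: set[str] = set()
        for g in genes:
            if g in seen:
                raise FormatError(f"duplicate gene symbol: {g!r}")
            seen.add(g)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in {path}: {exc}") from exc
    return genes, [str(c) for c in df.columns], values


def read_expression(path: str, pairs_path: str, cohort_id: str | None = None) -> PairedCohort:
    """Read a genes x samples expression TSV plus a 3-column pairing TSV."""
    genes, samples, values = _read_matrix_tsv(path)
    if np.any(np.isnan(values)):
        raise FormatError(f"missing value in expression matrix {path}")
    pdf = pd.read_csv(pairs_path, sep="\t", dtype=str)
    required = ["patient_id", "tumor_sample", "normal_sample"]
    if list(pdf.columns[:3]) != required:
        raise FormatError(
            f"pairing file must have columns {required}, got {list(pdf.columns)}"
        )
    pairs = [
        (row.patient_id, row.tumor_sample, row.normal_sample)
        for row in pdf.itertuples()
    ]
    if cohort_id is None:
        import os

        cohort_id = os.path.splitext(os.path.basename(path))[0]
    return PairedCohort(
        cohort_id=cohort_id, genes=genes, samples=samples, expr=values, pairs=pairs
    )


def _float_repr(v: float) -> str:
    # shortest string that round-trips the double exactly
    return repr(float(v))


def write_expression(cohort: PairedCohort, path: str, pairs_path: str) -> None:
    df = pd.DataFrame(cohort.expr, index=cohort.genes, columns=cohort.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=_float_repr)
    pdf = pd.DataFrame(
        cohort.pairs, columns=["patient_id", "tumor_sample", "normal_sample"]
    )
    pdf.to_csv(pairs_path, sep="\t", index=False)


def read_gmt(path: str, kind: str = "category") -> GeneCatalog:
    """Read a GMT file (name, description, members per tab-separated line).

    For ``kind == "tissue"`` the description field is interpreted as the
    matched cohort id.  Duplicate members within a line are collapsed.
    """
    if kind not in SET_KINDS:
        raise FormatError(f"unknown set kind {kind!r}")
    sets: dict[str, set[str]] = {}
    set_kind: dict[str, str] = {}
    tissue_to_cohort: dict[str, str] = {}
    universe: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            for m in members:
                _check_gene_symbol(m)
            sets[name] = set(members)
            set_kind[name] = kind
            universe |= sets[name]
            if kind == "tissue":
                tissue_to_cohort[name] = desc
    return GeneCatalog(
        universe=universe,
        sets=sets,
        set_kind=set_kind,
        tissue_to_cohort=tissue_to_cohort,
    )


def write_gmt(catalog: GeneCatalog, path: str, kind: str | None = None) -> None:
    """Write the catalog's sets (optionally one kind only) as GMT."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(catalog.sets):
            if kind is not None and catalog.set_kind[name] != kind:
                continue
            desc = catalog.tissue_to_cohort.get(name, "na")
            members = sorted(catalog.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_network(path: str) -> PPINetwork:
    """Read a two-column edge list; self-loops dropped with a warning,
    duplicate and reversed-duplicate edges collapsed."""
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    n_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: edge line needs exactly 2 fields"
                )
            a, b = fields
            _check_gene_symbol(a)
            _check_gene_symbol(b)
            if a == b:
                n_loops += 1
                continue
            nodes.add(a)
            nodes.add(b)
            edges.add((a, b) if a <= b else (b, a))
    if n_loops:
        logger.warning("dropped %d self-loop(s) while reading %s", n_loops, path)
    return PPINetwork(nodes=nodes, edges=edges)


def write_network(network: PPINetwork, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def read_molecular(path: str, assay: str) -> MolecularMatrix:
    genes, samples, values = _read_matrix_tsv(path)
    return MolecularMatrix(assay=assay, genes=genes, samples=samples, values=values)


def write_molecular(mat: MolecularMatrix, path: str) -> None:
    df = pd.DataFrame(mat.values, index=mat.genes, columns=mat.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=_float_repr)


def intersect_universe(
    cohort: PairedCohort,
    catalog: GeneCatalog | None = None,
    network: PPINetwork | None = None,
    mats: list[MolecularMatrix] | None = None,
) -> RestrictedViews:
    """Restrict catalog, network and molecular matrices to the genes measured
    in the cohort's expression matrix.

    The restriction is idempotent, never enlarges a set, and leaves the
    cohort's expression values untouched.  Per-set retained counts are
    reported; a category emptied by restriction is kept empty with a warning.
    """
    measured = set(cohort.genes)
    counts: dict[str, int] = {}
    rcat = None
    if catalog is not None:
        rcat, counts = catalog.restricted(measured)
    rnet = network.restricted(measured) if network is not None else None
    rmats = [m.restricted(measured) for m in (mats or [])]
    return RestrictedViews(
        cohort=cohort,
        catalog=rcat,
        network=rnet,
        mats=rmats,
        retained_counts=counts,
    )
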