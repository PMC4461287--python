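"""Signed directed interaction networks and Booleanized phenotypes.

A prior-knowledge network (PKN) is a signed, directed graph whose nodes are
genes or gene products and whose edges are regulatory effects: activation
(+1) or inhibition (-1).  Contextualization never removes nodes, only edges,
so a pruned candidate shares the full node set of its PKN.

Phenotypes are Booleanized expression profiles: each measured gene is either
active (1) or inactive (0) in a given stable cellular state.  A two-condition
differential-expression comparison maps onto a pair of phenotypes in which
up-regulated genes are 0 initially and 1 finally, and vice versa for
down-regulated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

log = logging.getLogger(__name__)

ACTIVATION = 1
INHIBITION = -1

#: (source gene, target gene, sign) with sign in {+1, -1}
Edge = tuple[str, str, int]

_EFFECT_TOKENS = {
    "activate": ACTIVATION,
    "+": ACTIVATION,
    "1": ACTIVATION,
    "inhibit": INHIBITION,
    "-": INHIBITION,
    "-1": INHIBITION,
}
_EFFECT_NAMES = {ACTIVATION: "activate", INHIBITION: "inhibit"}


class NetworkParseError(ValueError):
    """Raised for malformed interaction-network files."""


class PhenotypeParseError(ValueError):
    """Raised for malformed phenotype tables."""


@dataclass(frozen=True)
class SignedDigraph:
    """An immutable signed directed graph.

    Duplicate (source, target, sign) triples collapse by set semantics;
    a node pair may carry both an activating and an inhibiting edge
    (dual regulation), and self-loops are permitted.
    """

    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for src, tgt, sign in self.edges:
            if sign not in (ACTIVATION, INHIBITION):
                raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
            if src not in self.nodes or tgt not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: ({src}, {tgt})")

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], nodes: Iterable[str] = ()
    ) -> "SignedDigraph":
        """Build a graph from an edge iterable plus optional isolated nodes."""
        eset = frozenset((str(s), str(t), int(g)) for s, t, g in edges)
        nset = frozenset(nodes) | {s for s, _, _ in eset} | {t for _, t, _ in eset}
        return cls(nodes=nset, edges=eset)

    # -- convenience ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.nodes))

    def sorted_edges(self) -> tuple[Edge, ...]:
        return tuple(sorted(self.edges))

    def in_degree(self) -> dict[str, int]:
        """Number of incoming edges per node (dual edges count twice)."""
        deg = {n: 0 for n in self.nodes}
        for _, tgt, _ in self.edges:
            deg[tgt] += 1
        return deg

    def is_subnetwork_of(self, other: "SignedDigraph") -> bool:
        return self.nodes == other.nodes and self.edges <= other.edges

    def with_edges(self, edges: Iterable[Edge]) -> "SignedDigraph":
        """A graph over the same node set with a different edge set."""
        eset = frozenset(edges)
        for src, tgt, _ in eset:
            if src not in self.nodes or tgt not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: ({src}, {tgt})")
        return SignedDigraph(nodes=self.nodes, edges=eset)

    # -- interchange ------------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.sorted_nodes())
        for src, tgt, sign in self.sorted_edges():
            g.add_edge(src, tgt, sign=sign)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph | nx.MultiDiGraph) -> "SignedDigraph":
        edges = []
        for src, tgt, data in g.edges(data=True):
            if "sign" not in data:
                raise ValueError(f"edge ({src}, {tgt}) lacks a 'sign' attribute")
            edges.append((src, tgt, int(data["sign"])))
        return cls.from_edges(edges, nodes=g.nodes())


def read_network(path: str | Path, dialect: str = "sif_tsv") -> SignedDigraph:
    """Read a signed edge list: ``source <TAB> effect <TAB> target``.

    The effect token is one of activate/inhibit/+/-/1/-1 (case-insensitive).
    Lines starting with '#' and blank lines are ignored; duplicate triples
    collapse.  UTF-8, Unix or Windows line endings.
    """
    if dialect != "sif_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    edges: list[Edge] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            src, effect, tgt = fields
            sign = _EFFECT_TOKENS.get(effect.lower())
            if sign is None:
                raise NetworkParseError(
                    f"{path}:{lineno}: unknown effect token {effect!r}"
                )
            if not src or not tgt:
                raise NetworkParseError(f"{path}:{lineno}: empty gene name")
            edges.append((src, tgt, sign))
    return SignedDigraph.from_edges(edges)


def write_network(graph: SignedDigraph, path: str | Path) -> None:
    """Write a graph in the 3-column TSV edge-list dialect (sorted, stable)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for src, tgt, sign in graph.sorted_edges():
            fh.write(f"{src}\t{_EFFECT_NAMES[sign]}\t{tgt}\n")
        isolated = graph.nodes - {s for s, _, _ in graph.edges} - {
            t for _, t, _ in graph.edges
        }
        for node in sorted(isolated):
            fh.write(f"# isolated node: {node}\n")


@dataclass(frozen=True)
class Phenotype:
    """A named Boolean state vector over measured genes."""

    name: str
    states: Mapping[str, int]

    def __post_init__(self) -> None:
        for gene, value in self.states.items():
            if value not in (0, 1):
                raise ValueError(
                    f"phenotype {self.name!r}: gene {gene!r} has non-Boolean "
                    f"state {value!r}"
                )
        object.__setattr__(self, "states", dict(self.states))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.states)

    def __getitem__(self, gene: str) -> int:
        return self.states[gene]

    def restricted(self, genes: Iterable[str]) -> "Phenotype":
        keep = set(genes)
        return Phenotype(self.name, {g: v for g, v in self.states.items() if g in keep})

    def flipped(self, genes: Iterable[str]) -> "Phenotype":
        flip = set(genes)
        return Phenotype(
            self.name,
            {g: (1 - v if g in flip else v) for g, v in self.states.items()},
        )


@dataclass(frozen=True)
class PhenotypeSet:
    """An ordered collection of phenotypes over a shared gene universe."""

    phenotypes: tuple[Phenotype, ...]

    def __post_init__(self) -> None:
        phenos = tuple(self.phenotypes)
        object.__setattr__(self, "phenotypes", phenos)
        if len(phenos) < 1:
            raise ValueError("a PhenotypeSet needs at least one phenotype")
        universe = phenos[0].genes
        for p in phenos[1:]:
            if p.genes != universe:
                raise ValueError(
                    f"phenotype {p.name!r} covers a different gene set than "
                    f"{phenos[0].name!r}"
                )
        names = [p.name for p in phenos]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate phenotype names: {names}")

    @property
    def genes(self) -> frozenset[str]:
        return self.phenotypes[0].genes

    @property
    def n_p(self) -> int:
        return len(self.phenotypes)

    @property
    def n_g(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Phenotype]:
        return iter(self.phenotypes)

    def __len__(self) -> int:
        return len(self.phenotypes)

    def get(self, name: str) -> Phenotype:
        for p in self.phenotypes:
            if p.name == name:
                return p
        raise KeyError(f"no phenotype named {name!r}")

    def restricted(self, genes: Iterable[str]) -> "PhenotypeSet":
        keep = set(genes)
        return PhenotypeSet(tuple(p.restricted(keep) for p in self.phenotypes))

    def flipped(self, genes: Iterable[str]) -> "PhenotypeSet":
        return PhenotypeSet(tuple(p.flipped(genes) for p in self.phenotypes))


def read_phenotypes(path: str | Path) -> PhenotypeSet:
    """Read a phenotype table: ``gene <TAB> pheno1 <TAB> pheno2 ...``.

    The header row names the phenotypes; body cells must be 0 or 1.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise PhenotypeParseError(f"{path}: empty phenotype table")
    header = [f.strip() for f in lines[0].split("\t")]
    if len(header) < 2:
        raise PhenotypeParseError(f"{path}: header needs a gene column and at least one phenotype column")
    pheno_names = header[1:]
    columns: list[dict[str, int]] = [dict() for _ in pheno_names]
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != len(header):
            raise PhenotypeParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        gene = fields[0]
        if gene in columns[0]:
            raise PhenotypeParseError(f"{path}:{lineno}: duplicate gene row {gene!r}")
        for col, cell in zip(columns, fields[1:]):
            if cell not in ("0", "1"):
                raise PhenotypeParseError(
                    f"{path}:{lineno}: non-Boolean state {cell!r} for gene {gene!r}"
                )
            col[gene] = int(cell)
    return PhenotypeSet(
        tuple(Phenotype(name, col) for name, col in zip(pheno_names, columns))
    )


def write_phenotypes(phenotypes: PhenotypeSet, path: str | Path) -> None:
    path = Path(path)
    names = [p.name for p in phenotypes]
    genes = sorted(phenotypes.genes)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(names) + "\n")
        for g in genes:
            fh.write(g + "\t" + "\t".join(str(p[g]) for p in phenotypes) + "\n")


def booleanize_differential(
    up_genes: Sequence[str], down_genes: Sequence[str]
) -> PhenotypeSet:
    """Turn an up/down-regulated gene list into an initial/final phenotype pair.

    Up-regulated genes are inactive (0) in the initial condition and active
    (1) in the final one; down-regulated genes the opposite.  The two
    phenotypes are bitwise complements of each other over the listed genes.
    """
    overlap = set(up_genes) & set(down_genes)
    if overlap:
        raise ValueError(
            f"genes cannot be both up- and down-regulated: {sorted(overlap)}"
        )
    initial = {g: 0 for g in up_genes} | {g: 1 for g in down_genes}
    final = {g: 1 for g in up_genes} | {g: 0 for g in down_genes}
    return PhenotypeSet((Phenotype("initial", initial), Phenotype("final", final)))
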