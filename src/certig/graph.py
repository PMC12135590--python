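"""Abundance-annotated bidirected de Bruijn graph built from sequencing reads.

Nodes are canonical k-mers, edges canonical (k+1)-mers; the abundance of a
sequence is the number of occurrences of it or its reverse complement across
the read set.  Each node exposes two sides: the *forward* side extends the
canonical string on the right, the *backward* side on the left.  Every edge
is reachable from both flanking nodes with a consistent abundance, which is
what lets the assembler check uniqueness of an extension in both directions.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
from Bio import SeqIO

from ._kmers import canonical, decode_codes, encode_bases, revcomp, window_codes
from .errors import GraphError, ParseError

logger = logging.getLogger(__name__)

FORWARD = "F"   # extend the canonical k-mer on the right
BACKWARD = "B"  # extend the canonical k-mer on the left

Side = Literal["F", "B"]


@dataclass
class ReadSet:
    """Sequencing reads as (id, uppercased sequence) records."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> Iterator[str]:
        for _, seq in self.records:
            yield seq


@dataclass(frozen=True)
class AdjacencyEntry:
    """One edge incidence seen from a particular node side.

    ``symbol`` is the base appended (forward side) or prepended (backward
    side) to the node's canonical string; ``neighbor_side`` is the side of
    the neighbour that this edge is incident to.
    """

    symbol: str
    edge: str
    edge_abundance: int
    neighbor: str
    neighbor_side: Side


@dataclass
class KmerGraph:
    k: int
    nodes: dict[str, int]
    edges: dict[str, int]
    adjacency: dict[str, dict[Side, list[AdjacencyEntry]]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def max_abundance(self) -> int:
        return max(self.nodes.values(), default=0)


@dataclass
class AbundanceHistogram:
    """Number of distinct canonical k-mers at each abundance value."""

    counts: dict[int, int]

    def total(self) -> int:
        return sum(self.counts.values())

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.array(sorted(self.counts), dtype=np.int64)
        n = np.array([self.counts[x] for x in a], dtype=np.float64)
        return a, n


def _detect_format(path: str | Path) -> tuple[str, bool]:
    name = str(path).lower()
    gz = name.endswith(".gz")
    stem = name[:-3] if gz else name
    if stem.endswith((".fq", ".fastq")):
        return "fastq", gz
    return "fasta", gz


def read_sequences(
    path: str | Path,
    format: str | None = None,
    gzipped: bool | None = None,
) -> ReadSet:
    """Read FASTA/FASTQ records (optionally gzip-compressed) in file order.

    When ``format``/``gzipped`` are omitted they are inferred from the file
    extension.  Sequences are uppercased; a malformed record raises
    :class:`ParseError` naming the index of the offending record.
    """
    auto_fmt, auto_gz = _detect_format(path)
    fmt = format or auto_fmt
    gz = auto_gz if gzipped is None else gzipped
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {fmt!r}")
    opener = gzip.open if gz else open
    records: list[tuple[str, str]] = []
    try:
        with opener(path, "rt") as handle:
            parser = SeqIO.parse(handle, fmt)
            while True:
                try:
                    rec = next(parser)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise ParseError(
                        f"malformed {fmt} record at index {len(records)} "
                        f"in {path}: {exc}"
                    ) from exc
                records.append((rec.id, str(rec.seq).upper()))
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    return ReadSet(records)


def _count_canonical(big: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    codes, valid = window_codes(big, k)
    n_skipped = int(valid.size - valid.sum())
    uniq, counts = np.unique(codes[valid], return_counts=True)
    return uniq, counts, n_skipped


def count_kmers(reads: ReadSet, k: int) -> tuple[dict[str, int], dict[str, int]]:
    """Count canonical k-mers (nodes) and (k+1)-mers (edges) across the reads.

    A k-mer and its reverse complement are one object; windows containing an
    ambiguous base (N) are skipped.  k must be odd so that no k-mer is its
    own reverse complement.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not 3 <= k <= 31:
        raise ValueError("k must be in [3, 31]")
    # Concatenate reads with an N separator: one vectorised pass over all
    # windows, with separators invalidating windows that straddle reads.
    big = encode_bases("N".join(seq for seq in reads.sequences())) if len(reads) else np.empty(0, np.uint8)
    node_codes, node_counts, skipped = _count_canonical(big, k)
    edge_codes, edge_counts, _ = _count_canonical(big, k + 1)
    if skipped:
        # separators account for len(reads)-1 * k invalid windows at most
        logger.info("skipped %d k-mer windows containing N or read boundaries", skipped)
    nodes = dict(zip(decode_codes(node_codes, k), (int(c) for c in node_counts)))
    edges = dict(zip(decode_codes(edge_codes, k + 1), (int(c) for c in edge_counts)))
    return nodes, edges


def _incidence(edge: str, abundance: int, k: int) -> list[tuple[str, Side, AdjacencyEntry]]:
    """The one or two (node, side, entry) incidences of a canonical edge."""
    u, v = edge[:-1], edge[1:]
    cu, cv = canonical(u), canonical(v)
    if u == cu:
        side_u: Side = FORWARD
        sym_u = edge[-1]
    else:
        side_u = BACKWARD
        sym_u = revcomp(edge[-1])
    if v == cv:
        side_v: Side = BACKWARD
        sym_v = edge[0]
    else:
        side_v = FORWARD
        sym_v = revcomp(edge[0])
    out = [
        (cu, side_u, AdjacencyEntry(sym_u, edge, abundance, cv, side_v)),
        (cv, side_v, AdjacencyEntry(sym_v, edge, abundance, cu, side_u)),
    ]
    if out[0][:2] == out[1][:2] and out[0][2] == out[1][2]:
        # palindromic (k+1)-mer: both incidences coincide (hairpin edge)
        out = out[:1]
    return out


def build_graph(
    node_counts: dict[str, int], edge_counts: dict[str, int], k: int
) -> KmerGraph:
    """Assemble the bidirected graph from canonical count maps.

    Raises :class:`GraphError` if an edge's flanking k-mer is missing from
    the node map (dangling edge).
    """
    adjacency: dict[str, dict[Side, list[AdjacencyEntry]]] = {
        node: {FORWARD: [], BACKWARD: []} for node in node_counts
    }
    for edge, abundance in edge_counts.items():
        for node, side, entry in _incidence(edge, abundance, k):
            if node not in node_counts:
                raise GraphError(
                    f"dangling edge {edge}: flanking k-mer {node} absent from nodes"
                )
            adjacency[node][side].append(entry)
    for node in adjacency:
        for side in (FORWARD, BACKWARD):
            adjacency[node][side].sort(key=lambda e: e.symbol)
    return KmerGraph(k=k, nodes=dict(node_counts), edges=dict(edge_counts), adjacency=adjacency)


def graph_from_reads(reads: ReadSet, k: int) -> KmerGraph:
    nodes, edges = count_kmers(reads, k)
    return build_graph(nodes, edges, k)


def abundance_histogram(graph: KmerGraph) -> AbundanceHistogram:
    """Histogram of node abundances; totals equal the node count."""
    counts: dict[int, int] = {}
    for a in graph.nodes.values():
        counts[a] = counts.get(a, 0) + 1
    return AbundanceHistogram(counts)


def write_graph_tsv(graph: KmerGraph, path: str | Path) -> None:
    """Dump the graph as TSV: a K header, then one N/E line per node/edge."""
    with open(path, "w") as fh:
        fh.write(f"K\t{graph.k}\n")
        for kmer in sorted(graph.nodes):
            fh.write(f"N\t{kmer}\t{graph.nodes[kmer]}\n")
        for edge in sorted(graph.edges):
            fh.write(f"E\t{edge}\t{graph.edges[edge]}\n")


def read_graph_tsv(path: str | Path) -> KmerGraph:
    nodes: dict[str, int] = {}
    edges: dict[str, int] = {}
    k: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            tag = parts[0]
            try:
                if tag == "K":
                    k = int(parts[1])
                elif tag == "N":
                    nodes[parts[1]] = int(parts[2])
                elif tag == "E":
                    edges[parts[1]] = int(parts[2])
                else:
                    raise ValueError(f"unknown tag {tag!r}")
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if k is None:
        raise ParseError(f"{path}: missing K header line")
    return build_graph(nodes, edges, k)


def write_histogram_tsv(hist: AbundanceHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("abundance\tn_kmers\n")
        for a in sorted(hist.counts):
            fh.write(f"{a}\t{hist.counts[a]}\n")


def read_histogram_tsv(path: str | Path) -> AbundanceHistogram:
    counts: dict[int, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("abundance"):
            raise ParseError(f"{path}: expected 'abundance\\tn_kmers' header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            try:
                a, n = line.split("\t")
                counts[int(a)] = int(n)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return AbundanceHistogram(counts)
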