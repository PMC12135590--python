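"""Contig generation over the de Bruijn graph using only edges that qualify
as unique extensions in both directions.

An edge S->T qualifies when both flanking nodes are solid (abundance at or
above ``min_node_abundance``), both node abundances have a defined extension
threshold, and the edge abundance reaches the threshold of *each* endpoint.
The bidirectional requirement is what stops traversal at repeat boundaries
(the repeat-side node demands more evidence than the edge has) and at
sequencing-error boundaries (the erroneous node is filtered or its side
fails the check).

Because every defined threshold exceeds half the node abundance and the edge
abundances on one node side sum to at most the node abundance, at most one
edge per side can qualify: traversal is branch-free, and each maximal walk
is a contig.  Walks are seeded from unmarked eligible nodes in lexicographic
order, extended right then left, and every visited node is marked so the
contig paths partition the eligible nodes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._kmers import canonical, revcomp
from .errors import PathError
from .graph import KmerGraph
from .misassembly import ThresholdTable, total_misassembly_prob
from .repeat_model import RepeatPosterior

DEFAULT_MIN_NODE_ABUNDANCE = 5  # abundances below this are treated as sequencing error
DEFAULT_REPORT_FLOOR = 100      # contigs shorter than this are flagged, not dropped


@dataclass
class Contig:
    id: str
    sequence: str
    path: list[tuple[str, str]]            # (canonical node, '+'/'-') per step
    junction_probs: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.path)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContigSet:
    contigs: list[Contig]
    k: int
    epsilon: float | None = None

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def sequences(self) -> list[str]:
        return [c.sequence for c in self.contigs]


def edge_qualifies(
    graph: KmerGraph,
    table: ThresholdTable,
    edge: str,
    min_node_abundance: int = DEFAULT_MIN_NODE_ABUNDANCE,
) -> bool:
    """Bidirectional uniqueness check for one canonical (k+1)-mer edge."""
    f_e = graph.edges.get(edge)
    if f_e is None:
        raise KeyError(f"edge {edge} not in graph")
    for flank in (edge[:-1], edge[1:]):
        a = graph.nodes[canonical(flank)]
        if a < min_node_abundance:
            return False
        ell = table.thresholds.get(a)
        if ell is None or f_e < ell:
            return False
    return True


def spell_path(path: list[tuple[str, str]], k: int) -> str:
    """Spell a node path: first oriented k-mer plus the last base of each
    successor.  Consecutive oriented k-mers must overlap by k-1 characters
    (PathError otherwise); spelling the reversed, strand-flipped path gives
    the reverse complement.
    """
    if not path:
        return ""
    oriented = []
    for node, orient in path:
        if len(node) != k:
            raise PathError(f"node {node} has length {len(node)}, expected k={k}")
        if orient not in "+-":
            raise PathError(f"orientation must be '+' or '-', got {orient!r}")
        oriented.append(node if orient == "+" else revcomp(node))
    for i in range(len(oriented) - 1):
        if oriented[i][1:] != oriented[i + 1][:-1]:
            raise PathError(
                f"broken adjacency between path steps {i} and {i + 1}: "
                f"{oriented[i]} !~ {oriented[i + 1]}"
            )
    return oriented[0] + "".join(s[-1] for s in oriented[1:])


def _qualifying_successor(
    graph: KmerGraph,
    table: ThresholdTable,
    s: str,
    min_node_abundance: int,
) -> tuple[str, str, int] | None:
    """The unique qualifying right-extension of oriented k-mer ``s``, if any.

    Returns (next oriented k-mer, canonical edge, edge abundance).  Asserts
    branch-freeness: thresholds > a/2 make two qualifying edges on one side
    impossible.
    """
    a_s = graph.nodes[canonical(s)]
    ell_s = table.thresholds.get(a_s)
    if a_s < min_node_abundance or ell_s is None:
        return None
    found = []
    for c in "ACGT":
        e = canonical(s + c)
        f_e = graph.edges.get(e)
        if f_e is None or f_e < ell_s:
            continue
        t = s[1:] + c
        a_t = graph.nodes[canonical(t)]
        if a_t < min_node_abundance:
            continue
        ell_t = table.thresholds.get(a_t)
        if ell_t is None or f_e < ell_t:
            continue
        found.append((t, e, f_e))
    assert len(found) <= 1, (
        f"branch-freeness violated at {s}: {len(found)} qualifying extensions"
    )
    return found[0] if found else None


def _walk_right(
    graph: KmerGraph,
    table: ThresholdTable,
    start: str,
    min_node_abundance: int,
    marked: set[str],
    in_walk: set[str],
) -> list[str]:
    """Extend ``start`` rightwards across qualifying edges.  Stops at nodes
    already in this walk (cycle guard) or marked by a previous contig."""
    path = [start]
    s = start
    while True:
        step = _qualifying_successor(graph, table, s, min_node_abundance)
        if step is None:
            break
        t, _, _ = step
        ct = canonical(t)
        if ct in in_walk or ct in marked:
            break
        path.append(t)
        in_walk.add(ct)
        s = t
    return path


def generate_contigs(
    graph: KmerGraph,
    table: ThresholdTable,
    min_node_abundance: int = DEFAULT_MIN_NODE_ABUNDANCE,
    annotate: bool = False,
    posterior: RepeatPosterior | None = None,
) -> ContigSet:
    """Traverse the graph and spell one contig per maximal qualifying walk.

    Eligible nodes (abundance >= ``min_node_abundance``) seed walks in
    lexicographic order; each eligible node ends up in exactly one contig
    (possibly a singleton).  With ``annotate`` (requires ``posterior``),
    every used edge carries the worse of its two directional misassembly
    probabilities, each of which is below the table's epsilon by
    construction.
    """
    eligible = sorted(n for n, a in graph.nodes.items() if a >= min_node_abundance)
    for node in eligible:
        if graph.nodes[node] not in table:
            raise ValueError(
                f"threshold table has no row for observed abundance {graph.nodes[node]}"
            )
    if annotate and posterior is None:
        raise ValueError("annotate=True requires a repeat posterior")

    marked: set[str] = set()
    contigs: list[Contig] = []
    # junction probabilities depend only on (node abundance, edge abundance)
    prob_cache: dict[tuple[int, int], float] = {}

    def junction_prob(a: int, f_e: int) -> float:
        key = (a, f_e)
        if key not in prob_cache:
            prob_cache[key] = total_misassembly_prob(
                a, f_e, posterior.row(a), table.method)
        return prob_cache[key]

    for seed in eligible:
        if seed in marked:
            continue
        in_walk = {seed}
        right = _walk_right(graph, table, seed, min_node_abundance, marked, in_walk)
        left = _walk_right(graph, table, revcomp(seed), min_node_abundance, marked, in_walk)
        oriented = [revcomp(s) for s in reversed(left[1:])] + right
        marked.update(in_walk)
        path = [(canonical(s), "+" if s == canonical(s) else "-") for s in oriented]
        probs: list[float] = []
        if annotate:
            for s, t in zip(oriented, oriented[1:]):
                e = canonical(s + t[-1])
                f_e = graph.edges[e]
                p = 0.0
                for flank in (s, t):
                    p = max(p, junction_prob(graph.nodes[canonical(flank)], f_e))
                probs.append(p)
        contigs.append(Contig(
            id=f"contig_{len(contigs)}",
            sequence=spell_path(path, graph.k),
            path=path,
            junction_probs=probs,
        ))
    return ContigSet(contigs=contigs, k=graph.k, epsilon=table.epsilon)


def write_contigs(
    contigs: ContigSet,
    fasta_path: str | Path,
    annot_path: str | Path | None = None,
    report_floor: int = DEFAULT_REPORT_FLOOR,
) -> None:
    """Write contigs as FASTA and per-junction probabilities as TSV.

    Headers are ``contig_<n> len=<L> nodes=<m>`` with a ``short=yes`` flag
    for contigs below ``report_floor`` bp (still written; filtering is the
    caller's choice).  Junction i sits between sequence positions k-1+i and
    k+i of its contig.
    """
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("contig ids must be unique")
    with open(fasta_path, "w") as fh:
        for c in contigs:
            flag = " short=yes" if len(c) < report_floor else ""
            fh.write(f">{c.id} len={len(c)} nodes={c.n_nodes}{flag}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")
    if annot_path is not None:
        with open(annot_path, "w") as fh:
            fh.write("contig_id\tjunction_index\tprobability\n")
            for c in contigs:
                for i, p in enumerate(c.junction_probs):
                    fh.write(f"{c.id}\t{i}\t{p:.6e}\n")
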