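"""Contig traversal: bidirectional edge qualification, path spelling,
marking/partition semantics, and output writing."""
from __future__ import annotations

import numpy as np
import pytest

from certig import (
    ReadSet,
    abundance_histogram,
    build_graph,
    build_threshold_table,
    edge_qualifies,
    fit_mixture,
    generate_contigs,
    graph_from_reads,
    make_genome,
    posterior_table,
    read_sequences,
    simulate_reads,
    spell_path,
    write_contigs,
)
from certig._kmers import canonical, revcomp
from certig.errors import PathError
from certig.misassembly import ThresholdTable

from conftest import naive_revcomp, unique_posterior


def unique_table(max_abundance: int, epsilon: float = 0.01) -> ThresholdTable:
    """Threshold table for an all-unique posterior: ell*(a) = floor(a/2)+1."""
    return ThresholdTable(
        epsilon=epsilon,
        method="exact",
        thresholds={a: a // 2 + 1 for a in range(1, max_abundance + 1)},
    )


class TestSpellPath:
    def test_forward_path(self):
        assert spell_path([("AAA", "+"), ("AAC", "+"), ("ACC", "+")], 3) == "AAACC"

    def test_single_node(self):
        assert spell_path([("ACC", "+")], 3) == "ACC"
        assert spell_path([("ACC", "-")], 3) == "GGT"

    def test_broken_adjacency(self):
        with pytest.raises(PathError, match="broken adjacency"):
            spell_path([("AAA", "+"), ("CCC", "+")], 3)

    def test_reverse_path_spells_reverse_complement(self):
        """Holds for random paths derived from random sequences."""
        rng = np.random.default_rng(7)
        k = 5
        for _ in range(100):
            n = int(rng.integers(1, 12))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k + n - 1))
            path = []
            for i in range(n):
                w = seq[i : i + k]
                c = canonical(w)
                path.append((c, "+" if w == c else "-"))
            assert spell_path(path, k) == seq
            flipped = [(node, "-" if o == "+" else "+") for node, o in reversed(path)]
            assert spell_path(flipped, k) == naive_revcomp(seq)


class TestEdgeQualifies:
    def _graph(self, f_s: int, f_t: int, f_e: int):
        # AAC --AACC--> ACC, all three canonical
        return build_graph({"AAC": f_s, "ACC": f_t}, {"AACC": f_e}, 3)

    def test_qualifies_both_directions(self):
        g = self._graph(40, 40, 38)
        table = ThresholdTable(0.01, "exact", {40: 21})
        assert edge_qualifies(g, table, "AACC")

    def test_repeat_boundary_fails_one_direction(self):
        """Unique node S can extend towards repeat node T, but T has no
        defined threshold: the edge must not be used."""
        g = self._graph(40, 80, 38)
        table = ThresholdTable(0.01, "exact", {40: 21, 80: None})
        assert not edge_qualifies(g, table, "AACC")

    def test_below_min_node_abundance(self):
        g = self._graph(4, 40, 4)
        table = ThresholdTable(0.01, "exact", {4: 3, 40: 21})
        assert not edge_qualifies(g, table, "AACC", min_node_abundance=5)


class TestGenerateContigs:
    def test_repeat_free_genome_single_contig(self):
        truth = make_genome(2000, seed=9)
        reads = simulate_reads(truth, 40, 150, 0.0, seed=10)
        g = graph_from_reads(reads, 31)
        table = unique_table(g.max_abundance())
        contigs = generate_contigs(g, table)
        assert len(contigs) == 1
        seq = contigs.contigs[0].sequence
        assert len(seq) >= len(truth.genome) - 2 * 31
        assert seq in truth.genome or naive_revcomp(seq) in truth.genome

    def test_planted_repeat_splits_contigs(self, synthetic_instance):
        g = synthetic_instance["graph"]
        truth = synthetic_instance["truth"]
        contigs = generate_contigs(g, synthetic_instance["table"])
        assert len(contigs) >= 3
        for c in contigs:
            assert c.sequence in truth.genome or naive_revcomp(c.sequence) in truth.genome

    def test_all_nodes_below_min_abundance(self):
        g = graph_from_reads(ReadSet([("r", "ACGTTGCAACGTAT")]), 5)
        contigs = generate_contigs(g, unique_table(10))
        assert len(contigs) == 0

    def test_missing_threshold_row_raises(self):
        g = build_graph({"AAC": 40}, {}, 3)
        with pytest.raises(ValueError, match="abundance 40"):
            generate_contigs(g, ThresholdTable(0.01, "exact", {10: 6}))

    def test_eligible_nodes_partitioned(self, synthetic_instance):
        g = synthetic_instance["graph"]
        contigs = generate_contigs(g, synthetic_instance["table"])
        eligible = {n for n, a in g.nodes.items() if a >= 5}
        seen: list[str] = []
        for c in contigs:
            seen.extend(node for node, _ in c.path)
        assert len(seen) == len(set(seen))
        assert set(seen) == eligible

    def test_deterministic(self, synthetic_instance):
        g = synthetic_instance["graph"]
        t = synthetic_instance["table"]
        first = [c.sequence for c in generate_contigs(g, t)]
        second = [c.sequence for c in generate_contigs(g, t)]
        assert first == second

    def test_cycle_guard_on_circular_graph(self):
        """A hand-built circular component yields one linear contig covering
        every node exactly once (the walk stops before re-entering itself)."""
        k, length = 5, 30
        rng_seed = 0
        while True:  # first seed whose rotations have distinct canonical k-mers
            rng = np.random.default_rng(rng_seed)
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            ring = s + s[: k - 1]
            nodes = [canonical(ring[i : i + k]) for i in range(length)]
            ring_e = s + s[:k]
            edges = {canonical(ring_e[i : i + k + 1]) for i in range(length)}
            if len(set(nodes)) == length and len(edges) == length:
                break
            rng_seed += 1
        g = build_graph({n: 10 for n in nodes}, {e: 10 for e in edges}, k)
        contigs = generate_contigs(g, unique_table(10))
        assert len(contigs) == 1
        c = contigs.contigs[0]
        assert c.n_nodes == length
        assert len(c.sequence) == k + length - 1
        doubled = s + s
        assert c.sequence in doubled or naive_revcomp(c.sequence) in doubled

    def test_junction_probabilities_below_epsilon(self, synthetic_instance):
        contigs = generate_contigs(
            synthetic_instance["graph"],
            synthetic_instance["table"],
            annotate=True,
            posterior=synthetic_instance["posterior"],
        )
        assert any(c.junction_probs for c in contigs)
        for c in contigs:
            assert len(c.junction_probs) == max(0, c.n_nodes - 1)
            assert all(0.0 <= p < 0.01 for p in c.junction_probs)


class TestWriteContigs:
    def test_fasta_roundtrip_and_headers(self, tmp_path, synthetic_instance):
        contigs = generate_contigs(
            synthetic_instance["graph"],
            synthetic_instance["table"],
            annotate=True,
            posterior=synthetic_instance["posterior"],
        )
        fasta = tmp_path / "c.fasta"
        annot = tmp_path / "c.tsv"
        write_contigs(contigs, fasta, annot)
        back = read_sequences(fasta, format="fasta")
        assert [seq for _, seq in back.records] == contigs.sequences()
        header = fasta.read_text().splitlines()[0]
        assert header.startswith(">contig_0 len=") and "nodes=" in header
        lines = annot.read_text().splitlines()
        assert lines[0] == "contig_id\tjunction_index\tprobability"
        assert all(float(l.split("\t")[2]) < 0.01 for l in lines[1:])

    def test_single_node_contig_has_no_junction_rows(self, tmp_path):
        g = build_graph({"ACC": 9}, {}, 3)
        contigs = generate_contigs(g, unique_table(9))
        fasta = tmp_path / "one.fasta"
        annot = tmp_path / "one.tsv"
        write_contigs(contigs, fasta, annot)
        assert ">contig_0 len=3 nodes=1 short=yes" in fasta.read_text()
        assert annot.read_text().splitlines() == ["contig_id\tjunction_index\tprobability"]
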