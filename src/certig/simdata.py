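"""Synthetic genomes with planted repeats, simulated reads, and contig
validation against the known truth.

The generator emulates the structure the assembler has to cope with: a
uniform random background sequence in which each requested repeat is planted
as alpha exact copies at non-overlapping positions.  Reads are sampled
uniformly from either strand with independent per-base substitution errors
(no indels).  Validation declares a contig correct iff it is an exact
substring of the genome or its reverse complement, and measures the genome
fraction covered by correct contig placements — a minimal stand-in for
reference-based assembly evaluation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kmers import revcomp
from .errors import GenerationError
from .graph import ReadSet

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RepeatAnnotation:
    positions: list[int]   # start of each copy, 0-based
    length: int
    alpha: int             # copy count


@dataclass
class SyntheticTruth:
    genome: str
    repeats: list[RepeatAnnotation]
    seed: int
    read_length: int | None = None
    coverage: float | None = None
    error_rate: float | None = None

    def __len__(self) -> int:
        return len(self.genome)


@dataclass
class ValidationReport:
    n_contigs: int
    misassembled: int
    genome_fraction: float          # percent of genome positions covered
    correct_flags: list[bool] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, size=length)]


def make_genome(
    length: int,
    repeat_specs: list[tuple[int, int]] = (),
    seed: int = 0,
    max_tries: int = 1000,
) -> SyntheticTruth:
    """Uniform random genome with planted exact repeats.

    ``repeat_specs`` is a list of (copy count alpha, repeat length); each
    repeat is written as alpha identical copies at non-overlapping random
    positions.  alpha must lie in [2, 5] and the total repeat footprint must
    fit the genome.  Placement that keeps failing after ``max_tries``
    rejection rounds raises :class:`GenerationError`.
    """
    footprint = sum(alpha * rlen for alpha, rlen in repeat_specs)
    if footprint >= length:
        raise GenerationError(
            f"repeat footprint {footprint} does not fit genome length {length}"
        )
    for alpha, rlen in repeat_specs:
        if not 2 <= alpha <= 5:
            raise GenerationError(f"repeat copy count must be in [2, 5], got {alpha}")
    rng = np.random.default_rng(seed)
    genome = _random_dna(rng, length)
    occupied: list[tuple[int, int]] = []
    annotations: list[RepeatAnnotation] = []
    for alpha, rlen in repeat_specs:
        template = _random_dna(rng, rlen)
        placed: list[int] = []
        for _ in range(alpha):
            for _try in range(max_tries):
                pos = int(rng.integers(0, length - rlen + 1))
                if all(pos + rlen <= s or pos >= e for s, e in occupied):
                    occupied.append((pos, pos + rlen))
                    placed.append(pos)
                    break
            else:
                raise GenerationError(
                    f"could not place copy of a {rlen} bp repeat after {max_tries} tries"
                )
        for pos in placed:
            genome[pos : pos + rlen] = template
        annotations.append(RepeatAnnotation(sorted(placed), rlen, alpha))
    return SyntheticTruth(
        genome=genome.tobytes().decode("ascii"), repeats=annotations, seed=seed
    )


def simulate_reads(
    truth: SyntheticTruth,
    coverage: float,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniformly positioned reads from either strand with substitution errors.

    The read count is floor(coverage * genome length / read length), so the
    total base yield falls within one read of the requested coverage.
    """
    genome_len = len(truth.genome)
    if read_length > genome_len:
        raise ValueError(f"read length {read_length} exceeds genome length {genome_len}")
    rng = np.random.default_rng(seed)
    n_reads = int(coverage * genome_len // read_length)
    genome = np.frombuffer(truth.genome.encode("ascii"), dtype=np.uint8)
    starts = rng.integers(0, genome_len - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    records: list[tuple[str, str]] = []
    for i in range(n_reads):
        seq = genome[starts[i] : starts[i] + read_length].copy()
        if error_rate > 0.0:
            hit = np.where(rng.random(read_length) < error_rate)[0]
            if hit.size:
                # substitute with one of the three other bases
                cur = np.searchsorted(_ALPHABET, seq[hit])
                seq[hit] = _ALPHABET[(cur + rng.integers(1, 4, size=hit.size)) % 4]
        read = seq.tobytes().decode("ascii")
        if strands[i]:
            read = revcomp(read)
        records.append((f"read_{i}", read))
    truth.read_length = read_length
    truth.coverage = coverage
    truth.error_rate = error_rate
    return ReadSet(records)


def expected_kmer_coverage(base_coverage: float, read_length: int, k: int) -> float:
    """Mean k-mer coverage implied by base coverage: each read of length L
    contributes L - k + 1 k-mer windows, so coverage scales by (L-k+1)/L."""
    if k > read_length:
        raise ValueError(f"k={k} exceeds read length {read_length}")
    return base_coverage * (read_length - k + 1) / read_length


def validate_contigs(contigs, truth: SyntheticTruth) -> ValidationReport:
    """Exact-substring validation of contigs against the true genome.

    A contig is correct iff it occurs in the genome or its reverse
    complement; the genome fraction counts positions covered by at least one
    placement of a correct contig (all occurrences, both strands).
    """
    genome = truth.genome
    genome_rc = revcomp(genome)
    covered = np.zeros(len(genome), dtype=bool)
    flags: list[bool] = []
    sequences = contigs.sequences() if hasattr(contigs, "sequences") else list(contigs)
    for seq in sequences:
        ok = False
        for hay, reverse in ((genome, False), (genome_rc, True)):
            start = hay.find(seq)
            while start != -1:
                ok = True
                if reverse:
                    lo = len(genome) - start - len(seq)
                    covered[lo : lo + len(seq)] = True
                else:
                    covered[start : start + len(seq)] = True
                start = hay.find(seq, start + 1)
        flags.append(ok)
    fraction = 100.0 * covered.sum() / len(genome) if len(genome) else 0.0
    return ValidationReport(
        n_contigs=len(flags),
        misassembled=sum(not f for f in flags),
        genome_fraction=float(fraction),
        correct_flags=flags,
    )


def write_genome_fasta(truth: SyntheticTruth, path: str | Path, name: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(truth.genome), 80):
            fh.write(truth.genome[i : i + 80] + "\n")


def write_reads_fasta(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads.records:
            fh.write(f">{rid}\n{seq}\n")


def write_truth_bed(truth: SyntheticTruth, path: str | Path, name: str = "genome") -> None:
    """Repeat annotations as BED-like TSV (0-based, half-open)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\trepeat_id\talpha\n")
        for i, rep in enumerate(truth.repeats):
            for pos in rep.positions:
                fh.write(f"{name}\t{pos}\t{pos + rep.length}\trepeat_{i}\t{rep.alpha}\n")
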