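"""Probability that a de Bruijn graph extension is not unique, and the
abundance thresholds derived from it.

Model: let S be a k-mer with abundance a that occurs alpha >= 2 times in the
genome.  In the worst case alpha-1 of its genomic extensions agree and one
differs, so the abundance of the majority extension Sc is distributed as
Binomial(a, (alpha-1)/alpha).  The probability that Sc reaches abundance at
least ell despite not being a unique extension is the binomial right tail;
multiplying by alpha accounts for which extension plays the majority role.
Mixing over the repeat-multiplicity posterior P(alpha | a) (alpha = 0 and 1
contribute nothing: a unique k-mer cannot have a non-unique extension) gives
the total misassembly probability of an edge.

For each node abundance a, the minimal extension abundance ell*(a) with
total probability below a user bound epsilon is tabulated once and applied
to every node of that abundance.  The scan starts at floor(a/2)+1, so a
defined threshold always exceeds a/2 — which is what guarantees that at most
one edge per node side can qualify, making traversal branch-free.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ValidityError
from .repeat_model import MAX_ALPHA, RepeatPosterior

EXACT = "exact"
FERRANTE = "ferrante"
TAIL_METHODS = (EXACT, FERRANTE)

#: sentinel for "no threshold achieves the bound at this abundance"
ABSENT = None


def _check_args(a: int, ell: int, alpha: int) -> None:
    if a < 1:
        raise ValueError(f"abundance a must be >= 1, got {a}")
    if not 0 <= ell <= a:
        raise ValueError(f"ell must lie in [0, a={a}], got {ell}")
    if alpha < 2:
        raise ValueError(f"alpha must be >= 2 for a repeat, got {alpha}")


def binom_tail_exact(a: int, ell: int, alpha: int) -> float:
    """P(X >= ell) for X ~ Binomial(a, (alpha-1)/alpha), in log space.

    Sums C(a,i) p^i (1-p)^(a-i) for i = ell..a via log-gamma terms and
    logsumexp, which stays stable far into the tail.
    """
    _check_args(a, ell, alpha)
    if ell == 0:
        return 1.0
    p = (alpha - 1) / alpha
    i = np.arange(ell, a + 1)
    log_terms = (
        gammaln(a + 1) - gammaln(i + 1) - gammaln(a - i + 1)
        + i * np.log(p) + (a - i) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def ferrante_bound(a: int, ell: int, alpha: int) -> float:
    """Chernoff-type right-tail upper bound on the binomial tail.

    With x = ell/a and p = (alpha-1)/alpha the bound is

        1/(1-r) * 1/sqrt(2 pi x (1-x) a) * exp(-a D(x || p))

    where r = p(1-x) / (x(1-p)) is the odds ratio and D is the Bernoulli
    Kullback-Leibler divergence (natural log).  Valid only for x > p and
    ell < a; outside that region a :class:`ValidityError` is raised and the
    caller falls back to the exact tail.  The bound may exceed 1.
    """
    _check_args(a, ell, alpha)
    p = (alpha - 1) / alpha
    x = ell / a
    if x <= p:
        raise ValidityError(f"bound requires ell/a > (alpha-1)/alpha; got {x:.4g} <= {p:.4g}")
    if ell == a:
        raise ValidityError("bound undefined at ell = a; use the exact tail p**a")
    r = (p * (1.0 - x)) / (x * (1.0 - p))
    kl = x * np.log(x / p) + (1.0 - x) * np.log((1.0 - x) / (1.0 - p))
    return float(1.0 / (1.0 - r) / np.sqrt(2.0 * np.pi * x * (1.0 - x) * a) * np.exp(-a * kl))


@lru_cache(maxsize=1 << 20)
def _tail(a: int, ell: int, alpha: int, method: str) -> float:
    """Tail via the chosen method, falling back to exact outside the bound's
    validity region (ell/a <= p, or ell = a where p**a is exact)."""
    if method == EXACT:
        return binom_tail_exact(a, ell, alpha)
    if method == FERRANTE:
        try:
            return ferrante_bound(a, ell, alpha)
        except ValidityError:
            return binom_tail_exact(a, ell, alpha)
    raise ValueError(f"unknown tail method {method!r}; use one of {TAIL_METHODS}")


def nonunique_extension_prob(a: int, ell: int, alpha: int, method: str = EXACT) -> float:
    """min(1, alpha * tail): probability some extension of an alpha-repeat
    reaches abundance ell without being unique.  Errors from the chosen tail
    method propagate; use :func:`total_misassembly_prob` for the fallback
    behaviour."""
    if method == EXACT:
        tail = binom_tail_exact(a, ell, alpha)
    elif method == FERRANTE:
        tail = ferrante_bound(a, ell, alpha)
    else:
        raise ValueError(f"unknown tail method {method!r}; use one of {TAIL_METHODS}")
    return min(1.0, alpha * tail)


def total_misassembly_prob(
    a: int, ell: int, posterior_row: np.ndarray, method: str = EXACT
) -> float:
    """Mixture over repeat classes of the non-unique-extension probability.

    ``posterior_row`` is (P(alpha=0|a), ..., P(alpha=5|a)); classes 0 and 1
    contribute nothing.  Each class term is clamped at 1 before mixing.
    """
    row = np.asarray(posterior_row, dtype=float)
    if row.shape != (MAX_ALPHA + 1,):
        raise ValueError(f"posterior row must have {MAX_ALPHA + 1} entries")
    if abs(row.sum() - 1.0) > 1e-6:
        raise ValueError(f"posterior row sums to {row.sum():.6g}, not 1")
    total = 0.0
    for alpha in range(2, MAX_ALPHA + 1):
        w = row[alpha]
        if w > 0.0:
            total += w * min(1.0, alpha * _tail(a, ell, alpha, method))
    return min(1.0, total)


def threshold_for_abundance(
    a: int, posterior_row: np.ndarray, epsilon: float, method: str = EXACT
) -> int | None:
    """Smallest ell in [floor(a/2)+1, a] with misassembly probability < epsilon,
    or ABSENT (None) when even ell = a fails the bound."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    for ell in range(a // 2 + 1, a + 1):
        if total_misassembly_prob(a, ell, posterior_row, method) < epsilon:
            return ell
    return ABSENT


@dataclass
class ThresholdTable:
    """ell*(a) per node abundance for a fixed misassembly bound epsilon.

    ``thresholds[a]`` is the minimal qualifying extension abundance, or None
    where no threshold can guarantee the bound.  Defined entries always
    satisfy a/2 < ell*(a) <= a.
    """

    epsilon: float
    method: str
    thresholds: dict[int, int | None]

    def __getitem__(self, a: int) -> int | None:
        return self.thresholds[a]

    def __contains__(self, a: int) -> bool:
        return a in self.thresholds

    def defined(self) -> dict[int, int]:
        return {a: t for a, t in self.thresholds.items() if t is not None}


def build_threshold_table(
    posterior: RepeatPosterior, epsilon: float, method: str = EXACT
) -> ThresholdTable:
    """Tabulate ell*(a) for every abundance the posterior covers."""
    thresholds = {
        a: threshold_for_abundance(a, posterior.row(a), epsilon, method)
        for a in range(1, posterior.max_abundance + 1)
    }
    return ThresholdTable(epsilon=epsilon, method=method, thresholds=thresholds)


def write_thresholds_tsv(table: ThresholdTable, path: str | Path) -> None:
    """Export as TSV (abundance, threshold; NA where absent) with the epsilon
    and tail method recorded in comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# epsilon={table.epsilon:.17g}\n")
        fh.write(f"# method={table.method}\n")
        fh.write("abundance\tthreshold\n")
        for a in sorted(table.thresholds):
            t = table.thresholds[a]
            fh.write(f"{a}\t{'NA' if t is None else t}\n")


def read_thresholds_tsv(path: str | Path) -> ThresholdTable:
    epsilon = np.nan
    method = EXACT
    thresholds: dict[int, int | None] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# epsilon="):
                epsilon = float(line.split("=", 1)[1])
            elif line.startswith("# method="):
                method = line.split("=", 1)[1]
            elif line and not line.startswith(("#", "abundance")):
                a_str, t_str = line.split("\t")
                thresholds[int(a_str)] = None if t_str == "NA" else int(t_str)
    return ThresholdTable(epsilon=float(epsilon), method=method, thresholds=thresholds)


def plot_thresholds(table: ThresholdTable, path: str | Path) -> None:
    """Threshold vs abundance scatter with the ell = a diagonal (the maximum
    possible threshold) as a dashed reference; absent entries are gaps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a_all = sorted(table.thresholds)
    defined = table.defined()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(a_all, a_all, "--", color="grey", label="maximum possible threshold")
    if defined:
        ax.plot(sorted(defined), [defined[a] for a in sorted(defined)], ".", label=f"eps = {table.epsilon:g}")
    ax.set_xlabel("k-mer abundance")
    ax.set_ylabel("extension abundance threshold")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
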