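"""Repeat-multiplicity posterior P(alpha | abundance) from the k-mer spectrum.

A k-mer seen ``a`` times in the reads may occur alpha times in the genome
(alpha = 0 denotes a sequencing-error artefact, alpha = 1 a unique k-mer,
alpha >= 2 a repeat).  The abundance histogram is modelled as a mixture of
zero-truncated negative binomial components: an error component with its own
small mean, and genomic components with means alpha * lambda (lambda = mean
per-copy k-mer coverage) sharing one variance-to-mean dispersion.  alpha is
capped at 5; the top class absorbs everything above.

Fitting is EM on the binned histogram.  Component weights have the usual
closed-form update; (error mean, lambda, dispersion) are updated by a
Nelder-Mead step on the expected complete-data log-likelihood started from
the current values, so the observed log-likelihood never decreases.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import nbinom

from .errors import FitError, FormatError
from .graph import AbundanceHistogram

MAX_ALPHA = 5

_INIT_WEIGHTS = np.array([0.1, 0.7, 0.1, 0.05, 0.03, 0.02])


@dataclass
class MixtureModel:
    """Fitted abundance-spectrum mixture.

    lam          mean per-copy k-mer coverage (component alpha has mean alpha*lam)
    error_lam    mean of the sequencing-error component (alpha = 0)
    dispersion   shared variance-to-mean ratio (> 1; ~1 is Poisson-like)
    weights      prior P(alpha) for alpha = 0..max_alpha
    """

    lam: float
    error_lam: float
    dispersion: float
    weights: np.ndarray
    max_alpha: int = MAX_ALPHA
    converged: bool = True
    n_iter: int = 0
    loglik: float = np.nan
    loglik_history: list[float] = field(default_factory=list)

    def component_means(self) -> np.ndarray:
        return np.array([self.error_lam] + [a * self.lam for a in range(1, self.max_alpha + 1)])


def _nb_params(mean: float, dispersion: float) -> tuple[float, float]:
    # mean mu, var d*mu  ->  nbinom(n = mu/(d-1), p = 1/d)
    d = max(dispersion, 1.0 + 1e-6)
    return mean / (d - 1.0), 1.0 / d


def _log_pmf_matrix(
    a: np.ndarray, lam: float, error_lam: float, dispersion: float, max_alpha: int
) -> np.ndarray:
    """log f_alpha(a) for alpha=0..max_alpha, zero-truncated to a >= 1."""
    means = [error_lam] + [alpha * lam for alpha in range(1, max_alpha + 1)]
    out = np.empty((max_alpha + 1, a.size))
    for i, mu in enumerate(means):
        n, p = _nb_params(mu, dispersion)
        lp = nbinom.logpmf(a, n, p)
        lp0 = nbinom.logpmf(0, n, p)
        # renormalise over a >= 1 (abundance 0 is unobservable)
        with np.errstate(divide="ignore"):
            log_trunc = np.log1p(-np.exp(min(lp0, -1e-12)))
        out[i] = lp - log_trunc
    return out


def _observed_loglik(n_a: np.ndarray, log_w: np.ndarray, log_f: np.ndarray) -> float:
    return float(n_a @ logsumexp(log_w[:, None] + log_f, axis=0))


def fit_mixture(
    hist: AbundanceHistogram,
    max_alpha: int = MAX_ALPHA,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit the mixture to an abundance histogram by (generalised) EM.

    ``seed`` is accepted for interface stability; the default deterministic
    initialisation needs no randomness.  Raises :class:`FitError` on a
    degenerate histogram (fewer than two distinct abundance values).
    """
    a, n_a = hist.as_arrays()
    if a.size < 2:
        raise FitError("histogram is degenerate: need mass at >= 2 distinct abundances")

    # init: lambda <- histogram mode restricted to a >= 5 (fall back to global)
    above = a >= 5
    lam = float(a[above][np.argmax(n_a[above])]) if above.any() else float(a[np.argmax(n_a)])
    lam = max(lam, 2.0)
    error_lam = 1.0
    # moment estimate of dispersion around the mode
    window = (a >= 0.5 * lam) & (a <= 1.5 * lam)
    if window.sum() >= 2:
        w = n_a[window] / n_a[window].sum()
        m = float(w @ a[window])
        v = float(w @ (a[window] - m) ** 2)
        dispersion = max(v / m, 1.05) if m > 0 else 1.5
    else:
        dispersion = 1.5
    weights = _INIT_WEIGHTS[: max_alpha + 1].copy()
    weights /= weights.sum()

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_f = _log_pmf_matrix(a, lam, error_lam, dispersion, max_alpha)
        log_w = np.log(np.maximum(weights, 1e-300))
        joint = log_w[:, None] + log_f
        ll = float(n_a @ logsumexp(joint, axis=0))
        history.append(ll)
        if len(history) >= 2:
            prev = history[-2]
            if abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
        # E-step
        resp = np.exp(joint - logsumexp(joint, axis=0))
        # M-step: weights closed-form
        weighted = resp * n_a
        weights = weighted.sum(axis=1) / n_a.sum()

        # M-step: (error_lam, lam, dispersion) by Nelder-Mead on -Q, started
        # at the current point so Q (hence the log-likelihood) cannot drop
        def neg_q(theta: np.ndarray) -> float:
            el, lm, dd = np.exp(theta)
            lf = _log_pmf_matrix(a, lm, el, 1.0 + dd, max_alpha)
            return -float((weighted * lf).sum())

        x0 = np.log([error_lam, lam, max(dispersion - 1.0, 1e-6)])
        res = minimize(neg_q, x0, method="Nelder-Mead",
                       options={"maxiter": 120, "xatol": 1e-4, "fatol": 1e-6})
        if res.fun <= neg_q(x0):
            error_lam, lam, disp_minus1 = np.exp(res.x)
            dispersion = 1.0 + disp_minus1

    log_f = _log_pmf_matrix(a, lam, error_lam, dispersion, max_alpha)
    final_ll = _observed_loglik(n_a, np.log(np.maximum(weights, 1e-300)), log_f)
    return MixtureModel(
        lam=float(lam),
        error_lam=float(error_lam),
        dispersion=float(dispersion),
        weights=weights,
        max_alpha=max_alpha,
        converged=converged,
        n_iter=it,
        loglik=final_ll,
        loglik_history=history,
    )


@dataclass
class RepeatPosterior:
    """P(alpha = alpha' | abundance a) for a = 1..max_abundance, alpha' = 0..5."""

    max_abundance: int
    table: np.ndarray  # shape (max_abundance, 6); row i is abundance i+1

    def row(self, a: int) -> np.ndarray:
        if not 1 <= a <= self.max_abundance:
            raise KeyError(f"abundance {a} outside table range [1, {self.max_abundance}]")
        return self.table[a - 1]

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (self.max_abundance, MAX_ALPHA + 1):
            raise FormatError(
                f"posterior table shape {self.table.shape} != ({self.max_abundance}, {MAX_ALPHA + 1})"
            )
        sums = self.table.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6) or np.any(self.table < -1e-12) or np.any(self.table > 1 + 1e-12):
            raise FormatError("posterior rows must be probabilities summing to 1")


def posterior_table(model: MixtureModel, max_abundance: int) -> RepeatPosterior:
    """Bayes-invert the fitted mixture: P(alpha|a) ∝ w_alpha f_alpha(a)."""
    a = np.arange(1, max_abundance + 1)
    log_f = _log_pmf_matrix(a, model.lam, model.error_lam, model.dispersion, model.max_alpha)
    log_w = np.log(np.maximum(model.weights, 1e-300))
    joint = log_w[:, None] + log_f
    post = np.exp(joint - logsumexp(joint, axis=0)).T
    if model.max_alpha < MAX_ALPHA:
        post = np.hstack([post, np.zeros((max_abundance, MAX_ALPHA - model.max_alpha))])
    post /= post.sum(axis=1, keepdims=True)
    return RepeatPosterior(max_abundance=max_abundance, table=post)


_TSV_COLUMNS = ["abundance", "p0", "p1", "p2", "p3", "p4", "p5"]


def write_posterior_tsv(table: RepeatPosterior, path: str | Path) -> None:
    df = pd.DataFrame(table.table, columns=_TSV_COLUMNS[1:])
    df.insert(0, "abundance", np.arange(1, table.max_abundance + 1))
    df.to_csv(path, sep="\t", index=False)  # default float repr round-trips exactly


def read_posterior_tsv(path: str | Path) -> RepeatPosterior:
    """Load a posterior table (e.g. derived from an external multiplicity tool).

    The format contract: tab-separated, header ``abundance p0 p1 p2 p3 p4 p5``,
    one row per abundance from 1 with no gaps, each row summing to 1 within
    1e-6.  Violations raise :class:`FormatError`.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if list(df.columns) != _TSV_COLUMNS:
        raise FormatError(f"{path}: expected header {' '.join(_TSV_COLUMNS)}")
    abundances = df["abundance"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    if len(df) == 0 or not np.array_equal(abundances, expected):
        missing = sorted(set(range(1, int(abundances.max(initial=0)) + 1)) - set(abundances.tolist()))
        raise FormatError(f"{path}: abundance values must run 1..n without gaps (missing {missing})")
    probs = df[_TSV_COLUMNS[1:]].to_numpy(dtype=float)
    sums = probs.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
    if bad.size:
        raise FormatError(
            f"{path}: row for abundance {int(abundances[bad[0]])} sums to {sums[bad[0]]:.6g}, not 1"
        )
    return RepeatPosterior(max_abundance=len(df), table=probs)


def write_model_summary(model: MixtureModel, path: str | Path) -> None:
    """Small key-value summary of a fitted mixture."""
    with open(path, "w") as fh:
        fh.write(f"lambda\t{model.lam:.6g}\n")
        fh.write(f"error_lambda\t{model.error_lam:.6g}\n")
        fh.write(f"dispersion\t{model.dispersion:.6g}\n")
        for alpha, w in enumerate(model.weights):
            fh.write(f"w{alpha}\t{w:.6g}\n")
        fh.write(f"converged\t{model.converged}\n")
        fh.write(f"n_iter\t{model.n_iter}\n")
        fh.write(f"loglik\t{model.loglik:.6g}\n")


def sample_histogram(
    lam: float,
    weights: np.ndarray,
    dispersion: float,
    n_kmers: int,
    seed: int,
    error_lam: float = 1.0,
    max_alpha: int = MAX_ALPHA,
) -> AbundanceHistogram:
    """Simulate an abundance histogram from the mixture (zero counts dropped).

    Used for parameter-recovery checks: draw each k-mer's class from
    ``weights`` and its abundance from the class's negative binomial.
    """
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    classes = rng.choice(max_alpha + 1, size=n_kmers, p=weights)
    means = np.array([error_lam] + [a * lam for a in range(1, max_alpha + 1)])
    mu = means[classes]
    d = max(dispersion, 1.0 + 1e-6)
    draws = rng.negative_binomial(mu / (d - 1.0), 1.0 / d)
    draws = draws[draws > 0]
    values, counts = np.unique(draws, return_counts=True)
    return AbundanceHistogram(dict(zip((int(v) for v in values), (int(c) for c in counts))))
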