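"""Expectation-maximization estimation of haplotype frequencies.

The model: haplotypes ``h_1, h_2, ...`` segregate in a randomly mating
population with frequencies ``theta = (P(h_1), P(h_2), ...)``.  Under
Hardy-Weinberg equilibrium an individual's diplotype ``[h_l/h_m]`` has
prior ``P(h_l)^2`` when homozygous and ``2 P(h_l) P(h_m)`` otherwise.  The
observed data for individual ``j`` enter only through the multi-site
likelihoods ``lambda_jk`` of its candidate diplotypes ``d_jk``, so the
log-likelihood is

    ln L(theta) = sum_j ln sum_k lambda_jk P(d_jk | theta).

The E step computes posterior diplotype proportions
``w_jk = lambda_jk P(d_jk) / sum_k' lambda_jk' P(d_jk')`` and the M step
re-estimates each haplotype frequency as its posterior-weighted chromosome
count over ``2N``.  Iteration continues until the log-likelihood change
falls below a tolerance; multiple random restarts guard against local
maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .likelihood import DiplotypeExpansion
from .sites import Diplotype, Haplotype, SiteSpec, parse_haplotype

__all__ = [
    "FrequencyTable",
    "EMConfig",
    "EMResult",
    "hwe_prior",
    "e_step",
    "m_step",
    "log_likelihood",
    "run_em",
]

logger = logging.getLogger(__name__)


class FrequencyTable(Dict[Haplotype, float]):
    """Mapping from haplotype to population frequency.

    A valid table has non-negative entries summing to one (within a small
    tolerance); :meth:`validate` enforces this where it matters.
    """

    def normalized(self) -> "FrequencyTable":
        total = sum(self.values())
        if total <= 0:
            raise ValueError("cannot normalize: total frequency is not positive")
        return FrequencyTable({h: v / total for h, v in self.items()})

    def validate(self, atol: float = 1e-9) -> None:
        if any(v < -atol for v in self.values()):
            raise ValueError("negative frequency")
        total = sum(self.values())
        if abs(total - 1.0) > atol:
            raise ValueError(f"frequencies sum to {total!r}, not 1")

    def sorted_items(self) -> List[Tuple[Haplotype, float]]:
        """Items sorted by descending frequency, ties lexicographic."""
        return sorted(self.items(), key=lambda hv: (-hv[1], str(hv[0])))

    @classmethod
    def from_strings(cls, mapping: Mapping[str, float], sites: Sequence[SiteSpec]) -> "FrequencyTable":
        return cls({parse_haplotype(text, sites): float(v) for text, v in mapping.items()})

    @classmethod
    def from_diplotypes(cls, diplotypes: Iterable[Diplotype]) -> "FrequencyTable":
        """Empirical chromosome frequencies of a collection of diplotypes."""
        counts: Dict[Haplotype, float] = {}
        n = 0
        for d in diplotypes:
            counts[d.first] = counts.get(d.first, 0.0) + 1.0
            counts[d.second] = counts.get(d.second, 0.0) + 1.0
            n += 1
        if n == 0:
            raise ValueError("no diplotypes given")
        return cls({h: c / (2 * n) for h, c in counts.items()})


@dataclass(frozen=True)
class EMConfig:
    """Convergence and restart policy for :func:`run_em`.

    ``tolerance`` is the absolute log-likelihood change below which a chain
    stops.  ``n_restarts`` random (flat-Dirichlet) initializations are run
    in addition to one uniform initialization; the chain with the highest
    final log-likelihood wins, ties going to the earliest chain.
    """

    tolerance: float = 1e-8
    max_iterations: int = 10_000
    n_restarts: int = 10
    seed: int = 0
    initialization: str = "uniform"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be non-negative")
        if self.initialization not in ("uniform", "random"):
            raise ValueError("initialization must be 'uniform' or 'random'")


def hwe_prior(diplotype: Diplotype, freqs: Mapping[Haplotype, float]) -> float:
    """Hardy-Weinberg prior probability of a diplotype.

    ``P(h)^2`` for a homozygote, ``2 P(h_l) P(h_m)`` for a heterozygote;
    haplotypes absent from the table have frequency zero.
    """
    p = freqs.get(diplotype.first, 0.0)
    if diplotype.is_homozygous:
        return p * p
    return 2.0 * p * freqs.get(diplotype.second, 0.0)


class _Indexed:
    """Array view of an expansion for vectorized EM iterations.

    When every individual shares the same candidate list (the common case
    for spectra with identical positive-state sets, where the expansion
    reuses one enumeration template), the likelihoods form a dense
    ``(N, K)`` matrix and each EM iteration reduces to two matrix-vector
    products.  Otherwise a flat ragged layout indexed by individual is
    used.
    """

    def __init__(self, expansion: DiplotypeExpansion) -> None:
        universe: set = set()
        for dips in expansion.diplotypes:
            for d in dips:
                universe.add(d.first)
                universe.add(d.second)
        self.haplotypes: List[Haplotype] = sorted(universe, key=str)
        index = {h: i for i, h in enumerate(self.haplotypes)}
        self.n_individuals = len(expansion.individuals)
        self.n_haplotypes = len(self.haplotypes)
        first = expansion.diplotypes[0] if expansion.diplotypes else []
        self.shared = len(expansion.diplotypes) > 0 and all(
            dips is first for dips in expansion.diplotypes
        )
        if self.shared:
            self.l = np.array([index[d.first] for d in first], dtype=np.intp)
            self.m = np.array([index[d.second] for d in first], dtype=np.intp)
            self.lam_matrix = np.vstack(expansion.likelihoods)
        else:
            sizes = [len(d) for d in expansion.diplotypes]
            total = sum(sizes)
            self.j = np.repeat(np.arange(self.n_individuals, dtype=np.intp), sizes)
            self.l = np.empty(total, dtype=np.intp)
            self.m = np.empty(total, dtype=np.intp)
            self.offsets = np.concatenate(([0], np.cumsum(sizes)))
            pos = 0
            for dips in expansion.diplotypes:
                for d in dips:
                    self.l[pos] = index[d.first]
                    self.m[pos] = index[d.second]
                    pos += 1
            self.lam = (
                np.concatenate(expansion.likelihoods)
                if expansion.likelihoods
                else np.empty(0)
            )
        self.het = np.where(self.l == self.m, 1.0, 2.0)

    def priors(self, f: np.ndarray) -> np.ndarray:
        return self.het * f[self.l] * f[self.m]

    def slice(self, j: int) -> slice:
        return slice(self.offsets[j], self.offsets[j + 1])


def e_step(
    expansion: DiplotypeExpansion, freqs: Mapping[Haplotype, float]
) -> List[np.ndarray]:
    """Posterior diplotype proportions per individual.

    ``w_jk`` is proportional to ``lambda_jk`` times the Hardy-Weinberg prior
    and normalized to sum to one within each individual.  Individuals whose
    normalizer is zero (all candidates have zero likelihood or prior) get an
    all-NaN vector and a warning; callers treat them as excluded.
    """
    out: List[np.ndarray] = []
    for ind, dips, lam in zip(expansion.individuals, expansion.diplotypes, expansion.likelihoods):
        a = np.array([lik * hwe_prior(d, freqs) for d, lik in zip(dips, lam)])
        total = a.sum()
        if total <= 0:
            logger.warning("individual %s: zero posterior normalizer; excluded from this run", ind)
            out.append(np.full(len(a), np.nan))
        else:
            out.append(a / total)
    return out


def m_step(
    posteriors: Sequence[np.ndarray], expansion: DiplotypeExpansion
) -> FrequencyTable:
    """Posterior-weighted haplotype counting over ``2N`` chromosomes.

    A homozygous candidate contributes twice its weight to its haplotype, a
    heterozygous candidate once to each.  Individuals with NaN posteriors
    (excluded in the E step) do not count towards ``N``.
    """
    counts: Dict[Haplotype, float] = {}
    n_used = 0
    for w, dips in zip(posteriors, expansion.diplotypes):
        if np.any(np.isnan(w)):
            continue
        n_used += 1
        for wk, d in zip(w, dips):
            counts[d.first] = counts.get(d.first, 0.0) + wk
            counts[d.second] = counts.get(d.second, 0.0) + wk
    if n_used == 0:
        raise ValueError("no usable individuals in M step")
    return FrequencyTable({h: c / (2 * n_used) for h, c in counts.items()})


def log_likelihood(
    expansion: DiplotypeExpansion, freqs: Mapping[Haplotype, float]
) -> float:
    """Observed-data log-likelihood ``sum_j ln sum_k lambda_jk P(d_jk)``.

    Individuals with a non-positive inner sum are skipped with a warning,
    consistent with their exclusion in the E step.
    """
    total = 0.0
    for ind, dips, lam in zip(expansion.individuals, expansion.diplotypes, expansion.likelihoods):
        inner = sum(lik * hwe_prior(d, freqs) for d, lik in zip(dips, lam))
        if inner <= 0:
            logger.warning("individual %s: non-positive likelihood term; skipped", ind)
            continue
        total += np.log(inner)
    return float(total)


@dataclass
class EMResult:
    """Outcome of an EM run.

    ``loglik_trace`` records the observed-data log-likelihood at the start
    of each iteration of the winning chain and is non-decreasing.
    ``posteriors`` materializes the final diplotype proportions as
    ``{individual: {diplotype: w}}``; prefer :meth:`posterior_items` for
    large expansions.
    """

    frequencies: FrequencyTable
    loglik_trace: np.ndarray
    converged: bool
    n_individuals_used: int
    individuals: List[str]
    excluded: List[str]
    best_chain: int
    _diplotypes: List[Sequence[Diplotype]] = field(repr=False, default_factory=list)
    _weights: List[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def final_loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def posterior_items(self):
        """Yield ``(individual, diplotypes, weights)`` triples."""
        yield from zip(self.individuals, self._diplotypes, self._weights)

    @property
    def posteriors(self) -> Dict[str, Dict[Diplotype, float]]:
        return {
            ind: dict(zip(dips, map(float, w)))
            for ind, dips, w in self.posterior_items()
        }


def _deactivate(active: np.ndarray, dead: np.ndarray) -> None:
    for j in np.nonzero(dead)[0]:
        logger.warning(
            "individual index %d: zero posterior normalizer; excluded for this chain", j
        )
    active &= ~dead
    if not np.any(active):
        raise ValueError("no usable individuals remain in EM chain")


def _run_chain_dense(
    idx: _Indexed, f0: np.ndarray, tolerance: float, max_iterations: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, bool, np.ndarray]:
    """EM chain over a shared candidate list.

    With every individual holding the same K candidates, the per-iteration
    sums collapse to two products with the (N, K) likelihood matrix:
    ``denom = Lam @ prior`` and, for the M step,
    ``count_h = sum_k delta(h, d_k) prior_k sum_j Lam_jk / denom_j``.
    """
    lam = idx.lam_matrix
    n = idx.n_individuals
    f = f0.copy()
    active = np.ones(n, dtype=bool)
    trace: List[float] = []
    converged = False
    for _ in range(max_iterations):
        prior = idx.priors(f)
        denom = lam @ prior
        dead = active & (denom <= 0)
        if np.any(dead):
            _deactivate(active, dead)
        inv = np.zeros(n)
        inv[active] = 1.0 / denom[active]
        trace.append(float(np.sum(np.log(denom[active]))))
        pw = prior * (inv @ lam)
        counts = np.bincount(idx.l, weights=pw, minlength=idx.n_haplotypes) + np.bincount(
            idx.m, weights=pw, minlength=idx.n_haplotypes
        )
        f = counts / (2.0 * active.sum())
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tolerance:
            converged = True
            break
    # posteriors at the returned frequencies
    prior = idx.priors(f)
    denom = lam @ prior
    w = lam * prior[None, :]
    safe = np.where((denom > 0) & active, denom, 1.0)
    w /= safe[:, None]
    w[~active] = 0.0
    return f, w, np.array(trace), converged, active


def _run_chain_ragged(
    idx: _Indexed, f0: np.ndarray, tolerance: float, max_iterations: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, bool, np.ndarray]:
    """EM chain over per-individual candidate lists of varying shape."""
    n = idx.n_individuals
    f = f0.copy()
    active = np.ones(n, dtype=bool)
    trace: List[float] = []
    converged = False
    w = np.zeros_like(idx.lam)
    for _ in range(max_iterations):
        a = idx.lam * idx.priors(f)
        denom = np.bincount(idx.j, weights=a, minlength=n)
        dead = active & (denom <= 0)
        if np.any(dead):
            _deactivate(active, dead)
        if active.all():
            w = a / denom[idx.j]
        else:
            safe = np.where(denom > 0, denom, 1.0)
            w = np.where(active[idx.j], a / safe[idx.j], 0.0)
        trace.append(float(np.sum(np.log(denom[active]))))
        counts = np.bincount(idx.l, weights=w, minlength=idx.n_haplotypes) + np.bincount(
            idx.m, weights=w, minlength=idx.n_haplotypes
        )
        f = counts / (2.0 * active.sum())
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tolerance:
            converged = True
            break
    return f, w, np.array(trace), converged, active


def _run_chain(
    idx: _Indexed, f0: np.ndarray, tolerance: float, max_iterations: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, bool, np.ndarray]:
    """One EM chain from initial frequencies ``f0``; returns
    (f, w, trace, converged, active-individual mask)."""
    if idx.shared:
        return _run_chain_dense(idx, f0, tolerance, max_iterations)
    return _run_chain_ragged(idx, f0, tolerance, max_iterations)


def run_em(expansion: DiplotypeExpansion, config: EMConfig = EMConfig()) -> EMResult:
    """Estimate haplotype frequencies by EM with restarts.

    Runs one uniform-initialization chain (or random, per
    ``config.initialization``) plus ``config.n_restarts`` chains initialized
    from a flat Dirichlet, and returns the chain with the highest final
    log-likelihood.  The log-likelihood trace of the winning chain is
    checked for monotonicity (the EM ascent guarantee).

    Raises
    ------
    ValueError
        If the expansion contains no usable individual.
    """
    if expansion.n_individuals == 0:
        raise ValueError("no usable individuals in expansion")
    idx = _Indexed(expansion)
    rng = np.random.default_rng(config.seed)
    uniform = np.full(idx.n_haplotypes, 1.0 / idx.n_haplotypes)
    inits = [
        rng.dirichlet(np.ones(idx.n_haplotypes))
        if (config.initialization == "random" or chain > 0)
        else uniform
        for chain in range(1 + config.n_restarts)
    ]

    best = None
    for chain, f0 in enumerate(inits):
        f, w, trace, converged, active = _run_chain(
            idx, f0, config.tolerance, config.max_iterations
        )
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], chain, f, w, trace, converged, active)

    _, chain, f, w, trace, converged, active = best
    drops = np.diff(trace)
    if drops.size and drops.min() < -max(1e-8, 1e-12 * abs(trace[-1])):
        raise RuntimeError(
            f"EM log-likelihood decreased by {-drops.min():.3g}; ascent property violated"
        )

    freqs = FrequencyTable(
        {h: float(f[i]) for i, h in enumerate(idx.haplotypes)}
    )
    kept_ids: List[str] = []
    kept_dips: List[Sequence[Diplotype]] = []
    kept_w: List[np.ndarray] = []
    dropped: List[str] = list(expansion.excluded)
    for j, ind in enumerate(expansion.individuals):
        if active[j]:
            kept_ids.append(ind)
            kept_dips.append(expansion.diplotypes[j])
            kept_w.append(w[j] if idx.shared else w[idx.slice(j)])
        else:
            dropped.append(ind)
    return EMResult(
        frequencies=freqs,
        loglik_trace=trace,
        converged=converged,
        n_individuals_used=int(active.sum()),
        individuals=kept_ids,
        excluded=dropped,
        best_chain=chain,
        _diplotypes=kept_dips,
        _weights=kept_w,
    )
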