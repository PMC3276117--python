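"""Synthetic-data generation for the phasing EM.

The generator follows the standard evaluation design for likelihood-aware
phasing: known haplotype frequencies are sampled into Hardy-Weinberg
diplotypes; each diplotype's unphased per-site state determines a Gaussian
signal cluster from which a raw intensity is drawn; the same cluster model
then converts the intensity into a likelihood for *every* possible state,
yielding the GenoSpectrum input of the EM.

Cluster layout
--------------
Real array pipelines fit per-state Gaussian mixtures to intensities; those
fitted parameters are data-set specific.  The generator instead uses a
canonical layout — ICN clusters equally spaced along one (log-ratio-like)
axis, SNVC/SNP clusters on a two-channel grid at ``(a, b) * spacing`` for
``a`` copies of the first and ``b`` of the second allele — and calibrates a
common cluster standard deviation so that the expected rate at which the
argmax-likelihood state differs from the true state matches a target
miscall rate.  The miscall rate, not the raw spacing, is what determines
problem difficulty, so calibration pins the simulation to a stated noise
level.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .em import FrequencyTable
from .likelihood import (
    GaussianComponent,
    GenoSpectrum,
    SignalModel,
    icn_likelihoods_from_genotypes,
)
from .sites import (
    Diplotype,
    Haplotype,
    SiteSpec,
    SiteType,
    State,
    collapse_diplotype,
    diplotype_site_state,
    enumerate_unphased_states,
    state_to_str,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "default_cluster_means",
    "default_signal_model",
    "state_distribution",
    "calibrate_noise",
    "sample_population_hwe",
    "simulate_signals",
    "build_genospectrum",
    "exact_spectra",
    "simulate_dataset",
]


def default_cluster_means(site: SiteSpec, spacing: float = 1.0) -> Dict[State, np.ndarray]:
    """Canonical cluster means for every state allowed at *site*.

    ICN: total copy number ``T`` maps to the 1-D point ``T * spacing``.
    SNVC and SNP: a state maps to the point whose coordinates are the
    per-symbol base counts times *spacing* (two-channel layout for a
    two-letter alphabet).
    """
    means: Dict[State, np.ndarray] = {}
    for state in enumerate_unphased_states(site):
        if site.site_type is SiteType.ICN:
            means[state] = np.array([state * spacing], dtype=float)
        else:
            counts = np.array([state.count(sym) for sym in site.alphabet], dtype=float)
            means[state] = counts * spacing
    return means


def default_signal_model(
    sites: Sequence[SiteSpec],
    sd: Union[float, Mapping[str, float]],
    spacing: float = 1.0,
) -> SignalModel:
    """Spherical-Gaussian signal model on the canonical cluster layout."""
    components: Dict[str, Dict[State, GaussianComponent]] = {}
    for site in sites:
        site_sd = float(sd[site.site_id]) if isinstance(sd, Mapping) else float(sd)
        means = default_cluster_means(site, spacing)
        components[site.site_id] = {
            state: GaussianComponent(mean, site_sd**2 * np.eye(mean.size))
            for state, mean in means.items()
        }
    return SignalModel(components)


def state_distribution(
    freqs: Mapping[Haplotype, float], site: SiteSpec, site_index: int = 0
) -> Dict[State, float]:
    """Distribution of the unphased state at one site under HWE pairing."""
    haps = list(freqs)
    probs: Dict[State, float] = {}
    for i, hl in enumerate(haps):
        for hm in haps:
            p = freqs[hl] * freqs[hm]
            if p == 0:
                continue
            state = diplotype_site_state(Diplotype(hl, hm), site_index, site)
            probs[state] = probs.get(state, 0.0) + p
    total = sum(probs.values())
    return {s: p / total for s, p in probs.items()}


def _miscall_rate_1d(
    sd: float, means: np.ndarray, order: np.ndarray, probs: np.ndarray
) -> float:
    """Exact argmax miscall rate for 1-D equal-sd clusters (Voronoi intervals)."""
    mu = means[order]
    bounds = np.concatenate(([-np.inf], (mu[:-1] + mu[1:]) / 2.0, [np.inf]))
    correct = stats.norm.cdf((bounds[1:] - mu) / sd) - stats.norm.cdf((bounds[:-1] - mu) / sd)
    return 1.0 - float(np.dot(probs[order], correct))


def calibrate_noise(
    cluster_means: Mapping[State, np.ndarray],
    state_probs: Mapping[State, float],
    target_miscall_rate: float,
    tol: float = 0.005,
    mc_samples: int = 40_000,
    mc_seed: int = 20110601,
) -> float:
    """Common cluster standard deviation giving a target argmax miscall rate.

    The expected miscall rate is the probability, under the simulating state
    distribution, that a signal drawn from the true state's cluster lies
    closer to another cluster's mean (with a common spherical sd, nearest
    mean and argmax density coincide).  For 1-D layouts the rate is computed
    in closed form from the Voronoi interval boundaries; in higher
    dimensions it is estimated by Monte Carlo with common random numbers so
    that bisection is stable.  The returned sd reproduces the target within
    *tol*.

    Raises
    ------
    ValueError
        If fewer than two clusters are given, the target is outside (0, 1),
        or no sd attains the target.
    """
    states = sorted(cluster_means, key=repr)
    if len(states) < 2:
        raise ValueError("calibration needs at least two clusters")
    if not 0 < target_miscall_rate < 1:
        raise ValueError("target miscall rate must lie in (0, 1)")
    means = np.array([np.atleast_1d(cluster_means[s]) for s in states], dtype=float)
    probs = np.array([state_probs.get(s, 0.0) for s in states], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("state probabilities are all zero")
    probs = probs / probs.sum()
    dim = means.shape[1]

    if dim == 1:
        flat = means[:, 0]
        order = np.argsort(flat, kind="stable")

        def rate(sd: float) -> float:
            return _miscall_rate_1d(sd, flat, order, probs)

    else:
        rng = np.random.default_rng(mc_seed)
        z = rng.standard_normal((mc_samples, dim))
        weighted = np.nonzero(probs > 0)[0]

        def rate(sd: float) -> float:
            miss = 0.0
            for i in weighted:
                x = means[i] + sd * z
                d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
                miss += probs[i] * float(np.mean(np.argmin(d2, axis=1) != i))
            return miss

    gaps = np.sqrt(((means[:, None, :] - means[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(gaps, np.inf)
    scale = float(gaps.min())
    lo, hi = 1e-9 * scale, scale
    for _ in range(40):
        if rate(hi) >= target_miscall_rate:
            break
        hi *= 2.0
    else:
        raise ValueError(f"target miscall rate {target_miscall_rate} is unattainable")

    if dim == 1:
        sd = float(brentq(lambda s: rate(s) - target_miscall_rate, lo, hi, xtol=1e-10))
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if rate(mid) < target_miscall_rate:
                lo = mid
            else:
                hi = mid
        sd = 0.5 * (lo + hi)
    if abs(rate(sd) - target_miscall_rate) > tol:
        raise ValueError(
            f"calibration did not reach target {target_miscall_rate} within {tol}"
        )
    return sd


def sample_population_hwe(
    freqs: Mapping[Haplotype, float],
    n: int,
    rng: Union[int, np.random.Generator],
) -> List[Diplotype]:
    """Draw ``2n`` haplotypes i.i.d. from *freqs* and pair them into ``n``
    Hardy-Weinberg diplotypes."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    haps = sorted(freqs, key=str)
    p = np.array([freqs[h] for h in haps], dtype=float)
    if np.any(p < 0):
        raise ValueError("negative frequency")
    p = p / p.sum()
    draws = rng.choice(len(haps), size=2 * n, p=p)
    return [Diplotype(haps[draws[2 * i]], haps[draws[2 * i + 1]]) for i in range(n)]


def simulate_signals(
    true_diplotypes: Sequence[Diplotype],
    sites: Sequence[SiteSpec],
    model: SignalModel,
    rng: Union[int, np.random.Generator],
) -> Dict[str, np.ndarray]:
    """Draw one Gaussian signal per individual and site from the cluster of
    the individual's true unphased state.

    Returns ``{site_id: array of shape (n, d)}`` in individual order.
    A zero covariance yields the cluster mean exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(true_diplotypes)
    out: Dict[str, np.ndarray] = {}
    for s, site in enumerate(sites):
        states = [diplotype_site_state(d, s, site) for d in true_diplotypes]
        comps = [model.component(site.site_id, st) for st in states]
        dim = comps[0].ndim
        x = np.empty((n, dim))
        z = rng.standard_normal((n, dim))
        chol_cache: Dict[int, np.ndarray] = {}
        for i, comp in enumerate(comps):
            key = id(comp)
            chol = chol_cache.get(key)
            if chol is None:
                cov = comp.cov
                chol = np.zeros_like(cov) if not cov.any() else np.linalg.cholesky(cov)
                chol_cache[key] = chol
            x[i] = comp.mean + chol @ z[i]
        out[site.site_id] = x
    return out


def build_genospectrum(
    measurements: Mapping[str, np.ndarray],
    individuals: Sequence[str],
    sites: Sequence[SiteSpec],
    model: SignalModel,
) -> GenoSpectrum:
    """Likelihood tables from raw signals under a cluster model.

    Per (individual, site) the likelihood of every state is the Gaussian
    density of the measurement under that state's cluster.  When an ICN
    site's model is parameterized by genotype clusters, genotype likelihoods
    sharing a copy number are summed into total-copy-number likelihoods.
    """
    n = len(individuals)
    per_site_tables: Dict[str, List[Dict[State, float]]] = {}
    for site in sites:
        x = np.asarray(measurements[site.site_id], dtype=float)
        if x.shape[0] != n:
            raise ValueError(f"site {site.site_id!r}: {x.shape[0]} measurements for {n} individuals")
        comps = model.components[site.site_id]
        model_states = list(comps)
        liks = np.column_stack([comps[st].pdf(x) for st in model_states])
        tables: List[Dict[State, float]] = []
        genotype_parameterized_icn = (
            site.site_type is SiteType.ICN
            and model_states
            and not isinstance(model_states[0], int)
        )
        for i in range(n):
            table = {st: float(liks[i, k]) for k, st in enumerate(model_states)}
            if genotype_parameterized_icn:
                table = icn_likelihoods_from_genotypes(table)
            tables.append(table)
        per_site_tables[site.site_id] = tables
    return GenoSpectrum(
        {
            ind: {site.site_id: per_site_tables[site.site_id][i] for site in sites}
            for i, ind in enumerate(individuals)
        },
        sites,
    )


def exact_spectra(
    true_diplotypes: Sequence[Diplotype],
    individuals: Sequence[str],
    sites: Sequence[SiteSpec],
) -> GenoSpectrum:
    """Noise-free spectra: a point mass on each individual's true state."""
    tables = {}
    for ind, d in zip(individuals, true_diplotypes):
        tables[ind] = {
            site.site_id: {diplotype_site_state(d, s, site): 1.0}
            for s, site in enumerate(sites)
        }
    return GenoSpectrum(tables, sites)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated study condition.

    Either an explicit ``signal_model`` is given, or one is built on the
    canonical layout with ``spacing`` and either a fixed ``sd`` or a
    ``target_miscall_rate`` to which the sd is calibrated per site.
    """

    sites: Tuple[SiteSpec, ...]
    frequencies: FrequencyTable
    n_individuals: int
    signal_model: Optional[SignalModel] = None
    spacing: float = 1.0
    sd: Optional[Union[float, Mapping[str, float]]] = None
    target_miscall_rate: Optional[float] = None
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        freqs = FrequencyTable(self.frequencies)
        freqs.normalized().validate(atol=1e-9)
        object.__setattr__(self, "frequencies", freqs.normalized())
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be at least 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.signal_model is None and self.sd is None and self.target_miscall_rate is None:
            raise ValueError("give a signal_model, an sd, or a target_miscall_rate")


@dataclass
class SimulatedDataset:
    """One simulated replicate: truth, raw signals and likelihood tables."""

    sites: Tuple[SiteSpec, ...]
    individuals: List[str]
    true_diplotypes: Dict[str, Diplotype]
    measurements: Dict[str, np.ndarray]
    spectra: GenoSpectrum
    model: SignalModel
    empirical_frequencies: FrequencyTable
    sd_by_site: Dict[str, float]


@functools.lru_cache(maxsize=64)
def _calibrated_sd_cached(
    site_key: tuple, freq_key: tuple, spacing: float, target: float
) -> float:
    site = SiteSpec(*site_key)
    means = default_cluster_means(site, spacing)
    probs = dict(freq_key)
    return calibrate_noise(means, probs, target)


def _site_sd(config: SimConfig, site: SiteSpec, site_index: int) -> float:
    if config.sd is not None:
        return float(config.sd[site.site_id]) if isinstance(config.sd, Mapping) else float(config.sd)
    probs = state_distribution(config.frequencies, site, site_index)
    # cache on everything but site_id so replicate sites share one calibration
    site_key = ("", site.site_type.value, site.alphabet,
                site.max_total_copies, site.max_allele_copies)
    freq_key = tuple(sorted(probs.items(), key=lambda kv: repr(kv[0])))
    return _calibrated_sd_cached(site_key, freq_key, config.spacing,
                                 config.target_miscall_rate)


def resolve_signal_model(config: SimConfig) -> Tuple[SignalModel, Dict[str, float]]:
    """The signal model a configuration implies, plus the per-site sd used."""
    if config.signal_model is not None:
        return config.signal_model, {}
    sd_by_site = {
        site.site_id: _site_sd(config, site, i) for i, site in enumerate(config.sites)
    }
    return default_signal_model(config.sites, sd_by_site, config.spacing), sd_by_site


def simulate_dataset(config: SimConfig, replicate: int = 0) -> SimulatedDataset:
    """Generate one replicate of the full pipeline.

    Deterministic in ``(config.seed, replicate)``: the population draw and
    the signal draw use independent streams spawned from that pair.
    """
    model, sd_by_site = resolve_signal_model(config)
    model.validate_against(config.sites)
    pop_rng = np.random.default_rng([config.seed, replicate, 1])
    sig_rng = np.random.default_rng([config.seed, replicate, 2])
    diplotypes = sample_population_hwe(config.frequencies, config.n_individuals, pop_rng)
    individuals = [f"ind{i + 1:04d}" for i in range(config.n_individuals)]
    measurements = simulate_signals(diplotypes, config.sites, model, sig_rng)
    spectra = build_genospectrum(measurements, individuals, config.sites, model)
    return SimulatedDataset(
        sites=config.sites,
        individuals=individuals,
        true_diplotypes=dict(zip(individuals, diplotypes)),
        measurements=measurements,
        spectra=spectra,
        model=model,
        empirical_frequencies=FrequencyTable.from_diplotypes(diplotypes),
        sd_by_site=sd_by_site,
    )
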