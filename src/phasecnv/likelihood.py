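"""Signal models, per-individual likelihood tables and diplotype expansions.

The probabilistic input to the phasing EM is not a hard genotype call but a
per-individual, per-site table mapping every possible unphased state to a
likelihood (a :class:`GenoSpectrum`).  Likelihoods are relative: any
positive per-(individual, site) rescaling leaves every downstream result
unchanged.  They are typically obtained as Gaussian probability densities of
the observed signal intensity under a per-state cluster model
(:class:`SignalModel`), the kind of model an array-calling pipeline fits.

From a spectrum, :func:`build_expansion` enumerates all multi-site
diplotypes consistent with any positive-likelihood state and attaches to
each diplotype the product, over sites, of the likelihood of the unphased
state it implies.  Diplotypes that collapse to the same per-site states
share the same likelihood — signal intensities do not distinguish, say,
[0/3] from [1/2].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .sites import (
    Diplotype,
    InconsistentStatesError,
    SiteSpec,
    SiteType,
    State,
    collapse_diplotype,
    enumerate_site_diplotypes,
    enumerate_unphased_states,
    expand_multisite,
    state_to_str,
)

__all__ = [
    "GaussianComponent",
    "SignalModel",
    "GenoSpectrum",
    "DiplotypeExpansion",
    "state_likelihood",
    "icn_likelihoods_from_genotypes",
    "missing_call_spectrum",
    "prune_states",
    "build_expansion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian signal cluster: mean vector and covariance matrix.

    One-dimensional components may be constructed from scalars.  A
    zero covariance is allowed for sampling (degenerate cluster) but not
    for density evaluation.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 0:
            cov = cov.reshape(1, 1)
        elif cov.ndim == 1:
            cov = np.diag(cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError(f"covariance shape {cov.shape} does not match mean size {mean.size}")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def ndim(self) -> int:
        return self.mean.size

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """Log density of one point (scalar for 1-D, shape ``(d,)``) or a
        batch (``(n, d)``); returns a scalar or a length-``n`` array."""
        x = np.asarray(x, dtype=float)
        if self.ndim == 1:
            single = x.ndim == 0 or x.shape == (1,)
            pts = x.reshape(-1, 1)
        else:
            single = x.ndim == 1
            pts = np.atleast_2d(x)
        if pts.shape[-1] != self.ndim:
            raise ValueError(f"point dimension {pts.shape[-1]} != component dimension {self.ndim}")
        if self.ndim == 1:
            sd = math.sqrt(float(self.cov[0, 0]))
            if sd <= 0:
                raise ValueError("degenerate (zero-variance) component has no density")
            out = stats.norm.logpdf(pts[:, 0], loc=float(self.mean[0]), scale=sd)
        else:
            out = np.atleast_1d(
                stats.multivariate_normal.logpdf(pts, mean=self.mean, cov=self.cov)
            )
        return float(out[0]) if single else out

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))


class SignalModel:
    """Per-site map from unphased state to a Gaussian component.

    Parameters
    ----------
    components
        ``{site_id: {state: GaussianComponent}}``.  For an ICN site the
        states may instead be base multisets (genotype clusters); the
        spectrum builder then sums genotype likelihoods sharing a copy
        number via :func:`icn_likelihoods_from_genotypes`.
    """

    def __init__(self, components: Mapping[str, Mapping[State, GaussianComponent]]) -> None:
        self.components: Dict[str, Dict[State, GaussianComponent]] = {
            sid: dict(comps) for sid, comps in components.items()
        }

    def component(self, site_id: str, state: State) -> GaussianComponent:
        try:
            return self.components[site_id][state]
        except KeyError:
            raise KeyError(f"signal model has no component for state {state!r} at site {site_id!r}") from None

    def validate_against(self, sites: Sequence[SiteSpec]) -> None:
        """Check that every state allowed by each site's caps has a component."""
        for site in sites:
            comps = self.components.get(site.site_id)
            if comps is None:
                raise KeyError(f"signal model has no site {site.site_id!r}")
            if site.site_type is SiteType.ICN and comps and not isinstance(next(iter(comps)), int):
                # genotype-cluster parameterization of an ICN site: every
                # total copy number must be reachable from some genotype
                sizes = {len(state) for state in comps}
                missing = set(range(site.max_total_copies + 1)) - sizes
            else:
                missing = set(enumerate_unphased_states(site)) - set(comps)
            if missing:
                raise KeyError(
                    f"signal model misses states at site {site.site_id!r}: "
                    + ", ".join(sorted(state_to_str(s, site) if not isinstance(s, int) else str(s)
                                       for s in missing))
                )


def state_likelihood(x: np.ndarray, state: State, model: SignalModel, site_id: str) -> float:
    """Gaussian density of the measurement *x* under the cluster of *state*.

    This is a density, not a probability mass; only its relative value
    across states matters downstream.
    """
    return float(model.component(site_id, state).pdf(x))


def icn_likelihoods_from_genotypes(genotype_likelihoods: Mapping[Tuple[str, ...], float]) -> Dict[int, float]:
    """Sum genotype likelihoods sharing a total copy number.

    Signal clusters are often parameterized per sequence genotype even at a
    site analysed as pure copy number; the likelihood of a total copy number
    is then the sum of the likelihoods of all genotypes of that size.
    """
    out: Dict[int, float] = {}
    for genotype, lik in genotype_likelihoods.items():
        out[len(genotype)] = out.get(len(genotype), 0.0) + float(lik)
    return out


def missing_call_spectrum(site: SiteSpec) -> Dict[State, float]:
    """Uninformative (uniform) likelihood table over all states of *site*."""
    return {state: 1.0 for state in enumerate_unphased_states(site)}


class GenoSpectrum:
    """Per-individual, per-site likelihood tables over unphased states.

    Parameters
    ----------
    tables
        ``{individual_id: {site_id: {state: likelihood}}}``.  Likelihoods
        must be non-negative and finite; missing (individual, site) entries
        are treated as missing calls downstream.
    sites
        The ordered site specifications of the locus.
    """

    def __init__(
        self,
        tables: Mapping[str, Mapping[str, Mapping[State, float]]],
        sites: Sequence[SiteSpec],
    ) -> None:
        self.sites: Tuple[SiteSpec, ...] = tuple(sites)
        self._by_id = {s.site_id: s for s in self.sites}
        if len(self._by_id) != len(self.sites):
            raise ValueError("duplicate site_id in sites")
        self.tables: Dict[str, Dict[str, Dict[State, float]]] = {}
        for ind, per_site in tables.items():
            row: Dict[str, Dict[State, float]] = {}
            for sid, table in per_site.items():
                if sid not in self._by_id:
                    raise KeyError(f"individual {ind!r}: unknown site {sid!r}")
                clean = {}
                for state, lik in table.items():
                    lik = float(lik)
                    if not math.isfinite(lik) or lik < 0:
                        raise ValueError(
                            f"individual {ind!r}, site {sid!r}: bad likelihood {lik!r}"
                        )
                    clean[state] = lik
                row[sid] = clean
            self.tables[str(ind)] = row

    @property
    def individuals(self) -> List[str]:
        return list(self.tables)

    def site(self, site_id: str) -> SiteSpec:
        return self._by_id[site_id]

    def table(self, individual: str, site_id: str) -> Optional[Dict[State, float]]:
        """Likelihood table for one (individual, site), or ``None`` if missing."""
        return self.tables.get(individual, {}).get(site_id)

    def point_mass(self) -> "GenoSpectrum":
        """Collapse every table to a point mass on its most likely state.

        This reproduces the deterministic input of earlier phasing
        algorithms that accept only hard calls.  Ties are broken by
        canonical state string.
        """
        out: Dict[str, Dict[str, Dict[State, float]]] = {}
        for ind, per_site in self.tables.items():
            row = {}
            for sid, table in per_site.items():
                if not table:
                    continue
                site = self._by_id[sid]
                top = max(table.values())
                candidates = [s for s, v in table.items() if v == top]
                best = min(candidates, key=lambda s: state_to_str(s, site))
                row[sid] = {best: 1.0}
            out[ind] = row
        return GenoSpectrum(out, self.sites)

    def argmax_states(self) -> Dict[str, Tuple[State, ...]]:
        """Per individual, the most likely state at every site, in site order.

        Missing tables fall back to the uniform missing-call table, whose
        argmax is the canonically first state.
        """
        out: Dict[str, Tuple[State, ...]] = {}
        for ind in self.tables:
            states = []
            for site in self.sites:
                table = self.table(ind, site.site_id) or missing_call_spectrum(site)
                top = max(table.values())
                candidates = [s for s, v in table.items() if v == top]
                states.append(min(candidates, key=lambda s: state_to_str(s, site)))
            out[ind] = tuple(states)
        return out


def prune_states(spectra: GenoSpectrum, threshold: float) -> GenoSpectrum:
    """Drop states whose normalized likelihood falls below *threshold*.

    Per (individual, site) the table is normalized to sum to one, states
    below the threshold are removed (the single best state is always kept)
    and the survivors are renormalized.  A threshold of 0 only normalizes.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    out: Dict[str, Dict[str, Dict[State, float]]] = {}
    for ind, per_site in spectra.tables.items():
        row = {}
        for sid, table in per_site.items():
            total = sum(table.values())
            if total <= 0:
                row[sid] = dict(table)
                continue
            site = spectra.site(sid)
            normed = {s: v / total for s, v in table.items()}
            kept = {s: v for s, v in normed.items() if v >= threshold}
            if not kept:
                top = max(normed.values())
                best = min((s for s, v in normed.items() if v == top),
                           key=lambda s: state_to_str(s, site))
                kept = {best: normed[best]}
            subtotal = sum(kept.values())
            row[sid] = {s: v / subtotal for s, v in kept.items()}
        out[ind] = row
    return GenoSpectrum(out, spectra.sites)


@dataclass
class DiplotypeExpansion:
    """Enumerated consistent diplotypes with likelihoods, per individual.

    ``diplotypes[j]`` lists the candidate multi-site diplotypes of
    individual ``individuals[j]`` and ``likelihoods[j]`` the matching
    multi-site likelihoods (products of per-site state likelihoods).
    Individuals whose every candidate has zero likelihood are listed in
    ``excluded`` and carry no entry.
    """

    sites: Tuple[SiteSpec, ...]
    individuals: List[str]
    diplotypes: List[Sequence[Diplotype]]
    likelihoods: List[np.ndarray]
    excluded: List[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def __post_init__(self) -> None:
        if not (len(self.individuals) == len(self.diplotypes) == len(self.likelihoods)):
            raise ValueError("per-individual lists must be aligned")


class _Template:
    """Shared enumeration for all individuals with the same positive-state sets."""

    def __init__(self, sites: Sequence[SiteSpec], pos_states: Sequence[Sequence[State]]) -> None:
        per_site_sets = []
        for site, states in zip(sites, pos_states):
            one_site: set = set()
            for state in states:
                one_site |= enumerate_site_diplotypes(state, site)
            per_site_sets.append(one_site)
        self.diplotypes: List[Diplotype] = sorted(expand_multisite(per_site_sets))
        # Implied per-site state of each candidate, as an index into the
        # positive-state list of that site.
        self.state_index = np.empty((len(self.diplotypes), len(sites)), dtype=np.intp)
        lookup = [{state: i for i, state in enumerate(states)} for states in pos_states]
        for k, dip in enumerate(self.diplotypes):
            implied = collapse_diplotype(dip, sites)
            for s in range(len(sites)):
                self.state_index[k, s] = lookup[s][implied[s]]


def build_expansion(
    spectra: GenoSpectrum,
    sites: Optional[Sequence[SiteSpec]] = None,
) -> DiplotypeExpansion:
    """Enumerate candidate diplotypes and multi-site likelihoods per individual.

    Every state with positive likelihood contributes its consistent one-site
    diplotypes; the one-site sets are combined across sites and each
    candidate's likelihood is the product, over sites, of the likelihood of
    the state it implies (accumulated in log space).  Missing
    (individual, site) tables — absent or all-zero — are replaced by the
    uninformative uniform table with a logged warning.  Individuals with no
    consistent candidate are excluded with a warning.
    """
    site_list: Tuple[SiteSpec, ...] = tuple(sites) if sites is not None else spectra.sites
    templates: Dict[tuple, _Template] = {}
    individuals: List[str] = []
    diplotypes: List[Sequence[Diplotype]] = []
    likelihoods: List[np.ndarray] = []
    excluded: List[str] = []

    for ind in spectra.tables:
        pos_states: List[List[State]] = []
        log_tables: List[np.ndarray] = []
        for site in site_list:
            table = spectra.table(ind, site.site_id)
            if table is None or not any(v > 0 for v in table.values()):
                if table is not None:
                    logger.warning(
                        "individual %s, site %s: all-zero likelihoods; using missing-call table",
                        ind, site.site_id,
                    )
                table = missing_call_spectrum(site)
            states = sorted(
                (s for s, v in table.items() if v > 0),
                key=lambda s: state_to_str(s, site),
            )
            pos_states.append(states)
            log_tables.append(np.log(np.array([table[s] for s in states], dtype=float)))

        key = tuple(
            (site.site_id, tuple(states)) for site, states in zip(site_list, pos_states)
        )
        template = templates.get(key)
        if template is None:
            try:
                template = _Template(site_list, pos_states)
            except InconsistentStatesError:
                logger.warning("individual %s: no diplotype consistent with observed states; excluded", ind)
                excluded.append(ind)
                continue
            templates[key] = template
        if not template.diplotypes:
            logger.warning("individual %s: no diplotype consistent with observed states; excluded", ind)
            excluded.append(ind)
            continue

        log_lam = np.zeros(len(template.diplotypes))
        for s in range(len(site_list)):
            log_lam += log_tables[s][template.state_index[:, s]]
        lam = np.exp(log_lam)
        if not np.any(lam > 0):
            logger.warning("individual %s: all candidate likelihoods underflowed to zero; excluded", ind)
            excluded.append(ind)
            continue
        individuals.append(ind)
        diplotypes.append(template.diplotypes)
        likelihoods.append(lam)

    return DiplotypeExpansion(site_list, individuals, diplotypes, likelihoods, excluded)
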