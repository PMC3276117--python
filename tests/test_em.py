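"""EM engine: priors, E/M steps, convergence and oracle equivalence."""

import itertools

import numpy as np
import pytest

from phasecnv.em import (
    EMConfig,
    FrequencyTable,
    e_step,
    hwe_prior,
    log_likelihood,
    m_step,
    run_em,
)
from phasecnv.likelihood import DiplotypeExpansion, GenoSpectrum, build_expansion
from phasecnv.sites import Diplotype, Haplotype, SiteSpec, SiteType


def hap(*alleles):
    return Haplotype(tuple(alleles))


def icn_expansion(per_individual, site=None):
    """Expansion over a single ICN site from explicit (diplotype, lambda) lists."""
    site = site or SiteSpec("s", SiteType.ICN, (), 4, 2)
    individuals = [f"j{i}" for i in range(len(per_individual))]
    dips = [[d for d, _ in entries] for entries in per_individual]
    lams = [np.array([l for _, l in entries], dtype=float) for entries in per_individual]
    return DiplotypeExpansion((site,), individuals, dips, lams)


H0, H1, H2 = hap(0), hap(1), hap(2)


# -------------------------------------------------------------------- priors
def test_hwe_prior_homozygote():
    freqs = FrequencyTable({H1: 0.9})
    assert hwe_prior(Diplotype(H1, H1), freqs) == pytest.approx(0.81)


def test_hwe_prior_heterozygote():
    freqs = FrequencyTable({H1: 0.9, H2: 0.1})
    assert hwe_prior(Diplotype(H1, H2), freqs) == pytest.approx(0.18)


def test_hwe_prior_sums_to_one_over_all_diplotypes():
    freqs = FrequencyTable({H0: 0.2, H1: 0.5, H2: 0.3})
    haps = list(freqs)
    total = sum(
        hwe_prior(Diplotype(a, b), freqs)
        for a, b in itertools.combinations_with_replacement(haps, 2)
    )
    assert total == pytest.approx(1.0)


def test_hwe_prior_absent_haplotype_is_zero():
    assert hwe_prior(Diplotype(H0, H1), FrequencyTable({H1: 1.0})) == 0.0


# --------------------------------------------------------------------- E step
def test_e_step_normalizes_prior_weighted_likelihoods():
    exp = icn_expansion([[(Diplotype(H1, H1), 1.0), (Diplotype(H0, H2), 1.0)]])
    freqs = FrequencyTable({H1: 0.9, H0: 0.1, H2: 0.1})
    (w,) = e_step(exp, freqs)
    # priors 0.81 and 2*0.1*0.1=0.02
    assert w == pytest.approx([0.81 / 0.83, 0.02 / 0.83])


def test_e_step_single_candidate_gets_weight_one():
    exp = icn_expansion([[(Diplotype(H1, H2), 0.3)]])
    (w,) = e_step(exp, FrequencyTable({H1: 0.5, H2: 0.5}))
    assert w == pytest.approx([1.0])


def test_e_step_uniform_priors_cancel():
    exp = icn_expansion([[(Diplotype(H0, H1), 0.9), (Diplotype(H1, H2), 0.1)]])
    (w,) = e_step(exp, FrequencyTable({H0: 1 / 3, H1: 1 / 3, H2: 1 / 3}))
    assert w == pytest.approx([0.9, 0.1])


# --------------------------------------------------------------------- M step
def test_m_step_single_heterozygote():
    exp = icn_expansion([[(Diplotype(H1, H2), 1.0)]])
    freqs = m_step([np.array([1.0])], exp)
    assert freqs[H1] == pytest.approx(0.5)
    assert freqs[H2] == pytest.approx(0.5)


def test_m_step_homozygote_counts_twice():
    exp = icn_expansion([[(Diplotype(H1, H1), 1.0)]])
    freqs = m_step([np.array([1.0])], exp)
    assert freqs[H1] == pytest.approx(1.0)


def test_m_step_hand_summed_two_individuals():
    exp = icn_expansion(
        [
            [(Diplotype(H1, H1), 1.0)],
            [(Diplotype(H1, H2), 1.0), (Diplotype(H1, H0), 1.0)],
        ]
    )
    freqs = m_step([np.array([1.0]), np.array([0.5, 0.5])], exp)
    assert freqs[H1] == pytest.approx(0.75)
    assert freqs[H2] == pytest.approx(0.125)
    assert freqs[H0] == pytest.approx(0.125)


# ------------------------------------------------------------- log-likelihood
def test_log_likelihood_single_term():
    exp = icn_expansion([[(Diplotype(H1, H2), 1.0)]])
    freqs = FrequencyTable({H1: 0.5, H2: 0.25, H0: 0.25})
    assert log_likelihood(exp, freqs) == pytest.approx(np.log(0.25))


def test_log_likelihood_scale_freeness():
    entries = [[(Diplotype(H1, H1), 0.4), (Diplotype(H0, H2), 0.2)]] * 3
    exp = icn_expansion(entries)
    doubled = icn_expansion(
        [[(d, 2 * l) for d, l in individual] for individual in entries]
    )
    freqs = FrequencyTable({H0: 0.2, H1: 0.6, H2: 0.2})
    assert log_likelihood(doubled, freqs) == pytest.approx(
        log_likelihood(exp, freqs) + 3 * np.log(2)
    )


def test_log_likelihood_additive_over_identical_individuals():
    one = icn_expansion([[(Diplotype(H1, H1), 0.7), (Diplotype(H0, H2), 0.3)]])
    two = icn_expansion([[(Diplotype(H1, H1), 0.7), (Diplotype(H0, H2), 0.3)]] * 2)
    freqs = FrequencyTable({H0: 0.25, H1: 0.5, H2: 0.25})
    assert log_likelihood(two, freqs) == pytest.approx(2 * log_likelihood(one, freqs))


# -------------------------------------------------------------------- run_em
def test_unambiguous_individuals_give_empirical_counts():
    exp = icn_expansion(
        [
            [(Diplotype(H1, H1), 1.0)],
            [(Diplotype(H1, H2), 1.0)],
            [(Diplotype(H1, H1), 1.0)],
            [(Diplotype(H0, H1), 1.0)],
        ]
    )
    result = run_em(exp, EMConfig(n_restarts=0))
    assert result.frequencies[H1] == pytest.approx(6 / 8)
    assert result.frequencies[H2] == pytest.approx(1 / 8)
    assert result.frequencies[H0] == pytest.approx(1 / 8)
    assert result.converged


def test_run_em_matches_classic_em_on_point_mass_input(icn_site):
    """With point-mass spectra the likelihood-aware EM must equal a direct
    reimplementation of the classic (hard-call) EM on the same data."""
    rng = np.random.default_rng(7)
    totals = rng.choice([1, 2, 3], size=30, p=[0.25, 0.6, 0.15])
    spectra = GenoSpectrum(
        {f"j{i}": {"icn1": {int(t): 1.0}} for i, t in enumerate(totals)}, [icn_site]
    )
    exp = build_expansion(spectra)
    result = run_em(exp, EMConfig(n_restarts=2, seed=5))

    # independent classic EM with lambda == 1 over hard-call enumerations
    from phasecnv.sites import enumerate_icn_diplotypes

    cand = [sorted(enumerate_icn_diplotypes(int(t), icn_site)) for t in totals]
    universe = sorted({h for dips in cand for d in dips for h in d.pair}, key=str)
    f = {h: 1.0 / len(universe) for h in universe}
    for _ in range(3000):
        counts = {h: 0.0 for h in universe}
        for dips in cand:
            pri = np.array([hwe_prior(d, f) for d in dips])
            w = pri / pri.sum()
            for wk, d in zip(w, dips):
                counts[d.first] += wk
                counts[d.second] += wk
        f = {h: c / (2 * len(totals)) for h, c in counts.items()}
    for h in universe:
        assert result.frequencies[h] == pytest.approx(f[h], abs=1e-6)


def test_loglik_trace_monotone_and_posteriors_normalized(icn_site):
    rng = np.random.default_rng(11)
    tables = {}
    for i in range(25):
        liks = rng.random(5)
        tables[f"j{i}"] = {"icn1": {t: float(liks[t]) for t in range(5)}}
    exp = build_expansion(GenoSpectrum(tables, [icn_site]))
    result = run_em(exp, EMConfig(n_restarts=3, seed=1))
    assert np.all(np.diff(result.loglik_trace) >= -1e-8)
    total = sum(result.frequencies.values())
    assert total == pytest.approx(1.0, abs=1e-9)
    for _, _, w in result.posterior_items():
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


def test_scale_invariance_of_frequencies_and_posteriors(icn_site):
    rng = np.random.default_rng(3)
    tables = {
        f"j{i}": {"icn1": {t: float(v) for t, v in enumerate(rng.random(5))}}
        for i in range(10)
    }
    exp1 = build_expansion(GenoSpectrum(tables, [icn_site]))
    scaled = {
        ind: {"icn1": {t: v * (7.5 if ind == "j3" else 1.0) for t, v in per["icn1"].items()}}
        for ind, per in tables.items()
    }
    exp2 = build_expansion(GenoSpectrum(scaled, [icn_site]))
    cfg = EMConfig(n_restarts=2, seed=9)
    r1, r2 = run_em(exp1, cfg), run_em(exp2, cfg)
    for h, v in r1.frequencies.items():
        assert r2.frequencies[h] == pytest.approx(v, abs=1e-12)
    w1 = {ind: w for ind, _, w in r1.posterior_items()}
    for ind, _, w in r2.posterior_items():
        assert np.allclose(w, w1[ind], atol=1e-12)


def test_dense_and_ragged_paths_agree(icn_site):
    """The shared-template mat-vec path and the generic ragged path must
    produce identical frequencies and posteriors."""
    rng = np.random.default_rng(21)
    tables = {
        f"j{i}": {"icn1": {t: float(v) for t, v in enumerate(rng.random(5))}}
        for i in range(12)
    }
    exp_dense = build_expansion(GenoSpectrum(tables, [icn_site]))
    assert all(d is exp_dense.diplotypes[0] for d in exp_dense.diplotypes)
    # break template sharing by copying the candidate lists
    exp_ragged = DiplotypeExpansion(
        exp_dense.sites,
        list(exp_dense.individuals),
        [list(d) for d in exp_dense.diplotypes],
        [l.copy() for l in exp_dense.likelihoods],
    )
    cfg = EMConfig(n_restarts=2, seed=2)
    r1, r2 = run_em(exp_dense, cfg), run_em(exp_ragged, cfg)
    assert r1.final_loglik == pytest.approx(r2.final_loglik, abs=1e-10)
    for h, v in r1.frequencies.items():
        assert r2.frequencies[h] == pytest.approx(v, abs=1e-10)


def test_grid_search_oracle_equivalence(icn_site):
    """On a tiny instance the EM fixed point must match direct maximization
    of the observed-data likelihood over a fine grid of the simplex."""
    tables = {
        "j0": {"icn1": {2: 1.0}},
        "j1": {"icn1": {1: 0.6, 2: 0.4}},
        "j2": {"icn1": {3: 0.7, 2: 0.3}},
        "j3": {"icn1": {2: 1.0}},
        "j4": {"icn1": {1: 0.5, 3: 0.5}},
    }
    exp = build_expansion(GenoSpectrum(tables, [icn_site]))
    result = run_em(exp, EMConfig(n_restarts=10, seed=4))
    haps = sorted(result.frequencies, key=str)
    assert len(haps) == 3

    # vectorized grid search over the 2-simplex, step 1e-3
    step = 1e-3
    p0 = np.arange(0.0, 1.0 + step / 2, step)
    g0, g1 = np.meshgrid(p0, p0, indexing="ij")
    mask = g0 + g1 <= 1.0 + 1e-12
    g0, g1 = g0[mask], g1[mask]
    g2 = 1.0 - g0 - g1
    grid = {haps[0]: g0, haps[1]: g1, haps[2]: g2}
    lnl = np.zeros_like(g0)
    for dips, lam in zip(exp.diplotypes, exp.likelihoods):
        inner = np.zeros_like(g0)
        for d, l in zip(dips, lam):
            pa, pb = grid[d.first], grid[d.second]
            prior = pa * pb if d.is_homozygous else 2 * pa * pb
            inner += l * prior
        lnl += np.log(np.maximum(inner, 1e-300))
    best = int(np.argmax(lnl))
    for h in haps:
        assert result.frequencies[h] == pytest.approx(float(grid[h][best]), abs=2e-3)


def test_parameter_recovery_from_noise_free_spectra():
    """With point-mass spectra and a large sample the EM recovers the
    simulating frequencies."""
    from phasecnv.simulate import exact_spectra, sample_population_hwe

    site = SiteSpec("icn1", SiteType.ICN, (), 4, 2)
    freqs = FrequencyTable({H0: 0.0196, H1: 0.9608, H2: 0.0196})
    dips = sample_population_hwe(freqs, 2000, 123)
    individuals = [f"j{i}" for i in range(len(dips))]
    spectra = exact_spectra(dips, individuals, [site])
    result = run_em(build_expansion(spectra), EMConfig(n_restarts=3, seed=8))
    for h, p in freqs.items():
        assert result.frequencies[h] == pytest.approx(p, abs=0.02)


def test_no_usable_individuals_is_an_error():
    exp = DiplotypeExpansion(
        (SiteSpec("s", SiteType.ICN, (), 4, 2),), [], [], [], excluded=["j0"]
    )
    with pytest.raises(ValueError):
        run_em(exp)


def test_frequency_table_normalization_and_sorting():
    t = FrequencyTable({H1: 3.0, H0: 1.0})
    n = t.normalized()
    assert n[H1] == pytest.approx(0.75)
    with pytest.raises(ValueError):
        t.validate()
    assert [str(h) for h, _ in n.sorted_items()] == ["1", "0"]
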