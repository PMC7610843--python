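"""Generative-model tests: nesting, variance decomposition, sampling paths."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetsim import (
    GroupSpec,
    TraitSpec,
    draw_group_sample,
    estimate_variance_components,
    sample_animals,
    sample_site,
    simulate_population,
    welch_test,
)
from tests.conftest import CHIMP_NEOPHOBIA


def test_trait_spec_rejects_negative_sigma():
    with pytest.raises(ValueError, match="sigma_S"):
        TraitSpec("x", beta0=0, sigma_L=1, sigma_S=-1, sigma_e=1)


def test_group_spec_rejects_duplicate_traits():
    t = TraitSpec("x", 0, 1, 1, 1)
    with pytest.raises(ValueError, match="duplicate"):
        GroupSpec("g", [t, t])


@pytest.mark.parametrize("n_sites,n_per_site", [(0, 10), (10, 0), (-1, 5)])
def test_simulate_population_rejects_nonpositive_counts(chimp_group, rng, n_sites, n_per_site):
    with pytest.raises(ValueError):
        simulate_population(chimp_group, n_sites, n_per_site, rng)


def test_score_decomposition_is_exact(chimp_group, rng):
    """Every record reconstructs score = beta0 + site + subject + residual."""
    pop = simulate_population(chimp_group, 20, 30, rng)
    beta0 = pop["trait"].map({t.name: t.beta0 for t in chimp_group.traits})
    resid = pop["score"] - (
        beta0 + pop["site_effect"] + pop["subject_effect"] + pop["residual"]
    )
    assert np.all(resid == 0)
    assert len(pop) == 20 * 30 * 2


def test_site_effect_shared_within_site(chimp_group, rng):
    """All animals at one site share a single site effect per trait."""
    pop = simulate_population(chimp_group, 15, 25, rng)
    n_unique = pop.groupby(["trait", "site_id"])["site_effect"].nunique()
    assert (n_unique == 1).all()
    # and distinct sites (a.s.) have distinct effects
    per_trait = pop.groupby("trait")["site_effect"].nunique()
    assert (per_trait == 15).all()


def test_zero_variance_population_is_constant(rng):
    spec = TraitSpec("flat", beta0=42.0, sigma_L=0, sigma_S=0, sigma_e=0)
    pop = simulate_population(GroupSpec("g", [spec]), 5, 8, rng)
    assert np.all(pop["score"].to_numpy() == 42.0)


def test_population_moments_match_spec(chimp_group, rng):
    """100 sites x 100 animals: grand mean ~800, total SD ~150 for neophobia."""
    pop = simulate_population(chimp_group, 100, 100, rng)
    neo = pop[pop["trait"] == "neophobia"]["score"]
    # SE of the grand mean is sqrt(sigma_L^2/100 + sigma_W^2/10000) ~ 10.1
    assert neo.mean() == pytest.approx(800, abs=40)
    assert neo.std(ddof=1) == pytest.approx(150, abs=8)


def test_intraclass_correlation_recovered(chimp_group, rng):
    """Variance decomposition of a large population recovers ICC = 10000/22500."""
    pop = simulate_population(chimp_group, 300, 60, rng)
    est = estimate_variance_components(pop, "neophobia")
    icc = est["sigma2_between"] / (est["sigma2_between"] + est["sigma2_within"])
    assert icc == pytest.approx(10000 / 22500, abs=0.04)
    assert CHIMP_NEOPHOBIA.icc == pytest.approx(10000 / 22500, rel=1e-12)


def test_sample_site_single_site_and_empty(rng):
    pop = simulate_population(GroupSpec("g", [TraitSpec("t", 0, 1, 1, 1)]), 1, 5, rng)
    assert sample_site(pop, rng) == 0
    with pytest.raises(ValueError):
        sample_site(pop.iloc[0:0], rng)


def test_sample_site_is_uniform(rng):
    pop = simulate_population(GroupSpec("g", [TraitSpec("t", 0, 1, 1, 1)]), 8, 2, rng)
    draws = np.array([sample_site(pop, rng) for _ in range(4000)])
    freq = np.bincount(draws, minlength=8) / 4000
    # binomial SE per cell ~ 0.0052; allow 4 SEs
    assert np.all(np.abs(freq - 1 / 8) < 0.021)


def test_sample_animals_contract(chimp_group, rng):
    pop = simulate_population(chimp_group, 10, 30, rng)
    site = sample_site(pop, rng)
    sample = sample_animals(pop, site, 10, rng)
    assert sample["subject_id"].nunique() == 10
    assert set(sample["site_id"]) == {site}
    # nesting: sampled animals carry the site's effect
    for trait in chimp_group.trait_names:
        effects = sample[sample["trait"] == trait]["site_effect"].unique()
        assert len(effects) == 1
    # n equal to site size returns the whole site
    full = sample_animals(pop, site, 30, rng)
    assert len(full) == 30 * 2
    with pytest.raises(ValueError, match="only"):
        sample_animals(pop, site, 31, rng)
    with pytest.raises(ValueError, match="not present"):
        sample_animals(pop, 99, 5, rng)


def test_sample_mean_se_around_true_site_mean(rng):
    """Mean of 10 sampled animals deviates from its site's true mean
    (beta0 + site effect) with expected squared deviation
    (sigma_S^2 + sigma_e^2)/10, averaged over sites."""
    spec = TraitSpec("t", beta0=800, sigma_L=100, sigma_S=100, sigma_e=50)
    pop = simulate_population(GroupSpec("g", [spec]), 60, 100, rng)
    true_site_means = spec.beta0 + pop.groupby("site_id")["site_effect"].first()
    devs = np.empty(3000)
    for i in range(3000):
        site = sample_site(pop, rng)
        devs[i] = sample_animals(pop, site, 10, rng)["score"].mean() - true_site_means[site]
    expected = (100**2 + 50**2) / 10  # 1250
    # MC SE over 3000 draws plus residual site-level noise from 60 sites
    assert np.mean(devs**2) == pytest.approx(expected, abs=0.15 * expected)


def test_draw_group_sample_degenerate_and_errors(rng):
    flat = GroupSpec("g", [TraitSpec("t", 7.0, 0, 0, 0)])
    sample = draw_group_sample(flat, 5, rng)
    assert np.all(sample["score"].to_numpy() == 7.0)
    with pytest.raises(ValueError):
        draw_group_sample(flat, 1, rng)


def test_group_sample_mean_is_unbiased_with_clustered_variance(rng):
    """Across replicate one-site samples, the sample mean is centered on
    beta0 with variance sigma_L^2 + (sigma_S^2+sigma_e^2)/n = 11250: the
    site effect does not shrink with n."""
    group = GroupSpec("chimpanzee", [CHIMP_NEOPHOBIA])
    means = np.array(
        [draw_group_sample(group, 10, rng)["score"].mean() for _ in range(3000)]
    )
    assert means.mean() == pytest.approx(800, abs=4 * np.sqrt(11250 / 3000))
    assert np.var(means, ddof=1) == pytest.approx(11250, rel=4 * np.sqrt(2 / 3000))


def test_shortcut_and_explicit_paths_agree_in_distribution():
    """draw_group_sample vs population -> random site -> random animals:
    the two routes' sample-mean distributions are indistinguishable."""
    group = GroupSpec("g", [CHIMP_NEOPHOBIA])
    rng = np.random.default_rng(515)
    shortcut = np.array(
        [draw_group_sample(group, 10, rng)["score"].mean() for _ in range(3000)]
    )
    explicit = np.empty(3000)
    for i in range(3000):
        pop = simulate_population(group, 3, 10, rng)
        site = sample_site(pop, rng)
        explicit[i] = sample_animals(pop, site, 10, rng)["score"].mean()
    res = welch_test(shortcut, explicit)
    assert res.p_value > 0.01
    # second moments agree too (variance ratio near 1)
    assert np.var(shortcut) / np.var(explicit) == pytest.approx(1.0, abs=0.15)


def test_simulation_is_deterministic_given_seed(chimp_group):
    pop1 = simulate_population(chimp_group, 12, 7, np.random.default_rng(99))
    pop2 = simulate_population(chimp_group, 12, 7, np.random.default_rng(99))
    pd.testing.assert_frame_equal(pop1, pop2)
    s1 = draw_group_sample(chimp_group, 6, np.random.default_rng(5))
    s2 = draw_group_sample(chimp_group, 6, np.random.default_rng(5))
    pd.testing.assert_frame_equal(s1, s2)


def test_variance_components_require_trait_and_balance(chimp_group, rng):
    pop = simulate_population(chimp_group, 5, 10, rng)
    with pytest.raises(ValueError, match="not present"):
        estimate_variance_components(pop, "nope")
    unbalanced = pop[~((pop["site_id"] == 0) & (pop["subject_id"] == 0))]
    with pytest.raises(ValueError, match="balanced"):
        estimate_variance_components(unbalanced, "neophobia")


@settings(max_examples=25, deadline=None)
@given(
    beta0=st.floats(-1e3, 1e3),
    sigma_L=st.floats(0, 50),
    sigma_S=st.floats(0, 50),
    sigma_e=st.floats(0, 50),
    n_sites=st.integers(1, 6),
    n_per_site=st.integers(1, 6),
    seed=st.integers(0, 2**31 - 1),
)
def test_decomposition_property(beta0, sigma_L, sigma_S, sigma_e, n_sites, n_per_site, seed):
    """For arbitrary valid parameters the per-record decomposition is exact
    and the table shape/nesting invariants hold."""
    spec = TraitSpec("t", beta0, sigma_L, sigma_S, sigma_e)
    pop = simulate_population(
        GroupSpec("g", [spec]), n_sites, n_per_site, np.random.default_rng(seed)
    )
    assert len(pop) == n_sites * n_per_site
    recon = beta0 + pop["site_effect"] + pop["subject_effect"] + pop["residual"]
    assert np.allclose(pop["score"], recon, rtol=0, atol=0)
    assert (pop.groupby("site_id")["site_effect"].nunique() == 1).all()
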