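"""Unit and property tests of the one-generation recursion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resistsim.genetics as gen
from resistsim import config as cfg
from resistsim.deployment import build_exposure_profile, DeploymentSpec
from resistsim.genotypes import (
    COUPLING,
    GENOTYPE_INDEX,
    REPULSION,
    Sex,
    swap_loci_genotype_permutation,
    swap_loci_niche_permutation,
)

from _oracles import brute_force_offspring, one_locus_next


# ---------------------------------------------------------------------------
# initialisation


@pytest.mark.parametrize(
    "p1,p2,genotype,expected",
    [
        (0.0, 0.0, "SS1SS2", 1.0),
        (1.0, 1.0, "RR1RR2", 1.0),
        (0.5, 0.5, "RS1RS2(c)", 0.125),
        (0.5, 0.5, "RS1RS2(r)", 0.125),
    ],
)
def test_init_from_allele_freqs(p1, p2, genotype, expected):
    F = gen.init_from_allele_freqs(p1, p2)
    assert F.value(Sex.FEMALE, genotype) == pytest.approx(expected, abs=1e-15)
    assert np.allclose(F.freq[0], F.freq[1])


def test_init_rejects_out_of_range():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        gen.init_from_allele_freqs(1.2, 0.1)


def test_init_from_genotype_freqs_consistency_and_validation():
    F = gen.init_from_allele_freqs(0.3, 0.7)
    G = gen.init_from_genotype_freqs(F.freq.copy())
    assert np.allclose(F.freq, G.freq)
    # slightly off-sum tables are renormalised
    near = F.freq * 0.999999999
    G2 = gen.init_from_genotype_freqs(near)
    assert np.allclose(G2.freq.sum(axis=1), 1.0)
    bad = F.freq.copy()
    bad[0, 0] = -0.01
    with pytest.raises(ValueError):
        gen.init_from_genotype_freqs(bad)


# ---------------------------------------------------------------------------
# fitness tables


def test_single_locus_fitness_idealised():
    # a fully effective insecticide with fully dominant, fully restoring
    # resistance: SS dies, RS and RR are untouched
    p = gen.InsecticideParams.from_restoration(1.0, 1.0, 1.0)
    w = gen.single_locus_fitness_table(p, p)
    assert w.value(1, "SS", "A,-") == 0.0
    assert w.value(1, "RS", "A,-") == 1.0
    assert w.value(1, "RR", "A,-") == 1.0
    # no cost: insecticide-free fitnesses are all 1
    assert np.allclose(w.w[:, :, 0], 1.0)


def test_single_locus_fitness_survival_calibration():
    # published DDT-style survival: SS 27%, RR 50%
    p = gen.InsecticideParams(effectiveness=0.73, dominance=0.5, selection=0.23)
    w = gen.single_locus_fitness_table(p, p)
    assert w.value(1, "SS", "A,-") == pytest.approx(0.27)
    assert w.value(1, "RR", "A,-") == pytest.approx(0.50)


def test_fitness_cost_in_free_niche():
    p = gen.InsecticideParams(
        effectiveness=0.9, dominance=0.5, selection=0.5, cost=0.2, cost_dominance=0.25
    )
    w = gen.single_locus_fitness_table(p, p)
    assert w.value(1, "SS", "-,-") == 1.0
    assert w.value(1, "RS", "-,-") == pytest.approx(1 - 0.25 * 0.2)
    assert w.value(1, "RR", "-,-") == pytest.approx(0.8)


def test_calibration_error_is_loud():
    with pytest.raises(gen.CalibrationError, match="exceeds effectiveness"):
        gen.InsecticideParams(effectiveness=0.3, dominance=0.5, selection=0.5)


def test_two_locus_fitness_multiplicative_and_interaction():
    # survival 0.3 to A alone and 0.2 to B alone multiply to 0.06 in the
    # dual niche; an interaction factor scales it linearly
    pa = gen.InsecticideParams(effectiveness=0.7, dominance=0.0, selection=0.0)
    pb = gen.InsecticideParams(effectiveness=0.8, dominance=0.0, selection=0.0)
    Wn = gen.two_locus_fitness_tables(gen.single_locus_fitness_table(pa, pb))
    assert Wn.value("SS1SS2", "A,B") == pytest.approx(0.06)
    lam = gen.InteractionFactors(AB=2.0)
    Wn2 = gen.two_locus_fitness_tables(gen.single_locus_fitness_table(pa, pb), lam)
    assert Wn2.value("SS1SS2", "A,B") == pytest.approx(0.12)
    # coupling and repulsion double heterozygotes share fitness everywhere
    assert np.allclose(Wn.w[COUPLING], Wn.w[REPULSION])


def test_marginal_fitness_curtis_mixture():
    cal = cfg.curtis_idealised()
    W = gen.marginal_fitness(
        cal.niche_fitness(), build_exposure_profile(cfg.curtis_mixture_spec())
    )
    assert W.value(Sex.MALE, "SS1SS2") == pytest.approx(0.1)
    assert W.value(Sex.MALE, "RS1RS2(c)") == pytest.approx(1.0)
    # equal exposure of the sexes gives identical fitnesses
    assert np.allclose(W.w[0], W.w[1])


def test_marginal_fitness_no_exposure_is_neutral():
    cal = cfg.curtis_idealised()
    W = gen.marginal_fitness(cal.niche_fitness(), gen.ExposureProfile.unexposed())
    assert np.allclose(W.w, 1.0)


# ---------------------------------------------------------------------------
# gametes and random union


def _neutral_W():
    return gen.MarginalFitness(np.ones((2, 10)))


def _monomorphic(genotype):
    f = np.zeros((2, 10))
    f[:, GENOTYPE_INDEX[genotype]] = 1.0
    return gen.GenotypeFrequencies(f)


@pytest.mark.parametrize(
    "genotype,r,expected",
    [
        ("SS1SS2", 0.5, [1.0, 0.0, 0.0, 0.0]),
        ("RS1RS2(c)", 0.5, [0.25, 0.25, 0.25, 0.25]),
        ("RS1RS2(c)", 0.0, [0.5, 0.0, 0.0, 0.5]),
        ("RS1RS2(r)", 0.0, [0.0, 0.5, 0.5, 0.0]),
    ],
)
def test_gamete_frequencies_from_monomorphic_parents(genotype, r, expected):
    G = gen.gamete_frequencies(_monomorphic(genotype), _neutral_W(), r)
    assert np.allclose(G.freq, [expected, expected])


def test_extinction_error():
    W = gen.MarginalFitness(np.zeros((2, 10)))
    with pytest.raises(gen.ExtinctionError):
        gen.gamete_frequencies(gen.init_from_allele_freqs(0.1, 0.1), W, 0.5)


def test_next_generation_enumerated():
    # gametes SS and RR at 0.5 each in both sexes: offspring are
    # SS1SS2 (1/4), RR1RR2 (1/4) and the coupling double het (1/2)
    freq = np.tile([0.5, 0.0, 0.0, 0.5], (2, 1))
    G = gen.GameteFrequencies(freq, np.ones(2))
    F = gen.next_generation(G)
    assert F.value(Sex.FEMALE, "SS1SS2") == pytest.approx(0.25)
    assert F.value(Sex.FEMALE, "RR1RR2") == pytest.approx(0.25)
    assert F.value(Sex.FEMALE, "RS1RS2(c)") == pytest.approx(0.5)
    assert F.value(Sex.FEMALE, "RS1RS2(r)") == 0.0


# ---------------------------------------------------------------------------
# summaries


def test_allele_frequency_round_trip():
    F = gen.init_from_allele_freqs(0.01, 0.001)
    af = gen.allele_frequencies(F)
    assert af.mean == pytest.approx((0.01, 0.001), abs=1e-15)
    assert gen.allele_frequencies(_monomorphic("RR1RR2")).mean == (1.0, 1.0)
    assert gen.allele_frequencies(_monomorphic("RS1RS2(c)")).mean == (0.5, 0.5)


@pytest.mark.parametrize(
    "freqs,expected",
    [
        ([0.5, 0.0, 0.0, 0.5], 0.25),
        ([0.0, 0.5, 0.5, 0.0], -0.25),
        ([0.25, 0.25, 0.25, 0.25], 0.0),
    ],
)
def test_linkage_disequilibrium_by_hand(freqs, expected):
    G = gen.GameteFrequencies(np.tile(freqs, (2, 1)), np.ones(2))
    assert gen.linkage_disequilibrium(G) == pytest.approx(expected, abs=1e-15)


def test_mean_population_fitness_curtis_start():
    cal = cfg.curtis_idealised()
    W = gen.marginal_fitness(
        cal.niche_fitness(), build_exposure_profile(cfg.curtis_mixture_spec())
    )
    wbar = gen.mean_population_fitness(cal.initial_state(), W)
    # 0.1 + 0.9 (1 - 0.99^2)(1 - 0.999^2), by hand
    assert wbar == pytest.approx(0.1 + 0.9 * (1 - 0.99**2) * (1 - 0.999**2), abs=1e-12)
    assert gen.mean_population_fitness(cal.initial_state(), _neutral_W()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# one-generation paper anchors


def test_solo_one_generation_update():
    # fully dominant, fully restoring, fully effective insecticide at 90%
    # exposure drives 0.1% resistance to 0.98% in one generation
    cal = cfg.curtis_idealised(start_freq1=0.0, start_freq2=0.001)
    W = gen.marginal_fitness(
        cal.niche_fitness(), build_exposure_profile(cfg.curtis_single_spec(2))
    )
    F1 = gen.step(cal.initial_state(), W, 0.5)
    assert gen.allele_frequencies(F1).mean[1] == pytest.approx(0.0098, abs=5e-5)


def test_mixture_one_generation_update():
    # in the mixture, the rarer allele rises 0.1% -> 0.118% and the
    # commoner 1% -> ~1.018%
    cal = cfg.curtis_idealised()
    W = gen.marginal_fitness(
        cal.niche_fitness(), build_exposure_profile(cfg.curtis_mixture_spec())
    )
    af = gen.allele_frequencies(gen.step(cal.initial_state(), W, 0.5))
    assert af.mean[1] == pytest.approx(0.00118, abs=5e-6)
    assert af.mean[0] == pytest.approx(0.01018, abs=5e-5)


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 1.0), min_size=20, max_size=20), st.floats(0, 0.5))
def test_mating_oracle_and_conservation(raw, r):
    """The engine's selection + gamete production + random union must match
    a brute-force enumeration of all ordered parental crosses."""
    freq = np.array(raw).reshape(2, 10)
    freq /= freq.sum(axis=1, keepdims=True)
    F = gen.GenotypeFrequencies(freq)
    w = np.array(raw).reshape(2, 10) * 0.9 + 0.1  # fitnesses in (0.1, 1)
    W = gen.MarginalFitness(w)
    offspring = gen.step(F, W, r)
    assert np.allclose(offspring.freq.sum(axis=1), 1.0, atol=1e-12)
    assert (offspring.freq >= 0).all()
    expected = brute_force_offspring(freq, w, r)
    assert np.allclose(offspring.freq[0], expected, atol=1e-10)
    assert np.allclose(offspring.freq[1], expected, atol=1e-10)


@pytest.mark.parametrize("r", [0.0, 0.2, 0.5])
def test_neutral_ld_decay(r, rng):
    """Without selection, allele frequencies are invariant and gametic LD
    decays by a factor (1 - r) each generation (state identical across
    sexes, as the autosomal model guarantees after one round of mating)."""
    table = rng.random(10)
    table /= table.sum()
    F = gen.GenotypeFrequencies(np.tile(table, (2, 1)))
    W = _neutral_W()
    q0 = gen.allele_frequencies(F).mean
    d = gen.linkage_disequilibrium(gen.gamete_frequencies(F, W, r))
    for _ in range(5):
        F = gen.step(F, W, r)
        d_next = gen.linkage_disequilibrium(gen.gamete_frequencies(F, W, r))
        assert d_next == pytest.approx(d * (1 - r), abs=1e-12)
        d = d_next
    q5 = gen.allele_frequencies(F).mean
    assert q5 == pytest.approx(q0, abs=1e-12)


def test_single_locus_reduction():
    """With insecticide 2 never deployed and no costs, locus 2 is inert and
    locus 1 follows the scalar one-locus recursion exactly."""
    p1 = gen.InsecticideParams(effectiveness=0.8, dominance=0.3, selection=0.6)
    p2 = gen.InsecticideParams(effectiveness=0.5, dominance=0.5, selection=0.2)
    spec = DeploymentSpec(
        strategy="single", exposure=0.7, male_exposure_prop=0.4, insecticide=1
    )
    Wn = gen.two_locus_fitness_tables(gen.single_locus_fitness_table(p1, p2))
    W = gen.marginal_fitness(Wn, build_exposure_profile(spec))
    F = gen.init_from_allele_freqs(0.05, 0.3)
    # scalar marginal one-locus fitnesses per sex
    alpha = build_exposure_profile(spec).alpha
    w1 = np.array([1 - 0.8, 1 - 0.8 + 0.3 * 0.6, 1 - 0.8 + 0.6])
    w_sex = np.stack([(1 - e) + e * w1 for e in (0.7, 0.7 * 0.4)])
    q_f = q_m = 0.05
    for _ in range(6):
        F = gen.step(F, W, 0.5)
        q_f, q_m = one_locus_next(q_f, q_m, w_sex[0], w_sex[1])
        af = gen.allele_frequencies(F)
        assert af.female[0] == pytest.approx((q_f + q_m) / 2, abs=1e-12)
        assert af.female[1] == pytest.approx(0.3, abs=1e-12)


def test_label_swap_symmetry():
    """Exchanging the insecticides, loci and starting frequencies swaps the
    outputs exactly."""
    pa = gen.InsecticideParams(effectiveness=0.9, dominance=0.2, selection=0.5, cost=0.05)
    pb = gen.InsecticideParams(effectiveness=0.6, dominance=0.8, selection=0.3)
    gperm = swap_loci_genotype_permutation()
    nperm = swap_loci_niche_permutation()
    w_ab = gen.two_locus_fitness_tables(gen.single_locus_fitness_table(pa, pb))
    w_ba = gen.two_locus_fitness_tables(gen.single_locus_fitness_table(pb, pa))
    assert np.allclose(w_ab.w, w_ba.w[gperm][:, nperm])
    spec = DeploymentSpec(strategy="mixture", exposure=0.8, correct_mix_deploy=0.7)
    alpha = build_exposure_profile(spec)
    W_ab = gen.marginal_fitness(w_ab, alpha)
    W_ba = gen.marginal_fitness(w_ba, alpha)  # mixture exposure is symmetric
    F_ab = gen.init_from_allele_freqs(0.02, 0.2)
    F_ba = gen.init_from_allele_freqs(0.2, 0.02)
    for _ in range(4):
        F_ab = gen.step(F_ab, W_ab, 0.5)
        F_ba = gen.step(F_ba, W_ba, 0.5)
        assert np.allclose(F_ab.freq, F_ba.freq[:, gperm], atol=1e-14)


def test_equal_exposure_sexes_identical(curtis_cal):
    W = gen.marginal_fitness(
        curtis_cal.niche_fitness(), build_exposure_profile(cfg.curtis_mixture_spec())
    )
    F = curtis_cal.initial_state()
    for _ in range(4):
        G = gen.gamete_frequencies(F, W, 0.5)
        assert np.allclose(G.freq[0], G.freq[1])
        F = gen.next_generation(G)
        assert np.allclose(F.freq[0], F.freq[1])


def test_hwe_le_restored_under_neutrality(rng):
    """One neutral generation with free recombination halves LD; allele
    frequencies then reconstruct the genotype table of an HWE/LE start as
    LD vanishes."""
    from conftest import random_genotype_frequencies

    F = gen.GenotypeFrequencies(random_genotype_frequencies(rng))
    W = _neutral_W()
    for _ in range(60):
        F = gen.step(F, W, 0.5)
    af = gen.allele_frequencies(F)
    expected = gen.init_from_allele_freqs(*af.mean)
    assert np.allclose(F.freq, expected.freq, atol=1e-12)
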