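"""Meiosis, inheritance and additive phenotype prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import breedsim as bs
from breedsim.genetics import _gametes_from


def one_locus_map(**effects):
    return bs.LinkageMap([bs.Locus("L1", "C1", 0.0, tuple(effects.get("effects", ())))])


def two_locus_map(distance):
    return bs.LinkageMap([bs.Locus("L1", "C1", 0.0), bs.Locus("L2", "C1", distance)])


def inbred(lmap, allele):
    return bs.LineGenotype(np.full((2, lmap.n_loci), allele, dtype=np.int8), lmap)


@pytest.mark.parametrize(
    "d, expected",
    [(0.0, 0.0), (10.0, 0.5 * (1 - np.exp(-0.2))), (1e6, 0.5)],
)
def test_recombination_fraction_haldane(d, expected):
    assert bs.recombination_fraction(d) == pytest.approx(expected, abs=1e-12)


def test_recombination_fraction_rejects_negative_distance():
    with pytest.raises(ValueError):
        bs.recombination_fraction(-1.0)


def test_gamete_of_homozygote_equals_haplotype(rng):
    lmap = two_locus_map(25.0)
    parent = inbred(lmap, bs.CADENZA)
    g = bs.sample_gamete(parent, rng)
    assert np.array_equal(g, parent.haplotypes[0])


def test_f1_gamete_allele_frequency_is_half(rng):
    lmap = one_locus_map()
    f1 = bs.make_f1(inbred(lmap, bs.AVALON), inbred(lmap, bs.CADENZA))
    n = 100_000
    geno = np.broadcast_to(f1.haplotypes, (n, 2, 1))
    g = _gametes_from(geno, lmap.switch_probabilities, rng)
    freq = g.mean()
    assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)


def test_two_locus_recombinant_frequency_matches_map_function(rng):
    d = 10.0
    lmap = two_locus_map(d)
    f1 = bs.make_f1(inbred(lmap, bs.AVALON), inbred(lmap, bs.CADENZA))
    n = 100_000
    geno = np.broadcast_to(f1.haplotypes, (n, 2, 2))
    g = _gametes_from(geno, lmap.switch_probabilities, rng)
    r_obs = (g[:, 0] != g[:, 1]).mean()
    r = bs.recombination_fraction(d)
    assert abs(r_obs - r) < 3 * np.sqrt(r * (1 - r) / n)


def test_f1_heterozygous_exactly_at_differing_loci(study_fixture):
    for (p1, p2), expected in [(("DH61", "DH182"), 13), (("DH109", "DH160"), 16),
                               (("DH27", "DH61"), 15)]:
        f1 = bs.make_f1(study_fixture.parents[p1], study_fixture.parents[p2])
        assert len(f1.heterozygous_loci()) == expected


def test_f1_of_identical_parents_is_the_parent(study_fixture):
    p = study_fixture.parents["DH61"]
    assert bs.make_f1(p, p) == p


def test_f1_rejects_heterozygous_parent(rng):
    lmap = one_locus_map()
    het = bs.LineGenotype(np.array([[0], [1]], dtype=np.int8), lmap)
    with pytest.raises(ValueError):
        bs.make_f1(het, inbred(lmap, bs.AVALON))


def test_dh_from_homozygote_is_identical(rng, study_fixture):
    p = study_fixture.parents["DH27"]
    assert bs.make_dh(p, rng) == p


def test_dh_lines_are_always_fully_homozygous(rng, study_fixture):
    f1 = bs.make_f1(study_fixture.parents["DH61"], study_fixture.parents["DH182"])
    pop = bs.Population(np.broadcast_to(f1.haplotypes, (500, 2, study_fixture.map.n_loci)),
                        study_fixture.map)
    dh = bs.make_dh_population(pop, np.arange(500), rng)
    assert dh.is_homozygous().all()


def test_dh_class_frequencies_uniform_for_unlinked_loci(rng):
    # k unlinked heterozygous loci: each DH genotype class has frequency (1/2)^k
    k, n = 3, 40_000
    lmap = bs.LinkageMap([bs.Locus(f"L{i}", f"C{i}", 0.0) for i in range(k)])
    f1 = bs.make_f1(inbred(lmap, bs.AVALON), inbred(lmap, bs.CADENZA))
    pop = bs.Population(np.broadcast_to(f1.haplotypes, (n, 2, k)), lmap)
    dh = bs.make_dh_population(pop, np.arange(n), rng)
    codes = dh.genotypes[:, 0, :] @ (1 << np.arange(k))
    counts = np.bincount(codes, minlength=2 ** k)
    chi2 = ((counts - n / 2 ** k) ** 2 / (n / 2 ** k)).sum()
    assert stats.chi2.sf(chi2, 2 ** k - 1) > 0.001


def test_selfing_single_heterozygote_gives_1_2_1(rng):
    lmap = one_locus_map()
    f1 = bs.make_f1(inbred(lmap, bs.AVALON), inbred(lmap, bs.CADENZA))
    n = 100_000
    seeds = bs.self_plant(f1, rng, n)
    dosage = seeds.allele_dosage()[:, 0]
    counts = np.bincount(dosage, minlength=3)
    expected = np.array([0.25, 0.5, 0.25]) * n
    chi2 = ((counts - expected) ** 2 / expected).sum()
    assert stats.chi2.sf(chi2, 2) > 0.001


def test_selfing_homozygote_breeds_true(rng, study_fixture):
    p = study_fixture.parents["DH160"]
    seeds = bs.self_plant(p, rng, 50)
    assert (seeds.genotypes == p.haplotypes).all()


def test_residual_heterozygosity_halves_per_selfing_generation(rng):
    # four generations of single-seed selfing: residual heterozygosity (1/2)^4
    lmap = one_locus_map()
    f1 = bs.make_f1(inbred(lmap, bs.AVALON), inbred(lmap, bs.CADENZA))
    n = 50_000
    pop = bs.Population(np.broadcast_to(f1.haplotypes, (n, 2, 1)), lmap)
    for _ in range(4):
        pop = bs.self_population(pop, np.arange(n), rng)
    het = (~pop.is_homozygous()).mean()
    p = 0.5 ** 4
    assert abs(het - p) < 3 * np.sqrt(p * (1 - p) / n)


# -- phenotype prediction ----------------------------------------------------

def test_prediction_with_no_effect_loci_is_baseline(study_fixture):
    pred = bs.predict_phenotype(study_fixture.parents["DH61"], "UNKNOWN_TRAIT", baseline=7.4)
    assert pred.value == 7.4
    assert pred.n_effect_loci == 0


def test_major_yield_locus_contributes_twice_its_additive_effect(study_fixture):
    # lines differing only at the 2D yield locus: GY gap = 2 * 0.37 t/ha
    lmap = study_fixture.map
    i = lmap.index["qGY-psr-2D.1"]
    hom_c = np.ones((2, lmap.n_loci), dtype=np.int8)
    hom_a_at_2d = hom_c.copy()
    hom_a_at_2d[:, i] = bs.AVALON
    gy_c = bs.predict_phenotype(bs.LineGenotype(hom_c, lmap), "GY").value
    gy_a = bs.predict_phenotype(bs.LineGenotype(hom_a_at_2d, lmap), "GY").value
    assert gy_c - gy_a == pytest.approx(2 * 0.37)


def test_major_height_locus_homozygote_contribution_is_signed_effect(scenario_effects):
    import breedsim.scenarios as sc
    spec = bs.default_spec(1, scenario_effects)
    lmap = sc.build_scenario_map(spec, scenario_effects)
    i = lmap.index["qPH-psr-2D"]
    tall = np.zeros((2, lmap.n_loci), dtype=np.int8)
    tall[:, i] = bs.CADENZA  # height-increasing origin at the 2D locus
    short = np.zeros((2, lmap.n_loci), dtype=np.int8)
    ph_tall = [c for lid, c in
               bs.predict_phenotype(bs.LineGenotype(tall, lmap), "PH", "MET").contributions
               if lid == "qPH-psr-2D"][0]
    ph_short = [c for lid, c in
                bs.predict_phenotype(bs.LineGenotype(short, lmap), "PH", "MET").contributions
                if lid == "qPH-psr-2D"][0]
    assert ph_tall == pytest.approx(4.92)
    assert ph_short == pytest.approx(-4.92)


def test_heterozygote_contributes_zero(rng):
    lmap = one_locus_map(effects=(bs.TraitEffect("GY", "MET", 0.3, "C"),))
    het = bs.LineGenotype(np.array([[0], [1]], dtype=np.int8), lmap)
    assert bs.predict_phenotype(het, "GY").value == 0.0


def test_population_values_match_per_line_predictions(study_fixture, rng):
    f1 = bs.make_f1(study_fixture.parents["DH27"], study_fixture.parents["DH61"])
    pop = bs.self_plant(f1, rng, 40)
    values = bs.genotypic_values(pop, "GY")
    for i in range(pop.n):
        assert values[i] == pytest.approx(bs.predict_phenotype(pop.line(i), "GY").value)


# -- allele conservation property --------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 31 - 1), k=st.integers(1, 6))
def test_alleles_always_trace_to_a_parent(seed, k):
    rng = np.random.default_rng(seed)
    fix = bs.generate_synthetic_cross(k, rng=rng)
    f1 = bs.make_f1(fix.parents["P1"], fix.parents["P2"])
    pop = bs.self_plant(f1, rng, 30)
    pool = np.stack([fix.parents["P1"].haplotypes[0], fix.parents["P2"].haplotypes[0]])
    ok = (pop.genotypes[:, :, :] == pool[0]) | (pop.genotypes[:, :, :] == pool[1])
    assert ok.all()
    dh = bs.make_dh_population(pop, rng.integers(0, 30, 20), rng)
    assert dh.is_homozygous().all()
    assert np.isin(dh.genotypes, (bs.AVALON, bs.CADENZA)).all()
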