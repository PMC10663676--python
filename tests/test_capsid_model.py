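import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsidkit import capsid_model as cm


# ---------------------------------------------------------------------------
# molar extinction at 214 nm
# ---------------------------------------------------------------------------


def oracle_epsilon214(sequence: str) -> float:
    """Independent residue-by-residue table sum (spreadsheet-style)."""
    if not sequence:
        return 0.0
    total = 923.0 * (len(sequence) - 1)
    for i, aa in enumerate(sequence):
        if aa == "P" and i == 0:
            total += 30.0
        else:
            total += cm.SIDE_CHAIN_E214[aa]
    return total


def test_epsilon_empty_sequence_is_zero():
    assert cm.molar_extinction_214("") == 0.0


def test_epsilon_gg_is_one_bond_plus_two_gly():
    # hand sum: 1 peptide bond (923) + 2 x Gly side chain (0)
    assert cm.molar_extinction_214("GG") == pytest.approx(923.0)


def test_epsilon_single_residue_has_no_bond():
    assert cm.molar_extinction_214("W") == pytest.approx(29050.0)


def test_epsilon_nterminal_proline_special_case():
    # N-terminal proline is not engaged in a preceding peptide bond
    assert cm.molar_extinction_214("PG") == pytest.approx(923.0 + 30.0)
    assert cm.molar_extinction_214("GP") == pytest.approx(923.0 + 2675.0)


def test_epsilon_vp3_fixture_matches_bruteforce_oracle(vp_species):
    vp3 = next(s for s in vp_species if s.name == "VP3")
    expected = oracle_epsilon214(vp3.sequence)
    assert cm.molar_extinction_214(vp3.sequence) == pytest.approx(
        expected, rel=1e-6
    )


def test_epsilon_unknown_residue_names_char_and_position():
    with pytest.raises(ValueError, match=r"'X' at position 3"):
        cm.molar_extinction_214("GGXG")


@given(st.text(alphabet=sorted(cm.SIDE_CHAIN_E214), min_size=0, max_size=50))
def test_epsilon_matches_oracle_for_random_sequences(seq):
    assert cm.molar_extinction_214(seq) == pytest.approx(oracle_epsilon214(seq))


# ---------------------------------------------------------------------------
# rounding convention
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value,expected",
    [(0.315, 0.32), (0.3151, 0.32), (0.2667, 0.27), (0.265, 0.27), (-0.315, -0.32)],
)
def test_round_half_away(value, expected):
    assert cm.round_half_away(value, 2) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# stoichiometry from areas
# ---------------------------------------------------------------------------


def _areas_for_ratio(ratio, eps):
    return np.asarray(ratio) * np.asarray(eps)


EPS4 = (1.5e6, 1.3e6, 1.15e6, 1.1e6)


def test_stoichiometry_low_density_ratio_rounds_to_032():
    res = cm.stoichiometry_from_areas(_areas_for_ratio([1.0, 1.3, 6.9, 0.4], EPS4), EPS4)
    assert res.vp12_over_vp3total == pytest.approx(2.3 / 7.3)
    assert res.vp12_over_vp3total_rounded() == 0.32


def test_stoichiometry_high_density_ratio_rounds_to_027():
    res = cm.stoichiometry_from_areas(_areas_for_ratio([1.0, 1.4, 8.6, 0.4], EPS4), EPS4)
    assert res.vp12_over_vp3total == pytest.approx(2.4 / 9.0)
    assert res.vp12_over_vp3total_rounded() == 0.27


def test_stoichiometry_equal_areas_equal_eps_is_symmetric():
    res = cm.stoichiometry_from_areas([2.0] * 4, [1.0] * 4)
    assert np.allclose(res.ratios, 1.0)
    assert res.vp12_over_vp3total == pytest.approx(1.0)


def test_stoichiometry_invariants():
    res = cm.stoichiometry_from_areas(_areas_for_ratio([1.0, 1.3, 6.9, 0.4], EPS4), EPS4)
    assert res.fractions.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(res.fractions >= 0)
    assert res.expected_counts_60.sum() == pytest.approx(60.0, abs=1e-9)


@given(scale=st.floats(min_value=1e-6, max_value=1e6))
def test_stoichiometry_scale_invariance(scale):
    areas = _areas_for_ratio([1.0, 1.3, 6.9, 0.4], EPS4)
    a = cm.stoichiometry_from_areas(areas, EPS4)
    b = cm.stoichiometry_from_areas(areas * scale, EPS4)
    assert np.allclose(a.ratios, b.ratios, rtol=1e-9)
    assert a.vp12_over_vp3total == pytest.approx(b.vp12_over_vp3total, rel=1e-9)


def test_stoichiometry_zero_vp1_errors():
    with pytest.raises(ValueError, match="VP1"):
        cm.stoichiometry_from_areas([0.0, 1.0, 1.0, 1.0], EPS4)


def test_stoichiometry_zero_vp3_total_errors():
    with pytest.raises(ValueError, match="VP3_total"):
        cm.stoichiometry_from_areas(
            [1.0, 1.0, 0.0, 0.0], EPS4, names=("VP1", "VP2", "VP3", "VP3clip")
        )


# ---------------------------------------------------------------------------
# expected counts in a 60-mer
# ---------------------------------------------------------------------------


def test_expected_counts_1_1_10():
    counts = cm.expected_counts_60(np.array([1, 1, 10]) / 12.0)
    assert counts == pytest.approx([5.0, 5.0, 50.0])


def test_expected_counts_degenerate():
    assert cm.expected_counts_60([1.0, 0, 0, 0]) == pytest.approx([60, 0, 0, 0])


def test_expected_counts_low_density_ratio():
    ratio = np.array([1.0, 1.3, 6.9, 0.4])
    counts = cm.expected_counts_60(ratio / ratio.sum())
    assert counts.sum() == pytest.approx(60.0, abs=1e-9)
    # arithmetic oracle: VP3 copies = 60 * 6.9 / 9.6
    assert counts[2] == pytest.approx(60.0 * 6.9 / ratio.sum())


def test_expected_counts_negative_fraction_errors():
    with pytest.raises(ValueError):
        cm.expected_counts_60([1.2, -0.2])


# ---------------------------------------------------------------------------
# particle mass and assembly moments
# ---------------------------------------------------------------------------


def test_theoretical_mass_single_species(ensemble_factory):
    spec = ensemble_factory([80_000.0], [1.0])
    assert cm.theoretical_particle_mass(spec) == pytest.approx(4_800_000.0)


def test_theoretical_mass_two_species_with_genome(ensemble_factory):
    spec = ensemble_factory([60_000.0, 80_000.0], [0.5, 0.5], genome_mass=700_000.0)
    assert cm.theoretical_particle_mass(spec) == pytest.approx(4_900_000.0)


def test_theoretical_mass_identity(ensemble_factory):
    spec = ensemble_factory([61_234.0, 80_000.0], [1.0, 0.0], genome_mass=5_000.0)
    assert cm.theoretical_particle_mass(spec) == pytest.approx(60 * 61_234.0 + 5_000.0)


def test_moments_single_species_no_variance(ensemble_factory):
    mom = cm.assembly_mass_moments(ensemble_factory([80_000.0], [1.0]))
    assert mom.sd == 0.0
    assert mom.fwhm == 0.0


def test_moments_binomial_oracle(ensemble_factory):
    # exact binomial variance: 60 * p(1-p) * (m2-m1)^2 = 60 * 0.25 * 1 = 15
    mom = cm.assembly_mass_moments(ensemble_factory([1.0, 2.0], [0.5, 0.5]))
    assert mom.sd == pytest.approx(math.sqrt(15.0))
    assert mom.fwhm == pytest.approx(2.0 * math.sqrt(2 * math.log(2)) * mom.sd)


def test_moments_match_monte_carlo(f11_spec):
    mom = cm.assembly_mass_moments(f11_spec)
    _, masses = cm.sample_assembly_arrays(f11_spec, 100_000, seed=42)
    assert masses.mean() == pytest.approx(mom.mean, rel=1e-3)
    assert masses.std(ddof=1) == pytest.approx(mom.sd, rel=0.02)


# ---------------------------------------------------------------------------
# multinomial sampling
# ---------------------------------------------------------------------------


def test_sample_degenerate_fraction(ensemble_factory):
    spec = ensemble_factory([10.0, 20.0], [1.0, 0.0])
    particles = cm.sample_assembly(spec, 50, seed=0)
    assert all(p.counts == (60, 0) for p in particles)


def test_sample_mean_mass_close_to_theory(f22_spec):
    _, masses = cm.sample_assembly_arrays(f22_spec, 100_000, seed=7)
    assert masses.mean() == pytest.approx(
        cm.theoretical_particle_mass(f22_spec), rel=1e-3
    )


def test_sample_deterministic_under_seed(f11_spec):
    a = cm.sample_assembly(f11_spec, 100, seed=123)
    b = cm.sample_assembly(f11_spec, 100, seed=123)
    assert a == b


def test_sample_requires_positive_n(f11_spec):
    with pytest.raises(ValueError):
        cm.sample_assembly(f11_spec, 0)


# ---------------------------------------------------------------------------
# composition enumeration
# ---------------------------------------------------------------------------


def oracle_compositions(target, tolerance, masses, genome):
    """Independent recursive enumeration used as the exhaustive oracle."""
    results = []

    def recurse(prefix, remaining):
        if len(prefix) == len(masses) - 1:
            counts = prefix + [remaining]
            mass = sum(c * m for c, m in zip(counts, masses)) + genome
            if abs(mass - target) <= tolerance:
                results.append((tuple(counts), mass))
            return
        for c in range(remaining + 1):
            recurse(prefix + [c], remaining - c)

    recurse([], 60)
    return sorted(results, key=lambda cm_: (round(abs(cm_[1] - target), 6), cm_[0]))


def test_compositions_unique_solution(ensemble_factory):
    spec = ensemble_factory([10.0, 20.0, 30.0], [1 / 3] * 3)
    out = cm.compositions_for_mass(1800.0, 0.0, spec)
    assert [c.counts for c in out] == [(0, 0, 60)]


def test_compositions_infinite_tolerance_counts_weak_compositions(ensemble_factory):
    spec = ensemble_factory([10.0, 20.0, 30.0], [1 / 3] * 3)
    out = cm.compositions_for_mass(0.0, math.inf, spec)
    assert len(out) == 1891  # C(62, 2) weak compositions of 60 into 3 parts


def test_compositions_self_consistency(f11_spec):
    m = f11_spec.monomer_masses
    target = float(np.dot([5, 5, 50, 0], m) + f11_spec.genome_mass)
    out = cm.compositions_for_mass(target, 0.0, f11_spec)
    assert (5, 5, 50, 0) in [c.counts for c in out]


@pytest.mark.parametrize("k,seed", [(2, 0), (3, 1), (4, 2)])
def test_compositions_match_recursive_oracle(ensemble_factory, k, seed):
    rng = np.random.default_rng(seed)
    masses = np.round(rng.uniform(50, 120, size=k), 1)
    genome = 500.0
    spec = ensemble_factory(masses, np.full(k, 1.0 / k), genome_mass=genome)
    target = float(np.dot(np.full(k, 60.0 / k), masses) + genome)
    tolerance = 40.0
    ours = cm.compositions_for_mass(target, tolerance, spec)
    oracle = oracle_compositions(target, tolerance, masses.tolist(), genome)
    assert [(c.counts, pytest.approx(c.mass)) for c in ours] == [
        (counts, pytest.approx(mass)) for counts, mass in oracle
    ]


def test_compositions_empty_result_is_valid(ensemble_factory):
    spec = ensemble_factory([10.0, 20.0], [0.5, 0.5])
    assert cm.compositions_for_mass(1e9, 1.0, spec) == []


# ---------------------------------------------------------------------------
# ppm error
# ---------------------------------------------------------------------------


def test_ppm_small_difference():
    assert cm.mass_ppm_error(59_750.5, 59_750.0) == pytest.approx(8.368, abs=0.01)


def test_ppm_equal_masses():
    assert cm.mass_ppm_error(5.0e6, 5.0e6) == 0.0


def test_ppm_large_scale():
    # arithmetic oracle: 1e6 * 0.12e6 / 4.58e6
    assert cm.mass_ppm_error(4.70e6, 4.58e6) == pytest.approx(26_200, rel=0.01)


def test_ppm_requires_positive_theoretical():
    with pytest.raises(ValueError):
        cm.mass_ppm_error(1.0, 0.0)


# ---------------------------------------------------------------------------
# cross-cutting invariants
# ---------------------------------------------------------------------------


def test_mass_ordering_follows_vp12_ratio(f11_spec, f22_spec):
    # same genome; more VP1/VP2 -> strictly heavier particle
    assert f11_spec.genome_mass == f22_spec.genome_mass
    assert cm.theoretical_particle_mass(f11_spec) > cm.theoretical_particle_mass(
        f22_spec
    )


@pytest.mark.parametrize("name", ["f1_1", "f2_2", "m203v", "m211v"])
def test_concentrating_on_dominant_species_narrows_sd(scenarios, name):
    spec = scenarios[name].ensemble
    dom = int(np.argmax(spec.fractions))
    sds = []
    for t in np.linspace(0.0, 1.0, 11):
        p = (1 - t) * spec.fractions + t * np.eye(len(spec.fractions))[dom]
        shifted = cm.CapsidEnsembleSpec(spec.species, p, spec.genome_mass)
        sds.append(cm.assembly_mass_moments(shifted).sd)
    assert all(a >= b - 1e-9 for a, b in zip(sds, sds[1:]))


def test_monte_carlo_sd_matches_closed_form_all_scenarios(scenarios):
    for name, scen in scenarios.items():
        for comp in scen.components:
            mom = cm.assembly_mass_moments(comp)
            _, masses = cm.sample_assembly_arrays(comp, 100_000, seed=11)
            assert masses.std(ddof=1) == pytest.approx(mom.sd, rel=0.02), name


# ---------------------------------------------------------------------------
# species / FASTA round trip
# ---------------------------------------------------------------------------


def test_species_mass_matches_sequence(vp_species):
    for sp in vp_species:
        assert sp.mass_matches_sequence(tol_ppm=25.0)


def test_species_mass_override_flagged():
    sp = cm.VPSpecies(
        name="VP3", monomer_mass=59_750.0, epsilon214=1e6, sequence="GGWGG" * 100
    )
    assert not sp.mass_matches_sequence(tol_ppm=25.0)


def test_fasta_round_trip(tmp_path, vp_species):
    path = tmp_path / "vps.fasta"
    with open(path, "w") as fh:
        for sp in vp_species:
            fh.write(f">{sp.name}\n{sp.sequence}\n")
    loaded = cm.read_vp_fasta(path)
    assert [s.name for s in loaded] == [s.name for s in vp_species]
    for got, want in zip(loaded, vp_species):
        assert got.monomer_mass == pytest.approx(want.monomer_mass, rel=1e-9)
        assert got.epsilon214 == pytest.approx(want.epsilon214)


def test_csv_outputs(tmp_path, f11_spec):
    res = cm.stoichiometry_from_areas(
        _areas_for_ratio([1.0, 1.3, 6.9, 0.4], EPS4), EPS4
    )
    cm.stoichiometry_to_csv(res, tmp_path / "stoich.csv")
    cands = cm.compositions_for_mass(
        cm.theoretical_particle_mass(f11_spec), 5e4, f11_spec
    )
    cm.candidates_to_csv(cands, f11_spec.names, tmp_path / "cands.csv")
    import pandas as pd

    stoich = pd.read_csv(tmp_path / "stoich.csv")
    assert list(stoich.columns) == [
        "species", "ratio_vs_vp1", "molar_fraction", "expected_count_60mer",
    ]
    assert len(pd.read_csv(tmp_path / "cands.csv")) == len(cands) > 0
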