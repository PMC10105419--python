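"""Ring classification, ring-aware fragments, desulfurization, inference."""

import pytest

from lanmine.chem import DERIVED_RESIDUE_FORMULAS, RESIDUE_FORMULAS, ModificationSet
from lanmine.ms1 import PeptideSpecies
from lanmine.rings import (
    RingTopology,
    TopologyError,
    annotate_spectrum,
    classify_topology,
    desulfurize,
    enumerate_candidate_topologies,
    infer_topology_from_desulfurization,
    score_topologies,
    theoretical_fragments,
)
from lanmine.simulate import (
    SpectrumSimSpec,
    generate_ms2,
    generate_ms2_from_fragments,
)
from lanmine.spectra import Peak, Spectrum


def test_classify_alpha_bicycle_is_disjoint(alpha):
    assert classify_topology(alpha.rings) == "disjoint"


def test_classify_beta_intertwined_is_interlocking(beta):
    assert classify_topology(beta.rings) == "interlocking"


def test_classify_nested():
    rings = RingTopology(((2, 5), (3, 4)))
    assert classify_topology(rings) == "nested"


def test_duplicate_residue_use_rejected():
    with pytest.raises(TopologyError):
        RingTopology(((2, 5), (5, 8)))


def test_link_types_from_core(alpha):
    assert alpha.rings.link_types() == ("MeLan", "Lan")


def test_linear_gg_fragments_textbook_by():
    species = PeptideSpecies("GG", ModificationSet())
    frags = theoretical_fragments(species, None, charges=(1,))
    by = {(f.series, f.index): f.mz for f in frags}
    gly = RESIDUE_FORMULAS["G"].mass
    assert by[("b", 1)] == pytest.approx(gly + 1.007276, abs=1e-5)
    assert by[("y", 1)] == pytest.approx(gly + 18.0106 + 1.007276, abs=1e-3)


def test_by_complementarity_alpha_all_cleavages(alpha):
    species = alpha.species()
    frags = theoretical_fragments(species, alpha.rings, charges=(1,))
    n = len(species.core)
    b = {f.index: f.neutral_mass for f in frags if f.series == "b"}
    y = {f.index: f.neutral_mass for f in frags if f.series == "y"}
    for i in range(1, n):
        assert abs(b[i] + y[n - i] - species.neutral_mass) < 1e-6


def test_by_complementarity_beta_with_methylation(beta):
    species = beta.species()
    frags = theoretical_fragments(species, beta.rings, charges=(1, 2))
    n = len(species.core)
    b = {f.index: f.neutral_mass for f in frags if f.series == "b"}
    y = {f.index: f.neutral_mass for f in frags if f.series == "y"}
    for i in range(1, n):
        assert abs(b[i] + y[n - i] - species.neutral_mass) < 1e-6


def test_intra_ring_cleavage_carries_rupture_shifts(alpha):
    """Cleavage inside the Cys2-Thr5 ring marks Cys2 as Dha (-34 nominal)."""
    species = alpha.species()
    frags = theoretical_fragments(species, alpha.rings, charges=(1,))
    b3 = next(f for f in frags if f.series == "b" and f.index == 3)
    assert "Cys2->Dha(-34)" in b3.ring_states
    y9 = next(f for f in frags if f.series == "y" and f.index == 9)
    assert "Thr5(+16)" in y9.ring_states
    # cleavage between 5 and 6 lies between the two rings: standard b/y pair
    b5 = next(f for f in frags if f.series == "b" and f.index == 5)
    assert b5.ring_states == ()
    # cleavage between 7 and 8 sits inside the Cys6-Ser10 ring
    b7 = next(f for f in frags if f.series == "b" and f.index == 7)
    assert "Cys6->Dha(-34)" in b7.ring_states


def test_nominal_rupture_shift_constants():
    cys = RESIDUE_FORMULAS["C"].mass
    dha = DERIVED_RESIDUE_FORMULAS["Dha"].mass
    ser = RESIDUE_FORMULAS["S"].mass
    donor_thio = DERIVED_RESIDUE_FORMULAS["Ser(+S-O)"].mass
    assert round(cys - dha) == 34
    assert round(cys - ser) == 16
    assert round(donor_thio - ser) == 16
    # monoisotopic values behind the nominal labels
    assert cys - dha == pytest.approx(33.9877, abs=1e-3)
    assert donor_thio - ser == pytest.approx(15.9772, abs=1e-3)


def test_suppress_mode_drops_intra_ring_cleavages(alpha):
    species = alpha.species()
    frags = theoretical_fragments(species, alpha.rings, (1,), mode="suppress")
    b_indices = {f.index for f in frags if f.series == "b"}
    # rings span 2-5 and 6-10: cleavages 2,3,4 and 6,7,8,9 suppressed
    assert b_indices == {1, 5, 10, 11}


def test_annotate_round_trip_coverage(alpha):
    species = alpha.species()
    spec = SpectrumSimSpec(seed=5, jitter_ppm_sd=5.0, noise_fraction=0.2)
    spectrum = generate_ms2(species, alpha.rings, spec)
    frags = theoretical_fragments(species, alpha.rings, (1, 2))
    ann = annotate_spectrum(spectrum, frags, tol_ppm=10, core_length=12)
    assert ann.coverage >= 0.8


def test_annotate_empty_spectrum_zero_coverage(alpha):
    frags = theoretical_fragments(alpha.species(), alpha.rings, (1,))
    ann = annotate_spectrum(Spectrum(()), frags, 10, core_length=12)
    assert ann.coverage == 0.0
    assert ann.assignments == ()


def test_annotate_single_matching_peak(alpha):
    frags = theoretical_fragments(alpha.species(), alpha.rings, (1,))
    y2 = next(f for f in frags if f.series == "y" and f.index == 2)
    ann = annotate_spectrum(
        Spectrum((Peak(y2.mz, 1.0),)), frags, 10, core_length=12
    )
    assert len(ann.assignments) == 1
    assert ann.assignments[0][1].series == "y"
    assert ann.assignments[0][1].index == 2


def test_score_topologies_true_alpha_ranks_first(alpha):
    species = alpha.species()
    spectrum = generate_ms2(
        species, alpha.rings, SpectrumSimSpec(seed=9, jitter_ppm_sd=5.0)
    )
    wrong = RingTopology(((11, 6), (5, 2)), alpha.core)  # Ser11-Cys6 instead
    scores, indeterminate = score_topologies(
        spectrum, species, [wrong, alpha.rings], tol_ppm=10
    )
    assert not indeterminate
    assert scores[0].topology.crosslinks == alpha.rings.crosslinks


def test_score_topologies_no_ring_ions_indeterminate(alpha):
    species = alpha.species()
    frags = theoretical_fragments(species, alpha.rings, (1,))
    b11 = next(f for f in frags if f.series == "b" and f.index == 11)
    wrong = RingTopology(((11, 6), (5, 2)), alpha.core)
    # b11 spans both candidate ring systems entirely: shared by both
    scores, indeterminate = score_topologies(
        Spectrum((Peak(b11.mz, 1.0),)), species, [alpha.rings, wrong], 10
    )
    assert indeterminate


def test_score_topologies_empty_candidates_error(alpha):
    with pytest.raises(ValueError):
        score_topologies(Spectrum(()), alpha.species(), [], 10)


def test_enumerate_candidate_topologies_counts(alpha, beta):
    # alpha core: 2 Cys, 4 Ser/Thr donors -> C(2,2)*C(4,2)*2! = 12
    assert len(enumerate_candidate_topologies(alpha.core, 2)) == 12
    # beta core: 2 Cys, 3 Ser donors -> C(2,2)*C(3,2)*2! = 6
    assert len(enumerate_candidate_topologies(beta.core, 2)) == 6
    assert len(enumerate_candidate_topologies(alpha.core, 0)) == 1
    assert enumerate_candidate_topologies(alpha.core, 3) == []


def test_desulfurization_mass_ledger(beta):
    """-S +2H per opened link (reagent H); +(D-H) more per link with D."""
    species = beta.species()
    for links in ([(4, 13)], [(4, 13), (6, 14)]):
        prod_h = desulfurize(species, beta.rings, links, "H")
        for v in prod_h.variants:
            delta = species.neutral_mass - v.neutral_mass
            expected = len(links) * (31.9720707 - 2 * 1.0078250319)
            assert delta == pytest.approx(expected, abs=1e-6)
        prod_d = desulfurize(species, beta.rings, links, "D")
        for v in prod_d.variants:
            delta_d = species.neutral_mass - v.neutral_mass
            assert delta_d == pytest.approx(
                expected - len(links) * 1.00628, abs=1e-4
            )


def test_desulfurize_beta_partial_products(beta):
    species = beta.species()
    # open Ser4-Cys13: Ser6/Cys14 crosslink intact, deuterated Ala variants
    prod = desulfurize(species, beta.rings, [(4, 13)], "D")
    assert prod.remaining_rings.crosslinks == ((6, 14),)
    placements = {v.deuterated_positions for v in prod.variants}
    assert placements == {(4,), (13,)}
    v4 = next(v for v in prod.variants if v.deuterated_positions == (4,))
    assert v4.residue_labels[3] == "Ala(d1)"  # deuterated Ala from Ser4
    # open Ser6-Cys14: Ser4/Cys13 intact, deuterated Ala from Cys14 variant
    prod2 = desulfurize(species, beta.rings, [(6, 14)], "D")
    assert prod2.remaining_rings.crosslinks == ((4, 13),)
    v14 = next(v for v in prod2.variants if v.deuterated_positions == (14,))
    assert v14.residue_labels[13] == "Ala(d1)"


def test_desulfurize_empty_set_is_identity(beta):
    species = beta.species()
    prod = desulfurize(species, beta.rings, [], "H")
    assert len(prod.variants) == 1
    assert prod.variants[0].formula == species.formula


def test_desulfurize_unknown_link_rejected(beta):
    with pytest.raises(TopologyError):
        desulfurize(beta.species(), beta.rings, [(9, 13)], "H")


def test_product_fragment_complementarity(beta):
    species = beta.species()
    prod = desulfurize(species, beta.rings, [(4, 13)], "D")
    for v in prod.variants:
        frags = prod.fragments(v, charges=(1,))
        n = len(species.core)
        b = {f.index: f.neutral_mass for f in frags if f.series == "b"}
        y = {f.index: f.neutral_mass for f in frags if f.series == "y"}
        for i in range(1, n):
            assert abs(b[i] + y[n - i] - v.neutral_mass) < 1e-6


def _beta_partial_spectra(beta, seed, jitter=5.0, noise=0.2):
    species = beta.species()
    spectra = []
    for link, placement in (((4, 13), (4,)), ((6, 14), (14,))):
        prod = desulfurize(species, beta.rings, [link], "D")
        variant = next(
            v for v in prod.variants if v.deuterated_positions == placement
        )
        frags = prod.fragments(variant, charges=(1, 2))
        spectra.append(
            generate_ms2_from_fragments(
                frags,
                SpectrumSimSpec(seed=seed, jitter_ppm_sd=jitter, noise_fraction=noise),
            )
        )
    return spectra


def test_infer_topology_beta_round_trip(beta):
    """Two partial desulfurization spectra recover the intertwined rings."""
    species = beta.species()
    parent = generate_ms2(
        species, beta.rings, SpectrumSimSpec(seed=21, jitter_ppm_sd=5.0)
    )
    products = _beta_partial_spectra(beta, seed=22)
    result = infer_topology_from_desulfurization(parent, products, species)
    assert result.topology is not None
    assert result.topology.crosslinks == ((4, 13), (6, 14))
    assert result.label == "interlocking"
    opened = {r["opened_link"] for r in result.per_spectrum_assignment}
    assert opened == {(4, 13), (6, 14)}


def test_infer_topology_disjoint_ground_truth():
    core = "GATCAGASAGCA"
    # donors T3, S8; acceptors C4, C11; truth: T3-C4 ring and S8-C11 ring
    truth = RingTopology(((3, 4), (8, 11)), core)
    assert classify_topology(truth) == "disjoint"
    species = PeptideSpecies(core, ModificationSet(n_dehydration=2))
    parent = generate_ms2(
        species, truth, SpectrumSimSpec(seed=31, jitter_ppm_sd=5.0)
    )
    spectra = []
    for link in truth.crosslinks:
        prod = desulfurize(species, truth, [link], "D")
        frags = prod.fragments(prod.variants[0], charges=(1, 2))
        spectra.append(
            generate_ms2_from_fragments(
                frags, SpectrumSimSpec(seed=32, jitter_ppm_sd=5.0)
            )
        )
    result = infer_topology_from_desulfurization(parent, spectra, species)
    assert result.topology is not None
    assert result.topology.crosslinks == truth.crosslinks
    assert result.label == "disjoint"


def test_infer_topology_requires_product_spectra(beta):
    with pytest.raises(ValueError):
        infer_topology_from_desulfurization(None, [], beta.species())
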