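"""Species enumeration, MS1 peak matching, ranking and BGC linking."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from lanmine import chem
from lanmine.mining import Orf, PrecursorCandidate, scan_leader_motif
from lanmine.ms1 import (
    ModificationSpace,
    PeptideSpecies,
    enumerate_species,
    link_bgc_to_peaks,
    match_ms1,
    rank_matches,
)
from lanmine.chem import ModificationSet
from lanmine.spectra import Peak


def test_enumerate_species_counts_12():
    space = ModificationSpace(
        max_dehydrations=5, allow_methylation=True, max_methylations=1
    )
    species = enumerate_species("GCGFTCSPFSSW", space)
    assert len(species) == 12  # 6 dehydration counts x 2 methylation counts


def test_enumerate_species_zero_space_is_unmodified():
    species = enumerate_species(
        "GCW", ModificationSpace(max_dehydrations=0)
    )
    assert len(species) == 1
    assert species[0].formula == chem.peptide_formula("GCW")


def test_auto_dehydration_bound_counts_ser_thr():
    space = ModificationSpace(max_dehydrations="auto")
    assert space.dehydration_bound("GCGFTCSPFSSW") == 4  # 3 Ser + 1 Thr
    assert space.dehydration_bound("GLPSASMYSFEHCC") == 3
    species = enumerate_species("GCGFTCSPFSSW", space)
    assert len(species) == 5


def test_enumerate_species_monotone_in_space():
    small = enumerate_species("GCGFTCSPFSSW", ModificationSpace(2))
    large = enumerate_species(
        "GCGFTCSPFSSW", ModificationSpace(4, allow_methylation=True)
    )
    small_f = {s.formula for s in small}
    assert small_f <= {s.formula for s in large}


def test_match_ms1_worked_examples(alpha, beta):
    a_species = enumerate_species(
        alpha.core, ModificationSpace(max_dehydrations=4)
    )
    matches = match_ms1([Peak(621.7382, 1.0, 2)], a_species, tol_ppm=10)
    assert len(matches) == 1
    assert matches[0].species.mods.n_dehydration == 2
    assert abs(matches[0].ppm) == pytest.approx(1.29, abs=0.1)

    b_species = enumerate_species(
        beta.core, ModificationSpace(max_dehydrations=3, allow_methylation=True)
    )
    matches = match_ms1([Peak(755.3012, 1.0, 2)], b_species, tol_ppm=10)
    assert len(matches) == 1
    assert matches[0].species.mods.n_dehydration == 2
    assert matches[0].species.mods.n_methylation == 1
    assert abs(matches[0].ppm) == pytest.approx(0.53, abs=0.1)

    assert match_ms1([Peak(500.0, 1.0, 2)], a_species + b_species, tol_ppm=10) == []


def test_match_ms1_matches_brute_force_oracle():
    rngs = itertools.product(range(4), range(2))
    species = [
        PeptideSpecies("GCGFTCSPFSSW", ModificationSet(nd, nm))
        for nd, nm in rngs
    ]
    peaks = [
        Peak(m, 1.0, None)
        for m in (415.0, 622.0, 621.7390, 612.73, 1242.47, 830.0, 700.0)
    ]
    charges = (1, 2, 3)
    got = {
        (m.peak.mz, m.species.formula, m.charge)
        for m in match_ms1(peaks, species, charges, tol_ppm=25)
    }
    oracle = set()
    for p in peaks:
        for sp in species:
            for z in charges:
                theo = chem.mz_from_neutral(sp.neutral_mass, z)
                if abs(chem.ppm_error(p.mz, theo)) <= 25:
                    oracle.add((p.mz, sp.formula, z))
    assert got == oracle


def test_match_ms1_honours_peak_charge_annotation():
    species = [PeptideSpecies("GCGFTCSPFSSW", ModificationSet(2))]
    theo_z1 = chem.mz_from_neutral(species[0].neutral_mass, 1)
    # peak annotated z=2 must not match the z=1 hypothesis
    assert match_ms1([Peak(theo_z1, 1.0, 2)], species, (1, 2), 5) == []
    assert len(match_ms1([Peak(theo_z1, 1.0, None)], species, (1, 2), 5)) == 1


@given(tol=st.floats(min_value=1.0, max_value=50.0))
@settings(max_examples=20, derandomize=True)
def test_match_monotone_in_tolerance(tol):
    species = [
        PeptideSpecies("GCGFTCSPFSSW", ModificationSet(nd)) for nd in range(4)
    ]
    peaks = [Peak(621.7390, 1.0, None), Peak(604.0, 1.0, None)]
    small = match_ms1(peaks, species, (1, 2), tol)
    large = match_ms1(peaks, species, (1, 2), tol * 2)
    keys = lambda ms: {(m.peak.mz, m.species.formula, m.charge) for m in ms}
    assert keys(small) <= keys(large)


def test_rank_matches_parsimony_then_ppm():
    sp2 = PeptideSpecies("GCGFTCSPFSSW", ModificationSet(2))
    sp4 = PeptideSpecies("GCGFTCSPFSSW", ModificationSet(4))
    peak = Peak(621.7390, 1.0, 2)
    m_few = match_ms1([peak], [sp2], (2,), 10)[0]
    m_many_precise = match_ms1([Peak(sp4.mz(2), 1.0, 2)], [sp4], (2,), 10)[0]
    ranked = rank_matches([m_many_precise, m_few])
    assert ranked[0].species.mods.n_dehydration == 2
    # same mod count: smaller |ppm| first
    a = match_ms1([Peak(sp2.mz(2) * (1 + 1.1e-6), 1.0, 2)], [sp2], (2,), 10)[0]
    b = match_ms1([Peak(sp2.mz(2) * (1 + 0.4e-6), 1.0, 2)], [sp2], (2,), 10)[0]
    assert rank_matches([a, b])[0] is b
    assert rank_matches([a]) == [a]


def _alpha_candidate(alpha):
    aa = alpha.precursor
    orf = Orf("ctg", 0, 3 * len(aa) + 3, "+", 0, aa, 150)
    return PrecursorCandidate(
        orf, 150, True, motif_hits=tuple(scan_leader_motif(aa))
    )


def test_link_bgc_to_peaks_alpha_fixture(alpha):
    report = link_bgc_to_peaks(
        [_alpha_candidate(alpha)],
        [Peak(621.7382, 1.0, 2)],
        ModificationSpace(max_dehydrations="auto"),
        tol_ppm=10,
        min_core=12,
        max_core=12,
    )
    assert len(report) == 1
    links = report[0]["links"]
    assert len(links) == 1
    assert links[0]["core"] == "GCGFTCSPFSSW"
    assert links[0]["modifications"]["n_dehydration"] == 2
    assert links[0]["formula"] == "C57H71N13O15S2"


def test_link_bgc_no_peaks_in_tolerance_is_empty_not_error(alpha):
    report = link_bgc_to_peaks(
        [_alpha_candidate(alpha)],
        [Peak(400.0, 1.0, None)],
        ModificationSpace(max_dehydrations="auto"),
        tol_ppm=5,
        min_core=12,
        max_core=12,
    )
    assert report[0]["links"] == []


def test_two_cores_matching_one_peak_both_reported(alpha):
    # two candidates share the same core through different leaders
    aa2 = "MSEEL" + alpha.core
    orf2 = Orf("ctg", 500, 500 + 3 * len(aa2) + 3, "+", 0, aa2, 300)
    cand2 = PrecursorCandidate(orf2, 300, True)
    report = link_bgc_to_peaks(
        [_alpha_candidate(alpha), cand2],
        [Peak(621.7382, 1.0, 2)],
        ModificationSpace(max_dehydrations="auto"),
        tol_ppm=10,
        min_core=12,
        max_core=12,
    )
    assert len(report) == 2
    assert all(len(entry["links"]) == 1 for entry in report)
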