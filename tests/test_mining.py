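"""ORF scanning, precursor filtering, leader motif, leader/core splits."""

import re

import pytest
from Bio.Seq import Seq

from lanmine.mining import (
    Feature,
    GenomeRecord,
    Orf,
    PrecursorCandidate,
    START_CODONS,
    STOP_CODONS,
    enumerate_core_splits,
    filter_precursors,
    find_orfs,
    scan_leader_motif,
    select_adjacent,
)
from lanmine.simulate import GenomeSimSpec, generate_genome

CODON = {
    "M": "ATG", "A": "GCT", "C": "TGT", "S": "TCT", "T": "ACC", "G": "GGT",
    "F": "TTT", "K": "AAA", "Y": "TAT", "D": "GAT", "E": "GAA", "L": "CTG",
    "P": "CCG", "W": "TGG", "V": "GTT",
}


def encode(peptide: str) -> str:
    return "".join(CODON[aa] for aa in peptide) + "TAA"


def naive_six_frame_scan(seq: str, lo: int, hi: int, min_aa: int, max_aa: int):
    """Independent brute-force oracle: longest ORF per stop, both strands."""
    results = []
    for strand in ("+", "-"):
        window = seq[lo:hi]
        if strand == "-":
            window = str(Seq(window).reverse_complement())
        n = len(window)
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = window[i : i + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        aa_len = (i - start) // 3
                        if min_aa <= aa_len <= max_aa:
                            aa = "M" + str(Seq(window[start + 3 : i]).translate())
                            if strand == "+":
                                g = (lo + start, lo + i + 3)
                            else:
                                g = (lo + n - i - 3, lo + n - start)
                            results.append((g[0], g[1], strand, aa))
                        start = None
                elif start is None and codon in START_CODONS:
                    start = i
    return sorted(results)


def make_genome(inserts, total=4000, lanm=(1000, 1300)):
    """A backbone with no start codons on either strand, plus planted genes.

    CTA repeats read Leu/stop-free forward and pure TAG stops in reverse,
    so every ORF in the record is a planted one.
    """
    seq = list("CTA" * (total // 3 + 1))[:total]
    seq[lanm[0] : lanm[1]] = list("ATG" + "GAA" * 98 + "TAA")
    feats = [Feature("lanM_1", "ctg", lanm[0], lanm[0] + 300, "+", "lanM")]
    for pos, gene in inserts:
        seq[pos : pos + len(gene)] = list(gene)
    return GenomeRecord("ctg", "".join(seq), tuple(feats))


def test_find_orfs_empty_window():
    genome = make_genome([])
    anchor = genome.features_of_type("lanM")[0]
    # backbone CTA repeats contain no start codon outside the anchor
    assert find_orfs(genome, anchor, min_len_aa=5) == []


def test_find_orfs_recovers_planted_orf_at_known_distance():
    gene = encode("M" + "A" * 59)  # 60 codons + stop
    anchor_end = 1300
    pos = anchor_end + 200
    genome = make_genome([(pos, gene)])
    anchor = genome.features_of_type("lanM")[0]
    orfs = find_orfs(genome, anchor, min_len_aa=20)
    assert len(orfs) == 1
    orf = orfs[0]
    assert (orf.start, orf.end, orf.strand) == (pos, pos + len(gene), "+")
    assert orf.distance_to_anchor == 200
    assert orf.aa_sequence == "M" + "A" * 59


def test_find_orfs_minus_strand_reverse_complement():
    gene = encode("MGCGFTCSPFSSW")
    rc = str(Seq(gene).reverse_complement())
    pos = 1300 + 150
    genome = make_genome([(pos, rc)])
    anchor = genome.features_of_type("lanM")[0]
    orfs = find_orfs(genome, anchor, min_len_aa=5)
    planted = [o for o in orfs if o.aa_sequence == "MGCGFTCSPFSSW"]
    assert len(planted) == 1
    assert planted[0].strand == "-"
    assert (planted[0].start, planted[0].end) == (pos, pos + len(rc))


def test_find_orfs_matches_naive_oracle_on_synthetic_genome():
    spec = GenomeSimSpec(
        seed=11, n_true=2, decoy_clauses=("too_long", "no_cys", "no_st")
    )
    genome, _ = generate_genome(spec)
    anchor = genome.features_of_type("lanM")[0]
    lo = max(0, anchor.start - 6000)
    hi = min(len(genome.sequence), anchor.end + 6000)
    oracle = naive_six_frame_scan(genome.sequence, lo, hi, 20, 200)
    oracle = [
        o for o in oracle if not (o[0] < anchor.end and o[1] > anchor.start)
    ]
    got = sorted(
        (o.start, o.end, o.strand, o.aa_sequence)
        for o in find_orfs(genome, anchor, min_len_aa=20, max_len_aa=200)
    )
    assert got == oracle


def test_find_orfs_requires_anchor_annotation():
    genome = make_genome([])
    rogue = Feature("other", "ctg", 10, 40, "+", "lanM")
    with pytest.raises(ValueError, match="anchor"):
        find_orfs(genome, rogue)


def test_select_adjacent_distances_and_ties():
    def orf_at(d, start):
        return Orf("ctg", start, start + 33, "+", 0, "M" * 10, d)

    orfs = [orf_at(d, 100 * d) for d in range(100, 1300, 100)]
    assert len(orfs) == 12
    top = select_adjacent(orfs, k=10)
    assert [o.distance_to_anchor for o in top] == list(range(100, 1100, 100))
    few = select_adjacent(orfs[:3], k=10)
    assert len(few) == 3
    # equal distance: smaller start first, then + before -
    a = Orf("ctg", 50, 83, "-", 0, "M" * 10, 200)
    b = Orf("ctg", 50, 83, "+", 0, "M" * 10, 200)
    c = Orf("ctg", 20, 53, "-", 0, "M" * 10, 200)
    assert select_adjacent([a, b, c], k=3) == [c, b, a]


@pytest.mark.parametrize(
    "length,tail,kept",
    [
        (99, "AACAASAA", True),  # C and S in C-terminal window
        (100, "AACAASAA", False),  # strictly shorter than 100
        (50, None, False),  # only Cys sits 25 residues from the C-terminus
    ],
)
def test_filter_precursors_rules(length, tail, kept):
    if tail is not None:
        aa = "M" + "A" * (length - 1 - len(tail)) + tail
    else:
        aa = "M" + "A" * 23 + "C" + "A" * 25  # Cys at -26
        assert len(aa) == 50
    orf = Orf("ctg", 0, 3 * len(aa) + 3, "+", 0, aa, 100)
    got = filter_precursors([orf])
    assert bool(got) is kept


def test_filter_precursors_idempotent():
    genome, _ = generate_genome(GenomeSimSpec(seed=3, n_true=2))
    anchor = genome.features_of_type("lanM")[0]
    cands = filter_precursors(find_orfs(genome, anchor))
    again = filter_precursors([c.orf for c in cands])
    assert [c.orf for c in again] == [c.orf for c in cands]


@pytest.mark.parametrize(
    "seq,positions",
    [
        ("KAYDAAF", [0]),
        ("KAADAAF", []),  # third position not Y/F
        ("AKAYDAAFKAFEAAY", [1, 8]),
    ],
)
def test_scan_leader_motif(seq, positions):
    assert [p for p, _ in scan_leader_motif(seq)] == positions


def test_scan_leader_motif_matches_regex_oracle():
    rx = re.compile(r"(?=(K.[YF][DE]..[FY]))")
    seq = "MKAYDAAFKVFEKSYKAYDACFWKRYEAAYKKFDAAFY"
    oracle = [m.start() for m in rx.finditer(seq)]
    assert [p for p, _ in scan_leader_motif(seq)] == oracle


def _candidate(aa):
    orf = Orf("ctg", 0, 3 * len(aa) + 3, "+", 0, aa, 0)
    return PrecursorCandidate(
        orf, 0, True, motif_hits=tuple(scan_leader_motif(aa))
    )


def test_enumerate_core_splits_fixture_core():
    cand = _candidate("MKAYDAAFELGCGFTCSPFSSW")
    splits = enumerate_core_splits(cand, 12, 12)
    assert len(splits) == 1
    split, leader, core, motif_ok = splits[0]
    assert core == "GCGFTCSPFSSW"
    assert leader == "MKAYDAAFEL"
    assert motif_ok  # motif at position 1 lies wholly in the leader


def test_enumerate_core_splits_requires_cys_and_hydroxyl():
    cand = _candidate("MAAAAGGGGG")
    assert enumerate_core_splits(cand, 3, 8) == []


def test_enumerate_core_splits_matches_suffix_enumeration():
    aa = "MKAYDAAFELGCGFTCSPFSSW"
    cand = _candidate(aa)
    splits = enumerate_core_splits(cand, 1, len(aa))
    oracle = [
        aa[i:]
        for i in range(1, len(aa))
        if "C" in aa[i:] and (set(aa[i:]) & {"S", "T"})
    ]
    assert sorted(core for _, _, core, _ in splits) == sorted(oracle)
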