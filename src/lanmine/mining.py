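"""Precursor-peptide mining around annotated lanM loci.

Class II lanthipeptide precursors (LanAs) are short ORFs encoded next to the
hallmark synthetase gene *lanM*.  This module scans a window around each
annotated lanM feature in all six reading frames, keeps the k nearest small
ORFs, applies the precursor filter (length < 100 aa, and both a Cys and a
Ser/Thr inside the C-terminal 20 residues), scans the conserved archaeal
leader motif Kx(Y/F)(D/E)xx(F/Y), and enumerates candidate leader/core
splits.  lanM identification itself is an input annotation, not a homology
search.

Coordinates are 0-based half-open internally; GFF3 on disk is 1-based closed
(see :mod:`lanmine.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "GenomeRecord",
    "Orf",
    "PrecursorCandidate",
    "LEADER_MOTIF_LENGTH",
    "START_CODONS",
    "STOP_CODONS",
    "find_orfs",
    "select_adjacent",
    "filter_precursors",
    "scan_leader_motif",
    "enumerate_core_splits",
]

#: Start codons recognised by the ORF caller.  Archaea (like bacteria)
#: commonly initiate at GTG/TTG in addition to ATG; all translate to Met.
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
LEADER_MOTIF_LENGTH = 7


@dataclass(frozen=True)
class Feature:
    """A genome annotation row (GFF3-derived), 0-based half-open."""

    feature_id: str
    contig: str
    start: int
    end: int
    strand: str
    type: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad coordinates [{self.start}, {self.end}) for {self.feature_id}"
            )


@dataclass(frozen=True)
class GenomeRecord:
    """One contig plus its annotations."""

    contig: str
    sequence: str
    annotations: Tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA symbols in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        for f in self.annotations:
            if f.contig == self.contig and f.end > len(seq):
                raise ValueError(
                    f"feature {f.feature_id} end {f.end} beyond contig "
                    f"length {len(seq)}"
                )

    def features_of_type(self, ftype: str) -> List[Feature]:
        return [f for f in self.annotations if f.type == ftype]


@dataclass(frozen=True)
class Orf:
    """A called open reading frame; genomic span includes the stop codon."""

    contig: str
    start: int
    end: int
    strand: str
    frame: int
    aa_sequence: str
    distance_to_anchor: int = 0

    def __post_init__(self) -> None:
        if (self.end - self.start) != 3 * len(self.aa_sequence) + 3:
            raise ValueError(
                "genomic span must equal 3*aa_length + 3 (stop included): "
                f"span {self.end - self.start}, aa {len(self.aa_sequence)}"
            )
        if "*" in self.aa_sequence:
            raise ValueError("aa sequence must not contain a stop symbol")

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True)
class PrecursorCandidate:
    """An ORF near lanM wrapped with filter, motif and split information."""

    orf: Orf
    distance_to_lanM: int
    passes_filters: bool
    motif_hits: Tuple[Tuple[int, str], ...] = ()
    core_splits: Tuple[Tuple[int, str, str], ...] = ()

    @property
    def aa_sequence(self) -> str:
        return self.orf.aa_sequence


def _translate(codon_seq: str) -> str:
    return str(Seq(codon_seq).translate())


def _scan_strand(
    seq: str,
    strand: str,
    lo: int,
    hi: int,
    min_len_aa: int,
    max_len_aa: int,
    contig: str,
) -> List[Orf]:
    """Call ORFs on one strand of the window [lo, hi) of ``seq``.

    Within each frame, nested starts sharing a stop are collapsed to the
    longest ORF per stop (earliest start after the previous stop).
    """
    window = seq[lo:hi]
    if strand == "-":
        window = str(Seq(window).reverse_complement())
    orfs: List[Orf] = []
    n = len(window)
    for frame in range(3):
        start_idx: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = window[i : i + 3]
            if codon in STOP_CODONS:
                if start_idx is not None:
                    aa_len = (i - start_idx) // 3
                    if min_len_aa <= aa_len <= max_len_aa:
                        coding = window[start_idx:i]
                        aa = _translate(coding)
                        # alternative starts initiate Met
                        aa = "M" + aa[1:]
                        if strand == "+":
                            g_start = lo + start_idx
                            g_end = lo + i + 3
                        else:
                            g_start = lo + (n - (i + 3))
                            g_end = lo + (n - start_idx)
                        orfs.append(
                            Orf(contig, g_start, g_end, strand, frame, aa)
                        )
                    start_idx = None
            elif start_idx is None and codon in START_CODONS:
                start_idx = i
    return orfs


def _edge_distance(start: int, end: int, anchor_start: int, anchor_end: int) -> int:
    """Signed nearest edge-to-edge distance; negative = upstream of anchor."""
    if end <= anchor_start:
        return end - anchor_start
    if start >= anchor_end:
        return start - anchor_end
    return 0


def find_orfs(
    genome: GenomeRecord,
    anchor: Feature,
    min_len_aa: int = 20,
    max_len_aa: int = 200,
    window_bp: int = 6000,
) -> List[Orf]:
    """Six-frame ORF scan in a window around a lanM anchor feature.

    An ORF runs from a start codon (ATG/GTG/TTG) to the next in-frame stop;
    the reported span includes the stop codon and the translation excludes
    it.  ORFs overlapping the anchor's own CDS are excluded; the result is
    sorted by absolute edge distance to the anchor (ties: smaller start,
    then ``+`` before ``-``).
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    if anchor not in genome.annotations:
        raise ValueError(
            f"anchor {anchor.feature_id!r} is not an annotation of contig "
            f"{genome.contig!r}"
        )
    lo = anchor.start - window_bp
    hi = anchor.end + window_bp
    if lo < 0 or hi > len(genome.sequence):
        logger.warning(
            "window [%d, %d) clipped to contig bounds [0, %d)",
            lo,
            hi,
            len(genome.sequence),
        )
    lo = max(0, lo)
    hi = min(len(genome.sequence), hi)

    orfs: List[Orf] = []
    for strand in ("+", "-"):
        orfs.extend(
            _scan_strand(
                genome.sequence, strand, lo, hi, min_len_aa, max_len_aa,
                genome.contig,
            )
        )
    kept = []
    for o in orfs:
        if o.start < anchor.end and o.end > anchor.start:
            continue  # overlaps the anchor CDS
        d = _edge_distance(o.start, o.end, anchor.start, anchor.end)
        kept.append(replace(o, distance_to_anchor=d))
    kept.sort(
        key=lambda o: (abs(o.distance_to_anchor), o.start, o.strand == "-")
    )
    return kept


def select_adjacent(orfs: Sequence[Orf], k: int = 10) -> List[Orf]:
    """The k ORFs nearest the anchor by absolute edge distance.

    Ties break by smaller genomic start, then ``+`` strand before ``-``.
    Fewer than k ORFs are returned unchanged.
    """
    ranked = sorted(
        orfs, key=lambda o: (abs(o.distance_to_anchor), o.start, o.strand == "-")
    )
    return ranked[:k]


def filter_precursors(
    orfs: Sequence[Orf],
    max_len: int = 100,
    cterm_window: int = 20,
) -> List[PrecursorCandidate]:
    """Apply the precursor filter and wrap survivors as candidates.

    An ORF survives when its translation is strictly shorter than
    ``max_len`` residues AND the last ``cterm_window`` residues contain at
    least one Cys and at least one Ser or Thr — the residues indispensable
    for thioether crosslink formation.
    """
    out: List[PrecursorCandidate] = []
    for orf in orfs:
        aa = orf.aa_sequence
        if len(aa) >= max_len:
            logger.debug("reject %s: length %d >= %d", orf, len(aa), max_len)
            continue
        tail = aa[-cterm_window:]
        if "C" not in tail or not (set(tail) & {"S", "T"}):
            logger.debug("reject %s: C-terminal window lacks Cys or Ser/Thr", orf)
            continue
        out.append(
            PrecursorCandidate(
                orf=orf,
                distance_to_lanM=orf.distance_to_anchor,
                passes_filters=True,
                motif_hits=tuple(scan_leader_motif(aa)),
            )
        )
    return out


def scan_leader_motif(aa_seq: str) -> List[Tuple[int, str]]:
    """All (possibly overlapping) hits of the leader motif Kx(Y/F)(D/E)xx(F/Y).

    Returns 0-based positions with the matched 7-mer.
    """
    hits: List[Tuple[int, str]] = []
    for i in range(len(aa_seq) - LEADER_MOTIF_LENGTH + 1):
        w = aa_seq[i : i + LEADER_MOTIF_LENGTH]
        if w[0] == "K" and w[2] in "YF" and w[3] in "DE" and w[6] in "FY":
            hits.append((i, w))
    return hits


def enumerate_core_splits(
    candidate: PrecursorCandidate,
    min_core: int,
    max_core: int,
) -> List[Tuple[int, str, str, bool]]:
    """Candidate leader/core splits of a precursor.

    Every suffix with length in [min_core, max_core] that contains at least
    one Cys and one Ser/Thr is a candidate core.  Each split is returned as
    ``(split_index, leader, core, motif_consistent)`` where motif_consistent
    is True when some leader-motif hit lies wholly inside the leader (it is
    False whenever the precursor has no motif hit at all).
    """
    if min_core > max_core:
        raise ValueError("min_core must be <= max_core")
    aa = candidate.aa_sequence
    n = len(aa)
    splits: List[Tuple[int, str, str, bool]] = []
    for core_len in range(min_core, min(max_core, n - 1) + 1):
        split = n - core_len
        if split < 1:
            continue
        core = aa[split:]
        if "C" not in core or not (set(core) & {"S", "T"}):
            continue
        motif_ok = any(
            pos + LEADER_MOTIF_LENGTH <= split for pos, _ in candidate.motif_hits
        )
        splits.append((split, aa[:split], core, motif_ok))
    return splits
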