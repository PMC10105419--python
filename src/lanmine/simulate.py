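"""Seeded synthetic data: genomes with planted precursors, MS1/MS2 spectra.

Every pipeline stage can be exercised without downloads.  Genomes carry a
dummy lanM locus with planted precursor genes at controlled distances plus
decoy ORFs, each decoy violating exactly one precursor-filter clause.
Spectra are generated from ground-truth modified species with Gaussian ppm
jitter and uniform noise peaks.  All randomness flows through
``numpy.random.default_rng`` with explicit integer seeds; identical specs
and seeds give identical outputs.

The two in-paper fixtures, archalan α and β from *Halorussus salinus*
YJ-37-H, are available through :func:`load_fixture`; their leader sequences
are synthetic stand-ins carrying the conserved Kx(Y/F)(D/E)xx(F/Y) motif
(only the cores, modifications, rings and observed m/z are literature
values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ModificationSet
from .mining import Feature, GenomeRecord
from .ms1 import PeptideSpecies
from .rings import FragmentIon, RingTopology, theoretical_fragments
from .spectra import Peak, Spectrum

__all__ = [
    "GenomeSimSpec",
    "SpectrumSimSpec",
    "Fixture",
    "DEFAULT_LEADER",
    "generate_genome",
    "generate_ms1",
    "generate_ms2",
    "generate_ms2_from_fragments",
    "random_core",
    "load_fixture",
    "FIXTURE_NAMES",
]

#: Synthetic leader carrying the conserved archaeal motif (KVYDAAF).
DEFAULT_LEADER = "MTDEQLKVYDAAFEN"

# One fixed sense codon per amino acid (deterministic reverse translation;
# no internal stops by construction).
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "E": "GAA", "Q": "CAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "TCT", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTT",
}

# Self-reverse-complement cassette containing stop codons in all six frames;
# spliced into intergenic background so random DNA cannot spawn long ORFs.
_STOP_CASSETTE = "TTAATTAATTAA"
_CASSETTE_PERIOD = 30

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DECOY_CLAUSES = ("too_long", "no_cys", "no_st", "too_far")


@dataclass(frozen=True)
class GenomeSimSpec:
    """Recipe for one synthetic contig with a lanM locus.

    ``cores=None`` generates ``n_true`` random cores (12 aa, >=1 Cys and
    >=2 Ser/Thr in the C-terminal window); each decoy clause plants one ORF
    violating exactly that clause of the precursor filter.
    """

    seed: int = 0
    contig: str = "synth_contig_1"
    n_true: int = 1
    cores: Optional[Tuple[str, ...]] = None
    decoy_clauses: Tuple[str, ...] = ()
    leader: str = DEFAULT_LEADER
    gc: float = 0.45
    window_bp: int = 6000
    start_distance: int = 150
    spacing: int = 350
    pad_bp: int = 400
    minus_strand_fraction: float = 0.0

    def __post_init__(self) -> None:
        for clause in self.decoy_clauses:
            if clause not in DECOY_CLAUSES:
                raise ValueError(
                    f"unknown decoy clause {clause!r}; choose from {DECOY_CLAUSES}"
                )
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Recipe for simulated spectra from ground-truth species.

    With ``jitter_ppm_sd=0`` and no noise the generated peaks equal the
    theoretical values exactly.  ``noise_fraction`` scales the noise-peak
    count by the signal-peak count unless ``n_noise`` overrides it.
    """

    seed: int = 0
    jitter_ppm_sd: float = 5.0
    noise_fraction: float = 0.2
    n_noise: Optional[int] = None
    noise_mz_range: Optional[Tuple[float, float]] = None
    fragment_fraction: float = 1.0
    charges: Tuple[int, ...] = (1, 2)
    intensity_model: str = "rank-decay"  # or "uniform"
    annotate_charge: bool = True

    def __post_init__(self) -> None:
        if self.jitter_ppm_sd < 0:
            raise ValueError("jitter_ppm_sd must be >= 0")
        if not (0.0 <= self.fragment_fraction <= 1.0):
            raise ValueError("fragment_fraction must be in [0, 1]")
        if self.intensity_model not in ("rank-decay", "uniform"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")

    def noise_count(self, n_signal: int) -> int:
        if self.n_noise is not None:
            return self.n_noise
        return int(round(self.noise_fraction * n_signal))


def random_core(
    rng: np.random.Generator,
    length: int = 12,
    n_cys: int = 1,
    n_st: int = 2,
) -> str:
    """A random core with Cys and Ser/Thr planted in the C-terminal half."""
    if n_cys + n_st > length:
        raise ValueError("core too short for requested Cys and Ser/Thr counts")
    background = "GAVLFPWYEHQN"
    core = [background[rng.integers(len(background))] for _ in range(length)]
    tail_lo = max(0, length - 10)
    slots = list(rng.permutation(np.arange(tail_lo, length)))
    for _ in range(n_cys):
        core[slots.pop()] = "C"
    for _ in range(n_st):
        core[slots.pop()] = "S" if rng.random() < 0.6 else "T"
    return "".join(core)


def _background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    seq = list("".join(bases))
    pos = _CASSETTE_PERIOD
    while pos + len(_STOP_CASSETTE) <= length:
        seq[pos : pos + len(_STOP_CASSETTE)] = _STOP_CASSETTE
        pos += _CASSETTE_PERIOD + len(_STOP_CASSETTE)
    return "".join(seq)


def _encode_gene(peptide: str) -> str:
    """Coding sequence for a peptide: fixed codons plus one stop."""
    return "".join(_CODON[aa] for aa in peptide) + "TAA"


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _decoy_peptide(
    clause: str, rng: np.random.Generator, leader: str
) -> str:
    if clause == "too_long":
        filler = "".join(
            "GAVLFPE"[rng.integers(7)] for _ in range(100 - len(leader) - 12)
        )
        pep = leader + filler + random_core(rng, 12)
        assert len(pep) == 100
        return pep
    if clause == "no_cys":
        return leader + "".join(
            "GAVLFPE"[rng.integers(7)] for _ in range(15)
        ) + "GGSSTGGAGG"
    if clause == "no_st":
        return leader + "".join(
            "GAVLFPE"[rng.integers(7)] for _ in range(15)
        ) + "GGCGGAGGCG"
    if clause == "too_far":
        return leader + random_core(rng, 12)
    raise ValueError(f"unknown decoy clause {clause!r}")


def generate_genome(spec: GenomeSimSpec) -> Tuple[GenomeRecord, pd.DataFrame]:
    """Build a synthetic contig and its ground-truth table.

    Layout: pad | lanM locus | planted genes downstream at increasing edge
    distances (``start_distance``, then +gene+``spacing`` each), with a
    ``too_far`` decoy (if requested) placed beyond the mining window.  The
    truth table lists every planted ORF with coordinates, class and encoded
    peptide; planted genes have valid start/stop codons and no in-frame
    internal stops by construction.
    """
    rng = np.random.default_rng(spec.seed)

    cores = spec.cores
    if cores is None:
        cores = tuple(random_core(rng, 12) for _ in range(spec.n_true))
    elif len(cores) != spec.n_true:
        raise ValueError("len(cores) must equal n_true")
    peptides = [(f"true_{i + 1}", "true", "", spec.leader + c) for i, c in enumerate(cores)]
    for j, clause in enumerate(spec.decoy_clauses):
        peptides.append(
            (f"decoy_{clause}_{j + 1}", "decoy", clause,
             _decoy_peptide(clause, rng, spec.leader))
        )

    # near genes first (true + near decoys), far decoys after the window
    near = [p for p in peptides if p[2] != "too_far"]
    far = [p for p in peptides if p[2] == "too_far"]

    lanm_pep = "M" + "".join(
        "GAVLIFPEDKRHQN"[rng.integers(14)] for _ in range(299)
    )
    lanm_gene = _encode_gene(lanm_pep)

    parts: List[str] = [_background(rng, spec.pad_bp, spec.gc)]
    lanm_start = spec.pad_bp
    parts.append(lanm_gene)
    lanm_end = lanm_start + len(lanm_gene)

    rows = []
    cursor = lanm_end
    next_distance = spec.start_distance

    def _place(pep_entry, distance: int) -> None:
        nonlocal cursor
        name, cls, clause, pep = pep_entry
        gene = _encode_gene(pep)
        strand = "+" if rng.random() >= spec.minus_strand_fraction else "-"
        if strand == "-":
            gene = _revcomp(gene)
        gap = lanm_end + distance - cursor
        if gap < len(_STOP_CASSETTE):
            raise ValueError(
                f"contig too short for requested layout: gene {name} at "
                f"distance {distance} leaves no room for the stop cassette"
            )
        # flank each gene with the all-frame stop cassette so background
        # starts can never extend a planted ORF beyond its true coordinates
        parts.append(_background(rng, gap - len(_STOP_CASSETTE), spec.gc))
        parts.append(_STOP_CASSETTE)
        start = cursor + gap
        parts.append(gene)
        gene_end = start + len(gene)
        parts.append(_STOP_CASSETTE)
        cursor = gene_end + len(_STOP_CASSETTE)
        rows.append(
            {
                "name": name,
                "class": cls,
                "clause": clause,
                "contig": spec.contig,
                "start": start,
                "end": gene_end,
                "strand": strand,
                "distance": distance,
                "peptide": pep,
            }
        )

    for entry in near:
        _place(entry, next_distance)
        next_distance = rows[-1]["end"] - lanm_end + spec.spacing
    far_distance = spec.window_bp + 500
    for entry in far:
        _place(entry, max(far_distance, next_distance))
        next_distance = rows[-1]["end"] - lanm_end + spec.spacing

    parts.append(_background(rng, spec.pad_bp, spec.gc))
    sequence = "".join(parts)

    features = [
        Feature(
            feature_id="lanM_1",
            contig=spec.contig,
            start=lanm_start,
            end=lanm_end,
            strand="+",
            type="lanM",
            attributes={"ID": "lanM_1"},
        )
    ]
    for row in rows:
        features.append(
            Feature(
                feature_id=row["name"],
                contig=spec.contig,
                start=row["start"],
                end=row["end"],
                strand=row["strand"],
                type="CDS",
                attributes={"ID": row["name"], "class": row["class"]},
            )
        )
    genome = GenomeRecord(
        contig=spec.contig, sequence=sequence, annotations=tuple(features)
    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "name", "class", "clause", "contig", "start", "end", "strand",
            "distance", "peptide",
        ],
    )
    return genome, truth


def _intensities(
    rng: np.random.Generator, n: int, model: str
) -> np.ndarray:
    if model == "uniform":
        return rng.uniform(0.5, 1.0, size=n)
    ranks = np.arange(1, n + 1)
    return 1.0 / ranks + rng.uniform(0, 0.05, size=n)


def generate_ms1(
    species: Sequence[PeptideSpecies],
    spec: SpectrumSimSpec,
    charges: Optional[Sequence[int]] = None,
) -> List[Peak]:
    """One jittered peak per species per charge state, plus noise peaks."""
    rng = np.random.default_rng(spec.seed)
    charges = tuple(charges) if charges is not None else spec.charges
    peaks: List[Peak] = []
    signal_mzs: List[float] = []
    for sp in species:
        for z in charges:
            theo = sp.mz(z)
            eps = rng.normal(0.0, spec.jitter_ppm_sd) if spec.jitter_ppm_sd else 0.0
            mz = theo * (1.0 + eps * 1e-6)
            signal_mzs.append(mz)
            peaks.append(
                Peak(
                    mz,
                    float(rng.uniform(0.5, 1.0)),
                    z if spec.annotate_charge else None,
                )
            )
    n_noise = spec.noise_count(len(peaks))
    if n_noise:
        lo, hi = spec.noise_mz_range or (
            min(signal_mzs, default=200.0) - 100.0,
            max(signal_mzs, default=1500.0) + 100.0,
        )
        lo = max(lo, 50.0)
        for _ in range(n_noise):
            peaks.append(
                Peak(float(rng.uniform(lo, hi)), float(rng.uniform(0.01, 0.3)), None)
            )
    return peaks


def generate_ms2_from_fragments(
    fragments: Sequence[FragmentIon],
    spec: SpectrumSimSpec,
    precursor_mz: Optional[float] = None,
    precursor_charge: Optional[int] = None,
    title: str = "",
) -> Spectrum:
    """Sample, jitter and contaminate a theoretical fragment list."""
    rng = np.random.default_rng(spec.seed)
    frags = list(fragments)
    if spec.fragment_fraction < 1.0:
        keep = rng.random(len(frags)) < spec.fragment_fraction
        frags = [f for f, k in zip(frags, keep) if k]
    intens = _intensities(rng, len(frags), spec.intensity_model)
    peaks = []
    for f, inten in zip(frags, intens):
        eps = rng.normal(0.0, spec.jitter_ppm_sd) if spec.jitter_ppm_sd else 0.0
        peaks.append(Peak(f.mz * (1.0 + eps * 1e-6), float(inten)))
    n_noise = spec.noise_count(len(peaks))
    if n_noise:
        if spec.noise_mz_range is not None:
            lo, hi = spec.noise_mz_range
        elif peaks:
            mzs = [p.mz for p in peaks]
            lo, hi = min(mzs), max(mzs)
        else:
            lo, hi = 100.0, 1500.0
        for _ in range(n_noise):
            peaks.append(
                Peak(float(rng.uniform(lo, hi)), float(rng.uniform(0.01, 0.2)))
            )
    return Spectrum(
        peaks=tuple(peaks),
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        title=title,
    )


def generate_ms2(
    species: PeptideSpecies,
    rings: Optional[RingTopology],
    spec: SpectrumSimSpec,
    mode: str = "cs-rupture",
    title: str = "",
) -> Spectrum:
    """Simulated MS/MS spectrum of a (ring-bearing) species."""
    frags = theoretical_fragments(species, rings, spec.charges, mode)
    z = 2
    return generate_ms2_from_fragments(
        frags,
        spec,
        precursor_mz=species.mz(z),
        precursor_charge=z,
        title=title or species.label(),
    )


@dataclass(frozen=True)
class Fixture:
    """A worked in-paper example: core, modifications, rings, observed ion.

    ``leader`` is a synthetic stand-in (literature prints only the core in
    the main text); the remaining fields are literature values.
    """

    name: str
    leader: str
    core: str
    mods: ModificationSet
    rings: RingTopology
    observed_mz: float
    observed_charge: int
    printed_formula: str
    synthetic_leader: bool = True

    @property
    def precursor(self) -> str:
        return self.leader + self.core

    def species(self) -> PeptideSpecies:
        return PeptideSpecies(core=self.core, mods=self.mods)


def _fixtures() -> Dict[str, Fixture]:
    alpha_core = "GCGFTCSPFSSW"
    beta_core = "GLPSASMYSFEHCC"
    return {
        "archalan_alpha": Fixture(
            name="archalan_alpha",
            leader=DEFAULT_LEADER,
            core=alpha_core,
            mods=ModificationSet(n_dehydration=2),
            # MeLan Thr5-Cys2, Lan Ser10-Cys6 ("bicycle", disjoint)
            rings=RingTopology(((5, 2), (10, 6)), alpha_core),
            observed_mz=621.7382,
            observed_charge=2,
            printed_formula="C57H71N13O15S2",
        ),
        "archalan_beta": Fixture(
            name="archalan_beta",
            leader=DEFAULT_LEADER,
            core=beta_core,
            mods=ModificationSet(n_dehydration=2, n_methylation=1),
            # Ser4-Cys13 and Ser6-Cys14 (intertwined, interlocking)
            rings=RingTopology(((4, 13), (6, 14)), beta_core),
            observed_mz=755.3012,
            observed_charge=2,
            printed_formula="C66H92N16O19S3",
        ),
    }


FIXTURE_NAMES = tuple(sorted(_fixtures()))


def load_fixture(name: str) -> Fixture:
    """Load an in-paper fixture by name; unknown names list the options."""
    fixtures = _fixtures()
    try:
        return fixtures[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(fixtures))}"
        ) from None
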