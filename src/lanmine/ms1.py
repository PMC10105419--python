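"""MS1 linking: enumerate modified peptide species and match observed peaks.

Candidate core peptides from genome mining are expanded into a lattice of
anticipated modified species (dehydrations, optional methylation, optional
dehydrogenation), their theoretical [M + zH]^z+ m/z values are computed, and
observed high-resolution MS1 peaks are matched within a ppm tolerance.
Matches rank by parsimony: fewest total modifications, then smallest
|ppm error|, then lower charge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from . import chem
from .chem import ModificationSet, MolecularFormula
from .mining import PrecursorCandidate
from .spectra import Peak

__all__ = [
    "ModificationSpace",
    "PeptideSpecies",
    "Peak",
    "Ms1Match",
    "enumerate_species",
    "match_ms1",
    "rank_matches",
    "link_bgc_to_peaks",
]


@dataclass(frozen=True)
class ModificationSpace:
    """Bounds of the anticipated-modification lattice for one core.

    ``max_dehydrations="auto"`` bounds dehydrations by the number of Ser+Thr
    in the core (each dehydration consumes one hydroxyl residue).
    """

    max_dehydrations: Union[int, str] = "auto"
    allow_methylation: bool = False
    max_methylations: int = 1
    allow_dehydrogenation: bool = False
    max_dehydrogenations: int = 1
    charge_states: Tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if isinstance(self.max_dehydrations, str):
            if self.max_dehydrations != "auto":
                raise ValueError("max_dehydrations must be an int or 'auto'")
        elif self.max_dehydrations < 0:
            raise ValueError("max_dehydrations must be >= 0")
        if self.max_methylations < 0 or self.max_dehydrogenations < 0:
            raise ValueError("modification limits must be >= 0")
        if any(z < 1 for z in self.charge_states):
            raise ValueError("charge states must be >= 1")

    def dehydration_bound(self, core: str) -> int:
        if self.max_dehydrations == "auto":
            return sum(core.count(r) for r in "ST")
        return int(self.max_dehydrations)


@dataclass(frozen=True)
class PeptideSpecies:
    """A core peptide carrying a concrete modification set.

    ``provenance`` lists every modification count-vector that produced this
    net formula (isobaric sets collapse to one species after deduplication).
    """

    core: str
    mods: ModificationSet
    formula: MolecularFormula = field(init=False)
    neutral_mass: float = field(init=False)
    provenance: Tuple[Tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        f = chem.apply_modifications(chem.peptide_formula(self.core), self.mods)
        object.__setattr__(self, "formula", f)
        object.__setattr__(self, "neutral_mass", f.mass)

    def mz(self, z: int) -> float:
        return chem.mz_from_neutral(self.neutral_mass, z)

    def label(self) -> str:
        return f"{self.core} [{self.mods.describe()}]"


@dataclass(frozen=True)
class Ms1Match:
    peak: Peak
    species: PeptideSpecies
    charge: int
    theoretical_mz: float
    ppm: float

    @property
    def score(self) -> Tuple[int, float, int]:
        """Lexicographic rank key: (total mods, |ppm|, charge); lower wins."""
        return (self.species.mods.total, abs(self.ppm), self.charge)


def enumerate_species(
    core: str, space: ModificationSpace
) -> List[PeptideSpecies]:
    """All modified species of ``core`` inside the modification space.

    The raw lattice is the Cartesian product of allowed counts; species with
    identical net formulas are merged, with every generating count-vector
    (n_dehydration, n_methylation, n_dehydrogenation) kept as provenance.
    The representative modification set of a merged species is the one with
    the fewest total modifications (first in lattice order on ties).
    """
    if not core:
        raise ValueError("core sequence must be non-empty")
    d_max = space.dehydration_bound(core)
    m_max = space.max_methylations if space.allow_methylation else 0
    g_max = space.max_dehydrogenations if space.allow_dehydrogenation else 0

    by_formula: Dict[MolecularFormula, List[Tuple[int, int, int]]] = {}
    order: List[MolecularFormula] = []
    base = chem.peptide_formula(core)
    for nd, nm, ng in itertools.product(
        range(d_max + 1), range(m_max + 1), range(g_max + 1)
    ):
        mods = ModificationSet(nd, nm, ng)
        try:
            f = chem.apply_modifications(base, mods)
        except chem.FormulaError:
            continue  # infeasible on this core (counts went negative)
        if f not in by_formula:
            by_formula[f] = []
            order.append(f)
        by_formula[f].append((nd, nm, ng))
    species = []
    for f in order:
        vecs = by_formula[f]
        nd, nm, ng = min(vecs, key=lambda v: (sum(v), vecs.index(v)))
        species.append(
            PeptideSpecies(
                core=core,
                mods=ModificationSet(nd, nm, ng),
                provenance=tuple(vecs),
            )
        )
    return species


def match_ms1(
    peaks: Sequence[Peak],
    species: Sequence[PeptideSpecies],
    charges: Iterable[int] = (1, 2, 3),
    tol_ppm: float = 10.0,
) -> List[Ms1Match]:
    """All (peak, species, charge) matches within the ppm tolerance.

    A peak carrying its own charge annotation is only tried at that charge;
    otherwise every charge state in ``charges`` is tried.  The search is
    complete: every candidate within tolerance is emitted.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    charges = tuple(charges)
    out: List[Ms1Match] = []
    for peak in peaks:
        zs = (peak.charge,) if peak.charge else charges
        for sp in species:
            for z in zs:
                theo = sp.mz(z)
                ppm = chem.ppm_error(peak.mz, theo)
                if abs(ppm) <= tol_ppm:
                    out.append(Ms1Match(peak, sp, z, theo, ppm))
    return out


def rank_matches(matches: Sequence[Ms1Match]) -> List[Ms1Match]:
    """Stable sort by (total modifications, |ppm|, charge) ascending."""
    return sorted(matches, key=lambda m: m.score)


def link_bgc_to_peaks(
    candidates: Sequence[PrecursorCandidate],
    peaks: Sequence[Peak],
    space: ModificationSpace,
    tol_ppm: float = 10.0,
    min_core: int = 5,
    max_core: int = 30,
) -> List[dict]:
    """Link precursor candidates to observed MS1 peaks.

    For every candidate and every admissible leader/core split, species are
    enumerated and matched; the best-ranked match per split is reported with
    full provenance.  The report is a list of plain dicts (JSON-ready),
    deterministic given the inputs.
    """
    from .mining import enumerate_core_splits

    report: List[dict] = []
    for cand in candidates:
        entry = {
            "orf": {
                "contig": cand.orf.contig,
                "start": cand.orf.start,
                "end": cand.orf.end,
                "strand": cand.orf.strand,
                "length_aa": cand.orf.length_aa,
                "distance_to_lanM": cand.distance_to_lanM,
            },
            "precursor": cand.aa_sequence,
            "motif_hits": [list(h) for h in cand.motif_hits],
            "links": [],
        }
        for split, leader, core, motif_ok in enumerate_core_splits(
            cand, min_core, max_core
        ):
            species = enumerate_species(core, space)
            matches = rank_matches(
                match_ms1(peaks, species, space.charge_states, tol_ppm)
            )
            if not matches:
                continue
            best = matches[0]
            entry["links"].append(
                {
                    "split_index": split,
                    "leader": leader,
                    "core": core,
                    "motif_consistent": motif_ok,
                    "peak_mz": best.peak.mz,
                    "charge": best.charge,
                    "theoretical_mz": round(best.theoretical_mz, 6),
                    "ppm": round(best.ppm, 4),
                    "modifications": {
                        "n_dehydration": best.species.mods.n_dehydration,
                        "n_methylation": best.species.mods.n_methylation,
                        "n_dehydrogenation": best.species.mods.n_dehydrogenation,
                    },
                    "formula": str(best.species.formula),
                    "n_candidate_matches": len(matches),
                }
            )
        report.append(entry)
    return report
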