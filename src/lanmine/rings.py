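"""Thioether ring topology: ring-aware fragmentation, annotation, inference.

Class II lanthipeptides carry lanthionine (Lan, Ser-derived) and
methyllanthionine (MeLan, Thr-derived) thioether crosslinks between a
dehydrated Ser/Thr donor and a Cys acceptor.  Ring topology is not readable
from the gene; it is inferred from two experimental signatures this module
models:

* **Ring-aware b/y fragmentation.**  Backbone cleavage inside a ring is
  only observed via rupture of the Cgamma-S bond: the Cys-derived residue
  appears as dehydroalanine (nominal -34 Da relative to Cys) and the
  Ser/Thr-derived residue retains the sulfur in place of its side-chain
  oxygen (nominal +16 Da relative to Ser/Thr).

* **Reductive desulfurization** (Ni boride with NaBH4 or NaBD4), which
  excises the thioether sulfur: Ser-derived halves become Ala, Thr-derived
  halves become Abu, Cys-derived halves become Ala; with NaBD4 each opened
  link deposits one deuterium, localising which ring was opened.  Partial
  desulfurization products fragmented by MS/MS discriminate between
  candidate topologies.

Residue positions are 1-based on the core in every report ("Cys2", "Ser10").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from . import chem
from .chem import (
    DERIVED_RESIDUE_FORMULAS,
    H2,
    METHYLENE,
    RESIDUE_FORMULAS,
    WATER,
    MolecularFormula,
    parse_formula,
)
from .ms1 import PeptideSpecies
from .spectra import Peak, Spectrum

__all__ = [
    "RingTopology",
    "FragmentIon",
    "AnnotationResult",
    "TopologyScore",
    "DesulfurizationProduct",
    "ProductVariant",
    "TopologyError",
    "classify_topology",
    "theoretical_fragments",
    "annotate_spectrum",
    "score_topologies",
    "enumerate_candidate_topologies",
    "desulfurize",
    "infer_topology_from_desulfurization",
]

_SULFUR = parse_formula("S")
_OXYGEN = parse_formula("O")
_H2S = parse_formula("H2S")
_H = parse_formula("H")
_D = parse_formula("D")


class TopologyError(ValueError):
    """Invalid ring topology for the given core peptide."""


@dataclass(frozen=True)
class RingTopology:
    """A set of thioether crosslinks on a core peptide.

    Each crosslink is (donor, acceptor): the 1-based positions of the
    dehydrated Ser/Thr donor and the Cys acceptor.  When ``core`` is given
    the links are validated against it and typed Lan (Ser donor) or MeLan
    (Thr donor).
    """

    crosslinks: Tuple[Tuple[int, int], ...]
    core: Optional[str] = None

    def __post_init__(self) -> None:
        links = tuple(
            (int(d), int(a)) for d, a in self.crosslinks
        )
        object.__setattr__(self, "crosslinks", links)
        used: List[int] = []
        for d, a in links:
            used.extend((d, a))
        if len(used) != len(set(used)):
            raise TopologyError(f"duplicate residue use in links {links}")
        if self.core is not None:
            n = len(self.core)
            for d, a in links:
                if not (1 <= d <= n and 1 <= a <= n):
                    raise TopologyError(f"link ({d},{a}) outside core of length {n}")
                if self.core[d - 1] not in "ST":
                    raise TopologyError(
                        f"donor position {d} is {self.core[d - 1]!r}, not Ser/Thr"
                    )
                if self.core[a - 1] != "C":
                    raise TopologyError(
                        f"acceptor position {a} is {self.core[a - 1]!r}, not Cys"
                    )

    @property
    def n_links(self) -> int:
        return len(self.crosslinks)

    def link_types(self) -> Tuple[str, ...]:
        """Lan for Ser donors, MeLan for Thr donors (requires ``core``)."""
        if self.core is None:
            raise TopologyError("link typing requires the core sequence")
        return tuple(
            "MeLan" if self.core[d - 1] == "T" else "Lan"
            for d, _ in self.crosslinks
        )

    def intervals(self) -> Tuple[Tuple[int, int], ...]:
        return tuple((min(d, a), max(d, a)) for d, a in self.crosslinks)

    def serialize(self) -> str:
        return ";".join(f"{d}-{a}" for d, a in self.crosslinks)


def classify_topology(rings: RingTopology) -> str:
    """Classify a ring set: ``disjoint``, ``nested`` or ``interlocking``.

    Interval algebra on (min, max) of each link: disjoint when no two
    intervals overlap; nested when some interval strictly contains another;
    interlocking ("intertwined") when two intervals overlap without
    containment.  Interlocking dominates nested in the summary label.
    """
    ivals = rings.intervals()
    label = "disjoint"
    for (a1, b1), (a2, b2) in itertools.combinations(ivals, 2):
        if b1 < a2 or b2 < a1:
            continue  # no overlap
        if (a1 < a2 and b2 < b1) or (a2 < a1 and b1 < b2):
            if label == "disjoint":
                label = "nested"
        else:
            return "interlocking"
    return label


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical b or y ion, possibly carrying ring-rupture shifts."""

    series: str  # "b" or "y"
    index: int  # number of residues in the fragment
    charge: int
    neutral_mass: float
    mz: float
    ring_states: Tuple[str, ...] = ()  # e.g. "Cys2->Dha(-34)", "Thr5(+16)"

    def label(self) -> str:
        sup = "+" * self.charge
        return f"{self.series}{self.index}{sup}"


# ---------------------------------------------------------------------------
# internal residue-state fragmentation engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _StateModel:
    """Per-position residue formulas + active rings + N-terminal delta.

    ``states[i]`` is the internal residue formula at 1-based position i+1
    (already reflecting free Dha/Dhb or desulfurized conversions).  Active
    rings contribute -H2O when wholly contained in a fragment and the
    Cgamma-S rupture states when a cleavage falls inside them.
    """

    core: str
    states: Tuple[MolecularFormula, ...]
    state_labels: Tuple[str, ...]
    rings: Tuple[Tuple[int, int], ...]  # (donor, acceptor), 1-based
    nterm_delta: MolecularFormula = MolecularFormula()
    disulfides: Tuple[Tuple[int, int], ...] = ()

    def neutral_mass(self) -> float:
        total = sum(s.mass for s in self.states) + WATER.mass
        total += self.nterm_delta.mass
        total -= len(self.rings) * WATER.mass
        total -= len(self.disulfides) * H2.mass
        return total


def _donor_rupture(f: MolecularFormula) -> MolecularFormula:
    return f - _OXYGEN + _SULFUR


def _acceptor_rupture(f: MolecularFormula) -> MolecularFormula:
    return f - _H2S


def _build_state_model(species: PeptideSpecies, rings: RingTopology) -> _StateModel:
    """Localise a species' modifications onto residues given its rings.

    Each ring consumes one dehydration.  Dehydrations beyond the ring count
    are placed on the N-terminal-most free Ser/Thr as Dha/Dhb.  Methylations
    sit on the N-terminus (+CH2 each).  Dehydrogenations are modelled as
    disulfides pairing free Cys residues in sequence order.
    """
    core = species.core
    mods = species.mods
    n_rings = rings.n_links
    if mods.n_dehydration < n_rings:
        raise TopologyError(
            f"{n_rings} rings require >= {n_rings} dehydrations, species has "
            f"{mods.n_dehydration}"
        )
    RingTopology(rings.crosslinks, core)  # validate against this core

    ring_positions = {p for link in rings.crosslinks for p in link}
    states = [RESIDUE_FORMULAS[aa] for aa in core]
    labels = list(core)

    extra_dehydrations = mods.n_dehydration - n_rings
    free_st = [
        i for i, aa in enumerate(core) if aa in "ST" and (i + 1) not in ring_positions
    ]
    if extra_dehydrations > len(free_st):
        raise TopologyError(
            f"{extra_dehydrations} free dehydrations but only {len(free_st)} "
            "free Ser/Thr residues"
        )
    for i in free_st[:extra_dehydrations]:
        states[i] = states[i] - WATER
        labels[i] = "Dhb" if core[i] == "T" else "Dha"

    free_cys = [
        i + 1 for i, aa in enumerate(core) if aa == "C" and (i + 1) not in ring_positions
    ]
    if 2 * mods.n_dehydrogenation > len(free_cys):
        raise TopologyError(
            f"{mods.n_dehydrogenation} dehydrogenations (disulfides) need "
            f"{2 * mods.n_dehydrogenation} free Cys, found {len(free_cys)}"
        )
    disulfides = tuple(
        (free_cys[2 * j], free_cys[2 * j + 1])
        for j in range(mods.n_dehydrogenation)
    )

    nterm = MolecularFormula()
    for _ in range(mods.n_methylation):
        nterm = nterm + METHYLENE
    for _, delta, sign in mods.extra:
        nterm = nterm + delta if sign > 0 else nterm - delta

    return _StateModel(
        core=core,
        states=tuple(states),
        state_labels=tuple(labels),
        rings=rings.crosslinks,
        nterm_delta=nterm,
        disulfides=disulfides,
    )


def _fragments_from_model(
    model: _StateModel,
    charges: Sequence[int],
    mode: str = "cs-rupture",
) -> List[FragmentIon]:
    """Emit b/y ions at every backbone cleavage of a state model.

    ``mode="cs-rupture"`` emits intra-ring cleavages via the Cgamma-S
    rupture pathway; ``mode="suppress"`` skips cleavages inside any ring
    (classical lanthipeptide behaviour).  Cleavages inside a disulfide span
    are always suppressed.
    """
    if mode not in ("cs-rupture", "suppress"):
        raise ValueError(f"unknown fragmentation mode {mode!r}")
    n = len(model.states)
    out: List[FragmentIon] = []
    for i in range(1, n):  # cleave between residues i and i+1 (1-based)
        crossing = [
            (d, a) for d, a in model.rings if min(d, a) <= i < max(d, a)
        ]
        if crossing and mode == "suppress":
            continue
        if any(lo <= i < hi for lo, hi in model.disulfides):
            continue
        # per-position formulas with crossing rings ruptured
        states = list(model.states)
        notes: List[Tuple[int, str]] = []
        for d, a in crossing:
            states[a - 1] = _acceptor_rupture(states[a - 1])
            states[d - 1] = _donor_rupture(states[d - 1])
            notes.append((a, f"{_res3(model.core[a - 1])}{a}->Dha(-34)"))
            notes.append((d, f"{_res3(model.core[d - 1])}{d}(+16)"))
        notes.sort()
        b_notes = tuple(txt for pos, txt in notes if pos <= i)
        y_notes = tuple(txt for pos, txt in notes if pos > i)

        b_neutral = sum(s.mass for s in states[:i]) + model.nterm_delta.mass
        y_neutral = sum(s.mass for s in states[i:]) + WATER.mass
        # rings wholly inside one fragment stay intact: -H2O on that side
        for d, a in model.rings:
            if (d, a) in crossing:
                continue
            hi_end = max(d, a)
            if hi_end <= i:
                b_neutral -= WATER.mass
            else:
                y_neutral -= WATER.mass
        for lo, hi in model.disulfides:
            if hi <= i:
                b_neutral -= H2.mass
            else:
                y_neutral -= H2.mass

        for z in charges:
            out.append(
                FragmentIon(
                    "b", i, z, b_neutral,
                    (b_neutral + z * chem.PROTON_MASS) / z, b_notes,
                )
            )
            out.append(
                FragmentIon(
                    "y", n - i, z, y_neutral,
                    (y_neutral + z * chem.PROTON_MASS) / z, y_notes,
                )
            )
    return out


_RES3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


def _res3(aa: str) -> str:
    return _RES3.get(aa, aa)


def theoretical_fragments(
    species: PeptideSpecies,
    rings: Optional[RingTopology] = None,
    charges: Sequence[int] = (1, 2),
    mode: str = "cs-rupture",
) -> List[FragmentIon]:
    """Ring-aware theoretical b/y ions of a modified species.

    b/y pairs at any cleavage satisfy neutral(b_i) + neutral(y_{n-i}) =
    precursor neutral mass, per emitted cleavage pathway.  a-ions, neutral
    losses and internal fragments are not modelled.
    """
    if rings is None:
        rings = RingTopology((), species.core)
    model = _build_state_model(species, rings)
    return _fragments_from_model(model, charges, mode)


# ---------------------------------------------------------------------------
# spectrum annotation and topology scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationResult:
    """Greedy peak-to-fragment assignment plus bond coverage."""

    assignments: Tuple[Tuple[Peak, FragmentIon, float], ...]  # (peak, frag, ppm)
    coverage: float
    n_annotated: int
    annotated_intensity: float


def annotate_spectrum(
    spectrum: Spectrum,
    fragments: Sequence[FragmentIon],
    tol_ppm: float = 10.0,
    core_length: Optional[int] = None,
) -> AnnotationResult:
    """Assign each peak its nearest-ppm fragment within tolerance.

    One fragment per peak (a fragment may annotate several peaks); ties
    break deterministically by (series, index, charge).  Coverage is the
    fraction of the core's inter-residue bonds supported by at least one
    annotated b or y ion; ``core_length`` defaults to the largest fragment
    extent + 1.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if core_length is None:
        core_length = max((f.index for f in fragments), default=0) + 1
    assignments = []
    for peak in spectrum.peaks:
        best = None
        for frag in fragments:
            ppm = chem.ppm_error(peak.mz, frag.mz)
            if abs(ppm) > tol_ppm:
                continue
            key = (abs(ppm), frag.series, frag.index, frag.charge)
            if best is None or key < best[0]:
                best = (key, frag, ppm)
        if best is not None:
            assignments.append((peak, best[1], best[2]))
    bonds = set()
    for _, frag, _ in assignments:
        if frag.series == "b":
            bonds.add(frag.index)
        else:
            bonds.add(core_length - frag.index)
    n_bonds = max(core_length - 1, 1)
    coverage = len([b for b in bonds if 1 <= b <= core_length - 1]) / n_bonds
    return AnnotationResult(
        assignments=tuple(assignments),
        coverage=coverage,
        n_annotated=len(assignments),
        annotated_intensity=sum(p.intensity for p, _, _ in assignments),
    )


@dataclass(frozen=True)
class TopologyScore:
    topology: RingTopology
    n_discriminating: int
    annotated_intensity: float
    coverage: float
    n_annotated: int
    rank_index: int

    @property
    def key(self) -> Tuple:
        """Descending-sort key (higher is better; rank_index breaks ties)."""
        return (
            -self.n_discriminating,
            -self.annotated_intensity,
            -self.coverage,
            self.rank_index,
        )


def score_topologies(
    spectrum: Spectrum,
    species: PeptideSpecies,
    candidate_topologies: Sequence[RingTopology],
    tol_ppm: float = 10.0,
    charges: Sequence[int] = (1, 2),
    mode: str = "cs-rupture",
) -> Tuple[List[TopologyScore], bool]:
    """Rank candidate ring topologies against one MS/MS spectrum.

    Primary key: annotated *topology-discriminating* ions — annotated peaks
    whose assigned fragment m/z is not produced by every candidate.  Ties
    break by total annotated intensity, then bond coverage, then candidate
    serialization order.  Returns (ranked scores, indeterminate) where
    indeterminate is True when no candidate annotates a discriminating ion.
    """
    if not candidate_topologies:
        raise ValueError("candidate topology list must be non-empty")
    n = len(species.core)
    frag_lists = [
        theoretical_fragments(species, t, charges, mode)
        for t in candidate_topologies
    ]
    mz_sets = [frozenset(round(f.mz, 4) for f in fl) for fl in frag_lists]
    common = frozenset.intersection(*mz_sets)
    scores = []
    for idx, (topo, frags) in enumerate(zip(candidate_topologies, frag_lists)):
        ann = annotate_spectrum(spectrum, frags, tol_ppm, core_length=n)
        disc = sum(
            1
            for _, frag, _ in ann.assignments
            if round(frag.mz, 4) not in common
        )
        scores.append(
            TopologyScore(
                topology=topo,
                n_discriminating=disc,
                annotated_intensity=ann.annotated_intensity,
                coverage=ann.coverage,
                n_annotated=ann.n_annotated,
                rank_index=idx,
            )
        )
    scores.sort(key=lambda s: s.key)
    indeterminate = scores[0].n_discriminating == 0
    return scores, indeterminate


def enumerate_candidate_topologies(
    core: str, n_links: int
) -> List[RingTopology]:
    """All injective pairings of n Cys acceptors with n Ser/Thr donors.

    Count = C(#C, n) * C(#S+#T, n) * n!.  ``n_links=0`` yields the single
    empty topology; an infeasible n yields an empty list.
    """
    cys = [i + 1 for i, aa in enumerate(core) if aa == "C"]
    donors = [i + 1 for i, aa in enumerate(core) if aa in "ST"]
    if n_links == 0:
        return [RingTopology((), core)]
    if n_links > min(len(cys), len(donors)):
        return []
    out = []
    for accs in itertools.combinations(cys, n_links):
        for dons in itertools.permutations(donors, n_links):
            links = tuple(sorted(zip(dons, accs)))
            out.append(RingTopology(links, core))
    # permutations of donors against a fixed acceptor combination can repeat
    # the same link set in different order; dedup preserving order
    seen = set()
    uniq = []
    for t in out:
        if t.crosslinks not in seen:
            seen.add(t.crosslinks)
            uniq.append(t)
    return uniq


# ---------------------------------------------------------------------------
# reductive desulfurization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProductVariant:
    """One deuteration-placement isomer of a desulfurization product."""

    deuterated_positions: Tuple[int, ...]
    residue_labels: Tuple[str, ...]
    formula: MolecularFormula
    neutral_mass: float


@dataclass(frozen=True)
class DesulfurizationProduct:
    """A (possibly partial) reductive-desulfurization product.

    Opened links lose their sulfur (-S +2H with NaBH4; -S +H +D with NaBD4,
    the deuterium landing on either the donor- or acceptor-derived residue —
    both placements are enumerated as ``variants``).  Intact links are
    untouched.
    """

    parent: PeptideSpecies
    rings: RingTopology
    opened_links: Tuple[Tuple[int, int], ...]
    reagent: str
    variants: Tuple[ProductVariant, ...]

    @property
    def remaining_rings(self) -> RingTopology:
        left = tuple(
            l for l in self.rings.crosslinks if l not in self.opened_links
        )
        return RingTopology(left, self.parent.core)

    def fragments(
        self,
        variant: ProductVariant,
        charges: Sequence[int] = (1, 2),
        mode: str = "cs-rupture",
    ) -> List[FragmentIon]:
        """Ring-aware b/y ions of one product variant."""
        model = _product_state_model(self, variant)
        return _fragments_from_model(model, charges, mode)


def _product_state_model(
    product: DesulfurizationProduct, variant: ProductVariant
) -> _StateModel:
    parent_model = _build_state_model(product.parent, product.rings)
    states = list(parent_model.states)
    labels = list(parent_model.state_labels)
    core = product.parent.core
    for d, a in product.opened_links:
        states[d - 1] = (
            DERIVED_RESIDUE_FORMULAS["Abu"]
            if core[d - 1] == "T"
            else DERIVED_RESIDUE_FORMULAS["Ala"]
        )
        labels[d - 1] = "Abu" if core[d - 1] == "T" else "Ala"
        states[a - 1] = DERIVED_RESIDUE_FORMULAS["Ala"]
        labels[a - 1] = "Ala"
    for pos in variant.deuterated_positions:
        states[pos - 1] = states[pos - 1] - _H + _D
        labels[pos - 1] = labels[pos - 1] + "(d1)"
    remaining = tuple(
        l for l in product.rings.crosslinks if l not in product.opened_links
    )
    return _StateModel(
        core=core,
        states=tuple(states),
        state_labels=tuple(labels),
        rings=remaining,
        nterm_delta=parent_model.nterm_delta,
        disulfides=parent_model.disulfides,
    )


def desulfurize(
    species: PeptideSpecies,
    rings: RingTopology,
    open_links: Sequence[Tuple[int, int]],
    reagent: str = "H",
) -> DesulfurizationProduct:
    """Simulate reductive desulfurization opening a subset of rings.

    Per opened link the net formula change is -S +2H (reagent ``"H"``,
    NaBH4) or -S +H +D (reagent ``"D"``, NaBD4).  Donor Ser-derived
    residues become Ala, Thr-derived become Abu, Cys-derived become Ala.
    With reagent D both deuterium placements (donor- vs acceptor-derived
    residue) are enumerated per link; a k-link opening yields 2^k variants.
    Opening the empty set returns a product identical to the parent.
    """
    if reagent not in ("H", "D"):
        raise ValueError(f"reagent must be 'H' or 'D', got {reagent!r}")
    open_links = tuple(tuple(l) for l in open_links)
    for l in open_links:
        if l not in rings.crosslinks:
            raise TopologyError(f"link {l} is not part of the topology")
    RingTopology(rings.crosslinks, species.core)  # validate

    k = len(open_links)
    base_formula = species.formula
    for _ in open_links:
        base_formula = base_formula - _SULFUR + H2

    variants: List[ProductVariant] = []
    if reagent == "H" or k == 0:
        placements = [()]
    else:
        placements = list(itertools.product(*[("donor", "acceptor")] * k))
    for placement in placements:
        f = base_formula
        dpos: List[int] = []
        for link, where in zip(open_links, placement):
            f = f - _H + _D
            dpos.append(link[0] if where == "donor" else link[1])
        labels = _variant_labels(species.core, open_links, tuple(dpos))
        variants.append(
            ProductVariant(
                deuterated_positions=tuple(dpos),
                residue_labels=labels,
                formula=f,
                neutral_mass=f.mass,
            )
        )
    return DesulfurizationProduct(
        parent=species,
        rings=rings,
        opened_links=open_links,
        reagent=reagent,
        variants=tuple(variants),
    )


def _variant_labels(
    core: str,
    open_links: Tuple[Tuple[int, int], ...],
    dpos: Tuple[int, ...],
) -> Tuple[str, ...]:
    labels = list(core)
    for d, a in open_links:
        labels[d - 1] = "Abu" if core[d - 1] == "T" else "Ala"
        labels[a - 1] = "Ala"
    for p in dpos:
        labels[p - 1] += "(d1)"
    return tuple(labels)


# ---------------------------------------------------------------------------
# topology inference from partial desulfurization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InferenceResult:
    topology: Optional[RingTopology]
    label: str  # classification of the winner, or "indeterminate"
    total_discriminating: int
    per_spectrum_assignment: Tuple[dict, ...]
    ranked: Tuple[Tuple[str, int, float], ...]  # (serialized topo, disc, intensity)


def infer_topology_from_desulfurization(
    parent_spectrum: Optional[Spectrum],
    product_spectra: Sequence[Spectrum],
    species: PeptideSpecies,
    n_links: Optional[int] = None,
    reagent: str = "D",
    tol_ppm: float = 10.0,
    charges: Sequence[int] = (1, 2),
    mode: str = "cs-rupture",
) -> InferenceResult:
    """Infer ring topology from MS/MS of partial desulfurization products.

    Every candidate topology (all injective donor/acceptor pairings with
    ``n_links`` links, default = the species' dehydration count) is scored
    jointly: the parent spectrum against the intact candidate, and each
    product spectrum against the best single-link-opened simulated product
    (both deuteration placements tried).  Discriminating ions are annotated
    peaks whose fragment m/z is not shared by every candidate's best
    explanation of that spectrum.  Returns the maximizing topology, with
    per-spectrum opened-link assignments; when no candidate annotates any
    discriminating ion the result is labelled ``indeterminate``.
    """
    if not product_spectra:
        raise ValueError("at least one partial-product spectrum is required")
    if n_links is None:
        n_links = species.mods.n_dehydration
    candidates = enumerate_candidate_topologies(species.core, n_links)
    if not candidates:
        raise ValueError(
            f"no feasible {n_links}-link topology on core {species.core!r}"
        )
    n = len(species.core)

    # parent spectrum scored like score_topologies
    per_cand_disc = [0] * len(candidates)
    per_cand_intensity = [0.0] * len(candidates)
    per_cand_ann = [0] * len(candidates)
    if parent_spectrum is not None and len(parent_spectrum) > 0:
        scores, _ = score_topologies(
            parent_spectrum, species, candidates, tol_ppm, charges, mode
        )
        for s in scores:
            per_cand_disc[s.rank_index] += s.n_discriminating
            per_cand_intensity[s.rank_index] += s.annotated_intensity
            per_cand_ann[s.rank_index] += s.n_annotated

    assignments_per_spectrum: List[List[dict]] = []
    for spec_idx, spectrum in enumerate(product_spectra):
        # best (opened link, placement) per candidate
        best_per_cand: List[dict] = []
        for topo in candidates:
            best = None
            for link in topo.crosslinks:
                product = desulfurize(species, topo, [link], reagent)
                for variant in product.variants:
                    frags = product.fragments(variant, charges, mode)
                    ann = annotate_spectrum(spectrum, frags, tol_ppm, n)
                    key = (ann.n_annotated, ann.annotated_intensity)
                    if best is None or key > best["key"]:
                        best = {
                            "key": key,
                            "opened_link": link,
                            "deuterated_positions": variant.deuterated_positions,
                            "annotation": ann,
                            "mz_set": frozenset(round(f.mz, 4) for f in frags),
                        }
            best_per_cand.append(best)
        common = frozenset.intersection(*[b["mz_set"] for b in best_per_cand])
        for ci, b in enumerate(best_per_cand):
            ann = b["annotation"]
            disc = sum(
                1
                for _, frag, _ in ann.assignments
                if round(frag.mz, 4) not in common
            )
            b["disc"] = disc
            per_cand_disc[ci] += disc
            per_cand_intensity[ci] += ann.annotated_intensity
            per_cand_ann[ci] += ann.n_annotated
        assignments_per_spectrum.append(best_per_cand)

    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -per_cand_disc[i],
            -per_cand_intensity[i],
            -per_cand_ann[i],
            i,
        ),
    )
    winner = order[0]
    indeterminate = per_cand_disc[winner] == 0
    per_spectrum = tuple(
        {
            "spectrum_index": si,
            "opened_link": assignments_per_spectrum[si][winner]["opened_link"],
            "deuterated_positions": assignments_per_spectrum[si][winner][
                "deuterated_positions"
            ],
            "n_annotated": assignments_per_spectrum[si][winner][
                "annotation"
            ].n_annotated,
            "n_discriminating": assignments_per_spectrum[si][winner]["disc"],
        }
        for si in range(len(product_spectra))
    )
    topo = candidates[winner]
    return InferenceResult(
        topology=None if indeterminate else topo,
        label="indeterminate" if indeterminate else classify_topology(topo),
        total_discriminating=per_cand_disc[winner],
        per_spectrum_assignment=per_spectrum,
        ranked=tuple(
            (
                candidates[i].serialize(),
                per_cand_disc[i],
                round(per_cand_intensity[i], 3),
            )
            for i in order
        ),
    )
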