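# Methods

This note documents the models, conventions and design choices behind
`lanmine`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic-data tests do and do not show.

## Mass arithmetic

All masses are monoisotopic, computed from a fixed internal atomic-mass
table (C 12.000000, H 1.0078250319, N 14.0030740, O 15.9949146,
S 31.9720707 Da; deuterium is its own symbol D at 2.0141018 Da so that
NaBD₄ labelling stays element-wise). A peptide's neutral formula is the
sum of internal residue formulas plus one water for the free termini.
Charged species are protonated, m/z = (M + z·m_p)/z with the
electron-corrected proton mass m_p = 1.007276 Da. ppm error is signed,
10⁶·(obs − theo)/theo, with the absolute value used for tolerance checks.

Instruments and vendor software differ in their electron-mass and rounding
conventions; published theoretical m/z values are therefore only expected
to agree with ours to ~0.1 ppm, and the worked-example assertions use that
band. With these conventions the archalan α identity (GCGFTCSPFSSW − 2H₂O
= C57H71N13O15S2) computes to |Δ| = 1.25 ppm against the observed
621.7382 (printed as 1.29 ppm), and the β identity (GLPSASMYSFEHCC
− 2H₂O + CH₂ = C66H92N16O19S3) to 0.55 ppm against 755.3012 (printed
0.53 ppm). The β "net modification loss" is defined observationally — the
unmodified core mass minus the neutral mass back-calculated from the
observed m/z — giving 22.0063 Da; the purely theoretical −2H₂O+CH₂ delta
is 22.0055 Da. Modifications are counted, not localized, at the MS1 stage;
N-terminal methylation enters the whole-species formula as +CH₂ with its
site tracked separately for fragmentation.

## Precursor mining

Class II lanthipeptide precursors are short ORFs near the *lanM*
synthetase gene, which the pipeline takes as an input annotation (GFF3
`type=lanM`): homology detection of LanM is out of scope. Within a window
(default 6 kb each side, clipped at contig edges with a logged warning)
all six frames are scanned; an ORF runs from a start codon to the next
in-frame stop, with the span including the stop codon and the translation
excluding it. Start codons are ATG/GTG/TTG (archaea frequently initiate at
the alternatives; all are translated Met), minimum length 20 aa. Nested
starts sharing a stop collapse to the longest ORF per stop. "Adjacent" is
interpreted as the k = 10 nearest ORFs by absolute edge-to-edge genomic
distance across both strands, ties broken by smaller start then + before
−; k is configurable. The precursor filter keeps ORFs strictly shorter
than 100 residues whose C-terminal 20 residues contain at least one Cys
and at least one Ser/Thr — the residues required to form thioether rings.
The conserved haloarchaeal leader motif Kx(Y/F)(D/E)xx(F/Y) is scanned
with all overlapping hits reported; because the true split position is not
derivable from sequence alone, all leader/core splits with core length in
a configurable range (and ≥1 Cys, ≥1 Ser/Thr in the core) are enumerated,
flagged motif-consistent when a motif hit lies wholly inside the leader.
Coordinates are 0-based half-open in memory and 1-based closed in GFF3.

## MS1 linking

The anticipated-modification lattice is the Cartesian product of
dehydration count (bounded by the core's Ser+Thr count when "auto"),
methylation count (enabled only when the gene cluster is annotated with a
methyltransferase, or explicitly by the caller) and dehydrogenation count.
Isobaric count-vectors collapse to one species per net formula, with all
generating vectors retained as provenance. Matching is complete within the
ppm tolerance (default 10 ppm — generous relative to the ≤1.3 ppm errors
of a modern QTOF, to tolerate noisy synthetic data); peaks carrying a
charge annotation are tried only at that charge, others at every
configured state (default {1,2,3}). There is no probabilistic score:
matches rank lexicographically by (total modification count, |Δppm|,
charge), i.e. parsimony first, which reproduces the manual practice of
preferring the least-modified explanation.

## Ring-aware fragmentation

Only b/y ions are modelled (no a-ions, neutral losses or internal
fragments). A ring (donor Ser/Thr d, acceptor Cys a) consumes one
dehydration. For cleavages outside every ring the standard b/y masses
apply, with a ring wholly contained in a fragment contributing its −H₂O.
For a cleavage inside a ring interval, ions are emitted only via the Cγ–S
rupture pathway observed in lanthipeptide MS/MS: the Cys-derived residue
appears as Dha (−H₂S vs Cys, monoisotopic −33.9877 Da, nominal −34) and
the donor-derived residue retains the sulfur in place of its side-chain
oxygen (+S−O, +15.9772 Da, nominal +16). The two shifts cancel exactly
against the intact ring's −H₂O, so b_i + y_{n−i} equals the precursor
neutral mass (≤1e-6 Da) for every emitted pathway — the invariant the
test suite checks at every cleavage. A `suppress` mode instead drops all
intra-ring cleavages (classical behaviour for very stable rings).

Dehydrations beyond the ring count are localized to the N-terminal-most
free Ser/Thr as Dha/Dhb (a deterministic convention; their true positions
are not inferable at this stage). Dehydrogenations are modelled as
disulfides pairing free Cys residues in sequence order, with cleavages
inside a disulfide span suppressed. Neither case occurs in the archalan
fixtures; the rules exist so the complementarity invariant holds for every
emitted ion on arbitrary species.

## Spectrum annotation and topology scoring

Annotation is greedy nearest-ppm: each peak takes its closest theoretical
fragment within tolerance (ties broken by series, index, charge); a
fragment may annotate several peaks. Coverage is the fraction of
inter-residue bonds supported by at least one annotated b or y ion.
Candidate topologies — all injective pairings of n Cys acceptors with n
Ser/Thr donors — are ranked by the number of annotated
*topology-discriminating* ions (annotated peaks whose fragment m/z is not
produced by every candidate), then total annotated intensity, then
coverage, with a deterministic tie-break on candidate order. When no
discriminating ion is annotated the result is reported indeterminate
rather than picking arbitrarily.

## Reductive desulfurization

Ni-boride reduction excises the thioether sulfur of an opened ring:
Ser-derived halves become Ala, Thr-derived become Abu, Cys-derived become
Ala; the net formula change per opened link is −S+2H with NaBH₄ and
−S+H+D with NaBD₄ (ΔΔ = 1.00628 Da per link). The mechanism does not fix
which carbon receives the deuterium, so both placements (donor- vs
acceptor-derived residue) are enumerated as isomer variants. Intact links
are untouched; methionine sulfur is not reduced by default. Topology
inference scores each candidate jointly over the parent spectrum (intact
fragments) and each partial-product spectrum (best single-link-opened
simulation over links × deuteration placements), maximizing annotated
discriminating ions; it reports which link each product spectrum is
assigned to — reproducing, e.g., "intact Ser6/Cys14 with deuterated Ala
at position 4" versus "intact Ser4/Cys13 with deuterated Ala at 14" for
the interlocking archalan β pair.

## Synthetic data

The genome generator emulates the mining inputs: a contig with a dummy
*lanM* CDS, planted precursor genes (leader carrying the conserved motif +
core) at controlled edge distances on either strand, and decoy ORFs each
violating exactly one filter clause (length 100, no C-terminal Cys, no
C-terminal Ser/Thr, or placed beyond the window). Genes are
reverse-translated with one fixed codon per residue, so planted ORFs have
exact coordinates and no internal stops. Intergenic background is random
at a configurable GC fraction but spliced every 30 bp with a
self-reverse-complement stop cassette (`TTAATTAATTAA`, stops in all six
frames) and each planted gene is flanked by the same cassette; this
prevents random background from spawning long spurious ORFs or extending
planted ones, which would otherwise make exact-recovery assertions
flaky. The cost is realism: real intergenic DNA has no such cassettes,
and real genomes contain many passenger ORFs, so the 100% planted-truth
recovery shown on these genomes demonstrates correctness of the scanning
and filtering logic, not expected precision on real assemblies.

Spectrum generators draw per-peak ppm errors from Normal(0, sd) (default
sd 5 ppm), sample a configurable fraction of the theoretical fragment
list, and add uniform noise peaks (default 20% of the signal count) with
low intensities; intensities follow a rank-decay model by default. With
zero jitter, zero noise and fraction 1 the output equals the theoretical
values exactly, which anchors the round-trip tests. All generators use
`numpy.random.default_rng` with explicit integer seeds and no global
state; identical specs and seeds give byte-identical outputs. Real
spectra additionally contain isotope envelopes, chimeric fragments and
intensity structure that these generators do not emulate, so recovery
rates on synthetic spectra are an upper bound on real-data performance.

The archalan fixtures carry the published cores, modification counts,
ring assignments and observed ions; their leader sequences are synthetic
stand-ins (flagged as such on the fixture) built around the conserved
leader motif, since only the cores are available as transcribed text.

## Problem sizes and defaults

The recovery experiments run at sizes chosen to exercise every code path
while staying trivially fast: precursor recovery over 5 genomes × 2
planted precursors with three decoy classes; topology recovery over 20
seeded simulations of 2-ring species on random 10–20 aa cores (2 Cys, 3
Ser/Thr), 5 ppm jitter, 20% noise peaks, charges {1,2}, scored at 10 ppm.
Both reach 100% at these settings; the acceptance threshold for topology
recovery is ≥90%.

## Known limitations

- ORF calling reports the longest ORF per stop; genuinely nested
  precursors sharing a stop are not separately reported.
- No probabilistic match scoring or FDR; ranking is purely lexicographic
  parsimony, appropriate for the small candidate sets of this workflow.
- Fragment intensities are not predicted; scoring uses counts and
  observed intensities only.
- Isotope patterns beyond the monoisotopic peak are not modelled.
- Stereochemistry (DL/LL of Lan/MeLan) and NMR-level structure are out of
  scope; topology inference is mass-spectrometric only.
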