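# lanmine

Genome-to-metabolite discovery of **class II lanthipeptides**: mine
lanM-adjacent precursor ORFs from an annotated genome, enumerate
post-translationally modified core-peptide species, match them to
high-resolution MS1 peaks, and infer thioether ring topology from
ring-aware MS/MS fragmentation and simulated reductive desulfurization.

## Who this is for

Natural-product and RiPP researchers connecting biosynthetic gene clusters
(BGCs) to peptide metabolites ("metabologenomics"). Lanthipeptides are
ribosomally synthesized peptides whose Ser/Thr residues are dehydrated to
Dha/Dhb and cyclized onto Cys thiols, forming lanthionine (Lan) and
methyllanthionine (MeLan) thioether rings. In class II systems a single
bifunctional synthetase, LanM, installs both steps, and its gene anchors
the search: precursor peptides (leader + core) are short ORFs encoded next
to *lanM*. The package was built around the discovery workflow for the
archaeal lanthipeptides archalan α and β from the haloarchaeon *Halorussus
salinus* YJ-37-H, whose cores (`GCGFTCSPFSSW`, `GLPSASMYSFEHCC`) ship as
worked fixtures.

## The computation

1. **Precursor mining** (`lanmine.mining`). Six-frame ORF scan in a window
   around each annotated `lanM` feature; keep the *k* = 10 nearest ORFs;
   retain those shorter than 100 aa with at least one Cys **and** one
   Ser/Thr in the C-terminal 20 residues; scan the conserved archaeal
   leader motif `Kx(Y/F)(D/E)xx(F/Y)`; enumerate leader/core splits.
2. **MS1 linking** (`lanmine.ms1`). For each candidate core, enumerate the
   lattice of anticipated modifications — *n*<sub>deh</sub> dehydrations
   (−H₂O each), optional methylation (+CH₂), optional dehydrogenation
   (−H₂) — compute monoisotopic [M + zH]<sup>z+</sup> values
   (m/z = (M + z·1.007276)/z), and report every observed peak within a ppm
   tolerance, ranked by parsimony (fewest modifications, then smallest
   |Δppm|, then lowest z).
3. **Ring topology** (`lanmine.rings`). Backbone cleavage inside a
   thioether ring is emitted only via Cγ–S rupture: the Cys-derived
   residue appears as Dha (nominal −34 Da) and the Ser/Thr-derived residue
   keeps the sulfur in place of its hydroxyl oxygen (nominal +16 Da).
   Candidate topologies (all injective Cys↔Ser/Thr pairings) are ranked by
   annotated topology-discriminating ions. Reductive desulfurization
   (NiCl₂ with NaBH₄/NaBD₄) is simulated per opened link as −S+2H (or
   −S+H+D, localizing a deuterium), so MS/MS of partial products
   discriminates intertwined from disjoint ring systems.
4. **Synthetic data** (`lanmine.simulate`). Seeded generators for genomes
   with planted precursors + clause-violating decoys, and MS1/MS2 spectra
   with Gaussian ppm jitter and noise peaks, so the whole pipeline runs
   and is tested without downloads.

## Worked example

```python
from lanmine import chem
from lanmine.chem import ModificationSet

core = "GCGFTCSPFSSW"                      # archalan alpha core peptide
f = chem.peptide_formula(core)             # C57H75N13O17S2
m = chem.apply_modifications(f, ModificationSet(n_dehydration=2))
print(m)                                   # C57H71N13O15S2
mz = chem.mz_from_neutral(m.mass, 2)
print(round(mz, 4))                        # 621.739
print(round(chem.ppm_error(621.7382, mz), 2))   # -1.25
```

The doubly dehydrated core is `C57H71N13O15S2`; the observed doubly
protonated ion at m/z 621.7382 sits 1.25 ppm from the calculated value —
a confident BGC↔metabolite link. The same arithmetic for
`GLPSASMYSFEHCC` − 2H₂O + CH₂ gives `C66H92N16O19S3` (0.55 ppm from the
observed 755.3012, net observed loss 22.0063 Da versus the unmodified
core).

End-to-end on synthetic data, from a shell:

```bash
lanmine simulate --preset alpha --seed 7 --outdir demo
lanmine mine --fasta demo/genome.fasta --gff demo/annotations.gff3
lanmine link --fasta demo/genome.fasta --gff demo/annotations.gff3 \
             --peaks demo/ms1_peaks.tsv
```

The `link` report ties the mined core `GCGFTCSPFSSW` to its peak with
exactly two dehydrations; the `rings` subcommand (or `run-all` with MS/MS
input) then ranks the 12 candidate two-ring topologies and returns the
disjoint "bicycle" {Cys2–Thr5, Cys6–Ser10}, while the archalan β fixture
yields the interlocking (intertwined) {Ser4–Cys13, Ser6–Cys14} pair.

## Layout

```
src/lanmine/
  chem.py        molecular formulas, residue tables, masses, m/z, ppm
  mining.py      ORF scan, precursor filter, leader motif, core splits
  ms1.py         species enumeration, peak matching, BGC linking
  rings.py       ring-aware b/y ions, annotation, desulfurization, inference
  simulate.py    seeded genome/spectrum generators and archalan fixtures
  evaluation.py  planted-truth recovery experiments
  pipeline.py    configuration + run orchestration
  cli.py         `lanmine` command (mine, link, rings, simulate, run-all)
  io.py          FASTA / GFF3 / MGF / TSV / JSON
```

See `docs/methods.md` for the modelling assumptions, numerical
conventions and known limitations.
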