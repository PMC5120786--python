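# cgr — complex chromosomal insertions: reconstruction and mechanism

Chromosomal insertions — a segment of one chromosome translocated into a
non-homologous chromosome or a non-adjacent locus — are found in roughly
1 in 500 individuals referred for clinical chromosomal microarray, and a
subset are *complex*: they carry extra copy-number changes at the donor
and acceptor loci and more than two breakpoint junctions.  Resolving such
a case means answering three questions from aCGH copy-number profiles and
Sanger-sequenced junction fragments:

1. **What does each junction look like?**  Microhomology (short sequence
   shared by both reference flanks, present once in the derivative), an
   untemplated insert, or a *templated* insert copied from one or more
   reference loci — possibly on a third chromosome.
2. **What derivative chromosome explains all the data?**  An ordered walk
   of oriented reference segments whose per-segment use counts reproduce
   the observed copy numbers and whose novel adjacencies use every
   sequenced junction exactly once — adding the minimum number of
   *hypothetical* ('??') junctions when the sequenced set cannot close a
   walk.
3. **What mechanism made it?**  End joining (NHEJ/MMEJ) leaves blunt or
   short-microhomology joints and no copy-number gain; replicative repair
   with iterative template switching (FoSTeS/MMBIR) leaves multiple gains
   — including triplications such as the DUP-TRP/INV-DUP signature —
   longer microhomology (>4 bp) and templated insertions, the
   chromothripsis-like pattern called chromoanasynthesis.

This package implements that desk workflow as tested code for researchers
working on structural-variant mechanisms: a ground-truth rearrangement
simulator (template-switch chains and end-joining exchanges over toy
genomes, with emulated probe tables and junction-spanning reads), the
junction annotator, a probe segmenter with per-chromosome pattern strings
(`DUP-NML-DEL-NML-DEL`), a breakpoint-graph reconstructor with minimal
hypothetical-junction inference, a rule-based mechanism classifier with an
itemized evidence trail, and a meiotic-transmission model that predicts
the unbalanced children of balanced-insertion carriers (independent
segregation for interchromosomal insertions, single crossovers for
intrachromosomal ones).  Nine resolved cases ship as transcribed fixtures
on toy coordinates and serve as the acceptance surface.

## Worked example

```sh
$ cgr run-case Cplex6
pattern chr5: DUP
pattern chrX: DUP-TRP-DUP
DUP-TRP/INV-DUP: True
reconstruction: 3 junctions (1 hypothetical); 6 minimal model(s)
derivative of chrX:
  [3] chrX:136001-170000 (+)
      | hyp1 ?? hypothetical
  [4] chrX:130001-136000 (-)
      | Cplex6_Jct2 376bp templated insertion
  [5] chr5:50001-55800 (+)
      | Cplex6_Jct1 blunt ends
  ...
mechanism: chromoanasynthesis (proposed repair: FoSTeS/MMBIR-iterative)
```

Reading this: the chrX profile shows a triplication embedded in a
duplication (`DUP-TRP-DUP`); the derivative walk places the triplicated
segment once in inverted orientation (walk step 4), reached from the
duplication's distal side through a junction that could not be sequenced
(the `??` hypothetical joint the search inferred), and carries the
inserted chr5 duplication via a 376 bp templated insert and a blunt joint.
Copy-number gains plus a long templated insertion classify the case as
chromoanasynthesis — replicative repair with iterative template switches.

The same machinery runs on files rather than fixtures:

```sh
cgr simulate --preset chromoanasynthesis --seed 7 --out sim/
cgr annotate --reads sim/reads.fa --genome sim/genome.fa --out ann/
cgr call-cnv --probes sim/probes.tsv --genome sim/genome.fa --out cnv/
cgr reconstruct --calls cnv/calls.tsv --junctions ann/junctions.vcf \
    --genome sim/genome.fa --out rec/
```

## Analyses

Numbered drivers under `analysis/` reproduce the package's result tables
under `results/`:

* `01_simulation_validation.py` — round-trip, copy-number-recovery and
  reconstruction rates on seeded simulations (all 100%);
* `02_resolved_cases.py` — all nine case fixtures through the pipeline,
  every published per-case conclusion checked (junction counts, pattern
  strings, DUP-TRP/INV-DUP, the 3-vs-3 mechanism split, the 1-in-500
  incidence arithmetic);
* `03_family_transmission.py` — predicted transmission outcomes for the
  three balanced-insertion carrier families and the matching of each
  observed child profile.

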