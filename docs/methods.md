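# Methods

## Coordinates and the junction model

All internal coordinates are 1-based and fully closed (`chr9:5874574-5875388`
spans 815 bp); BED exports convert to 0-based half-open and VCF exports stay
1-based.  A breakend records which reference flank survives into the
derivative (`retains_left` keeps `(..pos]`, `retains_right` keeps `[pos..)`)
and the strand on which that flank is read; a junction is an unordered pair
of breakends.  A junction whose breakends retain same-handed flanks inverts
orientation relative to the reference.

**Microhomology is positionally ambiguous by nature**: the shared tract can
be attributed to either flank.  We canonicalize — the tract belongs to the
`retains_left` breakend when the sides differ, otherwise to the breakend
with the smaller `(chromosome, tract-free position)`.  Both the simulator
and the annotator apply the same rule, so breakend coordinates compare
exactly, flank extents never overlap, and a derivative sequence is the plain
concatenation of its oriented segment sequences plus junctional inserts.
Whether published junction tables measure microhomology on the derivative
joint or the reference plus strand is generally unstated for inverted
joints; we define it on the derivative joint, which is what a junction-
spanning read shows.

## The simulator

Two generative models produce ground truth:

*Replicative template switching.*  A chain starts on a recipient
chromosome, performs an ordered list of switches — each specifying a target
locus, orientation, replicated length, and joint signature — and resolves
back on the recipient.  Each switch yields exactly one junction.  Copy
numbers follow from segment-use counting; skipped recipient intervals are
deletions, re-copied templates are duplications/triplications.

Joint signatures are *constructed, not sampled post hoc*.  With
`plant=False` the simulator searches ±50 bp around the requested landing for
flanks that share exactly the requested number of terminal bases and fails
loudly (naming the joint) if none exists.  With `plant=True` (how the seeded
case generators run) it writes the required bases into a copy of the toy
genome before any sequence is copied, only ever touching bases outside every
copied or protected interval; a guard refuses plants that would rewrite
sequence already incorporated.  Exactness is enforced in both directions:
the base one deeper than the tract and the departure-side continuation base
are set to mismatch, so the realized microhomology is exactly the requested
length.  Untemplated inserts are drawn uniformly over ACGT, their edge bases
redrawn so they extend neither anchor, and inserts of ≥10 bp are redrawn
until they contain no reference match of template length (otherwise the
truth label "untemplated" would be wrong by construction).  Templated
inserts are concatenations of oriented reference fetches; the reference base
following each source is set to mismatch the next insert base so greedy
decomposition recovers the part boundaries crisply.

*End joining.*  A donor fragment is excised and inserted at an acceptor
position, optionally exchanging a reciprocal acceptor-side fragment, and
optionally trimming the donor flanks (a small deletion at the donor locus).
Joints are taken exactly as the flanks give them: blunt when they share
nothing, otherwise a 1–3 bp edge-fitted untemplated insert.  The genome is
never edited here — forcing microhomology at an end-joining joint would
require rewriting sequence that is already part of both derivatives.  The
repertoire (blunt / tiny inserts, never gains) is what distinguishes these
truths from the replicative ones.

*Emulated assays.*  Probe tables place one probe per `spacing_bp` (default
200 bp, the high-density aCGH scale) on every chromosome with value
`log2(cn/baseline) + N(0, noise_sd)`; copy number 0 is floored at 1/32 copy
(arrays saturate rather than report −∞).  Junction reads carry `flank_bp`
derivative bases each side of the joint plus the insert; hypothetical
junctions emit nothing; reads clipped by a derivative end are flagged.  All
randomness flows from explicit integer seeds; there is no global state.

The simulator emulates neither read-level sequencing artifacts (no FASTQ,
no base errors) nor aCGH GC waves, and toy genomes are repeat-free except
where a test plants a repeat.  Passing round trips therefore demonstrate
the annotator's logic, not its robustness to sequencing noise or to the
repeat-rich contexts where real junctions become unmappable — the latter is
exercised only by explicit planted-repeat ambiguity tests.

## Junction annotation

Anchors are maximal exact matches (either strand, any chromosome) of the
read's prefix and suffix, each required to be ≥ `min_anchor` (30) bp and
uniquely placed; several placements raise an ambiguity error listing the
candidate loci (the unmappable low-copy-repeat junction is this case).
Matching is exact because the toy genomes are mutation-free, which keeps
the simulator–annotator relationship provable.  Overlapping anchors signal
microhomology (tract assigned canonically as above); a gap between them is
insert sequence, decomposed greedily left-to-right into maximal reference
matches of ≥ `min_template_len` (10) bp.  The longest match wins; at equal
length a match within `near_window_bp` (20 kb) of either breakend beats a
genome-wide one, and remaining ties break by lowest chromosome name, then
coordinate, `+` before `-`.  Full decomposition → templated insertion with
ordered source parts; no qualifying match → untemplated; partial
decomposition → templated with the unmatched remainder flagged.  The 10 bp
threshold separates "templated" from "small insertion": observed
untemplated inserts in this event class are 2–18 bp and described templated
ones carry identifiable sources, so the boundary is configurable and logged
in output headers.

## Copy-number segmentation and patterns

Segmentation is deliberately simple — greedy recursive binary splitting on
the mean log2 ratio, accepting a change point when its z statistic (against
a MAD-of-first-differences noise estimate) exceeds `z_thresh` (4), with at
least `min_probes` (5) per side — because nothing downstream depends on
segmentation sophistication.  Segments snap to the nearest integer copy
number (`round(baseline·2^mean)`), with per-chromosome baselines taken from
the genome ploidy, never inferred from data.  Boundaries land midway
between flanking probes, so recovered coordinates are exact only to probe
resolution; `snap_calls_to_junctions` aligns array-derived call edges to
sequenced breakends (within a tolerance) before graph building.  Pattern
strings join the ordered calls with `NML` at positive gaps, so an embedded
triplication reads `DUP-TRP-DUP`.  The DUP-TRP/INV-DUP detector requires a
triplication strictly embedded in duplicated cover *and* an
orientation-inverting junction at a triplication boundary — a triplication
whose junctions are all direct does not qualify.

## Derivative reconstruction

Chromosomes are split at every CNV boundary and junction breakend (the
common refinement; zero tolerance on exact coordinates).  Each segment's
required multiplicity is `max(cn − (baseline − 1), 0)`, which encodes the
assumption that one homolog of every involved chromosome is intact — the
constitutional, heterozygous situation in every modeled pedigree.  A
reconstruction is one telomere-to-telomere walk per involved chromosome
jointly consuming every multiplicity, with every sequenced junction used
exactly once; unresolved junctions constrain nothing but are reported.

The search is exhaustive depth-first with memoized dead states — instances
here are ≤ ~20 segments, so this is instantaneous — iteratively deepened
over the number of hypothetical junctions allowed (default cap 3; beyond
the cap the case is reported unreconstructable with no partial guesses).
A hypothetical junction is a jump from the current dangling breakend to any
segment end still carrying multiplicity.  All complete models at the
minimal hypothetical count are collected and ranked (fewest inverting
joins, then lexicographically smallest walk); the full minimal set is
reported rather than asserting uniqueness, mirroring the language of
"most parsimonious" models.  Genuine ambiguity exists: when a donor gap
segment sits between two copied fragments, the gap's single use can ride in
either the derivative or the donor's own walk — both are returned.

## Mechanism classification

Feature extraction merges abutting gain calls into gain regions (an
embedded triplication is one gain), takes the maximum microhomology over
resolved junctions, counts templated insertions, and counts involved
chromosomes including those contributing only templated-insert material.
The cascade:

1. **chromoanasynthesis** — gain evidence (≥2 gain regions or a
   triplication) together with replicative junction evidence
   (microhomology > 4 bp or any templated insertion).  A single gain with
   a templated insertion — a combination absent from the described cases —
   is also routed here, with an explanatory note.
2. **basic complex insertion** — exactly one gain inserted at a deletion
   site, microhomology ≤ 3 bp, no templated insertions (the
   NHEJ/MMEJ/single-switch signature).
3. **balanced end-joining exchange** — net balanced, allowing flanking
   CNVs up to `small_cnv_max` (10 kb; the observed flanking CNVs in
   balanced carriers are a few kb).  No microhomology ceiling is applied
   here: a balanced bidirectional exchange is attributed to end joining on
   the absence of copy-number gains, even when a joint shows 6 bp
   microhomology or carries the reciprocally exchanged fragment as an
   "insertion" — without gains there is no evidence of iterative
   replicative copying, and MMEJ accommodates such joints.
4. otherwise **unclassified**.  The intrachromosomal carrier with two
   sizeable flanking duplications but a single sequenced junction showing
   only an 18 bp untemplated insert lands here deliberately: its published
   replicative interpretation rests on the architecture, not on junction
   signatures the cascade can see.

Blunt joints never veto a replicative call (replicative events show blunt
ends at a subset of joints), and inheritance status is carried in the
evidence trail but never used by a rule — it is pedigree metadata, not
molecular signal.  Repeat-element context is a pure lookup against a
user-supplied interval list; nothing recomputes repeat annotation.

## Inheritance modelling

Child profiles assume the other parent contributes one reference copy of
every chromosome (configurable in principle, reference by default).
Junctional templated inserts of ≥500 bp count as copy-number material in
predicted profiles — an exchanged 815 bp fragment is visible at
high-density probe spacing and is exactly how such an exchange betrays
itself in a child — while shorter inserts sit below assay resolution.
Interchromosomal carriers segregate independently (2^k outcomes over the k
derivative-bearing chromosomes).  Intrachromosomal carriers undergo a
single crossover, sampled on a grid between the outermost junction
breakends; a position hosts a crossover only if exactly one walk element
covers it, in direct orientation, strictly interior — crossovers inside
inverted or multiply-used segments would create further complexity and are
excluded.  Positions inside a displaced but single-copy segment are
enumerated (the products are structurally valid even where the pairing
register is ectopic); outcome matching against observed child calls uses
reciprocal interval overlap and reports unexplained residual CNVs.
Double crossovers are out of scope; no pedigree modeled requires one.

## Case fixtures

The nine resolved cases are transcribed as structured text.  Coordinate
policy: Mb-scale "~" sizes are reduced 100× (11.8 Mb → 118 kb) to keep
desk-scale chromosomes; kb-scale printed sizes are kept as printed; exact
printed values (815, 376, 8192, 5167 bp and the pair chr9:5874574–5875388)
are preserved verbatim.  Family fixtures stay entirely at printed scale so
size thresholds like `small_cnv_max` keep their real meaning.  One
transcription inconsistency is preserved deliberately: the printed
13,357 bp templated-insertion length disagrees by 2 bp with its printed
part lengths (8,192 + 5,167); the fixture stores both and the loader flags
the discrepancy instead of reconciling it.  In the intrachromosomal family
the three insertion-side junctions of the published model were never
sequenced and are marked hypothetical; only the deletion junction carries a
printed signature.  The second-cohort incidence (76 insertion carriers
among 38,000 individuals tested → 1 in 500) is arithmetic over printed
counts, not something recomputed from any database.

## Problem sizes and numerical choices

Simulation suites run on 3-chromosome toy genomes of 50–80 kb per
chromosome: 200 seeded chains for the junction round trip, 100 for
reconstruction recovery and classifier agreement, 50 for segmentation
recovery — sizes at which the exhaustive reconstruction search and the
exact string searches are effectively instant while still exercising every
code path (0–12 bp microhomology, 1–18 bp untemplated inserts, 1–3-part
templated inserts, inverted segments, 2–4 switches).  Random loci keep a
2 kb margin from chromosome ends and from each other so that planted
signatures never collide and every true CNV has enough baseline probes on
both sides to be segmentable.  Zero-noise probe tables use an sd floor of
1e-6 in the z statistic; tie-breaks throughout (template search, walk
ranking) are lexicographic and documented above, so identical inputs and
seeds give byte-identical outputs.

## Known limitations

Exact-match anchoring presumes mutation-free references; real data needs
alignment, which is out of scope.  The segmentation routine is not CBS and
inherits probe-resolution boundaries.  The classifier is a transparent
rule cascade, not a calibrated probabilistic model; cases outside the
described classes land in `unclassified` by design.  Mosaicism,
allele-specific copy number, double crossovers, and ISCN nomenclature
generation are not modeled.
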