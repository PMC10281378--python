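# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic data does and does not emulate, and the design choices
made where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and labeling conventions

* All genomic coordinates are 0-based, half-open.  1-based numbering
  appears only in human-readable tables (logo positions).
* PAM positions are numbered 1..L, 3′ from the protospacer end on the
  spacer-matching strand.
* The **cut offset** is the distance in nt from the PAM-proximal end of the
  protospacer to the scissile phosphate on a strand, so a blunt cut between
  the 3rd and 4th protospacer positions from the PAM is offset 3 on both
  strands:

  ```
  5'-…N N N N | N N N-PAM-…-3'   spacer-matching (top) strand
  3'-…N N N N | N N N-PAM-…-5'   bottom strand      (blunt, offset 3)
              ^ cut, offset 3
  ```

* Editing alleles are labeled relative to the cut: position −1 is the base
  immediately 5′ of the cut, +1 immediately 3′; `-2:1D` deletes one base
  starting at −2, `+1:2I` inserts two bases exactly at the cut.  Indels are
  reported at their leftmost equivalent placement (the usual variant-caller
  normalization); the generators record both the raw planted label and its
  normalized form so recovery tests compare like with like.

## In vivo PAM-depletion screen

Model: each library molecule carries one PAM variant; transformation plus
nuclease interference is collapsed into a single per-variant survival
probability (a Bernoulli per molecule).  The treatment arm is a multinomial
draw from the library composition reweighted by survival; the control arm
from the composition itself.

Scoring: `log2fc = log2(f_C / f_T)` with pseudocounted frequencies
`f = (count + c)/(total + cV)`, `c = 1` read per variant by default.  The
direction of the published ratio is not stated; this sign convention
(higher = more depleted = more nuclease-permissive) is fixed here and
printed by the CLI on every run.  Whether the original analysis used
pseudocounts or excluded zero-count variants is likewise unstated; with
`c = 0` the module returns ±inf for zero counts rather than guessing.
Selection takes variants **strictly** above the threshold (default 7).
Replicates are pooled by summing counts; a per-replicate mode returns one
score table per replicate.

Noise floor: with per-base substitution error `e`, reads from inactive
variants leak into an active variant's label when an error inside the PAM
window converts one.  For the TNNN library this bounds the achievable
depletion ratio near `0.25/e` regardless of depth — at the default
`e = 0.001` (Illumina NovaSeq-scale post-filter error) the ceiling is
log2 ≈ 8, comfortably above the threshold of 7, but at `e = 0.002` the
ceiling sits almost exactly at 2⁷ and the hard threshold stops separating.
Arm depths below the default 10⁵ reads additionally push scores down
through the pseudocount floor.  The defaults (depth 10⁵ molecules,
10⁵ reads per arm, `e = 0.001`, survival 10⁻⁴ for permissive PAMs) reflect
the reported experiment scale (~10⁵ pooled colonies; deep short-read
sequencing); actual library skew and read depths were not reported, so the
composition is uniform by default with a lognormal `skew` knob.

## In vitro cleavage screen

Normalized occurrence per variant: `norm = f_T × mean(f_C) / f_C`, where
the mean control frequency is taken **over variants** (exactly 1/V for a
complete library); taking it over replicates instead would only rescale all
values by a constant.  The identity `uniform control ⇒ norm = f_T` and
scale invariance in the control counts are property-tested.

The PFM over the top 10 % of PAMs (⌊0.10·V⌋ variants, cutoff ties broken
lexicographically) is weighted by normalized occurrence by default, since
frequency-ranked selection carries magnitude information worth preserving;
an unweighted mode exists.  Consensus calling from the PFM uses thresholds
that are this package's own (the source experiments report only the
resulting strings): a base with frequency ≥ 0.9 is required; a base with
frequency ≤ 0.05 is excluded (IUPAC code over the remainder); a base with
frequency ≥ 0.5 is preferred.  Under the packaged activity rule (G required
at positions 2–3, cytosine disfavored at 4, thymine preferred at 5) these
produce `NGGNNNN` (required) and `NGGDTNN` (preferred).

## Cut-site inference

Adapter-ligated fragment reads begin at a cut terminus.  Reads are mapped
onto the target context (PAM positions masked to N) by a Hamming scan of
the first 25 nt of the fragment (≤ 2 mismatches, N positions skipped);
orientation decides the strand, and the junction position contributes to
that strand's terminus histogram.  The modal offset per strand is the call;
ties for the mode are flagged `ambiguous` (smallest offset reported) rather
than raised as errors.  Generated fragments are error-free reads from a
linear context — real libraries add PCR chimeras, adapter read-through, and
background nicking, none of which are modeled, so recovery here shows the
geometry bookkeeping is right, not that the mapper is robust to library
artifacts.

## Locus mining

Array detection seeds on exact 12-mers recurring at a periodicity
compatible with the geometry bounds (repeat 18–45 nt, spacer 15–45 nt),
extends each seed pair to the maximal equal substring, validates geometry,
and chains further units at the same period allowing ≤ 2 substitutions.
Overlapping detections are deduplicated preferring more units, then fewer
unit-vs-consensus mismatches, then leftmost start: with only two units the
maximal extension can overrun the true boundary whenever the flanking base
coincides with a spacer-edge base, and the mismatch criterion resolves
exactly that case.  The contig generator therefore pins the two background
bases flanking the planted array to differ from the spacer edge bases, so
planted geometry is recoverable by construction — a deliberate property of
the fixture, with the residual limitation that arrays of ≥ 3 units whose
spacers share edge bases can still be reported one or two bases wide.

ORFs are maximal ATG→stop spans in all six frames (≥ 100 aa by default);
open-ended spans at contig edges are excluded unless requested, which keeps
counts reproducible on fixtures.  The generator precedes its planted ORF
with an in-frame stop so the planted start is maximal.

The anti-repeat search is a substitution-only Hamming scan of the repeat
and its reverse complement over ± 2 kb around the array (array units
excluded), sorted by mismatches then distance.  Gapless scanning is
deterministic and oracle-checkable; true tracrRNA anti-repeats with
bulges would need gapped alignment and are out of scope, as is
promoter/terminator prediction — candidates are ranked by sequence evidence
only.

## sgRNA design

The scaffold is spacer + truncated repeat + linker + tracrRNA fragment.
Defaults follow the published architecture: 23-nt spacer, 18-nt repeat
truncation keeping the repeat's 3′ half (the crRNA-retained portion at the
spacer–repeat junction), GAAA tetraloop, 73-nt tracrRNA fragment taken from
the tracrRNA 5′ end, which begins with the anti-repeat — 118 nt total with
a 95-nt backbone.  The design records component coordinates and counts
repeat:anti-repeat duplex mismatches under reverse-complement alignment
(budget 6).  Which 23 of a 29-nt spacer's positions serve as guide is not
specified in the source; the PAM-proximal 23 nt are used — an assumption,
recorded here.  The exact tracrRNA fragment boundary within the ~100-nt
gene is configurable (`keep_tracr`).

## Amplicon INDEL quantification

Reads are aligned globally with affine gaps (match +2, mismatch −4, gap
open −6 including the first gapped base, extend −1), via Biopython's
pairwise aligner; the test suite checks scores against an independent
three-matrix dynamic-programming oracle.  Gap placements are then shifted
to their leftmost equal-score position.  Indel events touching cut-relative
positions −5..+5 (window configurable; the external tooling the field uses
does not state one) make a read `indel`; reads with substitutions but no
in-window indel are `snv_only` and are excluded from the editing
percentage; reads whose only indel lies outside the window count as `wt`
for editing, with the event retained for inspection.  Multi-indel reads get
a composite `;`-joined allele and count once.  Reads with alignment score
below 0 are dropped and reported.  An optional background mode subtracts a
control sample's editing percentage.  The amplicon generator plants
substitution noise only (no indel sequencing errors), so indel calls in
recovery tests are attributable to planted alleles alone; real data would
add indel-type sequencing errors that this suite does not probe.

## Packaged preset and synthetic stand-ins

The `eh` preset records the EH CRISPR-Cas9 geometry: 36-bp repeats, 29-bp
spacer, ~100-nt tracrRNA with 73 nt retained, TNNN / NNNNNNN library
patterns, TGGN editing PAM with 23-nt guides, blunt cut at offset 3,
1070-aa nuclease ORF, and 145 + 163-bp recombineering arms.  The in vivo
protospacer anchor (`CCTGTATATCGTGCGAAAAAGGATGGATA`) is the published
target sequence.  The repeat, array-spacer, and tracrRNA **sequences** are
synthetic stand-ins generated once with the published dimensions (the real
sequences exist only as figure panels); the tracrRNA's first 18 nt are the
reverse complement of the repeat's 3′ 18 nt carrying 4 substitutions.
Consequences: tests exercising architecture (lengths, coordinates, duplex
mismatch counts, array recovery) are meaningful; any conclusion tied to
the real EH sequence content (e.g. RNA secondary structure) is out of
reach by construction.

## Problem sizes and determinism

Every generator is a pure function of its arguments and an integer seed
(numpy `default_rng`); the CLI echoes seeds and writes a sha256 manifest so
identical configs produce identical runs.  The test suite runs screens at
10⁵ reads per arm, cut-site recovery at 10³–10⁴ molecules, alignment
oracles on ≤ 20-nt pairs, and indel recovery at 10⁴ reads (2 × 10³ per seed
for the 10-seed spectrum sweep) — sizes chosen so the whole suite completes
in well under a minute while keeping every statistical check ≥ 3 standard
deviations wide.  `scripts/acceptance.py` uses 10⁴ cleavage molecules and
the full 1070-aa locus contig.
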