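# cas9kit

A tested pipeline for the computational side of characterizing a Cas9
nuclease, written for microbiologists and genome-engineering groups who run
PAM screens, in vitro cleavage assays, and amplicon editing experiments.
It covers five analyses:

* **In vivo PAM-depletion screens** — a PAM-randomized plasmid library is
  transformed into nuclease-expressing cells; plasmids with permissive PAMs
  are cleaved and depleted among transformants.  Per-variant depletion is
  scored as `log2fc(v) = log2(f_control(v) / f_treatment(v))` with
  pseudocounted frequencies `f = (count + c)/(total + cV)`, variants with
  `log2fc > 7` are selected, and selected sets are summarized as a position
  frequency matrix with per-position information content `IC_j = 2 − H_j`
  (bits) for sequence logos.
* **In vitro cleavage screens** — PAM occurrence among cleavage-fragment
  reads is normalized for library composition,
  `norm(v) = f_T(v) · mean(f_C) / f_C(v)`, the top 10 % of PAMs by
  normalized occurrence feed an occurrence-weighted PFM, and required /
  preferred IUPAC consensus strings are called from it.
* **Cut-site inference** — adapters ligated to cleavage-fragment ends mean
  each read starts at a cut terminus; per-strand terminus histograms give
  the modal cut offset from the PAM-proximal protospacer end, the overhang,
  and blunt/staggered classification.
* **CRISPR locus mining and guide design** — repeat–spacer array detection
  (periodic k-mer seeding + maximal extension), six-frame ORF scanning,
  gapless anti-repeat (tracrRNA candidate) search, sgRNA scaffold assembly
  (spacer + truncated repeat + GAAA tetraloop + tracrRNA fragment),
  PAM-constrained target enumeration, and recombineering-template
  construction.
* **Amplicon INDEL quantification** — global affine-gap alignment to the
  reference, allele calls in cut-relative notation (`-2:1D` = 1-nt deletion
  starting 2 nt 5′ of the cut), and editing efficiency as the fraction of
  reads with indels near the cut, excluding SNV-only reads.

Every analysis stage has a matching seeded generator
(`cas9kit.synthetic_data`) that produces its inputs with machine-readable
ground truth, so each stage ships with recovery tests.  The packaged `eh`
preset carries the EH CRISPR-Cas9 architecture (36-bp repeats, 29-bp
spacer, 118-nt sgRNA with a 95-nt backbone, TGGN editing PAM, blunt cut 3 nt
from the PAM); see `docs/methods.md` for what is real and what is a
synthetic stand-in.

## Worked example

Simulate an in vivo TNNN PAM screen in which only NGG-at-positions-2–3
variants are cleaved (survival 10⁻⁴), then analyze it:

```sh
cas9kit simulate pam-screen --outdir sim --seed 7
cas9kit pam-invivo --outdir pam \
    --treatment sim/treatment.fastq --control sim/control.fastq
```

`pam/selected_pams.txt` then contains exactly the planted permissive set:

```
TGGA
TGGC
TGGG
TGGT
```

with scores (from `pam/log2fc.tsv`) `TGGA 10.65`, `TGGC 9.64`, `TGGG 8.46`,
`TGGT 8.02` — all above the selection threshold of 7, while the best
non-permissive variant sits at 0.04.  The logo matrix (`pam/logo.tsv`)
shows the fixed library T at position 1 and the recovered G requirement:

```
position  A     C     G     T     IC_bits
1         0.0   0.0   0.0   1.0   2.0
2         0.0   0.0   1.0   0.0   2.0
3         0.0   0.0   1.0   0.0   2.0
4         0.25  0.25  0.25  0.25  0.0
```

Position 4 carries no information (IC 0): any nucleotide is tolerated
there.  Assembling the packaged guide architecture:

```sh
cas9kit design --outdir design
# sgRNA length 118 nt (backbone 95 nt)
```

reports a 118-nt guide — 23-nt spacer, 18-nt truncated repeat, GAAA
tetraloop, 73-nt tracrRNA fragment — whose repeat part pairs with the
tracrRNA anti-repeat at 4 mismatches.

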