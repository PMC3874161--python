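# mitorecode

Detection and validation of sense-codon reassignment in small (typically
mitochondrial) genomes.

The genetic code is not frozen: in A+T-rich organellar genomes, rarely used
codons can vanish entirely ("codon liberation"), after which a tRNA with a
new charging identity can capture them.  The CUN family in yeast mitochondria
is the textbook case — Leu in the standard code, Thr in *Saccharomyces*
relatives, and Ala in *Ashbya (Eremothecium) gossypii*, where a
UAG-anticodon tRNA carrying the AlaRS identity signature G3:U70 reads CUA and
CUU.  `mitorecode` packages the complete computational chain for discovering
and validating such an event, plus a seeded synthetic-data generator so every
stage is testable without downloads.

## What it computes

* **`codes`** — genetic-code tables (standard, yeast-mito, ashbya-mito,
  vertebrate-mito, custom TSV), translation, anticodon read sets under
  wobble classes (unmodified-U34 "superwobble" reads all four third-position
  bases), and the *exact* minimum number of anticodons needed to read every
  sense codon, solved per codon box.  For the yeast mitochondrial code this
  minimum is 23, consistent with the classic "25 or fewer" organellar bound.
* **`usage`** — codon counts per gene and genome, unused ("liberated") sense
  codons with third-position breakdown, per-box family occupancy.
* **`infer`** — the core inference.  For every codon family, each site where
  the target genome uses the family contributes the residue-frequency
  profile of its ortholog-alignment column (target excluded).  Sites are
  weighted by column conservation `w = max_a f(a)` and filtered at
  `min_weight`; the family's support for amino acid *a* is
  `Σ w_i f_i(a) / Σ w_i`, and the call is the argmax when it beats the
  runner-up by `margin` (else AMBIGUOUS; NO-SIGNAL and ABSENT are reported
  explicitly).
* **`trna`** — cloverleaf parsing into conventional landmark numbering
  (acceptor pairs 1:72…7:66, anticodon 34–36, discriminator 73, optional
  −1), identity-element extraction (G3:U70, G−1:C73, A73, 8-nt anticodon
  loop with inserted U31), a rule-table classifier per synthetase
  (AlaRS / HisRS / ThrRS-MST1 / LeuRS-candidate) with an orthogonality flag,
  and landmark-coordinate mutations (`G3A`, `A3G`, `InsU31`, `dU31`) with
  automatic re-parse.
* **`scan`** — the 15-nt exact-window read scan: k-mers spanning the
  leader/gene junctions prove precursor transcripts; k-mers running off the
  gene 3' end into a non-encoded CCA prove maturation.  Windows occurring in
  both forms are labeled ambiguous.  Includes relative-expression and
  no-editing (sequence-equality) reports.
* **`masspec`** — variant proteomes (CUN as Leu/Thr/Ala), tryptic digestion
  (cleave after K/R, not before P, missed cleavages), monoisotopic peptide
  masses (carbamidomethyl-Cys fixed mod), and peptide-level matching of
  observed sequences or masses; a discriminating peptide pins the codon's
  amino acid.
* **`kinetics`** — Michaelis–Menten fits of aminoacylation velocities
  (`v = kcat·E·S/(Km+S)`) with standard errors, and relative catalytic
  efficiency `100·(kcat/Km)/(kcat/Km)_ref`, integer-rounded.
* **`simulate`** — generates every input above with known ground truth:
  star-phylogeny ortholog families with per-site conservation classes, an
  A+T-biased back-translated target CDS carrying a planted family
  reassignment, a tRNA built from chosen identity elements, reads from
  precursor/mature(+CCA) forms, and velocity tables.  Presets:
  `ashbya-like`, `klactis-like` (family absent), `standard-null`.

## Worked example

```
$ mitorecode simulate --preset ashbya-like --seed 1 --out demo
$ mitorecode infer --alignments demo/alignments --cds demo/cds.fasta \
      --target target --code yeast-mito --out demo/calls
85 calls written; 3 disagree with code yeast-mito
$ grep '^CU' demo/calls/calls.tsv
CUA/CUC/CUG/CUU  81  A   A:1.000  .
CUA              49  A   A:1.000  .
CUC               0  ABSENT  .   .
CUG               0  ABSENT  .   .
CUU              32  A   A:1.000  .
```

The synthetic genome uses 49 CUA and 32 CUU codons (and avoids CUC/CUG);
every one of the 81 sites sits in a column where the other species show an
invariant Ala, so the CUN family — and each used member separately — is
called `A` with support 1.000, while the unused members are reported ABSENT.
The three calls "disagreeing" with the yeast-mito code (which would read CUN
as Thr) are exactly the planted reassignment.  The minimal-decoding-set
computation is a one-liner:

```
$ mitorecode mincode --code yeast-mito
23
```

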