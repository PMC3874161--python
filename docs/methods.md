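# Methods

This note documents the models and procedures each module implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical/design decisions that were genuinely
open.

## Genetic codes and wobble decoding

Codes are 64-entry RNA-codon tables (DNA input is transcribed T→U on entry;
all reporting is in the RNA alphabet, matching how codons are written in the
reassignment literature).  The standard, yeast-mitochondrial
(CUN=Thr, AUA=Met, UGA=Trp) and vertebrate-mitochondrial tables come from
the NCBI translation tables via Biopython; the ashbya-mito table is the
yeast-mito table with the whole CUN family assigned to Ala.  CUC and CUG are
flagged `avoided` there: the genome does not use them, but a U34 tRNA would
superwobble-read all four family members, so the table encodes the predicted
translation of the unused pair rather than leaving it undefined.  This is a
prediction flag, not an observation.

Wobble classes are fixed as: unmodified U34 reads {A,C,G,U}; modified U34
reads {A,G}; G34 reads {C,U}; C34 reads {G}; A34 reads {U}.  Inosine and
rarer pairings are deliberately excluded — they can be supplied as a custom
class list, but the defaults model the organellar superwobble argument and
nothing more.

**Minimal anticodon set.**  Because codon positions 1–2 fix the box, the
constrained set cover decouples into 16 independent per-box covers, each
over at most five admissible anticodons (one per wobble class; an anticodon
is inadmissible when its read set touches a stop codon or spans two amino
acids).  Each box is solved by exhaustive subset enumeration, so the result
is the exact minimum, not a greedy bound.  For the yeast-mito code this
gives 23 (8 uniform family boxes × 1, 7 two-amino-acid boxes × 2, and the
UAN box needing only a G34 anticodon for Tyr).  The standard code is
uncoverable under this class table — AUA (Ile) would need a modified-C34
pairing outside the model — and the solver reports the offending codon
rather than silently skipping it.

## Codon usage and liberation

Counting excludes the terminal stop codon by default (`include_stops`
switches this), since liberation analysis concerns sense usage; whether
published usage tables include stops is rarely stated, so the default is
documented and reversible.  Genes with internal stops are rejected outright:
an internal stop means the wrong code or frame was assumed, and every
downstream zero-count would be corrupt.  The liberation report lists unused
sense codons with a third-position base breakdown (A+T-biased genomes
liberate C/G-ending codons first) and a per-box occupancy table.

## Conservation-based codon identity calls

The inference formalizes a by-eye alignment argument into a statistic.  For
an assessed codon family F and each gene alignment: every target codon in F
contributes its alignment column's residue-frequency profile computed over
the *other* species (the target is always excluded — using its own residue
would be circular; species suspected of sharing the reassignment can be
excluded too).  The site weight is the column's modal frequency.  Sites with
weight < `min_weight` (default 0.5) are dropped; support(a) is the
weight-averaged frequency of amino acid a over the remaining sites, a convex
combination in [0,1].  The call is the argmax when it beats the runner-up by
`margin` (default 0.2), otherwise AMBIGUOUS.  Families the target never uses
are ABSENT (codon-capture candidates); families with usage but no
conserved columns are NO-SIGNAL.

There is no quantitative threshold for this in the source literature — the
defaults are declared package choices, configurable per run.  No
multiple-testing correction is applied: the scores are descriptive evidence
summaries with an explicit ambiguity margin, not p-values.  Residue
similarity credit (substitution classes) is off by default; conservation is
counted at identity level.  Families are the synonymous codon groups within
each box under the comparison code, and per-single-codon calls are also
emitted, since experimental confirmation may cover only one family member.

## tRNA landmarks and identity rules

Landmark numbering follows conventional tRNA numbering (acceptor pairs
1:72 … 7:66, anticodon 34–36, discriminator 73, optional genomic −1);
internal coordinates are 0-based, reports use canonical numbers.  Parsing is
anchored at the acceptor stem (first 7 bases against the 7 before the
discriminator; at least 5 of 7 must pair, G:U counting as a pair — the
wobble pair at 3:70 is itself the AlaRS identity element).  The anticodon
arm is found either from a dot-bracket structure (central hairpin) or
heuristically: each candidate 5-bp stem closing a 7/8/9-nt loop in the
central region is scored together with the best 4-bp D-arm hairpin fitting
before it and the best 5-bp T-arm hairpin after it (WC pairs 2, G:U 1); ties
prefer the canonical 7-nt loop, then centrality.  Scoring the whole
decomposition rather than the stem alone is what makes the heuristic agree
with structure-based parsing on the generator's fixtures.

In 8-nt loops the extra base is taken to sit immediately 3' of stem position
31 (the first loop slot), so the anticodon is the loop's 4th–6th bases; the
insertion point is fixed by the conventional mutation names (InsU31/dU31)
since the structural literature marks only "an insertion producing an 8-nt
loop".  `insert at 31` and `delete at 31` are exact inverses.

Synthetase rules are data (an editable TSV), defaulting to:
AlaRS ⇔ pair 3:70 = G:U; HisRS ⇔ G at −1 ∧ C73 ∧ anticodon GUG (the
anticodon condition can be relaxed to score candidates that would require a
HisRS specificity change, e.g. a UCG-anticodon tRNA carrying the G−1:C73
signal); ThrRS-MST1 ⇔ 8-nt loop ∧ inserted U ∧ anticodon UAG; LeuRS
candidate ⇔ A73 (LeuRS largely ignores the anticodon).  A missing element
(e.g. no −1 base in the input) makes a rule UNDETERMINED, never violated.
A tRNA is orthogonal when exactly one rule matches.  The discriminator base
of the Ala-type fixture is a generator choice (G), not an asserted fact
about any real genome.

## Read-window scan

Exact substring matching only, mirroring the grep-style counting the
approach derives from; no mismatch tolerance.  A read containing a window
counts once per window.  Windows are labeled on precursor coordinates:
5'/3' junction windows (precursor-only evidence), mature-body windows
(shared by all forms; the single window starting at the gene 5' end is
tracked separately), and mature-3'CCA windows that run past the gene 3' end
into an appended CCA.  A window whose sequence occurs in both the precursor
and the mature form — a trailer starting with C mimics the CCA, a leader
echoing the gene start — is demoted to ambiguous, since it carries no
processing information.  When the CCA is genome-encoded there are no
CCA-specific windows at all.  How 5'/3' "processing intermediates" are
operationally separated from mature reads is not standardized; the junction
labeling here is one explicit formalization.  The no-editing check is a
plain sequence-equality report between genomic and observed mature
sequence, not an alignment.

## Variant proteomes and peptide matching

Three (or any chosen set of) proteomes are inferred with the assessed family
translated as each candidate; they differ only at family codon positions.
Digestion cleaves after K/R except before P, with missed-cleavage variants
up to a limit; the 0-missed peptides concatenate back to the protein.
Masses are monoisotopic with water, computed via pyteomics' residue table,
with carbamidomethyl-Cys (+57.02146 Da) as the default fixed modification
(standard reduction/alkylation prep).  Matching is at peptide level —
sequence identity or mass within a ppm tolerance (default 10 ppm, a modern
instrument convention; the tolerance is configurable because source assay
settings are generally unpublished).  The verdict per study is the
intersection of variants consistent with every discriminating observation;
matches to non-discriminating peptides constrain nothing.  Fragment-ion
scoring, FDR/decoy search and PTM search are out of scope: the biological
conclusion rests on which variant's discriminating peptide is identified,
which peptide-level matching captures.

## Kinetics

`v = kcat·E·S/(Km+S)` is fit by bounded nonlinear least squares
(scipy `curve_fit`), with standard errors from the fit covariance.  The
enzyme concentration cannot be inferred from velocities and is an explicit
input (default 1, making "kcat" a Vmax in velocity units).  Initial
velocities may alternatively be derived as linear slopes over the first
points of a product-vs-time course (window configurable) — time-course
assays and tabulated constants are routinely bridged this way without the
conversion being stated.  Relative efficiency is
`100·(kcat/Km)/(kcat/Km)_ref` rounded to the nearest integer, matching how
such tables are printed.  Note that published kcat/Km columns are typically
computed from unrounded fits, so they need not equal the ratio of the
rounded kcat and Km in the same row; relative efficiencies should therefore
be computed from the kcat/Km column itself.

## Synthetic-data generator

The generator defines the study conditions for all recovery tests.

* **Ortholog families**: a star phylogeny (every species diverges
  independently from one ancestor).  This is deliberate: the inference
  ignores tree structure, so correlated descent would change nothing the
  pipeline can observe.  Sites are invariant (30%), conserved (50%,
  ancestral residue retained with probability 0.9), or variable (20%).
  Planted reassignment sites are invariant columns whose ancestral residue
  is the planted amino acid — the reassignment signal sits in noiseless
  conserved columns, while the rest of the alignment carries realistic
  variation.
* **Planted usage**: the ashbya-like preset plants exactly 49 CUA and 32
  CUU codons across 8 genes of 120 codons over 9 non-target species —
  mirroring the documented usage of the motivating genome — and
  back-translates all other residues with third-position A/U probability
  0.9, never using family or avoided codons, so the planted counts are
  exact by construction.  The klactis-like preset plants nothing and
  forbids the family entirely (the codon-capture precursor state);
  standard-null plants nothing under the standard code.
* **tRNA and reads**: the tRNA is assembled from a fixed cloverleaf layout
  (73-nt body, 7-bp acceptor stem, 4-bp D-stem/8-nt loop, 5-bp anticodon
  stem with 7- or 8-nt loop, 5-nt variable region, 5-bp T-stem/7-nt loop)
  with the requested identity elements substituted and all other stems
  Watson-Crick.  Constructs with a chance competing decomposition (a random
  second perfect stem) are rejected and redrawn — real tRNAs are under
  selection for a single fold — as are trailers beginning with C, which
  would make CCA maturation invisible to exact-window counting.  Reads are
  sampled uniformly from the precursor and mature(+CCA) forms (default
  depth 100 each, lengths 20–50 nt, matching post-trimming small-RNA reads)
  with an optional uniform substitution error rate (default 0).
* **Kinetics**: noiseless or relative-Gaussian-noise velocities at
  substrate levels 0.1–10 µM around the sub-µM Km regime of the motivating
  assays (default constants kcat 2.1 min⁻¹, Km 0.53 µM).

Everything is driven by one integer seed; identical truth objects reproduce
byte-identical outputs.

**What the generator does not emulate** — and hence what passing recovery
tests do and do not show: no alignment errors or genuinely gapped target
rows (gaps are optional and only in non-target rows); no phylogenetic
correlation between species; no compositional heterogeneity along genes; no
RNA editing, introns or modified bases; no read quality profiles, adapters
or mapping artifacts; no chromatographic/spectral noise in peptide data.
Recovery at 100% on these fixtures demonstrates the correctness of the
inference arithmetic under its stated model, not robustness to real-data
pathologies.

## Problem sizes and tolerances

Default test problem sizes (8 genes × 120 codons × 10 species; 50 seeds for
recovery sweeps; read depths ≤ 200; 500-mer digest oracles) were chosen so
the whole suite exercises every stage in seconds while keeping counting
statistics meaningful (planted 81-site families, 3-s.e. binomial checks).
Mass identities are asserted to 1e-4 Da (printed precision of standard
residue tables); noiseless kinetic fits to 1e-6 relative; noisy fits to
3 fitted standard errors.

## Known limitations

* The cloverleaf heuristic targets canonical mitochondrial-style tRNAs
  (60–95 nt, 7-bp acceptor stem, 4/5-bp arm stems); bizarre armless
  mitochondrial tRNAs will not parse and are reported as parse failures.
* The identity-rule table is intentionally minimal and provisional — it
  encodes the handful of elements relevant to the Ala/Thr/His/Leu
  discrimination problem, not a general aaRS recognition model.
* Window-scan counts are exact-match only; a single sequencing error
  inside a 15-mer hides that window (by design, matching the original
  counting procedure).
* The liberation analysis is purely observational; it does not model
  mutational pressure or estimate how long a codon family has been absent.
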