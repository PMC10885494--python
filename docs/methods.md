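# Methods

## Candidate geometry

All coordinates are 0-based half-open internally; GenBank's 1-based
inclusive coordinates are converted at the I/O boundary.  Minus-strand
genes are handled by mirroring the locus into a reverse-complement "view"
so that frames, windows and motif scans always read left to right; view
boundaries map back to genomic coordinates by reflection.

**Joined genes.**  A two-segment `join` CDS is split into fragment
pseudo-genes.  The separation *d* between the fragments, measured in
reading direction, decides the label: *d* = 0 annotates a backward (−1)
shift and *d* = 1 a forward (+1) shift.  Annotation practice wobbles by
whole codons, so the mapping is taken mod 3 for *d* up to 10 nt
({0,3,6,9} → −1, {1,4,7,10} → +1); *d* mod 3 = 2 is rejected with a
warning, as are separations above 10 nt (introns, inteins, circular-genome
wrap-arounds and suspected annotation errors).  A one-base overlap
(*d* = −1) is accepted as backward: it is the other common way a −1 shift
is written, where the downstream fragment re-reads the slipped base — the
SARS-CoV-2 orf1ab join has this form.  Joins with more than two segments
are skipped.

**Overlap windows.**  Adjacent same-strand genes are paired when the
downstream gene starts no more than 10 nt past the upstream gene's stop
codon (mirroring the 10-nt join rule) and their frames differ.  The frame
offset is the mod-3 difference of the start coordinates: +2 means the
downstream frame is one base behind (−1 shift), +1 one base ahead.  The
search window runs from the first base after the nearest in-frame stop
codon in the downstream gene's frame (or the contig's frame start) to the
last base of the upstream gene's stop codon, clipped to start no earlier
than the upstream gene.  For fragment pseudo-genes the upstream "stop" is
the first in-frame stop at or beyond the fragment end — the stop the
frameshift bypasses; the search gives up 200 codons past the annotated end.

## Motif catalog

Ten motif classes are defined by run templates: *six* = (6),
*threethree* = (3,3), *fivetwo* = (5,2), *twofive* = (2,5),
*twofour* = (2,4), *threetwotwo* = (3,2,2), *five* = (5),
*twoonefour* = (2,1,4) for backward shifts, and *four* = (4),
*three* = (3) for forward shifts.  Each run is one repeated nucleotide;
adjacent runs must differ; non-adjacent runs and run identities are
otherwise unconstrained (no positional base restrictions).  Every template
is right-anchored at the last base of the P-site codon, so 7-nt templates
start one base before the E-site codon (the X XXY YYZ register), 6-nt
templates cover the E and P codons exactly, and the forward 3/4-nt
templates end at the P-codon boundary.

Where templates nest (every *six* is a *threethree*), the class with the
lowest iid-random match probability wins: 4·3^(g−1)/4^span for g runs.
Exact ties (e.g. *fivetwo* vs *twofive*) resolve by longer span, then by
catalog code.  Scanning walks every P-site codon boundary of the upstream
gene's frame inside the window; a match whose template would cross the
window's 5′ edge falls back to the rarest class that still fits, and the
last boundary considered leaves the stop codon in the A site (N = 0).
Windows containing ambiguous bases never match.  Forward candidates are
additionally required to have the shifted A-site codon more abundant than
the in-frame one (A1 > A0) — shifting onto a rarer codon is unfavourable,
and the filter keeps the frequent 3/4-base runs from flooding the
candidate set.

## Features

* **RBS1 (0–27).**  A 28-bin Shine–Dalgarno catalog in the style of the
  Prodigal gene finder: motif families are the exact substrings of AGGAGG
  (lengths 3–6), the gapped variants AGxAG/GGxGG/AGxAGG/AGGxGG, and
  one-mismatch variants of the 5/6-mers; spacers are binned 3–4, 5–10,
  11–12 and 13–15 nt from the motif's 3′ end to the E-site codon start.
  Bin 27 is the full AGGAGG at ideal (5–10 nt) spacing, bin 0 no match.
  The per-bin assignments are a reconstruction from the scorer's documented
  motif/spacer vocabulary, not a verbatim copy of its trained values; the
  score is the maximum bin over a 21-nt upstream window, so adding SD
  content never lowers it.
* **RBS2 (0.0–6.3).**  A weighted-motif SD score.  The table shipped is a
  synthetic surrogate (no published empirical weight table is bundled):
  weights grow with SD complementarity (1.4 per matched base beyond two,
  −1.6 per mismatch) and are scaled ×1.125 at ideal spacers (4–9 nt) and
  ×0.75 otherwise, capping the best hit at 6.3.  A custom
  (motif, spacer, weight) TSV can be loaded to replace it.
* **A0/A1.**  Relative codon usage tabulated over all annotated CDSs of
  the input genome, all 64 codons counted equally — stop codons, at one
  per gene, therefore register as rare, which is what makes a stop in the
  A site behave like a hungry codon.  Codons containing N are skipped and
  trailing partial codons dropped.
* **LF50/LF100, HK50/HK100 (0–1).**  Minimum free energy of the 50- and
  100-nt windows starting 3 nt past the P-site codon end (just after the
  A-site codon), folded by the hairpin engine (ViennaRNA nearest-neighbour
  fold) and the pseudoknot engine slot.  No pseudoknot-capable backend is
  bundled, so by default the pseudoknot slot runs the same thermodynamic
  fold and HK duplicates LF; the engine interface (`mfe(seq) -> kcal/mol`)
  accepts any replacement, and the duplication costs information, not
  correctness.  Raw MFE is divided by window length and by GC fraction
  (GC biases MFE), floored at GC = 0.01 to keep AT-only windows finite,
  and clamped to [0, 1].  Windows truncated by the contig end are folded
  and normalized at their actual length; empty windows score 0.
* **N (≥ 0).**  Nucleotides between the P-site codon end and the first
  in-frame stop, 0 when the stop waits in the A site.  The register is
  fixed by the orf1ab calibration: heptamer UUUAAAC followed by 15 nt and
  the bypassed stop gives N = 15.

## Classifier

`HistGradientBoostingClassifier` over the 11-feature vector with three
classes (−1, 0, +1); scikit-learn defaults except L2 regularization 1.0,
early stopping disabled and a fixed `random_state`, making training
deterministic for a fixed site order (sites are assembled in genome/file
order).  Training labels come from joins: a candidate inherits the join's
direction when its P-site boundary lies within 10 nt of the junction and
its direction matches; everything else — distant motifs inside true
overlaps included, since the curated junction position is itself a guess —
is labeled 0.  At prediction time at most one site per gene pair is
returned: among candidates whose argmax class is a shift, the one with the
highest class probability, ties broken by smaller N (sites near the stop
are a priori more plausible) and then by 5′ position.  Models serialize
with their feature-schema and motif-catalog versions; loading under a
mismatched schema is a hard error.

## Validation

Leave-one-group-out at four levels: CLUSTER and SUBCLUSTER from supplied
metadata, MASH95 computed from bottom-s MinHash sketches (canonical
16-mers, blake2b 64-bit hashes, sketch size 400; Mash distance
d = −ln(2j/(1+j))/k from the merged-sketch Jaccard estimate;
single-linkage clustering at d ≤ 0.05 with clusters named after their
lexicographically smallest member), and GENOME.  Features are computed
once per genome and reused across folds.  Scoring follows the 10-nt rule:
TP = prediction on a joined gene within 10 nt of the junction; a
prediction elsewhere on a joined gene counts both FP and (absent a TP) FN;
predictions on non-joined pairs are FP; non-joined pairs with candidates
but no prediction are TN.  With zero predictions precision is reported as
1.0 with a `precision_defined=False` flag so summaries stay total.

## Synthetic corpus

The generator emulates the signal structure of a curated phage corpus:
each planted PRF gene is a joined two-fragment CDS whose junction carries
a motif exemplar, an upstream AGGAGG at ideal spacing (optional), a
perfect-GC 12-bp hairpin starting 3 nt past the A-site codon, and the
bypassed in-frame stop — by default inside the hairpin loop at N = 15,
matching the short stop distances of real frameshifted chaperones;
backward plants cycle through all eight backward classes across families.
Forward plants park the stop in the A site (N = 0), using stop-codon
rarity to satisfy the A1 > A0 filter.  Honest negatives are decoy gene
pairs: overlapping ORFs whose window carries a bare motif 6–45 nt from
the stop but no hairpin and no planted SD, plus whatever motifs arise by
chance.  The region around each slippery site is built T-free so no stop
codon can invade the critical frames; defaults are 30 genomes in 5
families, 8 ordinary genes (30% on the minus strand), 3 decoy pairs and
1 planted PRF per genome at 64% GC in ~10-kb loci.  Families are founders
plus copies mutated at 2% per base outside the conserved frameshift
cassette, which puts within-family Mash distance near 0.02 and
between-family distance well above the 0.05 threshold.

What the generator does **not** emulate: real gene content and codon-bias
evolution, homology between frameshifted genes across families, imperfect
or pseudoknotted structures, low-GC genomes, and annotation noise (wrong
junctions, missing joins).  Passing the recovery tests therefore shows the
pipeline is correct and the features separate planted signal from bare
motifs; it does not certify recall on real corpora, where signal is
weaker and dirtier.

## Problem sizes and numerical choices

Validation and the acceptance script run the default 30-genome corpus:
~380 labeled candidate sites, 5 MASH95 folds and 30 GENOME folds, chosen
so the whole workflow completes in well under a minute on one core.
Numerical conventions collected in one place: GC floor 0.01 and [0,1]
clamp in MFE normalization; fold windows 50/100 nt at offset 3 are
part of the feature schema rather than runtime options — a model trained
at one window geometry cannot score features computed at another, so
changing them means changing the schema version; junction tolerance 10 nt applied
identically in training and scoring, measured at the P-site boundary;
stop-search cutoff 200 codons past a fragment end; ambiguous bases fold
as A and never match motifs; candidate ties broken (score, N, position).

## Known limitations

* The pseudoknot feature pair duplicates the hairpin fold unless an
  external pseudoknot engine is registered.
* RBS bin assignments and RBS2 weights are reconstructions, not trained
  tables; their ranges and monotonicity are enforced, their exact values
  are not field-calibrated.
* Only two-fragment joins are modelled; −2/+2 and larger recoding events
  present as −1/+1 frame offsets and are not distinguished.
* Genomes must arrive with gene calls; no gene finding is performed.
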