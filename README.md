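# prfscan

Detection of programmed ribosomal frameshift (PRF) sites in annotated
prokaryotic and viral genomes.

## The problem

During translation a ribosome normally advances three nucleotides at a time.
At a *slippery sequence* — canonically the heptamer X XXY YYZ read with the
E- and P-site tRNAs bound to XXY and YYZ — several signals can conspire to
stall the ribosome and slip it one base backward (−1) or forward (+1).  The
wobble position lets the tRNAs re-pair in the new register, the original
stop codon is no longer in frame, and translation continues to produce a
fusion protein.  Phage tail assembly chaperones, retroviral *gag/pol*, the
bacterial release factor 2 gene and the SARS-CoV-2 orf1ab polyprotein all
rely on this mechanism.  In GenBank annotations such genes appear as CDS
features with a discontinuous `join(a..b,c..d)` location; genomes fresh off
a gene caller instead show the two fragments as separate ORFs, and nothing
marks the shift.

`prfscan` scans the overlap region of every adjacent same-strand gene pair
for slippery motifs, computes eleven translation-related properties per
candidate site, and classifies each pair with a gradient-boosted tree model
as containing a backward shift, a forward shift, or none.  Predicted pairs
are re-joined into a single `join(...)` CDS in the output annotation.

## Model

For each candidate (a motif right-anchored at a P-site codon boundary
inside the overlap window) the feature vector is

| feature | meaning | range |
|---|---|---|
| DIR | shift direction implied by the frame offset | −1, +1 |
| RBS1 | Shine–Dalgarno score, 28-bin scheme | 0–27 |
| RBS2 | Shine–Dalgarno score, weighted-motif scheme | 0.0–6.3 |
| MOTIF | slippery motif class code | 0–9 |
| A0 | genome-wide usage of the in-frame A-site codon | 0–1 |
| A1 | usage of the shifted A-site codon | 0–1 |
| LF50 / LF100 | normalized hairpin-fold MFE, 50/100-nt downstream windows | 0–1 |
| HK50 / HK100 | same windows under the pseudoknot engine slot | 0–1 |
| N | nt from the P-site codon end to the in-frame stop | 0–∞ |

Ten motif classes are recognised — eight backward (*six*, *threethree*,
*fivetwo*, *twofive*, *twofour*, *threetwotwo*, *five*, *twoonefour*) and
two forward (*four*, *three*); names encode runs of identical nucleotides,
and overlapping matches resolve to the class with the lowest probability of
occurring in random sequence (4·3^(g−1)/4^span for g runs).  The classifier
is a `HistGradientBoostingClassifier` with L2 regularization 1.0 and early
stopping disabled, so results are deterministic; within each gene pair only
the highest-scoring shifting candidate is reported.

Validation is taxon-aware: genomes are grouped by externally supplied
cluster labels, by MinHash clustering at 95% identity (Mash distance
d = −ln(2j/(1+j))/k ≤ 0.05, sketch size 400, k = 16), or per genome, and
each group is predicted by a model trained on its complement.  A prediction
counts as a true positive when it lands on a `join`-annotated gene within
10 nt of the annotated junction.

## Worked example

`python examples/predict_frameshifts.py` trains on seven synthetic genomes
with planted frameshift genes and predicts on a held-out genome presented as
plain gene calls:

```
trained on 7 genomes; classes: {-1: 21, 0: 84}
genome  position  direction motif_name    score  N
FAM1G1      2541         -1        six 0.991216 15
planted junction (0-based boundary): 2545, motif six
re-joined CDS features written into the annotation: 1
```

The model saw 21 backward-labeled and 84 negative candidate sites.  On the
held-out genome it reports one site: a *six* motif starting at base 2541,
classified as a −1 shift with probability 0.99, sitting 15 nt upstream of
the in-frame stop — 4 nt from the planted junction, well within the 10-nt
tolerance, so the two gene calls are merged back into one joined CDS.

The same workflows are available from the shell:

```sh
prfscan fixtures -o corpus --n-genomes 30 --families 5 --seed 1
prfscan train corpus -o model.joblib --seed 1
prfscan predict genome.gbk --model model.joblib -o predictions
prfscan eval corpus --level mash95 --seed 1 -o report.tsv
```

`predict` writes `predictions.tsv` (one row per predicted site with all
eleven features) and `predictions.gbk` (the annotation with predicted pairs
merged into joined CDSs).

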