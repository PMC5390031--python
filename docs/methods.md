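# Methods

`mirseedscan` implements a desk-scale version of the classic
homology-based workflow for discovering plant microRNAs in expressed
sequence tags (ESTs), together with the downstream analytics that such
studies use to validate the predictions: hairpin thermodynamic
statistics, a structure-sequence classifier, target-site expectation
scoring, ontology-term enrichment, qPCR/RA-PCR expression analytics,
HPLC-style calibration, and neighbor-joining phylogenies. This note
records the models, the defaults that matter, and the design decisions
taken where the procedure was genuinely open.

## EST pre-processing

Single-pass cDNA reads carry poly(A) tails (or poly(T) heads on
reverse-strand reads). `trim_polyAT` removes a terminal run of at least
`min_run` (default 10) identical bases, tolerating one interruption per
10 bases of run — the behavior of the common EST-trimming scripts.
Trimming is idempotent: the surviving sequence never ends in a
qualifying run.

Low-complexity masking is a DUST-style score: for each window (default
12 nt) the sum of `c*(c-1)/2` over triplet counts, normalized by the
number of triplets; windows at or above the threshold (default 2.0) are
lowercased. Masked bases never seed the homology scan but still
participate in alignment extension — ordinary soft-masking semantics.
This intentionally replaces a full repeat library screen; tandem
low-complexity sequence is the failure mode that matters for seeded
scanning, and interspersed repeats are irrelevant at synthetic scale.

Assembly is a greedy suffix–prefix merger (default: overlap >= 30 nt at
>= 95% identity, left read wins inside the overlap, forward strand
only). It is *not* a production EST assembler; it exists because the
downstream scan only needs redundancy collapsed. Contig layouts are
validated in tests against a brute-force placement oracle. Vector
screening is an exact shared-16-mer filter against a user-supplied
contaminant FASTA.

## Homology scan

Known mature miRNAs (18–26 nt) are scanned against the units with an
exact 7-mer word index on both strands, followed by ungapped full-length
extension. A hit requires: no gaps, at most 3 mismatches, and at least
18 aligned bases (so a mature overhanging a unit end can still qualify
on its aligned core). The mismatch cap is deliberately the only filter:
at word size 7 any alignment passing it would also clear the very
permissive E-value thresholds used for this kind of census, so no
alignment statistics are computed. The scanner is proven equivalent, on
every tested instance, to a brute-force slide-and-count oracle; planted
homologs that keep one exact 7-mer are recovered at 100%.

`min_len` is exposed because the literature is ambiguous about whether
the full mature must align or only an 18-nt core; the default treats 18
as a minimum aligned coverage while the full mature footprint defines
the candidate locus (the mature+100 precursor geometry below only makes
sense for full-length loci).

## Precursor extraction and folding

Each hit is widened by 50-nt flanks on the hit strand. A 21-nt mature
therefore yields a 121-nt precursor and a 20-nt mature a 120-nt one;
candidates whose flanks truncate below 20 nt at a unit boundary are
rejected, because the arm opposite the mature could not be contained.

Folding is a pluggable contract. Two engines ship:

* **builtin** — an O(n^3) dynamic program over nested structures whose
  only energy terms are base-pair stacks: a stack of adjacent pairs
  contributes minus the mean stability of the two pairs (G:C 3.0,
  A:U 2.0, G:U 1.0), hairpin loops span at least 3 unpaired bases,
  isolated pairs carry no energy and are omitted from the traceback.
  It exists so the whole pipeline runs with zero external dependencies
  and is fully deterministic.
* **vienna** — the ViennaRNA bindings (Turner parameters, 37 °C), used
  automatically when importable.

The two engines agree on the pair set of designed perfect inverted
repeats (tested), and all downstream arithmetic consumes whatever MFE
the chosen engine reports, so the statistics below are engine-agnostic
by construction. Builtin MFE values are on a simplified scale and are
not comparable to thermodynamic kcal/mol.

Hairpin statistics, at full precision with 2-decimal display rounding
(half away from zero, computed on the decimal representation):

* `gc_percent = 100 (G+C)/L`; `au_percent = 100 − gc_percent`
* `amfe = mfe / L × 100` (MFE per 100 nt)
* `mfei = amfe / gc_percent` (the minimal folding free energy index)

The identity `mfei × gc_percent = amfe` holds to 1e−9 and is tested.
Two published cells for the five reference hairpins are internally
inconsistent with their own rows (one AMFE, and two MFEI cells that
round the wrong way); the package reproduces only the self-consistent
cells and reports the recomputed values for the rest.

## Hairpin filtering

**Triplet features.** For every interior position the paired/unpaired
status of the 3-window around it ('(' and ')' count equally as paired)
plus the middle base select one of 32 counters; counts normalize to
frequencies. This is the classic structure-sequence encoding for
pre-miRNA classification.

**Classifier.** No published weight vector is assumed. A linear-kernel
maximum-margin classifier (`LinearSVC`, C=1) is trained on generator
output: positives are synthetic hairpins (below), negatives the same
sequences mononucleotide-shuffled and refolded — composition preserved,
structure destroyed. Training is deterministic per seed and the model
serializes to JSON with a training digest. Five-fold cross-validated
accuracy on generator output exceeds 0.9 (tested).

**Coding/structural-RNA exclusion.** A candidate is dropped if any
reading frame (both strands) contains an ORF of >= 60 codons, or if it
shares an exact 16-mer with a user-supplied rRNA/tRNA/snRNA set. This
collapses the BLASTx-against-proteins and covariance-model screens of
the full-scale workflow into a self-contained rule; it is a documented
fidelity limitation, not an equivalent.

**Curation rules** (all thresholds config):

* mature wholly within one arm — every paired mature base points to the
  same side, outside the mature span;
* mature/star mismatches (mature bases left unpaired in the fold)
  <= 6;
* no multibranch junction overlapping the mature (single bracket
  orientation across the mature);
* AU% within [30, 70];
* |MFEI| >= 0.5. The common literature cutoff is 0.85, but the accepted
  reference hairpins reach only |MFEI| = 0.61, so the default follows
  the accepted set rather than the textbook value.

Relaxing any threshold never converts a pass into a fail (tested
monotonicity).

## Target scoring

A site's expectation is a penalty over the antiparallel miRNA:window
duplex: +1 per mismatch, +0.5 per G:U wobble, +2 per gap, doubled at
miRNA positions 2–13 from the 5' end (the plant-server seed
convention); at most one gap; sites above expectation 3.0 are not
reported. The minimal-penalty alignment is found by dynamic programming
over (miRNA position, window position, gaps used) and is tested equal
to exhaustive enumeration of all <= 1-gap alignments. A gap column is
attributed to the next unconsumed miRNA position from the 5' end (the
choice only matters for the seed doubling and is applied identically in
the enumeration oracle). Expectation is zero iff the window is the
exact reverse complement.

Inhibition mode follows central complementarity: any penalized column
at miRNA positions 10–11 calls translational repression, otherwise
cleavage. Target-site accessibility (UPE) is deliberately not scored.

## Enrichment

One hypergeometric upper tail per term with >= 1 study hit, accumulated
from log-binomial coefficients (`gammaln` + `logsumexp`) so that
p-values far below double underflow remain exact to ~1e−14 (tested
against rational enumeration for N <= 60). Benjamini–Hochberg step-up
correction spans exactly the tested terms. The significance default is
alpha = 0.05. Under a simulated null (random study sets), the
family-wise flag rate stays within alpha plus twice the Monte-Carlo
error over 500 repetitions.

## Expression analytics

Normalization follows the geometric-mean-of-references scheme: each
reference gene's relative quantity is 2^−(Ct − per-gene mean Ct), and a
sample's factor is the geometric mean over references. Fold changes are
2^−ΔΔCt with ΔCt taken against the arithmetic mean of the per-gene mean
reference Ct (the log of the geometric-mean quantity); replicates are
summarized by mean Ct before ΔCt and the replicate ΔCt SD is carried as
the spread. Two calibrator conventions are supported — a calibrator
*sample* (`fold_change_ddct`) and a control *gene* within each sample
(`fold_change_vs_control_gene`) — because assay designs legitimately
use both; the reference panel is an argument, never hard-coded.

RA-PCR: relative quantities of the 5', middle (target-site) and 3'
amplicons are formed per sample as 2^−Ct up to a common factor (which
cancels), and the statistic is `reduction = (1 − q_mid/q_3') × 100`.
A stage is called cleaved when the reduction exceeds the threshold
(default 0) and a transcript is cleaved overall only when every stage
is — the all-stages depletion argument. The 5' amplicon is reported
descriptively and never enters the call. miRNA–target anticorrelation
uses Pearson or Spearman across >= 3 stages with a sign call at |r| >
0.5; constant series return NA.

## HPLC quantification

Ordinary least squares of peak area on concentration per aglycone
(daidzein, glycitein, genistein), intercept free (forcing the origin
would be an uncited assumption), r² reported for QC. Inversion:
`ppm = (area − intercept)/slope`, then
`µg/g = ppm × extract_volume × dilution / sample_mass` with defaults
0.125 g flour and 6 ml extract (5 ml ethanol + 1 ml HCl). Replicates
are averaged before inversion. Totals are the sum of the three
aglycones. The noise-free generator→calibration→inversion chain is an
exact round trip (tested).

## Phylogeny

p-distance with pairwise gap deletion; Saitou–Nei neighbor joining with
deterministic tie-breaking (lexicographically smallest label pair),
negative branch lengths clamped to zero with the deficit moved to the
sister edge, and the final three lineages resolved by the closed-form
star formulas (so the root is the standard unrooted trifurcation). NJ
provably recovers the generating topology on additive matrices, which
is tested on random 5–8-taxon trees and cross-checked against an
independent NJ implementation. Bootstrap resamples alignment columns
with replacement, rebuilds the tree per replicate, and reports per-edge
bipartition support in percent; alignments with no variation are
flagged degenerate. The conventional 1000 replicates are the CLI
default; tests use 100 for speed. Alignment itself is out of scope —
inputs must be pre-aligned.

## Synthetic data

The generators define the conditions everything is tested under:

* **EST corpora** — background reads 300–800 nt, uniform bases with a
  GC knob (default 0.45, since the curation AU band makes hairpin
  statistics GC-sensitive); planted reads embed a reference mature
  (mutations, if any, avoid the first 7 bases so a seed word survives)
  inside a hairpin context of total length mature+100: pad + mature +
  11-nt loop + (optionally mutated) reverse-complement star + pad. 30%
  of reads get 3' poly(A) tails.
* **Expression tables** — two genotypes × four stages × three
  replicates, Ct noise SD 0.1 (a typical qPCR replicate spread);
  reference genes constant, target Ct = calibrator Ct − log2(planted
  fold) + noise, so the ΔΔCt chain inverts exactly at zero noise.
  RA-PCR tables shift the middle amplicon's Ct by −log2(1 − reduction)
  for cleaved transcripts (planted cleaved fraction 0.7, reductions
  uniform in 50–99%).
* **Annotation maps** — each gene draws 2 of 30 terms uniformly; study
  genes additionally receive the planted term at odds-scaled
  probability; odds 1 reduces to the null.
* **HPLC tables** — five standards (5/10/20/40/50 ppm) per analyte;
  sample areas are the exact inversion of the quantification
  arithmetic.

Every generator draws from one seeded `numpy` generator per call and is
byte-deterministic; ground truth serializes to JSON next to the data.
What the generators do *not* emulate — chromatogram base-calling
errors, realistic EST error profiles, amplification-efficiency
deviations from the 2^−ΔΔCt assumption, GO-graph structure among terms,
genome-scale corpus sizes — bounds what passing tests say about real
data: they demonstrate the analytics are correct and calibrated, not
that the simplified screens match the full-scale web-tool workflow.

## Problem sizes

The default verification runs use a 200-unit corpus with 10 planted
precursors for the discovery chain, 200 genes / 200 transcripts for the
expression-recovery studies, 500 repetitions for the enrichment null,
100 random trees for NJ recovery and 100 bootstrap replicates — sizes
chosen so the whole suite completes in well under a minute while the
Monte-Carlo margins stay comfortably inside the acceptance bands.

## Known limitations

* The coding/structural-RNA screen is a heuristic stand-in for
  full-scale protein and RNA-family searches.
* The builtin folding engine's energies are a simplified stacking
  model; use the ViennaRNA engine for thermodynamically meaningful MFE.
* Target scoring ignores site accessibility and conservation.
* The assembler has no quality awareness or chimera detection.
* Enrichment treats terms independently (no true-path propagation).
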