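# Methods

## Problem and model

`glycorbf` predicts O-linked glycosylation of serine and threonine residues
from protein sequence. Each candidate S/T site is represented by the
(2n+1)-mer window centered on it (default n = 14, a 29-mer), over a 21-symbol
alphabet: the 20 standard amino acids plus one terminal symbol that pads
windows hanging over sequence ends and absorbs non-standard residue codes.

Two feature blocks encode a window:

* **BLOSUM62 block** — each position contributes 21 numbers: the residue's
  row of the BLOSUM62 substitution matrix, min-max normalized to [0, 1]
  over the whole 20x20 matrix, plus a terminal slot (0 for amino acids; the
  terminal symbol is all-zeros except a 1 in that slot). A 29-mer yields a
  609-long vector. Distinct windows map to distinct vectors because BLOSUM62
  rows are pairwise distinct.
* **SAAP block** — one bit per *significant amino-acid pair* (SAAP): an
  anchor residue at an anchor flank position together with a one- or
  two-residue partner set at another flank position. The bit is 1 when the
  window satisfies both constraints.

The classifier is a Gaussian radial-basis-function network using **every**
training vector as a center with one fixed bandwidth sigma = 5:

    c_j(x) = sum_i  w_ji * exp(-||x - mu_i||^2 / (2 sigma^2)),   j in {neg, pos}

The output weights solve (Phi^T Phi + lambda I) W = Phi^T Y against one-hot
targets, with lambda = 0 by default; at lambda = 0 with distinct training
points the network interpolates its targets exactly, and fitting is
deterministic linear algebra. The decision rule is
`positive iff c_pos(x) - c_neg(x) > threshold` (threshold 0 by default,
exposed so users can trade sensitivity for specificity). Identical training
vectors with conflicting labels make the interpolation singular; this is
detected and resolved by an automatic, logged fallback ridge of 1e-8.

Four independent models are trained, one per stratum: {S, T} x
{transmembrane (TM), non-TM}, because the flanking-motif composition differs
between membrane and soluble glycoproteins.

## F-score and SAAP discovery

The discriminative power of a single feature is measured by the F-score

    F = [(m+ - m)^2 + (m- - m)^2] / (s+^2 + s-^2)

with grand mean m, class means m+/m-, and unbiased within-class variances.
It is invariant under class-label swap and affine rescaling. When both
variances vanish, F is defined as 0 if the class means agree and +inf
otherwise (only reachable on constructed data). For 0/1 indicators the
statistic is computed from per-class counts in closed form, which is
algebraically identical to the direct evaluation (tested to 1e-12).

Discovery per stratum:

1. every (flank position, residue) indicator is scored; the position with
   maximal score is the **anchor position** (ties: smaller |position|, then
   the N-terminal side, logged);
2. the `k_anchor` (default 3) most frequent amino acids among positives at
   the anchor position are anchor residues; for each anchor residue, each
   other flank position, and each partner residue with positive-class
   frequency >= `f_min` (default 0.10), the pair's indicator is scored; the
   best two-residue partner merge at a position is added when it strictly
   outscores both singletons (capped at two residues, the largest "or"
   grouping such pair tables use);
3. candidates are ranked by descending F-score and appended to the feature
   vector one at a time; the prefix maximizing pooled 5-fold cross-validated
   **balanced accuracy** wins (ties: shorter prefix; an empty prefix returns
   the sequence-only model). Balanced accuracy is the selection criterion
   because site data are heavily imbalanced toward negatives.

Discovery runs on the full fragment set; homology reduction (below) applies
to the classifier's training folds.

## Homology reduction

Two proteins with more than 30% pairwise identity are homologous; identity
is matches / alignment columns from a Smith-Waterman local alignment with
BLOSUM62 and BLAST-style affine gaps (open 11, extend 1; no positive-scoring
alignment means identity 0). Among homologous proteins, same-class fragments
with byte-identical windows collapse to one representative (kept: the
lexicographically smallest (protein id, position)); the same rule applies
within one protein. Because only byte-identical windows can ever collapse,
protein-level alignments are computed only inside window-collision groups,
which makes the reduction cheap without changing its result.

Note a consequence of the local-alignment identity definition: any two
proteins sharing one positive-scoring residue pair have a short 100%-identity
local alignment, so the 30% gate over-groups unrelated proteins. This is
harmless here because collapsing additionally requires byte-identical
windows, which unrelated proteins essentially never share.

Cross-validation applies the reduction per training fold by default (the
held-out fold is never reduced, so pooled counts conserve totals); a global
pre-reduction mode is also provided — the two differ only in whether
test-fold windows can influence which training fragments are removed.

## Evaluation

Cross-validation is sequence-level: whole proteins are randomly assigned to
k = 5 folds (sizes differing by at most one; 239 proteins give 48/48/48/48/47),
so no protein spans a train/test boundary. Fold confusion counts are pooled
(micro-averaged) into Pr, Sn, Sp, Acc, BAcc = (Sn+Sp)/2, and MCC. Pooling is
used rather than mean-of-folds because benchmark tables in this area report
integer pooled counts. Conventions: any 0/0 rate is 0, including MCC; reports
round percentages to 1 decimal and MCC to 2 decimals.

**Membrane-topology filter.** Glycosyltransferases cannot reach residues
buried in the membrane, so observed glycosylation sites avoid TM segments
entirely. For TM proteins a veto forces any positively predicted site inside
a TM segment to negative; nothing else changes, and negatives are never
flipped positive. Topology is consumed as input (segments labeled
L/N/E/C/TM/S with 1-based inclusive, non-overlapping coordinates); predicting
topology is out of scope.

## Synthetic data

The generator emulates a glycoprotein corpus: sequences drawn i.i.d. from a
background residue distribution (default uniform with S and T enriched to
0.10 each so candidate sites exist; real corpora are close to uniform at this
level of abstraction), a configurable fraction of TM proteins with 1-3
non-overlapping TM helices of 15-25 residues (a typical helix span)
alternating with E/C segments, and positive sites sampled from S/T positions
outside TM segments — either per-site with probability `positive_rate`
(default 0.05, matching the roughly 5% positive share of curated site data)
or as exact requested totals. Implanted pair motifs rewrite the flanks of
positive sites with a given penetrance; an implant may omit its partner to
create a single-position signal. Output is deterministic given the seed.

What the generator does **not** emulate: residue autocorrelation and
compositional bias of real proteins, homologous families (generated proteins
are essentially unrelated, so homology reduction rarely fires), mucin-like
S/T-rich clustering of real O-glycosylation, and any glycan chemistry.
Passing recovery tests therefore shows the pipeline extracts the signal it
is pointed at under realistic imbalance — not that real glycosylation motifs
are this clean.

Two deterministic benchmark fixtures are constructed directly (not via a
trained model; both are synthetic by construction):

* `reference_confusion_fixture` — 2652 labeled TM-protein site predictions
  arranged so the pre-filter confusion is (TP, FP, TN, FN) =
  (132, 462, 1988, 70) with exactly 145 false positives inside TM segments
  and no true positive in one, so the veto yields (132, 317, 2133, 70), a
  31.4% false-positive reduction.
* `topology_distribution_fixture` — 202 positive sites distributed
  177 E / 22 L / 1 N / 2 uncovered, an 87.6% extracellular share.

## Numerical and design choices

* Gaussian kernel with the 2 sigma^2 denominator; sigma = 5 and
  all-centers are fixed model constants.
* lambda = 0 default honors exact interpolation; the weight solve uses an
  LAPACK least-squares solve at lambda = 0 and the normal equations
  otherwise; agreement with a dense oracle solve is tested to 1e-8 at k = 200.
* No bias node, no class rebalancing, no output calibration.
* Anchor F-score ties and forward-selection BAcc ties are broken
  deterministically (documented above), so discovery is reproducible given
  data, config and fold seed.
* Problem sizes in tests and the acceptance script (30-50 proteins, 40-50
  positive / 300-500 negative sites, 50 anchor-recovery replicates) were
  chosen as the smallest sets at which the imbalance and signal levels above
  are representative; all complete in seconds.

## Known limitations

* The identity gate inherits the local-alignment caveat described above.
* SAAP discovery on the full dataset before cross-validation mirrors the
  standard protocol of this method family but leaks feature-selection
  information into CV estimates; the forward-selection trainer itself is
  fold-honest.
* The per-position F-score aggregates residue indicators by the maximum;
  other aggregations (e.g. encoding-weighted) are possible readings.
* With sigma fixed at 5 on 609-dimensional encodings, kernel values are
  compressed toward 1; the interpolating solve handles this, but scores are
  not calibrated probabilities.
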