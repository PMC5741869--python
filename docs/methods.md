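# Methods

## Consensus model

The package combines per-residue scores from up to five upstream sources
(`crpred`, `discern`, `exia2_rank`, `wcn`, `catsid`) into one ranking score
per residue. The combination is deliberately assumption-light: each
method's scores are z-normalized and the available z-scores are averaged
with a binary availability mask. There is no learned weighting — the model
assumes only that each constituent is positively (if noisily) informative
and that their errors are partly independent, so averaging shrinks the
noise while preserving the shared signal.

Normalization constants μ(j), σ(j) are computed **per protein, per method,
over the residues that method scored**. Per-protein scoping is the only
choice compatible with scoring a single query chain in isolation; scoping
to scored residues only avoids biasing μ toward zero for partially covered
methods. The standard deviation uses the population (n) denominator — the
distinction is negligible at protein length and cannot change any
within-method ranking.

Degenerate normalizations (a single scored residue, or all scores
identical, σ = 0) map every z-score of that method to 0 with a logged
warning: the method then contributes "average" evidence instead of
aborting the consensus. This keeps short chains and constant-score inputs
usable.

Template hits (`catsid`) become a residue score table by summing the
template score over every hit in which a query residue is aligned, with no
template-score cut-off. A residue aligned more than once *within* a single
hit contributes once for that hit — the alternative (counting multiplicity)
is only observable with duplicated template residues and would double-count
a single piece of template evidence.

The rank score (`exia2_rank`) is defined only for the 12 polar/charged
amino-acid types (R, N, D, C, Q, E, H, K, S, T, Y, W); the loader warns if
a rank score appears on one of the remaining 8 types.

## Weighted contact number

WCN_i = Σ_{j≠i} 1/r_ij² over all other residues of the chain, with no
distance cut-off — the canonical inverse-square contact number. The
representative point is the C-α (falling back to the residue's heavy-atom
centroid when C-α is absent); a side-chain-centroid variant is exposed as a
configuration option because contact-number flavours in the literature
differ on the reference point, defaulting to C-α. Altloc conformers resolve
to the highest-occupancy one; hetero residues and waters are excluded. Two
residues at identical coordinates are an error rather than an infinite
score.

## Pocket boost

Pockets from two detectors are re-ranked by *poc_sc*, the mean meta-score
of their residues. Residues without a meta-score are excluded from both
numerator and denominator (a 0 placeholder would drag every partially
scored pocket toward 0); a pocket with no scored residue at all scores 0
with a warning. The top 5 pockets per detector (configurable; 5 captures
essentially all catalytic residues recoverable from these detectors) are
pooled and merged.

Merging: two pockets merge when their common residues are at least 50 % of
the **smaller** pocket (configurable to Jaccard). The smaller-set
denominator is the usual convention for "X % of common residues" and makes
nested pockets merge. Merging is applied transitively to closure,
re-testing overlap against current unions, which makes the outcome
independent of input order; merged pockets carry their constituents' ids as
provenance and their *poc_sc* is recomputed on the union, since that is the
pocket actually used downstream. Merging operates on the pooled set from
both detectors, which subsumes within-detector merging.

*poc_Rsc* is the maximum *poc_sc* over the merged pockets containing a
residue and 0 outside all pockets; the boosted score is the plain sum
av-csc + poc_Rsc. Negative pocket scores pass through unclamped by default
— a residue in a genuinely poor pocket is arguably *less* likely catalytic
— but `--clamp-pocket-score` floors poc_Rsc at 0 for users who prefer the
boost to be non-penalizing.

## Ranking and cut-offs

Rankings are by descending score with ties broken by residue position
(chain, number, insertion code) — arbitrary but deterministic and
configurable in principle; ties are measure-zero for continuous scores.
Polar/non-polar subset evaluation filters **before** ranking, so ranks are
within-subset. The two suggested operating points are rank ≤ 20 and a 4 %
filtration ratio; the filtration count is ⌈k·N/100⌉ (ceiling), so a
positive ratio always selects at least one residue even for short chains.
Residues no method scored are appended after all scored residues (flagged
`unscored` in profile output) so a ranking can always cover the whole
chain.

## Evaluation

All statistics sweep the rank cutoff n, calling the top-n residues
positive.

* **ROC**: per-protein (FPR, TPR) points at every cutoff; vertical
  averaging linearly interpolates each protein's TPR on a fixed FPR grid
  (step 0.01 by default, configurable) taking the best achievable TPR where
  several cutoffs share an FPR, then averages across proteins; AUCROC is
  the trapezoid area of the averaged curve.
* **AveS / MAS**: AveS = Σ_r S(r)·pos(r) / Npos with pos(r) = 1 iff the
  residue *at* rank r is catalytic, i.e. the mean specificity evaluated at
  each catalytic residue's own rank. This reading gives AveS = 1 exactly
  for a perfect ranking. MAS is the dataset mean.
* **PR**: per-protein precision between achievable recall levels is
  interpolated with the Davis–Goadrich local-skew rule — true positives are
  added one unit at a time while false positives grow by the local
  increment, giving precision TP/(TP + FP_A + s·ΔTP) — never linearly,
  which is known to overstate PR areas. Below the first achievable recall
  the first positive's precision is carried flat to recall 0. The averaged
  curve takes the mean interpolated precision per grid recall; AUCPR is its
  trapezoid area. AP is the mean precision at each catalytic residue's
  retrieval rank; MAP the dataset mean.
* **RFR / coverage**: mean recall within the top ⌈k·N/100⌉ residues as a
  function of k; and the fraction of proteins whose catalytic-residue
  coverage reaches 0.5 / 0.8 / 1.0 at each rank r ≤ 100.
* **Method comparison**: two-sided Wilcoxon signed-rank test on paired
  per-protein AveS (or AP) values; zero differences are dropped, at least 6
  informative pairs are required, and an all-zero difference vector returns
  p = 1 with a warning.

Proteins with no annotated catalytic residue are excluded from dataset
averages with a logged count (AveS and AP are undefined at Npos = 0).
Evaluation requires the ranking to contain every gold residue; rankings
from partially covering methods are completed by appending unscored
residues (see above) before evaluation.

## Synthetic benchmark

The generator emulates the statistical structure the consensus exploits,
not protein chemistry:

* chain length uniform in 60–250 (desk-scale while spanning the length
  range where rank statistics behave like real chains);
* catalytic-residue count drawn from N(3.3, 1.9), truncated to
  [1, length/3] — the count statistics of curated catalytic-site
  benchmarks;
* 92 % of catalytic residues drawn from the polar/charged types, matching
  the observed predominance (> 90 %) of polar/charged catalytic residues;
* per-method raw scores N(δ_j, 1) for catalytic and N(0, 1) for
  non-catalytic residues, with per-method coverage masks and the 12-type
  restriction for the rank score. The default effect δ = 1.0 is calibrated
  so a single synthetic method's ranking quality lands in the MAS range
  reported for real constituent predictors on curated benchmarks
  (≈ 0.79–0.91); at that setting the full pipeline reproduces the published
  regime qualitatively (consensus MAS ≈ 0.94, boosted ≈ 0.96, pooled median
  catalytic rank improving from 5 to 4). Substantially larger effects
  saturate the task — nearly every catalytic residue ranks in the top 2 —
  and rank-based comparisons lose resolution to ties;
* coordinates from a 3.8 Å self-avoiding random walk (no non-adjacent pair
  closer than 3 Å): geometrically plausible for contact-number computation
  only;
* per detector, 5–8 pockets: one "true" pocket containing each catalytic
  residue with probability `pocket_enrichment` (default 0.9) plus random
  fillers, independently perturbed per detector so the two true pockets
  overlap but differ, and contiguous random decoys; `pocket_enrichment = 0`
  removes the preferential placement entirely (chance membership);
* template hits constructed as one single-residue template per scored
  residue, so summing them reproduces the generated `catsid` table exactly.

Everything is reproducible from (seed, protein index) via independent
generator streams.

**What passing on this benchmark does and does not show.** The generator
plants exactly the kind of signal the consensus assumes: independent,
Gaussian, equal-variance method scores and a single enriched pocket. Passing
demonstrates the machinery is correct and that averaging and pocket
boosting behave as designed under those assumptions; it does not
demonstrate performance on real enzymes, where constituent errors are
correlated, score distributions are heavy-tailed, coverage is structured
rather than random, and pockets are imperfectly detected.

## Numerical choices and limitations

* Curve grids default to step 0.01 on [0, 1]; areas are trapezoid.
* Tie-breaks (ranking by residue position; pocket selection by native rank
  then id) are deterministic everywhere; the whole pocket stage is a pure
  function of its inputs.
* The gold-annotation dialect carries no insertion codes; chains whose
  catalytic residues sit on inserted positions need the generic
  score-table/pocket dialects, which do.
* Structures are read from PDB-format files only (first model); upstream
  predictors and pocket detectors are not executed — their outputs are
  inputs, in the documented dialects.
* Per-protein ROC/PR evaluation requires complete rankings; methods that
  rank only a residue subset are evaluated with unscored residues appended
  in position order, which is a conservative convention for them.
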