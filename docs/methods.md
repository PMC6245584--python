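# Methods

## Model

`codac` treats annotation transfer as bipartite link prediction inside a
tripartite graph G(X, Y, Z, E). Two dense evidence layers G₁(X, Z, E₁) and
G₂(Y, Z, E₂) connect the two target vocabularies to a shared item set Z;
the target layer G₃(X, Y, E₃) is sparse but reliable. The modelling
assumption is that a true direct association (x, y) manifests as
correlated neighbourhoods: N(x) ≈ N(y) in Z. Candidate edges are scored by
the cosine of the 0/1 neighbourhood vectors,

    C(x, y) = |N(x) ∩ N(y)| / sqrt(deg(x) · deg(y)),

computed as the sparse matrix product of the row-normalised biadjacency
matrices. Zero-degree items score 0 against everything (the normalised zero
row is kept as zeros, never NaN). Pairs without a common neighbour are not
materialised; the dense |X|×|Y| product never exists in memory.

Implicit assumptions worth stating: edges are unweighted and symmetric in
evidence value; Z items are exchangeable once redundancy clustering has
collapsed duplicates; and the known layer E₃ is *correct but incomplete* —
it is used as positives for calibration, never as negatives.

## Evidence combination

Each evidence dataset d yields its own score matrix Cᵈ over its own Z. The
consensus is the weighted average CS = Σ w_d Cᵈ / Σ w_d over the union of
the per-dataset vocabularies, with Cᵈ(x, y) = 0 where dataset d has no
entry for the pair. Dividing by the full weight sum (not the number of
datasets with data) keeps that zero-fill semantics literal and makes CS
invariant under uniform weight rescaling — consequently only weight
*ratios* matter, which the weight search exploits by evaluating rankings of
the weighted sum directly.

Weights live on the grid 1.0, 1.1, …, 10.0 and are chosen to maximise the
ROC AUC (Mann–Whitney midrank form, ties credited 0.5) of the known
positives ranked against *all other scored pairs*. Known pairs absent from
every dataset enter the ranking at score 0, so weightings that drop
positives are penalised. Two search strategies exist: exhaustive grid
enumeration (allowed for ≤ 3 datasets) and the default coordinate ascent —
start at all-equal weights, sweep one weight at a time over the grid in
dataset input order taking the first grid value achieving the sweep
maximum, stop when a full cycle changes nothing (capped at 20 cycles).
Because the current value is always among the sweep candidates, the final
AUC can never fall below the equal-weights AUC; on two-dataset problems the
sweep provably explores every weight ratio and empirically matches the
full 91² grid (tested on random instances).

## Calibration against a shuffled null

Negatives are manufactured, not assumed: each dataset's G₁ and G₂ are
shuffled by random double-edge swaps (10·|E| attempts), which preserve
every node degree by construction, followed by targeted swaps that remove
any edge still coinciding with an original one; the procedure restarts up
to `max_tries` times and reports infeasibility otherwise (a complete
bipartite graph, for instance, admits no non-overlapping rearrangement).
Scoring the shuffled graphs with the fitted weights gives the chance-level
score distribution; |N| = |P| negatives are sampled uniformly from its
nonzero entries, excluding known pairs.

For thresholding, positives carry their real consensus scores and
negatives carry the shuffled-consensus scores they were sampled with —
using real-matrix scores for negatives would collapse almost all of them
to zero and make the calibration trivial. The gold standard is split
half/half into Training and Test, stratified by label (Training takes the
extra item on odd counts). The decision threshold scans the grid 0.000,
0.001, …, 1.000; a pair is predicted positive iff score > t (strict,
uniformly — the same strict rule is used in the final filter and in the
p < α significance call). The selected t maximises the Training
F-measure, F₁ = 2RP/(R+P), with F₁ defined as 0 whenever R+P = 0.

**Tie-break.** The maximal-F₁ plateau is typically wide. Its lower edge
hugs the maximum of the sampled negatives — but |N| = |P| samples
under-represent the tail of the full unlabelled background, so that edge
lets background pairs through. Its upper edge hugs the minimum of the
training positives and generalises poorly when |P| is small. We therefore
take the *midpoint* of the plateau (the median grid index among thresholds
achieving the maximum): a maximum-margin choice that behaved best across
both regimes in held-out recovery experiments. The Test-half F-measure at
the selected threshold is reported as an independent check but never used
for selection.

Degenerate inputs are surfaced, not silently absorbed: no known positives,
fewer eligible shuffled candidates than |P|, or an all-zero positive score
vector (F₁ ≡ 0) each raise a dedicated calibration error.

## Significance and quality classes

For each kept edge and each dataset with data for it (both endpoints of
positive degree there), the common-neighbour count K is tested against the
hypergeometric upper tail P(K ≥ K_xy) with parameters (N_z, N_x, N_y) taken
from that dataset's *clustered* graphs — the same graphs that produced the
scores, so N_z is the dataset's post-clustering Z universe. The tail is
evaluated through `scipy`'s survival function (stable up to N_z ≈ 10⁷).
With |E₃*| kept edges tested, Bonferroni sets α = 0.05/|E₃*|; significance
is strict p < α. The edge count entering α is the post-filter,
pre-most-specific count. Classes: **Gold** — every dataset with data is
significant; **Silver** — more than half; **Bronze** — otherwise (exactly
half is Bronze). Datasets without data are excluded from both numerator and
denominator rather than counted as non-significant; a source that never
saw the pair carries no evidence against it.

## Ontology handling

The X vocabulary may sit in a rooted DAG of is_a relations (GO). Only is_a
parents are honoured; part_of and other OBO relations are ignored (the
`relations` argument of `load_obo` makes this configurable). Cycles are
rejected at load time, before any operation runs. Two operations use the
DAG: optional ancestor propagation of the X–Z layer before scoring (each
edge (x, z) also annotates every ancestor of x *already present in the
vocabulary*; idempotent and monotone), and the most-specific filter on
predictions (per Y item, keep the antichain of terms none of whose
descendants is also predicted). Both propagate-then-predict and
predict-then-filter paths are exposed (`propagate` and `most_specific`
miner parameters, both off by default); runs are single-namespace.

## Synthetic data

The generator plants `n_planted` (x, y) associations, assigns each a
dedicated block of Z items (disjoint blocks, `n_z // n_planted` items
each), and links each block item to x and to y independently with
probability `signal` (scaled by a per-dataset quality multiplier); every
possible X–Z and Y–Z edge additionally appears with probability `noise`.
Each Z item is split into 1 + Poisson(`cluster_redundancy`) redundant
copies that partition its edges; the emitted cluster map collapses them
back, so the clustering stage genuinely restores signal rather than merely
relabelling. An artificial layered is_a DAG is built over the X terms with
all planted terms as leaves (so the most-specific filter is exercised), and
a random half of the planted pairs is declared known (the calibration
positives) with the other half held out as recovery ground truth.

Defaults — n_x = 50, n_y = 50, n_z = 500, n_planted = 60, signal = 0.8,
noise = 0.01, 3 datasets, cluster_redundancy = 0.5 — are the package's
study conditions: block signal well above the noise floor but with planted
pairs sharing endpoints (60 pairs over 50 terms), which dilutes cosine
scores exactly the way multi-function domains do. What the generator does
*not* emulate: the heavy-tailed degree distributions of real GO/Pfam
corpora, term-frequency structure within the ontology, correlated (rather
than independent) noise from annotation pipelines, and dataset sizes in
the millions. Passing recovery tests therefore demonstrates correctness of
the machinery and sane calibration behaviour at desk scale, not expected
precision on real corpora.

## Problem sizes and tolerances

The test suite runs oracle comparisons at: cosine vs. set arithmetic on
100 random graph pairs up to 50×50×200 (1e-12); hypergeometric tails vs.
exhaustive subset enumeration for all admissible tuples with n_z ≤ 12
(1e-12); 1000 degree-preserving shuffles; threshold selection vs. an
independent 1001-point grid scan on 50 random gold standards (exact);
AUC vs. pairwise counting on ≤ 200-pair inputs including ties (1e-12);
coordinate ascent vs. the exhaustive 91² grid on 10 two-dataset instances;
and the full pipeline at the study conditions above (held-out F1 ≥ 0.9,
seed 7). These sizes keep the whole suite under a minute of compute while
leaving every oracle exhaustive over its domain.

## Known limitations

- Coordinate ascent is a local search; beyond two datasets it is not
  guaranteed to reach the global grid optimum (it is guaranteed not to
  fall below equal weights).
- The shuffle reports infeasibility after a retry budget; it cannot prove
  that no valid rearrangement exists.
- One calibration (one negative sample, one split) per run; no
  cross-validation beyond the single train/test split, and no
  FDR-style alternatives to Bonferroni.
- Similarity-threshold clustering of Z (e.g. 99 % sequence identity) is
  out of scope; the package consumes a precomputed cluster map and
  synthesises identity maps when none is given. One shared map across
  datasets is the documented default, but a per-dataset mapping is
  accepted.
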