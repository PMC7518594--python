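# Methods

## Problem and objective

Given L omic matrices over a shared sample set (samples may be missing from
some omics), the method searches for disjoint sample modules, each with its
own covered-omic set. Per omic *l* a full signed graph `G_l` is built on the
global sample index; `w_l(u,v) > 0` is evidence that u and v belong together
in omic *l*, `w_l(u,v) < 0` evidence against. A module M is scored
`weight(M) = Σ_{l∈omics(M)} Σ_{unordered pairs u,v ∈ samples(M)} w_l(u,v)`,
and the global objective is the sum of module weights; lonely samples
contribute nothing. Each unordered pair is counted once — an ordered-pair
convention would multiply every module weight by two and cannot change the
argmax, while the per-pair calibration of the constant C below refers to the
unordered mean. The requirement that a weighting scheme emit both positive
and negative weights is structural: with non-negative weights the single
all-sample, all-omic module would be trivially optimal.

Samples unmeasured in an omic have identically zero rows in that omic's
weight matrix, so a partial sample is pulled into modules only by the omics
in which it was actually measured.

## Weighting schemes

### Consensus (default)

For each omic, R = 100 runs are performed (run r seeded `rng_seed + r`; omic
i's base seed is offset by `1_000_003·i` so omics do not share subsample
draws). Each run clusters a uniform 80% subsample of the measured samples
with the pluggable base clusterer, records the co-clustering indicator
`cl_r(u,v)`, and centres it by the run's mean co-clustering rate `avg(cl_r)`
over the run's sampled unordered pairs. The weight of a measured pair is

```
w_l(u,v) = mean_{r : u,v both sampled} ( cl_r(u,v) − avg(cl_r) ) − C + shift
```

with C = 0.2 and shift = 0 by default. Pairs never jointly sampled (probability
≈ (1−0.64)^100 under defaults, i.e. negligible) get weight 0 — no evidence
either way. C trades off coverage: a pair consistently co-clustered in one
omic contributes ≈ `1 − avg − C` there, so larger C demands stronger
within-omic evidence before an additional omic is worth covering. Weights lie
in `[−1−C+shift, 1−C+shift]`.

`global_shift` adds a constant to every measured pair; raising it encourages
fewer, larger modules and lowering it more, smaller ones. It is exposed as a
generic knob and left at 0 everywhere in this package's experiments.

### Base clusterer

The consensus formula only consumes co-clustering indicators, so any
single-omic clusterer can be plugged in (`SingleOmicClusterer` protocol). The
default is spectral clustering with the cluster count chosen by the largest
normalised-Laplacian eigengap in [2, 15], k-means on the row-normalised
embedding, and a kNN-sparsified Gaussian affinity. Two deliberate choices:

* **Global kernel bandwidth** (median distance to the 7th neighbour), not
  per-point local scaling. Local scaling adapts to each point's own density
  and thereby welds diffuse, mutually dissimilar samples into one stable
  "background" cluster; the consensus weights of such samples would then be
  strongly positive, and modules would wrongly cover omics in which their
  samples share no structure. Under a global bandwidth, diffuse samples
  attach inconsistently to whichever genuine cluster is nearest, which the
  consensus centring converts into ≈ −C weights.
* **Per-run feature subsampling** (a random 50% of features per run, seeded).
  Consensus clustering of a *fixed* structureless matrix repeats the same
  chance partition in every run — a known null pathology of consensus methods
  — which would make chance structure look like real structure. Resampling the
  feature space moves the dominant chance directions between runs, so
  spurious partitions do not repeat, while planted structure spread across
  many informative features survives subsetting.

### Gaussian mixture (classification scheme)

Measured samples are projected to 10 principal components and a Gaussian
mixture is fitted with the component count K selected by BIC over 2–10.
Diagonal covariances are the default: PCA scores are decorrelated, and full
covariances (10 dims, ~65 parameters per component) overfit at cohort sizes
of a few hundred, biasing BIC toward merging planted groups. With γ_u the
posterior component vector of sample u and π the mixing weights,

```
w(u,v) = γ_u·γ_v − Σ_k π_k² − C + shift .
```

`Σ_k π_k²` is the co-membership probability of two independent draws, so the
scheme is centred like the consensus scheme and the mean weight over pairs
sits near −C. The fitted projection + mixture is frozen per omic so weights
to *new* samples are computable — this is why classification uses this scheme;
the consensus scheme would need a full re-clustering per new sample and is
deliberately unsupported for classification.

## Search

Seeds: S = 15 seeds are carved iteratively from the omic-summed graph — a
random remaining anchor plus its (up to) k = ⌊n/15⌋ remaining neighbours of
highest strictly positive summed weight, covering all omics; an anchor with
no positive neighbour yields a singleton seed, left for the optimiser to
resolve. Remaining samples start lonely.

Optimisation proceeds in epochs over a fresh random permutation of the
current modules; the visited module's candidate actions are evaluated and
the single best strictly-positive-gain action is applied. Convergence is one
full epoch with no applied action — equivalent, at convergence, to the
uniform random module selection it replaces, but testable. Action kinds, in
the fixed tie-break order (equal gains resolve to the earlier kind, then to
the lowest sample/omic index; the min-degree peel also breaks degree ties by
lowest index):

1. **add samples** — lonely samples join the module; batched greedily up to
   `batch_cap` = 10 (n/50 if n > 1000), each addition individually positive,
   marginal gains updated after each pick;
2. **remove sample** — the member of most negative summed weight leaves;
3. **move samples** — single-sample moves between the visited module and any
   other, in either direction, batched as in (1) with score vectors updated
   after each virtual move;
4. **add omic** / 5. **remove omic** — gain is ± the module's internal pair
   sum in that omic (an omic can be removed only if another remains);
6. **merge** — union of two modules' samples; all four covered-omic options
   (union, intersection, either side's set) are scored;
7. **split** — heavy subgraph of the module's internal omic-summed graph;
   both parts keep the omic set and both must satisfy η;
8. **discard** — the module dissolves; each sample moves to the module of
   highest (non-negative) summed weight under that module's omics, else
   lonely; the recorded gain is the exact objective delta, including pair
   weights among co-moved samples;
9. **new module** — heavy subgraph per omic over the lonely samples; the
   heaviest result forms a single-omic module if it has ≥ η samples and
   strictly positive weight;
10. **split by adding an omic** — for each uncovered omic, the heavy subgraph
    of the module's induced graph in it becomes a sibling module that
    additionally covers that omic;
11. **split with an omic** — as (10) over covered omics; the extracted part
    covers only the splitting omic.

η = max(round(n/30), 10) is the minimum module size: no action may shrink a
module below it, and split parts must satisfy it (for (10)/(11), only
non-empty parts). Seeds may start below η; if an undersized module survives
to convergence (possible, because discard requires strictly positive gain) it
is force-dissolved by the discard rule and optimisation resumes once — the
forced dissolution is a feasibility repair, not a greedy action, and is
logged as a separate objective-trace segment since it may lower the
objective. Within each trace segment the objective is strictly increasing,
and it is bounded above by the sum of positive weights, so the search
terminates; `max_epochs` = 10000 is a pure safety net.

Heavy subgraphs use min-weighted-degree peeling in the spirit of Charikar's
densest-subgraph 2-approximation: remove the minimum-degree node until none
remain and return the heaviest of the nested subgraphs visited (empty set
included, so an all-negative graph returns nothing; among zero-weight ties
nothing is returned, among positive ties the larger set wins). On random
graphs of ≤ 12 nodes with a planted positive clique the peel provably-by-test
matches exhaustive enumeration; in general it is a heuristic.

The whole search restarts 15 times (restart i seeded `rng_seed + i`; graphs
are built once) and the best objective wins, ties to the earliest restart.
All randomness flows from two integer seeds (weighting, search), making runs
bit-reproducible.

## Significance filtering

Each detected module is compared against `n_null` = 500 modules of identical
size and omic set assembled uniformly at random from *all* samples (the
module's own samples are eligible — the simplest exchangeable null; the
sampling frame is otherwise unconstrained). The module is kept iff its weight
strictly exceeds the ⌈0.99·500⌉-th (495th) null order statistic. By
exchangeability a truly random module survives with probability
(500−495+1)/501 ≈ 1.2%, which the calibration test confirms empirically. By
default all modules are tested (`minimal_size_only` restricts testing to
modules of size ≤ η, the practical shortcut — larger modules essentially
never fail, so the two scopes coincide at negligible cost). Removed modules'
samples become lonely; retained modules are untouched. No multiple-testing
correction is applied across modules.

## Classification and cross-validation

The association score of sample u with module M is the gain of adding u:
`Σ_{l∈omics(M)} Σ_{v∈samples(M)} w_l(u,v)`, also available per omic as a
diagnostic. A new sample joins the argmax module; it stays lonely only when
*every* score is negative (a score of exactly zero classifies — documented
boundary). The 10-fold harness refits on each fold's training samples and
reports per fold: stability (ARI between the full-data and fold solutions on
shared samples), RFC (ARI after classifying the held-out samples, over all
samples), and — when ground truth exists — preCA (truth vs fold solution on
its samples) and postCA (truth vs classified solution on all samples), plus
the fraction of held-out samples landing in the found module their true
module maps to under maximal-overlap (Hungarian) matching.

ARI is Hubert–Arabie pair counting; because module solutions are partial
partitions, three lonely conventions are provided and reported explicitly:
`own_cluster` (all lonely pooled as one extra cluster — the headline
convention), `singleton_cluster`, and `exclude` (drop samples lonely in
either labelling).

## Synthetic data

The generator plants k modules of given sizes over L omics with a boolean
coverage matrix. In an omic a module covers, its samples' informative
features (default 30 of 100) are drawn N(μ, sd²) around a module-specific
offset μ whose entries are ±`effect_size`·sd (default 2.5·1.0) with fresh
random signs per module; modules can be forced to share μ in an omic
(`shared_mean_groups`), making them indistinguishable there, and omics can
be flagged *weak* (default 5 informative features at effect 1.0).

Samples of modules *not* covering an omic, and outliers everywhere, are
**unstructured**: each draws its informative features around an independent,
sample-specific random offset of the same magnitude. This is a deliberate
definition of "background". Drawing all unstructured samples from one fixed
distribution would concentrate them into a tight cluster — genuine shared
structure, the opposite of what "this module has no signal in this omic"
means — and no clusterer could be faulted for finding it. Per-sample offsets
make unstructured samples mutually dissimilar and roughly equidistant from
everything, which is the intended semantics.

Two presets reproduce the benchmark designs: `sim1` (five 60-sample modules
over two omics — coverage rows (1,0), (0,1), (1,1), (1,1), (1,1) — plus five
outliers; 305 samples) and `sim2` (five 30-sample modules over three omics;
module 1 distinct everywhere, modules 2–5 share a mean in omic 1, are weakly
separated in omic 2 and clearly separated in omic 3; `include_omic3=False`
drops omic 3). `make_partial` hides samples from omics either independently
(a fraction per omic, never leaving a sample measured nowhere) or in the
three-group style used for three-omic cohorts (a fraction of samples split
into three groups, each removed from one omic).

What passing on this generator does and does not show: the planted data are
Gaussian with homoscedastic noise, independent features and exactly equal
module sizes; real omics have heavy tails, correlated features (the feature-
subsampling argument weakens under strong feature correlation), batch
effects and count distributions. Recovery here validates the machinery —
weighting calibration, coverage selection, search and filtering — not
robustness to real-data marginals, which should be addressed by
omic-appropriate preprocessing (the loader offers per-feature
standardisation; count models are out of scope).

## Defaults and problem sizes

C = 0.2, R = 100, subsample fraction 0.8, S = 15, k = ⌊n/15⌋,
η = max(round(n/30), 10), batch cap 10 (n/50 if n > 1000), 15 restarts,
500 nulls at the 1% level. The test-suite runs the two preset designs at
their full sizes (305 and 150 samples, 5 generator seeds each) with these
defaults; auxiliary robustness checks (partial data, cross-validation) use
reduced R (30) and restarts (3–4) on the same or smaller designs — choices
made to keep the suite brisk while leaving the defaults untouched where the
benchmark numbers are computed. `scripts/acceptance.py` recomputes the two
headline ARIs at full defaults.

## Known limitations

* The optimisation is heuristic; only a local maximum per restart is
  guaranteed, and complexity is O(L²n²) per epoch on full graphs, practical
  to a few thousand samples.
* The Gaussian-mixture scheme is a documented reconstruction built around
  posterior co-membership; other soft-clustering schemes would slot into the
  same interface.
* Classification is defined only for weighting schemes with frozen models
  (the consensus scheme would require re-clustering).
* The significance null is exchangeable-uniform over samples; it does not
  condition on, e.g., per-sample measurement patterns in partial datasets.
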