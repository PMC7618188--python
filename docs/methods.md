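# Methods

## Graph construction

Lesion masks are analysed on a common grid (default 4 mm isotropic). Each
patient's binary mask yields an adjacency edge for every pair of lesioned
voxels that are spatial neighbours under 26-connectivity; no self-loops.
Restricting edges to spatial neighbours keeps the graph sparse (node degree
≤ 26) and matches the edge densities this kind of analysis reports; a
`clique` switch joins *all* co-lesioned pairs for tiny inputs.

Accumulated over the cohort, each edge carries a lesion co-occurrence count
`A_lesion = Σ_k A^k` and a task weight `A_task = Σ_k A^k / t_k` where `t_k`
is the behavioural score; patients with `t_k = 0` are excluded from the
task sum. Nodes are then filtered to the best-sampled half (unweighted
degree at or above the median, ties retained), nodes left with fewer than
three connections are dropped in a single pass, and both channels are
min-max rescaled to [0, 1] over the retained edges (constant channels map
to zero). Filtering precedes rescaling. Each edge contributes one entry
per nonzero channel to a two-layer graph: layer 0 lesion (counts carried
alongside; declared Poisson-family), layer 1 task (real-valued, declared
Gaussian). The null model permutes the layer labels over the edge entries,
conserving the weight multiset and per-layer entry counts.

## Description length

A flat partition `b` with `B` non-empty blocks of sizes `n_r` costs

```
S = ln N + ln C(N−1, B−1) + ln N! − Σ_r ln n_r!          (partition)
  + Σ_l Σ_{r≤s} [ ln(N_rs + 1) + ln C(N_rs + m − 1, m) ]  (placement)
  + Σ_l Σ_{r≤s} W(values in group)                        (weights)
```

where `N_rs` is the number of available node pairs between blocks `r` and
`s`, `m` the layer-`l` entry count in the group, and `W` a conjugate
normal-inverse-gamma code (prior mean 0.5, prior scale 0.25, one
pseudo-observation) for the entry values, quantised at δ = 0.01 of the
rescaled range. The multiset placement code keeps the null well defined
when randomisation puts both of an edge's entries into one layer.

Both layers' weight terms use the same real-valued code on the rescaled
values. The declared per-layer families (Poisson counts / Gaussian reals)
describe the channels' data types, but a *common* code is what makes
`S_null − S_layered` a coherent comparison: the two graphs then differ
only in how the identical multiset of values is grouped. Under a null
cohort (no behavioural effect) the task channel is, edge for edge, nearly
a rescaled copy of the lesion channel, so layered and null description
lengths agree closely; a genuine deficit decouples the channels around the
critical substrate and the layered grouping codes measurably shorter. A
count-specific code for the lesion layer would destroy this comparability
(the null mixes count-typed and real-typed entries within a layer) — this
is a deliberate deviation from modelling the lesion layer with a count
code, recorded here as the package's design choice.

## Fitting and the null comparison

Fitting is annealed MCMC over partitions: sequential greedy insertion
(agglomerative initialisation), then sweeps of single-node moves (90%
proposals to a random neighbour's block, otherwise to a uniform block
including a fresh one) and block merges, accepted by Metropolis on ΔS with
the inverse temperature swept geometrically over `beta_range` (default
1 → 10, cyclically, so the chain reheats and re-converges). The sampler
terminates when no new record-low `S` appears for `wait` sweeps (default
100, capped at `max_sweeps`), then applies a deterministic polish
(best-single-move hill-climbing plus greedy merges) from the record-best
partition. Runs are exactly reproducible given the seed.

At desk scale the gap `S_null − S_layered` (tens to hundreds of nats) is
comparable to the spread of the stochastic search across seeds, so the
null comparison is *matched*: both graphs are fitted independently, each
is additionally polished from the other's best partition, and each side's
description length is the minimum over the shared candidate pool. The
reported odds then measure how well each layer assignment codes under the
best partitions found, not which search got luckier. Two residual
properties follow and are worth knowing: (i) under a null cohort the odds
sit slightly *below* zero (≈ −0.02% of S), because the null graph's
randomised layers contain exploitable chance structure that its own fit
can overfit — a conservative bias; (ii) the positive odds under a true
effect are correspondingly understated.

## Block screening and back-projection

For each lowest-level block, the incident entries' task and lesion weights
are compared. Each channel is first standardised over all entries of its
layer, because min-max anchors differ between channels cohort by cohort
and would otherwise swamp block-specific structure with a global offset.
The test statistic is the per-node paired difference (mean incident task z
minus mean incident lesion z), averaged over the block's nodes; node-level
aggregation is used because raw edge arrays are heavily pseudo-replicated
(each patient contributes many edges, each edge is incident to two nodes),
making edge-level t-intervals degenerate at realistic edge counts. The raw
edge-array variant of the test remains available (`unit="edge"`).

Retention is calibrated against layer permutation: the same partition is
re-evaluated on (default) 20 layer-randomised copies of the graph, and a
block is retained when its paired-difference t-interval lies beyond the
typical (median over permutations) largest absolute gap any block shows
under randomisation — a familywise reference that adapts to cohort and
graph size, unlike a fixed significance level, which saturates into
retaining everything at these sample sizes. No multiple-comparisons
correction is applied beyond this, a sensitivity-maximising choice.
Retained task-dominant blocks are back-projected: every voxel of such a
block receives the block's mean (raw, rescaled) task weight.

## ROI comparison

A candidate ROI is extracted from a (pseudo) meta-analytic z map by strict
thresholding at z > 3.1 and 26-connected component labelling, keeping the
largest component whose voxel majority falls within the requested
anatomical label (default: medial wall). Patients × voxels binary damage
matrices for the SBM-inferred support (any retained task weight > 0), the
ROI, and both, are reduced to five principal components each
(column-centred PCA; the combined model concatenates the two score sets).
Scores are regressed on the components under a Gaussian likelihood with a
Zellner g-prior (`g = n` unit-information default, intercept excluded from
shrinkage, Jeffreys prior on the noise variance) by single-chain Gibbs
sampling, 10 000 kept draws after 10 000 burn-in. Candidates are ranked by
`WAIC = −2(lppd − p_waic)`; a crude lag-1 effective-sample-size check is
logged instead of multi-chain diagnostics.

## Synthetic study conditions

The default template is a 24³ grid at 4 mm with an ellipsoidal brain
(~5400 voxels) split into left/right frontal and posterior compartments
plus a two-voxel-thick anterior medial wall. Pathology archetypes emulate
vascular territories: a broad left-frontal territory elongated from the
lateral convexity to the medial wall (median 12 cm³, 35% of patients)
plus two focal branch archetypes at the lateral pole and the medial wall
(median 7 cm³, 10% each), and three further territories (right frontal,
left/right posterior, 15% each, median 10 cm³). Lesion volumes are
log-normal (σ = 0.7–0.8) and growth is stochastic 26-neighbourhood
accretion biased by the territory field with a mild random anisotropy, so
lesions are connected, irregular and territory-like.

The planted critical substrate is a ~94-voxel lateral prefrontal ball; the
decoy is a ~112-voxel medial-wall patch. Both lie in the broad territory,
so they are co-lesioned by the same pathology (overlap-fraction
correlation across patients ≈ 0.2–0.5 under the default mix, > 0.5 when a
single spanning territory is used); the branch archetypes supply patients
who damage one but not the other — the coverage variability that makes
disentangling possible at all. Scores are
`max(0.5, baseline − β·overlap + ε)` with baseline N(100, 10), noise
N(0, 5) and β = 20, i.e. destroying the whole substrate costs about two
standard deviations of performance; the 0.5 floor keeps inverse weights
finite. Covariates (age, sex, education) are generated but unused.

What the generator does **not** emulate: registration error, aetiology
differences (tumour vs stroke), mass effects, multi-focal damage,
behavioural floor/ceiling effects, and any true hierarchical vascular
anatomy beyond the two branch archetypes. Passing tests therefore show
that the machinery behaves as designed under its own assumptions, not that
it is validated on clinical data.

## Resolution limits at desk scale

With median lesion diameters around 6–8 voxels, deficit attribution is
intrinsically smeared: voxels adjacent to the substrate are damaged almost
whenever the substrate is, and their incident edges genuinely carry
elevated task weights. The fitted partitions do isolate substrate-heavy
blocks (an oracle allowed to pick blocks by ground-truth purity reaches
Dice ≈ 0.65–0.7 with the substrate), but any truth-blind retention rule
must also accept the immediately adjacent halo blocks whose elevation is
real, merely mediated. Median substrate Dice of the retained map at the
default conditions is therefore ≈ 0.35 rather than the ~0.5 the block
oracle would allow, while decoy Dice stays ≈ 0 — the qualitative
disentangling (lateral substrate in, medial decoy out) is robust even
where voxel-precise recovery is not.

## Numerical choices and degenerate inputs

Weight-code quantisation δ = 0.01; NIG prior (μ₀ = 0.5, κ₀ = 1, α₀ = 1,
β₀ = 0.0625). Blocks with fewer than two testable units per channel are
flagged untestable and never retained. Constant weight channels rescale to
zero. Empty lesion masks warn and contribute no edges; cohorts whose
scores are all zero are rejected. Ties in WAIC ranking are broken by
declared candidate order and flagged. The per-stage seeds are derived from
the master seed through named spawn keys of a `SeedSequence`, so every
artifact is reproducible from the config alone. The description length is
maintained incrementally inside the sampler and re-synchronised against a
full evaluation every 25 sweeps to bound floating-point drift; the
vectorised evaluator and the kernel agree to ~1e-8 and the test suite
checks it.

Problem sizes used by the test suite (20 cohorts of 150 patients for the
disentangling checks, 10 for null calibration, 50 tiny graphs for the
exhaustive-oracle sweep) were chosen to keep a full run in the tens of
minutes on one core while leaving the Monte-Carlo margins interpretable.
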