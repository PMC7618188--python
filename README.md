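# lesiongraph

Graph lesion-deficit mapping with layered weighted stochastic block models.

## The problem

Classical voxel-based lesion-symptom mapping asks, voxel by voxel, whether
damage predicts impaired behaviour. That mass-univariate view is blind to a
structural confound: lesions are not sprinkled independently over the brain
but generated by pathological processes (e.g. infarction of a vascular
territory) that damage whole sets of voxels together. A region that is
merely *co-lesioned* with the true neural substrate of a task will show a
spurious lesion-deficit association.

`lesiongraph` implements a network formulation of the problem. Each voxel
of the analysis grid is a node; an edge joins two neighbouring voxels that
were damaged together in at least one patient, and carries two weights
accumulated over the cohort of `N` patients with lesion adjacency matrices
`A^k` and behavioural scores `t_k`:

```
A_lesion[i,j] = Σ_k A^k[i,j]              (lesion co-occurrence count)
A_task[i,j]   = Σ_k A^k[i,j] / t_k        (inverse-score task weight,
                                           summed over patients with t_k ≠ 0)
```

The two channels are assigned to separate layers of a layered weighted
stochastic block model (SBM) fitted by minimum-description-length (MDL):
the partition of voxels into blocks is chosen to minimise the total cost
`S` (in nats) of encoding the partition, the per-layer edge placement, and
the per-layer edge weights within each block pair. The fitted `S` is
compared with that of a *null* graph in which the two kinds of weight are
randomly redistributed across the layers; the difference
`S_null − S_layered` is the natural-log posterior odds that the split of
weights into a lesion layer and a task layer captures real structure.
Blocks whose incident task weights exceed their lesion weights beyond what
layer randomisation produces are retained and back-projected into brain
space as the task-critical map. Finally, the marginal predictive value of
any candidate region of interest (ROI) is tested by Bayesian linear
regression of the behavioural score on principal components of regional
damage, under a Zellner g-prior, ranked by WAIC (smaller is better).

Because clinical lesion cohorts are rarely shareable, the package ships a
first-class synthetic cohort generator: vascular-territory-like pathology
archetypes grow connected lesions by stochastic accretion; scores degrade
in proportion to overlap with a planted critical substrate; and a decoy
region is co-lesioned with the substrate but causally irrelevant — the
exact confound the layered model is designed to reject.

## Worked example

```python
from lesiongraph.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(master_seed=11, output_dir="out"))
print(report["graph"], report["log_posterior_odds"],
      report["dice_substrate"], report["dice_decoy"])
```

A run at the default study conditions (24³ grid at 4 mm, 150 synthetic
patients, ~2 SD substrate effect) printed:

```
{'n_nodes': 1769, 'n_edges': 17913} 54.05605017024209 0.33707865168539325 0.057971014492753624
```

meaning: the filtered cohort graph had 1769 voxels and 17 913 edges; the
layered model coded the graph 54 nats more compactly than its
layer-randomised null (posterior odds e^54 in favour of genuine layering);
the retained task-dominant map overlapped the planted substrate with Dice
0.34 while the co-lesioned decoy was essentially excluded (Dice 0.06). The
same report carries the WAIC comparison of the SBM-inferred region, the
decoy ROI and their combination (per-candidate `waic`, `lppd`, `p_waic`
and rank).

The command-line interface exposes the same stages
(`lesiongraph simulate | build-graph | fit | localize | compare | run-all`).

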