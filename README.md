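# spnnet

Graph-theoretical analysis of whole-brain functional networks from
event-related task fMRI, built around normalized-mutual-information
connectivity, percolation-thresholded weighted graphs, modular
decomposition, and a hub taxonomy. It targets case-control task-fMRI
studies (for example a picture-naming speech-production paradigm in
Parkinson's disease patients versus healthy controls), where per-subject
ROI time series are turned into condition-specific group networks and
compared with permutation statistics. A synthetic cohort generator with
planted modular structure, hub roles and group attenuation lets every
stage be tested without access to clinical data.

## The model

**Edges.** For each subject and condition, the 4-TR windows of all
correct trials are concatenated and every ROI pair (X, Y) is scored with
normalized mutual information,

    NMI(X, Y) = MI(X, Y) / sqrt(H(X) · H(Y)) ∈ [0, 1],

estimated on a joint equal-width histogram (Rice-rule bin count by
default). NMI is non-negative and captures nonlinear dependence while
preserving the nonzero structure of a correlation matrix.

**Networks.** Subject matrices are group-averaged per condition (after
excluding subjects whose mean connectivity strength falls outside
Tukey's fences) and thresholded at the percolation point: the largest
edge weight τ* such that deleting all edges weaker than τ* still leaves
the giant connected component intact. Weights are preserved, not
binarized.

**Metrics.** Five network measures summarize integration and
segregation: density, mean nodal degree k̄/N and strength s̄/N
(normalized by node count N), the Onnela weighted clustering coefficient
(geometric mean of triangle weights, scaled by the network maximum), and
global efficiency E = mean of 1/d(i,j) with path length d summing inverse
edge weights.

**Communities and hubs.** Modules maximize the Newman modularity
Q = (1/2W) Σᵢⱼ [wᵢⱼ − sᵢsⱼ/2W] δ(mᵢ, mⱼ) via seeded restarts
(greedy agglomeration and random starts, refined by Kernighan–Lin
single-node sweeps; best of 100 runs). Partitions are aligned across
networks by optimal label assignment and compared with the normalized
variation of information ("partition distance"). Nodes whose degree or
strength exceeds the network mean by more than 1 SD are hubs; hubs are
connector hubs when their participation coefficient
Pᵢ = 1 − Σₘ (sᵢₘ/sᵢ)² reaches 10% of the network maximum, otherwise
provincial. Non-hub nodes in the top 30% of both degree and strength are
high-influence nodes; hubs at ≥ 1.5 SD are network pillars. Category
frequencies are compared across networks with a χ² test of homogeneity,
and metric differences with permutation t tests (20,000 randomizations
by default, exact enumeration when feasible).

## Worked example

Simulate a small cohort (60 ROIs, 4 planted modules, 8 + 8 subjects,
30% connectivity attenuation in the second group) and run the full
pipeline:

```bash
spnnet simulate --out demo/data --seed 3 --attenuation 0.3
python - <<'EOF'
from spnnet import PipelineConfig
PipelineConfig(data_dir="demo/data", out_dir="demo/out", n_modularity_runs=10,
               n_permutations=999, n_subject_permutations=49, seed=1).to_yaml("demo/config.yaml")
EOF
spnnet run-all --config demo/config.yaml
```

which prints

```
groupA/neutral: density=0.2051 E=0.1307 Q=0.7279
groupA/disgusted: density=0.1938 E=0.1230 Q=0.7574
groupB/neutral: density=0.0932 E=0.0827 Q=0.7455
groupB/disgusted: density=0.1226 E=0.0914 Q=0.7170
```

The attenuated group B yields sparser, less efficient networks at a
similar modularity. `demo/out/comparisons.json` holds the node-level
permutation tests — for the neutral-condition group contrast:

```
degree_norm    0.2017 vs 0.0917  p=0.001
strength_norm  0.0620 vs 0.0238  p=0.001
clustering     0.7388 vs 0.4601  p=0.001
efficiency     0.1307 vs 0.0827  p=0.001
```

i.e. the planted 30% attenuation reproduces the expected pattern of
reduced integration and segregation in the "patient" group, while the
partition distance between the group networks is 0.0 (both recover the
planted modules). The output directory also contains per-network
node-metric and hub-profile TSVs, partition tables, BrainNet Viewer
`.node`/`.edge` exports and a run log keyed by config digest and master
seed.

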