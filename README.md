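# symnet

Network analysis of binary symptom records. Given a case × symptom 0/1
table with a per-case group label, `symnet` estimates a sparse Ising
symptom network per group (eLasso: node-wise L1-regularised logistic
regression, EBIC model selection with γ = 0.25, AND-rule), computes
weighted node centralities (strength, harmonic closeness, betweenness),
detects symptom clusters with a Walktrap-style random-walk agglomeration
cut at maximum modularity, quantifies accuracy and stability with edge
bootstraps and the case-dropping correlation-stability (CS) coefficient,
and compares two groups with a permutation network-comparison test
(structure M, global strength S, per-edge tests) after size-matching
subsampling.

Because real clinical symptom records are typically access-restricted,
the package ships a first-class synthetic-data module: a Gibbs sampler
for {0,1} Ising models (so ground-truth parameters live in exactly the
parameterisation the estimator recovers), planted-cluster network
generators for recovery tests, and independent-Bernoulli fixtures at
specified marginal occurrence rates.

## Layout

| module | contents |
| --- | --- |
| `symnet.core_data` | data model, delimited-text I/O, occurrence screening, occurrence/group-comparison table |
| `symnet.synthetic_data` | Gibbs sampler, planted networks, Bernoulli fixtures |
| `symnet.ising` | eLasso estimation, EBIC, Spearman density Σs, global strength, network I/O |
| `symnet.metrics` | centrality table and core-symptom selection |
| `symnet.communities` | Walktrap, modularity, core cluster, partition comparison (ARI) |
| `symnet.resampling` | edge bootstrap CIs, case-dropping CS coefficient, bootstrapped difference tests |
| `symnet.comparison` | subsampling + permutation network-comparison test |
| `symnet.pipeline` / `symnet.cli` | full-run orchestration, JSON run report, CLI |

## CLI

All tables are tab-separated; metadata is JSON; every source of
randomness takes an explicit seed.

```bash
symnet screen data.tsv --out screened.tsv                # 1%/99% occurrence screen
symnet occurrence screened.tsv --out occurrence.tsv
symnet estimate screened.tsv --out-prefix net            # net_edges.tsv, net_thresholds.tsv
symnet metrics --edges net_edges.tsv --thresholds net_thresholds.tsv --out centrality.tsv
symnet communities --edges net_edges.tsv --thresholds net_thresholds.tsv --out clusters.tsv
symnet stability screened.tsv --seed 7 --out-prefix stab
symnet compare group_a.tsv group_b.tsv --seed 7 --out nct.json
symnet run --config config.json                          # full pipeline
```

A full-pipeline config is a JSON document mirroring
`symnet.pipeline.PipelineConfig` (input path, group labels, screening
bounds, γ, walk length, bootstrap sizes, permutation count, seeds,
output directory). The run writes, per group: occurrence table, edge
list + thresholds, centrality table, community membership, bootstrap
summaries; plus the comparison results and a top-level `report.json`
(sample accounting, core symptom and core cluster per group, density Σs,
global strength, CS coefficients, seeds, versions). Reruns with the same
config are byte-identical.

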