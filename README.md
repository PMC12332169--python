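# netmediator

Sample-specific network mediator analysis for two-group expression
cohorts. Given a gene × sample expression matrix, a case/control split
and a protein–protein interaction network, the pipeline identifies
**central genes** — genes that mediate global transcriptomic differences
between the two groups even when their own fold change is small:

1. **Node weights** (per case sample): signed log2 fold change against
   the control median, a local-linear tricube (loess-style) fit of
   |log2FC| against control expression, and the positive residual
   (observed − expected) plus a small floor as the weight.
2. **Path scoring**: weights are mapped onto the interactome; each edge
   (u, v) costs `1/sqrt(ŵ_u·ŵ_v)` with weights normalized by their
   maximum, so cheap paths traverse consistently high-weight nodes.
   Minimum-cost paths are computed between the top-weight terminal
   nodes.
3. **Permutation null**: node weights are shuffled over nodes 200 times
   and each pair's shortest-path cost recomputed; plus-one p-values are
   BH-adjusted and significant paths form the per-sample **TopNet**.
4. **Ripple centrality**: `r(v) = sqrt(R_out·R_in)/(n−1)` on the
   directed TopNet; the per-sample top-100 genes are aggregated by
   frequency across case samples into the final central-gene table.

Downstream utilities: differential expression (Welch / moderated t) with
top-k DEG selection, hypergeometric over-representation against GMT
collections, Fisher-exact overlap with reference gene lists
(odds ratio in an explicit 20,000-gene background), Jaccard redundancy
reduction, single-cell cell-type overlays (ANOVA, z-scoring,
log observed/expected expressed fractions), cross-validated classifier
evaluation (AUROC/AUPRC/F1, bootstrap CIs, DeLong's test) and hub-gene
selection with drug-target annotation. A synthetic-data module generates
cohorts with planted DEGs and network mediators, scale-free networks and
over-dispersed single-cell matrices for testing all of the above.

## CLI

All stages are subcommands of `netmediator`:

```sh
# synthetic inputs (expression, groups, network, truth tables)
netmediator simulate --seed 7 --out data/

# individual stages
netmediator ingest  --expr data/expression.tsv --groups data/groups.tsv \
                    --network data/network.tsv --min-conf 0.7
netmediator deg     --expr ... --groups ... --method moderated --out degs.tsv
netmediator weights --expr ... --groups ... --sample case000 --out w.tsv
netmediator pathext --expr ... --groups ... --network ... --sample case000 \
                    --nperm 200 --alpha 0.05 --seed 11 --out topnet.tsv
netmediator central --expr ... --groups ... --network ... --seed 11 --out central.tsv
netmediator enrich  --genes central.txt --gmt hallmarks.gmt --background universe.txt --out ora.tsv
netmediator overlap --genes central.txt --ref tf_list.txt --background 20000
netmediator sc-overlay --matrix cells.tsv --labels types.tsv --genes central.txt --out overlay.tsv
netmediator classify --expr ... --groups ... --genes central.txt --model svm --out eval.json
netmediator hubs    --genes central.txt --network string_edges.tsv --min-conf 0.7 --top 10

# everything end-to-end from a YAML config (see PipelineConfig fields)
netmediator run-all --config config.yaml
```

To analyse the opposite subtype, swap the case/control labels in the
group file (or use `ExpressionMatrix.swapped_groups()`) and re-run.

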