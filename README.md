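# coexscreen

A differential co-expression network screen for candidate regulator genes.

Starting from a two-group, gene-by-sample expression matrix, the pipeline:

1. calls differentially expressed genes (DEGs) — Welch test on the
   normalized log-scale matrix, Benjamini–Hochberg FDR, call at
   FDR < 0.05 and |log2FC| > 1 (a precomputed DEG table can be supplied
   instead);
2. scores user-supplied GO / pathway gene sets (GMT) for DEG
   over-representation (one-sided Fisher exact + χ²) and selects network
   genes: DEGs belonging to at least one significant GO term *and* one
   significant pathway (raw Fisher P < 0.01), plus the 30 highest-|log2FC|
   lncRNA-biotype genes;
3. builds one signed co-expression network per group: all-pairs Pearson
   correlation over that group's samples, analytic two-sided p-values from
   the t-transform (df = n − 2), BH-FDR across all pairs, edges kept at
   FDR < 0.01;
4. computes per-gene degree and core number in each group's network, the
   differential statistics dif-degree and dif-kcore (case minus control),
   and a top-k ranking;
5. screens candidates relative to an anchor gene: a gene is a candidate
   iff both |dif-degree| and |dif-kcore| reach the anchor's values
   (componentwise dominance in magnitude, ties allowed).

A synthetic-data module generates two-group matrices with planted DEGs,
planted correlation modules (shared latent factor per module) and
group-specific module activity, so every stage is testable with known
ground truth. Reference values from the published CD274 psoriasis screen
(GEO accession GSE114286) are bundled under `coexscreen.datasets` and used
as fixtures.

## CLI

```sh
# synthetic data with known ground truth
coexscreen simulate --spec spec.yaml --out-dir sim/

# individual stages
coexscreen deg     --matrix matrix.tsv --design design.tsv --out deg.tsv
coexscreen enrich  --matrix matrix.tsv --design design.tsv \
                   --go go.gmt --pathway kegg.gmt --out-dir enrich/
coexscreen network --matrix matrix.tsv --design design.tsv \
                   --genes enrich/network_genes.txt --group control --out net_control.tsv
coexscreen screen  --case-net net_case.tsv --control-net net_control.tsv \
                   --anchor CD274 --out-dir screen/

# full pipeline from a YAML config (thresholds default to the reference
# screen's settings)
coexscreen run --config cfg.yaml
```

Config keys for `run`: `matrix`, `design`, `go_gmt`, `pathway_gmt`,
`out_dir`, `anchor`, plus optional `biotype`, `deg_table`,
`network_genes`, and thresholds (`deg_fdr_max`, `deg_min_abs_log2fc`,
`enrich_p_max`, `edge_fdr_max`, `n_lnc`, `top_k`). Outputs: `deg.tsv`,
`enrichment_go.tsv`, `enrichment_pathway.tsv`, `network_genes.txt`,
`network_{control,case}.tsv/.graphml`, `topology.tsv`, `top_ranked.tsv`,
`candidates.tsv`, `manifest.json`.

## Input formats

- Expression matrix: TSV/CSV, genes in rows, header row of sample ids;
  values are assumed already normalized and log-scaled (no normalization
  is performed).
- Sample design: two-column TSV `sample_id<TAB>group` with groups
  `control` / `case`; at least 3 samples per group.
- Gene sets: GMT (term, description, tab-separated members).
- Optional biotype table: two-column TSV `gene_id<TAB>biotype` with
  biotypes `protein_coding` / `lncRNA` / `other` (needed only when
  `n_lnc > 0`).

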