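# metataxa

Species-level profiling of gut-microbiota communities from near full-length
16S rRNA amplicons — a complete, tested re-implementation of the
*metataxonomics* workflow, driven by a synthetic-data generator so that every
stage is verifiable without external downloads.

Short-read 16S surveys usually bottom out at the genus level. With
near full-length reads (~1,450 nt, PacBio CCS-class accuracy, per-base error
≈ 0.159%) species-level resolution becomes possible, but it requires a
phylogenetic, not purely identity-based, assignment procedure. This package
implements that procedure end to end:

1. **Read QC** — reads with ambiguous bases are removed, positions outside a
   10–1,490 window are trimmed, and a reference-based bimera check removes
   chimeric reads.
2. **OTU clustering** — greedy centroid clustering at the species
   discrimination threshold (98.7% identity; global affine-gap alignment,
   identity = matches / alignment columns, terminal gaps excluded). The most
   abundant sequence of each OTU is its representative.
3. **Phylogenetic placement** — representatives are aligned to a type-strain
   reference profile, columns are screened with a 30% conservational filter,
   Jukes–Cantor distances feed a neighbor-joining reference tree rooted on an
   outgroup, and each query is inserted on the edge minimizing least-squares
   added distance.
4. **OPU / SLP calling** — an *operational phylogenetic unit* is the smallest
   monophyletic clade joining queries to their closest reference (a type
   strain whenever possible). Each OPU is one *species-level phylotype* (SLP)
   and is categorized as a **classified species** (anchored to a type strain
   at > 98.7% identity), a **potential new species** (independent lineage
   within a clear genus), or a **potential new higher taxon** (the anchoring
   clade spans several genera or more; the new rank is one below the lowest
   rank on which the clade's references agree).
5. **Prevalence strata** — SLPs are split into low (< 10%), medium (10–60%)
   and high (> 60%) prevalence groups, with 5%-interval histograms,
   per-individual carriage summaries and probiotic / commensal / pathogen
   role annotation from user-supplied species lists.
6. **Compositional statistics** — count-zero-multiplicative zero replacement,
   CLR transform, Aitchison distances, Ward (ward.D2) clustering with
   silhouette validation, PCoA/PCA ordination, seeded perMANOVA with BH
   adjustment, Dirichlet Monte-Carlo differential abundance (256 posterior
   instances, Welch + Wilcoxon, FDR < 0.05 or |effect| ≥ 1), and
   proportionality networks (ρ > 0.3 or < −0.3) with fast-greedy modularity.

The synthetic generator plants the structure the analysis is supposed to
find: a rank-calibrated reference taxonomy whose identity bands straddle the
98.7% threshold, two community types each dominated by a distinct taxon and
reinforced by co-varying guilds (the P-type / B-type enterotype picture),
three prevalence tiers, sequencing error, optional chimeras, and withheld
"novel" species and genera. See `docs/methods.md` for the model.

## Worked example

```python
from metataxa import PipelineConfig, run_pipeline, prevalence, stratify
from metataxa import evaluation as ev

cfg = PipelineConfig(n_samples=12, depth=300)
res = run_pipeline(cfg, seed=11)

print(len(res.retained_reads), "reads ->", len(res.otus), "OTUs ->",
      len(res.opus), "SLPs")
typing = ev.two_type_recovery(res, seed=1)
print(f"ARI={typing.ari:.2f} silhouette={typing.mean_silhouette:.3f} "
      f"perMANOVA p={typing.permanova_p:.4f}")
```

prints

```
3600 reads -> 40 OTUs -> 40 SLPs
ARI=1.00 silhouette=0.480 perMANOVA p=0.0030
```

The 40 SLPs split into 31 classified species, 6 potential new species and 3
potential new taxa — the planted novelty recovered from reads alone; the
measured per-base error of the simulated reads is 0.159%, and the two planted
community types are recovered exactly (adjusted Rand index 1.0) with a
positive silhouette and a significant community-type effect.

The same stages are available from the shell:

```bash
metataxa simulate --config cfg.json --outdir sim --seed 5
metataxa cluster  --reads sim/reads.fasta --refs sim/refs.fasta \
                  --tax sim/taxonomy.tsv --outdir clust
metataxa opu      --refs sim/refs.fasta --tax sim/taxonomy.tsv \
                  --queries clust/otus.fasta --otu-map clust/otu_map.tsv \
                  --reads sim/reads.fasta --outdir opu
metataxa profile  --table opu/opu_table.tsv --outdir prof
metataxa stats    --table opu/opu_table.tsv --meta meta.tsv --outdir stats
```

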