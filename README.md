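# selectigene

Microbiome-selective gene design.

Microbial communities exchange genetic material constantly through
horizontal gene transfer, so any construct introduced into a microbiome
will eventually be sampled by members it was never intended for.
`selectigene` addresses this at the sequence level: given annotated
genomes partitioned into **wanted hosts** (set A, which should express a
gene of interest) and **unwanted hosts** (set B, which should not), it
engineers three independent layers of the construct so that each layer
carries the same selectivity even if transferred alone:

1. **ORF** — differential codon-usage optimisation. Per-codon weights
   `w_i` are computed per host under CAI (reference-set codon counts,
   `w_i = count_i / max_count` within a synonymous family), tAI
   (`W_i = Σ_j (1 − s_ij)·tGCN_ij` over recognising anticodons), or TDR
   (inverse ribosome-footprint densities); a gene scores
   `exp(mean(log w_i))`. A greedy hill climb over bulk synonymous
   recodings maximises

       f(X′) = α · mean_{a∈A} (CUB_a(X′) − μ_a)/σ_a
                 − mean_{b∈B} (CUB_b(X′) − μ_b)/σ_b

   where (μ_h, σ_h) are each host's proteome score distribution; an
   alternative per-amino-acid method picks each family's best codon by a
   ratio or difference score. Results are summarised by the
   *optimization index*
   `mean_A((CUB(X′) − CUB(X))/σ) − mean_B(…)`.
2. **Promoter** — contrastive motif construction. Per wanted host,
   motifs enriched in strong promoters vs intergenic sequence; per
   unwanted host, "anti-motifs" enriched in intergenic sequence. Motifs
   are compared by Spearman correlation of their probability matrices
   against per-host thresholds calibrated on random PSSMs, aggregated
   across hosts (`α·Σ_A δ + (1−α)·Σ_B δ`), and cut at the 75th
   percentile into one final motif set used to rank and fine-tune
   candidate promoters by MAST-style combined E-values.
3. **Restriction sites** — sites recognised only by unwanted hosts are
   inserted by synonymous codon changes (greedy, conflict-aware,
   maximising the number of unwanted hosts that can cut the sequence);
   sites recognised by any wanted host are removed where a synonymous
   escape exists. The protein sequence is never altered.

A synthetic-microbiome generator (codon-bias-contrasted proteomes,
planted promoter motifs, tGCN tables, enzyme repertoires, 16S
sequences) makes the whole pipeline testable without downloading
genomes; it is first-class, tested code.

## Worked example

```python
from selectigene import (FixtureSpec, make_microbiome, make_goi,
                         design_microbiome)

spec = FixtureSpec(seed=11, n_wanted=3, n_unwanted=3, genes_per_host=60,
                   gene_length_codons=100, planted_motif="TATAWTAT",
                   disjoint_enzymes=True)
mb = make_microbiome(spec)
goi = make_goi(120, seed=12)
report = design_microbiome(mb, goi, scheme="CAI", method="hill", seed=11)

print("optimization index:", round(report.opt_index.index, 3))
for host, score in report.opt_index.per_host.items():
    print(f"  {host}: {score:+.3f}")
sr = report.site_report
print("unwanted hosts with >=1 site:", sorted(sr.unwanted_hosts_with_site))
print("wanted hosts with >=1 site:  ", sorted(sr.wanted_hosts_with_site))
print("unwanted-site occurrences:", sr.unwanted_occurrences_before, "->",
      sr.unwanted_occurrences_after)
```

prints

```
optimization index: 9.509
  wanted0: +8.139
  wanted1: +8.879
  wanted2: +8.224
  unwanted0: -1.941
  unwanted1: -0.628
  unwanted2: -0.717
unwanted hosts with >=1 site: ['unwanted0', 'unwanted1', 'unwanted2']
wanted hosts with >=1 site:   []
unwanted-site occurrences: 0 -> 11
```

The per-host scores are CUB improvements in units of each host's
proteome standard deviation: the redesigned ORF moved ~8σ up in every
wanted host and slightly down in every unwanted host, for an index of
9.5. After site editing, all three unwanted hosts — and no wanted host —
carry at least one recognition site on the construct (11 unwanted-only
occurrences were realised by synonymous changes).
`report.selected_promoters` holds the ranked candidate promoters with
their combined-match E-values.

## Command line

```bash
selectigene fixtures --seed 7 --out fixtures/ --planted-motif TATAWTAT
selectigene optimize-orf --goi fixtures/goi.fasta \
    --wanted fixtures/wanted --unwanted fixtures/unwanted \
    --scheme cai --method hill --out engineered.fasta --report report.tsv
selectigene edit-sites --orf engineered.fasta --rebase fixtures/rebase.tsv \
    --wanted wanted_ids.txt --unwanted unwanted_ids.txt --out final.fasta
selectigene design-promoter --wanted fixtures/wanted \
    --unwanted fixtures/unwanted --seed 7 --out promoters.tsv
selectigene design --config design.yaml          # full pipeline from YAML
selectigene evaluate scaleup --pool-size 20 --sizes 4,8,16 --seed 1
```

Hosts load from FASTA+GFF3 or GenBank; expression and tGCN tables from
TSV; enzyme repertoires from a REBASE-style flat file or TSV.

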