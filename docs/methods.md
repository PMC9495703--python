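# Methods

`selectigene` designs a gene construct so that its expression is favoured
in a chosen subset of a microbiome (the *wanted* hosts, set A) and
disfavoured in the rest (the *unwanted* hosts, set B). Horizontal gene
transfer exposes any introduced construct to every community member, so
each element of the construct — the coding sequence, the promoter, and
the restriction-site footprint — is engineered separately to carry the
same selectivity. This note describes the models, the parameters that
matter, the synthetic data the tests run on, and the numerical choices.

## Codon-usage model

Three per-codon weighting schemes are supported; all are normalised so
the best codon of a host has weight 1, and stop codons are never
weighted (they are not decoded by elongating ribosomes).

* **CAI.** Weights come from the codon counts of a highly expressed
  reference gene set: within each synonymous family,
  `w_i = count_i / max_count`. The reference set is the top tertile of
  genes by measured expression; without expression data, genes are
  ranked by CAI against genes annotated as ribosomal proteins (or the
  whole proteome if none are annotated). Codons never observed in the
  reference set receive a pseudo-weight of 0.5 (configurable) — the
  geometric mean below takes logs, so zero weights are forbidden.
* **tAI.** `W_i = Σ_j (1 − s_ij) · tGCN_ij` over the anticodons that
  decode codon *i*: the Watson–Crick anticodon plus third-position
  wobble partners (G:U, inosine:C, inosine:A, U:G), restricted to
  anticodons whose Watson–Crick codon encodes the same amino acid, plus
  the lysidine-modified CAT anticodon reading ATA. The interaction
  penalties `s` ship as a data file
  (`selectigene/data/wobble_s.tsv`, the dos Reis selective-constraint
  values: 0 for Watson–Crick, 0.41 G:U, 0.28 I:C, 0.9999 I:A, 0.68 U:G,
  0.89 lysidine:A) and can be overridden. Weights are divided by the
  maximum; codons with zero raw weight get the geometric mean of the
  nonzero weights.
* **TDR.** Typical decoding rate from ribosome-profiling codon
  densities: the rate is the reciprocal of the mean normalised footprint
  density, divided by the maximum rate; codons missing from the table
  get the median observed rate. Computing densities from raw reads is
  out of scope — only codon-level tables are consumed.

A gene's score under any scheme is the geometric mean of its codon
weights, `exp(mean(log w_i))`; a host's proteome profile is the mean μ
and sample (n−1) standard deviation σ of those scores over its genes.
Proteomes whose gene scores are all identical (σ = 0) are rejected —
per-σ distances are undefined there.

## ORF redesign

Two strategies recode the gene of interest without changing its protein.

**Proteome-relative hill climbing.** Candidate moves recode *all* codons
of one amino acid `s` to one synonymous codon `s_i` (`X′ = X[s→s_i]`).
Each candidate is scored by how many proteome standard deviations its
CUB score sits from each host's proteome mean,
`dist_h = (CUB_h(X′) − μ_h) / σ_h`, combined as

    f(X′) = α · mean_{a∈A}(dist_a) − mean_{b∈B}(dist_b)

with α = 1 by default (symmetric weighting of optimisation and
deoptimisation; exposed as a parameter). The best strictly improving
move is accepted each iteration; ties are broken toward the
lexicographically smaller sequence, and amino acids/codons are evaluated
in alphabetical/lexicographic order, so the algorithm is fully
deterministic (the `seed` parameter is reserved for optional random
restarts, off by default). Termination is a local maximum or `max_iter`
(default 200). Because the geometric mean depends only on codon counts,
each candidate is evaluated in O(hosts) from the current per-host
log-weight sums.

**Individual amino-acid method.** Each synonymous family is recoded
independently to the codon with the best selection score across hosts,
where each host's weights are first divided by its within-family
maximum (this makes the scores comparable across hosts; a global
maximum is the other defensible reading). Two scores exist: the ratio
score `R_i = Σ_A w_i/max − Σ_B w_i/max`, and a difference score D. The
published rendering of D mixes signs (it grows when the *wanted* host
weight is small); both variants are implemented behind
`d_formula={"printed","corrected"}` with `corrected` — wanted hosts
contribute `w_i/max`, unwanted hosts `1 − w_i/max` — as the default,
since only the corrected form agrees with R on binary weight patterns
with one host per side. Ties go to the lexicographically smallest codon.

**Evaluation.** Any redesign is summarised by the optimization index:
`Score_h = (CUB_h(X′) − CUB_h(X)) / σ_h` per host, and
`index = mean_A(Score) − mean_B(Score)`. The index is exactly
antisymmetric under swapping A and B.

## Promoter selection

Promoters are the up-to-200 bp immediately 5′ of an ORF on its own
strand, truncated at the contig edge or the previous same-strand
feature; stretches shorter than 30 bp after truncation are dropped so
small genomes stay usable. Intergenic sequence is everything on a strand
that is neither ORF nor promoter.

Per host, motifs are discovered by contrast: for wanted hosts the strong
(top-tertile) promoters are the primary set and intergenic chunks the
control (*enhancing* motifs); for unwanted hosts the contrast is
reversed, yielding *anti-motifs* enriched in non-expressed sequence. The
default backend is internal: k-mer presence counts (widths 6 and 8) are
tested per k-mer with a one-sided Fisher exact test, Bonferroni-corrected
over the k-mers tested, thresholded at 0.05; near-duplicate and shifted
seeds are collapsed; surviving seeds are refined into 4×L probability
matrices (PSSMs) by a ZOOPS EM against a 0-order control background.
When the MEME suite is installed, STREME (order-3 background, widths
6–20, p ≤ 0.05) can be used instead; its text output is parsed into the
same PSSM type.

Motif similarity is the Spearman correlation between two PSSMs flattened
column-major, maximised over ungapped offsets of the shorter within the
longer and over reverse complement (the minimal completion of "a
correlation between a pair of PSSMs" for unequal lengths). Each host
gets its own similarity threshold `D_h`: the 95th percentile (linear
interpolation) of correlations between its motifs and 100 seeded random
PSSMs (per-column symmetric Dirichlet(1), lengths uniform on [6, 20]).

The candidate set C is the union of wanted hosts' enhancing motifs. For
each motif, `δ_h = 1` if it matches host h's set at or above `D_h`, and
the aggregated score is `α·Σ_A δ + (1−α)·Σ_B δ` with α = 0.5 — matching
an unwanted host's *anti*-motifs is desirable, since anti-motifs mark
transcriptionally silent sequence. The final set F keeps motifs scoring
strictly above the 75th percentile of all aggregated scores. The strict
inequality makes F empty when all scores tie (a warning is emitted);
with one shared motif and little else this happens easily, which is why
the synthetic fixtures plant host-private decoy motifs alongside the
shared one (below).

Candidate promoters (the top quartile of wanted hosts' promoters by
expression or CUB proxy; the tertile/quartile split is a parameter) are
ranked by a MAST-style combined E-value: per motif, the best window
log-odds score — quantised to integer units of 0.01 bits, which makes
the null distribution of the window score exactly computable by dynamic
programming over columns — gives a position p-value, converted to a
sequence-level p-value over the scanned positions; the per-motif
p-values are multiplied and converted with the product-of-p-values
formula `Q·Σ_{i<k}(−ln Q)^i/i!`, then scaled by the number of
candidates. Promoters are scanned on their own strand only (promoter
function is directional). Top promoters are tailored by correcting
individual motif mismatches to the motif's modal base: one variant per
single mismatch plus one fully corrected variant.

## Restriction-site editing

Recognition sites (IUPAC strings from a REBASE-style repertoire file;
strains of a species merged, 'Unidentified bacterium' entries dropped)
are classified as wanted-only, unwanted-only, or shared. The editor
first *inserts* unwanted-only sites: all placements realisable purely by
synonymous codon changes are located on both strands (restriction acts
on dsDNA; palindromic sites are scanned once), conflict-free placements
are realised first, then conflicted groups in ascending conflict-set
size, choosing within a group by newly covered unwanted hosts, then a
site count weighted toward hosts with fewer existing sites
(`Σ 1/(1+count_h)`), then lexicographic site and smallest offset.
Placements whose realisation would destroy an already-present
unwanted-only occurrence, or create a wanted-recognised site that could
not later be removed without undoing the insertion, are skipped. On
large repertoires the candidate placements are capped at three per site
and strand (fewest codon changes first) — one placement already covers a
host, extras only add count coverage — which keeps the greedy selection
tractable at REBASE scale.

It then *removes* every wanted-only or shared occurrence for which a
synonymous escape exists, preferring the fewest codon changes and, among
those, the change with the smallest wanted-host log-weight perturbation
(protecting the translation optimisation already applied). Removal never
re-creates a previously removed occurrence and avoids destroying
inserted unwanted-only sites unless no alternative exists (logged).
Occurrences forced by the amino-acid sequence and site ambiguity are
reported as irremovable. Insertion runs before removal because inserting
an unwanted-host site can create a wanted-recognised one; the pair is
iterated to a fixed point (at most six rounds), which makes the editor
idempotent. Avoiding *shared* sites sacrifices some unwanted-host
cutting; this follows the rule of avoiding any site a wanted host
recognises, and is surfaced in the report.

The terminal stop codon is never edited. The protein sequence is
asserted unchanged before and after every edit.

## Full pipeline and evaluation protocols

`design` runs optimise-ORF → edit-sites → design-promoter in that fixed
order; the promoter stage never mutates the ORF. Reports echo the full
configuration and are digest-stable under a fixed config and seed.

Three protocols evaluate the design at pool scale:

* **Scale-up**: for each microbiome size, random subsets of a host pool
  are split half wanted / half unwanted (10 replicates), the gene
  redesigned, and the optimization index averaged.
* **Pairwise resolution**: for every host pair (|A| = |B| = 1), the 16S
  sequences are globally aligned (Needleman–Wunsch, match 1, mismatch
  −1, gap −2; distance = mismatches + gap columns) and correlated
  (Spearman) with the pair's optimization index.
* **Site scale-up**: for each size and wanted ratio, random splits of a
  repertoire pool are edited and the fraction of hosts in each group
  with at least one recognised site recorded.

## Synthetic microbiomes

The fixture generator emulates what the pipeline consumes from annotated
genomes. Per synonymous family a preference vector is drawn
(Dirichlet(1)); the unwanted-host vector is the convex combination of
that vector and its reversal, scaled by `bias_strength` (0 = identical
spectra, 1 = fully mirrored). Hosts get small Dirichlet jitter so they
are not clones. Each host carries `genes_per_host` genes (default 50) of
`gene_length_codons` codons (default 200) sampled from its preference
vector, lognormal(0, 1) expression values, 250-bp gaps (200-bp promoter
+ 50-bp intergenic), a tGCN table and a ribosome-density table
consistent with its preferences, a Poisson-sized enzyme repertoire
(mean 4.6 sites per host, the REBASE v110 per-organism mean) drawn from
a shared pool of 6-bp sites (palindromes, non-palindromes, and sites
with one ambiguity; only 64 palindromic 6-mers exist, so large pools are
mostly non-palindromic), and a 600-bp 16S sequence mutated from a shared
root. An optional motif (e.g. TATAWTAT) is planted into a random subset
of the strong promoters of wanted hosts, together with a few
host-private decoy motifs — real discovery runs return many host-private
motifs, and without that spread the strict percentile cut of the final
motif set degenerates. A separate gradient pool places hosts along a
preference gradient with 16S divergence proportional to position, for
the resolution protocol.

What the fixtures do *not* emulate: phylogenetic covariance among hosts,
operonic gene structure, GC-content gradients, real promoter
architecture (−10/−35 spacing), methyltransferase protection, and the
high ambiguity of many real REBASE sites. Passing tests therefore show
that the algorithms recover signal they are pointed at and respect their
invariants — not that effect sizes on real genomes will match. In
particular the fixture repertoires are *less* ambiguous than REBASE's,
so the fraction of wanted hosts that still recognise the edited sequence
is lower on fixtures than analyses on real genome collections observe.

## Numerical choices and problem sizes

Percentiles use linear interpolation throughout, so the strict ">" of
the final-set cut is reproducible. Log-odds scanning uses integer scores
(0.01-bit units); the DP null distribution is exact for that scoring.
Spearman correlations on constant inputs are defined as 0. Hill-climb
ties break toward the lexicographically smaller sequence; per-codon
selection ties toward the smaller codon; promoter E-value ties toward
the smaller promoter id. All randomness flows through explicitly passed
seeded NumPy generators.

The shipped tests and the acceptance script run on deliberately small
problem sizes — pools of up to 50 hosts, proteomes of 2–60 genes of
30–200 codons, genes of interest of 60–300 codons, 10 replicates per
protocol point — chosen so the full battery completes in a few minutes
while every property (oracle equivalence, certified local maxima,
synonymy, recovery, idempotence) is still exercised end to end.

## Known limitations

The hill climb is greedy and certifies only a local maximum; the
individual method ignores inter-family dependencies by construction.
Removal searches synonymous escapes over at most two codons per
occurrence (exhaustive singles, capped pairs); sites forced by deeper
combinatorics are reported rather than pursued. mRNA folding, ramp
effects, translation-initiation strength and joint promoter+ORF
co-optimisation are out of scope.
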