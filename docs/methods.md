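# Methods

This note records the models, parameter choices and numerical conventions
behind `trendseq`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and strand conventions

All coordinates are 0-based half-open internally; GTF (1-based closed) is
converted at the I/O boundary and BED is emitted natively. "Downstream" is
always strand-aware: increasing coordinates on `+`, decreasing on `-`. A
read's 3′-terminal coordinate is the strand-aware downstream end of its
alignment interval; a poly(A) site's `position` is that coordinate for the
reads supporting it. For a minus-strand gene the annotated 3′ terminus is
the *smallest* exon coordinate and the stop-codon boundary `cds_end` is the
upper bound of the 3′ UTR, so the tandem region is `[ann3, cds_end)`.

## Annotation

**PASS filtering.** A read supports a genuine poly(A) site when its
soft-clipped terminal adenosines exceed the genome-templated A's immediately
downstream of its alignment end by at least `min_untemplated_a = 2`.
Templated A's are counted in strand sense (genomic T's upstream of a
minus-strand 3′ end). The threshold is configurable; 2 untemplated A's is
the conventional minimum for tail evidence.

**Site clustering.** Peaks are built by single-linkage clustering of PASS
3′-end coordinates per contig and strand with a gap of ≤ 25 nt — a typical
poly(A)-site cluster width. The site position is the modal coordinate;
modal ties resolve to the strand-aware downstream-most mode so that the
reported cleavage position is never upstream of the bulk of the evidence.
Clusters need `min_support = 2` reads; singletons are noise-prone.
Clustering is idempotent: re-clustering the emitted site positions
reproduces them, because distinct sites are separated by more than the gap.

**Gene assignment.** A site is assigned to the same-strand gene whose span
contains it; otherwise to a gene whose annotated 3′ end lies upstream
within `max_downstream = 5000` nt (a novel 3′ UTR isoform). When several
genes qualify, the nearest annotated 3′ end wins, then the
lexicographically smaller gene id — a deterministic order. Unassignable
sites are dropped and logged. Isoforms are ranked 1..k per gene in 5′→3′
order (rank 1 = most proximal).

**Classification.** Non-coding gene → `non_coding`; past the annotated 3′
end → `novel`; between the stop-codon boundary and the annotated 3′ end →
`tandem`; upstream of the stop codon → `internal`. The partition is
exhaustive and exclusive for every assigned site; a coding gene without a
stop-codon boundary is a hard error rather than a silent guess.

**Internal priming.** A site is flagged when the 20-nt downstream window
contains > 12 adenosines or a run of > 6 consecutive adenosines (strand
sense). These are the prevailing A-rich-filter conventions; both numbers
are configurable. Windows truncated at a contig end scale the count
threshold proportionally, leaving the run threshold untouched.

## Quantification

Demultiplexing matches the in-lane barcode exactly — no mismatch tolerance,
since the default 9-nt barcode set is well separated and exact matching is
deterministic — and drops pairs whose insert read has mean Phred ≤ 20.
Trimming removes a leading T-run (oligo-dT remnant) and the first A-run of
≥ 5 nt together with everything 3′ of it; the removed A-run length is the
soft-clipped tail used downstream as PASS evidence. Reads shorter than
15 nt after trimming are dropped.

Counting is an intersection-strict scheme on 3′-end coordinates: each
isoform owns a ±50 nt window around its site (covering cluster spread after
25-nt clustering), and a read counts for an isoform only when its 3′ end
falls in exactly one window; reads hitting zero or several windows are
tallied (`no_feature` / `ambiguous`) so that assigned + ambiguous +
no_feature + internal-priming-removed = total, per sample. Before counting,
reads ending in a flagged site's window, or ending at an unannotated
position with an A-rich downstream window, are removed as internal-priming
artefacts.

## Differential isoform usage

Counts are pooled per condition (the test is replicate-free by design; no
negative-binomial dispersion model is attempted). For each isoform of a
gene with ≥ 2 isoforms and ≥ 10 pooled reads per condition, the 2×2 table
(isoform vs rest-of-gene, knockdown vs control) is tested with the
two-sided Fisher exact test under the point-probability rule; sidedness is
two-sided because the screen looks for shifts in either direction. BH
adjustment is applied across all isoform tests of one knockdown-vs-control
comparison — the screen's natural family — not across knockdowns.

Fold-regulation normalises each gene to 100% per condition and divides the
knockdown percentage by the control percentage, which makes it invariant to
any per-condition library scaling. A pseudocount of 0.5 is added to every
isoform count *only* for the percentage computation (never for the Fisher
test) to avoid division by zero; it is configurable and its effect
vanishes at screen-scale depths.

The *Zero-isoform* is the longest (strand-aware most distal) significantly
affected isoform of annotated class (tandem/internal/non-coding; novel
isoforms are excluded). Significant isoforms are reported with their signed
distance from it (negative = upstream = shorter transcript). The shortening
index takes the gene's two most significant isoforms (ties: smaller raw p,
then more distal site), orders them by 3′ position and reports
`si = log2(fc_shorter / fc_longer)`; swapping the two conditions inverts
every fold-regulation and hence negates `si` exactly. Genes with a single
detected isoform are untestable, not `p = 1`.

Set enrichment (e.g. of affected genes in a category) is the upper-tail
hypergeometric probability.

## Regulator network

Each knockdown's profile is the map gene → direction (+1 shortened, −1
lengthened) over its significantly shifted genes. For a pair, concordance
is the fraction of co-affected genes with equal direction, and the edge
score `(2·concordance − 1)·|shared|/min(|A|,|B|)` lands at +1 for a clone
pair, −1 for a mirrored (antagonistic) pair and ≈ 0 for independent
profiles. Edge significance is the hypergeometric overlap p. The qualitative
contract — synergy attracts, antagonism repels, scaled by overlap and
significance — is fixed; the specific coefficients are package choices and
are exposed as configuration, as is the default pruning (p ≤ 0.05 and ≥ 5
shared genes). The layout is a Fruchterman–Reingold iteration where synergy
edges add attraction `score·min(−log10 p, 10)` and antagonism edges add
pairwise repulsion of the analogous magnitude; with a fixed seed the layout
is bit-reproducible. `networkx` is used only for GraphML export — its
spring layout has no repulsive-edge term, so the signed variant is
implemented here.

## Clinical signature stage

**Probe mapping.** Tandem sites partition a gene's 3′ UTR in transcript
orientation: probes upstream of the proximal site (bounded by
`upstream_span`, default 2000 nt) measure the common region shared by all
isoforms and proxy the shortest isoform; probes between consecutive sites
are specific to the longer isoform ending at the distal boundary. Probes
straddling a site or matching no region are dropped; genes whose probes
resolve fewer than two isoforms are dropped.

**Preprocessing.** Per-array background (5th percentile by default) is
subtracted with a small positive floor, then arrays are quantile-normalised
to the mean sorted distribution, so all columns share identical sorted
values. Quantile normalisation assumes most probes are unchanged between
groups; when a large fraction of probes shifts in one group it redistributes
part of that shift onto unchanged probes — the null checks in the tests are
therefore run at zero effect.

**Lengthening index and ROC.** `li = expr(long)/expr(shortest)` per gene
and sample (linear scale in outputs; group t-tests are computed on log2 li
because it is ratio data). ROC AUC is the normalised Mann–Whitney statistic
with half-credit for ties; signature genes must exceed AUC 0.7 strictly.
The multifactor score is a ridge-penalised logistic combination of per-gene
log2 short-to-long ratios, fitted on a stratified 70% split and evaluated
on the held-out 30% — the 0.7 split mirrors the Cox stage, and the ridge
penalty handles collinear (duplicated) signature genes. Paired AUC
comparisons use DeLong placement-value covariances (implemented here; no
installed Python package provides the paired test) or paired bootstrap
percentiles.

**Survival.** Kaplan–Meier curves and the two-group log-rank test come from
`lifelines`; when several candidate groupings are scanned, the scan's
p-values are BH-adjusted. The Cox pipeline draws, per bootstrap replicate,
an event-stratified 0.7 train split, fits each named covariate set by Cox
partial likelihood (Efron tie handling, the common default), and scores the
held-out 30% by Harrell's C-index; models are compared by a paired
two-sided t-test over the 100 replicate C-indices. Replicates that fail to
converge are dropped and counted; more than 20% failures is a hard error.
Replicate RNG streams are derived from the master seed so runs are
reproducible.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed once:
300 genes with 2–4 tandem sites each (≥ 100 nt apart in 600–1500 nt UTRs),
depth 200 reads per gene per condition, symmetric Dirichlet usage with
concentration 2, 30% of genes perturbed with a distal usage shift of 0.3,
0.2 A-rich decoys per kb of intergenic sequence, 9-nt barcodes, 50-nt
insert reads with 5–15 nt poly(A) tails around mean Phred 30, log2 array
noise sd 0.25 over 100 clinical samples, exponential survival with baseline
hazard 0.1, ratio coefficient 1.0 and censoring rate 0.05. Everything runs
in seconds at this scale.

The *effect* parameter is the probability mass moved onto the distal-most
isoform (capped at 0.97), with the remaining isoforms rescaled — an additive
usage shift, the natural reading of "a proximal→distal usage shift of 0.3",
and symmetric under sign change. A positive effect therefore plants
lengthening (expected `si < 0`).

Two deliberate idealisations make the zero-noise round trip exact: gene
bodies contain no A/T run of ≥ 4 nt (so genuine inserts survive stretch
trimming with their 3′ ends intact), and each planted site carries a C/G-only
patch covering its last 4 transcript bases plus the 20-nt downstream window
(so templated-A counts are zero and no true site is A-rich-flagged). Decoy
reads terminate immediately upstream of planted 20-A runs, exactly as
internal priming would. Consequences: the generator does not emulate
sequencing errors, true sites inside A-rich context (which real filters do
sacrifice), overlapping genes, splicing, or UMI duplicates — passing tests
show the pipeline's logic is exact under its own assumptions, not that real
libraries are free of these effects. A k-mer exact-match locator stands in
for the external aligner on synthetic genomes only; real alignments are
consumed as SAM.

Each stage draws from a named sub-stream (`reference`, `counts`, `fastq`,
`array`, `survival`) derived from the single global seed by hashing, so any
stage can be regenerated independently and prefixes do not depend on how
many draws other stages consume.

## Known limitations

- The Fisher test on pooled counts ignores biological replicate variance;
  at very high depth small usage drifts become significant.
- The intersection-strict ±50 nt counting window can merge sites closer
  than 50 nt (such sites are also merged by 25-nt clustering upstream).
- Quantile normalisation distorts null genes under massive global shifts
  (see above).
- The network edge-score coefficients and the multifactor combiner are
  package design choices within a qualitative contract, not estimates of
  any particular published figure's parameters.
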