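# Methods

## The measurement model

PRO-IP-seq reads report two coordinates of a single engaged RNA
polymerase II complex. The nascent RNA's 5'-end is the transcription
start nucleotide (TSN): run-on is performed on chromatin fragments
small enough (<80 bp) to hold one polymerase, and the transcript's
first nucleotide is preserved through decapping and 5'-adapter
ligation. The 3'-end is the biotin-labeled nucleotide incorporated in
the active site, i.e. the polymerase's current template position.
Projecting aligned reads onto these two ends gives strand-specific
single-nucleotide count tracks (`tracks.EndTrack`): for a plus-strand
alignment `[start, end)` the 5'-end is `start` and the 3'-end
`end − 1`; on the minus strand the roles swap. Internally all
coordinates are 0-based half-open; TSN-relative distances are reported
in the field's 1-based convention (+1 = TSN, −1 = first upstream
nucleotide, no position 0).

## Read preprocessing

Libraries carry a 6-nt inline barcode in the 3'-adapter (after a
constant G at the ligation site) and a 6-nt UMI in the 5'-adapter
(before a constant C). In Read 1, which runs antisense to the RNA,
this appears as `barcode + C + revcomp(insert) + G + UMI-field +
adapter`. Processing: demultiplex on the leading hexamer (exact match
by default — the mismatch tolerance is configurable but defaults to 0,
since inline-barcode splitting is conventionally exact; barcode tables
must keep pairwise Hamming distance > 2×tolerance, which also makes
ambiguous assignment impossible), strip the adapter and both 7-nt
tags, reverse-complement into nascent-RNA orientation, then collapse
PCR duplicates on the (UMI, sequence) key, keeping the first
occurrence. Collapse is idempotent and invariant to duplicating the
input. Reads with N in the barcode are unassigned; reads lacking a
recognizable adapter or empty after tag removal are dropped and
counted. Positional (post-alignment) deduplication is deliberately not
implemented — deduplication happens pre-alignment, as in the
fastp-based convention this mirrors.

## Spike-in counting and the cross-map mask

Foreign (mouse) chromatin spiked into each sample at a fixed
proportion (~0.5% of chromatin: 2.5×10⁵ diploid cells of a 2.5 Gb
genome per 3×10⁷ ~triploid cells of a 2.9 Gb genome,
`normalize.estimate_spikein_fraction`) provides an extrinsic
normalization reference. Regions of the spike-in genome that attract
cross-mapping primary-organism reads are masked: the mask is the
merged union of foreign-read intervals (optionally padded; no padding
by default), applied as N's to the reference and as an exclusion
filter when counting. A spike-in read counts if it is uniquely mapped
and overlaps the mask by 0 bp — any ≥1 bp overlap excludes it, the
conservative choice when the alternative is counting potentially
cross-mapped signal.

## nf-cRPM normalization

Each sample's counts are multiplied by
`(1/nf_spikein) × (1/nf_longGE) × 10⁶/control_depth` where:

* `nf_spikein = spikeCount_sample / spikeCount_unPh(same condition)` —
  within-condition correction against the unphosphorylated-CTD
  pulldown of the same run-on reaction (assumes equal pulldown of
  spike-in material; surfaced in provenance, not checked);
* `nf_longGE = endCount_unPh(test) / endCount_unPh(reference)` over
  the far ends of genes longer than 150 kb. The end window is the
  final 25% of the gene, capped at the last 50 kb: a 30-minute
  perturbation wave at ~2 kb/min moves ≤60 kb, so on >150 kb genes
  this window is untouched and provides an intrinsic anchor between
  conditions. Raw (not spike-in-corrected) 3'-end counts enter the
  ratio, matching the factor's definition in terms of end counts;
  3'-end counts (rather than full-read coverage) were chosen for
  consistency with every other quantification in the package.
* `control_depth` — the designated control sample's total
  primary-genome read count (read-count depth, not nucleotide
  coverage).

The control sample (unphosphorylated CTD, unstressed condition) gets
`nf_spikein = nf_longGE = 1` by construction, so its output is its own
sequencing-depth RPM and every other sample lands on that scale.
Replicates are merged by positionwise summation of raw counts, with
spike-in counts summed alongside, before any factor is computed — the
pooled factor is thus count-weighted.

## TSN and pause calling

The TSN is the argmax of 5'-end counts over the strand-aware window
−100..+400 nt around the annotated TSS; the pause nucleotide is the
argmax of 3'-end counts over the same window. Ties break to the most
upstream position (deterministic, biased toward the annotated
direction of transcription); zero signal leaves a gene uncalled. One
representative TSN — called from the unphosphorylated-CTD, unstressed
sample — anchors all antibodies and conditions of a gene by default; a
flag enables per-sample TSNs. Pause distances are classified early
(+1..+30) or late (+31..+60); these counting windows follow the
histogram definition of the pause regions, not the narrower +18..+30
band sometimes used to describe where the early peak concentrates.
Pause fractions are areas under the 3'-end curve over the two windows
divided by the +1..+60 sum. The "clear pause" flag (peak ≥ 5 counts
and ≥ 3× the median per-nt background over +201..+400) is this
package's own operational criterion; both parameters are exposed.
Only the single dominant TSN per gene is called; multi-TSN promoters
are out of scope.

## Ratio tracks and composite profiles

Phospho/unphospho comparisons are computed on nf-cRPM-normalized
3'-end tracks as `log2((num + 0.5) / (den + 0.5))` at every position
covered by either track. The symmetric pseudocount (default 0.5) keeps
zero-denominator positions defined and preserves exact centering:
equal inputs give 0 everywhere, including empty positions.

Composite profiles extract per-gene signal strand-aware (minus-strand
genes are coordinate-reversed so downstream is rightward; antisense
signal is read from the opposite genomic strand) in three anchor
modes: linear windows around the TSN, linear windows around the CPS,
and gene bodies scaled to 50 bins. Linear windows are averaged into
1- or 5-nt bins; gene-body bin edges are `round(linspace(0, L, 51))`,
bin value = mean per-nt signal, so per-gene mass
(Σ bin mean × bin width) equals the body sum exactly up to float
round-off. Genes shorter than 50 nt are excluded with a warning. Each
profile reports the per-bin mean and the 12.5–87.5% quantile band
across genes; summary statistics are invariant to gene input order.
Domain boundaries between two per-bin profiles (`crossing_point`) are
the first bin where the difference turns positive and stays positive
for ≥5 consecutive bins, suppressing single-bin noise excursions.

## Activity and response classification

gbRPK = (Σ normalized 3'-end counts in the gene body) / body length ×
1000. The body runs from TSN+500 to the CPS: the first 500 nt are
excluded so promoter-proximal pausing does not contaminate the
elongation measure; the offset is configurable since conventions vary.
Summed-antibody activity adds the four CTD states' gbRPK. Activity
groups are quantile splits (default quartiles) with ties broken by
gene id. Heat-shock response classes use fold-change thresholds
(defaults: activated ≥2×, repressed ≤0.5×, minimum activity 1 gbRPK in
the conditioning sample) — operational defaults of this package, since
published gene lists rest on dataset-specific filters; with symmetric
thresholds the classifier is antisymmetric under swapping conditions.

Genome-wide figures from sequencing studies of this assay (e.g.
~10,600 active genes, 77%/59%/56% clear-pause detection rates, mean
77 nt / median 55 nt TSN–TSS offsets, ~770 heat-activated genes)
depend on full-depth deposited data and unspecified filter settings;
they are context for the defaults above, not quantities this package
claims to reproduce.

## The synthetic-data generator

`simulate.SimConfig` defines the study conditions; defaults are chosen
once to match the assay's design and are not tuned:

* **TSN offsets**: discretized exponential with median 55 nt (scale
  55/ln 2, implying mean ≈ 79 nt), capped at +400 so every true TSN is
  inside the calling window — emulating start nucleotides tens of nt
  downstream of reference TSS annotations.
* **Pause mixture**: early component truncated-normal on +1..+30
  (mean +25, sd 3 — the early pause peaks at +25), late component on
  +31..+60 (mean +45, sd 6), weights 0.6/0.4. Each gene draws one
  dominant pause offset; 60% of its pause reads land exactly there and
  the rest follow the mixture.
* **CTD weights** (pause, body, termination): unPh (0.70, 0.25, 0.05),
  Ser2Ph (0.30, 0.50, 0.20), Ser5Ph (0.50, 0.45, 0.05), Ser7Ph
  (0.45, 0.45, 0.10) — unphosphorylated polymerase pause-dominant,
  Ser2P weighted toward elongation/termination.
* **Spike-in fraction** 0.005 (the 0.5% chromatin estimate), **noise**
  2% uniform background by default, **PCR duplication** Poisson with
  mean 0.5 extra copies.
* **Heat shock**: 10% of genes activated (×4), 10% repressed (×0.25);
  genes longer than 150 kb are forced to "unchanged" because the
  between-condition factor is defined by their ends being
  unperturbed.
* Gene expression weights are log-normal (σ = 1); 5'-ends sit exactly
  at the TSN with probability 0.9 (small geometric jitter otherwise).

Reads are apportioned by binomial draws (spike-in, then noise), then
multinomially across genes; per-sample generators are derived from the
seed and the sample's (condition, antibody, replicate) via a CRC
stream id, so any sample is reproducible in isolation and byte-identical
across reruns. The aligned-coordinate path emits one record per
molecule and is the primary test surface; FASTQ emission adds the full
adapter architecture and PCR duplicates, with identical molecules
guaranteed distinct UMIs (an idealized UMI space — real libraries can
collide, in which case collapse undercounts molecules).

What the generator does **not** emulate: realistic sequence
composition, splicing, enhancer and antisense transcription,
nucleosome positioning, mappability structure, cross-genome homology
(cross-mapping reads for mask tests are injected explicitly), or
pulldown-efficiency differences between antibodies. Passing tests
therefore demonstrate correctness of the computations under the
assay's idealized statistical model, not robustness to every artifact
of real libraries.

## Numerical and I/O choices

Tracks are sparse sorted (position, count) arrays per (chromosome,
strand); counts are float64 so raw and normalized tracks share one
container. bedGraph output is 0-based half-open, single-nucleotide
intervals, no track lines, minus-strand values positive in separate
`_pl`/`_mn` files; write→read round-trips are exact. bigWig export is
omitted so the package has no binary-format backend requirement. GTF
input (1-based) is converted on read; BED is native. Quantiles use
numpy's default linear interpolation. Pipeline outputs carry a
provenance JSON (package version, config, factors, seed) and contain
no timestamps, making reruns byte-identical.

## Problem sizes

Tests and the acceptance script run on simulated experiments of
30–200 genes on a 1.5–6 Mb genome with 10⁴–2.5×10⁵ reads per sample
(the determinism check uses the full 2-condition × 4-antibody ×
2-replicate design at 10⁵ reads/sample). These sizes exercise every
code path at depths where per-gene recovery statistics are stable.

## Known limitations

* Alignment and bam→bed conversion are out of scope; the package
  consumes BED6 with a score-encoded uniqueness flag.
* `nf_longGE` requires at least one >150 kb gene with nonzero
  reference signal; experiments without long genes must rely on
  spike-in factors alone.
* Single dominant TSN/pause per gene; bimodal promoters are reported
  by their stronger site only.
* Paired-end re-pairing and quality trimming are not implemented
  (inputs are assumed synchronized).
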