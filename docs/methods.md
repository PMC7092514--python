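# Methods

This note documents the models, conventions and design choices behind
splicescape, in the order a run encounters them.

## Annotation model and coordinates

GFF3 and GTF files are 1-based inclusive and are stored that way in
`TranscriptModel`; interval arithmetic inside region derivation converts to
0-based half-open and back, so boundary bases are never double counted.
Exons and CDS spans are kept in transcript orientation (descending genomic
start on the minus strand). The GFF3 phase of CDS span *k+1* must equal
`(3 − ((Σ span lengths ≤ k − phase₁) mod 3)) mod 3`; the validator enforces
this, and translation takes phase from the annotation rather than
recomputing it.

Region derivation assigns every exonic base of a coding transcript to
exactly one region: bases 5' of the first CDS base (in transcript
orientation) are 5'UTR, bases 3' of the last CDS base are 3'UTR, everything
between is CDS. Non-coding transcripts are unclassifiable and are excluded
from region statistics (logged), but their exon lengths still enter the
genomic length distribution.

**"Possible splicing locations" are exonic segments, not bases.** Splicing
events address exonic nodes, so the genomic expectation counts, per region,
the number of exon fragments after region splitting; an exon spanning a
region boundary contributes one location to each region it touches (either
region could host an event in that exon). Counts are per transcript by
default; `annotation.isoform_policy: longest` switches to one
representative isoform per gene for sensitivity checks, since either
convention is defensible when multiple mRNAs per gene exist.

## Differential inclusion

The point estimate for a node is the difference of group mean PSI over
non-missing values; missing PSI is dropped per node, never imputed, which
matches per-event quantifiability in splice-graph quantifiers. The reported
probability is a nonparametric bootstrap over replicate samples: within
each group, samples are resampled with replacement `n_boot` times (default
10,000, giving Monte-Carlo error < 0.005 near the 0.95 threshold) and the
probability is the fraction of resampled differences sharing the sign of
the point estimate, with exact-zero resamples counting half. A point
estimate of exactly 0 has no sign and reports probability 0.5, the only
symmetric convention. The two groups are processed in a canonical
(higher-mean-first) order, so swapping the groups negates ΔPSI and leaves
the probability bit-identical. Per-node seeds are derived from the run seed
and a CRC32 of the gene id, making results independent of iteration order
and of the process hash salt.

An optional `delta.method: beta` draws each sample's PSI from a Beta
distribution with the sample's point estimate as mean and a variance
implied by its confidence-interval width (treated as an ~90% interval,
sd ≈ width/3.29). This approximates posterior-sampling approaches used
upstream; the replicate bootstrap is the default because it is reproducible
from a PSI table alone.

The significance filter keeps events with probability > 0.95 (strict) and
|ΔPSI| ≥ 0.1 (inclusive). No multiple-testing correction is applied by
default — the downstream landscape statistics operate on raw calls — and
the filter thresholds live in the config. The sensitivity re-call
(`sensitivity_recall`) returns the |ΔPSI| < 0.1 events with probability
≥ 1 − α, quantifying how much the effect-size cut biases the ΔPSI
distribution toward the modes.

## Landscape statistics

Chi-square goodness of fit uses Eᵢ = n·pᵢ with uniform pᵢ unless an
expectation is supplied; expected cells below 5 log a warning but the test
still runs (small tallies are inherent to per-type, per-tissue cells).
Region assignment of an event takes the region with maximal base overlap,
pooled over the gene's coding transcripts, with ties broken
CDS > 5'UTR > 3'UTR — deterministic, and consonant with CDS being the
dominant host region. Per-region significance is a 1-df region-vs-complement
chi-square plus a 2-df omnibus over the three regions.

`region_deviation_test` scales expected counts to the observed total by
default, in which case deviations weighted by expected proportions sum to
zero exactly. When the baseline event rate is known — e.g. a simulation
that thins one region — the optional `expected_total` argument measures
deviations against that baseline instead, so a 50% thinning of a region is
recovered as a deviation of −0.5 rather than the renormalized −0.5p/(1−…)
value.

The exon-length comparison is a two-sided Mann–Whitney test with midranks:
exact when both samples have ≤ 10 values and no cross-group ties (scipy's
exact null ignores ties, so tied small samples fall back to an in-package
deviation-counting enumeration), asymptotic with tie correction otherwise.
Fully degenerate input (every value identical) returns p = 1.

Exclusive-isoform detection flags an isoform for group G when its TPM is
≥ `on_min` (default 1.0) in at least `min_frac` (default 0.75) of G's
samples and ≤ `off_max` (default 0.1) in every sample outside G. The
thresholds are conventional expressed/silent cutoffs, config-exposed and
echoed in the output; under shared expression the expected result is zero
flags.

## Exon peptides

Exon extraction returns the transcript-orientation sequence (reverse
complement on the minus strand). Translation uses GFF3 phase semantics
(bases to skip), the standard genetic code, `*` for stops, and `X` for any
codon containing N — even codons like GGN that are formally resolvable are
masked, a deliberate draft-genome conservatism. By default only the
CDS-overlapping portion of an exon is translated, because UTR bases carry
no reading frame; `exons.whole_exon: true` translates the full exon in the
CDS phase for boundary-spanning exons of interest. External protein-motif
databases are not bundled: `motif_scan` defines the adapter contract
(per-peptide hits, failures recorded without aborting the scan) and ships a
regex scanner that reports overlapping matches, sufficient for pipeline
plumbing and tests.

## GO parent-term rollup

"Parent terms" are the depth-1 children of each namespace root — the
granularity of PANTHER-style summaries ("binding", "catalytic activity").
A leaf reachable from several depth-1 terms counts toward each;
deduplication happens at the gene × parent level. The ontology is read from
OBO restricted to `is_a` edges (`part_of` behind a flag). Expected
abundance per parent is the genome-wide fraction of genes carrying it times
the spliced-gene count; the per-term test is a 1-df annotated-vs-not
chi-square, the reported deviation is (observed − expected)/tissue event
total, and parents on < 2% of genome genes are dropped from reports.
Because the genome proportions are computed from whatever association file
is supplied, the expectation and the observation always share one
annotation universe — running the test with the whole genome as the spliced
set returns observed = expected identically.

## Synthetic cohort

The generator's defaults are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| design | 3 tissues × 2 sexes × 2 treatments, n = 12 per cell | 48 birds, 144 libraries; replication level of the emulated design |
| exons per gene | Poisson(8), clipped to [3, 14] | ~8 exons per gene, the commonly cited vertebrate average |
| event mix | CE 0.55, RI 0.16, AA 0.12, AD 0.12, rest 0.05 | CE-dominant; CE+AA+AD+RI carry 95% of events |
| PSI noise | Beta, concentration 24 | sd ≈ 0.1 at PSI 0.5, a realistic replicate spread |
| effect nodes | 5% of nodes per contrast family | sparse true effects |
| effect sizes | |ΔPSI| ~ U(0.15, 0.5), sign symmetric | all true effects clear the 0.1 filter; both directions occur |
| convergence_factor | 0.5 | half the sex-dimorphic nodes lose their effect under stress |

Genes carry valid ORFs (ATG…stop, no internal stops) with phase-consistent
CDS spans on both strands, so translation tests run against the generated
genome. Sex effects are injected as ±effect/2 shifts of the male/female
means in one tissue of one treatment stratum; under stress only a
`convergence_factor` fraction of those nodes keeps its effect, reproducing
the qualitative convergence of the sexes' splicing landscapes. Treatment
effects are injected analogously within one sex. Gonads are generated as
sex-specific tissue and are only ever compared within sex. Everything
derives from one integer seed and reruns are byte-identical.

What the generator does **not** emulate: read-level sampling noise and
mapping bias, correlated PSI across nodes of one gene, realistic base
composition or intron length distributions, annotation errors, and
PSI–expression coupling. Passing tests therefore demonstrate correctness of
the statistics and plumbing under the assumed noise model, not performance
on real sequencing data.

## Pipeline and reproducibility

The standard contrast set is male-vs-female within each treatment for
hypothalamus and pituitary, and control-vs-stress within each sex for all
three tissues (10 comparisons). Every stage logs counts at each filter step
(events in → significant → region-assigned), writes outputs atomically
without timestamps, and registers files in `manifest.json` (config
snapshot, seed, per-stage counts, sha256 per file). Default problem sizes —
60 genes, ~450 nodes, 10,000 bootstrap draws — keep a full run at well
under a minute on one core while leaving every per-cell tally large enough
to exercise the tests; they are config keys, not constants.

## Known limitations

* The bootstrap probability is not a posterior; with n = 12 it is granular
  (resolution ~1/n_boot but effective resolution set by the 12¹² resample
  space) and conservative for very small effects.
* Region expectation counts segments, not bases; analyses that weight by
  exonic length would need a different expectation (config-level choice).
* The exact rank-sum mode is limited to n ≤ 10 per group; beyond that the
  tie-corrected normal approximation is used.
* GO conclusions inherit whatever association table is supplied; no
  ontology snapshot is bundled beyond the toy DAG used for simulation.
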