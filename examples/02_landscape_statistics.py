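"""Landscape statistics: event-count chi-square tests and region deviation.

Reproduces the kind of numbers an event-tally table yields: a two-cell
chi-square for tissue abundance (here using 225 pituitary vs 158
hypothalamus events), the matching percent change, and the deviation of
observed splicing locations from a genomic region expectation.
"""

from splicescape import (
    ExpectationModel,
    TranscriptRegion,
    chi_square_gof,
    percent_change,
    region_deviation_test,
)

res = chi_square_gof([225, 158])
print(f"pituitary vs hypothalamus events: chi2={res.statistic:.2f}, "
      f"df={res.df}, n={res.n}, p={res.p:.3g}")
print(f"percent change: {percent_change(225, 158):.0f}%")
# p < 0.05: splicing events are not evenly split between the two tissues.

R5, RC, R3 = TranscriptRegion.FIVE_UTR, TranscriptRegion.CDS, TranscriptRegion.THREE_UTR
expectation = ExpectationModel(
    region_location_counts={R5: 20, RC: 60, R3: 20},  # genome-wide segments
    exon_length_sample=[120] * 10,
)
observed = {R5: 30, RC: 62, R3: 8}  # 3'UTR events depleted
deviations, tests = region_deviation_test(observed, expectation)
for d in deviations:
    p = tests[d.region.name].p
    print(f"  {d.region.value}: observed={d.observed} expected={d.expected:.1f} "
          f"deviation={d.deviation:+.2f} (p={p:.3g})")
# deviation = (observed - expected)/expected; -0.6 means 60% fewer events
# in that region than the genome-wide distribution of splice locations predicts.
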