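"""GO parent-term rollup and deviation from genomic expectation.

Abstracts leaf GO terms to the depth-1 children of their namespace root
and tests whether a spliced gene set over-represents a parent term
relative to the genome-wide proportion.
"""

import tempfile
from pathlib import Path

from splicescape import ExpectationModel, TranscriptRegion, abstract_term, go_deviation_test
from splicescape.ontology import OntologyDag
from splicescape.simulate import _write_obo

with tempfile.TemporaryDirectory() as tmp:
    obo = Path(tmp) / "toy.obo"
    _write_obo(obo)
    dag = OntologyDag.from_obo(obo)

for term in ("GO:0036094", "GO:0140096", "GO:0005488"):
    print(f"{term} -> parents {sorted(abstract_term(term, dag))}")
# 'small molecule binding' rolls up to 'binding'; a multi-parent leaf
# reaches every depth-1 category it descends from.

# 20 spliced genes, all annotated under 'binding', against a genome where
# 40% of genes carry that parent:
assoc = {f"g{i}": {"GO:0036094"} for i in range(20)}
expectation = ExpectationModel(
    region_location_counts={r: 1 for r in TranscriptRegion},
    exon_length_sample=[100],
    go_parent_proportions={"GO:0005488": 0.40},
    n_genome_genes=100,
)
(dev,) = go_deviation_test(assoc, assoc, dag, expectation, tissue_total=50)
print(f"binding: observed={dev.observed} expected={dev.expected:.1f} "
      f"normalized deviation={dev.normalized_deviation:+.2f} p={dev.p:.2g}")
# observed - expected, normalized by the tissue's event total: the scale
# used to compare parent-term abundance across tissues.
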