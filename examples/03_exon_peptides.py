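"""Phase- and strand-aware translation of spliced exons.

Extracts an exon from a toy genome on both strands, translates it using
GFF3 phase semantics, and scans the peptide with the bundled toy regex
motif scanner.
"""

import tempfile
from pathlib import Path

from splicescape import RegexScanner, extract_exon, motif_scan, translate_exon
from splicescape.peptides import ExonPeptide

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "toy.fa"
    fasta.write_text(">chrT\nATGGCCAAAAAGCGCTCCTAA\n")

    fwd = extract_exon(fasta, "chrT", 1, 21, "+")
    rev = extract_exon(fasta, "chrT", 1, 21, "-")

print(f"forward nucleotides: {fwd}")
print(f"reverse complement:  {rev}")
for phase in (0, 1, 2):
    print(f"  phase {phase}: {translate_exon(fwd, phase)!r}")
# Phase is the number of bases skipped before the first complete codon
# (GFF3 semantics); phase 0 of this exon is the ORF MAKKRS*.

peptide = ExonPeptide(event_key="toy:1", nucleotides=fwd, phase=0,
                      strand="+", peptide=translate_exon(fwd, 0)[:-1],
                      region=None)
hits = motif_scan([peptide], RegexScanner({"double-basic": "[KR][KR]"}))
for h in hits["toy:1"]:
    print(f"motif {h.motif} at {h.start}-{h.end} in {peptide.peptide}")
# Overlapping matches are all reported; positions are 1-based inclusive.
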