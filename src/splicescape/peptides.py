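"""Phase- and strand-aware extraction and translation of spliced exons.

Phase follows GFF3 semantics: the number of bases to skip at the 5' end of
a CDS feature to reach the first complete codon (not GTF frame).  Phase is
taken from the annotation, not recomputed; the annotation validator
cross-checks it against cumulative CDS length.

By default only the CDS-overlapping portion of an exon is translated; UTR
portions have no reading frame.  A ``whole_exon`` switch translates the
full exon in the CDS phase instead, for exons whose UTR side is of
interest.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

from Bio.Data.CodonTable import standard_dna_table as _STANDARD_TABLE
from Bio.Seq import Seq
from pyfaidx import Fasta

from .annotation import TranscriptModel, TranscriptRegion, derive_regions
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExonPeptide",
    "MotifHit",
    "RegexScanner",
    "extract_exon",
    "translate_exon",
    "exon_peptide",
    "motif_scan",
    "write_peptide_fasta",
]


@dataclass
class ExonPeptide:
    """A spliced exon's nucleotide sequence and its translation."""

    event_key: str
    nucleotides: str
    phase: int
    strand: str
    peptide: str
    region: TranscriptRegion | None


@dataclass(frozen=True)
class MotifHit:
    """A motif match in a peptide (1-based inclusive positions)."""

    motif: str
    start: int
    end: int
    score: float


def extract_exon(
    genome: Fasta | str | Path,
    chrom: str,
    start: int,
    end: int,
    strand: str,
) -> str:
    """Genomic sequence of an interval (1-based inclusive), stranded.

    Minus strand returns the reverse complement, i.e. the transcript-
    orientation sequence.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    if chrom not in fa:
        raise ValidationError(f"chromosome {chrom!r} absent from genome")
    if start < 1 or end > len(fa[chrom]) or end < start:
        raise ValidationError(
            f"interval {start}-{end} out of bounds for {chrom} (len {len(fa[chrom])})"
        )
    seq = fa[chrom][start - 1 : end].seq.upper()
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_exon(nt: str, phase: int) -> str:
    """Translate a nucleotide string after skipping ``phase`` bases.

    Standard genetic code; stops are "*", any codon containing N is "X"
    (draft-genome tolerance — even resolvable ambiguity codes are masked),
    trailing partial codons are dropped.
    """
    if phase not in (0, 1, 2):
        raise ValidationError(f"phase must be 0/1/2, got {phase}")
    nt = nt.upper()
    if set(nt) - set("ACGTN"):
        raise ValidationError("nucleotides must be over A/C/G/T/N")
    body = nt[phase:]
    body = body[: len(body) - len(body) % 3]
    aa = []
    for i in range(0, len(body), 3):
        codon = body[i : i + 3]
        if "N" in codon:
            aa.append("X")
        elif codon in _STANDARD_TABLE.stop_codons:
            aa.append("*")
        else:
            aa.append(_STANDARD_TABLE.forward_table[codon])
    return "".join(aa)


def exon_peptide(
    model: TranscriptModel,
    exon: tuple[int, int],
    genome: Fasta | str | Path,
    event_key: str = "",
    whole_exon: bool = False,
) -> ExonPeptide:
    """Extract and translate one exon of a coding transcript.

    The translated portion is the exon ∩ CDS (in transcript orientation)
    with the annotated phase of the containing CDS span; UTR-only exons
    yield an empty peptide.  ``whole_exon=True`` translates the full exon
    sequence in that same phase.
    """
    if exon not in model.exons:
        raise ValidationError(f"{model.transcript_id}: exon {exon} not in model")
    nt_full = extract_exon(genome, model.chrom, exon[0], exon[1], model.strand)
    minus = model.strand == "-"

    # CDS span overlapping this exon, with its annotated phase
    cds_part = None
    phase = 0
    for (cs, ce), ph in zip(model.cds_spans, model.phases):
        os_, oe = max(cs, exon[0]), min(ce, exon[1])
        if os_ <= oe:
            cds_part, phase = (os_, oe), ph
            break
    region = None
    if model.is_coding:
        pieces = derive_regions(model)[exon]
        regions = {r for _, r in pieces}
        region = (
            TranscriptRegion.CDS
            if TranscriptRegion.CDS in regions
            else next(iter(regions))
        )

    if cds_part is None:
        peptide = translate_exon(nt_full, phase) if whole_exon else ""
        nt = nt_full
    else:
        if whole_exon:
            nt = nt_full
        else:
            nt = extract_exon(genome, model.chrom, cds_part[0], cds_part[1], model.strand)
        peptide = translate_exon(nt, phase)
    return ExonPeptide(
        event_key=event_key or f"{model.transcript_id}:{exon[0]}-{exon[1]}",
        nucleotides=nt,
        phase=phase,
        strand=model.strand,
        peptide=peptide,
        region=region,
    )


class Scanner(Protocol):
    """Adapter contract for external motif searches."""

    def __call__(self, peptide: str) -> list[MotifHit]: ...


class RegexScanner:
    """Bundled toy scanner: named regex motifs, overlapping hits reported.

    Stands in for external protein-motif searches (PFAM-style databases are
    deliberately not bundled); the adapter contract is the point.
    """

    def __init__(self, motifs: dict[str, str]):
        self.motifs = {name: re.compile(f"(?=({pat}))") for name, pat in motifs.items()}

    def __call__(self, peptide: str) -> list[MotifHit]:
        hits = []
        for name, pat in self.motifs.items():
            for m in pat.finditer(peptide):
                matched = m.group(1)
                hits.append(
                    MotifHit(
                        motif=name,
                        start=m.start() + 1,
                        end=m.start() + len(matched),
                        score=float(len(matched)),
                    )
                )
        return sorted(hits, key=lambda h: (h.start, h.motif))


def motif_scan(
    peptides: Iterable[ExonPeptide],
    scanner: Scanner,
) -> dict[str, list[MotifHit] | Exception]:
    """Scan peptides for motifs; adapter failures are recorded per peptide
    and the scan continues."""
    peptides = list(peptides)
    if not peptides:
        raise ValidationError("no peptides to scan")
    out: dict[str, list[MotifHit] | Exception] = {}
    for p in peptides:
        try:
            out[p.event_key] = scanner(p.peptide)
        except Exception as exc:  # adapter is external code
            logger.warning("motif scan failed for %s: %s", p.event_key, exc)
            out[p.event_key] = exc
    return out


def write_peptide_fasta(peptides: Iterable[ExonPeptide], out: str | Path) -> int:
    """Write peptides as FASTA keyed by event; returns the record count."""
    n = 0
    with open(out, "w") as fh:
        for p in peptides:
            region = p.region.value if p.region else "unclassified"
            fh.write(f">{p.event_key} phase={p.phase} strand={p.strand} region={region}\n")
            fh.write(p.peptide + "\n")
            n += 1
    return n
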