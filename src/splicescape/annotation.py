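"""Genome annotation model: GFF3 parsing, transcript regions, GTF export,
and the genome-wide expectation model used by every null comparison.

Coordinates in :class:`TranscriptModel` are stored as they appear in GFF3
(1-based, inclusive).  Interval arithmetic inside this module converts to
0-based half-open and back, so boundary bases are never double counted.

A "splicing location" is an exonic segment: one exon contributes one
location to every transcript region (5'UTR / CDS / 3'UTR) it touches.
Splicing events address exonic nodes, so the natural unit of the null model
is the segment, not the base.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .errors import GffParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptRegion",
    "TranscriptModel",
    "ExpectationModel",
    "parse_gff3",
    "gff_to_gtf",
    "derive_regions",
    "build_expectation_model",
]


class TranscriptRegion(Enum):
    """The three transcript regions, in transcript (5'→3') orientation."""

    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"


@dataclass
class TranscriptModel:
    """One mRNA: exon/CDS structure with strand and per-CDS-span phase.

    ``exons`` and ``cds_spans`` are (start, end) pairs, 1-based inclusive,
    ordered 5'→3' in transcript orientation (descending genomic start on
    the minus strand).  ``phases[k]`` is the GFF3 phase of ``cds_spans[k]``:
    the number of bases to skip to reach the first complete codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_spans: list[tuple[int, int]] = field(default_factory=list)
    phases: list[int] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_spans)

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_spans)

    def validate(self) -> None:
        """Check exon ordering, CDS containment, and phase consistency."""
        if self.strand not in "+-":
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons {s1}-{e1} and {s2}-{e2}"
                )
        expected = sorted(self.exons, reverse=self.strand == "-")
        if self.exons != expected:
            raise ValidationError(
                f"{self.transcript_id}: exons not sorted 5'->3' in transcript orientation"
            )
        for cs, ce in self.cds_spans:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS {cs}-{ce} not contained in any exon"
                )
        if self.cds_spans:
            if len(self.phases) != len(self.cds_spans):
                raise ValidationError(
                    f"{self.transcript_id}: {len(self.cds_spans)} CDS spans but "
                    f"{len(self.phases)} phases"
                )
            # phase[k+1] = (3 - ((cumulative CDS length - phase0) % 3)) % 3
            cum = 0
            phase0 = self.phases[0]
            for k, ((cs, ce), ph) in enumerate(zip(self.cds_spans, self.phases)):
                if ph not in (0, 1, 2):
                    raise ValidationError(
                        f"{self.transcript_id}: CDS span {k} has invalid phase {ph}"
                    )
                if k > 0:
                    want = (3 - ((cum - phase0) % 3)) % 3
                    if ph != want:
                        raise ValidationError(
                            f"{self.transcript_id}: CDS span {k} phase {ph}, "
                            f"expected {want} from cumulative length"
                        )
                cum += ce - cs + 1


@dataclass
class ExpectationModel:
    """Genome-derived null proportions for region, exon-length and GO tests.

    ``region_location_counts`` counts exonic segments per transcript region
    across the genome; ``exon_length_sample`` is the genomic exon-length
    distribution; ``go_parent_proportions`` is the fraction of genome genes
    annotated (after parent-term abstraction) to each parent term.
    """

    region_location_counts: dict[TranscriptRegion, int]
    exon_length_sample: list[int]
    go_parent_proportions: dict[str, float] = field(default_factory=dict)
    n_genome_genes: int = 0

    @property
    def region_proportions(self) -> dict[TranscriptRegion, float]:
        total = sum(self.region_location_counts.values())
        if total == 0:
            raise ValidationError("expectation model has no region locations")
        return {r: c / total for r, c in self.region_location_counts.items()}

    def validate(self) -> None:
        if not self.exon_length_sample:
            raise ValidationError("exon_length_sample is empty")
        props = self.region_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValidationError("region proportions do not sum to 1")
        for term, p in self.go_parent_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"GO proportion out of range for {term}: {p}")


def _prevalidate_gff3(path: Path) -> None:
    """Cheap line-level scan so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GffParseError(
                    f"non-integer coordinates {fields[3]!r}/{fields[4]!r}", lineno
                ) from None
            if start < 1 or end < start:
                raise GffParseError(f"invalid interval {start}-{end}", lineno)
            if fields[6] not in {"+", "-", ".", "?"}:
                raise GffParseError(f"invalid strand {fields[6]!r}", lineno)


def parse_gff3(path: str | Path) -> list[TranscriptModel]:
    """Parse a GFF3 file into one validated :class:`TranscriptModel` per mRNA.

    Features are grouped by their ``Parent`` attribute; exon order follows
    transcript orientation.  Raises :class:`GffParseError` with the line
    number on malformed lines and :class:`ValidationError` on dangling
    Parent references, missing CDS phases, or CDS outside the exon union.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_gff3(path)

    if path.stat().st_size == 0 or not any(
        line.strip() and not line.startswith("#") for line in open(path)
    ):
        logger.warning("annotation file %s has no features", path)
        return []

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    mrna_ids = set()
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        mrna_ids.add(mrna.id)
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int, int]] = []
        for child in db.children(mrna.id):
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype == "CDS":
                if child.frame not in ("0", "1", "2"):
                    raise ValidationError(
                        f"{mrna.id}: CDS {child.start}-{child.end} lacks a phase"
                    )
                cds.append((child.start, child.end, int(child.frame)))
        minus = mrna.strand == "-"
        exons.sort(reverse=minus)
        cds.sort(key=lambda t: t[:2], reverse=minus)
        model = TranscriptModel(
            transcript_id=mrna.id,
            gene_id=gene_id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds_spans=[(s, e) for s, e, _ in cds],
            phases=[p for _, _, p in cds],
        )
        model.validate()
        models.append(model)

    # dangling Parent check: any exon/CDS whose Parent is not a known mRNA
    for feat in db.features_of_type(("exon", "CDS")):
        for parent in feat.attributes.get("Parent", []):
            if parent not in mrna_ids:
                raise ValidationError(
                    f"{feat.featuretype} at {feat.seqid}:{feat.start}-{feat.end} "
                    f"references unknown Parent {parent!r}"
                )
    return models


def gff_to_gtf(
    models: Iterable[TranscriptModel],
    out: str | Path,
    source: str = "splicescape",
    emit_transcript_rows: bool = False,
) -> int:
    """Write models as GTF2.2 and return the number of feature rows written.

    Exon and CDS rows are emitted with quoted ``gene_id``/``transcript_id``
    attributes; the GFF3 phase is copied into the GTF frame column.
    """
    out = Path(out)
    n = 0
    with open(out, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            rows: list[tuple[str, int, int, str, str]] = []
            if emit_transcript_rows:
                lo = min(s for s, _ in m.exons)
                hi = max(e for _, e in m.exons)
                rows.append(("transcript", lo, hi, ".", attrs))
            for s, e in sorted(m.exons):
                rows.append(("exon", s, e, ".", attrs))
            minus = m.strand == "-"
            genomic_cds = sorted(zip(m.cds_spans, m.phases), key=lambda t: t[0])
            for (s, e), ph in genomic_cds:
                rows.append(("CDS", s, e, str(ph), attrs))
            for ftype, s, e, frame, a in rows:
                fh.write(
                    f"{m.chrom}\t{source}\t{ftype}\t{s}\t{e}\t.\t{m.strand}\t{frame}\t{a}\n"
                )
                n += 1
            del minus
    return n


def derive_regions(
    model: TranscriptModel,
) -> dict[tuple[int, int], list[tuple[tuple[int, int], TranscriptRegion]]]:
    """Assign every exonic base of a coding transcript to one region.

    Returns ``{exon: [(sub_interval, region), ...]}`` with sub-intervals
    1-based inclusive in genomic coordinates but region labels in transcript
    orientation: bases 5' of the first CDS base are FIVE_UTR, bases 3' of
    the last CDS base are THREE_UTR, everything between is CDS.

    Raises :class:`ValidationError` for non-coding transcripts, which are
    excluded from region statistics.
    """
    if not model.is_coding:
        raise ValidationError(
            f"{model.transcript_id}: non-coding transcript has no regions"
        )
    cds_lo = min(s for s, _ in model.cds_spans)
    cds_hi = max(e for _, e in model.cds_spans)
    minus = model.strand == "-"

    result: dict[tuple[int, int], list[tuple[tuple[int, int], TranscriptRegion]]] = {}
    for exon in model.exons:
        s, e = exon
        pieces: list[tuple[tuple[int, int], TranscriptRegion]] = []
        # genomic-left of CDS span start
        left = (s, min(e, cds_lo - 1)) if s < cds_lo else None
        mid_s, mid_e = max(s, cds_lo), min(e, cds_hi)
        mid = (mid_s, mid_e) if mid_s <= mid_e else None
        right = (max(s, cds_hi + 1), e) if e > cds_hi else None
        left_region = TranscriptRegion.THREE_UTR if minus else TranscriptRegion.FIVE_UTR
        right_region = TranscriptRegion.FIVE_UTR if minus else TranscriptRegion.THREE_UTR
        if left:
            pieces.append((left, left_region))
        if mid:
            pieces.append((mid, TranscriptRegion.CDS))
        if right:
            pieces.append((right, right_region))
        if minus:  # keep pieces in transcript orientation
            pieces.reverse()
        result[exon] = pieces
    return result


def build_expectation_model(
    models: Sequence[TranscriptModel],
    go_assoc: Mapping[str, set[str]] | None = None,
    ontology=None,
    isoform_policy: str = "all",
) -> ExpectationModel:
    """Build genome-wide null proportions from an annotation set.

    Region locations are counted per exonic segment: an exon contributes one
    location to each region it touches.  ``isoform_policy`` is ``"all"``
    (count every mRNA) or ``"longest"`` (one representative mRNA per gene,
    the one with the greatest summed exon length).

    GO parent proportions are the fraction of genome genes whose leaf
    annotations abstract to each parent term; they are empty (with a
    warning) when no association table is supplied.
    """
    if isoform_policy not in ("all", "longest"):
        raise ValueError(f"unknown isoform_policy {isoform_policy!r}")
    if isoform_policy == "longest":
        by_gene: dict[str, TranscriptModel] = {}
        for m in models:
            cur = by_gene.get(m.gene_id)
            if cur is None or sum(m.exon_lengths()) > sum(cur.exon_lengths()):
                by_gene[m.gene_id] = m
        selected: Sequence[TranscriptModel] = list(by_gene.values())
    else:
        selected = models

    if not any(m.is_coding for m in selected):
        raise ValidationError("expectation model requires >=1 coding transcript")

    counts: Counter[TranscriptRegion] = Counter()
    lengths: list[int] = []
    for m in selected:
        lengths.extend(m.exon_lengths())
        if not m.is_coding:
            continue
        for pieces in derive_regions(m).values():
            for region in {r for _, r in pieces}:
                counts[region] += 1

    go_props: dict[str, float] = {}
    n_genes = len({m.gene_id for m in selected})
    if go_assoc is not None and ontology is not None:
        from .ontology import abstract_gene_terms

        parent_counter: Counter[str] = Counter()
        annotated = 0
        for gene in sorted({m.gene_id for m in selected}):
            terms = go_assoc.get(gene, set())
            parents = abstract_gene_terms(terms, ontology)
            if parents:
                annotated += 1
            for p in parents:
                parent_counter[p] += 1
        if annotated == 0:
            logger.warning("no genome gene carries a GO annotation")
        go_props = {t: c / n_genes for t, c in sorted(parent_counter.items())}
    elif go_assoc is not None or ontology is not None:
        logger.warning("need both go_assoc and ontology; GO proportions left empty")

    em = ExpectationModel(
        region_location_counts={r: counts.get(r, 0) for r in TranscriptRegion},
        exon_length_sample=lengths,
        go_parent_proportions=go_props,
        n_genome_genes=n_genes,
    )
    em.validate()
    return em
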