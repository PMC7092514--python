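"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a three-tissue (hypothalamus / pituitary / gonad),
two-sex, two-treatment replicated design with 12 birds per sex per
treatment — every bird contributes one sample per tissue.  Per-node PSI is
Beta-distributed around a node baseline; a configurable fraction of nodes
carries true ΔPSI effects of at least 0.1, either between sexes (within a
treatment stratum) or between treatments (within a sex).  Under stress,
only ``convergence_factor`` of the sex-dimorphic nodes keep their effect,
emulating the convergence of male and female splicing landscapes under
restraint.  Gonads are sex-specific tissue and are never compared male vs
female.

Transcript models have distinct 5'UTR / CDS / 3'UTR exon composition, valid
open reading frames (ATG ... stop, no internal stops) and phase-consistent
CDS spans on both strands, so region derivation and phase-aware translation
are exercised end to end.  Everything is driven by one integer seed and is
byte-identical across reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import TranscriptModel
from .errors import ValidationError
from .events import EVENT_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "AnnotationBundle",
    "PsiBundle",
    "simulate_genome_annotation",
    "simulate_psi_tables",
    "simulate_tpm",
    "two_group_psi_table",
]

TISSUES = ("hypothalamus", "pituitary", "gonad")
SEXES = ("M", "F")
TREATMENTS = ("control", "stress")

#: CE-dominant mixture; the four dominant types carry 95% of the mass.
DEFAULT_EVENT_MIX = {
    "CE": 0.55, "AA": 0.12, "AD": 0.12, "RI": 0.16,
    "TE": 0.0125, "TS": 0.0125, "AF": 0.0125, "AL": 0.0125,
}

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 12 replicates per sex × treatment
    cell across three tissues, ~8 exons per gene, a CE-dominant event
    mixture, Beta PSI noise with concentration 24 (sd ≈ 0.1 at PSI 0.5),
    effect sizes drawn uniformly from ±[0.15, 0.5], and a convergence
    factor of 0.5 halving the number of sex-dimorphic nodes under stress.
    """

    seed: int = 0
    n_genes: int = 60
    n_chromosomes: int = 4
    mean_exons_per_gene: float = 8.0
    n_per_cell: int = 12
    event_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX)
    )
    effect_fraction: float = 0.05
    effect_size_range: tuple[float, float] = (0.15, 0.5)
    psi_concentration: float = 24.0
    convergence_factor: float = 0.5
    n_exclusive_isoforms: int = 0

    def validate(self) -> None:
        if self.n_per_cell < 2:
            raise ValidationError("n_per_cell must be >= 2")
        if abs(sum(self.event_type_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("event_type_mix must sum to 1")
        if set(self.event_type_mix) - set(EVENT_TYPES):
            raise ValidationError("unknown event type in mix")
        lo, hi = self.effect_size_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("effect sizes must lie in (0, 1]")
        if not 0.0 <= self.convergence_factor <= 1.0:
            raise ValidationError("convergence_factor must be in [0, 1]")


@dataclass
class AnnotationBundle:
    """File paths plus in-memory objects from genome/annotation simulation."""

    fasta: Path
    gff3: Path
    go_association: Path
    ontology_obo: Path
    models: list[TranscriptModel]
    genome: dict[str, str]
    go_assoc: dict[str, set[str]]


@dataclass
class PsiBundle:
    """Per-sample PSI tables, design, and the injected-effect truth table."""

    sample_paths: dict[str, Path]
    design: dict[str, dict[str, str]]
    truth: pd.DataFrame
    nodes: pd.DataFrame


# ---------------------------------------------------------------------------
# toy ontology: 3 namespaces, depth-1 parents, multi-parent leaves

TOY_ONTOLOGY: dict[str, tuple[str, str, list[str]]] = {
    # id: (name, namespace, is_a parents)
    "GO:0003674": ("molecular_function", "molecular_function", []),
    "GO:0005488": ("binding", "molecular_function", ["GO:0003674"]),
    "GO:0003824": ("catalytic activity", "molecular_function", ["GO:0003674"]),
    "GO:0005215": ("transporter activity", "molecular_function", ["GO:0003674"]),
    "GO:0005198": ("structural molecule activity", "molecular_function", ["GO:0003674"]),
    "GO:0036094": ("small molecule binding", "molecular_function", ["GO:0005488"]),
    "GO:0008144": ("drug binding", "molecular_function", ["GO:0005488"]),
    "GO:1901363": ("heterocyclic compound binding", "molecular_function", ["GO:0005488"]),
    "GO:0016740": ("transferase activity", "molecular_function", ["GO:0003824"]),
    # multi-parent leaf: reachable from both binding and catalytic activity
    "GO:0140096": ("catalytic activity, acting on a protein", "molecular_function",
                   ["GO:0003824", "GO:0005488"]),
    "GO:0008150": ("biological_process", "biological_process", []),
    "GO:0008152": ("metabolic process", "biological_process", ["GO:0008150"]),
    "GO:0009987": ("cellular process", "biological_process", ["GO:0008150"]),
    "GO:0050896": ("response to stimulus", "biological_process", ["GO:0008150"]),
    "GO:0006950": ("response to stress", "biological_process", ["GO:0050896"]),
    "GO:0044237": ("cellular metabolic process", "biological_process",
                   ["GO:0008152", "GO:0009987"]),
    "GO:0005575": ("cellular_component", "cellular_component", []),
    "GO:0016020": ("membrane", "cellular_component", ["GO:0005575"]),
    "GO:0043226": ("organelle", "cellular_component", ["GO:0005575"]),
    "GO:0005634": ("nucleus", "cellular_component", ["GO:0043226"]),
}

#: leaves genes are annotated with (weighted toward binding terms)
_LEAF_TERMS = [
    "GO:0036094", "GO:0008144", "GO:1901363", "GO:0016740", "GO:0140096",
    "GO:0005215", "GO:0005198", "GO:0006950", "GO:0044237", "GO:0008152",
    "GO:0016020", "GO:0005634",
]
_LEAF_WEIGHTS = np.array([3, 2, 2, 2, 1, 1, 1, 2, 2, 1, 1, 1], dtype=float)


def _write_obo(path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy-go\n")
        for tid, (name, ns, parents) in TOY_ONTOLOGY.items():
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: {ns}\n")
            for p in parents:
                fh.write(f"is_a: {p} ! {TOY_ONTOLOGY[p][0]}\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_gene(
    rng: np.random.Generator, gene_id: str, tx_id: str, chrom: str, offset: int
) -> tuple[TranscriptModel, str, int]:
    """One coding gene: returns (model, locus sequence, locus length).

    The transcript is built 5'→3' (UTR5 + valid ORF + UTR3), cut into
    exons, and interleaved with introns; minus-strand genes store the
    reverse complement on the chromosome.
    """
    n_exons = int(np.clip(rng.poisson(8.0), 3, 14))
    utr5 = int(rng.integers(40, 160))
    n_codons = int(rng.integers(100, 300))
    cds = "ATG" + "".join(
        np.array(_NONSTOP_CODONS)[rng.integers(0, len(_NONSTOP_CODONS), n_codons - 2)]
    ) + _STOP_CODONS[rng.integers(0, 3)]
    utr3 = int(rng.integers(60, 220))
    tx_seq = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    tx_len = len(tx_seq)

    # cut the transcript into n_exons pieces of >= 25 bp
    min_len = 25
    free = tx_len - n_exons * min_len
    cuts = np.sort(rng.integers(0, free + 1, size=n_exons - 1))
    bounds = [0]
    for i, c in enumerate(cuts, start=1):
        bounds.append(int(c) + i * min_len)
    bounds.append(tx_len)
    tx_exons = [(bounds[i], bounds[i + 1]) for i in range(n_exons)]  # half-open

    strand = "+" if rng.random() < 0.5 else "-"
    intron_lens = rng.integers(80, 400, size=n_exons - 1)

    # transcript-order offsets within the locus concatenation (half-open)
    locus_parts = []
    exon_offsets = []
    pos = 0
    for i, (a, b) in enumerate(tx_exons):
        exon_offsets.append((pos, pos + (b - a)))
        locus_parts.append(tx_seq[a:b])
        pos += b - a
        if i < n_exons - 1:
            locus_parts.append(_random_seq(rng, int(intron_lens[i])))
            pos += int(intron_lens[i])
    locus_seq = "".join(locus_parts)
    locus_len = len(locus_seq)
    if strand == "-":
        locus_seq = str(Seq(locus_seq).reverse_complement())

    def to_genomic(a: int, b: int) -> tuple[int, int]:
        # half-open locus offsets -> 1-based inclusive chromosome coords
        if strand == "+":
            return offset + a + 1, offset + b
        return offset + locus_len - b + 1, offset + locus_len - a

    exons = [to_genomic(a, b) for a, b in exon_offsets]

    cds_lo, cds_hi = utr5, utr5 + len(cds)  # transcript coords, half-open
    cds_spans: list[tuple[int, int]] = []
    phases: list[int] = []
    cum = 0
    for (ta, tb), (oa, ob) in zip(tx_exons, exon_offsets):
        s, e = max(ta, cds_lo), min(tb, cds_hi)
        if s < e:
            phases.append((3 - cum % 3) % 3)
            la = oa + (s - ta)
            cds_spans.append(to_genomic(la, la + (e - s)))
            cum += e - s

    model = TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_spans=cds_spans,
        phases=phases,
    )
    model.validate()
    return model, locus_seq, locus_len


def _write_gff3(models: list[TranscriptModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            fh.write(
                f"{m.chrom}\tsplicescape-sim\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tsplicescape-sim\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chrom}\tsplicescape-sim\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}\n"
                )
            for (s, e), ph in sorted(zip(m.cds_spans, m.phases)):
                fh.write(
                    f"{m.chrom}\tsplicescape-sim\tCDS\t{s}\t{e}\t.\t{m.strand}\t{ph}\t"
                    f"Parent={m.transcript_id}\n"
                )


def simulate_genome_annotation(cfg: SimConfig, out_dir: str | Path) -> AnnotationBundle:
    """Write a toy genome FASTA, GFF3 annotation, GO associations and OBO.

    Genes are placed sequentially on ``cfg.n_chromosomes`` chromosomes with
    random intergenic spacers; ~half the genes are minus-strand.  Every
    gene receives 1–4 leaf GO terms from the bundled toy ontology.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))

    models: list[TranscriptModel] = []
    chrom_seqs: dict[str, list[str]] = {}
    chrom_pos: dict[str, int] = {}
    for i in range(cfg.n_genes):
        chrom = f"chr{i % cfg.n_chromosomes + 1}"
        if chrom not in chrom_seqs:
            pad = int(rng.integers(150, 400))
            chrom_seqs[chrom] = [_random_seq(rng, pad)]
            chrom_pos[chrom] = pad
        gene_id = f"gene{i + 1:04d}"
        model, locus_seq, locus_len = _make_gene(
            rng, gene_id, f"{gene_id}.t1", chrom, chrom_pos[chrom]
        )
        models.append(model)
        chrom_seqs[chrom].append(locus_seq)
        chrom_pos[chrom] += locus_len
        gap = int(rng.integers(200, 500))
        chrom_seqs[chrom].append(_random_seq(rng, gap))
        chrom_pos[chrom] += gap

    genome = {c: "".join(parts) for c, parts in sorted(chrom_seqs.items())}
    fasta = out_dir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")

    gff3 = out_dir / "annotation.gff3"
    _write_gff3(models, gff3)

    obo = out_dir / "ontology.obo"
    _write_obo(obo)

    go_assoc: dict[str, set[str]] = {}
    weights = _LEAF_WEIGHTS / _LEAF_WEIGHTS.sum()
    for m in models:
        k = int(rng.integers(1, 5))
        terms = rng.choice(_LEAF_TERMS, size=k, replace=False, p=weights)
        go_assoc[m.gene_id] = set(terms.tolist())
    assoc_path = out_dir / "go_association.tsv"
    with open(assoc_path, "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(go_assoc):
            for term in sorted(go_assoc[gene]):
                fh.write(f"{gene}\t{term}\n")

    return AnnotationBundle(
        fasta=fasta, gff3=gff3, go_association=assoc_path, ontology_obo=obo,
        models=models, genome=genome, go_assoc=go_assoc,
    )


def _design(cfg: SimConfig) -> dict[str, dict[str, str]]:
    """144-sample design: every bird sampled in all three tissues."""
    design = {}
    for sex in SEXES:
        for treatment in TREATMENTS:
            for r in range(1, cfg.n_per_cell + 1):
                for tissue in TISSUES:
                    sid = f"{sex}{r:02d}_{treatment}_{tissue[:3]}"
                    design[sid] = {"sex": sex, "treatment": treatment, "tissue": tissue}
    return design


def simulate_psi_tables(
    cfg: SimConfig, bundle: AnnotationBundle, out_dir: str | Path
) -> PsiBundle:
    """Per-sample PSI TSVs plus the design and injected-effect truth table.

    Each exon of each gene is a splice-graph node with an event type drawn
    from the CE-dominant mixture and a baseline PSI ~ U(0.15, 0.85).
    Effects are injected as ± effect/2 shifts of the two group means:

    * sex-dimorphic nodes (fraction ``effect_fraction``) differ M vs F in
      hypothalamus or pituitary within the control stratum; only a
      ``convergence_factor`` subset keeps the effect under stress;
    * treatment-responsive nodes (an independent ``effect_fraction`` draw)
      differ control vs stress within one sex and one tissue.

    Sample PSI ~ Beta(mean, concentration); the CI_Width column is the
    ~90% interval width implied by the Beta sd.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))

    node_rows = []
    for m in bundle.models:
        for j, (s, e) in enumerate(m.exons, start=1):
            node_rows.append(
                {
                    "gene_id": m.gene_id, "node_id": j, "chrom": m.chrom,
                    "start": s, "end": e, "strand": m.strand,
                }
            )
    nodes = pd.DataFrame(node_rows)
    n_nodes = len(nodes)
    mix_types = sorted(cfg.event_type_mix)
    mix_p = np.array([cfg.event_type_mix[t] for t in mix_types])
    nodes["event_type"] = rng.choice(mix_types, size=n_nodes, p=mix_p)
    nodes["baseline"] = rng.uniform(0.15, 0.85, size=n_nodes)

    lo, hi = cfg.effect_size_range
    truth_rows = []
    n_effect = int(round(cfg.effect_fraction * n_nodes))

    mvf_idx = rng.choice(n_nodes, size=n_effect, replace=False)
    keep_stress = set(
        rng.choice(
            mvf_idx, size=int(round(cfg.convergence_factor * n_effect)), replace=False
        ).tolist()
    )
    mvf_effects: dict[tuple[int, str, str], float] = {}
    for idx in mvf_idx:
        size = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
        tissue = ("hypothalamus", "pituitary")[rng.integers(0, 2)]
        strata = ["control"] + (["stress"] if idx in keep_stress else [])
        for treatment in strata:
            mvf_effects[(int(idx), treatment, tissue)] = size
            truth_rows.append(
                {
                    "gene_id": nodes.at[int(idx), "gene_id"],
                    "node_id": int(nodes.at[int(idx), "node_id"]),
                    "contrast": "MvF", "stratum": treatment, "tissue": tissue,
                    "effect": size,
                }
            )

    cvs_idx = rng.choice(n_nodes, size=n_effect, replace=False)
    cvs_effects: dict[tuple[int, str, str], float] = {}
    for idx in cvs_idx:
        size = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
        tissue = TISSUES[rng.integers(0, 3)]
        sex = SEXES[rng.integers(0, 2)]
        cvs_effects[(int(idx), sex, tissue)] = size
        truth_rows.append(
            {
                "gene_id": nodes.at[int(idx), "gene_id"],
                "node_id": int(nodes.at[int(idx), "node_id"]),
                "contrast": "CvS", "stratum": sex, "tissue": tissue,
                "effect": size,
            }
        )

    design = _design(cfg)
    conc = cfg.psi_concentration
    sample_paths: dict[str, Path] = {}
    baseline = nodes["baseline"].to_numpy()
    for sid in sorted(design):
        d = design[sid]
        mean = baseline.copy()
        for (idx, treatment, tissue), size in mvf_effects.items():
            if d["treatment"] == treatment and d["tissue"] == tissue:
                mean[idx] += size / 2 if d["sex"] == "M" else -size / 2
        for (idx, sex, tissue), size in cvs_effects.items():
            if d["sex"] == sex and d["tissue"] == tissue:
                mean[idx] += size / 2 if d["treatment"] == "control" else -size / 2
        mean = np.clip(mean, 0.02, 0.98)
        psi = rng.beta(mean * conc, (1 - mean) * conc)
        sd = np.sqrt(mean * (1 - mean) / (conc + 1))
        ci = np.clip(3.29 * sd, 0, 1)
        path = out_dir / f"{sid}.psi.tsv"
        with open(path, "w") as fh:
            fh.write("Gene\tNode\tCoord\tStrand\tType\tPsi\tCI_Width\n")
            for i, row in enumerate(nodes.itertuples(index=False)):
                fh.write(
                    f"{row.gene_id}\t{row.node_id}\t"
                    f"{row.chrom}:{row.start}-{row.end}\t{row.strand}\t"
                    f"{row.event_type}\t{psi[i]:.5f}\t{ci[i]:.5f}\n"
                )
        sample_paths[sid] = path

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "node_id", "contrast", "stratum", "tissue", "effect"],
    )
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    design_path = out_dir / "design.tsv"
    with open(design_path, "w") as fh:
        fh.write("sample_id\tsex\ttreatment\ttissue\n")
        for sid in sorted(design):
            d = design[sid]
            fh.write(f"{sid}\t{d['sex']}\t{d['treatment']}\t{d['tissue']}\n")

    return PsiBundle(
        sample_paths=sample_paths, design=design, truth=truth,
        nodes=nodes.drop(columns=["baseline"]),
    )


def two_group_psi_table(
    n_nodes: int,
    n_per_group: int = 12,
    delta: float = 0.0,
    seed: int = 0,
    concentration: float = 24.0,
    base_mean: float = 0.5,
):
    """A minimal two-group PSI table for calibration and power studies.

    Every node has the same true group difference ``delta`` (group A mean
    ``base_mean + delta/2``, group B ``base_mean − delta/2``); per-sample
    PSI is Beta with the given concentration.  ``delta=0`` gives a pure
    null.  Returns ``(PsiTable, Comparison)`` ready for
    :func:`splicescape.events.delta_psi_all`.
    """
    from .events import Comparison, PsiTable  # local import, avoids a cycle

    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    mean_a = float(np.clip(base_mean + delta / 2, 0.02, 0.98))
    mean_b = float(np.clip(base_mean - delta / 2, 0.02, 0.98))
    design = {}
    rows = []
    for grp, sex, mean in (("A", "M", mean_a), ("B", "F", mean_b)):
        for r in range(1, n_per_group + 1):
            sid = f"{grp}{r:02d}"
            design[sid] = {"sex": sex, "treatment": "control",
                           "tissue": "hypothalamus"}
            psi = rng.beta(mean * concentration, (1 - mean) * concentration,
                           size=n_nodes)
            for i in range(n_nodes):
                rows.append(
                    (sid, f"g{i + 1:04d}", 1, "chr1", 100 * i + 1, 100 * i + 50,
                     "+", "CE", float(psi[i]), None)
                )
    data = pd.DataFrame(
        rows,
        columns=["sample_id", "gene_id", "node_id", "chrom", "start", "end",
                 "strand", "event_type", "psi", "ci_width"],
    )
    table = PsiTable(data=data, design=design)
    cmp = Comparison(label="MvF:control:hypothalamus",
                     group_a={"sex": "M"}, group_b={"sex": "F"})
    return table, cmp


def simulate_tpm(
    cfg: SimConfig, bundle: AnnotationBundle, out_dir: str | Path
) -> pd.DataFrame:
    """Isoform × sample TPM table (log-normal), with optional injected
    group-exclusive isoforms.

    Base expression is shared across all samples (no group structure), so
    exclusive-isoform detection should return nothing unless
    ``cfg.n_exclusive_isoforms`` injects exclusives, each expressed in one
    randomly chosen treatment group only.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    design = _design(cfg)
    samples = sorted(design)
    isoforms = [m.transcript_id for m in bundle.models]
    base = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=len(isoforms))
    tpm = base[:, None] * rng.lognormal(0.0, 0.3, size=(len(isoforms), len(samples)))
    df = pd.DataFrame(tpm, index=isoforms, columns=samples)

    for k in range(cfg.n_exclusive_isoforms):
        group = TREATMENTS[rng.integers(0, 2)]
        name = f"exclusive{k + 1}.t1"
        row = np.zeros(len(samples))
        for j, s in enumerate(samples):
            if design[s]["treatment"] == group:
                row[j] = rng.lognormal(np.log(5.0), 0.2)
        df.loc[name] = row

    df = df.round(4)
    df.index.name = "isoform"
    df.to_csv(out_dir / "tpm.tsv", sep="\t")
    return df
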