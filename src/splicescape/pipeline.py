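"""Pipeline orchestration: simulate → delta → landscape → exons → go.

Each stage reads the previous stage's TSV outputs from a shared output
directory, logs event counts at every filter step, and registers every
file it writes in a run manifest (config snapshot, seed, per-stage counts,
sha256 per file).  Outputs are written atomically (temp file + rename) and
contain no timestamps, so a rerun with the same seed and config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from collections import Counter
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from . import __version__
from .annotation import (
    ExpectationModel,
    TranscriptRegion,
    build_expectation_model,
    gff_to_gtf,
    parse_gff3,
)
from .config import load_config
from .errors import InputError
from .events import (
    Comparison,
    SplicingEvent,
    call_significant,
    delta_psi_all,
    read_diff_table,
    read_psi_table,
    sensitivity_recall,
    write_diff_table,
)
from .ontology import OntologyDag, go_deviation_test, read_gene_associations
from .peptides import RegexScanner, exon_peptide, motif_scan, write_peptide_fasta
from .simulate import (
    SEXES,
    TISSUES,
    TREATMENTS,
    SimConfig,
    simulate_genome_annotation,
    simulate_psi_tables,
    simulate_tpm,
)
from .stats import (
    chi_square_gof,
    exclusive_isoforms,
    exon_length_test,
    percent_change,
    psi_distribution,
    region_assign,
    region_deviation_test,
    tally_events,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "standard_comparisons",
    "cmd_simulate",
    "cmd_delta",
    "cmd_landscape",
    "cmd_exons",
    "cmd_go",
    "cmd_all",
]

_TISSUE_ABBR = {"hypothalamus": "H", "pituitary": "P", "gonad": "G"}


class RunManifest:
    """Registry of run inputs, outputs, and per-stage counts."""

    def __init__(self, config: Mapping[str, Any], seed: int):
        self.config = dict(config)
        self.seed = seed
        self.files: dict[str, str] = {}
        self.counts: dict[str, int] = {}

    def register(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path.relative_to(root))] = digest

    def count(self, key: str, value: int) -> None:
        self.counts[key] = value

    def write(self, path: Path, root: Path) -> None:
        payload = {
            "tool_version": __version__,
            "seed": self.seed,
            "config": self.config,
            "counts": dict(sorted(self.counts.items())),
            "files": dict(sorted(self.files.items())),
        }
        _atomic_write(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")
        # the manifest lists every other output; it is not self-listed


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def standard_comparisons() -> list[Comparison]:
    """The study's contrast set.

    Male vs female within each treatment stratum for hypothalamus and
    pituitary (gonads are sex-specific tissue and are never compared
    across sexes), and control vs stress within each sex for all three
    tissues.  Labels are ``family:stratum:tissue``.
    """
    cmps = []
    for treatment in TREATMENTS:
        for tissue in ("hypothalamus", "pituitary"):
            cmps.append(
                Comparison(
                    label=f"MvF:{treatment}:{tissue}",
                    group_a={"sex": "M", "treatment": treatment, "tissue": tissue},
                    group_b={"sex": "F", "treatment": treatment, "tissue": tissue},
                )
            )
    for sex in SEXES:
        for tissue in TISSUES:
            cmps.append(
                Comparison(
                    label=f"CvS:{sex}:{tissue}",
                    group_a={"sex": sex, "treatment": "control", "tissue": tissue},
                    group_b={"sex": sex, "treatment": "stress", "tissue": tissue},
                )
            )
    return cmps


def _sim_config(cfg: Mapping[str, Any]) -> SimConfig:
    s = cfg["simulate"]
    return SimConfig(
        seed=int(cfg["seed"]),
        n_genes=int(s["n_genes"]),
        n_chromosomes=int(s["n_chromosomes"]),
        n_per_cell=int(s["n_per_cell"]),
        effect_fraction=float(s["effect_fraction"]),
        effect_size_range=tuple(s["effect_size_range"]),
        psi_concentration=float(s["psi_concentration"]),
        convergence_factor=float(s["convergence_factor"]),
        n_exclusive_isoforms=int(s["n_exclusive_isoforms"]),
    )


def cmd_simulate(cfg: Mapping[str, Any], out_dir: str | Path,
                 manifest: RunManifest | None = None) -> Path:
    """Generate the full fixture bundle under ``out_dir/sim``."""
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    sim_cfg = _sim_config(cfg)
    bundle = simulate_genome_annotation(sim_cfg, sim_dir)
    psi = simulate_psi_tables(sim_cfg, bundle, sim_dir)
    simulate_tpm(sim_cfg, bundle, sim_dir)
    gff_to_gtf(bundle.models, sim_dir / "annotation.gtf")
    logger.info(
        "simulated %d genes, %d nodes, %d samples",
        sim_cfg.n_genes, len(psi.nodes), len(psi.design),
    )
    if manifest is not None:
        manifest.count("sim.genes", sim_cfg.n_genes)
        manifest.count("sim.nodes", len(psi.nodes))
        manifest.count("sim.samples", len(psi.design))
        for p in sorted(sim_dir.iterdir()):
            if p.is_file() and not p.name.endswith(".fai"):
                manifest.register(p, out_dir)
    return sim_dir


def _load_design(sim_dir: Path) -> dict[str, dict[str, str]]:
    path = sim_dir / "design.tsv"
    if not path.exists():
        raise InputError(f"design table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        r.sample_id: {"sex": r.sex, "treatment": r.treatment, "tissue": r.tissue}
        for r in df.itertuples(index=False)
    }


def cmd_delta(cfg: Mapping[str, Any], out_dir: str | Path,
              manifest: RunManifest | None = None) -> dict[str, list[SplicingEvent]]:
    """Differential calls for every standard comparison.

    Writes ``diff/<label>.diff.tsv`` (all events) and ``diff/<label>.sig.tsv``
    (the significant subset) and returns the significant events per label.
    """
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    design = _load_design(sim_dir)
    paths = {sid: sim_dir / f"{sid}.psi.tsv" for sid in design}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise InputError(f"missing PSI tables: {missing[:3]}...")
    diff_dir = out_dir / "diff"
    diff_dir.mkdir(parents=True, exist_ok=True)

    d = cfg["delta"]
    significant: dict[str, list[SplicingEvent]] = {}
    tables: dict[str, Any] = {}
    for cmp in standard_comparisons():
        # each comparison only needs its own tissue's samples
        tissue = cmp.group_a["tissue"]
        if tissue not in tables:
            sub_design = {s: v for s, v in design.items() if v["tissue"] == tissue}
            tables[tissue] = read_psi_table(
                {s: paths[s] for s in sub_design}, sub_design
            )
        table = tables[tissue]
        events = delta_psi_all(
            table, cmp, n_boot=int(d["n_boot"]), seed=int(cfg["seed"]),
            method=d["method"],
        )
        sig = call_significant(events, float(d["prob_min"]), float(d["dpsi_min"]))
        label_safe = cmp.label.replace(":", "_")
        write_diff_table(events, diff_dir / f"{label_safe}.diff.tsv")
        write_diff_table(sig, diff_dir / f"{label_safe}.sig.tsv")
        logger.info(
            "%s: %d events in -> %d significant + %d nonsignificant",
            cmp.label, len(events), len(sig), len(events) - len(sig),
        )
        assert len(events) == len(sig) + (len(events) - len(sig))
        significant[cmp.label] = sig
        if manifest is not None:
            manifest.count(f"delta.{cmp.label}.events_in", len(events))
            manifest.count(f"delta.{cmp.label}.significant", len(sig))
    if manifest is not None:
        for p in sorted(diff_dir.iterdir()):
            manifest.register(p, out_dir)
    return significant


def load_significant_events(out_dir: str | Path) -> dict[str, list[SplicingEvent]]:
    """Read back per-comparison significant events written by cmd_delta."""
    diff_dir = Path(out_dir) / "diff"
    if not diff_dir.exists():
        raise InputError(f"diff tables not found under {diff_dir}; run delta first")
    out: dict[str, list[SplicingEvent]] = {}
    for path in sorted(diff_dir.glob("*.sig.tsv")):
        label = path.name[: -len(".sig.tsv")].replace("_", ":")
        events = read_diff_table(path)
        for e in events:
            e.comparison = label
            e.tissue = label.split(":")[2]
        out[label] = events
    return out


def _family_events(
    significant: Mapping[str, list[SplicingEvent]], family: str
) -> list[SplicingEvent]:
    return [
        e
        for label, evs in significant.items()
        if label.startswith(family + ":")
        for e in evs
    ]


def _landscape_rows(
    significant: Mapping[str, list[SplicingEvent]],
    expectation: ExpectationModel,
    models,
) -> tuple[list[dict], dict]:
    """Build the Table-1-shaped test report plus summary quantities."""
    rows: list[dict] = []
    summary: dict[str, Any] = {}

    def add(analysis: str, description: str, res) -> None:
        rows.append(
            {
                "analysis": analysis, "description": description,
                "p": f"{res.p:.6g}", "statistic": f"{res.statistic:.6g}",
                "df": res.df, "n": res.n, "test": res.test,
            }
        )

    for family in ("MvF", "CvS"):
        events = _family_events(significant, family)
        if not events:
            continue
        by_tissue = Counter(e.tissue for e in events)
        # tissue abundance
        tissues = [t for t in TISSUES if by_tissue.get(t, 0) > 0]
        if len(tissues) >= 2:
            res = chi_square_gof([by_tissue[t] for t in tissues])
            names = " vs ".join(_TISSUE_ABBR[t] for t in tissues)
            add(f"{family} tissue", f"splicing abundance across tissues ({names})", res)
        if by_tissue.get("pituitary", 0) > 0 and by_tissue.get("hypothalamus", 0) > 0:
            summary[f"{family}.percent_change_P_vs_H"] = percent_change(
                by_tissue["pituitary"], by_tissue["hypothalamus"]
            )
        # stratum contrast per tissue (control-vs-stress counts for MvF,
        # male-vs-female counts for CvS)
        strata = TREATMENTS if family == "MvF" else SEXES
        for tissue in tissues:
            per_stratum = Counter(
                e.comparison.split(":")[1] for e in events if e.tissue == tissue
            )
            if all(per_stratum.get(s, 0) > 0 for s in strata):
                res = chi_square_gof([per_stratum[s] for s in strata])
                abbr = _TISSUE_ABBR[tissue]
                add(
                    f"{family} tissue",
                    f"{abbr}: abundance {strata[0]} vs {strata[1]}",
                    res,
                )
        # event types per tissue
        for tissue in tissues:
            per_type = Counter(e.event_type for e in events if e.tissue == tissue)
            counts = [c for _, c in sorted(per_type.items())]
            if len(counts) >= 2:
                res = chi_square_gof(counts)
                top = max(per_type, key=per_type.get)
                add(
                    f"{family} event type",
                    f"{top} most abundant - {_TISSUE_ABBR[tissue]}",
                    res,
                )
        # regions per tissue, against the genomic expectation
        for tissue in tissues:
            assigned: Counter[TranscriptRegion] = Counter()
            for e in events:
                if e.tissue != tissue:
                    continue
                region = region_assign(e, models)
                if region is not None:
                    assigned[region] += 1
            if sum(assigned.values()) == 0:
                continue
            deviations, results = region_deviation_test(assigned, expectation)
            abbr = _TISSUE_ABBR[tissue]
            for dev in deviations:
                res = results[dev.region.name]
                direction = "more" if dev.deviation > 0 else "less"
                add(
                    f"{family} region",
                    f"{direction} splicing in {dev.region.value} - {abbr} "
                    f"(deviation {dev.deviation:+.3f})",
                    res,
                )
            add(f"{family} region", f"region distribution omnibus - {abbr}",
                results["omnibus"])
        # exon lengths per tissue (CE events) vs genomic distribution
        for tissue in tissues:
            lengths = [
                e.end - e.start + 1
                for e in events
                if e.tissue == tissue and e.event_type == "CE"
            ]
            if len(lengths) >= 2:
                res = exon_length_test(lengths, expectation.exon_length_sample)
                add(
                    f"{family} exon length",
                    f"spliced CE exon lengths vs genome - {_TISSUE_ABBR[tissue]}",
                    res,
                )
        summary[f"{family}.total_events"] = len(events)
    return rows, summary


def cmd_landscape(cfg: Mapping[str, Any], out_dir: str | Path,
                  manifest: RunManifest | None = None) -> Path:
    """Tallies, chi-square/rank-sum test table, PSI histograms, exclusives.

    Writes ``landscape/tests.tsv`` in the report shape
    (analysis, description, p, df, n) plus tally, histogram, summary and
    exclusive-isoform TSVs.
    """
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    land_dir = out_dir / "landscape"
    land_dir.mkdir(parents=True, exist_ok=True)

    significant = load_significant_events(out_dir)
    models = parse_gff3(sim_dir / "annotation.gff3")
    dag = OntologyDag.from_obo(sim_dir / "ontology.obo")
    assoc = read_gene_associations(sim_dir / "go_association.tsv")
    expectation = build_expectation_model(
        models, go_assoc=assoc, ontology=dag,
        isoform_policy=cfg["annotation"]["isoform_policy"],
    )

    group_of = {label: label.split(":")[1] for label in significant}
    all_events = [e for evs in significant.values() for e in evs]
    tally = tally_events(all_events, group_of)
    _atomic_write(land_dir / "tally.tsv", tally.to_frame().to_csv(sep="\t", index=False))

    rows, summary = _landscape_rows(significant, expectation, models)
    tests = pd.DataFrame(
        rows, columns=["analysis", "description", "p", "statistic", "df", "n", "test"]
    )
    _atomic_write(land_dir / "tests.tsv", tests.to_csv(sep="\t", index=False))

    if all_events:
        hist = psi_distribution(all_events, bins=int(cfg["landscape"]["bins"]))
        _atomic_write(land_dir / "psi_histogram.tsv", hist.to_csv(sep="\t", index=False))

    # relaxed re-call: low-effect events admitted at p <= 0.05
    recalled = []
    diff_dir = out_dir / "diff"
    for path in sorted(diff_dir.glob("*.diff.tsv")):
        label = path.name[: -len(".diff.tsv")].replace("_", ":")
        events = read_diff_table(path)
        for e in events:
            e.comparison, e.tissue = label, label.split(":")[2]
        recalled.extend(sensitivity_recall(events))
    recall_df = pd.DataFrame(
        [
            {"comparison": e.comparison, "tissue": e.tissue, "gene": e.gene_id,
             "node": e.node_id, "delta_psi": f"{e.delta_psi:.5f}",
             "probability": f"{e.probability:.5f}"}
            for e in recalled
        ],
        columns=["comparison", "tissue", "gene", "node", "delta_psi", "probability"],
    )
    _atomic_write(land_dir / "sensitivity_recall.tsv",
                  recall_df.to_csv(sep="\t", index=False))
    summary["sensitivity_recall.count"] = len(recalled)

    tpm_path = sim_dir / "tpm.tsv"
    if tpm_path.exists():
        tpm = pd.read_csv(tpm_path, sep="\t", index_col="isoform")
        design = _load_design(sim_dir)
        t = cfg["tpm"]
        flags = []
        for field in ("treatment", "sex"):
            flags.extend(
                (iso, field, grp)
                for iso, grp in exclusive_isoforms(
                    tpm, design, field,
                    on_min=float(t["on_min"]), off_max=float(t["off_max"]),
                    min_frac=float(t["min_frac"]),
                )
            )
        excl_df = pd.DataFrame(flags, columns=["isoform", "field", "group"])
        _atomic_write(land_dir / "exclusive_isoforms.tsv",
                      excl_df.to_csv(sep="\t", index=False))
        summary["exclusive_isoforms.count"] = len(flags)

    summary_df = pd.DataFrame(
        sorted(summary.items()), columns=["quantity", "value"]
    )
    _atomic_write(land_dir / "summary.tsv", summary_df.to_csv(sep="\t", index=False))

    if manifest is not None:
        for key, value in summary.items():
            if isinstance(value, int):
                manifest.count(f"landscape.{key}", value)
        for p in sorted(land_dir.iterdir()):
            manifest.register(p, out_dir)
    return land_dir / "tests.tsv"


def cmd_exons(cfg: Mapping[str, Any], out_dir: str | Path,
              manifest: RunManifest | None = None) -> Path:
    """Peptides of significantly spliced exons plus a region/length report."""
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    exon_dir = out_dir / "exons"
    exon_dir.mkdir(parents=True, exist_ok=True)

    significant = load_significant_events(out_dir)
    models = parse_gff3(sim_dir / "annotation.gff3")
    by_gene: dict[str, list] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    peptides = []
    report_rows = []
    seen = set()
    for label in sorted(significant):
        for e in significant[label]:
            key = (e.gene_id, e.node_id)
            if key in seen:
                continue
            seen.add(key)
            for m in by_gene.get(e.gene_id, []):
                match = next(
                    (x for x in m.exons
                     if max(x[0], e.start) <= min(x[1], e.end)),
                    None,
                )
                if match is None or not m.is_coding:
                    continue
                pep = exon_peptide(
                    m, match, sim_dir / "genome.fa",
                    event_key=f"{e.gene_id}:{e.node_id}",
                    whole_exon=bool(cfg["exons"]["whole_exon"]),
                )
                peptides.append(pep)
                report_rows.append(
                    {
                        "event": pep.event_key, "comparison": label,
                        "exon_length": match[1] - match[0] + 1,
                        "region": pep.region.value if pep.region else "unclassified",
                        "phase": pep.phase, "strand": pep.strand,
                        "peptide_length": len(pep.peptide),
                    }
                )
                break

    write_peptide_fasta(peptides, exon_dir / "peptides.fasta")
    report = pd.DataFrame(
        report_rows,
        columns=["event", "comparison", "exon_length", "region", "phase",
                 "strand", "peptide_length"],
    )
    _atomic_write(exon_dir / "exon_report.tsv", report.to_csv(sep="\t", index=False))

    motifs = {str(k): str(v) for k, v in cfg["exons"]["motifs"].items()}
    if peptides and motifs:
        hits = motif_scan(peptides, RegexScanner(motifs))
        hit_rows = [
            {"event": key, "motif": h.motif, "start": h.start, "end": h.end,
             "score": h.score}
            for key in sorted(hits)
            if not isinstance(hits[key], Exception)
            for h in hits[key]
        ]
        hits_df = pd.DataFrame(
            hit_rows, columns=["event", "motif", "start", "end", "score"]
        )
        _atomic_write(exon_dir / "motif_hits.tsv", hits_df.to_csv(sep="\t", index=False))

    if manifest is not None:
        manifest.count("exons.peptides", len(peptides))
        for p in sorted(exon_dir.iterdir()):
            manifest.register(p, out_dir)
    return exon_dir / "peptides.fasta"


def cmd_go(cfg: Mapping[str, Any], out_dir: str | Path,
           manifest: RunManifest | None = None) -> Path:
    """Parent-term deviation TSVs per contrast family and tissue."""
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    go_dir = out_dir / "go"
    go_dir.mkdir(parents=True, exist_ok=True)

    significant = load_significant_events(out_dir)
    models = parse_gff3(sim_dir / "annotation.gff3")
    dag = OntologyDag.from_obo(sim_dir / "ontology.obo")
    assoc = read_gene_associations(sim_dir / "go_association.tsv")
    expectation = build_expectation_model(
        models, go_assoc=assoc, ontology=dag,
        isoform_policy=cfg["annotation"]["isoform_policy"],
    )

    written = 0
    for family in ("MvF", "CvS"):
        events = _family_events(significant, family)
        for tissue in TISSUES:
            tissue_events = [e for e in events if e.tissue == tissue]
            if not tissue_events:
                continue
            genes = {e.gene_id for e in tissue_events}
            devs = go_deviation_test(
                genes, assoc, dag, expectation,
                tissue_total=len(tissue_events),
                min_genome_fraction=float(cfg["go"]["min_genome_fraction"]),
            )
            df = pd.DataFrame(
                [
                    {
                        "parent": d.parent, "observed": d.observed,
                        "expected": f"{d.expected:.4f}",
                        "normalized_deviation": f"{d.normalized_deviation:.5f}",
                        "p": f"{d.p:.6g}",
                        "genome_proportion": f"{d.genome_proportion:.4f}",
                    }
                    for d in devs
                ],
                columns=["parent", "observed", "expected",
                         "normalized_deviation", "p", "genome_proportion"],
            )
            path = go_dir / f"{family}_{tissue}.go.tsv"
            _atomic_write(path, df.to_csv(sep="\t", index=False))
            written += 1
    if manifest is not None:
        manifest.count("go.reports", written)
        for p in sorted(go_dir.iterdir()):
            manifest.register(p, out_dir)
    return go_dir


def cmd_all(config_path: str | Path | None, out_dir: str | Path,
            seed: int | None = None) -> Path:
    """Full pipeline on the seeded synthetic bundle; writes manifest.json."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg, int(cfg["seed"]))
    cmd_simulate(cfg, out_dir, manifest)
    cmd_delta(cfg, out_dir, manifest)
    cmd_landscape(cfg, out_dir, manifest)
    cmd_exons(cfg, out_dir, manifest)
    cmd_go(cfg, out_dir, manifest)
    manifest.write(out_dir / "manifest.json", out_dir)
    return out_dir / "manifest.json"
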