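"""Comparative statistics over significant splicing events.

Event tallies by type/tissue/comparison; chi-square goodness-of-fit tests
against uniform or genome-derived expectations; transcript-region deviation
from genomic proportions; exon-size rank-sum tests against the genomic
length distribution; PSI/ΔPSI histograms; and exclusive-isoform detection
from TPM tables.

The chi-square statistic is Σ (Oᵢ−Eᵢ)²/Eᵢ with k−1 degrees of freedom.
For two uniform cells this reduces to (a−b)²/(a+b), which is the form every
pairwise abundance test in this package takes.  Per-region significance
uses a region-vs-complement 1-df test plus a 2-df omnibus over the three
regions.
"""

from __future__ import annotations

import itertools
import logging

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import ExpectationModel, TranscriptModel, TranscriptRegion, derive_regions
from .errors import ValidationError
from .events import CORE_EVENT_TYPES, EVENT_TYPES, SplicingEvent

logger = logging.getLogger(__name__)

__all__ = [
    "TallyTable",
    "ComparisonResult",
    "RegionDeviation",
    "tally_events",
    "chi_square_gof",
    "percent_change",
    "region_assign",
    "region_deviation_test",
    "exon_length_test",
    "psi_distribution",
    "exclusive_isoforms",
]

#: tie-break precedence when a node overlaps several regions equally
REGION_PRECEDENCE = (
    TranscriptRegion.CDS,
    TranscriptRegion.FIVE_UTR,
    TranscriptRegion.THREE_UTR,
)


@dataclass
class ComparisonResult:
    """Outcome of one statistical test (chi-square or rank-sum)."""

    statistic: float
    df: int
    n: int
    p: float
    test: str

    def __post_init__(self):
        if self.df < 1:
            raise ValidationError(f"df must be >= 1, got {self.df}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p out of range: {self.p}")


@dataclass
class RegionDeviation:
    """Observed-vs-expected splicing abundance for one transcript region."""

    region: TranscriptRegion
    observed: int
    expected: float
    deviation: float  # (observed - expected) / expected


@dataclass
class TallyTable:
    """Counts of significant events per (comparison, tissue, event type, group)."""

    cells: dict[tuple[str, str, str, str], int] = field(default_factory=dict)

    def total(self, comparison: str | None = None, tissue: str | None = None) -> int:
        return sum(
            c
            for (cmp_, tis, _, _), c in self.cells.items()
            if (comparison is None or cmp_ == comparison)
            and (tissue is None or tis == tissue)
        )

    def by_type(
        self, comparison: str, tissue: str, collapse: bool = False
    ) -> dict[str, int]:
        """Per-type counts; ``collapse=True`` keeps the four dominant types
        (CE/AA/AD/RI) and folds the rest into "other".  Totals are conserved
        either way."""
        counts: Counter[str] = Counter()
        for (cmp_, tis, etype, _), c in self.cells.items():
            if cmp_ == comparison and tis == tissue:
                if collapse and etype not in CORE_EVENT_TYPES:
                    counts["other"] += c
                else:
                    counts[etype] += c
        return dict(counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"comparison": c, "tissue": t, "event_type": e, "group": g, "count": n}
            for (c, t, e, g), n in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows, columns=["comparison", "tissue", "event_type", "group", "count"]
        )


def tally_events(
    events: Iterable[SplicingEvent],
    group_of: Mapping[str, str] | None = None,
) -> TallyTable:
    """Count significant events per (comparison, tissue, type, group).

    ``group_of`` optionally maps a comparison label to a group-of-origin
    label (e.g. which treatment stratum a male-vs-female contrast belongs
    to); unmapped comparisons get group "".
    """
    cells: Counter[tuple[str, str, str, str]] = Counter()
    for e in events:
        group = (group_of or {}).get(e.comparison, "")
        cells[(e.comparison, e.tissue, e.event_type, group)] += 1
    return TallyTable(cells=dict(cells))


def chi_square_gof(
    observed: Sequence[int],
    expected_proportions: Sequence[float] | None = None,
) -> ComparisonResult:
    """Chi-square goodness of fit of observed counts to expected proportions.

    Uniform expectation when ``expected_proportions`` is omitted.  Expected
    cells below 5 trigger a logged warning but the test still runs.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValidationError("need >= 2 categories")
    n = obs.sum()
    if n < 1:
        raise ValidationError("total observed count must be >= 1")
    if expected_proportions is None:
        props = np.full(obs.size, 1.0 / obs.size)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if props.size != obs.size:
            raise ValidationError("proportions length mismatch")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError("expected proportions must sum to 1")
    exp = n * props
    if np.any(exp == 0):
        raise ValidationError("an expected count is zero")
    if np.any(exp < 5):
        logger.warning("chi-square expected count < 5 in some cell")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    return ComparisonResult(statistic=stat, df=df, n=int(n), p=p, test="chi_square_gof")


def percent_change(count_a: int, count_b: int, digits: int = 0) -> float:
    """Signed percent change of a relative to b: 100·(a−b)/b."""
    if count_b == 0:
        raise ValidationError("reference count is zero; percent change undefined")
    value = 100.0 * (count_a - count_b) / count_b
    return round(value, digits) if digits else float(round(value))


def region_assign(
    event: SplicingEvent,
    models: Sequence[TranscriptModel],
) -> TranscriptRegion | None:
    """Assign an event's node to the transcript region it overlaps most.

    Overlap is pooled over every coding transcript of the event's gene.
    Ties break CDS > 5'UTR > 3'UTR.  Returns None (logged) when the node
    overlaps no classified exon, in which case the event is excluded from
    region statistics.
    """
    overlap: Counter[TranscriptRegion] = Counter()
    for m in models:
        if m.gene_id != event.gene_id or not m.is_coding or m.chrom != event.chrom:
            continue
        for pieces in derive_regions(m).values():
            for (s, e), region in pieces:
                ov = min(e, event.end) - max(s, event.start) + 1
                if ov > 0:
                    overlap[region] += ov
    if not overlap:
        logger.warning(
            "event %s node %d overlaps no classified exon", event.gene_id, event.node_id
        )
        return None
    best = max(overlap.values())
    for region in REGION_PRECEDENCE:
        if overlap.get(region) == best:
            return region
    raise AssertionError("unreachable")


def region_deviation_test(
    assigned: Mapping[TranscriptRegion, int],
    expectation: ExpectationModel,
    expected_total: int | None = None,
) -> tuple[list[RegionDeviation], dict[str, ComparisonResult]]:
    """Observed-vs-expected splicing abundance per transcript region.

    Expected counts are the genome region proportions scaled to the
    observed total (or to ``expected_total`` when the baseline event rate
    is known, e.g. in simulations with injected depletion).  Returns the
    per-region deviations, three 1-df region-vs-complement tests, and a
    2-df omnibus test under key "omnibus".
    """
    props = expectation.region_proportions
    for region, p in props.items():
        if p == 0:
            raise ValidationError(f"region proportion is zero for {region}")
    total_obs = sum(assigned.values())
    if total_obs < 1:
        raise ValidationError("no assigned events")
    total = expected_total if expected_total is not None else total_obs

    deviations = []
    results: dict[str, ComparisonResult] = {}
    for region in TranscriptRegion:
        obs = assigned.get(region, 0)
        exp = total * props[region]
        deviations.append(
            RegionDeviation(
                region=region, observed=obs, expected=exp,
                deviation=(obs - exp) / exp,
            )
        )
        # 1-df region vs complement, scaled to the observed total
        exp_r = total_obs * props[region]
        stat = (obs - exp_r) ** 2 / exp_r + (
            (total_obs - obs) - (total_obs - exp_r)
        ) ** 2 / (total_obs - exp_r)
        results[region.name] = ComparisonResult(
            statistic=float(stat),
            df=1,
            n=total_obs,
            p=float(sps.chi2.sf(stat, 1)) if stat > 0 else 1.0,
            test="chi_square_expected",
        )
    omnibus = chi_square_gof(
        [assigned.get(r, 0) for r in TranscriptRegion],
        [props[r] for r in TranscriptRegion],
    )
    omnibus.test = "chi_square_expected"
    results["omnibus"] = omnibus
    return deviations, results


def _rank_sum_exact_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating all group labelings.

    Midranks handle ties; tractable only for small samples (C(n+m, n)
    labelings).  Returns (U statistic of x, p).
    """
    pooled = np.asarray(list(x) + list(y), dtype=float)
    n, m = len(x), len(y)
    ranks = sps.rankdata(pooled)
    r_obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2.0
    dev_obs = abs(r_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev_obs - 1e-9:
            count += 1
    u = r_obs - n * (n + 1) / 2.0
    return float(u), count / total


def exon_length_test(
    spliced_lengths: Sequence[int],
    reference_lengths: Sequence[int],
) -> ComparisonResult:
    """Two-sided rank-sum test of spliced exon lengths vs the genomic
    length distribution.

    Exact enumeration when both samples have ≤ 10 values and no ties span
    the groups; otherwise the tie-corrected normal approximation.  Inputs
    that are entirely one tied value return p = 1.
    """
    x = np.asarray(spliced_lengths, dtype=float)
    y = np.asarray(reference_lengths, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs >= 2 values")
    n = int(x.size + y.size)
    if np.unique(np.concatenate([x, y])).size == 1:
        u = float(x.size * y.size / 2.0)
        return ComparisonResult(statistic=u, df=1, n=n, p=1.0, test="rank_sum")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 10 and y.size <= 10:
        if has_ties:
            u, p = _rank_sum_exact_p(x, y)  # midrank-aware enumeration
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            u, p = float(res.statistic), float(res.pvalue)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(statistic=u, df=1, n=n, p=min(p, 1.0), test="rank_sum")


def psi_distribution(
    events: Iterable[SplicingEvent],
    bins: int = 20,
) -> pd.DataFrame:
    """Histograms of ΔPSI (over [−1,1]) and group PSI (over [0,1]) per
    (comparison, tissue, event type).

    The default significance filter discounts |ΔPSI| < 0.1, so central
    ΔPSI bins are empty for filtered input — the distribution is biased
    bimodal by construction, which is why the relaxed re-call exists.
    """
    events = list(events)
    if not events:
        raise ValidationError("no events to histogram")
    rows = []
    keyfn = lambda e: (e.comparison, e.tissue, e.event_type)
    for key, group in itertools.groupby(sorted(events, key=keyfn), key=keyfn):
        group = list(group)
        dpsi = np.array([e.delta_psi for e in group])
        psis = np.array([[e.psi_a, e.psi_b] for e in group]).ravel()
        d_counts, d_edges = np.histogram(dpsi, bins=bins, range=(-1.0, 1.0))
        p_counts, p_edges = np.histogram(psis, bins=bins, range=(0.0, 1.0))
        for quantity, counts, edges in (
            ("delta_psi", d_counts, d_edges),
            ("psi", p_counts, p_edges),
        ):
            for i, c in enumerate(counts):
                rows.append(
                    {
                        "comparison": key[0], "tissue": key[1], "event_type": key[2],
                        "quantity": quantity,
                        "bin_lo": round(float(edges[i]), 6),
                        "bin_hi": round(float(edges[i + 1]), 6),
                        "count": int(c),
                    }
                )
    return pd.DataFrame(rows)


def exclusive_isoforms(
    tpm: pd.DataFrame,
    design: Mapping[str, Mapping[str, str]],
    group_field: str,
    on_min: float = 1.0,
    off_max: float = 0.1,
    min_frac: float = 0.75,
) -> list[tuple[str, str]]:
    """Isoforms expressed in one design group and silent in its complement.

    ``tpm`` is isoform × sample.  An isoform is flagged for group value G
    of ``group_field`` when TPM ≥ on_min in ≥ min_frac of G's samples and
    TPM ≤ off_max in every sample outside G.  Returns (isoform, group)
    pairs — expected to be empty under shared expression.
    """
    if (tpm.to_numpy() < 0).any():
        raise ValidationError("TPM values must be nonnegative")
    values = sorted({d[group_field] for d in design.values()})
    flagged = []
    for g in values:
        in_g = [s for s in tpm.columns if design[s][group_field] == g]
        out_g = [s for s in tpm.columns if design[s][group_field] != g]
        if not in_g or not out_g:
            continue
        on = (tpm[in_g] >= on_min).sum(axis=1) / len(in_g) >= min_frac
        off = (tpm[out_g] <= off_max).all(axis=1)
        for isoform in tpm.index[on & off]:
            flagged.append((isoform, g))
    return flagged
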