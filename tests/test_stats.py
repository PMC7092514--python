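"""Landscape statistics: chi-square tests with printed-value checks,
percent change, region assignment/deviation, rank-sum with a permutation
oracle, PSI histograms, and exclusive-isoform detection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from splicescape.annotation import (
    ExpectationModel,
    TranscriptRegion,
    parse_gff3,
)
from splicescape.errors import ValidationError
from splicescape.events import SplicingEvent
from splicescape.stats import (
    chi_square_gof,
    exclusive_isoforms,
    exon_length_test,
    percent_change,
    psi_distribution,
    region_assign,
    region_deviation_test,
    tally_events,
)

R5, RC, R3 = TranscriptRegion.FIVE_UTR, TranscriptRegion.CDS, TranscriptRegion.THREE_UTR


def sig_figs(x, n=3):
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def make_event(start=120, end=180, gene="geneA", etype="CE", dpsi=0.5,
               comparison="MvF:control:hypothalamus", tissue="hypothalamus"):
    return SplicingEvent(
        gene_id=gene, node_id=1, chrom="chrT", start=start, end=end, strand="+",
        event_type=etype, psi_a=0.8, psi_b=0.8 - dpsi, delta_psi=dpsi,
        probability=0.99, n_a=3, n_b=3, comparison=comparison, tissue=tissue,
    )


class TestChiSquare:
    @pytest.mark.parametrize(
        "observed,expected_p",
        [
            ((225, 158), 6.18e-4),
            ((99, 59), 1.46e-3),
            ((123, 102), 0.162),
        ],
    )
    def test_two_cell_uniform_reproduces_printed_p(self, observed, expected_p):
        res = chi_square_gof(observed)
        assert sig_figs(res.p) == expected_p
        assert res.df == 1 and res.n == sum(observed)

    @pytest.mark.parametrize("a,b", [(10, 3), (140, 99), (7, 7), (500, 430)])
    def test_two_cell_uniform_equals_closed_form(self, a, b):
        res = chi_square_gof((a, b))
        assert res.statistic == pytest.approx((a - b) ** 2 / (a + b))

    def test_perfect_fit(self):
        res = chi_square_gof((50, 50))
        assert res.statistic == 0 and res.p == 1.0

    def test_explicit_proportions(self):
        res = chi_square_gof((20, 8), expected_proportions=(0.4, 0.6))
        exp = np.array([28 * 0.4, 28 * 0.6])
        assert res.statistic == pytest.approx(
            ((np.array([20, 8]) - exp) ** 2 / exp).sum()
        )

    def test_small_expected_warns_but_runs(self, caplog):
        with caplog.at_level("WARNING"):
            res = chi_square_gof((5, 2))
        assert "expected count" in caplog.text
        assert res.p > 0

    def test_zero_expected_is_error(self):
        with pytest.raises(ValidationError):
            chi_square_gof((5, 5), expected_proportions=(1.0, 0.0))


class TestPercentChange:
    def test_printed_pituitary_increase(self):
        assert percent_change(225, 158) == 42.0

    def test_no_change(self):
        assert percent_change(37, 37) == 0.0

    def test_signed_decrease(self):
        assert percent_change(158, 225) == -30.0  # 100*(158-225)/225

    def test_zero_reference_is_error(self):
        with pytest.raises(ValidationError):
            percent_change(10, 0)


class TestTally:
    def test_readback_of_known_counts(self):
        events = [make_event(etype="CE") for _ in range(5)] + [
            make_event(etype="RI") for _ in range(2)
        ]
        tally = tally_events(events, {"MvF:control:hypothalamus": "control"})
        by_type = tally.by_type("MvF:control:hypothalamus", "hypothalamus")
        assert by_type == {"CE": 5, "RI": 2}

    def test_empty_events(self):
        assert tally_events([]).total() == 0

    def test_totals_conserved_under_type_collapse(self):
        events = (
            [make_event(etype=t) for t in ("CE", "AA", "AD", "RI", "TE", "TS")]
            + [make_event(etype="CE")]
        )
        tally = tally_events(events)
        full = tally.by_type("MvF:control:hypothalamus", "hypothalamus")
        collapsed = tally.by_type(
            "MvF:control:hypothalamus", "hypothalamus", collapse=True
        )
        assert sum(full.values()) == sum(collapsed.values()) == 7
        assert collapsed["other"] == 2


class TestRegionAssign:
    # geneA regions: (1-50) 5UTR, (51-100)+(201-300)+(401-450) CDS, (451-500) 3UTR
    def test_node_inside_cds(self, toy_gff3):
        models = parse_gff3(toy_gff3)
        assert region_assign(make_event(210, 260), models) == RC

    def test_maximal_overlap_wins(self, toy_gff3):
        models = parse_gff3(toy_gff3)
        # 40 bp in 5'UTR (11-50), 50 bp in CDS (51-100)
        assert region_assign(make_event(11, 100), models) == RC

    def test_tie_breaks_toward_cds(self, toy_gff3):
        models = parse_gff3(toy_gff3)
        # 50 bp CDS (401-450), 50 bp 3'UTR (451-500)
        assert region_assign(make_event(401, 500), models) == RC

    def test_no_overlap_returns_none(self, toy_gff3, caplog):
        models = parse_gff3(toy_gff3)
        with caplog.at_level("WARNING"):
            assert region_assign(make_event(150, 190), models) is None


def make_expectation(p5=0.2, pc=0.6, p3=0.2, n=100):
    return ExpectationModel(
        region_location_counts={
            R5: int(p5 * n), RC: int(pc * n), R3: int(p3 * n)
        },
        exon_length_sample=[100] * 10,
    )


class TestRegionDeviation:
    def test_all_events_in_cds(self):
        em = make_expectation()
        devs, results = region_deviation_test({RC: 10}, em)
        by_region = {d.region: d.deviation for d in devs}
        assert by_region[R5] == -1.0
        assert by_region[RC] == pytest.approx(2 / 3, abs=1e-9)
        assert by_region[R3] == -1.0
        assert results["omnibus"].df == 2

    def test_proportional_observation_is_null(self):
        em = make_expectation()
        devs, results = region_deviation_test({R5: 20, RC: 60, R3: 20}, em)
        assert all(d.deviation == 0 for d in devs)
        assert results["omnibus"].p == 1.0
        for region in ("FIVE_UTR", "CDS", "THREE_UTR"):
            assert results[region].p == pytest.approx(1.0)

    def test_weighted_deviations_sum_to_zero(self):
        em = make_expectation(0.25, 0.55, 0.2)
        devs, _ = region_deviation_test({R5: 13, RC: 61, R3: 9}, em)
        props = em.region_proportions
        weighted = sum(d.deviation * props[d.region] for d in devs)
        assert weighted == pytest.approx(0.0, abs=1e-12)

    def test_injected_three_prime_depletion_recovered(self):
        """Thinning 3'UTR events to half their expected rate must yield a
        deviation near −0.5 against the known baseline total."""
        rng = np.random.default_rng(42)
        em = make_expectation()
        n_base = 4000
        regions = rng.choice([R5, RC, R3], size=n_base, p=[0.2, 0.6, 0.2])
        counts = {r: int((regions == r).sum()) for r in (R5, RC, R3)}
        counts[R3] = int(rng.binomial(counts[R3], 0.5))  # 50% depletion
        devs, _ = region_deviation_test(counts, em, expected_total=n_base)
        dev3 = next(d for d in devs if d.region == R3)
        assert dev3.deviation == pytest.approx(-0.5, abs=0.06)

    def test_zero_proportion_is_error(self):
        em = make_expectation(0.0, 0.8, 0.2)
        with pytest.raises(ValidationError):
            region_deviation_test({RC: 5}, em)


def rank_sum_brute_force(x, y):
    """Oracle: two-sided p by enumerating all C(n+m, n) group labelings of
    the pooled midranks."""
    from scipy.stats import rankdata

    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n = len(x)
    mu = n * (len(pooled) + 1) / 2
    obs = abs(ranks[:n].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestExonLengthTest:
    def test_identical_lists_give_p_one(self):
        res = exon_length_test([100, 100, 100], [100, 100, 100])
        assert res.p == 1.0

    def test_separated_triples_match_brute_force(self):
        res = exon_length_test([10, 12, 14], [100, 120, 140])
        assert res.p == pytest.approx(rank_sum_brute_force([10, 12, 14],
                                                           [100, 120, 140]))
        assert res.p == pytest.approx(2 / 20)  # both extreme labelings / C(6,3)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mode_equals_permutation_enumeration(self, seed):
        """Exact mode agrees with brute-force enumeration for every
        tie-free fixture with n ≤ 8."""
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 9, size=2)
        pooled = rng.choice(np.arange(10, 500), size=sizes.sum(), replace=False)
        x, y = pooled[: sizes[0]], pooled[sizes[0]:]
        res = exon_length_test(x.tolist(), y.tolist())
        assert res.p == pytest.approx(rank_sum_brute_force(x, y))

    def test_tied_small_samples_still_match_enumeration(self):
        x, y = [10, 10, 30], [10, 30, 50]
        res = exon_length_test(x, y)
        assert res.p == pytest.approx(rank_sum_brute_force(x, y))

    def test_null_type_one_error_controlled(self):
        """Samples drawn from the reference distribution reject at ~alpha."""
        rng = np.random.default_rng(3)
        genome = rng.lognormal(np.log(150), 0.6, size=500).astype(int) + 1
        rejections = 0
        reps = 200
        for _ in range(reps):
            sample = rng.choice(genome, size=20, replace=True)
            if exon_length_test(sample.tolist(), genome.tolist()).p < 0.05:
                rejections += 1
        assert rejections / reps < 0.09

    def test_tiny_sample_is_error(self):
        with pytest.raises(ValidationError):
            exon_length_test([5], [1, 2, 3])


class TestPsiDistribution:
    def test_filtered_input_leaves_central_bins_empty(self):
        events = [make_event(dpsi=d) for d in (0.3, -0.5, 0.12, 0.9, -0.11)]
        hist = psi_distribution(events, bins=20)
        central = hist[
            (hist["quantity"] == "delta_psi")
            & (hist["bin_lo"] >= -0.1)
            & (hist["bin_hi"] <= 0.1)
        ]
        assert central["count"].sum() == 0

    def test_single_event_single_bin(self):
        hist = psi_distribution([make_event(dpsi=0.35)], bins=10)
        dpsi = hist[hist["quantity"] == "delta_psi"]
        assert (dpsi["count"] > 0).sum() == 1

    def test_bimodal_mixture_readback(self):
        events = [make_event(dpsi=0.85) for _ in range(10)] + [
            make_event(dpsi=-0.85) for _ in range(10)
        ]
        hist = psi_distribution(events, bins=4)  # bins: [-1,-.5,0,.5,1]
        dpsi = hist[hist["quantity"] == "delta_psi"].set_index("bin_lo")["count"]
        assert dpsi[-1.0] == 10 and dpsi[0.5] == 10


def tpm_frame(values):
    return pd.DataFrame(values).T


class TestExclusiveIsoforms:
    DESIGN = {
        "c1": {"treatment": "control"}, "c2": {"treatment": "control"},
        "s1": {"treatment": "stress"}, "s2": {"treatment": "stress"},
    }

    def test_stress_exclusive_is_flagged(self):
        tpm = pd.DataFrame(
            {"c1": [0.0], "c2": [0.05], "s1": [5.0], "s2": [4.0]}, index=["iso1"]
        )
        flags = exclusive_isoforms(tpm, self.DESIGN, "treatment")
        assert flags == [("iso1", "stress")]

    def test_ubiquitous_isoform_not_flagged(self):
        tpm = pd.DataFrame(
            {"c1": [5.0], "c2": [6.0], "s1": [5.0], "s2": [4.0]}, index=["iso1"]
        )
        assert exclusive_isoforms(tpm, self.DESIGN, "treatment") == []

    def test_shared_expression_null_yields_no_flags(self):
        rng = np.random.default_rng(12)
        samples = list(self.DESIGN)
        tpm = pd.DataFrame(
            rng.lognormal(np.log(10), 0.5, size=(50, 4)),
            index=[f"iso{i}" for i in range(50)],
            columns=samples,
        )
        assert exclusive_isoforms(tpm, self.DESIGN, "treatment") == []

    def test_negative_tpm_rejected(self):
        tpm = pd.DataFrame({"c1": [-1.0], "c2": [0.0], "s1": [0.0], "s2": [0.0]})
        with pytest.raises(ValidationError):
            exclusive_isoforms(tpm, self.DESIGN, "treatment")
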