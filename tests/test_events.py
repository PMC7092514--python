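"""Differential PSI calls: I/O, bootstrap probability (with an exhaustive
enumeration oracle), significance filter semantics, and statistical
calibration of the caller."""

import itertools

import numpy as np
import pandas as pd
import pytest

from splicescape.errors import TableParseError, ValidationError
from splicescape.events import (
    Comparison,
    PsiTable,
    SplicingEvent,
    call_significant,
    delta_psi,
    delta_psi_all,
    read_diff_table,
    read_psi_table,
    sensitivity_recall,
    write_diff_table,
)
from splicescape.simulate import two_group_psi_table


def make_table(group_a, group_b, event_type="CE"):
    """PsiTable with a single node measured in two groups."""
    rows, design = [], {}
    for sex, values in (("M", group_a), ("F", group_b)):
        for i, v in enumerate(values, start=1):
            sid = f"{sex}{i}"
            design[sid] = {"sex": sex, "treatment": "control", "tissue": "hypothalamus"}
            rows.append((sid, "g1", 1, "chr1", 100, 200, "+", event_type, v, None))
    data = pd.DataFrame(
        rows,
        columns=["sample_id", "gene_id", "node_id", "chrom", "start", "end",
                 "strand", "event_type", "psi", "ci_width"],
    )
    return PsiTable(data=data, design=design)


CMP = Comparison("MvF", {"sex": "M"}, {"sex": "F"})


def enumerate_bootstrap_probability(a, b):
    """Oracle: exhaustively enumerate every within-group resample.

    For groups of size n and m there are n^n × m^m equally likely bootstrap
    draws; the probability is the fraction whose mean difference shares the
    sign of the point estimate (ties count half).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    point = a.mean() - b.mean()
    if point == 0:
        return 0.5
    means_a = [np.mean([a[i] for i in idx])
               for idx in itertools.product(range(len(a)), repeat=len(a))]
    means_b = [np.mean([b[i] for i in idx])
               for idx in itertools.product(range(len(b)), repeat=len(b))]
    same = ties = 0
    for ma in means_a:
        for mb in means_b:
            d = ma - mb
            if d == 0:
                ties += 1
            elif (d > 0) == (point > 0):
                same += 1
    total = len(means_a) * len(means_b)
    return (same + 0.5 * ties) / total


class TestReadPsiTable:
    def _write(self, path, rows):
        with open(path, "w") as fh:
            fh.write("Gene\tNode\tCoord\tStrand\tType\tPsi\tCI_Width\n")
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")

    def test_two_samples_three_nodes(self, tmp_path):
        design = {}
        paths = {}
        for sid in ("s1", "s2"):
            rows = [("g1", n, f"chr1:{n}00-{n}50", "+", "CE", 0.5, 0.1)
                    for n in (1, 2, 3)]
            p = tmp_path / f"{sid}.tsv"
            self._write(p, rows)
            paths[sid] = p
            design[sid] = {"sex": "M", "treatment": "control", "tissue": "gonad"}
        table = read_psi_table(paths, design)
        assert len(table.data) == 6

    def test_na_psi_is_retained_as_missing(self, tmp_path):
        p = tmp_path / "s.tsv"
        self._write(p, [("g1", 1, "chr1:100-150", "+", "CE", "NA", "NA")])
        table = read_psi_table(
            {"s": p}, {"s": {"sex": "M", "treatment": "control", "tissue": "gonad"}}
        )
        assert len(table.data) == 1
        assert table.data["psi"].isna().all()

    def test_malformed_coord_reports_line(self, tmp_path):
        p = tmp_path / "s.tsv"
        self._write(p, [("g1", 1, "chr1:100", "+", "CE", 0.5, 0.1)])
        with pytest.raises(TableParseError, match="line 2"):
            read_psi_table(
                {"s": p},
                {"s": {"sex": "M", "treatment": "control", "tissue": "gonad"}},
            )

    def test_unknown_event_type_named_in_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        self._write(p, [("g1", 1, "chr1:100-150", "+", "XX", 0.5, 0.1)])
        with pytest.raises(ValidationError, match="XX"):
            read_psi_table(
                {"s": p},
                {"s": {"sex": "M", "treatment": "control", "tissue": "gonad"}},
            )

    def test_sample_missing_from_design(self, tmp_path):
        p = tmp_path / "s.tsv"
        self._write(p, [("g1", 1, "chr1:100-150", "+", "CE", 0.5, 0.1)])
        with pytest.raises(ValidationError, match="design"):
            read_psi_table({"s": p}, {})


class TestDeltaPsi:
    def test_fully_separated_groups(self):
        table = make_table([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        ev = delta_psi(table, CMP, ("g1", 1), n_boot=500, seed=0)
        assert ev.delta_psi == 1.0 and ev.probability == 1.0

    def test_identical_groups_report_half(self):
        table = make_table([0.5, 0.5], [0.5, 0.5])
        ev = delta_psi(table, CMP, ("g1", 1), n_boot=500, seed=0)
        assert ev.delta_psi == 0.0 and ev.probability == 0.5

    @pytest.mark.parametrize(
        "a,b",
        [
            ([0.8, 0.7, 0.9], [0.4, 0.5, 0.3]),
            ([0.6, 0.45, 0.55], [0.5, 0.52, 0.4]),
            ([0.3, 0.5, 0.45], [0.45, 0.45, 0.5]),
            ([0.2, 0.9, 0.5], [0.55, 0.4, 0.6]),
        ],
    )
    def test_probability_matches_exhaustive_enumeration(self, a, b):
        """Monte-Carlo probability agrees with the 27x27 exhaustive
        bootstrap enumeration within ±0.01 on 3-vs-3 fixtures."""
        expected = enumerate_bootstrap_probability(a, b)
        table = make_table(a, b)
        ev = delta_psi(table, CMP, ("g1", 1), n_boot=10_000, seed=3)
        assert ev.probability == pytest.approx(expected, abs=0.01)

    def test_empty_group_is_skipped_with_warning(self, caplog):
        table = make_table([0.5, 0.6], [None, None])
        with caplog.at_level("WARNING"):
            assert delta_psi(table, CMP, ("g1", 1), n_boot=100, seed=0) is None

    def test_antisymmetry_under_group_swap(self):
        table = make_table([0.8, 0.55, 0.7], [0.5, 0.65, 0.4])
        swapped = Comparison("FvM", {"sex": "F"}, {"sex": "M"})
        e1 = delta_psi(table, CMP, ("g1", 1), n_boot=4000, seed=9)
        e2 = delta_psi(table, swapped, ("g1", 1), n_boot=4000, seed=9)
        assert e1.delta_psi == -e2.delta_psi
        assert e1.probability == e2.probability

    def test_same_seed_same_probability(self):
        table = make_table([0.8, 0.55, 0.7], [0.5, 0.65, 0.4])
        e1 = delta_psi(table, CMP, ("g1", 1), n_boot=2000, seed=5)
        e2 = delta_psi(table, CMP, ("g1", 1), n_boot=2000, seed=5)
        assert e1.probability == e2.probability

    def test_beta_method_agrees_on_separated_groups(self):
        table = make_table([0.95, 0.9, 0.92], [0.05, 0.1, 0.08])
        ev = delta_psi(table, CMP, ("g1", 1), n_boot=2000, seed=1, method="beta")
        assert ev.probability > 0.99

    def test_all_matches_single_node_calls(self):
        table = make_table([0.8, 0.55, 0.7], [0.5, 0.65, 0.4])
        from splicescape.events import _node_seed

        whole = delta_psi_all(table, CMP, n_boot=2000, seed=5)
        single = delta_psi(
            table, CMP, ("g1", 1), n_boot=2000, seed=_node_seed(5, "g1", 1)
        )
        assert len(whole) == 1
        assert whole[0].probability == single.probability
        assert whole[0].delta_psi == single.delta_psi


class TestSignificanceFilter:
    def base(self, probability, dpsi):
        return SplicingEvent(
            gene_id="g", node_id=1, chrom="c", start=1, end=10, strand="+",
            event_type="CE", psi_a=0.5, psi_b=0.5 - dpsi, delta_psi=dpsi,
            probability=probability, n_a=3, n_b=3,
        )

    def test_probability_cut_is_strict(self):
        assert call_significant([self.base(0.95, 0.5)]) == []
        assert len(call_significant([self.base(0.951, 0.5)])) == 1

    def test_effect_cut_is_inclusive(self):
        assert len(call_significant([self.base(0.96, 0.1)])) == 1
        assert call_significant([self.base(0.96, 0.0999)]) == []

    def test_negative_effects_pass_on_magnitude(self):
        assert len(call_significant([self.base(0.99, -0.3)])) == 1

    def test_empty_input(self):
        assert call_significant([]) == []

    def test_recall_empty_when_all_effects_large(self):
        events = [self.base(0.99, 0.4), self.base(0.97, -0.2)]
        assert sensitivity_recall(events) == []

    def test_recall_returns_low_effect_high_probability(self):
        ev = self.base(0.97, 0.05)
        assert sensitivity_recall([ev]) == [ev]

    def test_recall_counts_constructed_cohort(self):
        low = [self.base(0.95 + 0.0005 * i, 0.05) for i in range(1, 61)]
        high = [self.base(0.99, 0.5) for _ in range(20)]
        weak = [self.base(0.5, 0.05) for _ in range(30)]
        assert len(sensitivity_recall(low + high + weak)) == 60


class TestDiffTable:
    def test_round_trip(self, tmp_path):
        table = make_table([0.8, 0.7], [0.3, 0.2])
        ev = delta_psi(table, CMP, ("g1", 1), n_boot=200, seed=0)
        path = tmp_path / "diff.tsv"
        assert write_diff_table([ev] * 3, path) == 3
        back = read_diff_table(path)
        assert len(back) == 3
        assert back[0].delta_psi == pytest.approx(ev.delta_psi, abs=1e-5)
        assert back[0].gene_id == "g1" and back[0].event_type == "CE"

    def test_empty_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        assert write_diff_table([], path) == 0
        assert path.read_text().count("\n") == 1


class TestCalibration:
    def test_null_false_positive_rate_below_two_percent(self):
        """Under a shared Beta (n=12 per group), fewer than 2% of 1000
        null nodes pass the default significance filter."""
        table, cmp = two_group_psi_table(1000, n_per_group=12, delta=0.0, seed=7)
        events = delta_psi_all(table, cmp, n_boot=10_000, seed=7)
        sig = call_significant(events)
        assert len(events) == 1000
        assert len(sig) / len(events) < 0.02

    def test_injected_effects_recovered(self):
        """True ΔPSI = 0.3 with per-sample sd ≈ 0.1 and n=12 per group is
        recovered ≥ 90% of the time with an unbiased estimate."""
        table, cmp = two_group_psi_table(
            200, n_per_group=12, delta=0.3, seed=8, concentration=21.75
        )
        events = delta_psi_all(table, cmp, n_boot=10_000, seed=8)
        sig = call_significant(events)
        assert len(sig) / len(events) >= 0.90
        mean_delta = np.mean([e.delta_psi for e in events])
        assert mean_delta == pytest.approx(0.3, abs=0.03)
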