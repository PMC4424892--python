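"""Event enumeration against manual oracles, PSI arithmetic, the LRT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ersplice.splice_events import (
    call_events,
    compare_events_across_lines,
    enumerate_events,
    psi,
)
from ersplice.splice_events import test_event as event_test

from conftest import make_annotation, make_gene


class TestEnumeration:
    def test_canonical_cassette_exon(self):
        ann = make_annotation(make_gene("g", "chr1", "+", {
            "t1": [(100, 200), (300, 400), (500, 600)],
            "t2": [(100, 200), (500, 600)],
        }))
        events = list(enumerate_events(ann).values())
        assert len(events) == 1
        assert events[0].event_type == "SE"
        assert events[0].coords == (200, 300, 400, 500)

    def test_plus_strand_donor_shift_is_a5ss(self):
        ann = make_annotation(make_gene("g", "chr1", "+", {
            "t1": [(100, 200), (500, 600)],
            "t2": [(100, 260), (500, 600)],
        }))
        events = list(enumerate_events(ann).values())
        assert [e.event_type for e in events] == ["A5SS"]
        assert events[0].coords == (200, 260, 500)

    def test_minus_strand_swaps_donor_acceptor(self):
        ann = make_annotation(make_gene("g", "chr1", "-", {
            "t1": [(100, 200), (500, 600)],
            "t2": [(100, 260), (500, 600)],
        }))
        (event,) = enumerate_events(ann).values()
        assert event.event_type == "A3SS"

    def test_mutually_exclusive_exons(self):
        ann = make_annotation(make_gene("g", "chr1", "+", {
            "t1": [(100, 200), (300, 400), (500, 600)],
            "t2": [(100, 200), (420, 480), (500, 600)],
        }))
        (event,) = enumerate_events(ann).values()
        assert event.event_type == "MXE"
        assert event.coords == (200, 300, 400, 420, 480, 500)

    def test_intron_retention_with_alternative_tss_yields_only_ri(self):
        # minus-strand gene: the variant starts from a different promoter
        # AND retains the first intron; the TSS change itself is not an event
        ann = make_annotation(make_gene("g", "chr1", "-", {
            "major": [(1000, 1200), (1500, 1700), (2000, 2200)],
            "variant": [(1000, 1200), (1500, 2500)],
        }))
        events = list(enumerate_events(ann).values())
        assert [e.event_type for e in events] == ["RI"]
        assert events[0].coords == (1500, 1700, 2000, 2500)

    def test_four_isoform_toy_matches_manual_enumeration(self, four_isoform_toy):
        ann, manual = four_isoform_toy
        assert set(enumerate_events(ann)) == manual

    def test_single_isoform_gene_has_no_events(self):
        ann = make_annotation(make_gene("g", "chr2", "+", {
            "t1": [(10, 50), (80, 120)],
        }))
        assert enumerate_events(ann) == {}


class TestPsi:
    def test_equal_lengths(self):
        assert psi(30, 10, 1, 1) == pytest.approx(0.75)

    def test_length_normalization(self):
        # (30/2) / (30/2 + 10/1) = 15/25
        assert psi(30, 10, 2, 1) == pytest.approx(0.6)

    def test_zero_inclusion(self):
        assert psi(0, 5, 2, 1) == 0.0

    def test_undefined_when_no_reads(self):
        with pytest.raises(ValueError):
            psi(0, 0, 2, 1)

    @given(st.integers(0, 10_000), st.integers(0, 10_000),
           st.integers(1, 4), st.integers(1, 4))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, ijc, sjc, li, ls):
        if ijc == 0 and sjc == 0:
            return
        assert psi(ijc, sjc, li, ls) + psi(sjc, ijc, ls, li) == pytest.approx(1.0)


class TestEventTest:
    def test_identical_counts_give_p_one(self):
        res = event_test([50, 40], [50, 60], [50, 40], [50, 60], 2, 1, c=0.1)
        assert res["dpsi"] == 0.0
        assert res["p"] == 1.0

    def test_no_reads_excluded(self):
        assert event_test([0, 0], [0, 0], [5], [5], 1, 1) is None

    def test_condition_swap_flips_dpsi_sign(self, rng):
        i1, s1 = [30, 25, 28], [10, 12, 11]
        i2, s2 = [12, 14, 11], [30, 29, 33]
        a = event_test(i1, s1, i2, s2, 2, 1)
        b = event_test(i2, s2, i1, s1, 2, 1)
        assert a["dpsi"] == pytest.approx(-b["dpsi"])
        assert a["p"] == pytest.approx(b["p"])

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            event_test([1], [1], [1], [1], 1, 1, c=1.0)

    def _simulate(self, rng, psi_veh, psi_e2, reads_per_cond=300, n_rep=3):
        out = []
        for p_true in (psi_veh, psi_e2):
            n = rng.poisson(reads_per_cond / n_rep, n_rep)
            ijc = rng.binomial(n, p_true)
            out.append((ijc, n - ijc))
        return out

    def test_power_at_planted_delta(self, rng):
        # |delta psi| = 0.3 with ~300 junction reads per condition should be
        # caught by the interval-null LRT at p < 0.05 nearly always
        hits = 0
        trials = 100
        for _ in range(trials):
            (i1, s1), (i2, s2) = self._simulate(rng, 0.45, 0.75)
            res = event_test(i1, s1, i2, s2, 1, 1, c=0.1)
            if res["p"] < 0.05:
                hits += 1
        assert hits / trials >= 0.8

    def test_interval_null_absorbs_small_changes(self, rng):
        # planted change of 0.05 sits inside the null interval |dpsi| <= 0.1
        hits = 0
        trials = 200
        for _ in range(trials):
            (i1, s1), (i2, s2) = self._simulate(rng, 0.50, 0.55)
            res = event_test(i1, s1, i2, s2, 1, 1, c=0.1)
            if res["p"] < 0.05:
                hits += 1
        assert hits / trials <= 0.05


class TestCrossLineEvents:
    def table(self, rows):
        return pd.DataFrame(
            rows, columns=["event_key", "significant", "dpsi"]
        )

    def test_common_and_opposite_sets(self):
        wt = self.table([("e1", True, 0.2), ("e2", True, 0.3),
                         ("e3", False, 0.0)])
        ct = self.table([("e1", True, -0.2), ("e2", True, 0.25),
                         ("e3", True, 0.4)])
        nt = self.table([("e1", True, -0.15), ("e2", True, 0.2),
                         ("e3", False, 0.0)])
        common, opposite = compare_events_across_lines(wt, ct, nt)
        assert common == {"e1", "e2"}
        assert opposite == {"e1"}

    def test_single_line_event_in_neither_set(self):
        wt = self.table([("e", False, 0.0)])
        ct = self.table([("e", True, 0.3)])
        nt = self.table([("e", False, 0.0)])
        common, opposite = compare_events_across_lines(wt, ct, nt)
        assert common == frozenset() and opposite == frozenset()


def test_call_events_applies_effect_and_fdr_gate(small_dataset):
    from ersplice.splice_events import EFFECTIVE_LENGTHS

    events = enumerate_events(small_dataset.annotation)
    sub = small_dataset.junction_counts.query("cell_line == 'wt'")
    calls = call_events(sub, events, c=0.1, alpha=0.05)
    sig = calls[calls["significant"]]
    assert (sig["q"] <= 0.05).all()
    assert (sig["dpsi"].abs() >= 0.1).all()
    assert set(calls["event_type"]) <= set(EFFECTIVE_LENGTHS)
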