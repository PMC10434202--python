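"""Segmentation, event taxonomy, breakpoints and translocation pairing."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lohscan as ls
from lohscan.calling import DEFAULT_THRESHOLDS, _merge_short_runs, _runs

LEVELS = (0.0, 0.5, 1.0, 1.5)


def profile_from_states(genome, chrom, w_states, y_states):
    pos = genome.snp_positions(chrom)[: len(w_states)]
    return pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "rc_w": [LEVELS[s] for s in w_states],
        "rc_y": [LEVELS[s] for s in y_states],
        "in_repeat": False,
    })


def brute_force_segmentation(rc, min_snps=3):
    """Exhaustive minimal-misfit segmentation of one homolog's RC values:
    all partitions into runs of >= min_snps sites (adjacent runs in
    different states), each run at its best-fitting copy-state level."""
    n = len(rc)
    best = (float("inf"), None)

    def run_cost(lo, hi):
        costs = [sum(abs(v - L) for v in rc[lo:hi]) for L in LEVELS]
        s = int(np.argmin(costs))
        return costs[s], s

    def partitions(start):
        if start == n:
            yield []
            return
        for end in range(start + min_snps, n + 1):
            if n - end not in (0,) and n - end < min_snps:
                continue
            for rest in partitions(end):
                yield [(start, end)] + rest

    for part in partitions(0) if n >= min_snps else [[(0, n)]]:
        cost, states = 0.0, []
        for lo, hi in part:
            c, s = run_cost(lo, hi)
            cost += c
            states.append((lo, hi, s))
        if any(a[2] == b[2] for a, b in zip(states, states[1:])):
            continue
        if cost < best[0] - 1e-12:
            best = (cost, states)
    out = np.empty(n, dtype=int)
    for lo, hi, s in best[1]:
        out[lo:hi] = s
    return out


class TestSegmentation:
    def test_constant_half_gives_single_state_one_segment(self, yeast):
        prof = profile_from_states(yeast, "I", [1] * 50, [1] * 50)
        segs = ls.segment_copy_states(prof)
        assert len(segs) == 2  # one per homolog
        assert all(s.state == 1 and s.n_snps == 50 for s in segs)

    def test_interstitial_tract_gives_three_segments_each(self, yeast):
        w = [1] * 10 + [0] * 6 + [1] * 10
        y = [1] * 10 + [2] * 6 + [1] * 10
        segs = ls.segment_copy_states(profile_from_states(yeast, "XV", w, y))
        by_h = {h: [s.state for s in segs if s.homolog == h] for h in ("W", "Y")}
        assert by_h["W"] == [1, 0, 1]
        assert by_h["Y"] == [1, 2, 1]

    def test_short_run_merged_into_dominant_neighbor(self, yeast):
        w = [1] * 12 + [0] * 2 + [1] * 4
        segs = ls.segment_copy_states(profile_from_states(yeast, "I", w, [1] * 18))
        w_states = [s.state for s in segs if s.homolog == "W"]
        assert w_states == [1]

    def test_matches_exhaustive_minimal_misfit_on_noiseless_instances(self, yeast):
        """Every noiseless <=12-SNP instance with runs >= min_snps equals the
        brute-force minimal-misfit segmentation."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            runs = []
            total = 0
            while total < 9:
                L = int(rng.integers(3, 6))
                s = int(rng.integers(0, 4))
                if runs and s == runs[-1][1]:
                    continue
                runs.append((L, s))
                total += L
            states = [s for L, s in runs for _ in range(L)][:12]
            rc = [LEVELS[s] for s in states]
            prof = profile_from_states(yeast, "I", states, [1] * len(states))
            segs = [s for s in ls.segment_copy_states(prof) if s.homolog == "W"]
            got = np.concatenate([[s.state] * s.n_snps for s in segs])
            oracle = brute_force_segmentation(rc)
            np.testing.assert_array_equal(got, oracle)

    def test_run_length_encoding_helpers(self):
        states = np.array([1, 1, 0, 0, 0, 2, 2, 2, 2])
        assert _runs(states) == [(0, 1, 1), (2, 4, 0), (5, 8, 2)]
        merged = _merge_short_runs(states.copy(), 3)
        assert _runs(merged)[0][2] == 0  # 2-run absorbed by longer neighbor


class TestEventCalling:
    def test_interstitial_loh_call(self, yeast):
        w = [1] * 10 + [0] * 6 + [1] * 10
        y = [1] * 10 + [2] * 6 + [1] * 10
        prof = profile_from_states(yeast, "XV", w, y)
        segs = ls.segment_copy_states(prof)
        pos = {"XV": prof["pos"].to_numpy()}
        events = ls.call_events(segs, yeast, positions=pos)
        assert len(events) == 1
        e = events[0]
        assert (e.type, e.class_code, e.homolog) == ("I-LOH", "A1", "Y")
        assert e.states == (0, 2)

    def test_left_telomeric_tract_is_terminal_loh(self, yeast):
        n = 40
        w = [0] * 15 + [1] * (n - 15)
        y = [2] * 15 + [1] * (n - 15)
        prof = profile_from_states(yeast, "XIV", w, y)
        events = ls.call_events(ls.segment_copy_states(prof), yeast,
                                positions={"XIV": prof["pos"].to_numpy()})
        assert [e.type for e in events] == ["T-LOH"]
        assert events[0].start == 1

    def test_whole_chromosome_loss_and_gain(self, yeast, exact_depths_fn):
        events_in = [
            ls.TrueEvent("UPD", "IX", 1, 439_888, "W"),
            ls.TrueEvent("TRISOMY", "I", 1, 230_218, "Y"),
            ls.TrueEvent("MONOSOMY", "V", 1, 576_874, "W"),
        ]
        kt, _ = ls.spike_events(yeast, ls.SimulationConfig(rng_seed=1, events=events_in))
        res = ls.CopyStateModel(ls.compute_rc(exact_depths_fn(kt), yeast), yeast,
                                smooth_window=1).fit()
        got = {(e.type, e.chrom, e.class_code, e.whole_chromosome) for e in res.events}
        assert got == {
            ("UPD", "IX", "D4", True),
            ("TRISOMY", "I", "D2", True),
            ("MONOSOMY", "V", "D3", True),
        }

    def test_terminal_deletion_call(self, yeast, exact_depths_fn):
        ev = ls.TrueEvent("T-DEL", "III", 1, 175_342, "W")
        kt, _ = ls.spike_events(yeast, ls.SimulationConfig(rng_seed=1, events=[ev]))
        res = ls.CopyStateModel(ls.compute_rc(exact_depths_fn(kt), yeast), yeast,
                                smooth_window=1).fit()
        assert [(e.type, e.class_code, e.chrom, e.start) for e in res.events] == [
            ("T-DEL", "C1", "III", 1)
        ]

    def test_fully_heterozygous_gives_empty_list(self, yeast, exact_depths_fn):
        kt, _ = ls.spike_events(yeast, ls.SimulationConfig(rng_seed=1, events=[]))
        res = ls.CopyStateModel(ls.compute_rc(exact_depths_fn(kt), yeast), yeast).fit()
        assert res.events == []

    def test_uninterpretable_region_reported_not_dropped(self, yeast):
        # interior single-homolog deletion is outside the taxonomy
        n = 40
        w = [1] * 15 + [0] * 10 + [1] * (n - 25)
        prof = profile_from_states(yeast, "II", w, [1] * n)
        events = ls.call_events(ls.segment_copy_states(prof), yeast,
                                positions={"II": prof["pos"].to_numpy()})
        assert [e.type for e in events] == ["UNCLASSIFIED"]
        assert events[0].class_code == "NA"

    def test_copy_neutrality_of_loh_calls(self, yeast, exact_depths_fn):
        rng = np.random.default_rng(19)
        cfg = ls.SimulationConfig(rng_seed=19, rates=ls.FURFURAL_RATES, divisions=400)
        for _ in range(5):
            kt, _ = ls.spike_events(yeast, cfg, rng=rng)
            res = ls.CopyStateModel(ls.compute_rc(exact_depths_fn(kt), yeast), yeast,
                                    smooth_window=1).fit()
            for e in res.events:
                if e.type in ("I-LOH", "T-LOH", "UPD"):
                    assert sum(e.states) == 2

    def test_conversion_associated_terminal_loh_flagged_b5(self, yeast):
        n = 60
        # terminal tract to SNP 20, het gap, then a conversion tract nearby
        w = [0] * 20 + [1] * 4 + [0] * 5 + [1] * (n - 29)
        y = [2] * 20 + [1] * 4 + [2] * 5 + [1] * (n - 29)
        prof = profile_from_states(yeast, "VII", w, y)
        events = ls.call_events(ls.segment_copy_states(prof), yeast,
                                positions={"VII": prof["pos"].to_numpy()})
        assert len(events) == 1
        e = events[0]
        assert e.type == "T-LOH" and e.class_code == "B5" and e.conversion_associated
        assert e.n_snps == 25


class TestClassification:
    @pytest.mark.parametrize(
        "etype, homolog, kwargs, code",
        [
            ("I-LOH", "Y", {}, "A1"),
            ("I-LOH", "W", {}, "A2"),
            ("T-LOH", "Y", {}, "B1"),
            ("T-LOH", "W", {}, "B2"),
            ("T-DEL", "W", {}, "C1"),
            ("T-DEL", "Y", {}, "C2"),
            ("T-DUP", "W", {}, "C3"),
            ("T-DUP", "Y", {}, "C4"),
            ("TRISOMY", "W", {}, "D1"),
            ("TRISOMY", "Y", {}, "D2"),
            ("MONOSOMY", "W", {}, "D3"),
            ("UPD", "Y", {}, "D4"),
            ("T-LOH", "W", {"conversion_associated": True}, "B5"),
        ],
    )
    def test_default_codes(self, yeast, etype, homolog, kwargs, code):
        e = ls.EventCall(type=etype, chrom="I", start=1, end=50_000,
                         homolog=homolog, n_snps=10, **kwargs)
        assert ls.classify_event(e, yeast) == code

    def test_centromere_spanning_terminal_loh_is_b3_b4(self, yeast):
        # chr I centromere at ~151.5 kb; a left-terminal tract past it spans it
        e = ls.EventCall(type="T-LOH", chrom="I", start=1, end=200_000,
                         homolog="Y", n_snps=50)
        assert ls.classify_event(e, yeast) == "B3"
        e2 = ls.EventCall(type="T-LOH", chrom="I", start=1, end=100_000,
                          homolog="Y", n_snps=30)
        assert ls.classify_event(e2, yeast) == "B1"

    def test_taxonomy_remap(self, yeast):
        e = ls.EventCall(type="T-LOH", chrom="I", start=1, end=200_000,
                         homolog="Y", n_snps=50)
        assert ls.classify_event(e, yeast, taxonomy={"B3": "B1"}) == "B1"


class TestBreakpoints:
    def test_interval_brackets_the_transition(self, yeast):
        w = [1] * 10 + [0] * 6 + [1] * 10
        y = [1] * 10 + [2] * 6 + [1] * 10
        prof = profile_from_states(yeast, "XV", w, y)
        events = ls.call_events(ls.segment_copy_states(prof), yeast,
                                positions={"XV": prof["pos"].to_numpy()})
        pos = prof["pos"].to_numpy()
        e = events[0]
        assert (e.bp_left.lo, e.bp_left.hi) == (pos[9], pos[10])
        assert (e.bp_right.lo, e.bp_right.hi) == (pos[15], pos[16])
        assert e.bp_left.lo < e.bp_left.midpoint < e.bp_left.hi

    def test_resolve_breakpoint_matches_call(self, yeast):
        w = [1] * 10 + [0] * 6 + [1] * 10
        y = [1] * 10 + [2] * 6 + [1] * 10
        prof = profile_from_states(yeast, "XV", w, y)
        events = ls.call_events(ls.segment_copy_states(prof), yeast,
                                positions={"XV": prof["pos"].to_numpy()})
        bp = ls.resolve_breakpoint(events[0], prof, side="left")
        assert (bp.lo, bp.hi) == (events[0].bp_left.lo, events[0].bp_left.hi)

    def test_transition_at_chromosome_start_clamps_to_one(self, yeast):
        n = 40
        w = [0] * 15 + [1] * (n - 15)
        y = [2] * 15 + [1] * (n - 15)
        prof = profile_from_states(yeast, "XIV", w, y)
        events = ls.call_events(ls.segment_copy_states(prof), yeast,
                                positions={"XIV": prof["pos"].to_numpy()})
        e = events[0]
        assert e.bp_left.lo == 1
        bp = ls.resolve_breakpoint(e, prof)  # auto: the non-telomeric edge
        assert bp.lo == prof["pos"].iloc[14]


class TestTranslocationPairing:
    def test_paired_terminal_duplications(self, yeast):
        """Two left-terminal duplications, one centric fragment: a single
        monocentric product of 818,333 bp."""
        dup2 = ls.EventCall(type="T-DUP", chrom="II", start=1, end=635_650,
                            homolog="W", n_snps=400, event_id="e1")
        dup13 = ls.EventCall(type="T-DUP", chrom="XIII", start=1, end=182_683,
                             homolog="W", n_snps=100, event_id="e2")
        pairing = ls.pair_translocations([dup2, dup13], yeast)
        assert len(pairing) == 1
        h = pairing.hypotheses[0]
        assert h.predicted_size == 818_333
        assert h.acceptor.chrom == "II" and h.acceptor.has_centromere
        assert h.donor.chrom == "XIII" and not h.donor.has_centromere
        assert pairing.unresolved == []

    def test_paired_terminal_deletions_pair_via_complements(self, yeast):
        del3 = ls.EventCall(type="T-DEL", chrom="III", start=1, end=175_342,
                            homolog="W", n_snps=90, event_id="e1")
        del14 = ls.EventCall(type="T-DEL", chrom="XIV", start=1, end=518_591,
                             homolog="W", n_snps=250, event_id="e2")
        pairing = ls.pair_translocations([del3, del14], yeast)
        assert len(pairing) == 1
        h = pairing.hypotheses[0]
        # retained complements: III right part (acentric) + XIV right part (CEN14)
        assert h.predicted_size == (316_620 - 175_342) + (784_333 - 518_591)
        assert abs(h.predicted_size - 400_000) / 400_000 < 0.05
        assert h.acceptor.chrom == "XIV"

    def test_single_unpaired_terminal_cnv_is_unresolved(self, yeast):
        lone = ls.EventCall(type="T-DEL", chrom="III", start=1, end=175_342,
                            homolog="W", n_snps=90, event_id="e1")
        pairing = ls.pair_translocations([lone], yeast)
        assert len(pairing) == 0
        assert pairing.unresolved == [lone]

    def test_two_centric_fragments_rejected(self, yeast):
        # both duplicated fragments contain their centromere: no hypothesis
        a = ls.EventCall(type="T-DUP", chrom="II", start=1, end=635_650,
                         homolog="W", n_snps=10, event_id="a")
        b = ls.EventCall(type="T-DUP", chrom="XIV", start=1, end=700_000,
                         homolog="W", n_snps=10, event_id="b")
        pairing = ls.pair_translocations([a, b], yeast)
        assert len(pairing) == 0
        assert len(pairing.unresolved) == 2
        assert any("both" in r for r in pairing.rejected)

    def test_monocentric_constraint_enforced_by_type(self, yeast):
        frag = ls.Fragment("II", 1, 635_650, True)
        with pytest.raises(ValueError, match="centromere"):
            ls.TranslocationHypothesis(donor=frag, acceptor=frag)

    def test_best_pairing_minimises_unexplained_length(self, yeast):
        # three dups: the centric II fragment should pair with the larger
        # acentric fragment, leaving the smallest unexplained
        a = ls.EventCall(type="T-DUP", chrom="II", start=1, end=635_650,
                         homolog="W", n_snps=10, event_id="a")  # centric
        b = ls.EventCall(type="T-DUP", chrom="XIII", start=1, end=182_683,
                         homolog="W", n_snps=10, event_id="b")  # acentric
        c = ls.EventCall(type="T-DUP", chrom="V", start=1, end=20_000,
                         homolog="W", n_snps=5, event_id="c")  # acentric, small
        pairing = ls.pair_translocations([a, b, c], yeast)
        assert len(pairing) == 1
        assert pairing.hypotheses[0].donor.chrom == "XIII"
        assert [u.event_id for u in pairing.unresolved] == ["c"]


class TestEventIO:
    def test_events_tsv_round_trip(self, yeast, exact_depths_fn, tmp_path):
        spiked = [
            ls.TrueEvent("T-DEL", "III", 1, 175_342, "W"),
            ls.TrueEvent("I-LOH", "XV", 369_905, 372_085, "W"),
            ls.TrueEvent("UPD", "IX", 1, 439_888, "W"),
        ]
        kt, _ = ls.spike_events(yeast, ls.SimulationConfig(rng_seed=1, events=spiked))
        res = ls.CopyStateModel(ls.compute_rc(exact_depths_fn(kt), yeast), yeast,
                                smooth_window=1, isolate="LF1").fit()
        ls.write_events_tsv(res.events, tmp_path / "e.tsv")
        back = ls.read_events_tsv(tmp_path / "e.tsv")
        assert [(e.type, e.chrom, e.start, e.end, e.homolog, e.isolate) for e in back] == \
               [(e.type, e.chrom, e.start, e.end, e.homolog, e.isolate) for e in res.events]

    def test_bed_export_zero_based_half_open(self, tmp_path):
        e = ls.EventCall(type="T-DEL", chrom="III", start=1, end=175_342,
                         homolog="W", n_snps=90, class_code="C1")
        ls.write_events_bed([e], tmp_path / "e.bed")
        line = (tmp_path / "e.bed").read_text().strip().split("\t")
        assert line[:3] == ["III", "0", "175342"]

    def test_summary_mentions_calls(self, yeast, exact_depths_fn):
        ev = ls.TrueEvent("T-DEL", "III", 1, 175_342, "W")
        kt, _ = ls.spike_events(yeast, ls.SimulationConfig(rng_seed=1, events=[ev]))
        res = ls.CopyStateModel(ls.compute_rc(exact_depths_fn(kt), yeast), yeast,
                                smooth_window=1).fit()
        text = res.summary()
        assert "T-DEL" in text and "C1" in text
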