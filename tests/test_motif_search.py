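"""Sliding-window angular motif search: scoring, ranking, recovery."""

import math

import numpy as np
import pytest

from naworm.fixtures import make_decoy_worms, perturb_worm
from naworm.geometry import TorsionAngle
from naworm.motif_search import (
    ModeMismatchError,
    angle_delta,
    position_delta,
    search,
    write_results,
)
from naworm.wormdb import Worm, WormEntry, build_database, worm_from_chain

from oracles import brute_force_search, worm_angle_list


def _worm(source_id, pairs, mode="c4", seq_start=1):
    entries = [
        WormEntry(
            position=i + 1,
            seq_id=seq_start + i,
            residue_name="N",
            eta=TorsionAngle(e) if e is not None else TorsionAngle(None),
            theta=TorsionAngle(t) if t is not None else TorsionAngle(None),
        )
        for i, (e, t) in enumerate(pairs)
    ]
    return Worm(source_id=source_id, entries=entries, mode=mode)


class TestDeltas:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(10.0, 350.0, 20.0), (90.0, 90.0, 0.0), (0.0, 180.0, 180.0)],
        ids=["wraparound", "identity", "antipodal"],
    )
    def test_angle_delta(self, a, b, expected):
        assert angle_delta(a, b) == pytest.approx(expected)
        assert angle_delta(b, a) == pytest.approx(expected)  # symmetry

    @pytest.mark.parametrize(
        "probe,window,expected",
        [
            ((100.0, 200.0), (100.0, 200.0), 0.0),
            ((100.0, 200.0), (103.0, 196.0), 5.0),  # 3-4-5 triangle
            ((5.0, 200.0), (355.0, 200.0), 10.0),  # wraparound on eta only
        ],
        ids=["identical", "3-4-5", "wraparound-eta"],
    )
    def test_position_delta(self, probe, window, expected):
        assert position_delta(probe, window) == pytest.approx(expected)
        assert position_delta(window, probe) == pytest.approx(expected)

    def test_undefined_angle_is_incomparable(self):
        assert math.isnan(position_delta((None, 200.0), (100.0, 200.0)))


class TestSearch:
    @pytest.fixture()
    def fixture_worm(self, aform_chain):
        return worm_from_chain(aform_chain, mode="c4")

    def test_self_match_is_rank_one_with_score_zero(self, fixture_worm):
        probe = fixture_worm.subworm(3, 8)
        hits = search(probe, [fixture_worm], top_n=5)
        assert hits[0].window_start == 3
        assert hits[0].score == pytest.approx(0.0, abs=1e-12)
        assert hits[0].source_id == fixture_worm.source_id

    def test_single_position_perturbation_shifts_mean_score_by_delta_over_L(
        self, fixture_worm
    ):
        probe = perturb_worm(fixture_worm.subworm(3, 8), position=2, delta_eta=7.0)
        hits = search(probe, [fixture_worm], top_n=1)
        assert hits[0].window_start == 3
        assert hits[0].score == pytest.approx(7.0 / 6.0, abs=1e-9)
        # sum aggregation sees the raw 7 degrees
        hits_sum = search(probe, [fixture_worm], aggregator="sum", top_n=1)
        assert hits_sum[0].score == pytest.approx(7.0, abs=1e-9)

    def test_planted_motif_recovered_at_rank_one(self, fixture_worm):
        motif = _worm(
            "motif",
            [(12.0, 300.0), (250.0, 40.0), (90.0, 180.0), (5.0, 355.0),
             (200.0, 200.0), (330.0, 15.0)],
        )
        decoys = make_decoy_worms(20, 50, seed=7, planted_motif=motif)
        hits = search(motif, list(decoys.worms), top_n=3)
        assert hits[0].source_id == decoys.planted_source_id
        assert hits[0].window_start == decoys.planted_start
        assert hits[0].score == pytest.approx(0.0, abs=1e-9)

    def test_full_ranked_list_matches_brute_force_oracle(self, fixture_worm):
        decoys = make_decoy_worms(8, 60, seed=13).worms
        worms = [fixture_worm, *decoys]  # ~500 total positions
        probe = fixture_worm.subworm(4, 9)
        hits = search(probe, worms, top_n=10_000)
        expected = brute_force_search(
            worm_angle_list(probe),
            [(w.source_id, worm_angle_list(w)) for w in worms],
        )
        assert len(hits) == len(expected)
        for hit, (score, source_id, start) in zip(hits, expected):
            assert hit.source_id == source_id
            assert hit.window_start == start
            assert hit.score == pytest.approx(score, abs=1e-9)

    def test_global_angle_rotation_leaves_scores_unchanged(self):
        rng = np.random.default_rng(21)
        probe_pairs = [tuple(rng.uniform(0, 360, 2)) for _ in range(4)]
        worm_pairs = [tuple(rng.uniform(0, 360, 2)) for _ in range(30)]
        offset = 137.5

        def rotated(pairs):
            return [((e + offset) % 360, (t + offset) % 360) for e, t in pairs]

        base = search(_worm("p", probe_pairs), [_worm("w", worm_pairs)], top_n=100)
        rot = search(
            _worm("p", rotated(probe_pairs)),
            [_worm("w", rotated(worm_pairs))],
            top_n=100,
        )
        assert [h.window_start for h in base] == [h.window_start for h in rot]
        for a, b in zip(base, rot):
            assert a.score == pytest.approx(b.score, abs=1e-9)

    def test_ties_break_by_source_then_start(self):
        probe = _worm("p", [(0.0, 0.0), (0.0, 0.0)])
        # two worms, each with several exactly-matching windows
        flat = [(0.0, 0.0)] * 4
        hits = search(probe, [_worm("wB", flat), _worm("wA", flat)], top_n=10)
        assert [(h.source_id, h.window_start) for h in hits] == [
            ("wA", 1), ("wA", 2), ("wA", 3),
            ("wB", 1), ("wB", 2), ("wB", 3),
        ]

    def test_windows_with_undefined_angles_skipped_by_default(self, fixture_worm):
        probe = fixture_worm.subworm(3, 8)
        # full worm has undefined terminals: windows touching them skipped
        hits = search(probe, [fixture_worm], top_n=100)
        starts = {h.window_start for h in hits}
        assert 1 not in starts  # window 1 covers the undefined eta(1)
        assert max(starts) <= len(fixture_worm) - 6 + 1 - 1
        # relaxing the threshold admits windows with some undefined positions
        relaxed = search(
            probe, [fixture_worm], top_n=100, max_incomparable_fraction=0.4
        )
        assert 1 in {h.window_start for h in relaxed}

    def test_probe_longer_than_every_worm_yields_empty(self, fixture_worm, caplog):
        probe = fixture_worm  # length 12
        hits = search(probe, [fixture_worm.subworm(1, 5)], top_n=10)
        assert hits == []
        assert any("longer" in r.message for r in caplog.records)

    def test_mode_mismatch_is_a_hard_error(self, fixture_worm, tmp_path, aform_chain):
        from naworm.fixtures import write_helix

        d = tmp_path / "in"
        d.mkdir()
        write_helix("A-form", 12, d / "aform12.pdb")
        db = build_database(d, tmp_path / "db", mode="c1")
        probe = fixture_worm.subworm(3, 8)  # built in c4 mode
        with pytest.raises(ModeMismatchError):
            search(probe, db)

    def test_probe_shorter_than_two_rejected(self, fixture_worm):
        with pytest.raises(ValueError):
            search(fixture_worm.subworm(3, 3), [fixture_worm])


class TestWriteResults:
    def test_report_contains_header_and_ranked_lines(self, tmp_path, aform_chain):
        worm = worm_from_chain(aform_chain, mode="c4")
        probe = worm.subworm(3, 8)
        hits = search(probe, [worm], top_n=3)
        out = tmp_path / "results.txt"
        write_results(
            hits, out, probe_id=probe.source_id, mode="c4",
            aggregator="mean", database_root="db", probe_length=len(probe),
        )
        text = out.read_text()
        assert f"probe_id: {probe.source_id}" in text
        assert "probe_length: 6" in text
        lines = text.splitlines()
        rank1 = next(l for l in lines if l.startswith("1\t"))
        assert rank1.endswith("0.000")
        # window column shows author seq_ids
        assert "3-8" in rank1

    def test_empty_hit_list_reports_zero_hits(self, tmp_path):
        out = tmp_path / "results.txt"
        write_results([], out, probe_id="p", mode="c4",
                      aggregator="mean", database_root="db", probe_length=9)
        assert "0 hits" in out.read_text()
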