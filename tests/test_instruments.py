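"""Instrument scoring and DSM-5 classification rules."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdscreen.instruments import (
    DEFAULT_PCL5_PARTITION,
    DEFAULT_SYMPTOM_MAP,
    AsdsResponse,
    Pcl5Response,
    SubjectRecord,
    SymptomMap,
    ValidationError,
    _prorate_total,
    classify_wave,
    diagnose_ptsd,
    load_config,
    read_cohort_csv,
    score_asds,
    write_cohort_csv,
)
from asdscreen.synthetic import SyntheticConfig, generate_cohort

asds_items = st.lists(st.integers(1, 5), min_size=19, max_size=19).map(tuple)
pcl5_items = st.lists(st.integers(0, 4), min_size=20, max_size=20).map(tuple)


def _asds(items, **kw):
    return score_asds(AsdsResponse(items=tuple(items), **kw))


class TestAsdsScoring:
    @pytest.mark.parametrize(
        "items, total, count, diagnosis, intensity",
        [
            ([1] * 19, 19, 0, False, "low"),
            ([5] * 19, 95, 14, True, "high"),
        ],
    )
    def test_extreme_responses(self, items, total, count, diagnosis, intensity):
        res = _asds(items)
        assert (res.total, res.symptom_count) == (total, count)
        assert res.asd_diagnosis is diagnosis
        assert res.intensity_class == intensity

    @pytest.mark.parametrize("n_symptoms, diagnosis", [(9, True), (8, False)])
    def test_diagnosis_boundary_at_nine_of_fourteen(self, n_symptoms, diagnosis):
        """Endorsing exactly 9 symptoms flips the diagnosis; 8 does not."""
        thr = DEFAULT_SYMPTOM_MAP.endorsement_threshold
        items = [1] * 19
        for sid in range(1, n_symptoms + 1):
            item = min(DEFAULT_SYMPTOM_MAP.entries[sid])
            items[item - 1] = thr
        res = _asds(items)
        assert res.symptom_count == n_symptoms
        assert res.asd_diagnosis is diagnosis

    def test_total_matches_summation_oracle(self, rng):
        """Intensity total equals an independent item-by-item summation."""
        for _ in range(1000):
            items = [int(v) for v in rng.integers(1, 6, size=19)]
            oracle = 0
            for v in items:
                oracle += v
            assert _asds(items).total == oracle

    def test_multi_item_symptom_uses_max(self):
        # symptom 10 is fed by items 10 and 11 in the default map
        items = [1] * 19
        items[10] = 5  # item 11 high, item 10 low
        assert _asds(items).symptom_count == 1

    def test_cutoff_inclusive_by_default_and_strict_option(self):
        items = [3] * 19 + []  # total 57
        items[0] = 4  # total 58
        resp = AsdsResponse(items=tuple(items))
        assert score_asds(resp, cutoff=58).intensity_class == "high"
        assert score_asds(resp, cutoff=58, strict_cutoff=True).intensity_class == "low"

    @pytest.mark.parametrize(
        "items, message",
        [
            ((1,) * 18, "19 items"),
            ((1,) * 18 + (6,), "item 19"),
            ((0,) + (1,) * 18, "item 1"),
        ],
    )
    def test_validation_names_offending_item(self, items, message):
        with pytest.raises(ValidationError, match=message):
            AsdsResponse(items=items)

    @given(items=asds_items, bump=st.integers(0, 18))
    @settings(max_examples=200, deadline=None)
    def test_increasing_an_item_never_revokes_diagnosis(self, items, bump):
        before = _asds(items).asd_diagnosis
        raised = list(items)
        raised[bump] = min(5, raised[bump] + 1)
        after = _asds(raised).asd_diagnosis
        assert not (before and not after)


class TestSymptomMap:
    def test_default_map_covers_all_items_and_symptoms(self):
        used = set().union(*DEFAULT_SYMPTOM_MAP.entries.values())
        assert used == set(range(1, 20))
        assert set(DEFAULT_SYMPTOM_MAP.entries) == set(range(1, 15))

    def test_rejects_incomplete_or_invalid_maps(self):
        with pytest.raises(ValidationError):
            SymptomMap(entries={1: frozenset({1})})
        bad = dict(DEFAULT_SYMPTOM_MAP.entries)
        bad[14] = frozenset({25})
        with pytest.raises(ValidationError):
            SymptomMap(entries=bad)


class TestPcl5:
    def test_empty_response(self):
        res = diagnose_ptsd(Pcl5Response(items=(0,) * 20))
        assert res.severity == 0
        assert not (res.full_threshold or res.majority or res.six_plus or res.any_case)

    def test_minimal_full_threshold_case(self):
        """Items {1, 6, 8, 9, 15, 16} endorsed is the smallest full-threshold set."""
        items = [0] * 20
        for i in (1, 6, 8, 9, 15, 16):
            items[i - 1] = 2
        res = diagnose_ptsd(Pcl5Response(items=tuple(items)))
        assert res.criterion_counts == (1, 1, 2, 2)
        assert res.full_threshold and res.majority and res.six_plus

    def test_majority_without_full_or_six_plus(self):
        # B, D, E at full threshold, no C, five endorsed symptoms in total
        items = [0] * 20
        for i in (1, 8, 9, 15, 16):
            items[i - 1] = 3
        res = diagnose_ptsd(Pcl5Response(items=tuple(items)))
        assert not res.full_threshold
        assert res.majority
        assert not res.six_plus
        assert res.any_case

    def test_exhaustive_criterion_count_grid(self):
        """Enumerate every (B,C,D,E) endorsed-count vector on the 5x2x7x6 grid
        and check the caseness rules against first-principles logic."""
        part = DEFAULT_PCL5_PARTITION
        for b, c, d, e in itertools.product(range(6), range(3), range(8), range(7)):
            items = [0] * 20
            for crit, k in zip("BCDE", (b, c, d, e)):
                for i in list(part[crit])[:k]:
                    items[i - 1] = 2
            res = diagnose_ptsd(Pcl5Response(items=tuple(items)))
            met = (b >= 1, c >= 1, d >= 2, e >= 2)
            assert res.criterion_counts == (b, c, d, e)
            assert res.full_threshold == all(met)
            assert res.majority == (sum(met) >= 3)
            assert res.six_plus == (b + c + d + e >= 6)
            # implication chain: full threshold entails both subthreshold flags
            if res.full_threshold:
                assert res.majority and res.six_plus and res.any_case

    @given(items=pcl5_items, bump=st.integers(0, 19))
    @settings(max_examples=200, deadline=None)
    def test_increasing_an_item_never_revokes_caseness(self, items, bump):
        before = diagnose_ptsd(Pcl5Response(items=items))
        raised = list(items)
        raised[bump] = min(4, raised[bump] + 1)
        after = diagnose_ptsd(Pcl5Response(items=tuple(raised)))
        for flag in ("full_threshold", "majority", "six_plus"):
            assert not (getattr(before, flag) and not getattr(after, flag))

    def test_invalid_items_rejected(self):
        with pytest.raises(ValidationError, match="item 3"):
            Pcl5Response(items=(0, 0, 5) + (0,) * 17)


class TestClassifyWave:
    @staticmethod
    def _record(sid, w1=False, w2=False, pcl=True):
        return SubjectRecord(
            subject_id=sid,
            asds_w1=AsdsResponse(items=(3,) * 19, wave="W1") if w1 else None,
            asds_w2=AsdsResponse(items=(2,) * 19, wave="W2") if w2 else None,
            pcl5=Pcl5Response(items=(1,) * 20) if pcl else None,
        )

    def test_wave_tables_follow_participation(self):
        tables = classify_wave(
            [self._record("a", w1=True), self._record("b", w2=True)]
        )
        assert len(tables.w1) == 1 and len(tables.w2) == 1
        assert tables.exclusions.empty

    def test_incomplete_records_logged_not_fatal(self):
        tables = classify_wave(
            [
                self._record("a", w1=True),
                self._record("b", w1=True, pcl=False),
                SubjectRecord(subject_id="c", pcl5=Pcl5Response(items=(0,) * 20)),
            ]
        )
        assert len(tables.w1) == 1
        assert sorted(tables.exclusions["subject_id"]) == ["b", "c"]

    def test_row_counts_match_configured_availability(self):
        """Participation masks reproduce the per-wave analytic denominators
        (201 at wave 1, 368 at wave 2) when so configured."""
        config = SyntheticConfig(
            n_subjects=426, w1_only=58, w2_only=225, both_waves=143, seed=3
        )
        cohort = generate_cohort(config, calibration_n=20_000)
        tables = classify_wave(cohort.records)
        assert len(tables.w1) == 201
        assert len(tables.w2) == 368

    def test_scoring_is_order_independent(self, default_cohort):
        records = list(default_cohort.records)
        shuffled = records.copy()
        random.Random(5).shuffle(shuffled)
        a = classify_wave(records).w1.sort_values("subject_id").reset_index(drop=True)
        b = classify_wave(shuffled).w1.sort_values("subject_id").reset_index(drop=True)
        assert a.equals(b)


class TestCsvAndConfig:
    def test_csv_round_trip(self, default_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(default_cohort.records, path)
        back = read_cohort_csv(path)
        orig = classify_wave(default_cohort.records)
        again = classify_wave(back)
        assert orig.w1.equals(again.w1) and orig.w2.equals(again.w2)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = (
            "subject_id,wave,instrument,"
            + ",".join(f"item_{i:02d}" for i in range(1, 21))
            + ",age,gender,profession"
        )
        good = "s1,1,ASDS," + ",".join(["2"] * 19) + ",1,30,female,clinical"
        bad = "s2,1,ASDS," + ",".join(["9"] * 19) + ",1,30,female,clinical"
        path.write_text("\n".join([header, good, bad]) + "\n")
        with pytest.raises(ValidationError, match="line 3"):
            read_cohort_csv(path)

    def test_config_file_overrides_thresholds_and_map(self, tmp_path):
        lines = ["asds_cutoff = 60", "pcl5_endorsement_threshold = 3",
                 "asds_endorsement_threshold = 4"]
        lines += [f"symptom_{s} = {s}" for s in range(1, 15)]
        cfg = tmp_path / "cfg.txt"
        cfg.write_text("\n".join(lines) + "\n")
        opts = load_config(cfg)
        assert opts["asds_cutoff"] == 60
        assert opts["pcl5_endorsement_threshold"] == 3
        assert opts["symptom_map"].endorsement_threshold == 4
        assert opts["symptom_map"].entries[14] == frozenset({14})

    def test_prorated_total_requires_80_percent_answered(self):
        answered = [3] * 16 + [None, None, None]  # 16/19 ~ 84%
        assert _prorate_total(answered) == round(3 * 19)
        too_few = [3] * 15 + [None] * 4
        assert _prorate_total(too_few) is None
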