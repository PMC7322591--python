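import numpy as np
import pytest

from retscreen import dataset_builder as db
from retscreen.errors import ConfigError, DataError
from retscreen.image_io import ImageRecord


def make_records(per_grade: dict[int, int]) -> list[ImageRecord]:
    return [
        ImageRecord(f"g{g}_{i:06d}", f"g{g}_{i:06d}.png", g)
        for g in sorted(per_grade)
        for i in range(per_grade[g])
    ]


class TestAugmentImage:
    def test_horizontal_flip_is_involution(self, random_rgb):
        once = db.augment_image(random_rgb, "hflip")
        assert not np.array_equal(once, random_rgb)
        assert np.array_equal(db.augment_image(once, "hflip"), random_rgb)

    def test_rotation_group_is_cyclic(self, random_rgb):
        out = random_rgb
        for _ in range(4):
            out = db.augment_image(out, "rot90")
        assert np.array_equal(out, random_rgb)

    def test_rot180_equals_flip_composition(self, random_rgb):
        both = db.augment_image(db.augment_image(random_rgb, "hflip"), "vflip")
        assert np.array_equal(db.augment_image(random_rgb, "rot180"), both)

    def test_unknown_transform_rejected(self, random_rgb):
        with pytest.raises(ConfigError):
            db.augment_image(random_rgb, "shear")


class TestBalanceClasses:
    def test_screening_corpus_counts(self):
        # printed per-grade counts balanced to the study's targets
        records = make_records({0: 16500, 1: 1333, 2: 2000, 3: 645, 4: 645})
        plan = db.AugmentationPlan(
            targets={0: 16500, 1: 4375, 2: 4375, 3: 3875, 4: 3875}, seed=0
        )
        manifest = db.balance_classes(records, plan)
        assert len(manifest) == 33000
        counts = manifest.counts_by_grade()
        assert counts == plan.targets
        assert counts[0] / len(manifest) == 0.5

    def test_targets_equal_counts_is_identity(self):
        records = make_records({0: 5, 3: 4})
        plan = db.AugmentationPlan(targets={0: 5, 3: 4}, seed=1)
        manifest = db.balance_classes(records, plan)
        assert sorted(r.image_id for r in manifest.records) == sorted(
            r.image_id for r in records
        )
        assert all(r.transform == "none" for r in manifest.records)

    def test_subsampling_without_replacement(self):
        records = make_records({1: 10})
        manifest = db.balance_classes(records, db.AugmentationPlan(targets={1: 4}, seed=2))
        ids = [r.image_id for r in manifest.records]
        assert len(ids) == len(set(ids)) == 4
        assert set(ids) <= {r.image_id for r in records}
        assert all(r.transform == "none" for r in manifest.records)

    def test_pigeonhole_two_sources_target_seven(self):
        records = make_records({2: 2})
        plan = db.AugmentationPlan(targets={2: 7}, seed=3)
        manifest = db.balance_classes(records, plan)
        assert len(manifest) == 7
        by_source: dict[str, int] = {}
        pairs = set()
        for rec in manifest.records:
            by_source[rec.source_id] = by_source.get(rec.source_id, 0) + 1
            if rec.transform != "none":
                pair = (rec.source_id, rec.transform)
                assert pair not in pairs  # vocabulary not yet exhausted
                pairs.add(pair)
        assert all(n >= 3 for n in by_source.values())

    def test_cycling_past_transform_exhaustion(self):
        # 1 source, 5 transforms -> targets beyond 6 reuse pairs with new ids
        records = make_records({4: 1})
        manifest = db.balance_classes(records, db.AugmentationPlan(targets={4: 8}, seed=0))
        assert len(manifest) == 8
        assert len({r.image_id for r in manifest.records}) == 8

    def test_empty_class_with_target_rejected(self):
        with pytest.raises(DataError):
            db.balance_classes([], db.AugmentationPlan(targets={0: 3}))

    def test_deterministic_given_plan(self):
        records = make_records({1: 3, 2: 5})
        plan = db.AugmentationPlan(targets={1: 9, 2: 5}, seed=7)
        a = db.balance_classes(records, plan)
        b = db.balance_classes(records, plan)
        assert [(r.image_id, r.transform) for r in a.records] == [
            (r.image_id, r.transform) for r in b.records
        ]

    @pytest.mark.parametrize("targets", [{0: 7, 1: 2}, {0: 1, 1: 12}, {0: 3, 1: 3}])
    def test_count_conservation(self, targets):
        records = make_records({0: 3, 1: 3})
        manifest = db.balance_classes(records, db.AugmentationPlan(targets=targets, seed=5))
        assert manifest.counts_by_grade() == targets


class TestSplitTrainTest:
    def test_screening_corpus_split(self):
        records = make_records({0: 16500, 1: 1333, 2: 2000, 3: 645, 4: 645})
        plan = db.AugmentationPlan(
            targets={0: 16500, 1: 4375, 2: 4375, 3: 3875, 4: 3875}, seed=0
        )
        manifest = db.balance_classes(records, plan)
        split = db.split_train_test(
            manifest,
            {0: 15000, 1: 4000, 2: 4000, 3: 3500, 4: 3500},
            seed=0,
            paper_mode=True,
        )
        assert sum(r.split == "train" for r in split.records) == 30000
        assert sum(r.split == "test" for r in split.records) == 3000
        test_counts = split.counts_by_grade("test")
        assert test_counts == {0: 1500, 1: 375, 2: 375, 3: 375, 4: 375}

    def test_no_record_in_both_splits(self):
        records = make_records({0: 6, 2: 4})
        manifest = db.balance_classes(
            records, db.AugmentationPlan(targets={0: 6, 2: 12}, seed=1)
        )
        split = db.split_train_test(manifest, {0: 4, 2: 9}, seed=1)
        train_ids = {r.image_id for r in split.records if r.split == "train"}
        test_ids = {r.image_id for r in split.records if r.split == "test"}
        assert not train_ids & test_ids

    def test_group_split_has_no_augmentation_leakage(self):
        records = make_records({0: 8, 3: 5})
        manifest = db.balance_classes(
            records, db.AugmentationPlan(targets={0: 8, 3: 20}, seed=2)
        )
        split = db.split_train_test(manifest, {0: 4, 3: 8}, seed=2)
        split_by_source: dict[str, set] = {}
        for rec in split.records:
            split_by_source.setdefault(rec.source_id, set()).add(rec.split)
        assert all(len(s) == 1 for s in split_by_source.values())

    def test_paper_mode_can_leak_but_counts_exact(self):
        records = make_records({3: 5})
        manifest = db.balance_classes(records, db.AugmentationPlan(targets={3: 20}, seed=0))
        split = db.split_train_test(manifest, {3: 13}, seed=0, paper_mode=True)
        assert sum(r.split == "train" for r in split.records) == 13

    def test_determinism_and_seed_sensitivity(self):
        records = make_records({0: 30, 2: 30})
        manifest = db.balance_classes(
            records, db.AugmentationPlan(targets={0: 30, 2: 30}, seed=0)
        )
        a = db.split_train_test(manifest, {0: 20, 2: 20}, seed=5)
        b = db.split_train_test(manifest, {0: 20, 2: 20}, seed=5)
        c = db.split_train_test(manifest, {0: 20, 2: 20}, seed=6)
        key = lambda m: sorted((r.image_id, r.split) for r in m.records)
        assert key(a) == key(b)
        assert key(a) != key(c)
        assert c.counts_by_grade("train") == {0: 20, 2: 20}

    def test_insufficient_stratum_rejected(self):
        records = make_records({0: 3})
        manifest = db.balance_classes(records, db.AugmentationPlan(targets={0: 3}))
        with pytest.raises(DataError):
            db.split_train_test(manifest, {0: 4})

    def test_empty_test_set_warns(self):
        records = make_records({0: 4})
        manifest = db.balance_classes(records, db.AugmentationPlan(targets={0: 4}))
        with pytest.warns(UserWarning):
            db.split_train_test(manifest, {0: 4})

    def test_referable_count_equals_grade_two_plus(self):
        records = make_records({0: 5, 1: 4, 2: 3, 3: 2, 4: 1})
        manifest = db.balance_classes(
            records, db.AugmentationPlan(targets={0: 5, 1: 4, 2: 6, 3: 4, 4: 2}, seed=0)
        )
        assert manifest.referable_count() == sum(
            1 for r in manifest.records if r.grade >= 2
        )
        assert manifest.referable_count() == 12

    def test_csv_round_trip(self, tmp_path):
        records = make_records({0: 3, 2: 2})
        manifest = db.balance_classes(
            records, db.AugmentationPlan(targets={0: 3, 2: 5}, seed=1)
        )
        split = db.split_train_test(manifest, {0: 2, 2: 3}, seed=1)
        path = tmp_path / "dataset.csv"
        split.to_csv(path)
        loaded = db.DatasetManifest.from_csv(path)
        assert sorted((r.image_id, r.grade, r.split) for r in loaded.records) == sorted(
            (r.image_id, r.grade, r.split) for r in split.records
        )
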