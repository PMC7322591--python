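"""Augmentation, class balancing and train/test splitting.

Severity grades are heavily imbalanced in screening corpora (most eyes show
no retinopathy), so under-represented grades are expanded with lossless
geometric transforms — horizontal/vertical flips and 90-degree rotations —
and over-represented grades subsampled, to per-grade target counts.

Leakage policy: augmenting before splitting puts near-duplicates of one
source photograph into both train and test.  The default split here assigns
whole source groups (a source image and all its augmented copies) to one
split.  ``paper_mode=True`` instead splits at the record level, reproducing
the augment-then-split order of the original study with exact per-stratum
counts.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .image_io import ImageRecord, validate_rgb

__all__ = [
    "TRANSFORMS",
    "AugmentationPlan",
    "ManifestRecord",
    "DatasetManifest",
    "augment_image",
    "balance_classes",
    "split_train_test",
]

_TRANSFORM_FUNCS = {
    "hflip": lambda a: a[:, ::-1],
    "vflip": lambda a: a[::-1, :],
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
}

#: the lossless transform vocabulary (pixel-exact, no interpolation)
TRANSFORMS = tuple(_TRANSFORM_FUNCS)


def augment_image(image: np.ndarray, transform: str) -> np.ndarray:
    """Apply one named lossless transform ('hflip', 'vflip', 'rot90', ...)."""
    arr = validate_rgb(image)
    if transform not in _TRANSFORM_FUNCS:
        raise ConfigError(f"unknown transform {transform!r}; allowed: {TRANSFORMS}")
    return np.ascontiguousarray(_TRANSFORM_FUNCS[transform](arr))


@dataclass(frozen=True)
class AugmentationPlan:
    """Per-grade target counts plus the transform vocabulary and seed.

    A target above the source count triggers augmentation (cycling shuffled
    transforms round-robin over shuffled sources); a target below triggers
    subsampling without replacement.
    """

    targets: dict[int, int]
    transforms: tuple[str, ...] = TRANSFORMS
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.transforms:
            if t not in _TRANSFORM_FUNCS:
                raise ConfigError(f"unknown transform {t!r} in plan")
        if not self.transforms:
            raise ConfigError("plan needs at least one transform")
        for grade, count in self.targets.items():
            if not 0 <= grade <= 4 or count < 0:
                raise ConfigError(f"bad target {grade}: {count}")


@dataclass(frozen=True)
class ManifestRecord:
    """One dataset row: identity, provenance and split assignment.

    ``source_id`` names the original photograph the record derives from
    (equal to ``image_id`` for unaugmented records); ``transform`` is the
    geometric transform applied, or 'none'.
    """

    image_id: str
    source_id: str
    path: str
    grade: int
    transform: str = "none"
    split: str | None = None

    @property
    def referable(self) -> bool:
        return self.grade >= 2


@dataclass
class DatasetManifest:
    """Ordered record collection with the seed that produced it."""

    records: list[ManifestRecord] = field(default_factory=list)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def counts_by_grade(self, split: str | None = "any") -> dict[int, int]:
        out: dict[int, int] = {}
        for rec in self.records:
            if split == "any" or rec.split == split:
                out[rec.grade] = out.get(rec.grade, 0) + 1
        return out

    def referable_count(self, split: str | None = "any") -> int:
        return sum(
            1
            for rec in self.records
            if (split == "any" or rec.split == split) and rec.referable
        )

    def to_csv(self, path: str | Path) -> None:
        """Deterministic CSV export, rows sorted by image_id."""
        with open(Path(path), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["image_id", "source_id", "path", "transform", "grade", "referable", "split"]
            )
            for rec in sorted(self.records, key=lambda r: r.image_id):
                writer.writerow(
                    [rec.image_id, rec.source_id, rec.path, rec.transform, rec.grade,
                     int(rec.referable), rec.split or ""]
                )

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = 0) -> "DatasetManifest":
        records = []
        with open(Path(path), newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    ManifestRecord(
                        image_id=row["image_id"],
                        source_id=row["source_id"],
                        path=row.get("path", ""),
                        grade=int(row["grade"]),
                        transform=row["transform"],
                        split=row["split"] or None,
                    )
                )
        return cls(records=records, seed=seed)


def balance_classes(records: list[ImageRecord], plan: AugmentationPlan) -> DatasetManifest:
    """Expand or subsample each grade to the plan's target count.

    Augmented copies cycle the (shuffled) transform list round-robin over the
    (shuffled) sources, so source usage stays balanced and no (source,
    transform) pair repeats until the whole vocabulary is exhausted; beyond
    that the cycle restarts with fresh ids.  Deterministic given
    ``(records, plan)``.
    """
    rng = np.random.default_rng(plan.seed)
    by_grade: dict[int, list[ImageRecord]] = {}
    for rec in records:
        by_grade.setdefault(rec.grade, []).append(rec)

    out: list[ManifestRecord] = []
    for grade in sorted(plan.targets):
        target = plan.targets[grade]
        sources = sorted(by_grade.get(grade, []), key=lambda r: r.image_id)
        if target > 0 and not sources:
            raise DataError(f"no source images for grade {grade} (target {target})")

        if target <= len(sources):
            chosen = sources
            if target < len(sources):
                keep = rng.choice(len(sources), size=target, replace=False)
                chosen = [sources[i] for i in sorted(keep)]
            out.extend(
                ManifestRecord(r.image_id, r.image_id, r.path, r.grade) for r in chosen
            )
            continue

        out.extend(ManifestRecord(r.image_id, r.image_id, r.path, r.grade) for r in sources)
        order = list(rng.permutation(len(sources)))
        transforms = list(rng.permutation(np.array(plan.transforms)))
        n_extra = target - len(sources)
        for k in range(n_extra):
            src = sources[order[k % len(sources)]]
            tf = str(transforms[(k // len(sources)) % len(transforms)])
            cycle = k // (len(sources) * len(transforms))
            suffix = f"_{tf}" if cycle == 0 else f"_{tf}_{cycle}"
            out.append(
                ManifestRecord(src.image_id + suffix, src.image_id, src.path, src.grade, tf)
            )
    return DatasetManifest(records=out, seed=plan.seed)


def _record_level_split(manifest, train_counts, rng):
    records = sorted(manifest.records, key=lambda r: r.image_id)
    assigned = []
    for grade in sorted({r.grade for r in records}):
        stratum = [r for r in records if r.grade == grade]
        want = train_counts.get(grade, 0)
        if want > len(stratum):
            raise DataError(
                f"grade {grade}: requested {want} train records, only {len(stratum)} available"
            )
        train_idx = set(rng.choice(len(stratum), size=want, replace=False).tolist())
        for i, rec in enumerate(stratum):
            assigned.append(replace(rec, split="train" if i in train_idx else "test"))
    return assigned


def _group_level_split(manifest, train_counts, rng):
    # whole source groups go to one split; greedy packing with a single-swap
    # repair to hit the exact per-stratum record counts
    records = sorted(manifest.records, key=lambda r: r.image_id)
    assigned = []
    for grade in sorted({r.grade for r in records}):
        stratum = [r for r in records if r.grade == grade]
        want = train_counts.get(grade, 0)
        if want > len(stratum):
            raise DataError(
                f"grade {grade}: requested {want} train records, only {len(stratum)} available"
            )
        groups: dict[str, list] = {}
        for rec in stratum:
            groups.setdefault(rec.source_id, []).append(rec)
        keys = sorted(groups)
        order = [keys[i] for i in rng.permutation(len(keys))]
        taken: list[str] = []
        skipped: list[str] = []
        total = 0
        for key in order:
            size = len(groups[key])
            if total + size <= want:
                taken.append(key)
                total += size
            else:
                skipped.append(key)
        shortfall = want - total
        if shortfall:
            fixed = False
            for key in skipped:  # a skipped group of exactly the missing size
                if len(groups[key]) == shortfall:
                    taken.append(key)
                    fixed = True
                    break
            if not fixed:  # swap one in-group for a skipped group `shortfall` larger
                for tk in taken:
                    for sk in skipped:
                        if len(groups[sk]) - len(groups[tk]) == shortfall:
                            taken.remove(tk)
                            taken.append(sk)
                            fixed = True
                            break
                    if fixed:
                        break
            if not fixed:
                raise DataError(
                    f"grade {grade}: cannot reach exactly {want} train records with "
                    "whole source groups; adjust counts or use paper_mode"
                )
        train_keys = set(taken)
        for key in keys:
            split = "train" if key in train_keys else "test"
            assigned.extend(replace(rec, split=split) for rec in groups[key])
    return assigned


def split_train_test(
    manifest: DatasetManifest,
    train_counts: dict[int, int],
    seed: int = 0,
    paper_mode: bool = False,
) -> DatasetManifest:
    """Assign each record to train or test, stratified by grade.

    ``train_counts`` gives the number of *train* records per grade; the
    remainder of each stratum becomes the test set.  The default keeps every
    source group in a single split (no augmentation leakage); ``paper_mode``
    samples records directly, matching the original augment-then-split order.
    """
    rng = np.random.default_rng(seed)
    if paper_mode:
        assigned = _record_level_split(manifest, train_counts, rng)
    else:
        assigned = _group_level_split(manifest, train_counts, rng)
    if not any(rec.split == "test" for rec in assigned):
        warnings.warn("all records assigned to train; test set is empty", stacklevel=2)
    return DatasetManifest(records=assigned, seed=seed)
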