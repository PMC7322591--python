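"""End-to-end synthetic screening study.

Reproduces the structure of the original screening experiment on phantoms:
a class-balanced corpus whose per-grade mix inside each binary class
follows the screening-population proportions, the full preprocessing chain
(resize-free here: phantoms are rendered at working resolution, then
luminance/green extraction, unsharp masking, local entropy, unit rescale),
a grade-stratified leakage-free split, and training of the bichannel
network plus its two single-channel ablations.

Also exposes the corpus arithmetic of the original study (per-grade counts,
balancing targets, train/test composition) as pure manifest computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bichannel_network as net
from . import dataset_builder, evaluation, preprocess, synthetic_fundus
from .dataset_builder import AugmentationPlan, balance_classes, split_train_test
from .image_io import ImageRecord

__all__ = [
    "SCREENING_GRADE_COUNTS",
    "BALANCE_TARGETS",
    "TRAIN_COUNTS",
    "corpus_arithmetic",
    "class_balanced_grade_counts",
    "prepare_phantom_inputs",
    "run_benchmark",
]

#: per-grade image counts of the screening corpus the study drew on
SCREENING_GRADE_COUNTS = {0: 16500, 1: 1333, 2: 2000, 3: 645, 4: 645}

#: post-augmentation per-grade targets (grade 0 untouched, 50% of the total)
BALANCE_TARGETS = {0: 16500, 1: 4375, 2: 4375, 3: 3875, 4: 3875}

#: per-grade training-set composition; the remainder per grade is the test set
TRAIN_COUNTS = {0: 15000, 1: 4000, 2: 4000, 3: 3500, 4: 3500}


def _metadata_records(per_grade: dict[int, int]) -> list[ImageRecord]:
    return [
        ImageRecord(f"img_g{g}_{i:06d}", f"g{g}/{i:06d}.png", g)
        for g in sorted(per_grade)
        for i in range(per_grade[g])
    ]


def corpus_arithmetic(seed: int = 0) -> dict[str, float]:
    """Balance + split the screening corpus at the manifest level.

    Pure metadata computation (no pixels): augments/balances the printed
    per-grade counts to their targets and splits with the printed per-grade
    training composition, returning the resulting set sizes and the
    referable fraction of the source corpus.
    """
    source = _metadata_records(SCREENING_GRADE_COUNTS)
    n_source = len(source)
    referable_pct = 100.0 * sum(r.referable for r in source) / n_source

    plan = AugmentationPlan(targets=BALANCE_TARGETS, seed=seed)
    balanced = balance_classes(source, plan)
    split = split_train_test(balanced, TRAIN_COUNTS, seed=seed, paper_mode=True)
    counts_train = split.counts_by_grade("train")
    counts_test = split.counts_by_grade("test")
    return {
        "source_images": n_source,
        "source_referable_pct": referable_pct,
        "balanced_total": len(balanced),
        "balanced_grade0_pct": 100.0 * balanced.counts_by_grade()[0] / len(balanced),
        "train_total": sum(counts_train.values()),
        "test_total": sum(counts_test.values()),
        "test_grade0": counts_test.get(0, 0),
    }


def class_balanced_grade_counts(n_per_class: int = 1000) -> dict[int, int]:
    """Per-grade phantom counts for a corpus balanced at the binary level.

    Within each binary class (non-referable grades 0-1, referable grades
    2-4) grades are mixed in the screening-population proportions; largest
    remainder rounding keeps each class at exactly ``n_per_class``.
    """
    out: dict[int, int] = {}
    for grades in ((0, 1), (2, 3, 4)):
        weights = np.array([SCREENING_GRADE_COUNTS[g] for g in grades], dtype=float)
        exact = n_per_class * weights / weights.sum()
        floors = np.floor(exact).astype(int)
        remainder = n_per_class - floors.sum()
        order = np.argsort(-(exact - floors))
        for j in order[:remainder]:
            floors[j] += 1
        for g, c in zip(grades, floors):
            out[g] = int(c)
    return out


def prepare_phantom_inputs(
    per_grade_counts: dict[int, int],
    side: int = 100,
    seed: int = 0,
    um: preprocess.UMParams = preprocess.UMParams(),
    ep: preprocess.EntropyParams = preprocess.EntropyParams(),
):
    """Generate a phantom corpus and its two entropy-image input stacks.

    Returns ``(records, gray_stack, green_stack, labels)`` with the stacks
    as (N, side, side) float32 arrays of unit-scaled entropy images.
    """
    corpus = synthetic_fundus.generate_corpus(per_grade_counts, side=side, seed=seed)
    n = len(corpus)
    gray = np.empty((n, side, side), dtype=np.float32)
    green = np.empty((n, side, side), dtype=np.float32)
    labels = np.empty(n, dtype=np.float64)
    records = []
    for i, (image, record) in enumerate(corpus):
        gray[i] = preprocess.make_channel_input(image, um, ep, "gray")
        green[i] = preprocess.make_channel_input(image, um, ep, "green")
        labels[i] = float(record.referable)
        records.append(record)
    return records, gray, green, labels


@dataclass(frozen=True)
class BenchmarkResult:
    reports: dict[str, evaluation.EvalReport]  # keyed by model name
    n_train: int
    n_test: int


def pool2(stack: np.ndarray) -> np.ndarray:
    """2x2 mean-pool a (N, H, W) stack (H, W even)."""
    n, h, w = stack.shape
    return stack.reshape(n, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _augment_stack(stack: np.ndarray) -> np.ndarray:
    # horizontal + vertical flip copies; flips commute exactly with the
    # luminance/UM/local-entropy chain (symmetric kernels, square windows),
    # so flipping the entropy maps equals preprocessing flipped photographs
    return np.concatenate([stack, stack[:, :, ::-1], stack[:, ::-1, :]])


def _stratified_split_mask(records, train_fraction: float, seed: int) -> np.ndarray:
    manifest = dataset_builder.DatasetManifest(
        records=[
            dataset_builder.ManifestRecord(r.image_id, r.image_id, r.path, r.grade)
            for r in records
        ],
        seed=seed,
    )
    counts = manifest.counts_by_grade()
    train_counts = {g: int(round(train_fraction * c)) for g, c in counts.items()}
    split = split_train_test(manifest, train_counts, seed=seed)
    is_train = {rec.image_id: rec.split == "train" for rec in split.records}
    return np.array([is_train[r.image_id] for r in records], dtype=bool)


def run_benchmark(
    seed: int = 0,
    n_per_class: int = 1000,
    side: int = 100,
    train_fraction: float = 0.7,
    epochs: int = 15,
    bichannel_epochs: int = 20,
    model_names: tuple[str, ...] = ("bichannel", "gray", "green"),
    train_seed: int | None = None,
    precomputed=None,
    verbose: bool = False,
) -> BenchmarkResult:
    """Train the bichannel network and its single-channel ablations.

    One corpus/preprocessing pass (reusable via ``precomputed``), one
    stratified leakage-free split, flip augmentation of the training split,
    then one training run per requested model on centered, 2x2-mean-pooled
    entropy inputs.  ``train_seed`` varies only the network initialization
    and shuffling, for multi-seed medians on a fixed corpus.
    """
    if precomputed is None:
        counts = class_balanced_grade_counts(n_per_class)
        precomputed = prepare_phantom_inputs(counts, side=side, seed=seed)
    records, gray, green, labels = precomputed

    mask = _stratified_split_mask(records, train_fraction, seed)
    # center on the scale midpoint so first-layer units see signed inputs
    stacks = {"gray": pool2(gray) - 0.5, "green": pool2(green) - 0.5}
    input_side = next(iter(stacks.values())).shape[1]
    y_train = np.tile(labels[mask], 3)
    tseed = seed if train_seed is None else train_seed

    reports: dict[str, evaluation.EvalReport] = {}
    for name in model_names:
        branches = ("gray", "green") if name == "bichannel" else (name,)
        # the fused model has twice the parameters and gets the full epoch
        # budget; the singles converge earlier
        n_epochs = bichannel_epochs if name == "bichannel" else epochs
        config = net.benchmark_config(
            branches=branches, seed=tseed, epochs=n_epochs, input_side=input_side
        )
        model = net.build_model(config)
        train_x = [_augment_stack(stacks[b][mask]) for b in branches]
        test_x = [stacks[b][~mask] for b in branches]

        def tta_predict():
            # test-time augmentation over the same flip set stabilizes the
            # prediction against orientation-specific filter noise
            return np.mean(
                [
                    net.predict(model, test_x),
                    net.predict(model, [a[:, :, ::-1] for a in test_x]),
                    net.predict(model, [a[:, ::-1, :] for a in test_x]),
                ],
                axis=0,
            )

        # two-phase schedule (halve the Adam step after the first ten epochs)
        # with snapshot averaging: the reported probability is the mean over
        # the last four epochs' models, damping end-of-training jitter
        first = min(n_epochs, 10)
        net.train(model, train_x, y_train, epochs=first, verbose=verbose)
        snapshots = []
        if n_epochs > first:
            model._opt.lr *= 0.5
            for epoch in range(first, n_epochs):
                net.train(model, train_x, y_train, epochs=1, verbose=verbose)
                if epoch >= n_epochs - 4:
                    snapshots.append(tta_predict())
        probs = np.mean(snapshots, axis=0) if snapshots else tta_predict()
        reports[name] = evaluation.evaluate(labels[~mask], probs)
    return BenchmarkResult(
        reports=reports, n_train=int(mask.sum()), n_test=int((~mask).sum())
    )
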