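"""Dataset splitting and the repeated-trial evaluation protocol.

The evaluation design follows the transfer-learning study layout for
chromosome-type scoring:

* a test set of fixed size is removed first (at the level of whole cells,
  so no cell contributes images to both sides);
* the remaining pool — optionally augmented with extra rare-type images for
  class balance — is split image-wise into validation and training sets;
* a balanced training subset (equal counts per type) of a chosen size is
  drawn, the head is trained with validation-based model selection, and the
  model is scored on the test set;
* the whole selection/training cycle is repeated ``n_selections`` x
  ``n_repeats`` times with derived sub-seeds and the metrics are averaged
  (the study design uses 3 selections x 10 training cycles = 30 trials).

Metrics: concordance rate (percent of images where researcher labels — the
"example answers", EA — agree with model predictions, PA), the 3x3 confusion
matrix (EA rows, PA columns), and the per-type distribution of EA and PA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classify import TrainHyperParams, predict_batch, train_head
from .preprocess import PreprocessConfig
from .synthetic import LABELS, LabeledImage

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "split_dataset",
    "augment_pool",
    "select_validation_and_training",
    "balanced_subset",
    "concordance_rate",
    "type_distribution",
    "run_protocol",
    "training_size_sweep",
    "trial_seed",
]


@dataclass(frozen=True)
class SplitSpec:
    """Sizes and repetition counts of the evaluation protocol."""

    test_size: int = 654
    test_unit: str = "cell"  # "cell" or "image"
    validation_size: int = 400
    n_per_label_train: int = 231
    n_selections: int = 3
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test_unit not in ("cell", "image"):
            raise ValueError("test_unit must be 'cell' or 'image'")
        if self.n_selections < 1 or self.n_repeats < 1:
            raise ValueError("n_selections and n_repeats must be >= 1")


@dataclass
class EvaluationReport:
    """Metrics averaged over the repeated trials; per-trial values retained."""

    concordance: float  # percent
    confusion: np.ndarray  # 3x3 mean counts, EA rows / PA columns
    distribution: dict  # {"EA": [pct A,B,C], "PA": [pct A,B,C]}
    n_trials: int
    per_trial: list = field(default_factory=list)

    def round_for_display(self) -> dict:
        """One-decimal summary for tables."""
        return {
            "concordance": round(self.concordance, 1),
            "distribution": {
                k: [round(x, 1) for x in v] for k, v in self.distribution.items()
            },
            "n_trials": self.n_trials,
        }


def trial_seed(base_seed: int, selection: int, repeat: int = 0, stream: int = 0) -> int:
    """Derived sub-seed for one trial: reproducible, distinct per index."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(stream, selection, repeat))
    return int(ss.generate_state(1)[0] % (2**31))


def _labels_of(images) -> list[str]:
    return [im.label for im in images]


def split_dataset(
    dataset: list[LabeledImage], spec: SplitSpec, seed: int | None = None
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Remove the test set; return ``(test, pool)``, disjoint and exhaustive.

    With ``test_unit="cell"`` whole cells are assigned to the test side and
    the selection searches (greedily over a seeded cell order, retrying a
    bounded number of reshuffles) for a cell subset whose image count equals
    ``test_size`` exactly.
    """
    if spec.test_size > len(dataset):
        raise ValueError(
            f"test_size {spec.test_size} exceeds dataset size {len(dataset)}"
        )
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(trial_seed(seed, 0, stream=1))
    if spec.test_unit == "image":
        order = rng.permutation(len(dataset))
        test_idx = set(order[: spec.test_size].tolist())
        test = [dataset[i] for i in sorted(test_idx)]
        pool = [dataset[i] for i in range(len(dataset)) if i not in test_idx]
        return test, pool

    cells: dict[str, list[int]] = {}
    for i, im in enumerate(dataset):
        if not im.cell_id:
            raise ValueError("cell-level splitting requires cell_ids")
        cells.setdefault(im.cell_id, []).append(i)
    cell_ids = sorted(cells)
    for attempt in range(64):
        order = rng.permutation(len(cell_ids))
        chosen: list[str] = []
        count = 0
        for j in order:
            size = len(cells[cell_ids[j]])
            if count + size <= spec.test_size:
                chosen.append(cell_ids[j])
                count += size
            if count == spec.test_size:
                break
        if count == spec.test_size:
            chosen_set = set(chosen)
            test = [im for im in dataset if im.cell_id in chosen_set]
            pool = [im for im in dataset if im.cell_id not in chosen_set]
            return test, pool
    raise ValueError(
        f"could not assemble a cell-level test set of exactly {spec.test_size} "
        "images; consider test_unit='image'"
    )


def augment_pool(
    pool: list[LabeledImage], extra_images: list[LabeledImage]
) -> list[LabeledImage]:
    """Append extra images (e.g. rare type C) to the training/validation pool.

    Added images are flagged via the ``genotype``-independent attribute
    ``augmented`` so provenance stays inspectable.
    """
    for im in extra_images:
        if im.label not in LABELS:
            raise ValueError(f"extra image with invalid label {im.label!r}")
    out = list(pool)
    for im in extra_images:
        im.augmented = True  # provenance flag
        out.append(im)
    return out


def select_validation_and_training(
    pool: list[LabeledImage],
    validation_size: int,
    seed: int = 0,
    training_size: int | None = None,
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Image-level random split of the pool into validation and training.

    By default the split is exhaustive (training gets everything not in
    validation).  An explicit ``training_size`` instead randomly selects that
    many training images, leaving the remainder of the pool unused — the
    reference protocol selects both set sizes explicitly (400 validation and
    1,275 training from a pool of 1,711, leaving 36 images aside).
    """
    if validation_size >= len(pool):
        raise ValueError(
            f"validation_size {validation_size} must be < pool size {len(pool)}"
        )
    if training_size is not None and validation_size + training_size > len(pool):
        raise ValueError(
            f"validation_size + training_size = "
            f"{validation_size + training_size} exceeds pool size {len(pool)}"
        )
    rng = np.random.default_rng(trial_seed(seed, 0, stream=2))
    order = rng.permutation(len(pool))
    val_idx = set(order[:validation_size].tolist())
    validation = [pool[i] for i in sorted(val_idx)]
    if training_size is None:
        training = [pool[i] for i in range(len(pool)) if i not in val_idx]
    else:
        train_idx = sorted(order[validation_size : validation_size + training_size].tolist())
        training = [pool[i] for i in train_idx]
    return validation, training


def balanced_subset(
    training: list[LabeledImage], n_per_label: int, seed: int = 0
) -> list[LabeledImage]:
    """Draw exactly ``n_per_label`` images of each type from the training set."""
    rng = np.random.default_rng(trial_seed(seed, 0, stream=3))
    by_label = {lab: [im for im in training if im.label == lab] for lab in LABELS}
    subset: list[LabeledImage] = []
    for lab in LABELS:
        avail = by_label[lab]
        if len(avail) < n_per_label:
            raise ValueError(
                f"training set has only {len(avail)} images of type {lab}, "
                f"need {n_per_label}"
            )
        pick = rng.choice(len(avail), size=n_per_label, replace=False)
        subset.extend(avail[i] for i in sorted(pick))
    return subset


def concordance_rate(ea_labels, pa_labels) -> float:
    """Percent of positions where the two label vectors agree."""
    ea, pa = list(ea_labels), list(pa_labels)
    if len(ea) != len(pa):
        raise ValueError(f"label vectors differ in length: {len(ea)} vs {len(pa)}")
    if not ea:
        raise ValueError("label vectors must be non-empty")
    agree = sum(a == b for a, b in zip(ea, pa))
    return 100.0 * agree / len(ea)


def type_distribution(labels) -> np.ndarray:
    """Percent of types A, B, C in a label vector (sums to 100)."""
    labels = list(labels)
    if not labels:
        raise ValueError("label vector must be non-empty")
    counts = np.array([sum(l == lab for l in labels) for lab in LABELS], dtype=float)
    return 100.0 * counts / counts.sum()


def confusion_matrix(ea_labels, pa_labels) -> np.ndarray:
    """3x3 count table, EA rows by PA columns, label order A, B, C."""
    idx = {lab: i for i, lab in enumerate(LABELS)}
    mat = np.zeros((3, 3), dtype=float)
    for a, p in zip(ea_labels, pa_labels):
        mat[idx[a], idx[p]] += 1
    return mat


def run_protocol(
    dataset: list[LabeledImage],
    spec: SplitSpec,
    backbone="small_scratch",
    hyper: TrainHyperParams | None = None,
    preprocess: PreprocessConfig | None = None,
    base_seed: int = 0,
    extra_images: list[LabeledImage] | None = None,
    feature_cache: dict | None = None,
) -> EvaluationReport:
    """Full repeated-trial evaluation: split, train, test, average.

    Runs ``n_selections`` x ``n_repeats`` independent trials.  Each selection
    redraws validation/training from the pool; each repeat redraws the
    balanced subset and retrains the head from a fresh seeded initialisation.
    A shared ``feature_cache`` avoids recomputing frozen features for images
    reused across trials.
    """
    from .backbones import Backbone, build_backbone

    if not isinstance(backbone, Backbone):
        backbone = build_backbone(backbone)
    preprocess = preprocess or PreprocessConfig()
    if feature_cache is None:
        feature_cache = {}

    test, pool = split_dataset(dataset, spec, seed=base_seed)
    if extra_images:
        pool = augment_pool(pool, extra_images)
    ea = _labels_of(test)

    per_trial = []
    for sel in range(spec.n_selections):
        validation, training = select_validation_and_training(
            pool, spec.validation_size, seed=trial_seed(base_seed, sel, stream=4)
        )
        for rep in range(spec.n_repeats):
            seed = trial_seed(base_seed, sel, rep, stream=5)
            subset = balanced_subset(training, spec.n_per_label_train, seed=seed)
            model = train_head(
                backbone,
                subset,
                validation,
                hyper=hyper,
                seed=seed,
                preprocess=preprocess,
                feature_cache=feature_cache,
            )
            pa = predict_batch(model, test, feature_cache=feature_cache)
            per_trial.append(
                {
                    "selection": sel,
                    "repeat": rep,
                    "concordance": concordance_rate(ea, pa),
                    "confusion": confusion_matrix(ea, pa),
                    "distribution": {
                        "EA": type_distribution(ea),
                        "PA": type_distribution(pa),
                    },
                }
            )

    n_trials = len(per_trial)
    mean_conc = float(np.mean([t["concordance"] for t in per_trial]))
    mean_conf = np.mean([t["confusion"] for t in per_trial], axis=0)
    mean_dist = {
        key: np.mean([t["distribution"][key] for t in per_trial], axis=0)
        for key in ("EA", "PA")
    }
    return EvaluationReport(
        concordance=mean_conc,
        confusion=mean_conf,
        distribution=mean_dist,
        n_trials=n_trials,
        per_trial=per_trial,
    )


def training_size_sweep(
    dataset: list[LabeledImage],
    spec: SplitSpec,
    sizes,
    backbone="small_scratch",
    hyper: TrainHyperParams | None = None,
    base_seed: int = 0,
    extra_images: list[LabeledImage] | None = None,
    feature_cache: dict | None = None,
) -> list[tuple[int, float]]:
    """Averaged concordance for each training size (images per label).

    Each entry runs the full repeated-trial protocol with an independent
    derived seed (duplicate sizes get independent seeds by position).
    """
    if feature_cache is None:
        feature_cache = {}
    results = []
    for pos, size in enumerate(sizes):
        sub_spec = replace(spec, n_per_label_train=int(size))
        report = run_protocol(
            dataset,
            sub_spec,
            backbone=backbone,
            hyper=hyper,
            base_seed=trial_seed(base_seed, pos, stream=6),
            extra_images=extra_images,
            feature_cache=feature_cache,
        )
        results.append((int(size), report.concordance))
    return results
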