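"""Genotype comparison: detecting cohesion defects as distribution shifts.

A cohesion-defective genotype (e.g. a CTF18 knockout) shifts the chromosome
morphology mix away from tight type A toward arms-separated type B and fully
separated type C.  This module contrasts the per-type distributions of two
label vectors (model predictions or manual labels) and reports per-type
percentage-point deltas, raw counts, and — as supplementary output — a
chi-squared independence test on the 2x3 count table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import TrainedModel, predict_batch
from .protocol import type_distribution
from .synthetic import LABELS, LabeledImage

__all__ = ["GenotypeContrast", "contrast_genotypes", "classify_sample"]


@dataclass
class GenotypeContrast:
    genotype_names: tuple[str, str]
    #: percent per type (A, B, C) for (reference, mutant)
    distributions: dict
    #: mutant minus reference, percentage points per type; sums to ~0
    deltas: np.ndarray
    #: raw 2x3 count table (rows: genotypes; columns: A, B, C)
    counts: np.ndarray
    #: chi-squared independence test on the count table (supplementary; not
    #: part of the morphology readout itself)
    test_statistic: float
    p_value: float


def _count_vector(labels) -> np.ndarray:
    return np.array([sum(l == lab for l in labels) for lab in LABELS], dtype=float)


def contrast_genotypes(
    labels_ref, labels_mut, names: tuple[str, str] = ("WT", "mutant")
) -> GenotypeContrast:
    """Compare type distributions of a reference and a mutant sample."""
    ref, mut = list(labels_ref), list(labels_mut)
    if not ref or not mut:
        raise ValueError("both label vectors must be non-empty")
    dist_ref = type_distribution(ref)
    dist_mut = type_distribution(mut)
    counts = np.stack([_count_vector(ref), _count_vector(mut)])
    # chi-squared needs no all-zero columns; drop types absent from both
    keep = counts.sum(axis=0) > 0
    if keep.sum() >= 2:
        from scipy.stats import chi2_contingency

        stat, p = chi2_contingency(counts[:, keep])[:2]
    else:
        stat, p = float("nan"), float("nan")
    return GenotypeContrast(
        genotype_names=tuple(names),
        distributions={names[0]: dist_ref, names[1]: dist_mut},
        deltas=dist_mut - dist_ref,
        counts=counts,
        test_statistic=float(stat),
        p_value=float(p),
    )


def classify_sample(
    model: TrainedModel,
    images: list[LabeledImage],
    feature_cache: dict | None = None,
) -> list[tuple[str, str]]:
    """Predict labels for a sample; returns ``(predicted_label, genotype)``
    per image, order-preserving.  Deterministic for a fixed checkpoint."""
    preds = predict_batch(model, images, feature_cache=feature_cache)
    return [(lab, im.genotype) for lab, im in zip(preds, images)]
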