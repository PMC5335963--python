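"""Minority-class oversampling by nearest-neighbor interpolation.

Imbalanced cohorts (many patients, few controls) bias a margin classifier
toward the majority class. The remedy used here is SMOTE-style: pick a
minority sample at random, find its k nearest minority neighbors, and
interpolate one virtual sample uniformly at random on the segment to each
neighbor, repeating until the minority count matches a target. With the
study defaults (29 healthy controls raised to 107, k=2) this appends 78
synthetic controls.

Interpolation happens in raw concentration space (ppb), before any
per-fold z-scoring: normalization is refit inside each cross-validation
fold, while the oversampled set is generated once up front. Neighbors are
computed among the original minority samples only — synthetic points never
seed further synthesis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .cohort import SYNTHETIC, VOCTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OversampleConfig:
    """Parameters for minority oversampling.

    target_n
        Desired minority-class count after augmentation; ``None`` (the
        default) balances to the majority class's original count — 107
        for the study-sized cohort.
    k_neighbors
        Number of nearest minority neighbors interpolated toward per
        chosen sample (default 2).
    seed
        RNG seed; identical seed + input gives a bit-identical table.
    """

    target_n: int | None = None
    k_neighbors: int = 2
    seed: int = 0


def _minority_label(table: VOCTable) -> str:
    counts = table.class_counts(originals_only=True)
    # tie -> 'healthy' (the class oversampled in the study design)
    return min(sorted(counts), key=lambda lab: counts[lab])


def oversample_minority(table: VOCTable, config: OversampleConfig) -> VOCTable:
    """Append interpolated synthetic minority samples up to ``target_n``.

    Each synthetic sample is ``x_c + u * (x_nn - x_c)`` with ``u`` uniform
    on the open interval (0, 1), ``x_c`` a randomly chosen original
    minority sample and ``x_nn`` one of its ``k_neighbors`` nearest
    original minority neighbors (Euclidean distance on raw ppb; distance
    ties broken by sample index order). Each chosen sample contributes one
    point per neighbor; the final batch is truncated so the minority count
    hits ``target_n`` exactly. Original rows are untouched and majority
    counts unchanged.
    """
    minority = _minority_label(table)
    orig_idx = np.flatnonzero(table.is_original() & (table.labels == minority))
    n_min = len(orig_idx)
    if config.target_n is None:
        config = replace(config, target_n=max(table.class_counts().values()))
    if config.target_n < n_min:
        raise ValueError(
            f"target_n={config.target_n} is below the current minority "
            f"count {n_min}"
        )
    if not 1 <= config.k_neighbors < n_min:
        raise ValueError(
            f"k_neighbors={config.k_neighbors} requires at least "
            f"{config.k_neighbors + 1} minority samples (have {n_min})"
        )
    need = config.target_n - n_min
    if need == 0:
        return table.take(np.arange(table.n_samples))

    X = table.concentrations[orig_idx]
    # pairwise distances among original minority samples; ties resolved by
    # stable argsort => lower sample index wins
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbor_order = np.argsort(d2, axis=1, kind="stable")

    rng = np.random.default_rng(config.seed)
    new_rows, new_parents = [], []
    while len(new_rows) < need:
        c = int(rng.integers(n_min))
        for nn in neighbor_order[c, : config.k_neighbors]:
            if len(new_rows) >= need:
                break  # truncate the final batch
            u = float(rng.uniform())
            while not 0.0 < u < 1.0:  # open interval: avoid exact duplicates
                u = float(rng.uniform())
            new_rows.append(X[c] + u * (X[nn] - X[c]))
            new_parents.append(
                (table.sample_ids[orig_idx[c]], table.sample_ids[orig_idx[nn]])
            )
    logger.info(
        "oversampled %r class: %d originals + %d synthetic = %d",
        minority, n_min, need, config.target_n,
    )

    n0 = table.n_samples
    return VOCTable(
        voc_names=list(table.voc_names),
        concentrations=np.vstack([table.concentrations, np.array(new_rows)]),
        labels=np.concatenate([table.labels, np.full(need, minority, object)]),
        sample_ids=table.sample_ids + [f"syn{minority[0]}{i:04d}" for i in range(need)],
        stage=np.concatenate([table.stage, np.full(need, None, object)]),
        smoking=np.concatenate([table.smoking, np.full(need, None, object)]),
        origin=np.concatenate([table.origin, np.full(need, SYNTHETIC, object)]),
        parents=list(table.parents) + new_parents,
    )
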