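"""Cohort data model for exhaled-breath VOC concentration tables.

A breath-screening cohort is a samples x VOCs matrix of concentrations
(parts per billion, measured by GC/MS after chromatographic separation),
with a binary class label per sample (``cancer`` / ``healthy``), optional
cancer stage (I-IV) and smoking status, and an ``origin`` flag separating
original clinical samples from synthetic oversampled ones.

This module provides the :class:`VOCTable` container, CSV round-trip I/O,
room-air background subtraction, and the per-VOC univariate significance
screen (two-sided Wilcoxon rank-sum and two-sample Kolmogorov-Smirnov).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANCER = "cancer"
HEALTHY = "healthy"
LABELS = (CANCER, HEALTHY)
STAGES = ("I", "II", "III", "IV")
SMOKING = ("smoker", "ex-smoker", "nonsmoker")
ORIGINAL = "original"
SYNTHETIC = "synthetic"

#: metadata columns recognised in CSV files; everything else is a VOC column
META_COLUMNS = ("sample_id", "label", "stage", "smoking", "origin")


class CohortError(ValueError):
    """Raised for malformed cohort data (bad labels, missing cells, ...)."""


@dataclass
class VOCTable:
    """Samples x VOCs concentration matrix with per-sample metadata.

    Parameters
    ----------
    voc_names
        Ordered VOC identifiers, one per matrix column.
    concentrations
        Float matrix of shape ``(n_samples, n_vocs)``, ppb. Non-negative
        after background correction with floor enabled.
    labels
        Per-sample class, each ``"cancer"`` or ``"healthy"``.
    sample_ids
        Unique per-sample identifiers.
    stage
        Optional per-sample cancer stage (``"I"``..``"IV"`` or None).
        A stage may only be present on cancer samples.
    smoking
        Optional smoking status per sample (or None).
    origin
        ``"original"`` for measured samples, ``"synthetic"`` for
        oversampled ones. Synthetic samples never carry a stage.
    parents
        For synthetic samples, the ``(chosen_id, neighbor_id)`` pair they
        were interpolated between; None for originals.
    """

    voc_names: list[str]
    concentrations: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    stage: np.ndarray = None  # type: ignore[assignment]
    smoking: np.ndarray = None  # type: ignore[assignment]
    origin: np.ndarray = None  # type: ignore[assignment]
    parents: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voc_names = list(map(str, self.voc_names))
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.ndim != 2:
            raise CohortError("concentrations must be a 2-D matrix")
        n = self.concentrations.shape[0]
        if self.concentrations.shape[1] != len(self.voc_names):
            raise CohortError(
                f"matrix has {self.concentrations.shape[1]} columns for "
                f"{len(self.voc_names)} VOC names"
            )
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.stage is None:
            self.stage = np.full(n, None, dtype=object)
        else:
            self.stage = np.asarray(self.stage, dtype=object)
        if self.smoking is None:
            self.smoking = np.full(n, None, dtype=object)
        else:
            self.smoking = np.asarray(self.smoking, dtype=object)
        if self.origin is None:
            self.origin = np.full(n, ORIGINAL, dtype=object)
        else:
            self.origin = np.asarray(self.origin, dtype=object)
        if self.parents is None:
            self.parents = [None] * n
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = self.n_samples
        for arr, name in (
            (self.labels, "labels"),
            (self.stage, "stage"),
            (self.smoking, "smoking"),
            (self.origin, "origin"),
        ):
            if len(arr) != n:
                raise CohortError(f"{name} has length {len(arr)}, expected {n}")
        if len(self.parents) != n:
            raise CohortError("parents has wrong length")
        if len(set(self.sample_ids)) != n:
            dupes = pd.Series(self.sample_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise CohortError(f"duplicate sample IDs: {dupes}")
        if len(set(self.voc_names)) != len(self.voc_names):
            raise CohortError("duplicate VOC names")
        for i, lab in enumerate(self.labels):
            if lab not in LABELS:
                raise CohortError(
                    f"sample {self.sample_ids[i]!r} (row {i}) has invalid "
                    f"label {lab!r}; expected one of {LABELS}"
                )
        for i, st in enumerate(self.stage):
            if st is None:
                continue
            if st not in STAGES:
                raise CohortError(
                    f"sample {self.sample_ids[i]!r} has invalid stage {st!r}"
                )
            if self.labels[i] != CANCER:
                raise CohortError(
                    f"sample {self.sample_ids[i]!r} has a stage but is not "
                    "a cancer sample"
                )
            if self.origin[i] == SYNTHETIC:
                raise CohortError("synthetic samples cannot carry a stage")
        for i, sm in enumerate(self.smoking):
            if sm is not None and sm not in SMOKING:
                raise CohortError(
                    f"sample {self.sample_ids[i]!r} has invalid smoking "
                    f"status {sm!r}"
                )
        for i, og in enumerate(self.origin):
            if og not in (ORIGINAL, SYNTHETIC):
                raise CohortError(f"invalid origin flag {og!r}")
        if not np.isfinite(self.concentrations).all():
            bad = np.argwhere(~np.isfinite(self.concentrations))[0]
            raise CohortError(
                f"non-finite concentration at sample "
                f"{self.sample_ids[bad[0]]!r}, VOC {self.voc_names[bad[1]]!r}"
            )

    # -- accessors -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_vocs(self) -> int:
        return len(self.voc_names)

    def voc_index(self, names) -> np.ndarray:
        """Column indices for the given VOC names (order preserved)."""
        pos = {v: j for j, v in enumerate(self.voc_names)}
        try:
            return np.array([pos[n] for n in names], dtype=int)
        except KeyError as exc:
            raise CohortError(f"VOC {exc.args[0]!r} not in table") from None

    def values(self, subset=None) -> np.ndarray:
        """Concentration matrix, optionally restricted to a VOC subset."""
        if subset is None:
            return self.concentrations
        return self.concentrations[:, self.voc_index(subset)]

    def is_original(self) -> np.ndarray:
        return self.origin == ORIGINAL

    def class_counts(self, originals_only: bool = True) -> dict:
        mask = self.is_original() if originals_only else np.ones(self.n_samples, bool)
        return {
            CANCER: int(np.sum((self.labels == CANCER) & mask)),
            HEALTHY: int(np.sum((self.labels == HEALTHY) & mask)),
        }

    def take(self, indices) -> "VOCTable":
        """Row-subset / reorder the table (new object, data copied)."""
        idx = np.asarray(indices, dtype=int)
        return VOCTable(
            voc_names=list(self.voc_names),
            concentrations=self.concentrations[idx].copy(),
            labels=self.labels[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            stage=self.stage[idx].copy(),
            smoking=self.smoking[idx].copy(),
            origin=self.origin[idx].copy(),
            parents=[self.parents[i] for i in idx],
        )

    # -- pandas bridge ---------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": self.labels,
                "stage": self.stage,
                "smoking": self.smoking,
                "origin": self.origin,
            }
        )
        for j, v in enumerate(self.voc_names):
            df[v] = self.concentrations[:, j]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VOCTable":
        vocs = [c for c in df.columns if c not in META_COLUMNS]
        conc = df[vocs].to_numpy(dtype=float)

        def _col(name):
            if name not in df.columns:
                return None
            return (df[name].astype(object)
                    .where(df[name].notna(), None).to_numpy(dtype=object))

        ids = (
            df["sample_id"].astype(str).tolist()
            if "sample_id" in df.columns
            else [f"s{i}" for i in range(len(df))]
        )
        if "label" not in df.columns:
            raise CohortError("missing label column")
        return cls(
            voc_names=vocs,
            concentrations=conc,
            labels=df["label"].to_numpy(dtype=object),
            sample_ids=ids,
            stage=_col("stage"),
            smoking=_col("smoking"),
            origin=_col("origin") if "origin" in df.columns else None,
        )


def read_voc_table(path, schema: dict | None = None,
                   impute_missing_zero: bool = False) -> VOCTable:
    """Read a cohort CSV into a :class:`VOCTable`.

    The expected dialect is comma-separated UTF-8 with a header row and the
    sample ID in the first column. ``schema`` may rename columns, e.g.
    ``{"sample_id": "subject", "label": "diagnosis", "vocs": [...]}``; any
    column not mapped to metadata is treated as a VOC concentration column.

    Missing concentration cells raise :class:`CohortError` unless
    ``impute_missing_zero`` is set, in which case they become 0.0 and the
    imputation is logged.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns.size and "sample_id" not in df.columns and "sample_id" not in schema:
        # sample-ID-first-column convention
        schema.setdefault("sample_id", df.columns[0])
    rename = {
        schema[k]: k
        for k in ("sample_id", "label", "stage", "smoking", "origin")
        if k in schema and schema[k] in df.columns
    }
    df = df.rename(columns=rename)
    if "label" not in df.columns:
        raise CohortError("missing label column")
    if "vocs" in schema:
        keep = [c for c in META_COLUMNS if c in df.columns] + list(schema["vocs"])
        df = df[keep]
    voc_cols = [c for c in df.columns if c not in META_COLUMNS]
    for c in voc_cols:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortError(
                f"non-numeric concentration {df[c].iloc[row]!r} in column "
                f"{c!r}, row {row}"
            )
        if col.isna().any():
            if not impute_missing_zero:
                row = int(np.flatnonzero(col.isna())[0])
                raise CohortError(f"missing concentration in column {c!r}, row {row}")
            n_imp = int(col.isna().sum())
            logger.warning("imputed %d missing cells in %r as 0.0", n_imp, c)
            col = col.fillna(0.0)
        df[c] = col
    table = VOCTable.from_dataframe(df)
    counts = table.class_counts(originals_only=False)
    logger.info(
        "read cohort: %d samples (%d cancer, %d healthy), %d VOCs",
        table.n_samples, counts[CANCER], counts[HEALTHY], table.n_vocs,
    )
    return table


def write_voc_table(table: VOCTable, path) -> None:
    """Write a cohort CSV (full float precision, round-trips bit-exactly)."""
    # default float formatting is shortest-round-trip repr, i.e. lossless
    table.to_dataframe().to_csv(path, index=False)


def subtract_background(table: VOCTable, background,
                        floor_at_zero: bool = True) -> VOCTable:
    """Subtract ambient room-air VOC concentrations from a cohort table.

    Exhaled air always contains the room's background volatiles, so the
    ambient concentration measured alongside breath collection is removed
    per VOC before any analysis. ``background`` maps VOC name -> ppb (dict
    or :class:`pandas.Series`); a VOC absent from the mapping is treated as
    background 0 and logged. With ``floor_at_zero`` (default) negative
    differences are clamped to 0 ppb — concentrations are physically
    non-negative — and the clamp count is logged; with it off the result is
    exact element-wise subtraction (diagnostic mode).
    """
    bg = pd.Series(background, dtype=float)
    if (bg < 0).any():
        neg = bg[bg < 0].index.tolist()
        raise CohortError(f"negative background concentration for {neg}")
    missing = [v for v in table.voc_names if v not in bg.index]
    if missing:
        logger.info("no background value for %s; treated as 0 ppb", missing)
    vec = np.array([bg.get(v, 0.0) for v in table.voc_names])
    conc = table.concentrations - vec[None, :]
    if floor_at_zero:
        n_clamped = int((conc < 0).sum())
        if n_clamped:
            logger.info("clamped %d negative concentrations to 0 ppb", n_clamped)
        conc = np.maximum(conc, 0.0)
    return replace(table, concentrations=conc,
                   parents=list(table.parents))


def _two_sample_pvalues(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Wilcoxon rank-sum p, KS p) for two samples; defined even when
    everything is tied (p = 1.0: no evidence of a shift)."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    wil = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    ks = stats.ks_2samp(x, y)
    return float(wil.pvalue), float(ks.pvalue)


def significance_screen(table: VOCTable, alpha: float = 0.05) -> pd.DataFrame:
    """Univariate cancer-vs-healthy screen per VOC on original samples.

    Computes, per VOC, a two-sided Wilcoxon rank-sum (Mann-Whitney) p-value
    and a two-sample Kolmogorov-Smirnov p-value between the original cancer
    and healthy samples (synthetic samples are excluded), with boolean flags
    ``p < alpha``. Most breath VOCs show heavily overlapping class
    distributions, so only a minority of the panel is expected to flag —
    the multivariate subset search, not this screen, carries the diagnosis.

    Returns a DataFrame indexed by VOC name with columns
    ``wilcoxon_p``, ``ks_p``, ``wilcoxon_flag``, ``ks_flag``.
    """
    orig = table.is_original()
    x_mask = orig & (table.labels == CANCER)
    y_mask = orig & (table.labels == HEALTHY)
    if x_mask.sum() < 2 or y_mask.sum() < 2:
        raise CohortError(
            "significance screen needs >= 2 original samples per class "
            f"(got {int(x_mask.sum())} cancer, {int(y_mask.sum())} healthy)"
        )
    rows = []
    for j, voc in enumerate(table.voc_names):
        wp, kp = _two_sample_pvalues(
            table.concentrations[x_mask, j], table.concentrations[y_mask, j]
        )
        rows.append((voc, wp, kp, wp < alpha, kp < alpha))
    out = pd.DataFrame(
        rows, columns=["voc", "wilcoxon_p", "ks_p", "wilcoxon_flag", "ks_flag"]
    ).set_index("voc")
    return out
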