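"""In-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a probes x samples table
with a probe-class annotation (Endogenous / Housekeeping / Positive /
Negative), mirroring the structure of an nCounter codeset.  Sample metadata
travels as a plain :class:`pandas.DataFrame` indexed by sample id with a
``cohort`` column taking values NON / FOCAL / EXT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")
COHORTS = ("NON", "FOCAL", "EXT")

_CLASS_CANON = {c.lower(): c for c in PROBE_CLASSES}


def canonical_probe_class(token: str) -> str:
    """Map a probe-class token to its canonical spelling (case-insensitive)."""
    try:
        return _CLASS_CANON[str(token).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown probe class {token!r}; expected one of {PROBE_CLASSES}"
        ) from None


@dataclass
class ExpressionMatrix:
    """Probes x samples expression table with per-probe class labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.  Raw
        matrices hold nonnegative integers; normalized matrices hold reals.
    probe_classes
        Series aligned with ``values.index`` assigning each probe one of
        ``Endogenous``, ``Housekeeping``, ``Positive``, ``Negative``.
    """

    values: pd.DataFrame
    probe_classes: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {list(dups[:5])}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        self.probe_classes = pd.Series(self.probe_classes).reindex(self.values.index)
        if self.probe_classes.isna().any():
            missing = self.probe_classes.index[self.probe_classes.isna()]
            raise ValueError(f"probes without a class label: {list(missing[:5])}")
        self.probe_classes = self.probe_classes.map(canonical_probe_class)

    # ---- convenience accessors -------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def probes_of_class(self, cls: str) -> pd.Index:
        cls = canonical_probe_class(cls)
        return self.values.index[self.probe_classes.values == cls]

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.values.loc[self.probes_of_class("Endogenous")]

    @property
    def housekeeping(self) -> pd.DataFrame:
        return self.values.loc[self.probes_of_class("Housekeeping")]

    @property
    def positive(self) -> pd.DataFrame:
        return self.values.loc[self.probes_of_class("Positive")]

    @property
    def negative(self) -> pd.DataFrame:
        return self.values.loc[self.probes_of_class("Negative")]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a copy carrying the same probe classes but new values."""
        return ExpressionMatrix(values=values, probe_classes=self.probe_classes.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[:, list(sample_ids)])

    def is_integer(self) -> bool:
        arr = np.asarray(self.values, dtype=float)
        return bool(np.all(arr == np.round(arr)))


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table and return it.

    Requires a unique sample-id index, a ``cohort`` column restricted to
    NON / FOCAL / EXT, and, when present, a ``nerve_fraction`` column
    within [0, 1].
    """
    if not annotation.index.is_unique:
        raise ValueError("sample annotation index (sample ids) must be unique")
    if "cohort" not in annotation.columns:
        raise ValueError("annotation requires a 'cohort' column")
    bad = set(annotation["cohort"].unique()) - set(COHORTS)
    if bad:
        raise ValueError(f"unknown cohort labels {sorted(bad)}; expected {COHORTS}")
    if "nerve_fraction" in annotation.columns:
        nf = annotation["nerve_fraction"].astype(float)
        if ((nf < 0) | (nf > 1)).any():
            raise ValueError("nerve_fraction must lie within [0, 1]")
    return annotation


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) keyed by a unique set id."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())
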