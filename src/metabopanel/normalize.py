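"""Reading, filtering, and normalization of metabolite peak-area matrices.

Raw peak areas are first corrected for urine concentration (fluid intake) by
dividing each sample's values by its dilution factor — the sample's osmolality
over the cohort-median osmolality — and then each metabolite is scaled to its
median across the analyzed samples and log-transformed (natural log):

    value' = ln( (peak / dilution) / median_samples(peak / dilution) )

so a metabolite sitting at its cohort median maps to 0. Non-endogenous
compounds (xenobiotics and partially characterized molecules) are excluded
before any statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DataError

STATE_RAW = "raw"
STATE_NORMALIZED = "normalized"

_VALID_CATEGORIES = {"endogenous", "xenobiotic", "partially_characterized"}


@dataclass(frozen=True)
class MetaboliteMatrix:
    """Samples × metabolites peak-area (or normalized log-index) matrix.

    Attributes
    ----------
    values : DataFrame
        Rows indexed by sample id, columns by metabolite id.
    annotations : DataFrame
        Indexed by metabolite id, with ``category`` in {endogenous,
        xenobiotic, partially_characterized} and a free-text ``pathway``.
    state : str
        ``"raw"`` (peak areas) or ``"normalized"`` (log median-scaled index).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    state: str = STATE_RAW

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "MetaboliteMatrix":
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise DataError(f"unknown sample ids: {missing[:5]}")
        return replace(self, values=self.values.loc[list(sample_ids)])

    @classmethod
    def from_csv(cls, matrix_csv, annotations_csv, state: str = STATE_RAW) -> "MetaboliteMatrix":
        values = pd.read_csv(matrix_csv, index_col=0)
        annotations = pd.read_csv(annotations_csv, index_col=0)
        if "category" not in annotations.columns:
            raise DataError("annotations CSV must have a 'category' column")
        return cls(values=values, annotations=annotations, state=state)


def read_subjects(path) -> pd.DataFrame:
    subjects = pd.read_csv(path)
    required = {"id", "group", "age", "bmi", "ga1", "ga2", "osmolality"}
    missing = required - set(subjects.columns)
    if missing:
        raise DataError(f"subjects CSV missing columns: {sorted(missing)}")
    subjects = subjects.set_index("id", drop=False)
    subjects.index.name = None
    return subjects


def filter_endogenous(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Drop xenobiotic and partially characterized columns, preserving order.

    Every column must carry an annotation; an empty result is an error rather
    than a silently empty matrix.
    """
    ann = matrix.annotations
    for met in matrix.metabolites:
        if met not in ann.index:
            raise DataError(f"metabolite {met!r} has no annotation")
        cat = ann.loc[met, "category"]
        if cat not in _VALID_CATEGORIES:
            raise DataError(f"metabolite {met!r} has unknown category {cat!r}")
    keep = [m for m in matrix.metabolites if ann.loc[m, "category"] == "endogenous"]
    if not keep:
        raise DataError("no endogenous metabolites remain after filtering")
    return replace(
        matrix,
        values=matrix.values[keep],
        annotations=ann.loc[keep],
    )


class MedianLogScaler(TransformerMixin, BaseEstimator):
    """Median scaling on the log scale: ``ln(x / median(x))`` per feature.

    ``fit`` learns per-feature medians; ``transform`` maps strictly positive
    inputs to a log index centred so the per-feature median of ``exp(output)``
    is 1 on the fitting samples.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        if (X <= 0).any():
            raise DataError("median-log scaling requires strictly positive values")
        self.n_features_in_ = X.shape[1]
        self.medians_ = np.median(X, axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "medians_")
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if (X <= 0).any():
            raise DataError("median-log scaling requires strictly positive values")
        out = np.log(X / self.medians_[None, :])
        if columns is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out


def normalize(matrix: MetaboliteMatrix, subjects: pd.DataFrame) -> MetaboliteMatrix:
    """Fluid-intake (osmolality) correction followed by median-log scaling.

    Each sample's peak areas are divided by its dilution factor
    ``osmolality / median(osmolality)`` over the samples in ``matrix``; each
    metabolite is then scaled to its median adjusted value and ln-transformed.
    The per-metabolite median is taken across all analyzed samples, blind to
    group. Calling this on an already normalized matrix is an error.
    """
    if matrix.state != STATE_RAW:
        raise DataError(f"matrix is already {matrix.state}; normalize expects raw input")
    osm = subjects["osmolality"].reindex(matrix.sample_ids)
    if osm.isna().any():
        missing = list(osm.index[osm.isna()])[:5]
        raise DataError(f"samples missing from subject table: {missing}")
    if (osm <= 0).any():
        bad = list(osm.index[osm <= 0])[:5]
        raise DataError(f"non-positive osmolality for samples: {bad}")

    nonpos = (matrix.values <= 0).any(axis=0)
    if nonpos.any():
        raise DataError(
            f"metabolite {nonpos.idxmax()!r} has non-positive raw values; "
            "zeros/missing are not imputed"
        )

    dilution = osm / osm.median()
    adjusted = matrix.values.div(dilution.to_numpy(), axis=0)
    scaler = MedianLogScaler().fit(adjusted)
    normalized = scaler.transform(adjusted)
    return replace(matrix, values=normalized, state=STATE_NORMALIZED)
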