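"""Core in-memory containers shared by every pipeline stage.

Expression and metabolite data travel as :class:`OmicsMatrix`, a thin wrapper
around a features x samples :class:`pandas.DataFrame` plus optional per-feature
annotation (metabolite class, cuticle fraction).  Sample metadata is a plain
DataFrame with columns ``sample_id``, ``organ``, ``genotype``, ``replicate``,
validated by :func:`validate_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("sample_id", "organ", "genotype", "replicate")

DEFAULT_ORGANS = (
    "root",
    "coleoptile",
    "leaf-sheath-1",
    "encased-leaves",
    "leaf-blade-1",
    "leaf-blade-2",
)
DEFAULT_GENOTYPES = ("B73", "Mo17", "B73xMo17", "Mo17xB73")


class CutinetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CutinetError):
    """Invalid configuration or parameter value."""


class ParseError(CutinetError):
    """Malformed input file."""


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with optional feature annotation.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with sample ids as columns.
    feature_meta:
        Optional DataFrame indexed by feature id; typically holds a
        ``class`` column (metabolite class) and a ``fraction`` column
        (``"wax"`` or ``"lcw"``).
    """

    data: pd.DataFrame
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ParseError(f"duplicated feature id: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ParseError(f"duplicated sample id: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values.astype(float)).all():
            raise ParseError("matrix contains non-finite values")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, ids) -> "OmicsMatrix":
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.loc[[i for i in ids if i in self.feature_meta.index]]
        return OmicsMatrix(self.data.loc[list(ids)], meta)

    def subset_samples(self, ids) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(ids)], self.feature_meta)

    def copy(self) -> "OmicsMatrix":
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        return OmicsMatrix(self.data.copy(), meta)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return the validated frame.

    Requires the four canonical columns, unique sample ids and a unique
    (organ, genotype, replicate) triple per row.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ConfigurationError(f"metadata missing columns: {missing}")
    if metadata["sample_id"].duplicated().any():
        raise ConfigurationError("duplicated sample_id in metadata")
    triple = metadata[["organ", "genotype", "replicate"]]
    if triple.duplicated().any():
        raise ConfigurationError("duplicated (organ, genotype, replicate) in metadata")
    return metadata
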