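"""Reading, writing, filtering, standardizing and aligning omics matrices.

File conventions: TSV (tab) or CSV (comma) with a header row of sample ids and
feature ids in the first column; UTF-8 with '.' decimal separator.  Floats are
serialized with Python's shortest round-trip repr, so a write/load cycle is
the identity at full double precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigurationError, OmicsMatrix, ParseError, validate_metadata

logger = logging.getLogger(__name__)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_matrix(path, kind: str = "expression") -> OmicsMatrix:
    """Load a features x samples matrix from TSV/CSV.

    ``kind`` controls missing-cell policy: expression matrices reject missing
    cells, metabolite matrices treat them as 0 (non-detected) with a warning.
    """
    path = Path(path)
    sep = _sep_for(path)
    header = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                raise ParseError(
                    f"{path.name}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {len(header)})"
                )
            rows.append([lineno, parts[0], parts[1:]])

    if header is None:
        raise ParseError(f"{path.name}: empty file")
    sample_ids = header[1:]
    feature_ids = []
    values = np.empty((len(rows), len(sample_ids)), dtype=float)
    n_missing = 0
    for i, (lineno, fid, cells) in enumerate(rows):
        feature_ids.append(fid)
        for j, cell in enumerate(cells):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                if kind == "expression":
                    raise ParseError(
                        f"{path.name}:{lineno}: missing cell for gene {fid!r}"
                    )
                values[i, j] = 0.0
                n_missing += 1
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric cell {cell!r}"
                ) from None
    if n_missing:
        logger.warning(
            "%s: %d missing metabolite cells treated as 0 (non-detected)",
            path.name,
            n_missing,
        )
    seen: set[str] = set()
    for fid in feature_ids:
        if fid in seen:
            raise ParseError(f"{path.name}: duplicated feature id {fid!r}")
        seen.add(fid)
    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return OmicsMatrix(df)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix as TSV/CSV with exact (repr) float serialization."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["feature_id", *matrix.sample_ids]) + "\n")
        values = matrix.values
        for i, fid in enumerate(matrix.feature_ids):
            fh.write(sep.join([str(fid), *(repr(float(v)) for v in values[i])]) + "\n")


def load_metadata(path) -> pd.DataFrame:
    sep = _sep_for(path)
    md = pd.read_csv(path, sep=sep)
    md["replicate"] = md["replicate"].astype(int)
    return validate_metadata(md)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep=_sep_for(path), index=False)


def filter_low_expression(expr: OmicsMatrix, min_fraction: float = 0.5) -> OmicsMatrix:
    """Keep genes expressed (value > 0) in strictly more than ``min_fraction``
    of the samples; survivor order is preserved."""
    if not 0 <= min_fraction < 1:
        raise ConfigurationError("min_fraction must be in [0, 1)")
    frac = (expr.values > 0).mean(axis=1)
    keep = [fid for fid, f in zip(expr.feature_ids, frac) if f > min_fraction]
    return expr.subset_features(keep)


def standardize(m: OmicsMatrix) -> OmicsMatrix:
    """Per-feature z-scoring: mean 0, sample variance 1 (n-1 denominator).

    Constant features cannot be standardized and are dropped with a warning.
    """
    values = m.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if constant.any():
        dropped = [fid for fid, c in zip(m.feature_ids, constant) if c]
        logger.warning("dropping %d constant feature(s): %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    keep = ~constant
    z = (values[keep] - mean[keep]) / sd[keep]
    df = pd.DataFrame(z, index=np.asarray(m.feature_ids)[keep], columns=m.sample_ids)
    meta = None
    if m.feature_meta is not None:
        meta = m.feature_meta.loc[[f for f in df.index if f in m.feature_meta.index]]
    return OmicsMatrix(df, meta)


def stratify_by_expression(
    expr: OmicsMatrix, threshold: float = 100.0
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Split genes into a highly expressed stratum (mean FPKM strictly above
    ``threshold``) and the remaining (low) stratum.

    The stratification statistic is the per-gene mean FPKM across all
    samples; a gene sitting exactly on the threshold goes to the low stratum.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0")
    means = expr.values.mean(axis=1)
    high = [fid for fid, mu in zip(expr.feature_ids, means) if mu > threshold]
    low = [fid for fid, mu in zip(expr.feature_ids, means) if mu <= threshold]
    return expr.subset_features(high), expr.subset_features(low)


def align_samples(matrices, metadata: pd.DataFrame):
    """Re-order every matrix to the metadata sample order.

    Samples missing from any layer are dropped from all layers (and from the
    returned metadata) with a logged report; fewer than 3 shared samples is an
    error.

    Returns ``(aligned_matrices, aligned_metadata)``.
    """
    validate_metadata(metadata)
    shared = [sid for sid in metadata["sample_id"] if all(sid in m.data.columns for m in matrices)]
    if len(shared) < 3:
        raise ConfigurationError(
            f"only {len(shared)} samples shared across all layers (need >= 3)"
        )
    n_dropped = len(metadata) - len(shared)
    if n_dropped:
        logger.warning("align_samples: dropped %d sample(s) missing from some layer", n_dropped)
    aligned = [m.subset_samples(shared) for m in matrices]
    md = metadata[metadata["sample_id"].isin(shared)].reset_index(drop=True)
    return aligned, md


def load_annotation(path) -> dict[str, set[str]]:
    """Load a gene -> terms map from GMT or two-column TSV.

    GMT lines are ``term<TAB>description<TAB>gene1<TAB>gene2...``; the
    two-column form is ``gene<TAB>term`` with one pair per line (a header
    line starting with ``gene`` is tolerated).
    """
    ann: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return ann
    is_gmt = str(path).endswith(".gmt") or len(lines[0].split("\t")) > 2
    if is_gmt:
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ParseError(f"malformed GMT line: {ln[:60]!r}")
            term = parts[0]
            for gene in parts[2:]:
                if gene:
                    ann.setdefault(gene, set()).add(term)
    else:
        start = 1 if lines[0].lower().startswith("gene") else 0
        for ln in lines[start:]:
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ParseError(f"malformed annotation line: {ln[:60]!r}")
            ann.setdefault(parts[0], set()).add(parts[1])
    return ann


def write_annotation(ann: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")
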