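"""Reading and writing the pipeline's plain-text interchange formats.

All tables are tab-separated UTF-8 with a mandatory header row, '.' decimal
and no quoting; counts can additionally round-trip through a MatrixMarket
triplet (``.mtx`` plus sibling gene/sample index files).  Floats in tables
are written with 6 significant digits; the summary JSON keeps full
precision.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .data import CountMatrix, NormFactors, SampleDesign, ValidationError

__all__ = [
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_norm_factors",
    "write_norm_factors",
    "read_dge_result",
    "write_dge_result",
    "write_calls",
    "read_calls",
    "write_json_atomic",
]

FLOAT_FORMAT = "%.6g"


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(".genes.tsv"), path.with_suffix(".samples.tsv")


def read_counts(path) -> CountMatrix:
    """Load a count matrix from TSV (first column gene id) or MTX triplet."""
    path = Path(path)
    if path.suffix == ".mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise ValidationError(f"MTX index file missing: {p}")
        mat = scipy_io.mmread(path)
        genes = [line.strip() for line in genes_path.read_text().splitlines() if line.strip()]
        samples = [line.strip() for line in samples_path.read_text().splitlines() if line.strip()]
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        frame = pd.DataFrame(
            dense, index=pd.Index(genes, name="gene"), columns=samples
        )
        return CountMatrix(frame)

    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed counts file {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        line = int(np.nonzero(frame.index == dup)[0][1]) + 2  # header is line 1
        raise ValidationError(f"duplicate gene id {dup!r} at line {line} of {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
    if bad.to_numpy().any():
        gene_pos = int(np.nonzero(bad.any(axis=1).to_numpy())[0][0])
        raise ValidationError(
            f"non-integer count for gene {frame.index[gene_pos]!r} "
            f"at line {gene_pos + 2} of {path}"
        )
    return CountMatrix(numeric.astype(np.int64))


def write_counts(counts: CountMatrix, path) -> None:
    """Write counts as TSV, or as an MTX triplet when path ends in .mtx."""
    path = Path(path)
    if path.suffix == ".mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        scipy_io.mmwrite(path, sparse.coo_matrix(counts.counts.to_numpy()))
        genes_path.write_text("\n".join(map(str, counts.gene_ids)) + "\n")
        samples_path.write_text("\n".join(map(str, counts.sample_ids)) + "\n")
        return
    counts.counts.to_csv(path, sep="\t", index_label="gene")


def read_samples(path) -> SampleDesign:
    """Load the sample sheet; factor levels are validated on construction."""
    table = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in table.columns:
        raise ValidationError(f"sample sheet {path} must have a 'sample' column")
    return SampleDesign(table.set_index("sample"))


def write_samples(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample")


def write_norm_factors(factors: NormFactors, path) -> None:
    frame = factors.factors.rename("factor").to_frame()
    frame.to_csv(path, sep="\t", index_label="sample", float_format="%.12g")


def read_norm_factors(path, reference_sample: str = "") -> NormFactors:
    frame = pd.read_csv(path, sep="\t", index_col="sample")
    return NormFactors(frame["factor"], reference_sample=reference_sample)


def write_dge_result(result: pd.DataFrame, path) -> None:
    """topTable-compatible TSV: gene, logFC, AveExpr, t, P.Value, adj.P.Val."""
    cols = ["logFC", "AveExpr", "t", "P.Value", "adj.P.Val"]
    result[cols].to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def read_dge_result(path, contrast: str | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    missing = {"logFC", "adj.P.Val"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path} lacks column(s) {sorted(missing)}")
    if contrast is not None:
        frame.attrs["contrast"] = contrast
    return frame


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_json_atomic(obj, path) -> None:
    """Serialize to JSON via a temp file + rename so readers never see a torn file."""
    path = Path(path)

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
    os.replace(tmp, path)
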