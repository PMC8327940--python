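"""Core in-memory containers shared across the pipeline.

The experiment is a 2 x 2 x 2 factorial: artificial-selection history
(``line_type``: control vs. resistant), herbicide treatment (``treatment``:
unsprayed vs. sprayed) and sampling time after spray (``timepoint``: 8 or
32 hours).  Counts live in a gene x sample matrix; the design is modelled
with one coefficient per occupied cell of the factorial (group-means
parameterization), so every comparison of interest is a zero-sum contrast
over cell means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LINE_TYPES = ("control", "resistant")
TREATMENTS = ("unsprayed", "sprayed")
TIMEPOINTS = (8, 32)


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample library sizes.

    ``lib_sizes`` defaults to the column sums but is kept as separate state
    so that gene filtering can retain the pre-filter sequencing depth, which
    is what CPM values are defined against downstream.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame (genes x samples)")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if values.size and (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, dtype=float)
            if not self.lib_sizes.index.equals(self.counts.columns):
                self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
            if self.lib_sizes.isna().any():
                raise ValidationError("lib_sizes must cover every sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        """New matrix restricted to ``genes``; library sizes are retained."""
        return CountMatrix(self.counts.loc[list(genes)], self.lib_sizes.copy())


def _cell_label(line_type: str, treatment: str, timepoint: int) -> str:
    return f"{line_type}.{treatment}.{timepoint}"


@dataclass
class SampleDesign:
    """Per-sample factor levels plus the derived cell-means design matrix."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("line_type", "treatment", "timepoint")
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing column(s): {', '.join(missing)}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        for col, allowed in (("line_type", LINE_TYPES), ("treatment", TREATMENTS)):
            bad = set(self.table[col]) - set(allowed)
            if bad:
                raise ValidationError(
                    f"unknown {col} level(s) {sorted(bad)!r}; allowed: {list(allowed)}"
                )
        tp = pd.to_numeric(self.table["timepoint"], errors="coerce")
        if tp.isna().any() or set(tp.astype(int)) - set(TIMEPOINTS):
            raise ValidationError(
                f"timepoint must be one of {list(TIMEPOINTS)}; "
                f"got {sorted(set(self.table['timepoint']))!r}"
            )
        self.table = self.table.copy()
        self.table["timepoint"] = tp.astype(int)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def cells(self) -> pd.Series:
        """Cell label (line.treatment.timepoint) for each sample."""
        return pd.Series(
            [
                _cell_label(r.line_type, r.treatment, r.timepoint)
                for r in self.table.itertuples()
            ],
            index=self.table.index,
            name="cell",
        )

    def cell_order(self) -> list[str]:
        occupied = set(self.cells())
        ordered = [
            _cell_label(l, t, p)
            for l in LINE_TYPES
            for t in TREATMENTS
            for p in TIMEPOINTS
        ]
        return [c for c in ordered if c in occupied]

    def design_matrix(self) -> pd.DataFrame:
        """Indicator matrix (samples x occupied cells), full column rank."""
        cells = self.cells()
        cols = self.cell_order()
        mat = pd.DataFrame(0.0, index=self.table.index, columns=cols)
        for sample, cell in cells.items():
            mat.at[sample, cell] = 1.0
        return mat

    def cell_sizes(self) -> pd.Series:
        return self.cells().value_counts().reindex(self.cell_order())

    def smallest_cell_size(self) -> int:
        return int(self.cell_sizes().min())


@dataclass(frozen=True)
class Contrast:
    """Named zero-sum weight vector over design-matrix columns."""

    name: str
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nonzero = [c for c, w in self.weights.items() if w != 0]
        if len(nonzero) < 2:
            raise ValidationError(f"contrast {self.name!r} must weight >= 2 columns")
        if abs(sum(self.weights.values())) > 1e-12:
            raise ValidationError(f"contrast {self.name!r} weights must sum to zero")

    def vector(self, columns: Iterable[str]) -> np.ndarray:
        columns = list(columns)
        missing = [c for c, w in self.weights.items() if w != 0 and c not in columns]
        if missing:
            raise ValidationError(
                f"contrast {self.name!r} needs empty design cell(s): {missing}"
            )
        return np.array([self.weights.get(c, 0.0) for c in columns], dtype=float)


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors, geometric mean one."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        self.factors = pd.Series(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValidationError("normalization factors must be positive")
        log_gm = float(np.log(self.factors).mean())
        if abs(log_gm) > 1e-10:
            raise ValidationError("normalization factors must have unit geometric mean")
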