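"""Expression filtering and between-sample normalization.

Library-size scaling uses the trimmed mean of M-values (TMM): log-ratios of
each sample against a reference are doubly trimmed (by log-ratio M and by
average log-abundance A) and the surviving ratios averaged with
inverse-variance (delta-method binomial) weights.  Filtering keeps genes
that reach a CPM floor in at least as many samples as the smallest design
cell, so a gene expressed in only one experimental group survives.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CountMatrix, NormFactors, SampleDesign, ValidationError

__all__ = ["cpm", "filter_by_expression", "tmm_factors"]


def _effective_lib_sizes(counts: CountMatrix, factors: NormFactors | None) -> pd.Series:
    lib = counts.lib_sizes
    if factors is not None:
        lib = lib * factors.factors.reindex(lib.index)
    bad = lib[~(lib > 0)]
    if len(bad):
        raise ValidationError(f"zero/invalid library size for sample {bad.index[0]!r}")
    return lib


def cpm(
    counts: CountMatrix,
    log: bool = False,
    prior_count: float = 0.5,
    factors: NormFactors | None = None,
) -> pd.DataFrame:
    """Counts per million, optionally log2 with a prior count.

    Unlogged: ``count / (lib_size * factor) * 1e6``.  Logged follows the
    voom convention ``log2((count + prior) / (lib_size * factor + 2 * prior) * 1e6)``,
    which for the default prior of 0.5 adds one read to the library size.
    """
    lib = _effective_lib_sizes(counts, factors)
    if not log:
        return counts.counts.div(lib, axis=1) * 1e6
    num = counts.counts + prior_count
    return np.log2(num.div(lib + 2.0 * prior_count, axis=1) * 1e6)


def filter_by_expression(
    counts: CountMatrix,
    design: SampleDesign,
    cpm_min: float = 10.0,
    min_prop: float | None = None,
) -> CountMatrix:
    """Keep genes with CPM >= ``cpm_min`` in at least k samples (inclusive).

    k is the smallest design-cell size, or ``ceil(min_prop * n_samples)``
    when ``min_prop`` is given.  Library sizes of the returned matrix keep
    the pre-filter totals, which makes the operation idempotent.
    """
    if cpm_min < 0:
        raise ValidationError("cpm_min must be >= 0")
    if not design.sample_ids.equals(counts.sample_ids):
        raise ValidationError("sample sheet does not match count matrix columns")
    if min_prop is None:
        k = design.smallest_cell_size()
    else:
        k = int(np.ceil(min_prop * counts.n_samples))
    values = cpm(counts, log=False)
    keep = (values >= cpm_min).sum(axis=1) >= k
    return CountMatrix(counts.counts.loc[keep], counts.lib_sizes.copy())


def _rank_ordinal(x: np.ndarray) -> np.ndarray:
    """1-based ranks; ties broken by position (deterministic on fixtures)."""
    ranks = np.empty(len(x), dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(1, len(x) + 1)
    return ranks


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference is the sample whose 75th-percentile CPM is closest to the
    mean of those percentiles (lowest index on ties).  For each sample the
    genes nonzero in both members of the pair contribute
    ``M = log2 relative rate`` and ``A = mean log2 rate``; the upper and
    lower ``trim_m`` tails of M and ``trim_a`` tails of A are discarded and
    the survivors averaged with inverse-variance weights, the delta-method
    variance of M being ``(N_k - y_k)/(N_k y_k) + (N_r - y_r)/(N_r y_r)``.
    Factors are finally scaled to unit geometric mean.
    """
    y = counts.counts.to_numpy(dtype=float)
    lib = counts.lib_sizes.to_numpy(dtype=float)
    n_samples = counts.n_samples
    if n_samples < 2:
        raise ValidationError("TMM needs at least two samples")
    if (y.sum(axis=0) == 0).any():
        idx = int(np.argmin(y.sum(axis=0)))
        raise ValidationError(f"sample {counts.sample_ids[idx]!r} has no nonzero gene")

    rates = y / lib
    f75 = np.quantile(rates, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    y_r, n_r = y[:, ref], lib[ref]

    log_factors = np.zeros(n_samples)
    for k in range(n_samples):
        y_k, n_k = y[:, k], lib[k]
        mask = (y_k > 0) & (y_r > 0)
        if not mask.any():
            raise ValidationError(
                f"sample {counts.sample_ids[k]!r} shares no nonzero gene with the "
                f"reference {counts.sample_ids[ref]!r}"
            )
        yk, yr = y_k[mask], y_r[mask]
        m = np.log2((yk / n_k) / (yr / n_r))
        if k == ref or np.max(np.abs(m)) < 1e-6:
            continue
        a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
        # delta-method variance of M; survivors averaged inverse-variance
        var_m = (n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr)
        w = 1.0 / var_m
        n = len(m)
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n - int(np.floor(n * trim_m))
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n - int(np.floor(n * trim_a))
        rm, ra = _rank_ordinal(m), _rank_ordinal(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            log_factors[k] = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    log_factors -= log_factors.mean()  # unit geometric mean
    factors = pd.Series(2.0 ** log_factors, index=counts.sample_ids, name="factor")
    return NormFactors(factors, reference_sample=str(counts.sample_ids[ref]))
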