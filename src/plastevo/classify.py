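"""Adaptive vs. maladaptive plasticity calls and concordance statistics.

A gene's *plastic* response is the expression change induced by herbicide
spray within a genotype class; its *evolved* response is the difference
between resistance-selected and control lines in a common, unsprayed
environment (measuring selection in the sprayed environment would confound
the selective response with plasticity itself).  A gene significant in both
contrasts is *adaptive* when the two log2 fold changes share a sign and
*maladaptive* when they oppose; whether adaptive calls dominate is tested
with an exact two-sided binomial test against an even split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ValidationError
from .dge import bh_fdr

__all__ = [
    "PlasticityComparison",
    "ConcordanceTest",
    "classify_genes",
    "exact_binomial_two_sided",
    "concordance_test",
    "timepoint_concordance",
    "plasticity_amplification",
    "fisher_enrichment",
    "CALLS",
]

logger = logging.getLogger(__name__)

CALLS = ("adaptive", "maladaptive", "plastic_only", "evolved_only", "none", "unclassifiable")


@dataclass
class ConcordanceTest:
    """Split of doubly significant genes and its exact binomial p-value.

    ``p_two_sided`` is ``None`` when no gene is significant in both
    contrasts (the test is undefined, not non-significant).
    """

    n_both: int
    n_concordant: int
    p_two_sided: float | None
    direction: str  # adaptive-biased | maladaptive-biased | balanced


@dataclass
class PlasticityComparison:
    """Per-gene |log2 FC| comparison of plastic responses across lines."""

    per_gene: pd.DataFrame  # abs_lfc_control, abs_lfc_resistant, greater_in_resistant
    fraction_greater: float
    n_sig_control: int
    n_sig_resistant: int
    lfc_correlation: float


def _shared_genes(a: pd.DataFrame, b: pd.DataFrame) -> pd.Index:
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValidationError("the two results share no genes")
    return shared


def classify_genes(
    plastic: pd.DataFrame,
    evolved: pd.DataFrame,
    alpha: float = 0.1,
    allow_sprayed_evolved: bool = False,
) -> pd.DataFrame:
    """Assign each shared gene exactly one plasticity call.

    ``plastic`` and ``evolved`` are differential-expression tables with
    ``logFC`` and ``adj.P.Val`` columns.  The evolved table must come from
    the unsprayed comparison of resistant vs. control lines; if its contrast
    metadata names the sprayed comparison an error is raised unless
    ``allow_sprayed_evolved`` is set, because selection measured under spray
    confounds the evolved response with plasticity.
    """
    evolved_name = evolved.attrs.get("contrast", "")
    if "sprayed" in evolved_name and "unsprayed" not in evolved_name:
        if not allow_sprayed_evolved:
            raise ValidationError(
                f"evolved result comes from contrast {evolved_name!r}, measured under "
                "spray: selection assessed in the sprayed environment confounds the "
                "evolved response with plasticity. Use the unsprayed evolved contrast, "
                "or pass allow_sprayed_evolved=True to override."
            )
    shared = _shared_genes(plastic, evolved)
    p_lfc = plastic.loc[shared, "logFC"].to_numpy()
    p_fdr = plastic.loc[shared, "adj.P.Val"].to_numpy()
    e_lfc = evolved.loc[shared, "logFC"].to_numpy()
    e_fdr = evolved.loc[shared, "adj.P.Val"].to_numpy()

    p_sig = p_fdr < alpha
    e_sig = e_fdr < alpha
    call = np.full(len(shared), "none", dtype=object)
    call[p_sig & ~e_sig] = "plastic_only"
    call[~p_sig & e_sig] = "evolved_only"
    both = p_sig & e_sig
    zero = both & ((p_lfc == 0) | (e_lfc == 0))
    call[both & (np.sign(p_lfc) == np.sign(e_lfc)) & ~zero] = "adaptive"
    call[both & (np.sign(p_lfc) != np.sign(e_lfc)) & ~zero] = "maladaptive"
    call[zero] = "unclassifiable"

    return pd.DataFrame(
        {
            "plastic_lfc": p_lfc,
            "plastic_fdr": p_fdr,
            "evolved_lfc": e_lfc,
            "evolved_fdr": e_fdr,
            "call": call,
        },
        index=shared,
    )


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood convention.

    Sums the probabilities of all outcomes whose point probability does not
    exceed that of ``k``; at ``p0 = 0.5`` this equals doubling the smaller
    tail (capped at 1).
    """
    if not 0 <= k <= n:
        raise ValidationError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValidationError("p0 must lie strictly between 0 and 1")
    return float(stats.binomtest(int(k), int(n), p0).pvalue)


def concordance_test(calls: pd.DataFrame) -> ConcordanceTest:
    """Binomial test of the adaptive/maladaptive split among doubly significant genes."""
    counts = calls["call"].value_counts()
    n_unclass = int(counts.get("unclassifiable", 0))
    if n_unclass:
        logger.warning(
            "%d doubly significant gene(s) with an exactly-zero fold change "
            "excluded from the concordance test",
            n_unclass,
        )
    n_adaptive = int(counts.get("adaptive", 0))
    n_maladaptive = int(counts.get("maladaptive", 0))
    n_both = n_adaptive + n_maladaptive
    if n_both == 0:
        return ConcordanceTest(0, 0, None, "balanced")
    p = exact_binomial_two_sided(n_adaptive, n_both, 0.5)
    if n_adaptive * 2 > n_both:
        direction = "adaptive-biased"
    elif n_adaptive * 2 < n_both:
        direction = "maladaptive-biased"
    else:
        direction = "balanced"
    return ConcordanceTest(n_both, n_adaptive, p, direction)


def timepoint_concordance(
    plastic_8h: pd.DataFrame, plastic_32h: pd.DataFrame, alpha: float = 0.1
) -> tuple[float, int]:
    """Agreement of plastic responses across the two sampling times.

    Returns the Pearson correlation of log2 fold changes over all shared
    genes, and the number of genes significant at both timepoints whose
    response direction differs.
    """
    shared = _shared_genes(plastic_8h, plastic_32h)
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared genes for a correlation")
    l8 = plastic_8h.loc[shared, "logFC"].to_numpy()
    l32 = plastic_32h.loc[shared, "logFC"].to_numpy()
    r = float(np.corrcoef(l8, l32)[0, 1])
    sig = (plastic_8h.loc[shared, "adj.P.Val"].to_numpy() < alpha) & (
        plastic_32h.loc[shared, "adj.P.Val"].to_numpy() < alpha
    )
    changed = int(np.sum(sig & (np.sign(l8) * np.sign(l32) < 0)))
    return r, changed


def plasticity_amplification(
    plastic_control: pd.DataFrame,
    plastic_resistant: pd.DataFrame,
    alpha: float = 0.1,
) -> PlasticityComparison:
    """Did selection for resistance amplify the plastic response?

    Compares the magnitude of the spray response per gene between resistant
    and control lines over all shared genes.  Exact |LFC| ties count as not
    greater, which is conservative for any 'majority amplified' claim.
    """
    shared = _shared_genes(plastic_control, plastic_resistant)
    lc = plastic_control.loc[shared, "logFC"].to_numpy()
    lr = plastic_resistant.loc[shared, "logFC"].to_numpy()
    greater = np.abs(lr) > np.abs(lc)
    per_gene = pd.DataFrame(
        {
            "abs_lfc_control": np.abs(lc),
            "abs_lfc_resistant": np.abs(lr),
            "greater_in_resistant": greater,
        },
        index=shared,
    )
    return PlasticityComparison(
        per_gene=per_gene,
        fraction_greater=float(greater.mean()),
        n_sig_control=int((plastic_control.loc[shared, "adj.P.Val"] < alpha).sum()),
        n_sig_resistant=int((plastic_resistant.loc[shared, "adj.P.Val"] < alpha).sum()),
        lfc_correlation=float(np.corrcoef(lc, lr)[0, 1]),
    )


def fisher_enrichment(
    foreground,
    background,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-term over-representation of ``foreground`` within ``background``.

    ``annotation`` maps genes to terms (two columns: gene, term).  Each term
    gets a one-sided hypergeometric (Fisher) p-value and a BH-adjusted FDR
    across terms.  Terms annotating no background gene are skipped with a
    warning.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValidationError("foreground must be a subset of background")
    ann = annotation.iloc[:, :2]
    ann.columns = ["gene", "term"]
    term_genes: dict[str, set] = {}
    for term, group in ann.groupby("term"):
        genes = set(group["gene"]) & bg
        if not genes:
            warnings.warn(f"term {term!r} annotates no background gene; skipped")
            continue
        term_genes[str(term)] = genes
    if not term_genes:
        raise ValidationError("annotation covers no background gene")

    rows = []
    n_fg, n_bg = len(fg), len(bg)
    for term, genes in sorted(term_genes.items()):
        a = len(fg & genes)
        b = n_fg - a
        c = len(genes) - a
        d = n_bg - n_fg - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, a, len(genes), odds, p))
    out = pd.DataFrame(
        rows, columns=["term", "n_foreground", "n_background", "odds_ratio", "p_value"]
    ).set_index("term")
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values("p_value")
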