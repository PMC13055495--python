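"""Per-gene interaction typing for factorial differential-expression fits.

Applies Benjamini-Hochberg adjustment per design term, then classifies every
gene with a significant (adjusted) interaction using the same additive-null
taxonomy as the ecological engine, applied to the gene's log2 fold-changes.
Classification is invariant to positive rescaling of all three coefficients,
so log2 inputs are used as-is; the per-gene interaction ratio is reported as
2^lfc_int.  Main-effect significance does not gate classification - only
the point-estimate signs enter the sign rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from multistress.engine import classify_interaction
from multistress.types import InputError, PipelineOrderError, StressorCoefficients

__all__ = [
    "adjust_bh",
    "classify_gene_interactions",
    "summarize_interaction_frequencies",
    "InteractionTypeCounts",
]

_LN2 = math.log(2.0)
_GENE_CODES = ("S+", "S-", "A+", "A-", "R+/-", "R-/+")


@dataclass
class InteractionTypeCounts:
    """Counts and proportions of interaction-type codes among significant genes."""

    counts: Dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in _GENE_CODES}
    )
    n_significant: int = 0

    @property
    def proportions(self) -> Dict[str, float]:
        if self.n_significant == 0:
            return {}
        return {c: self.counts[c] / self.n_significant for c in _GENE_CODES}


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise InputError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_gene_interactions(
    fits: pd.DataFrame, alpha: float = 0.05
) -> Tuple[pd.DataFrame, InteractionTypeCounts]:
    """Assign an interaction-type code to every significantly interactive gene.

    Requires ``padj_int`` to be populated (run :func:`adjust_bh` on the
    term's p-value column first); raises :class:`PipelineOrderError`
    otherwise.  Genes with ``padj_int < alpha`` are classified by the shared
    additive-null sign rules on (lfc_w, lfc_p, lfc_int); all other genes are
    left uncoded (code "NA").  Returns the per-gene code table and the
    aggregated type counts.
    """
    if "padj_int" not in fits.columns or fits["padj_int"].isna().any():
        raise PipelineOrderError(
            "padj_int missing: run adjust_bh on the interaction p-values first"
        )
    codes = []
    counts = InteractionTypeCounts()
    for row in fits.itertuples(index=False):
        coef = StressorCoefficients(
            response=row.gene_id, date_label="gene", link="log",
            beta_w=row.lfc_w * _LN2, beta_p=row.lfc_p * _LN2,
            beta_int=row.lfc_int * _LN2,
            se_w=row.se_w * _LN2, se_p=row.se_p * _LN2, se_int=row.se_int * _LN2,
            p_w=row.p_w, p_p=row.p_p, p_int=row.padj_int,
        )
        cls = classify_interaction(coef, alpha_sig=alpha)
        codes.append((row.gene_id, cls.code, cls.category,
                      2.0 ** row.lfc_int, cls.mild))
        if cls.code in counts.counts:
            counts.counts[cls.code] += 1
            counts.n_significant += 1
    out = pd.DataFrame(
        codes, columns=["gene_id", "code", "category", "interaction_ratio", "mild"]
    )
    return out, counts


def summarize_interaction_frequencies(counts: InteractionTypeCounts) -> dict:
    """Merged-category (R/A/S) and per-code frequency summary.

    Proportions are percentages of significant-interaction genes; with no
    significant genes the proportions are reported as absent (None).
    """
    n = counts.n_significant
    per_code = {c: counts.counts.get(c, 0) for c in _GENE_CODES}
    merged = {
        "synergism": per_code["S+"] + per_code["S-"],
        "antagonism": per_code["A+"] + per_code["A-"],
        "reversal": per_code["R+/-"] + per_code["R-/+"],
    }
    if n > 0:
        code_pct = {c: 100.0 * v / n for c, v in per_code.items()}
        merged_pct = {c: 100.0 * v / n for c, v in merged.items()}
    else:
        code_pct = None
        merged_pct = None
    return {
        "n_significant": n,
        "counts": per_code,
        "category_counts": merged,
        "percent": code_pct,
        "category_percent": merged_pct,
    }
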