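"""COG functional-class assignment and expression ranking.

COG assignment consumes a domain-hit table (protein vs position-specific
scoring models) and the model-specific bitscore thresholds published
with the model set: a hit counts only when its bitscore equals or
exceeds the threshold of the model it hits (inclusive), and a protein
inherits the single-letter functional categories of every retained
model.  Expression ranking converts per-gene read counts to TPM
(length-normalized, summing to 10^6 per sample) with average-rank tie
handling, rank 1 being the most highly transcribed gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ANNOTATION_COLUMNS

log = logging.getLogger("tnseqfit")

__all__ = ["assign_cogs", "tpm_rank"]


def assign_cogs(
    hits: pd.DataFrame,
    thresholds: dict[str, float] | pd.DataFrame,
    model_categories: dict[str, str] | pd.DataFrame,
    gene_universe: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assign COG category letters from thresholded domain hits.

    ``hits`` needs columns ``protein, model, bitscore`` (``evalue``
    optional).  ``thresholds`` maps model id → bitscore threshold
    (retention is inclusive: bitscore >= threshold).  Hits to models
    missing from the threshold table are skipped with a warning.
    ``model_categories`` maps model id → category letter string;
    multi-class models contribute all their letters.

    Returns an annotation table (locus_tag, cog_categories, pul_id,
    cazyme_flag — the latter two empty here) and a coverage summary.
    Raising any threshold can only remove assignments, never add one.
    """
    if isinstance(thresholds, pd.DataFrame):
        thresholds = dict(zip(thresholds["model"], thresholds["threshold"].astype(float)))
    if isinstance(model_categories, pd.DataFrame):
        model_categories = dict(
            zip(model_categories["model"], model_categories["category"])
        )
    assigned: dict[str, set[str]] = {}
    skipped = 0
    for row in hits.itertuples(index=False):
        model = str(row.model)
        thr = thresholds.get(model)
        if thr is None:
            skipped += 1
            continue
        if float(row.bitscore) >= thr:
            letters = model_categories.get(model)
            if letters is None:
                raise KeyError(f"model {model!r} missing from the category map")
            assigned.setdefault(str(row.protein), set()).update(letters)
    if skipped:
        log.warning("assign_cogs: %d hit(s) to models without a threshold skipped", skipped)
    universe = list(gene_universe) if gene_universe is not None else sorted(assigned)
    table = pd.DataFrame(
        {
            "locus_tag": universe,
            "cog_categories": ["".join(sorted(assigned.get(g, set()))) for g in universe],
            "pul_id": "",
            "cazyme_flag": 0,
        }
    )[ANNOTATION_COLUMNS]
    n_assigned = int((table["cog_categories"] != "").sum())
    summary = {
        "n_genes": len(universe),
        "n_assigned": n_assigned,
        "fraction_assigned": n_assigned / len(universe) if len(universe) else float("nan"),
        "n_hits_skipped_no_threshold": skipped,
    }
    return table, summary


def tpm_rank(counts: pd.Series | pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """TPM normalization and descending expression rank per sample.

    ``TPM_i = 1e6 * (c_i / L_i) / Σ_j (c_j / L_j)``; each sample's TPM
    column sums to 10^6.  Ranks are descending by TPM with average-rank
    ties (rank 1 = highest).  Scaling all counts of a sample by a
    constant leaves its TPM unchanged.
    """
    if isinstance(counts, pd.Series):
        counts = counts.to_frame("counts")
    lengths = lengths_bp.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for every gene")
    out = pd.DataFrame(index=counts.index)
    for col in counts.columns:
        c = counts[col].astype(float)
        if c.sum() <= 0:
            raise ValueError(f"sample {col!r} has all-zero counts")
        rate = c / lengths
        tpm = 1e6 * rate / rate.sum()
        out[f"tpm_{col}"] = tpm
        out[f"rank_{col}"] = tpm.rank(method="average", ascending=False)
    out.insert(0, "length_bp", lengths)
    return out.reset_index(names="locus_tag")
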