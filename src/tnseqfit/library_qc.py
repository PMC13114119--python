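"""Barcode validation filters and per-gene insertion summaries.

A barcode is trusted only if it maps to exactly one genomic site and
that site is a TA dinucleotide; everything else is a mapping artifact.
Per-gene summaries report how saturated the library is: the number of
internal TA sites, the fraction bearing at least one insertion, and
distinct insertions per gene (internal-span and full-span variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TASiteIndex, internal_ta_sites, iter_gene_models

__all__ = ["FilterReport", "filter_barcode_map", "gene_insertion_stats"]

REASON_MULTI_SITE = "multi-site"
REASON_NON_TA = "non-TA"


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    rejections: pd.DataFrame  # reason, count

    def to_frame(self) -> pd.DataFrame:
        return self.rejections


def filter_barcode_map(
    raw: pd.DataFrame, index: TASiteIndex
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain barcodes mapping to exactly one site that is a TA site.

    Rejections are data, not errors: the report tallies them by reason
    (``multi-site`` for ambiguous mapping, ``non-TA`` for off-target
    positions).  Idempotent on its own output.
    """
    raw = raw.reset_index(drop=True)
    multi = raw["n_sites"].to_numpy() != 1
    at_ta = np.zeros(len(raw), dtype=bool)
    for contig, sub in raw.groupby("contig", sort=False):
        at_ta[sub.index.to_numpy()] = np.asarray(
            index.contains(str(contig), sub["position"].to_numpy())
        )
    keep = ~multi & at_ta
    rejections = pd.DataFrame(
        {
            "reason": [REASON_MULTI_SITE, REASON_NON_TA],
            "count": [int(multi.sum()), int((~multi & ~at_ta).sum())],
        }
    )
    filtered = raw.loc[keep].reset_index(drop=True)
    return filtered, FilterReport(len(raw), len(filtered), rejections)


def gene_insertion_stats(
    bmap: pd.DataFrame,
    genes: pd.DataFrame,
    index: TASiteIndex,
    head_frac: float = 0.05,
    tail_frac: float = 0.10,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene insertion statistics and a library-level summary.

    For each gene the internal span (terminus exclusion applied) yields
    ``n_internal_ta``, the number of those sites hit by ≥1 barcode, the
    hit fraction (NaN when a gene has no internal TA sites), the mean
    number of distinct insertions per internal site, and distinct
    insertion counts over both the internal and the full gene span.
    The summary reports mean/min/max insertions per gene for both span
    conventions.
    """
    barcodes_at: dict[tuple[str, int], int] = {}
    grouped = bmap.groupby(["contig", "position"]).size()
    for (contig, pos), n in grouped.items():
        barcodes_at[(str(contig), int(pos))] = int(n)

    rows = []
    for gene in iter_gene_models(genes):
        internal = internal_ta_sites(gene, index, head_frac, tail_frac)
        n_int = len(internal)
        counts = np.array(
            [barcodes_at.get((gene.contig, int(p)), 0) for p in internal], dtype=int
        )
        n_hit = int((counts > 0).sum())
        full = index.in_span(gene.contig, gene.start, gene.end)
        total_full = int(
            sum(barcodes_at.get((gene.contig, int(p)), 0) for p in full)
        )
        rows.append(
            (
                gene.locus_tag,
                n_int,
                n_hit,
                (n_hit / n_int) if n_int else np.nan,
                (counts.sum() / n_int) if n_int else np.nan,
                int(counts.sum()),
                total_full,
            )
        )
    stats = pd.DataFrame(
        rows,
        columns=[
            "locus_tag",
            "n_internal_ta",
            "n_internal_ta_hit",
            "frac_ta_hit",
            "mean_insertions_per_ta",
            "total_insertions",
            "total_insertions_full_span",
        ],
    )
    summary = {
        "n_genes": len(stats),
        "n_retained_barcodes": int(len(bmap)),
        "mean_insertions_per_gene": float(stats["total_insertions"].mean()),
        "min_insertions_per_gene": int(stats["total_insertions"].min()),
        "max_insertions_per_gene": int(stats["total_insertions"].max()),
        "mean_insertions_per_gene_full_span": float(
            stats["total_insertions_full_span"].mean()
        ),
        "min_insertions_per_gene_full_span": int(
            stats["total_insertions_full_span"].min()
        ),
        "max_insertions_per_gene_full_span": int(
            stats["total_insertions_full_span"].max()
        ),
    }
    return stats, summary
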