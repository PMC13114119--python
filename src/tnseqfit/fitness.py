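"""Per-gene fitness scoring from paired barcode tallies.

The comparison unit is one replicate mouse: an input sample (e.g. the
pre-gavage library, T0) and an output sample (feces at day 7 or 14).
Scoring proceeds in four fixed steps:

1. *positional-bias normalization* — counts at each TA site are scaled
   by the ratio of the median genomic-window mean to their own window's
   mean, removing replication-associated (origin-proximal) coverage
   gradients;
2. *depth-matched resampling* — the input sample is repeatedly resampled
   (multinomial, at the output sample's depth) to simulate random loss
   of barcodes over time; the per-site resample mean is the expected
   input count;
3. *per-gene scoring* — the fold change is the ratio of summed output
   to expected-input counts over the gene's internal TA sites (with a
   pseudocount), reported on the signed symmetric scale
   ``s = FC if FC >= 1 else -1/FC``; the p-value is a two-sided
   Mann-Whitney test of the observed per-site output counts against the
   expected per-site input counts (exact enumeration when both vectors
   are shorter than 8, tie-corrected normal approximation otherwise);
4. *replicate combination* — arithmetic-mean ``s`` and p across mice,
   and a composite rank averaging the rank by mean p (ascending) and by
   |mean s| (descending), with average-rank tie handling (half-integer
   ranks).

The model front-end follows the Model/Results convention:
``GeneFitnessModel(tally, genes, index, pairs).fit()`` returns a
:class:`GeneFitnessResults` with the per-gene table, ``summary()``,
``significant()`` and a volcano plot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import TASiteIndex, TATally, internal_ta_sites, iter_gene_models
from .condition_sets import SignificanceSet

log = logging.getLogger("tnseqfit")

__all__ = [
    "normalize_positional_bias",
    "resample_input",
    "mannwhitney_p",
    "gene_fitness_per_sample",
    "combine_replicates",
    "select_significant",
    "GeneFitnessModel",
    "GeneFitnessResults",
]

EXACT_MAX_N = 8  # exact enumeration when both vectors are shorter than this


def normalize_positional_bias(tally: TATally, window_bp: int = 10_000) -> TATally:
    """Remove smooth positional coverage bias from each sample.

    Sites are grouped into fixed ``window_bp`` genomic windows per
    contig; each site's count is scaled by (median window mean)/(its
    window's mean), computed over windows with non-zero counts (windows
    with zero counts are scaled by 1).  Window *means* per TA site are
    used rather than raw sums so that spatially uniform counts are an
    exact fixed point even when the last window of a contig is short.
    After scaling, each sample is rescaled to preserve its original
    total; before/after totals are logged.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    counts = tally.counts.astype(float).copy()
    contigs = counts.index.get_level_values(0).to_numpy()
    positions = counts.index.get_level_values(1).to_numpy()
    window = pd.Series(
        [f"{c}:{p // window_bp}" for c, p in zip(contigs, positions)],
        index=counts.index,
    )
    for sample in counts.columns:
        col = counts[sample]
        wmean = col.groupby(window).transform("mean")
        means = col.groupby(window).mean()
        nonzero = means[means > 0]
        if nonzero.empty:
            continue
        med = float(nonzero.median())
        factor = np.where(wmean.to_numpy() > 0, med / wmean.to_numpy(), 1.0)
        scaled = col.to_numpy() * factor
        before, after = col.sum(), scaled.sum()
        if after > 0:
            scaled *= before / after
        log.debug(
            "positional normalization %s: total %.1f -> %.1f (rescaled)",
            sample,
            before,
            scaled.sum(),
        )
        counts[sample] = scaled
    return TATally(counts=counts, samples=tally.samples.copy())


def resample_input(
    counts_in: np.ndarray,
    n_resamples: int,
    depth_out: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial resamples of the input sample at the output depth.

    Draws ``n_resamples`` multinomial vectors of size ``depth_out``
    from the input site proportions, simulating random barcode loss at
    matched sequencing depth.  Returns ``(matrix, per_site_mean)`` with
    ``matrix`` of shape (n_resamples, n_sites).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if depth_out <= 0:
        raise ValueError("depth_out must be positive")
    total = float(np.sum(counts_in))
    if total <= 0:
        raise ValueError("input sample has zero total count; cannot resample")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = np.asarray(counts_in, dtype=float) / total
    matrix = rng.multinomial(int(depth_out), p, size=n_resamples)
    return matrix, matrix.mean(axis=0)


def _exact_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration over all
    assignments of the pooled midranks (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2.0
    d_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    base = n1 * (n1 + 1) / 2.0
    for comb in combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - base
        total += 1
        if abs(u - mu) >= d_obs - 1e-9:
            extreme += 1
    return extreme / total


def mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p-value with an exact small-sample branch.

    When both vectors are shorter than 8 the p-value is computed by
    exact enumeration over all C(n1+n2, n1) rank assignments (ties via
    midranks); otherwise the tie-corrected normal approximation with
    continuity correction is used.  Degenerate pooled samples (all
    values identical) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) < EXACT_MAX_N and len(y) < EXACT_MAX_N:
        return _exact_mannwhitney_p(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def signed_fold_change(fc: float) -> float:
    """Symmetric signed scale: s = FC for FC >= 1, else -1/FC."""
    return fc if fc >= 1.0 else -1.0 / fc


def gene_fitness_per_sample(
    out_counts: np.ndarray,
    expected_in: np.ndarray,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Signed fold change and rank-test p for one gene in one replicate.

    ``out_counts`` are the observed (normalized) output counts and
    ``expected_in`` the depth-matched expected input counts, both over
    the gene's internal TA sites.  ``FC = (Σout + ψ)/(Σin + ψ)``.
    """
    out_counts = np.asarray(out_counts, dtype=float)
    expected_in = np.asarray(expected_in, dtype=float)
    if out_counts.size == 0:
        return float("nan"), float("nan")
    fc = (out_counts.sum() + pseudocount) / (expected_in.sum() + pseudocount)
    return signed_fold_change(fc), mannwhitney_p(out_counts, expected_in)


def combine_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Combine per-replicate (s, p) records into the per-gene table.

    ``records`` has columns ``locus_tag, replicate, s, p``.  Combined
    statistics are arithmetic means over the replicates in which the
    gene was scored; the composite rank is the average of the rank by
    mean p (ascending) and the rank by |mean s| (descending), each with
    average-rank tie handling, so half-integer ranks occur under ties.
    Invariant to replicate ordering.
    """
    if records["replicate"].nunique() < 1:
        raise ValueError("no replicates to combine")
    wide_s = records.pivot_table(index="locus_tag", columns="replicate", values="s")
    wide_p = records.pivot_table(index="locus_tag", columns="replicate", values="p")
    n_missing = int(wide_s.isna().sum().sum())
    if n_missing:
        log.info("combine_replicates: %d gene×replicate cells missing", n_missing)
    out = pd.DataFrame(index=wide_s.index)
    out["mean_s"] = wide_s.mean(axis=1)
    out["mean_p"] = wide_p.mean(axis=1)
    out["n_replicates"] = wide_s.notna().sum(axis=1)
    rank_p = out["mean_p"].rank(method="average", ascending=True)
    rank_s = out["mean_s"].abs().rank(method="average", ascending=False)
    out["rank"] = (rank_p + rank_s) / 2.0
    for rep in wide_s.columns:
        out[f"s_{rep}"] = wide_s[rep]
        out[f"p_{rep}"] = wide_p[rep]
    return out.reset_index()


def select_significant(
    combined: pd.DataFrame,
    fc_thresh: float = 2.0,
    p_thresh: float = 0.05,
    label: str = "",
) -> SignificanceSet:
    """Direction-tagged significant gene sets at strict cutoffs.

    decreased: ``mean_s < 0`` and ``|mean_s| > fc_thresh`` and
    ``mean_p < p_thresh``; increased analogously with ``mean_s > 0``.
    Inequalities are strict, so a gene at exactly the threshold is not
    selected.
    """
    ok = (combined["mean_s"].abs() > fc_thresh) & (combined["mean_p"] < p_thresh)
    dec = set(combined.loc[ok & (combined["mean_s"] < 0), "locus_tag"])
    inc = set(combined.loc[ok & (combined["mean_s"] > 0), "locus_tag"])
    return SignificanceSet(
        label=label or f"|s|>{fc_thresh}, p<{p_thresh}",
        decreased=dec,
        increased=inc,
        cutoffs={"fc_thresh": fc_thresh, "p_thresh": p_thresh},
    )


@dataclass
class _PairScores:
    replicate: str
    sample_in: str
    sample_out: str
    table: pd.DataFrame  # locus_tag, s, p, n_internal_ta


class GeneFitnessModel:
    """Per-gene fitness model for paired input/output barcode tallies.

    Parameters
    ----------
    tally
        Raw integer TA tally containing all samples named in ``pairs``.
    genes, ta_index
        Gene table and TA-site universe on the same coordinates.
    pairs
        DataFrame with columns ``replicate, sample_in, sample_out`` —
        one row per replicate-mouse comparison.
    head_frac, tail_frac
        Gene terminus exclusion for the internal-site spans.
    window_bp, n_resamples, pseudocount
        Normalization window, number of depth-matched input resamples,
        and the fold-change pseudocount ψ.
    """

    def __init__(
        self,
        tally: TATally,
        genes: pd.DataFrame,
        ta_index: TASiteIndex,
        pairs: pd.DataFrame,
        head_frac: float = 0.05,
        tail_frac: float = 0.10,
        window_bp: int = 10_000,
        n_resamples: int = 100,
        pseudocount: float = 0.5,
    ):
        for col in ("replicate", "sample_in", "sample_out"):
            if col not in pairs.columns:
                raise ValueError(f"pairs table lacks column {col!r}")
        known = set(tally.sample_ids)
        for col in ("sample_in", "sample_out"):
            unknown = set(pairs[col].astype(str)) - known
            if unknown:
                raise ValueError(f"pairs reference unknown sample(s): {sorted(unknown)}")
        self.tally = tally
        self.genes = genes
        self.ta_index = ta_index
        self.pairs = pairs.reset_index(drop=True)
        self.head_frac = head_frac
        self.tail_frac = tail_frac
        self.window_bp = window_bp
        self.n_resamples = n_resamples
        self.pseudocount = pseudocount

    def _gene_site_slices(self):
        """Row positions of each gene's internal TA sites in the tally."""
        idx = self.tally.counts.index
        lookup = {key: i for i, key in enumerate(idx)}
        slices = []
        for gene in iter_gene_models(self.genes):
            sites = internal_ta_sites(
                gene, self.ta_index, self.head_frac, self.tail_frac
            )
            rows = np.array(
                [lookup[(gene.contig, int(p))] for p in sites if (gene.contig, int(p)) in lookup],
                dtype=np.intp,
            )
            slices.append((gene.locus_tag, len(sites), rows))
        return slices

    def fit(self, seed: int = 0) -> "GeneFitnessResults":
        """Score every gene in every replicate pair and combine.

        ``seed`` drives the multinomial input resampling; one child
        seed per pair keeps pairs independent yet reproducible.
        """
        normalized = normalize_positional_bias(self.tally, self.window_bp)
        slices = self._gene_site_slices()
        rng = np.random.default_rng(seed)
        pair_scores: list[_PairScores] = []
        records = []
        for _, pair in self.pairs.iterrows():
            rep = str(pair["replicate"])
            s_in, s_out = str(pair["sample_in"]), str(pair["sample_out"])
            col_in = normalized.counts[s_in].to_numpy()
            col_out = normalized.counts[s_out].to_numpy()
            depth_out = int(round(col_out.sum()))
            _, expected_in = resample_input(
                col_in, self.n_resamples, depth_out, rng
            )
            rows_tab = []
            for locus_tag, n_sites, rows in slices:
                if n_sites == 0 or len(rows) == 0:
                    rows_tab.append((locus_tag, np.nan, np.nan, n_sites))
                    continue
                s, p = gene_fitness_per_sample(
                    col_out[rows], expected_in[rows], self.pseudocount
                )
                rows_tab.append((locus_tag, s, p, n_sites))
                records.append((locus_tag, rep, s, p))
            pair_scores.append(
                _PairScores(
                    rep,
                    s_in,
                    s_out,
                    pd.DataFrame(
                        rows_tab, columns=["locus_tag", "s", "p", "n_internal_ta"]
                    ),
                )
            )
        rec = pd.DataFrame(records, columns=["locus_tag", "replicate", "s", "p"])
        combined = combine_replicates(rec)
        no_data = [
            t for t, n, rows in slices if n == 0 or len(rows) == 0
        ]
        return GeneFitnessResults(
            model=self, combined=combined, per_pair=pair_scores, no_data=set(no_data)
        )


class GeneFitnessResults:
    """Fitted per-gene fitness estimates with ranks and significance."""

    def __init__(self, model, combined, per_pair, no_data):
        self.model = model
        self.table = combined
        self.per_pair = per_pair
        self.no_data = no_data
        # companion FDR column for users; the selection rule itself uses
        # raw p-values
        p = combined["mean_p"].to_numpy()
        self.table = self.table.assign(q_bh=_benjamini_hochberg(p))

    def significant(
        self, fc_thresh: float = 2.0, p_thresh: float = 0.05, label: str = ""
    ) -> SignificanceSet:
        return select_significant(self.table, fc_thresh, p_thresh, label)

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("rank")
        sig = self.significant()
        lines = [
            "Gene fitness results",
            "====================",
            f"genes scored:        {len(t)}",
            f"replicate pairs:     {len(self.per_pair)}",
            f"no-data genes:       {len(self.no_data)}",
            f"decreased (|s|>2, p<0.05): {len(sig.decreased)}",
            f"increased (|s|>2, p<0.05): {len(sig.increased)}",
            "",
            f"top {top} genes by composite rank:",
            t.head(top)[["locus_tag", "mean_s", "mean_p", "rank"]].to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def plot_volcano(self, ax=None, fc_thresh: float = 2.0, p_thresh: float = 0.05):
        """Volcano plot of mean signed fold change vs mean p."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        t = self.table.dropna(subset=["mean_s", "mean_p"])
        x = np.sign(t["mean_s"]) * np.log2(t["mean_s"].abs())
        y = -np.log10(np.maximum(t["mean_p"], 1e-300))
        sig = (t["mean_s"].abs() > fc_thresh) & (t["mean_p"] < p_thresh)
        ax.scatter(x[~sig], y[~sig], s=5, c="0.6", lw=0)
        ax.scatter(x[sig], y[sig], s=7, c="crimson", lw=0)
        ax.axhline(-math.log10(p_thresh), ls=":", c="k", lw=0.8)
        for v in (-1, 1):
            ax.axvline(v * math.log2(fc_thresh), ls=":", c="k", lw=0.8)
        ax.set_xlabel("signed log2 fold change")
        ax.set_ylabel("-log10 mean p")
        return ax


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs propagated)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = len(pv)
    if n == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q
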