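"""Essential-gene candidate calling with repeat masking.

The calling rule is deliberately operational rather than mechanistic: a
gene is a zero-insertion candidate when no validated barcode maps to
any of its internal TA sites (terminus exclusion applied).  Because
mariner insertions in multi-copy genomic elements cannot be uniquely
mapped, zero-insertion calls inside repeated sequence are artifacts;
they are masked by (1) filtering a genome self-alignment hit table for
long high-identity off-diagonal hits, (2) greedily clustering the hit
spans by sequence identity, and (3) excluding genes fully contained in
a cluster member span (genes only partially overlapped are kept).  A
small curated manual-removal list is an input, not an algorithm.

The zero-insertion set is then optionally expanded to genes whose
internal TA sites are hit at a fraction at or below ``max_frac``
(default 5%), which recovers essential genes tolerating insertions in a
sub-domain, and compared across strains via reciprocal-best-hit (RBH)
ortholog maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TASiteIndex, internal_ta_sites, iter_gene_models

log = logging.getLogger("tnseqfit")

__all__ = [
    "RepeatCluster",
    "EssentialCallSet",
    "ConcordanceReport",
    "filter_self_hits",
    "cluster_repeat_spans",
    "repeat_gene_exclusions",
    "call_zero_insertion",
    "finalize_core_set",
    "expand_candidates",
    "rbh_orthologs",
    "core_concordance",
]


# ---------------------------------------------------------------------------
# repeat discovery


def filter_self_hits(
    hits: pd.DataFrame,
    min_len: int = 1000,
    min_identity: float = 90.0,
    drop_trivial_self: bool = True,
    genome_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Retain long, high-identity off-diagonal genome self-hits.

    Keeps hits with alignment length strictly greater than ``min_len``
    and identity strictly greater than ``min_identity`` (literal reading
    of the thresholds).  The trivial full-length self-vs-self diagonal
    hit is dropped, and reciprocal duplicates (A→B and B→A) are
    collapsed to a single span pair.
    """
    df = hits.copy()
    if genome_lengths:
        for _, row in df.iterrows():
            glen = genome_lengths.get(str(row["qseqid"]))
            if glen is not None and (row["qend"] > glen or row["qstart"] < 0):
                raise ValueError(
                    f"hit span [{row['qstart']}, {row['qend']}) outside "
                    f"contig {row['qseqid']} of length {glen}"
                )
    keep = (df["length"] > min_len) & (df["pident"] > min_identity)
    df = df.loc[keep]
    if drop_trivial_self:
        diagonal = (
            (df["qseqid"] == df["sseqid"])
            & (df["qstart"] == df["sstart"])
            & (df["qend"] == df["send"])
        )
        df = df.loc[~diagonal]
    key = df.apply(
        lambda r: tuple(
            sorted(
                [
                    (r["qseqid"], int(r["qstart"]), int(r["qend"])),
                    (r["sseqid"], int(r["sstart"]), int(r["send"])),
                ]
            )
        ),
        axis=1,
    )
    df = df.loc[~key.duplicated()] if len(df) else df
    return df.reset_index(drop=True)


def hit_spans(retained: pd.DataFrame) -> pd.DataFrame:
    """Unique (contig, start, end) spans appearing on either side of
    the retained self-hits, sorted by length descending."""
    spans = pd.concat(
        [
            retained[["qseqid", "qstart", "qend"]].rename(
                columns={"qseqid": "contig", "qstart": "start", "qend": "end"}
            ),
            retained[["sseqid", "sstart", "send"]].rename(
                columns={"sseqid": "contig", "sstart": "start", "send": "end"}
            ),
        ],
        ignore_index=True,
    ).drop_duplicates()
    spans["length"] = spans["end"] - spans["start"]
    return spans.sort_values(
        ["length", "contig", "start"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass
class RepeatCluster:
    """A family of mutually similar genomic spans.

    The representative is the longest member; every member matches the
    representative at identity ≥ c over ≥ cov of the shorter sequence.
    """

    representative: tuple[str, int, int]
    members: list[tuple[str, int, int]] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pairwise_identity(
    seq_a: str, seq_b: str, k: int = 11, borderline: float | None = None
) -> float:
    """Identity of the shorter sequence contained in the longer one.

    A k-mer containment estimate (``J = |K(short) ∩ K(long)| /
    |K(short)|``, mapped through ``J**(1/k)`` as for independent
    substitutions) is used as a fast screen; when the estimate falls
    within ±0.05 of ``borderline`` the call is refined with an exact
    infix edit-distance alignment (edlib), whose identity is
    ``1 − dist/len(short)``.
    """
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    ks, kl = _kmer_set(short, k), _kmer_set(long_, k)
    if not ks:
        return 0.0
    containment = len(ks & kl) / len(ks)
    est = containment ** (1.0 / k)
    if borderline is not None and abs(est - borderline) <= 0.05:
        import edlib

        dist = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
        return 1.0 - dist / len(short)
    return est


def cluster_repeat_spans(
    spans: pd.DataFrame,
    sequences: dict[str, str],
    c: float = 0.90,
    cov: float = 0.90,
    k: int = 11,
) -> list[RepeatCluster]:
    """Greedy identity clustering of repeat spans, longest first.

    Spans are sorted by length descending; each joins the first cluster
    whose representative it matches at identity ≥ ``c`` over ≥ ``cov``
    of the shorter sequence, otherwise it founds a new cluster.  The
    sort makes membership independent of input row order.
    """
    spans = spans.copy()
    spans["length"] = spans["end"] - spans["start"]
    spans = spans.sort_values(
        ["length", "contig", "start"], ascending=[False, True, True]
    )
    clusters: list[RepeatCluster] = []
    rep_seq: list[str] = []
    for row in spans.itertuples(index=False):
        contig, start, end = str(row.contig), int(row.start), int(row.end)
        if contig not in sequences:
            raise ValueError(f"no sequence available for contig {contig!r}")
        seq = sequences[contig][start:end]
        if not seq:
            raise ValueError(f"empty sequence for span ({contig}, {start}, {end})")
        placed = False
        for cl, rseq in zip(clusters, rep_seq):
            # the containment alignment spans the shorter sequence end
            # to end, so coverage of the shorter sequence is complete
            # whenever an identity is returned; the cov threshold is
            # kept in the signature for compatibility with partial-
            # coverage estimators
            ident = pairwise_identity(seq, rseq, k=k, borderline=c)
            if ident >= c and 1.0 >= cov:
                cl.members.append((contig, start, end))
                cl.identities.append(float(ident))
                placed = True
                break
        if not placed:
            clusters.append(
                RepeatCluster(
                    representative=(contig, start, end),
                    members=[(contig, start, end)],
                    identities=[1.0],
                )
            )
            rep_seq.append(seq)
    return clusters


def repeat_gene_exclusions(
    clusters: list[RepeatCluster], genes: pd.DataFrame
) -> set[str]:
    """Genes fully contained in some cluster member span.

    A gene only partially overlapped by a repetitive span is kept — the
    unique flank still allows correct mapping.
    """
    excluded: set[str] = set()
    members = [m for cl in clusters for m in cl.members]
    for gene in iter_gene_models(genes):
        for contig, start, end in members:
            if gene.contig == contig and start <= gene.start and gene.end <= end:
                excluded.add(gene.locus_tag)
                break
    return excluded


# ---------------------------------------------------------------------------
# zero-insertion calling


def call_zero_insertion(
    bmap: pd.DataFrame,
    genes: pd.DataFrame,
    index: TASiteIndex,
    head_frac: float = 0.05,
    tail_frac: float = 0.10,
) -> tuple[set[str], set[str]]:
    """Genes with zero validated barcodes at internal TA sites.

    Returns ``(called, no_data)``: genes without any internal TA site
    carry no evidence either way, are never called, and are reported in
    the separate ``no_data`` set.
    """
    occupied: set[tuple[str, int]] = {
        (str(c), int(p)) for c, p in zip(bmap["contig"], bmap["position"])
    }
    called: set[str] = set()
    no_data: set[str] = set()
    for gene in iter_gene_models(genes):
        internal = internal_ta_sites(gene, index, head_frac, tail_frac)
        if len(internal) == 0:
            no_data.add(gene.locus_tag)
            continue
        if not any((gene.contig, int(p)) in occupied for p in internal):
            called.add(gene.locus_tag)
    return called, no_data


@dataclass
class EssentialCallSet:
    """Bookkeeping of the essential-candidate calling cascade."""

    zero_insertion: set[str]
    repeat_excluded: set[str]
    manual_excluded: set[str]
    final_core: set[str]
    expanded: set[str] = field(default_factory=set)
    no_data: set[str] = field(default_factory=set)

    def cardinalities(self) -> dict[str, int]:
        return {
            "zero_insertion": len(self.zero_insertion),
            "repeat_excluded_in_zero": len(self.zero_insertion & self.repeat_excluded),
            "manual_excluded": len(self.manual_excluded),
            "final_core": len(self.final_core),
            "expanded": len(self.expanded),
            "no_data": len(self.no_data),
        }


def finalize_core_set(
    zero_set: set[str],
    repeat_exclusions: set[str],
    manual_exclusions: set[str] = frozenset(),
) -> EssentialCallSet:
    """Core candidate set: zero-insertion minus repeat and manual removals.

    Set subtraction is union-aware — a gene in both removal lists is
    only removed once.  Manual exclusions not present in the
    zero-insertion set are warned about and ignored.
    """
    stray = set(manual_exclusions) - zero_set
    if stray:
        log.warning(
            "%d manual exclusion(s) not in the zero-insertion set ignored: %s",
            len(stray),
            sorted(stray)[:5],
        )
    manual = set(manual_exclusions) & zero_set
    final = zero_set - set(repeat_exclusions) - manual
    out = EssentialCallSet(
        zero_insertion=set(zero_set),
        repeat_excluded=set(repeat_exclusions),
        manual_excluded=manual,
        final_core=final,
    )
    log.info("essential-core bookkeeping: %s", out.cardinalities())
    return out


def expand_candidates(stats: pd.DataFrame, max_frac: float = 0.05) -> set[str]:
    """Genes whose internal TA sites are hit at a fraction ≤ ``max_frac``.

    Requires ``n_internal_ta > 0``; this is a superset of the
    zero-insertion genes that have internal TA sites, and recovers
    essential genes tolerating insertions in a small sub-domain.
    """
    ok = (stats["n_internal_ta"] > 0) & (stats["frac_ta_hit"] <= max_frac)
    return set(stats.loc[ok, "locus_tag"])


# ---------------------------------------------------------------------------
# cross-strain concordance


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Top hit per query by bitscore, ties broken by e-value then
    lexicographic subject id."""
    df = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return df.drop_duplicates("qseqid", keep="first")[["qseqid", "sseqid"]]


def rbh_orthologs(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal-best-hit ortholog pairs between proteomes A and B."""
    best_ab = _best_hits(hits_ab).rename(columns={"qseqid": "a", "sseqid": "b"})
    best_ba = _best_hits(hits_ba).rename(columns={"qseqid": "b", "sseqid": "a"})
    pairs = best_ab.merge(best_ba, on=["a", "b"], how="inner")
    return pairs.sort_values(["a", "b"]).reset_index(drop=True)


@dataclass
class ConcordanceReport:
    """Cross-strain agreement of the focal essential-candidate lists."""

    shared_core: set[str]  # focal genes essential in all comparison strains
    in_focal_core: set[str]
    in_focal_expanded: set[str]
    increment: set[str]  # recovered by expansion, missed by the core list

    def counts(self) -> dict[str, int]:
        return {
            "shared_core": len(self.shared_core),
            "in_focal_core": len(self.in_focal_core),
            "in_focal_expanded": len(self.in_focal_expanded),
            "increment": len(self.increment),
        }


def core_concordance(
    strain_essential: dict[str, set[str]],
    rbh_maps: dict[str, pd.DataFrame],
    focal_core: set[str],
    focal_expanded: set[str],
) -> ConcordanceReport:
    """Concordance of the focal candidate lists with the shared core.

    The shared core is the set of focal genes whose RBH ortholog is
    essential in every comparison strain.  The report counts how many
    of those are recovered by the focal zero-insertion core list and by
    the ≤5%-TA expanded list, and lists the expansion increment.
    """
    missing = set(strain_essential) - set(rbh_maps)
    if missing:
        raise ValueError(f"missing RBH map(s) for strain(s): {sorted(missing)}")
    core: set[str] | None = None
    for strain, essentials in strain_essential.items():
        pairs = rbh_maps[strain]
        ok = set(pairs.loc[pairs["b"].isin(essentials), "a"])
        core = ok if core is None else core & ok
    core = core or set()
    in_core = core & focal_core
    in_expanded = core & focal_expanded
    return ConcordanceReport(
        shared_core=core,
        in_focal_core=in_core,
        in_focal_expanded=in_expanded,
        increment=in_expanded - in_core,
    )
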