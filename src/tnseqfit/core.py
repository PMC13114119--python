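"""Core domain objects for RB-TnSeq analysis.

The coordinate convention throughout the package is 0-based, half-open
(``[start, end)``), and a TA dinucleotide site is identified by the
coordinate of its T on the forward strand.  Readers for 1-based external
formats (GFF3, BLAST tabular) convert at the boundary.

The central objects are:

``GeneModel``
    a single annotated gene span;
``TASiteIndex``
    per-contig sorted coordinates of every TA dinucleotide, the universe
    of possible mariner-transposon insertion sites;
``TATally``
    the count matrix of summed barcode reads per TA site per sample,
    with sample metadata (condition, replicate mouse, day).

Barcode→site maps and annotation flags are carried as plain
:class:`pandas.DataFrame` objects with documented column sets
(:data:`BARCODE_MAP_COLUMNS`, :data:`ANNOTATION_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "TASiteIndex",
    "TATally",
    "BARCODE_MAP_COLUMNS",
    "ANNOTATION_COLUMNS",
    "GENE_TABLE_COLUMNS",
    "internal_ta_sites",
    "iter_gene_models",
    "genes_to_frame",
]

#: Column contract for barcode→insertion-site maps.
BARCODE_MAP_COLUMNS = ["barcode", "contig", "position", "strand", "n_sites"]

#: Column contract for per-gene annotation flags.  ``cog_categories`` is a
#: string of single-letter COG functional classes (may be empty),
#: ``pul_id`` is a polysaccharide-utilization-locus identifier or empty,
#: ``cazyme_flag`` is 1 if the product is a predicted GH/PL/CE enzyme.
ANNOTATION_COLUMNS = ["locus_tag", "cog_categories", "pul_id", "cazyme_flag"]

#: Column contract for gene tables.
GENE_TABLE_COLUMNS = [
    "locus_tag",
    "contig",
    "start",
    "end",
    "strand",
    "is_protein_coding",
    "product",
]


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene span in 0-based half-open coordinates."""

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str
    is_protein_coding: bool = True
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.locus_tag}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.locus_tag}: strand must be '+' or '-'")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


class TASiteIndex:
    """Sorted TA-dinucleotide coordinates per contig.

    Every mapped insertion position in a validated barcode map must be a
    member of this index; insertions reported elsewhere are mapping
    artifacts and are filtered out upstream.
    """

    def __init__(self, positions: Mapping[str, Iterable[int]]):
        self._positions: dict[str, np.ndarray] = {}
        for contig, pos in positions.items():
            arr = np.asarray(sorted(set(int(p) for p in pos)), dtype=np.int64)
            self._positions[contig] = arr

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "TASiteIndex":
        """Scan sequences for 'TA' and record the coordinate of each T."""
        out: dict[str, np.ndarray] = {}
        for contig, seq in sequences.items():
            s = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            hits = np.nonzero((s[:-1] == ord("T")) & (s[1:] == ord("A")))[0]
            out[contig] = hits.astype(np.int64)
        return cls(out)

    @property
    def contigs(self) -> list[str]:
        return list(self._positions)

    def positions(self, contig: str) -> np.ndarray:
        try:
            return self._positions[contig]
        except KeyError:
            raise KeyError(f"contig {contig!r} not present in TA site index") from None

    def contains(self, contig: str, position: int | np.ndarray):
        """Membership test; vectorized over ``position``."""
        pos = self._positions.get(contig)
        if pos is None:
            return np.zeros(np.shape(position), dtype=bool) if np.ndim(position) else False
        idx = np.searchsorted(pos, position)
        idx = np.clip(idx, 0, len(pos) - 1)
        found = pos[idx] == position
        return found if np.ndim(position) else bool(found)

    def in_span(self, contig: str, start: int, end: int) -> np.ndarray:
        """TA positions overlapping ``[start, end)`` on ``contig``."""
        pos = self.positions(contig)
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]

    def __len__(self) -> int:
        return int(sum(len(p) for p in self._positions.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, TASiteIndex):
            return NotImplemented
        if set(self._positions) != set(other._positions):
            return False
        return all(
            np.array_equal(self._positions[c], other._positions[c])
            for c in self._positions
        )


@dataclass
class TATally:
    """Barcode read counts summed per TA site, one column per sample.

    ``counts`` is indexed by a ``(contig, position)`` MultiIndex; columns
    are unique sample ids.  ``samples`` is a metadata frame with columns
    ``sample_id, condition, replicate, day`` aligned to the columns of
    ``counts``.  A raw tally is integer-valued; positional-bias
    normalization produces real-valued tallies.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.counts.index, pd.MultiIndex):
            raise ValueError("TATally.counts must be indexed by (contig, position)")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in tally")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("tally counts must be non-negative")
        if self.samples is None:
            self.samples = pd.DataFrame(
                {
                    "sample_id": list(self.counts.columns),
                    "condition": "",
                    "replicate": "",
                    "day": "",
                }
            )
        self.samples = self.samples.set_index(
            self.samples["sample_id"].astype(str), drop=False
        )

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    def column(self, sample_id: str) -> pd.Series:
        return self.counts[sample_id]

    def depth(self, sample_id: str) -> float:
        return float(self.counts[sample_id].sum())

    def validate_against(self, index: TASiteIndex) -> None:
        """Every tallied site must be a TA site of the index."""
        for contig, sub in self.counts.groupby(level=0, sort=False):
            pos = sub.index.get_level_values(1).to_numpy()
            ok = index.contains(str(contig), pos)
            if not np.all(ok):
                bad = pos[~np.asarray(ok)][0]
                raise ValueError(
                    f"tally site ({contig}, {bad}) is not in the TA site index"
                )


def iter_gene_models(genes: pd.DataFrame) -> Iterator[GeneModel]:
    """Yield :class:`GeneModel` records from a gene table frame."""
    for row in genes.itertuples(index=False):
        yield GeneModel(
            locus_tag=str(row.locus_tag),
            contig=str(row.contig),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            is_protein_coding=bool(getattr(row, "is_protein_coding", True)),
            product=str(getattr(row, "product", "")),
        )


def genes_to_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    rows = [
        (g.locus_tag, g.contig, g.start, g.end, g.strand, g.is_protein_coding, g.product)
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    if df["locus_tag"].duplicated().any():
        dup = df.loc[df["locus_tag"].duplicated(), "locus_tag"].iloc[0]
        raise ValueError(f"duplicate locus_tag {dup!r}")
    return df


def internal_ta_sites(
    gene: GeneModel,
    index: TASiteIndex,
    head_frac: float = 0.05,
    tail_frac: float = 0.10,
) -> np.ndarray:
    """TA sites inside a gene after strand-aware terminus exclusion.

    Insertions near gene termini are often tolerated even in essential
    genes, so insertion-density rules ignore the first ``head_frac`` and
    last ``tail_frac`` of the gene measured from its 5′ end.  A site at
    genomic coordinate ``pos`` has 5′ offset ``pos - start`` on the +
    strand and ``(end - 1) - pos`` on the − strand; it is internal when
    ``head_frac <= offset/length < 1 - tail_frac`` (half-open on both
    edges).  Returned positions are ascending genomic coordinates.
    """
    if gene.contig not in index.contigs:
        raise KeyError(f"contig {gene.contig!r} not present in TA site index")
    pos = index.in_span(gene.contig, gene.start, gene.end)
    if len(pos) == 0:
        return pos
    if gene.strand == "+":
        offset = pos - gene.start
    else:
        offset = (gene.end - 1) - pos
    frac = offset / gene.length_bp
    keep = (frac >= head_frac) & (frac < 1.0 - tail_frac)
    return pos[keep]
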