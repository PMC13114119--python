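"""Readers and writers for the tabular dialects used by the pipeline.

All on-disk formats are plain TSV (or FASTA/GFF3 through Biopython and
gffutils).  1-based external coordinates (GFF3, BLAST tabular) are
converted to the package's 0-based half-open convention here and nowhere
else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    ANNOTATION_COLUMNS,
    BARCODE_MAP_COLUMNS,
    GENE_TABLE_COLUMNS,
    TASiteIndex,
    TATally,
)

log = logging.getLogger("tnseqfit")

__all__ = [
    "Bundle",
    "read_fasta",
    "write_fasta",
    "ta_index_from_fasta",
    "read_ta_index",
    "write_ta_index",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_genes_gff3",
    "read_barcode_map",
    "write_barcode_map",
    "read_tally",
    "write_tally",
    "read_annotation",
    "write_annotation",
    "read_blast_tab",
    "load_bundle",
    "write_bundle",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def ta_index_from_fasta(path) -> TASiteIndex:
    return TASiteIndex.from_sequences(read_fasta(path))


def read_ta_index(path) -> TASiteIndex:
    df = _read_tsv(path, dtype={"contig": str, "position": np.int64})
    _require(df, ["contig", "position"], path)
    return TASiteIndex(
        {str(c): g["position"].to_numpy() for c, g in df.groupby("contig", sort=False)}
    )


def write_ta_index(index: TASiteIndex, path) -> None:
    parts = [
        pd.DataFrame({"contig": c, "position": index.positions(c)})
        for c in index.contigs
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_genes_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"locus_tag": str, "contig": str, "strand": str})
    _require(df, ["locus_tag", "contig", "start", "end", "strand"], path)
    if "is_protein_coding" not in df.columns:
        df["is_protein_coding"] = True
    if "product" not in df.columns:
        df["product"] = ""
    df["product"] = df["product"].fillna("").astype(str)
    df["is_protein_coding"] = df["is_protein_coding"].astype(bool)
    bad = df.index[~(df["start"] < df["end"])]
    if len(bad):
        raise ValueError(
            f"{path}: line {bad[0] + 2}: start must be < end (0-based half-open)"
        )
    return df[GENE_TABLE_COLUMNS]


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes_gff3(path) -> pd.DataFrame:
    """Gene table from GFF3 gene/CDS features carrying a locus_tag.

    GFF3 is 1-based inclusive; converted to 0-based half-open here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    seen = set()
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype):
            tags = feat.attributes.get("locus_tag") or [feat.id]
            tag = tags[0]
            if tag in seen:
                continue
            seen.add(tag)
            product = (feat.attributes.get("product") or [""])[0]
            rows.append(
                (
                    tag,
                    feat.seqid,
                    feat.start - 1,
                    feat.end,
                    feat.strand if feat.strand in "+-" else "+",
                    ftype == "CDS",
                    product,
                )
            )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def read_barcode_map(path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        dtype={"barcode": str, "contig": str, "position": np.int64, "strand": str},
    )
    _require(df, BARCODE_MAP_COLUMNS, path)
    return df[BARCODE_MAP_COLUMNS]


def write_barcode_map(bmap: pd.DataFrame, path) -> None:
    bmap[BARCODE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tally(path, samples_path=None) -> TATally:
    df = _read_tsv(path, dtype={"contig": str})
    _require(df, ["contig", "position"], path)
    counts = df.set_index(["contig", "position"])
    empty = [c for c in counts.columns if counts[c].sum() == 0]
    if empty:
        log.warning("tally %s: sample column(s) with zero total counts: %s", path, empty)
    samples = None
    if samples_path is not None:
        samples = _read_tsv(samples_path, dtype=str)
        _require(samples, ["sample_id", "condition", "replicate", "day"], samples_path)
    return TATally(counts=counts, samples=samples)


def write_tally(tally: TATally, path, samples_path=None) -> None:
    tally.counts.reset_index().to_csv(path, sep="\t", index=False)
    if samples_path is not None:
        tally.samples.to_csv(samples_path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype=str).fillna("")
    _require(df, ANNOTATION_COLUMNS, path)
    df["cazyme_flag"] = df["cazyme_flag"].replace("", "0").astype(int)
    return df[ANNOTATION_COLUMNS]


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


#: Standard 12 columns of BLAST tabular output (outfmt 6).
BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_blast_tab(path) -> pd.DataFrame:
    """Read BLAST outfmt-6; convert coordinates to 0-based half-open.

    BLAST reports 1-based inclusive coordinates and may report subject
    hits on the minus strand with ``sstart > send``; spans are
    orientation-normalized so start < end always holds.
    """
    df = _read_tsv(path, header=None, names=BLAST6_COLUMNS, dtype={0: str, 1: str})
    qlo = np.minimum(df["qstart"], df["qend"]) - 1
    qhi = np.maximum(df["qstart"], df["qend"])
    slo = np.minimum(df["sstart"], df["send"]) - 1
    shi = np.maximum(df["sstart"], df["send"])
    df["qstart"], df["qend"] = qlo, qhi
    df["sstart"], df["send"] = slo, shi
    return df


@dataclass
class Bundle:
    """All inputs of one analysis run, cross-validated."""

    genes: pd.DataFrame
    ta_index: TASiteIndex
    barcode_map: pd.DataFrame
    tally: TATally
    annotation: pd.DataFrame | None = None
    sequences: dict[str, str] | None = None


_BUNDLE_FILES = {
    "genes": "genes.tsv",
    "ta_index": "ta_index.tsv",
    "barcode_map": "barcode_map.tsv",
    "tally": "tatally.tsv",
    "samples": "samples.tsv",
    "annotation": "annotation.tsv",
    "genome": "genome.fasta",
}


def load_bundle(directory, validate: bool = True) -> Bundle:
    """Load a bundle directory written by :func:`write_bundle`.

    Cross-references are checked: every tally site and every mapped
    barcode position must be a member of the TA index.
    """
    d = Path(directory)
    genes = read_genes_tsv(d / _BUNDLE_FILES["genes"])
    index = read_ta_index(d / _BUNDLE_FILES["ta_index"])
    bmap = read_barcode_map(d / _BUNDLE_FILES["barcode_map"])
    samples = d / _BUNDLE_FILES["samples"]
    tally = read_tally(
        d / _BUNDLE_FILES["tally"], samples if samples.exists() else None
    )
    ann_path = d / _BUNDLE_FILES["annotation"]
    annotation = read_annotation(ann_path) if ann_path.exists() else None
    fasta = d / _BUNDLE_FILES["genome"]
    sequences = read_fasta(fasta) if fasta.exists() else None
    if validate:
        tally.validate_against(index)
        uniq = bmap[bmap["n_sites"] == 1]
        for contig, sub in uniq.groupby("contig", sort=False):
            ok = index.contains(str(contig), sub["position"].to_numpy())
            if not np.all(ok):
                bad = sub.loc[~np.asarray(ok)].iloc[0]
                raise ValueError(
                    f"barcode {bad['barcode']} maps to ({contig}, "
                    f"{bad['position']}) which is not a TA site"
                )
    log.info(
        "bundle %s: %d genes, %d TA sites, %d barcodes, %d samples",
        d,
        len(genes),
        len(index),
        len(bmap),
        len(tally.sample_ids),
    )
    return Bundle(genes, index, bmap, tally, annotation, sequences)


def write_bundle(bundle: Bundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_genes_tsv(bundle.genes, d / _BUNDLE_FILES["genes"])
    write_ta_index(bundle.ta_index, d / _BUNDLE_FILES["ta_index"])
    write_barcode_map(bundle.barcode_map, d / _BUNDLE_FILES["barcode_map"])
    write_tally(
        bundle.tally, d / _BUNDLE_FILES["tally"], d / _BUNDLE_FILES["samples"]
    )
    if bundle.annotation is not None:
        write_annotation(bundle.annotation, d / _BUNDLE_FILES["annotation"])
    if bundle.sequences is not None:
        write_fasta(bundle.sequences, d / _BUNDLE_FILES["genome"])
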