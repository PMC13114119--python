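"""Synthetic RB-TnSeq libraries with known ground truth.

The generator emulates the statistical structure of a barcoded mariner
transposon screen in a gut anaerobe passaged through gnotobiotic mice:

* a genome tiled with genes and TA dinucleotide insertion sites;
* a library of uniquely barcoded insertion mutants placed uniformly
  over TA sites, with essential genes receiving no insertions in their
  internal span (first 5% / last 10% excluded);
* planted repeat families — sequence-identical genomic blocks whose
  barcodes cannot be uniquely mapped (multiplicity > 1);
* passage through a population bottleneck (gut transit), deterministic
  exponential growth at per-gene rates ``w_g`` (log2 fitness per
  generation), and multinomial sequencing at fixed read depth.

Growth is deterministic between the two multinomial sampling layers;
demographic noise during growth is subsumed into the bottleneck, the
minimal model that reproduces over-dispersion across replicate mice.
Fitness acts at the gene level: barcodes at internal TA sites of a gene
share its ``w_g``; terminus and intergenic insertions are neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    GeneModel,
    TASiteIndex,
    TATally,
    genes_to_frame,
    internal_ta_sites,
    iter_gene_models,
)
from .io import Bundle

__all__ = [
    "FitnessComponent",
    "SimConfig",
    "SimTruth",
    "SimLibrary",
    "simulate_library",
    "simulate_passage",
    "simulate_experiment",
]

_CONTIG = "sim_chr1"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FitnessComponent:
    """One component of the per-gene fitness-effect distribution.

    ``n_genes`` genes are drawn (without replacement, among
    non-essential non-repeat genes) and assigned
    ``w ~ Normal(w_mean, w_sd)``; ``w_sd = 0`` gives a point mass.
    """

    w_mean: float
    n_genes: int
    w_sd: float = 0.0


@dataclass
class SimConfig:
    """Simulator parameters; defaults are the desk-scale study design."""

    n_genes: int = 1000
    mean_gene_length: int = 3000
    ta_density_per_kb: float = 8.0
    n_barcodes: int = 50_000
    essential_fraction: float = 0.08
    fitness_effects: dict[str, list[FitnessComponent]] = field(default_factory=dict)
    generations: float = 10.0
    bottleneck: int = 100_000
    depth: int = 2_000_000
    n_replicates: int = 5
    n_repeat_families: int = 2
    repeat_length: int = 2000
    repeat_copies: int = 3
    max_barcodes_per_site: int = 10
    head_frac: float = 0.05
    tail_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "mean_gene_length",
            "n_barcodes",
            "bottleneck",
            "depth",
            "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        if not 0.0 <= self.essential_fraction <= 1.0:
            raise ValueError("essential_fraction must lie in [0, 1]")
        for comps in self.fitness_effects.values():
            for comp in comps:
                if not np.isfinite(comp.w_mean) or not np.isfinite(comp.w_sd):
                    raise ValueError("fitness effects must be finite")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["fitness_effects"] = {
            cond: [asdict(c) for c in comps]
            for cond, comps in self.fitness_effects.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["fitness_effects"] = {
            cond: [FitnessComponent(**c) for c in comps]
            for cond, comps in (d.get("fitness_effects") or {}).items()
        }
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth: per-gene essential flags and fitness effects, and
    per-barcode host gene / initial abundance, for recovery tests."""

    genes: pd.DataFrame  # locus_tag, essential, repeat_family, w_<condition>...
    barcodes: pd.DataFrame  # barcode, host_gene, internal, abundance

    def essential_set(self) -> set[str]:
        return set(self.genes.loc[self.genes["essential"], "locus_tag"])

    def genes_with_effect(self, condition: str, w_below: float = 0.0) -> set[str]:
        col = f"w_{condition}"
        return set(self.genes.loc[self.genes[col] < w_below, "locus_tag"])


@dataclass
class SimLibrary:
    """A simulated barcoded library at T0 plus its ground truth."""

    sequences: dict[str, str]
    genes: pd.DataFrame
    ta_index: TASiteIndex
    barcode_map: pd.DataFrame
    tally: TATally
    truth: SimTruth
    config: SimConfig
    repeat_spans: pd.DataFrame  # family, contig, start, end

    def as_bundle(self) -> Bundle:
        return Bundle(
            genes=self.genes,
            ta_index=self.ta_index,
            barcode_map=self.barcode_map,
            tally=self.tally,
            sequences=self.sequences,
        )


def _random_sequence_without_ta(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform random DNA with every TA dinucleotide removed.

    Replacing the A of each TA with C or G cannot create a new TA, so a
    single vectorized pass suffices.
    """
    seq = _BASES[rng.integers(0, 4, size=length)]
    is_ta = (seq[:-1] == ord("T")) & (seq[1:] == ord("A"))
    idx = np.nonzero(is_ta)[0] + 1
    seq[idx] = np.where(rng.integers(0, 2, size=len(idx)) == 0, ord("C"), ord("G"))
    return seq


def _plant_ta_sites(
    rng: np.random.Generator, seq: np.ndarray, density_per_kb: float
) -> None:
    """Overwrite TA dinucleotides at ~``density_per_kb`` sites per kb.

    Sites are drawn from even coordinates so planted sites never
    overlap; planting T at p and A at p+1 cannot create a TA elsewhere.
    """
    n_sites = int(round(len(seq) * density_per_kb / 1000.0))
    even = np.arange(0, len(seq) - 2, 2)
    chosen = rng.choice(even, size=min(n_sites, len(even)), replace=False)
    seq[chosen] = ord("T")
    seq[chosen + 1] = ord("A")


def _tile_genes(
    rng: np.random.Generator, config: SimConfig, repeat_gene_idx: set[int]
) -> list[GeneModel]:
    lengths = rng.normal(config.mean_gene_length, 0.2 * config.mean_gene_length,
                         size=config.n_genes)
    lengths = np.clip(np.round(lengths), 300, None).astype(int)
    for i in repeat_gene_idx:
        # repeat member genes sit fully inside a pasted repeat block
        lengths[i] = config.repeat_length - 200
    gaps = (50 + rng.exponential(250, size=config.n_genes + 1)).astype(int)
    for i in repeat_gene_idx:
        gaps[i] = max(gaps[i], 160)
        gaps[i + 1] = max(gaps[i + 1], 160)
    genes: list[GeneModel] = []
    pos = 0
    for i in range(config.n_genes):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"SIM_{i:05d}", _CONTIG, start, end, strand, True, ""))
        pos = end
    return genes


def simulate_library(config: SimConfig) -> SimLibrary:
    """Build a genome, barcode library, and T0 tally with known truth.

    Deterministic for a fixed ``config.seed``.  Raises if the requested
    number of barcodes cannot be placed on the available TA sites.
    """
    rng = np.random.default_rng(config.seed)

    n_repeat_genes = config.n_repeat_families * config.repeat_copies
    n_essential = int(round(config.essential_fraction * config.n_genes))
    if n_repeat_genes + n_essential > config.n_genes:
        raise ValueError(
            f"{n_repeat_genes} repeat-family genes plus {n_essential} essential "
            f"genes exceed n_genes={config.n_genes}"
        )
    perm = rng.permutation(config.n_genes)
    repeat_idx = perm[:n_repeat_genes]
    essential_idx = set(perm[n_repeat_genes : n_repeat_genes + n_essential])
    family_of: dict[int, int] = {}
    for f in range(config.n_repeat_families):
        for c in range(config.repeat_copies):
            family_of[int(repeat_idx[f * config.repeat_copies + c])] = f

    genes = _tile_genes(rng, config, set(family_of))
    genome_len = genes[-1].end + 200
    seq = _random_sequence_without_ta(rng, genome_len)
    _plant_ta_sites(rng, seq, config.ta_density_per_kb)

    # paste identical repeat blocks over each family member gene (plus
    # 100 bp flanks), so member copies are sequence-identical
    repeat_rows = []
    for f in range(config.n_repeat_families):
        block = _random_sequence_without_ta(rng, config.repeat_length)
        _plant_ta_sites(rng, block, config.ta_density_per_kb)
        for i, fam in family_of.items():
            if fam != f:
                continue
            start = genes[i].start - 100
            seq[start : start + config.repeat_length] = block
            repeat_rows.append((f, _CONTIG, start, start + config.repeat_length))
    repeat_spans = pd.DataFrame(
        repeat_rows, columns=["family", "contig", "start", "end"]
    )

    sequences = {_CONTIG: seq.tobytes().decode("ascii")}
    index = TASiteIndex.from_sequences(sequences)
    gene_frame = genes_to_frame(genes)

    # ground-truth per-gene fitness effects
    truth_genes = gene_frame[["locus_tag"]].copy()
    truth_genes["essential"] = [i in essential_idx for i in range(config.n_genes)]
    truth_genes["repeat_family"] = [family_of.get(i, -1) for i in range(config.n_genes)]
    eligible = np.array(
        [
            i
            for i in range(config.n_genes)
            if i not in essential_idx and i not in family_of
        ]
    )
    w_by_condition: dict[str, np.ndarray] = {}
    for cond, comps in config.fitness_effects.items():
        w = np.zeros(config.n_genes)
        pool = rng.permutation(eligible)
        used = 0
        for comp in comps:
            take = pool[used : used + comp.n_genes]
            if len(take) < comp.n_genes:
                raise ValueError(
                    f"condition {cond!r}: not enough eligible genes for "
                    f"fitness component ({comp.n_genes} requested)"
                )
            w[take] = comp.w_mean + comp.w_sd * rng.standard_normal(len(take))
            used += comp.n_genes
        w_by_condition[cond] = w
        truth_genes[f"w_{cond}"] = w

    # barcode placement: uniform over all TA sites except internal sites
    # of essential genes
    all_sites = index.positions(_CONTIG)
    excluded = set()
    for i in essential_idx:
        excluded.update(
            internal_ta_sites(genes[i], index, config.head_frac, config.tail_frac)
        )
    allowed = np.array(sorted(set(all_sites.tolist()) - excluded), dtype=np.int64)
    if config.n_barcodes > len(allowed) * config.max_barcodes_per_site:
        raise ValueError(
            f"cannot place {config.n_barcodes} barcodes on {len(allowed)} "
            f"available TA sites (max {config.max_barcodes_per_site} per site)"
        )
    site_of_barcode = rng.choice(allowed, size=config.n_barcodes, replace=True)

    barcode_seqs = _unique_barcodes(rng, config.n_barcodes)
    strands = np.where(rng.integers(0, 2, size=config.n_barcodes) == 0, "+", "-")

    multiplicity = np.ones(config.n_barcodes, dtype=int)
    for _, row in repeat_spans.iterrows():
        inside = (site_of_barcode >= row["start"]) & (site_of_barcode < row["end"])
        multiplicity[inside] = config.repeat_copies

    barcode_map = pd.DataFrame(
        {
            "barcode": barcode_seqs,
            "contig": _CONTIG,
            "position": site_of_barcode,
            "strand": strands,
            "n_sites": multiplicity,
        }
    )

    # host gene and internal/terminal classification per barcode
    starts = gene_frame["start"].to_numpy()
    ends = gene_frame["end"].to_numpy()
    gi = np.searchsorted(starts, site_of_barcode, side="right") - 1
    host = np.full(config.n_barcodes, "", dtype=object)
    in_gene = (gi >= 0) & (site_of_barcode < ends[np.clip(gi, 0, None)])
    host[in_gene] = gene_frame["locus_tag"].to_numpy()[gi[in_gene]]
    internal_sets = {
        genes[i].locus_tag: set(
            internal_ta_sites(genes[i], index, config.head_frac, config.tail_frac)
        )
        for i in range(config.n_genes)
    }
    internal = np.array(
        [
            bool(h) and int(p) in internal_sets[h]
            for h, p in zip(host, site_of_barcode)
        ]
    )

    abundance = rng.exponential(1.0, size=config.n_barcodes)
    abundance /= abundance.sum()

    truth_barcodes = pd.DataFrame(
        {
            "barcode": barcode_seqs,
            "host_gene": host,
            "internal": internal,
            "abundance": abundance,
        }
    )
    truth = SimTruth(genes=truth_genes, barcodes=truth_barcodes)

    t0 = rng.multinomial(config.depth, abundance)
    counts = _aggregate_to_sites(t0[:, None], site_of_barcode, all_sites, ["T0"])
    samples = pd.DataFrame(
        {"sample_id": ["T0"], "condition": ["T0"], "replicate": [""], "day": ["0"]}
    )
    tally = TATally(counts=counts, samples=samples)

    return SimLibrary(
        sequences=sequences,
        genes=gene_frame,
        ta_index=index,
        barcode_map=barcode_map,
        tally=tally,
        truth=truth,
        config=config,
        repeat_spans=repeat_spans,
    )


def _unique_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> np.ndarray:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        chunk = _BASES[rng.integers(0, 4, size=(n - len(out), length))]
        for row in chunk:
            bc = row.tobytes().decode("ascii")
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return np.array(out, dtype=object)


def _aggregate_to_sites(
    per_barcode: np.ndarray,
    site_of_barcode: np.ndarray,
    all_sites: np.ndarray,
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Sum per-barcode count columns into per-TA-site rows."""
    site_idx = np.searchsorted(all_sites, site_of_barcode)
    cols = {}
    for j, sid in enumerate(sample_ids):
        acc = np.zeros(len(all_sites), dtype=np.int64)
        np.add.at(acc, site_idx, per_barcode[:, j])
        cols[sid] = acc
    frame = pd.DataFrame(cols)
    frame.index = pd.MultiIndex.from_arrays(
        [np.repeat(_CONTIG, len(all_sites)), all_sites], names=["contig", "position"]
    )
    return frame


def _barcode_w(library: SimLibrary, condition: str) -> np.ndarray:
    """Per-barcode log2 fitness per generation under ``condition``.

    Only barcodes at internal TA sites of a gene inherit its ``w``;
    terminus and intergenic insertions are neutral.
    """
    col = f"w_{condition}"
    if col not in library.truth.genes.columns:
        return np.zeros(len(library.barcode_map))
    w_of_gene = dict(
        zip(library.truth.genes["locus_tag"], library.truth.genes[col])
    )
    bc = library.truth.barcodes
    return np.array(
        [
            w_of_gene.get(h, 0.0) if internal else 0.0
            for h, internal in zip(bc["host_gene"], bc["internal"])
        ]
    )


def simulate_passage(
    library: SimLibrary,
    condition: str,
    config: SimConfig | None = None,
    seed: int | None = None,
    start_abundance: np.ndarray | None = None,
    sample_prefix: str | None = None,
) -> tuple[TATally, np.ndarray]:
    """One passage per replicate: bottleneck → growth → sequencing.

    Per replicate mouse: (1) a multinomial draw of ``bottleneck`` cells
    over barcode abundances, (2) deterministic growth multiplying each
    barcode by ``2**(w_g * generations)``, (3) a multinomial sequencing
    draw of ``depth`` reads over the grown proportions, summed per TA
    site.  Returns the tally (one column per replicate) and the
    post-growth abundance matrix (replicates × barcodes) for chaining
    sequential passages.
    """
    config = config or library.config
    rng = np.random.default_rng(library.config.seed + 1 if seed is None else seed)
    w = _barcode_w(library, condition)
    growth = np.power(2.0, w * config.generations)
    if start_abundance is None:
        start_abundance = np.broadcast_to(
            library.truth.barcodes["abundance"].to_numpy(),
            (config.n_replicates, len(library.barcode_map)),
        )
    prefix = sample_prefix or condition
    per_barcode = np.empty((len(library.barcode_map), config.n_replicates), dtype=np.int64)
    post = np.empty_like(start_abundance, dtype=float)
    for r in range(config.n_replicates):
        p0 = start_abundance[r] / start_abundance[r].sum()
        cells = rng.multinomial(config.bottleneck, p0)
        grown = cells * growth
        total = grown.sum()
        if total == 0:
            raise ValueError("bottleneck extinguished the entire library")
        post[r] = grown / total
        per_barcode[:, r] = rng.multinomial(config.depth, post[r])
    sample_ids = [f"{prefix}_rep{r + 1}" for r in range(config.n_replicates)]
    all_sites = library.ta_index.positions(_CONTIG)
    counts = _aggregate_to_sites(
        per_barcode, library.barcode_map["position"].to_numpy(), all_sites, sample_ids
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": condition,
            "replicate": [str(r + 1) for r in range(config.n_replicates)],
            "day": "",
        }
    )
    return TATally(counts=counts, samples=samples), post


@dataclass
class SimExperiment:
    """A library plus passage outputs and the input/output pairing."""

    library: SimLibrary
    tally: TATally  # T0 column plus one column per replicate per condition
    pairs: pd.DataFrame  # replicate, sample_in, sample_out, condition


def simulate_experiment(
    config: SimConfig, conditions: Sequence[str] | None = None
) -> SimExperiment:
    """Library plus one passage per condition, each compared to T0.

    Mirrors the screen design: the pre-gavage broth-grown library (T0)
    is the shared input, and each replicate mouse contributes one output
    sample per condition.
    """
    library = simulate_library(config)
    conditions = list(conditions or config.fitness_effects or ["invivo"])
    counts = [library.tally.counts]
    samples = [library.tally.samples]
    rows = []
    for i, cond in enumerate(conditions):
        tally, _ = simulate_passage(library, cond, seed=config.seed + 1000 + i)
        counts.append(tally.counts)
        samples.append(tally.samples)
        for r, sid in enumerate(tally.sample_ids):
            rows.append((str(r + 1), "T0", sid, cond))
    merged = TATally(
        counts=pd.concat(counts, axis=1),
        samples=pd.concat(samples, ignore_index=True),
    )
    pairs = pd.DataFrame(rows, columns=["replicate", "sample_in", "sample_out", "condition"])
    return SimExperiment(library=library, tally=merged, pairs=pairs)
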