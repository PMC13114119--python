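"""Multi-condition refinement of significant gene sets and COG/PUL
enrichment accounting.

A condition screen (e.g. colitis, day 14 vs day 7) is confounded by
genes responding to extra colonization time and to the chemical
exposure itself; those are measured in dedicated control comparisons
and removed by direction-blind set subtraction with a full audit
trail, so the arithmetic (|refined| + |removed| = |condition|) is
checkable per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SignificanceSet",
    "refine_condition_set",
    "category_fraction",
    "annotation_overlap_count",
]


@dataclass
class SignificanceSet:
    """Direction-tagged significant gene sets with provenance."""

    label: str
    decreased: set[str] = field(default_factory=set)
    increased: set[str] = field(default_factory=set)
    cutoffs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.decreased & self.increased
        if overlap:
            raise ValueError(
                f"gene(s) in both directions of {self.label!r}: {sorted(overlap)[:5]}"
            )

    def all_genes(self) -> set[str]:
        return self.decreased | self.increased

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "decreased") for g in sorted(self.decreased)]
        rows += [(g, "increased") for g in sorted(self.increased)]
        return pd.DataFrame(rows, columns=["locus_tag", "direction"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "SignificanceSet":
        dec = set(df.loc[df["direction"] == "decreased", "locus_tag"])
        inc = set(df.loc[df["direction"] == "increased", "locus_tag"])
        return cls(label=label, decreased=dec, increased=inc)


def refine_condition_set(
    condition: SignificanceSet,
    time_control: SignificanceSet,
    exposure_control: SignificanceSet,
) -> tuple[SignificanceSet, pd.DataFrame]:
    """Remove time-effect and exposure-effect genes from a condition set.

    Removal is direction-blind: a gene significant in a control in
    either direction is removed from both directions of the condition
    set.  The audit frame lists every removed gene with its direction
    and reason; per direction,
    ``|refined| + |removed| = |condition|`` exactly.
    """
    time_genes = time_control.all_genes()
    exposure_genes = exposure_control.all_genes()
    audit_rows = []
    refined = {}
    for direction in ("decreased", "increased"):
        genes: set[str] = getattr(condition, direction)
        keep = set()
        for g in sorted(genes):
            if g in time_genes:
                audit_rows.append((g, direction, "time-control overlap"))
            elif g in exposure_genes:
                audit_rows.append((g, direction, "exposure-control overlap"))
            else:
                keep.add(g)
        refined[direction] = keep
    audit = pd.DataFrame(audit_rows, columns=["locus_tag", "direction", "removal_reason"])
    out = SignificanceSet(
        label=f"{condition.label} minus ({time_control.label}, {exposure_control.label})",
        decreased=refined["decreased"],
        increased=refined["increased"],
        cutoffs=dict(condition.cutoffs),
    )
    return out, audit


def _category_sets(annotation: pd.DataFrame) -> dict[str, set[str]]:
    """COG category letter → set of genes carrying it (multi-category
    genes count in each of their categories)."""
    cats: dict[str, set[str]] = {}
    for tag, letters in zip(annotation["locus_tag"], annotation["cog_categories"]):
        for letter in str(letters):
            if letter.strip():
                cats.setdefault(letter, set()).add(str(tag))
    return cats


def category_fraction(
    sig: SignificanceSet, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-COG-category fraction of genes significant in each direction.

    The denominator for category k is all annotated genes carrying k in
    the genome; genes without any category are excluded.  Categories
    present in the vocabulary but carried by zero genes are reported
    with an undefined (NaN) fraction.
    """
    cats = _category_sets(annotation)
    rows = []
    for letter in sorted(cats):
        genes = cats[letter]
        denom = len(genes)
        for direction in ("decreased", "increased"):
            num = len(genes & getattr(sig, direction))
            frac = num / denom if denom else float("nan")
            rows.append((letter, direction, num, denom, frac))
    return pd.DataFrame(
        rows, columns=["category", "direction", "numerator", "denominator", "fraction"]
    )


_FLAG_COLUMNS = {"pul": "pul_id", "cazyme": "cazyme_flag"}


def annotation_overlap_count(
    sig_genes: set[str],
    annotation: pd.DataFrame,
    flags: tuple[str, ...] = ("pul", "cazyme"),
) -> tuple[int, list[str]]:
    """Count significant genes carrying any of the requested flags.

    ``pul`` matches a non-empty PUL id, ``cazyme`` a non-zero predicted
    glycoside hydrolase / polysaccharide lyase / carbohydrate esterase
    flag; union semantics over the requested flags.
    """
    flagged: set[str] = set()
    for flag in flags:
        if flag not in _FLAG_COLUMNS:
            raise ValueError(
                f"unknown flag {flag!r}; known flags: {sorted(_FLAG_COLUMNS)}"
            )
        col = _FLAG_COLUMNS[flag]
        if flag == "pul":
            has = annotation[col].astype(str).str.strip() != ""
        else:
            has = annotation[col].astype(int) != 0
        flagged |= set(annotation.loc[has, "locus_tag"].astype(str))
    hit = sorted(sig_genes & flagged)
    return len(hit), hit
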