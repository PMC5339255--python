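"""Build the normalized 2D gene-variant map from score tables.

The map places one point per gene: ``x`` is the gene's disease-association
Z-score divided by the maximum Z-score in the input table (so the
strongest gene sits at x = 1), and ``y`` is the fraction of the gene's
variant deleteriousness mass carried by disease-associated variants,

    y(g) = sum of aggregated scores over disease-flagged variants of g
           / sum of aggregated scores over all variants of g.

Per-locus deleteriousness scores (1-SIFT or PolyPhen, both in [0, 1] with
higher = more damaging) may list several possible variations at a locus;
these are collapsed to one value per locus by the mean or the range
(max - min) before the ratio is taken.

Trait curation is external to this module: the ``disease_associated``
flag is an input column, not computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InputError

ScoreKind = Literal["one_minus_sift", "polyphen"]
Aggregation = Literal["mean", "range"]

SCORE_KINDS: tuple[str, ...] = ("one_minus_sift", "polyphen")
AGGREGATIONS: tuple[str, ...] = ("mean", "range")

#: Decimal places used when writing map TSVs.
MAP_FLOAT_FORMAT = "%.6f"


@dataclass(frozen=True)
class VariantRecord:
    """One variant locus: per-allele deleteriousness scores plus a disease flag.

    ``allele_scores`` holds one score in [0, 1] per possible variation at
    the locus (semantics: 1-SIFT or PolyPhen; higher = more damaging).
    """

    variant_id: str
    gene: str
    allele_scores: tuple[float, ...]
    disease_associated: bool

    def __post_init__(self) -> None:
        if len(self.allele_scores) == 0:
            raise InputError(
                f"variant {self.variant_id!r} ({self.gene}): empty allele_scores"
            )
        for s in self.allele_scores:
            if not (0.0 <= s <= 1.0) or not math.isfinite(s):
                raise InputError(
                    f"variant {self.variant_id!r} ({self.gene}): allele score "
                    f"{s!r} outside [0, 1]"
                )


@dataclass(frozen=True)
class GeneScoreRecord:
    """A gene symbol with its raw disease-association Z-score."""

    gene: str
    z_score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.z_score):
            raise InputError(f"gene {self.gene!r}: non-finite z_score")


@dataclass(frozen=True)
class GenePoint:
    """One gene on the map: x = normalized gene score, y = normalized variant score."""

    gene: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise InputError(
                f"gene {self.gene!r}: point ({self.x}, {self.y}) outside unit square"
            )


@dataclass
class GeneVariantMap:
    """The score-based 2D map of genes, ready for tessellation."""

    points: list[GenePoint]
    score_kind: str = "one_minus_sift"
    locus_aggregation: str = "mean"
    disease_label: str = ""

    def __post_init__(self) -> None:
        genes = [p.gene for p in self.points]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise InputError(f"duplicate gene symbols on map: {dupes}")
        if self.score_kind not in SCORE_KINDS:
            raise InputError(f"unknown score_kind {self.score_kind!r}")
        if self.locus_aggregation not in AGGREGATIONS:
            raise InputError(f"unknown locus_aggregation {self.locus_aggregation!r}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def genes(self) -> list[str]:
        return [p.gene for p in self.points]

    def coordinates(self) -> np.ndarray:
        """Return the (n, 2) array of (x, y) site coordinates."""
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    def __getitem__(self, gene: str) -> GenePoint:
        for p in self.points:
            if p.gene == gene:
                return p
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes,
             "x": [p.x for p in self.points],
             "y": [p.y for p in self.points]}
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the map as a 3-column TSV with 6-decimal coordinates."""
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format=MAP_FLOAT_FORMAT)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **meta) -> "GeneVariantMap":
        _require_columns(frame, ("gene", "x", "y"), "map table")
        points = [GenePoint(str(r.gene), float(r.x), float(r.y))
                  for r in frame.itertuples(index=False)]
        return cls(points=points, **meta)

    @classmethod
    def from_tsv(cls, path: str | Path, **meta) -> "GeneVariantMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"), **meta)


# ---------------------------------------------------------------------------
# table IO


def _require_columns(frame: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise InputError(f"{what}: missing column(s) {missing}")


def read_gene_table(path: str | Path) -> list[GeneScoreRecord]:
    """Read a gene-score TSV with columns ``gene``, ``z_score``."""
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ("gene", "z_score"), "gene table")
    return [GeneScoreRecord(str(r.gene), float(r.z_score))
            for r in frame.itertuples(index=False)]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant-score TSV.

    Columns: ``variant_id``, ``gene``, ``allele_scores`` (comma-separated
    reals in [0, 1]), ``disease_associated`` (0/1). Unknown columns are
    ignored.
    """
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ("variant_id", "gene", "allele_scores",
                             "disease_associated"), "variant table")
    records = []
    for r in frame.itertuples(index=False):
        scores = tuple(float(s) for s in str(r.allele_scores).split(","))
        records.append(VariantRecord(str(r.variant_id), str(r.gene), scores,
                                     bool(int(r.disease_associated))))
    _check_unique_variants(records)
    return records


def _check_unique_variants(records: Sequence[VariantRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.variant_id, rec.gene)
        if key in seen:
            raise InputError(f"duplicate (variant_id, gene) pair {key}")
        seen.add(key)


def genes_to_frame(genes: Iterable[GeneScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame({"gene": [g.gene for g in genes],
                         "z_score": [g.z_score for g in genes]})


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {"variant_id": [v.variant_id for v in variants],
         "gene": [v.gene for v in variants],
         "allele_scores": [",".join(repr(float(s)) for s in v.allele_scores)
                           for v in variants],
         "disease_associated": [int(v.disease_associated) for v in variants]}
    )


# ---------------------------------------------------------------------------
# score arithmetic


def aggregate_locus_score(record: VariantRecord, method: str = "mean") -> float:
    """Collapse a locus's per-allele scores to a single value in [0, 1].

    ``mean`` takes the arithmetic mean; ``range`` takes max - min (zero
    for a single-allele locus).
    """
    if method not in AGGREGATIONS:
        raise InputError(f"unknown aggregation method {method!r}")
    scores = record.allele_scores
    if method == "mean":
        return float(sum(scores) / len(scores))
    return float(max(scores) - min(scores))


def normalize_variant_score(records: Sequence[VariantRecord],
                            method: str = "mean") -> float:
    """Disease-associated fraction of a gene's total variant score mass.

    Raises :class:`DegenerateInputError` when every aggregated score is
    zero (0/0 is not evidence of absence; the caller excludes the gene).
    """
    if not records:
        raise InputError("no variant records supplied")
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise InputError(f"records span several genes: {sorted(genes)}")
    scores = [aggregate_locus_score(r, method) for r in records]
    denom = sum(scores)
    if denom <= 0.0:
        raise DegenerateInputError(
            f"gene {records[0].gene!r}: all aggregated variant scores are zero; "
            "disease ratio undefined"
        )
    numer = sum(s for s, r in zip(scores, records) if r.disease_associated)
    return float(numer / denom)


def normalize_gene_scores(genes: Sequence[GeneScoreRecord]) -> dict[str, float]:
    """Divide every Z-score by the maximum; the top gene maps to exactly 1."""
    if not genes:
        raise InputError("empty gene list")
    symbols = [g.gene for g in genes]
    if len(set(symbols)) != len(symbols):
        raise InputError("gene symbols not unique in gene table")
    z_max = max(g.z_score for g in genes)
    if z_max <= 0.0:
        raise DegenerateInputError(
            f"maximum z_score is {z_max}; normalization undefined"
        )
    return {g.gene: g.z_score / z_max for g in genes}


def build_map(genes: Sequence[GeneScoreRecord],
              variants: Sequence[VariantRecord],
              score_kind: str = "one_minus_sift",
              locus_aggregation: str = "mean",
              disease_label: str = "",
              drop_zero_disease_genes: bool = False) -> GeneVariantMap:
    """Compose the gene-variant map from the two score tables.

    One point is produced per gene that has at least one variant record
    and a defined variant ratio. Variants whose gene is absent from the
    gene table are dropped with a warning, as are genes whose variant
    denominator is zero. ``drop_zero_disease_genes`` additionally drops
    genes with no disease-associated variant (y = 0) instead of keeping
    them on the x-axis.
    """
    _check_unique_variants(variants)
    x_by_gene = normalize_gene_scores(genes)

    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in variants:
        if rec.gene not in x_by_gene:
            warnings.warn(
                f"variant {rec.variant_id!r}: gene {rec.gene!r} not in gene "
                "table; dropped", stacklevel=2)
            continue
        by_gene.setdefault(rec.gene, []).append(rec)

    points: list[GenePoint] = []
    for gene in (g.gene for g in genes):
        recs = by_gene.get(gene)
        if not recs:
            continue
        try:
            y = normalize_variant_score(recs, locus_aggregation)
        except DegenerateInputError:
            warnings.warn(
                f"gene {gene!r}: zero total variant score; excluded from map",
                stacklevel=2)
            continue
        if drop_zero_disease_genes and y == 0.0:
            continue
        points.append(GenePoint(gene, x_by_gene[gene], y))

    if len(points) < 3:
        raise DegenerateInputError(
            f"map has only {len(points)} point(s); at least 3 are required "
            "for tessellation"
        )
    return GeneVariantMap(points=points, score_kind=score_kind,
                          locus_aggregation=locus_aggregation,
                          disease_label=disease_label)
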