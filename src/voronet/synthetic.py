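"""Seeded synthetic inputs with known structure.

Two generators cover the two entry points of the pipeline:

* :func:`make_mock_map` emits a map directly — uniform background
  points plus isotropic Gaussian blobs truncated to the unit square —
  with the planted background/blob label of every point, emulating the
  normally-distributed mock data used to exercise tessellation and
  clustering. Blob spread (sd = 0.01) and size (15 points against 40
  background) are chosen so that blob cells are one to two orders of
  magnitude denser than background cells, putting planted clusters
  safely above any background-fitted threshold.
* :func:`make_toy_tables` emits small gene/variant score tables whose
  normalized map is hand-checkable, exercising the score-integration
  path.

Everything is driven by a single integer seed through
``numpy.random.default_rng``; identical seeds give byte-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .score_map import GenePoint, GeneVariantMap

__all__ = [
    "BlobSpec", "SyntheticSpec", "make_mock_map", "make_toy_tables",
    "two_blob_spec", "null_spec",
]


@dataclass(frozen=True)
class BlobSpec:
    """One planted cluster: isotropic normal at ``center`` with ``sd``."""

    center: tuple[float, float]
    sd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InputError("blob sd must be positive")
        if self.n_points < 1:
            raise InputError("blob must contain at least one point")


@dataclass(frozen=True)
class SyntheticSpec:
    """Mock-map recipe: uniform background plus zero or more blobs."""

    n_background: int
    blobs: tuple[BlobSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.n_background + sum(b.n_points for b in self.blobs)
        if total < 4:
            raise InputError(f"spec yields {total} points; at least 4 required")


def two_blob_spec(seed: int = 11) -> SyntheticSpec:
    """The planted-truth benchmark: two tight blobs on uniform background."""
    return SyntheticSpec(
        n_background=40,
        blobs=(BlobSpec((0.3, 0.3), 0.01, 15),
               BlobSpec((0.7, 0.7), 0.01, 15)),
        seed=seed)


def null_spec(seed: int = 11) -> SyntheticSpec:
    """The two-blob spec with the blobs removed: purely uniform background."""
    return SyntheticSpec(n_background=40, blobs=(), seed=seed)


def _truncated_normal(rng: np.random.Generator, center, sd: float,
                      n: int) -> np.ndarray:
    """Isotropic normal samples restricted to the unit square by resampling.

    Resampling (rather than clipping) avoids piling density onto the
    border.
    """
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        draw = rng.normal(loc=center, scale=sd, size=(n - filled, 2))
        ok = draw[np.all((draw >= 0.0) & (draw <= 1.0), axis=1)]
        out[filled:filled + len(ok)] = ok
        filled += len(ok)
    return out


def make_mock_map(spec: SyntheticSpec) -> tuple[GeneVariantMap, np.ndarray]:
    """Generate a mock map and the planted label of every point.

    Labels: 0 for background, k >= 1 for the k-th blob. Gene names are
    synthetic (``G0001`` ...). Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    parts = [rng.uniform(0.0, 1.0, size=(spec.n_background, 2))]
    labels = [np.zeros(spec.n_background, dtype=int)]
    for k, blob in enumerate(spec.blobs, start=1):
        parts.append(_truncated_normal(rng, blob.center, blob.sd, blob.n_points))
        labels.append(np.full(blob.n_points, k, dtype=int))
    points = np.vstack(parts)
    label_arr = np.concatenate(labels)
    gene_points = [GenePoint(f"G{i + 1:04d}", float(x), float(y))
                   for i, (x, y) in enumerate(points)]
    gvmap = GeneVariantMap(points=gene_points, disease_label="synthetic-mock")
    return gvmap, label_arr


def make_toy_tables(seed: int = 1, n_genes: int = 20,
                    mean_variants: float = 3.0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Small paired gene/variant score tables for the integration path.

    About ``n_genes`` genes (symbols ``TG01`` ...) with positive
    Z-scores and, per gene, 1-5 variant loci carrying 1-4 per-allele
    scores (3 decimals, in [0, 1]) and a Bernoulli(0.6) disease flag.
    Returns (gene table, variant table) as DataFrames matching the TSV
    schemas.
    """
    rng = np.random.default_rng(seed)
    genes = [f"TG{i + 1:02d}" for i in range(n_genes)]
    z = np.round(rng.uniform(0.5, 5.0, size=n_genes), 3)
    gene_frame = pd.DataFrame({"gene": genes, "z_score": z})

    rows = []
    rs = 1000
    for g in genes:
        k = int(rng.integers(1, 6))
        for _ in range(k):
            n_alleles = int(rng.integers(1, 5))
            scores = np.round(rng.uniform(0.0, 1.0, size=n_alleles), 3)
            rows.append({
                "variant_id": f"rs{rs}",
                "gene": g,
                "allele_scores": ",".join(f"{s:.3f}" for s in scores),
                "disease_associated": int(rng.random() < 0.6),
            })
            rs += 1
    variant_frame = pd.DataFrame(rows)
    return gene_frame, variant_frame
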