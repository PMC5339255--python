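"""Model/Results front end over the full pipeline.

:class:`VoronoiRiskModel` holds a gene-variant map;
:meth:`VoronoiRiskModel.fit` runs tessellation, density normalization,
background-threshold estimation and cluster detection, and returns a
:class:`VoronoiRiskResults` carrying the fitted background law, the
cluster set, a per-gene results table and the risk/association
accessors, in the spirit of a statsmodels results object.

Example
-------
>>> from voronet import VoronoiRiskModel, synthetic
>>> gvmap, labels = synthetic.make_mock_map(synthetic.two_blob_spec(seed=11))
>>> res = VoronoiRiskModel(gvmap).fit()
>>> len(res.clusters)
2
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import background as _background
from . import clustering as _clustering
from . import risk as _risk
from . import score_map as _score_map
from . import tessellation as _tessellation
from .background import BackgroundFit
from .clustering import ClusterSet
from .score_map import GeneVariantMap
from .tessellation import Tessellation

__all__ = ["VoronoiRiskModel", "VoronoiRiskResults"]


class VoronoiRiskModel:
    """Voronoi-tessellation risk model of a gene-variant map.

    Parameters
    ----------
    gene_variant_map
        A :class:`~voronet.score_map.GeneVariantMap` (build one with
        :meth:`from_tables` or :meth:`from_files`).
    jitter, seed
        Optional deterministic perturbation forwarded to the
        tessellation for maps with coinciding points.
    bounding_box
        Clip the diagram to the unit square so every cell is bounded
        (extension; the default excludes boundary cells).
    """

    def __init__(self, gene_variant_map: GeneVariantMap, *,
                 jitter: float = 0.0, seed: Optional[int] = None,
                 bounding_box: bool = False) -> None:
        self.map = gene_variant_map
        self.jitter = jitter
        self.seed = seed
        self.bounding_box = bounding_box

    @classmethod
    def from_tables(cls, genes, variants, *,
                    score_kind: str = "one_minus_sift",
                    locus_aggregation: str = "mean",
                    disease_label: str = "",
                    drop_zero_disease_genes: bool = False,
                    **kwargs) -> "VoronoiRiskModel":
        """Build the map from gene-score and variant-score record lists."""
        gvmap = _score_map.build_map(
            genes, variants, score_kind=score_kind,
            locus_aggregation=locus_aggregation, disease_label=disease_label,
            drop_zero_disease_genes=drop_zero_disease_genes)
        return cls(gvmap, **kwargs)

    @classmethod
    def from_files(cls, gene_table: Union[str, Path],
                   variant_table: Union[str, Path], **kwargs
                   ) -> "VoronoiRiskModel":
        """Build the map from the gene and variant TSV files."""
        genes = _score_map.read_gene_table(gene_table)
        variants = _score_map.read_variant_table(variant_table)
        return cls.from_tables(genes, variants, **kwargs)

    def fit(self, *, background_fraction: float = 0.8,
            significance: float = 0.9, min_size: int = 2,
            integer_b: bool = True) -> "VoronoiRiskResults":
        """Run the full pipeline and return the results object.

        Tessellates the map, normalizes bounded-cell densities, fits
        the chi-square background law to the lowest
        ``background_fraction`` of the densities, places the clustering
        threshold at the ``significance`` quantile of the fitted law,
        and detects clusters of at least ``min_size`` cells.
        """
        tess = _tessellation.tessellate(
            self.map, jitter=self.jitter, seed=self.seed,
            bounding_box=self.bounding_box)
        _tessellation.normalize_densities(tess)
        _tessellation.qualified_neighbors(tess)
        fit = _background.fit_threshold(
            tess.bounded_normalized_densities(),
            fraction=background_fraction, significance=significance,
            integer_b=integer_b)
        clusters = _clustering.detect_clusters(tess, fit.threshold,
                                               min_size=min_size)
        return VoronoiRiskResults(self, tess, fit, clusters)


class VoronoiRiskResults:
    """Fitted pipeline state: tessellation, background law, clusters, risks."""

    def __init__(self, model: VoronoiRiskModel, tessellation: Tessellation,
                 background_fit: BackgroundFit, clusters: ClusterSet) -> None:
        self.model = model
        self.map = model.map
        self.tessellation = tessellation
        self.background = background_fit
        self.clusters = clusters

    # ------------------------------------------------------------------
    # accessors

    @property
    def threshold(self) -> float:
        return self.background.threshold

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def frame(self) -> pd.DataFrame:
        """Per-gene table: coordinates, cell geometry, cluster and risk."""
        cells = _tessellation.cells_frame(self.tessellation)
        memb = _clustering.clusters_frame(self.clusters, self.tessellation)
        out = cells.merge(
            memb[["gene", "cluster_label", "cluster_score", "above_threshold"]],
            on="gene")
        out["risk"] = np.where(out["cluster_label"] > 0,
                               out["normalized_density"] * out["cluster_score"],
                               np.nan)
        return out

    def risk_score(self, gene: str) -> _risk.RiskScore:
        return _risk.risk_score(gene, self.clusters, self.tessellation)

    def relative_risk(self, gene_i: str, gene_j: str) -> float:
        """Unrounded relative risk between two clustered genes."""
        return _risk.relative_risk(self.risk_score(gene_i),
                                   self.risk_score(gene_j))

    def relative_disease_association(self, genes_i: Iterable[str],
                                     genes_j: Iterable[str]) -> dict:
        """Ratio of summed S_G * S_V products between two gene sets."""
        return _risk.relative_disease_association(
            _risk.association_scores(self.map, genes_i),
            _risk.association_scores(self.map, genes_j))

    # ------------------------------------------------------------------
    # reporting

    def summary(self) -> str:
        """Human-readable run summary."""
        t, bg = self.tessellation, self.background
        lines = [
            "Voronoi gene-variant risk analysis",
            "==================================",
            f"disease label:        {self.map.disease_label or '-'}",
            f"genes on map:         {t.n_sites}",
            f"bounded cells:        {t.n_finite}",
            f"qualified edges:      {len(t.qualified_edges())} "
            f"(of {len(t.edges)} Delaunay)",
            f"background:           lowest {bg.background_fraction:.0%}, "
            f"cutoff {bg.background_cutoff:.3g} (n={bg.n_background})",
            f"chi-square fit:       a={bg.a:.3g}, b={bg.b:.3g}, c={bg.c:.3g} "
            f"(objective {bg.objective:.3g})",
            f"threshold ({bg.significance:.0%}):      {bg.threshold:.4g}",
            f"clusters (>= {self.clusters.min_size} cells): {self.n_clusters}",
        ]
        names = self.tessellation.names
        for cl in self.clusters.clusters:
            members = ", ".join(sorted(names[i] for i in cl.members))
            lines.append(f"  cluster {cl.label}: score {cl.score:.2f}, "
                         f"{len(cl)} genes [{members}]")
        return "\n".join(lines)

    def plot(self, ax=None, show_labels: bool = False):
        """Voronoi diagram with cluster members highlighted by color."""
        import matplotlib.pyplot as plt
        from scipy.spatial import voronoi_plot_2d

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        vor = _voronoi_of(self.tessellation)
        voronoi_plot_2d(vor, ax=ax, show_vertices=False, show_points=False,
                        line_colors="0.6", line_width=0.8)
        sites = self.tessellation.sites
        labels = np.array([self.clusters.label_of(i)
                           for i in range(self.tessellation.n_sites)])
        ax.scatter(*sites[labels == 0].T, s=12, c="0.4", label="unclustered")
        cmap = plt.get_cmap("tab10")
        for cl in self.clusters.clusters:
            idx = sorted(cl.members)
            ax.scatter(*sites[idx].T, s=24, color=cmap((cl.label - 1) % 10),
                       label=f"cluster {cl.label} ({cl.score:.1f})")
        if show_labels:
            for name, (x, y) in zip(self.tessellation.names, sites):
                ax.annotate(name, (x, y), fontsize=6)
        ax.set_xlabel("normalized gene score $S_G$")
        ax.set_ylabel("normalized variant score $S_V$")
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.05, 1.05)
        ax.legend(loc="upper left", fontsize=8)
        return ax


def _voronoi_of(t: Tessellation):
    from scipy.spatial import Voronoi
    return Voronoi(t.sites)
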