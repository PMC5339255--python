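"""Cluster detection over the qualified-neighbor graph.

A cluster is a maximal connected group of bounded Voronoi cells whose
normalized densities strictly exceed the threshold, where connectivity
runs along qualified (midpoint-test) neighbor edges. Connected
components are canonical, so the result is independent of any visiting
order; the randomized flood-fill formulation gives the same partition
and is kept only as a test oracle. Unbounded cells never join clusters.

Components smaller than ``min_size`` (default 2: a one-cell "cluster"
has no network support) are left unclustered. The cluster score is the
sum of its members' normalized densities; labels 1, 2, ... are assigned
in descending score order, ties broken by the lexicographically
smallest member gene symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Optional

import math

import networkx as nx
import pandas as pd

from .exceptions import InputError
from .tessellation import Tessellation

__all__ = ["Cluster", "ClusterSet", "detect_clusters", "clusters_frame"]


@dataclass(frozen=True)
class Cluster:
    """A labelled cluster: member site indices and the summed f~ score."""

    label: int
    members: FrozenSet[int]
    score: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """All clusters of one map at one threshold, plus the leftover sites."""

    clusters: list[Cluster]
    threshold: float
    unclustered: FrozenSet[int]
    min_size: int = 2

    def __len__(self) -> int:
        return len(self.clusters)

    def label_of(self, site: int) -> int:
        """Cluster label of a site, 0 when unclustered."""
        for cl in self.clusters:
            if site in cl.members:
                return cl.label
        return 0

    def cluster_of(self, site: int) -> Optional[Cluster]:
        for cl in self.clusters:
            if site in cl.members:
                return cl
        return None

    def _check(self, n_sites: int) -> None:
        seen: set[int] = set()
        for cl in self.clusters:
            if seen & cl.members:
                raise AssertionError("clusters overlap")
            seen |= cl.members
        if seen | set(self.unclustered) != set(range(n_sites)):
            raise AssertionError("clusters + unclustered do not cover all sites")


def detect_clusters(t: Tessellation, threshold: float,
                    min_size: int = 2) -> ClusterSet:
    """Connected components of above-threshold cells under qualified edges.

    Membership requires a bounded cell with normalized density strictly
    greater than ``threshold``; components with fewer than ``min_size``
    members are reported as unclustered.
    """
    if not math.isfinite(threshold):
        raise InputError(f"threshold {threshold!r} is not finite")
    if min_size < 1:
        raise InputError("min_size must be >= 1")
    nd = t.normalized_densities
    eligible = {i for i, c in enumerate(t.cells)
                if c.bounded and c.normalized_density is not None
                and c.normalized_density > threshold}

    graph = nx.Graph()
    graph.add_nodes_from(eligible)
    graph.add_edges_from((a, b) for a, b in t.qualified_edges()
                         if a in eligible and b in eligible)

    raw = [frozenset(comp) for comp in nx.connected_components(graph)
           if len(comp) >= min_size]
    scored = [(float(sum(nd[i] for i in comp)), comp) for comp in raw]
    scored.sort(key=lambda sc: (-sc[0], min(t.names[i] for i in sc[1])))

    clusters = [Cluster(label=k, members=comp, score=score)
                for k, (score, comp) in enumerate(scored, start=1)]
    member_union: set[int] = set().union(*(c.members for c in clusters)) \
        if clusters else set()
    cs = ClusterSet(clusters=clusters, threshold=float(threshold),
                    unclustered=frozenset(set(range(t.n_sites)) - member_union),
                    min_size=min_size)
    cs._check(t.n_sites)
    return cs


def clusters_frame(cs: ClusterSet, t: Tessellation) -> pd.DataFrame:
    """Per-gene cluster table (label 0 = unclustered).

    ``above_threshold`` flags dense-but-unclustered singletons dropped
    by the ``min_size`` rule.
    """
    nd = t.normalized_densities
    labels = [cs.label_of(i) for i in range(t.n_sites)]
    score_by_label = {c.label: c.score for c in cs.clusters}
    return pd.DataFrame(
        {"gene": t.names,
         "cluster_label": labels,
         "normalized_density": nd,
         "cluster_score": [score_by_label.get(l, float("nan")) for l in labels],
         "above_threshold": [int(c.bounded and c.normalized_density is not None
                                 and c.normalized_density > cs.threshold)
                             for c in t.cells]}
    )
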