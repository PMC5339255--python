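"""Risk scores, relative risk, and relative disease association.

A clustered gene's disease risk score is the product of its own
normalized Voronoi cell density and the score (summed f~) of the
cluster it belongs to:

    risk(g) = f~(g) * cluster_score(cluster(g)).

The relative risk between two carriers i and j is the ratio
risk(i) / risk(j). Unclustered or unbounded genes carry *no* risk score
(absence of network support is not zero risk), signalled by
:class:`~voronet.exceptions.NoRiskDefinedError`.

Independently of the tessellation, a gene's disease-association weight
is the product of its two map coordinates S_G * S_V; the relative
disease association between two gene sets is the ratio of their summed
products. Internal arithmetic is unrounded throughout; alongside the
exact ratio, :func:`relative_disease_association` also reports the
ratio of the two-decimal-rounded sums (``ratio_as_reported``), the form
in which such ratios are commonly quoted, which can differ noticeably
from the exact value when the sums are small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .clustering import ClusterSet
from .exceptions import GeneNotFoundError, InputError, NoRiskDefinedError
from .score_map import GeneVariantMap
from .tessellation import Tessellation

__all__ = [
    "RiskScore", "AssociationScore", "risk_score", "relative_risk",
    "association_scores", "relative_disease_association",
]


@dataclass(frozen=True)
class RiskScore:
    """Per-gene risk: f~ times the score of the gene's cluster."""

    gene: str
    f_norm: float
    cluster_score: float
    cluster_label: int

    @property
    def risk(self) -> float:
        return self.f_norm * self.cluster_score


@dataclass(frozen=True)
class AssociationScore:
    """A gene's map coordinates; ``product`` = S_G * S_V in [0, 1]."""

    gene: str
    s_g: float
    s_v: float

    @property
    def product(self) -> float:
        return self.s_g * self.s_v


def risk_score(gene: str, clusters: ClusterSet, t: Tessellation) -> RiskScore:
    """Risk score of a clustered gene.

    Raises :class:`GeneNotFoundError` when the gene is not on the map
    and :class:`NoRiskDefinedError` when it is present but unclustered
    (including unbounded boundary cells).
    """
    try:
        idx = t.index_of(gene)
    except KeyError:
        raise GeneNotFoundError(gene) from None
    cell = t.cells[idx]
    cluster = clusters.cluster_of(idx)
    if cluster is None or not cell.bounded or cell.normalized_density is None:
        raise NoRiskDefinedError(
            f"gene {gene!r} is on the map but not in any cluster; "
            "no risk score is defined")
    return RiskScore(gene=gene, f_norm=float(cell.normalized_density),
                     cluster_score=float(cluster.score),
                     cluster_label=cluster.label)


def _risk_value(r: Union[RiskScore, float]) -> float:
    return r.risk if isinstance(r, RiskScore) else float(r)


def relative_risk(risk_i: Union[RiskScore, float],
                  risk_j: Union[RiskScore, float]) -> float:
    """Ratio of two risk scores, risk_i / risk_j, unrounded.

    Accepts :class:`RiskScore` objects or plain risk values; display
    conventionally rounds to two decimals.
    """
    ri, rj = _risk_value(risk_i), _risk_value(risk_j)
    if not rj > 0:
        raise InputError(f"reference risk must be positive, got {rj}")
    return ri / rj


def association_scores(gvmap: GeneVariantMap,
                       genes: Iterable[str]) -> list[AssociationScore]:
    """Look up S_G (x) and S_V (y) for the named genes on the map."""
    out = []
    for g in genes:
        try:
            p = gvmap[g]
        except KeyError:
            raise GeneNotFoundError(g) from None
        out.append(AssociationScore(gene=g, s_g=p.x, s_v=p.y))
    return out


def relative_disease_association(
        genes_i: Sequence[AssociationScore],
        genes_j: Sequence[AssociationScore]) -> dict:
    """Ratio of summed S_G * S_V products between two gene sets.

    Returns a dict with ``sum_i``, ``sum_j``, the exact ``ratio`` and
    ``ratio_as_reported`` (ratio of the sums rounded to two decimals;
    None when the rounded denominator is zero).
    """
    if not genes_i or not genes_j:
        raise InputError("both gene sets must be non-empty")
    sum_i = float(sum(a.product for a in genes_i))
    sum_j = float(sum(a.product for a in genes_j))
    if not sum_j > 0:
        raise InputError("denominator association sum is zero")
    rounded_i, rounded_j = round(sum_i, 2), round(sum_j, 2)
    reported = rounded_i / rounded_j if rounded_j > 0 else None
    return {
        "genes_i": [a.gene for a in genes_i],
        "genes_j": [a.gene for a in genes_j],
        "sum_i": sum_i,
        "sum_j": sum_j,
        "ratio": sum_i / sum_j,
        "ratio_as_reported": reported,
    }
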