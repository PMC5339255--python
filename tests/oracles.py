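"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (O(n^2)/O(n^3), plain loops, no
reuse of the package's geometry or graph code) so that agreement with
the package is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.spatial import cKDTree


def gabriel_pairs_brute(points: np.ndarray) -> set[tuple[int, int]]:
    """All site pairs whose open diametral disk contains no other site.

    The midpoint test over *all* pairs: (i, j) qualifies iff no third
    site is strictly closer to the midpoint than the endpoints are.
    """
    n = len(points)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            mid = 0.5 * (points[i] + points[j])
            r = np.linalg.norm(points[i] - mid)
            ok = True
            for k in range(n):
                if k in (i, j):
                    continue
                if np.linalg.norm(points[k] - mid) < r:
                    ok = False
                    break
            if ok:
                out.add((i, j))
    return out


def union_find_components(nodes: set[int],
                          edges: list[tuple[int, int]]) -> set[frozenset]:
    """Connected components by hand-rolled union-find."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        if a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    comps: dict[int, set[int]] = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    return {frozenset(c) for c in comps.values()}


def flood_fill_clusters(nodes: set[int], edges: list[tuple[int, int]],
                        rng: np.random.Generator) -> set[frozenset]:
    """Randomized flood fill: visit a random unvisited seed, grow through
    neighbors, repeat until exhausted."""
    adj: dict[int, set[int]] = {v: set() for v in nodes}
    for a, b in edges:
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    unvisited = set(nodes)
    clusters = set()
    while unvisited:
        seed = rng.choice(sorted(unvisited))
        frontier = [int(seed)]
        comp = set()
        while frontier:
            v = frontier.pop(int(rng.integers(len(frontier))))
            if v not in unvisited:
                continue
            unvisited.discard(v)
            comp.add(v)
            frontier.extend(w for w in adj[v] if w in unvisited)
        clusters.add(frozenset(comp))
    return clusters


def mc_cell_areas(points: np.ndarray, n_samples: int, seed: int,
                  box: tuple[float, float, float, float]) -> np.ndarray:
    """Monte-Carlo nearest-site area estimates inside ``box`` (x0,x1,y0,y1)."""
    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = box
    tree = cKDTree(points)
    counts = np.zeros(len(points), dtype=np.int64)
    chunk = 1_000_000
    left = n_samples
    while left > 0:
        m = min(chunk, left)
        samp = np.column_stack([rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)])
        _, nearest = tree.query(samp)
        counts += np.bincount(nearest, minlength=len(points))
        left -= m
    return counts / n_samples * (x1 - x0) * (y1 - y0)


def invert_cdf_quadrature(a: float, b: float, c: float,
                          significance: float) -> float:
    """Numeric inversion of the background CDF by quadrature + bisection.

    Integrates the model density (chi-square after the c*t**b change of
    variables) from 0 and bisects on the target probability; shares no
    code path with the package's quantile-function inversion.
    """
    from scipy.stats import chi2

    def pdf(t):
        u = c * t ** b
        return chi2.pdf(u, a) * c * b * t ** (b - 1)

    def cdf(t):
        val, _ = quad(pdf, 0.0, t, limit=200)
        return val

    hi = 1.0
    while cdf(hi) < significance:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("bracket expansion failed")
    lo = 0.0
    for _ in range(200):
        midpoint = 0.5 * (lo + hi)
        if cdf(midpoint) < significance:
            lo = midpoint
        else:
            hi = midpoint
        if hi - lo < 1e-12 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def blob_match_f1(clusters: list[frozenset], labels: np.ndarray) -> float:
    """Mean best-match F1 between planted blobs and detected clusters."""
    blob_ids = sorted(set(labels[labels > 0]))
    scores = []
    for blob in blob_ids:
        members = set(np.nonzero(labels == blob)[0])
        best = 0.0
        for cl in clusters:
            inter = len(members & set(cl))
            denom = len(cl) + len(members)
            if denom:
                best = max(best, 2.0 * inter / denom)
        scores.append(best)
    return float(np.mean(scores)) if scores else float("nan")
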