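"""Structural metrics of predation matrices and standardized property errors.

Eleven metrics are computed per web: proportions of basal, intermediate and
top species, proportion of herbivores, mean omnivory, clustering
coefficient, standard deviations of normalized generality and
vulnerability, diet similarity, mean path length, and nestedness (NODF,
0-100 scale). Metrics that are undefined on a given web (e.g. path length
on a web with no reachable pairs, omnivory without basal species) are
returned as ``None`` markers rather than numbers.

Definitions fixed here (different food web packages differ in detail):

* Species classification ignores self-links. Basal: no resources; top: at
  least one resource but no consumers; intermediate: both. The three
  proportions therefore always sum to 1.
* A herbivore is a consumer all of whose (non-self) resources are basal.
* Generality G_j / vulnerability V_i count all resources/consumers
  including self-links; sd is the sample standard deviation of the
  normalized values g = G / (L/S) and v = V / (L/S).
* Diet similarity is the mean Jaccard similarity of resource sets over
  unordered species pairs; two empty diets count as identical (1).
* Trophic level is shortest-path based: basal species are level 1, others
  are 1 + the shortest directed path to a basal species. Omnivory of a
  consumer is the population standard deviation of its resources' trophic
  levels; mean omnivory averages over consumers whose resource levels are
  all defined.
* Clustering is the mean local clustering coefficient of the undirected
  simple projection with self-loops dropped.
* Mean path length averages directed shortest-path lengths (edges point
  resource -> consumer) over ordered reachable pairs of distinct species.
* Nestedness is NODF over row pairs and column pairs of the binary matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .webio import PredationMatrix

__all__ = ["PropertySet", "PropertyErrorTable", "structural_properties", "standardized_errors", "nodf"]

PROPERTY_NAMES = (
    "prop_basal",
    "prop_intermediate",
    "prop_top",
    "prop_herbivores",
    "mean_omnivory",
    "clustering_coefficient",
    "sd_generality",
    "sd_vulnerability",
    "diet_similarity",
    "mean_path_length",
    "nestedness",
)


@dataclass(frozen=True)
class PropertySet:
    """Named structural metrics of one web; ``None`` marks an undefined value."""

    prop_basal: float
    prop_intermediate: float
    prop_top: float
    prop_herbivores: float
    mean_omnivory: float | None
    clustering_coefficient: float
    sd_generality: float
    sd_vulnerability: float
    diet_similarity: float
    mean_path_length: float | None
    nestedness: float

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def nodf(matrix: np.ndarray) -> float:
    """NODF nestedness of a binary matrix on the 0-100 scale.

    For every ordered pair within rows (and within columns) where the first
    member's marginal total strictly exceeds the second's, the pair
    contributes the percentage of the second's presences that overlap the
    first's; equal totals contribute zero. NODF is the mean contribution
    over all row pairs plus all column pairs.
    """
    m = np.asarray(matrix, dtype=bool)

    def _axis_sum(rows: np.ndarray) -> tuple[float, int]:
        n = rows.shape[0]
        total = 0.0
        fills = rows.sum(axis=1)
        for i, j in combinations(range(n), 2):
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            if fills[hi] > fills[lo] and fills[lo] > 0:
                total += 100.0 * np.sum(rows[hi] & rows[lo]) / fills[lo]
        return total, n * (n - 1) // 2

    row_sum, row_pairs = _axis_sum(m)
    col_sum, col_pairs = _axis_sum(m.T)
    pairs = row_pairs + col_pairs
    return (row_sum + col_sum) / pairs if pairs else 0.0


def _sd_normalized(counts: np.ndarray, L: int, S: int) -> float:
    if L == 0:
        return 0.0
    norm = counts / (L / S)
    return float(np.std(norm, ddof=1)) if S > 1 else 0.0


def structural_properties(web: PredationMatrix) -> PropertySet:
    links = web.links.astype(bool)
    S = web.size
    L = int(links.sum())
    offdiag = links.copy()
    np.fill_diagonal(offdiag, False)

    has_res = offdiag.any(axis=0)  # species with >= 1 non-self resource
    has_con = offdiag.any(axis=1)  # species with >= 1 non-self consumer
    basal = ~has_res
    top = has_res & ~has_con
    intermediate = has_res & has_con

    herb = np.array(
        [has_res[j] and bool(np.all(basal[offdiag[:, j]])) for j in range(S)]
    )

    # shortest-path trophic levels via multi-source BFS from the basal set
    dg = nx.from_numpy_array(offdiag.astype(int), create_using=nx.DiGraph)
    tl: dict[int, float] = {}
    if basal.any():
        dist = nx.multi_source_dijkstra_path_length(
            dg, set(np.nonzero(basal)[0].tolist()), weight=None
        )
        tl = {v: 1.0 + d for v, d in dist.items()}

    omnivory_vals = []
    if basal.any():
        for j in range(S):
            res = np.nonzero(offdiag[:, j])[0]
            if res.size and all(int(r) in tl for r in res):
                omnivory_vals.append(float(np.std([tl[int(r)] for r in res], ddof=0)))
    mean_omnivory = float(np.mean(omnivory_vals)) if omnivory_vals else None

    ug = nx.from_numpy_array(offdiag | offdiag.T, create_using=nx.Graph)
    clustering = float(nx.average_clustering(ug)) if S else 0.0

    sd_gen = _sd_normalized(links.sum(axis=0), L, S)
    sd_vul = _sd_normalized(links.sum(axis=1), L, S)

    resource_sets = [frozenset(np.nonzero(links[:, j])[0].tolist()) for j in range(S)]
    sims = []
    for u, v in combinations(range(S), 2):
        a, b = resource_sets[u], resource_sets[v]
        if not a and not b:
            sims.append(1.0)
        else:
            sims.append(len(a & b) / len(a | b))
    diet_similarity = float(np.mean(sims)) if sims else 1.0

    path_lengths = [
        d
        for src, dd in nx.all_pairs_shortest_path_length(dg)
        for dst, d in dd.items()
        if dst != src
    ]
    mean_path_length = float(np.mean(path_lengths)) if path_lengths else None

    return PropertySet(
        prop_basal=float(basal.mean()),
        prop_intermediate=float(intermediate.mean()),
        prop_top=float(top.mean()),
        prop_herbivores=float(herb.mean()),
        mean_omnivory=mean_omnivory,
        clustering_coefficient=clustering,
        sd_generality=sd_gen,
        sd_vulnerability=sd_vul,
        diet_similarity=diet_similarity,
        mean_path_length=mean_path_length,
        nestedness=float(nodf(web.links)),
    )


@dataclass(frozen=True)
class PropertyErrorTable:
    """Raw and standardized property errors for a stack of predicted webs.

    ``raw`` and ``standardized`` are (web x property) frames with NaN where
    either the observed or the predicted value was undefined; ``mean_per_web``
    averages the standardized errors over the defined properties of each web.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame
    mean_per_web: pd.Series


def standardized_errors(
    observed_props: PropertySet, predicted_props: list[PropertySet]
) -> PropertyErrorTable:
    """Normalize |observed - predicted| by the per-property maximum raw error.

    Properties undefined in the observed web, or undefined in a given
    predicted web, are excluded pairwise; a property whose raw errors are
    all zero gets standardized errors of zero rather than 0/0.
    """
    if not predicted_props:
        raise ValueError("need at least one predicted PropertySet")
    obs = observed_props.as_dict()
    raw = pd.DataFrame(
        [
            {
                name: (
                    abs(obs[name] - p.as_dict()[name])
                    if obs[name] is not None and p.as_dict()[name] is not None
                    else np.nan
                )
                for name in PROPERTY_NAMES
            }
            for p in predicted_props
        ]
    )
    max_err = raw.max(axis=0, skipna=True)
    std = raw.copy()
    for name in PROPERTY_NAMES:
        m = max_err[name]
        if pd.isna(m):
            continue
        std[name] = raw[name] / m if m > 0 else raw[name] * 0.0
    return PropertyErrorTable(
        raw=raw, standardized=std, mean_per_web=std.mean(axis=1, skipna=True)
    )
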