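"""Marker diversity statistics, genetic distances and tree building.

Band frequencies are computed per allele-locus over non-missing calls; a
marker's allele-frequency vector is its band-frequency vector normalized to
sum one (the dominant-scoring analogue of allele frequencies for an inbred
panel).  PIC uses the Botstein multiallelic form; gene diversity is Nei's
H = 1 - sum(p^2).  Genetic distance defaults to the mean character
difference on band profiles with pairwise deletion of missing calls; Dice
and Nei-Li coefficients are available as alternatives.  UPGMA (average
linkage, lexicographic tie-break) and Saitou-Nei neighbor joining are
implemented directly and emit scikit-bio trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import DataError, ParameterError
from .io import SSRPanel, split_locus_id


@dataclass
class FrequencyTable:
    band_freq: pd.Series  # per-locus band frequency over non-missing calls
    n_calls: pd.Series  # per-locus non-missing call count
    marker_freqs: dict[str, np.ndarray]  # per-marker normalized allele frequencies
    excluded_markers: list[str] = field(default_factory=list)

    def __post_init__(self):
        f = self.band_freq.dropna().to_numpy()
        if ((f < 0) | (f > 1)).any():
            raise DataError("band frequencies outside [0, 1]")
        for m, p in self.marker_freqs.items():
            if abs(p.sum() - 1.0) > 1e-9:
                raise DataError(f"marker {m}: allele frequencies do not sum to 1")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str = "mean_character_difference"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise DataError("distance matrix shape mismatch")
        if not np.allclose(m, m.T, atol=1e-9):
            raise DataError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal not zero")
        if (m < -1e-12).any():
            raise DataError("negative distances")
        self.matrix = m

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def mean_offdiagonal(self) -> float:
        n = len(self.ids)
        iu = np.triu_indices(n, 1)
        return float(self.matrix[iu].mean())


def allele_frequencies(panel: SSRPanel) -> FrequencyTable:
    """Per-locus band frequencies and per-marker normalized allele frequencies.

    Markers whose every call is missing (or whose bands never occur) cannot
    be normalized and are listed in ``excluded_markers``.
    """
    if panel.n_loci == 0 or panel.n_accessions == 0:
        raise DataError("empty panel")
    calls = panel.calls
    n_calls = np.sum(~np.isnan(calls), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(calls, axis=0) / np.where(n_calls > 0, n_calls, np.nan)
    band_freq = pd.Series(freq, index=panel.locus_ids)
    marker_freqs: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    loci_by_marker: dict[str, list[int]] = {}
    for j, l in enumerate(panel.locus_ids):
        loci_by_marker.setdefault(split_locus_id(l)[0], []).append(j)
    for marker, idx in loci_by_marker.items():
        p = freq[idx]
        if np.isnan(p).any() or p.sum() <= 0:
            excluded.append(marker)
            continue
        marker_freqs[marker] = p / p.sum()
    return FrequencyTable(
        band_freq=band_freq,
        n_calls=pd.Series(n_calls, index=panel.locus_ids),
        marker_freqs=marker_freqs,
        excluded_markers=excluded,
    )


def maf_filter(panel: SSRPanel, threshold: float = 0.05) -> SSRPanel:
    """Drop allele-loci with band frequency below ``threshold``.

    Idempotent; ``threshold = 0`` is the identity.
    """
    if not (0.0 <= threshold < 0.5):
        raise ParameterError("MAF threshold must lie in [0, 0.5)")
    freqs = allele_frequencies(panel).band_freq
    keep = [l for l in panel.locus_ids if not (freqs[l] < threshold) and not np.isnan(freqs[l])]
    return panel.select_loci(keep)


def pic(freqs: FrequencyTable) -> tuple[pd.Series, dict[str, float]]:
    """Botstein polymorphism information content per marker, plus mean/SD.

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.  A monomorphic marker
    scores 0.
    """
    vals = {}
    for m, p in freqs.marker_freqs.items():
        s2 = float(np.sum(p**2))
        cross = float((np.sum(p**2) ** 2 - np.sum(p**4)))  # sum_{i!=j} p_i^2 p_j^2
        vals[m] = 1.0 - s2 - cross if len(p) > 1 else 0.0
    series = pd.Series(vals)
    return series, {"mean": float(series.mean()), "sd": float(series.std(ddof=1))}


def gene_diversity(freqs: FrequencyTable) -> tuple[pd.Series, dict[str, float]]:
    """Nei's gene diversity H = 1 - sum(p^2) per marker, plus mean/SD."""
    vals = {m: (1.0 - float(np.sum(p**2)) if len(p) > 1 else 0.0) for m, p in freqs.marker_freqs.items()}
    series = pd.Series(vals)
    return series, {"mean": float(series.mean()), "sd": float(series.std(ddof=1))}


def allele_summary(panel: SSRPanel) -> pd.DataFrame:
    """Partition markers by allele (locus) count; columns n_markers, n_alleles."""
    counts: dict[int, int] = {}
    loci_by_marker: dict[str, int] = {}
    for l in panel.locus_ids:
        m = split_locus_id(l)[0]
        loci_by_marker[m] = loci_by_marker.get(m, 0) + 1
    for k in loci_by_marker.values():
        counts[k] = counts.get(k, 0) + 1
    rows = [
        {"allele_count": k, "n_markers": counts[k], "n_alleles": k * counts[k]}
        for k in sorted(counts)
    ]
    df = pd.DataFrame(rows, columns=["allele_count", "n_markers", "n_alleles"])
    df.attrs["total_markers"] = int(df["n_markers"].sum()) if len(df) else 0
    df.attrs["total_alleles"] = int(df["n_alleles"].sum()) if len(df) else 0
    return df


_METRICS = ("mean_character_difference", "dice", "nei_li")


def distance_matrix(panel: SSRPanel, metric: str = "mean_character_difference") -> DistanceMatrix:
    """Pairwise accession distances on band profiles with pairwise deletion.

    mean_character_difference: fraction of jointly scored loci whose band
    states differ.  dice / nei_li: 1 - 2a/(2a + b + c) on shared presences.
    """
    if panel.n_accessions < 2:
        raise DataError("need at least two accessions")
    if metric not in _METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {_METRICS}")
    X = panel.calls
    M = (~np.isnan(X)).astype(float)
    B = np.where(np.isnan(X), 0.0, X)
    shared = M @ M.T
    if (shared - np.diag(np.diag(shared)) == 0).any() and panel.n_accessions > 1:
        off = shared.copy()
        np.fill_diagonal(off, 1.0)
        if (off == 0).any():
            i, j = np.argwhere(off == 0)[0]
            raise DataError(
                f"accessions {panel.accession_ids[i]!r} and {panel.accession_ids[j]!r} "
                "share no scored loci; distance undefined"
            )
    mism = B @ (M - B).T + (M - B) @ B.T
    if metric == "mean_character_difference":
        with np.errstate(invalid="ignore", divide="ignore"):
            d = mism / shared
    else:  # dice == nei_li on binary data
        a = B @ B.T
        denom = 2 * a + mism
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, 1.0 - 2 * a / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(panel.accession_ids), d, metric)


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------


def _tip(name: str) -> skbio.TreeNode:
    return skbio.TreeNode(name=name)


def upgma(dist: DistanceMatrix) -> skbio.TreeNode:
    """Average-linkage (UPGMA) dendrogram; ultrametric by construction.

    Ties in the minimum pair are broken by the lexicographically smallest
    (representative-tip) pair of cluster labels.
    """
    n = len(dist.ids)
    if n < 2:
        raise DataError("need at least two taxa")
    D = {frozenset((i, j)): dist.matrix[i, j] for i in range(n) for j in range(i + 1, n)}
    nodes = {i: _tip(name) for i, name in enumerate(dist.ids)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    labels = {i: dist.ids[i] for i in range(n)}  # lexicographic representative
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for key, val in D.items():
            i, j = sorted(key)
            tie_key = tuple(sorted((labels[i], labels[j])))
            cand = (val, tie_key, i, j)
            if best is None or cand < best:
                best = cand
        _, _, i, j = best
        h = D[frozenset((i, j))] / 2.0
        parent = skbio.TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        for k in active - {i, j}:
            dik = D.pop(frozenset((i, k)))
            djk = D.pop(frozenset((j, k)))
            D[frozenset((next_id, k))] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        del D[frozenset((i, j))]
        nodes[next_id] = parent
        sizes[next_id] = sizes[i] + sizes[j]
        heights[next_id] = h
        labels[next_id] = min(labels[i], labels[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    root = nodes[active.pop()]
    root.method = "UPGMA"
    return root


def neighbor_joining(dist: DistanceMatrix) -> skbio.TreeNode:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  Returns an unrooted tree (trifurcating root).
    """
    n = len(dist.ids)
    if n < 2:
        raise DataError("need at least two taxa")
    if n == 2:
        d = dist.matrix[0, 1]
        a, b = _tip(dist.ids[0]), _tip(dist.ids[1])
        a.length = b.length = d / 2.0
        root = skbio.TreeNode(children=[a, b])
        root.method = "NJ"
        return root
    ids = list(range(n))
    D = dist.matrix.astype(float).copy()
    nodes = {i: _tip(name) for i, name in enumerate(dist.ids)}
    labels = {i: dist.ids[i] for i in range(n)}
    next_id = n
    index_of = {i: i for i in ids}  # node id -> row in D

    while len(ids) > 3:
        m = len(ids)
        r = D.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * D[a, b] - r[a] - r[b]
                ia, ib = ids[a], ids[b]
                tie_key = tuple(sorted((labels[ia], labels[ib])))
                cand = (q, tie_key, a, b)
                if best is None or cand < best:
                    best = cand
        _, _, a, b = best
        ia, ib = ids[a], ids[b]
        dab = D[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = la + lb, 0.0
        parent = skbio.TreeNode(children=[nodes[ia], nodes[ib]])
        nodes[ia].length = la
        nodes[ib].length = lb
        new_row = 0.5 * (D[a, :] + D[b, :] - dab)
        keep = [x for x in range(m) if x not in (a, b)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes[next_id] = parent
        labels[next_id] = min(labels[ia], labels[ib])
        ids = [ids[x] for x in keep] + [next_id]
        next_id += 1

    # connect the last three nodes to a central (unrooted) vertex
    i, j, k = ids
    li = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lj = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lk = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    lengths = [max(x, 0.0) for x in (li, lj, lk)]
    for node, ln in zip((i, j, k), lengths):
        nodes[node].length = ln
    root = skbio.TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    root.method = "NJ"
    return root


def tree_tip_heights(tree: skbio.TreeNode) -> dict[str, float]:
    return {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}


def is_ultrametric(tree: skbio.TreeNode, tol: float = 1e-9) -> bool:
    h = list(tree_tip_heights(tree).values())
    return (max(h) - min(h)) <= tol


def cluster_report(tree: skbio.TreeNode, dist: DistanceMatrix, gd_thresholds=(0.5, 0.4, 0.2)) -> list[dict]:
    """Cut an ultrametric dendrogram at genetic-distance thresholds.

    Two accessions fall in one group when their cophenetic distance (twice
    the merge height) is at or below the threshold.  Reports member lists
    and within/between-group mean distance per threshold.
    """
    ids = dist.ids
    pos = {a: i for i, a in enumerate(ids)}
    out = []
    # node height = distance from node down to any tip (ultrametric)
    for thr in gd_thresholds:
        groups: list[list[str]] = []

        def collect(node, budget):
            """Split while the subtree's cophenetic span exceeds the threshold."""
            tips = [t.name for t in node.tips()] or ([node.name] if node.name else [])
            if len(tips) <= 1:
                groups.append(tips)
                return
            height = max(t.accumulate_to_ancestor(node) for t in node.tips())
            if 2.0 * height <= budget:
                groups.append(tips)
            else:
                for child in node.children:
                    collect(child, budget)

        collect(tree, thr)
        groups = [g for g in groups if g]
        within, between = [], []
        for gi, g in enumerate(groups):
            for x in range(len(g)):
                for y in range(x + 1, len(g)):
                    within.append(dist.matrix[pos[g[x]], pos[g[y]]])
            for g2 in groups[gi + 1:]:
                for a in g:
                    for b in g2:
                        between.append(dist.matrix[pos[a], pos[b]])
        out.append(
            {
                "threshold": thr,
                "groups": {f"G{i + 1}": sorted(g) for i, g in enumerate(groups)},
                "n_groups": len(groups),
                "within_mean_gd": float(np.mean(within)) if within else float("nan"),
                "between_mean_gd": float(np.mean(between)) if between else float("nan"),
            }
        )
    return out
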