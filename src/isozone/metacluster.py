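"""Harmonize per-plot zones across plots.

The zone medians of N concentration, d15N and d13C (one row per plot.zone)
are clustered by UPGMA (average linkage) on Euclidean distances — the
tracers share a comparable numeric scale, so no standardization is applied
— and the dendrogram is cut at the k with the highest mean silhouette
width. Final clusters are relabelled by ascending median N concentration,
which lets the high-N, isotopically enriched invader-influence cluster be
read off directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """UPGMA merge tree. ``merges[m] = (id_a, id_b, height)`` where leaf ids
    are 0..n-1 and internal node ids continue from n in merge order."""

    merges: list[tuple[int, int, float]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> np.ndarray:
        """Cluster membership (0-based, arbitrary ids) of each leaf after
        keeping the last k-1 merges undone."""
        n = self.n_leaves
        if not (1 <= k <= n):
            raise ValueError(f"k={k} outside 1..{n}")
        parent = list(range(n + len(self.merges)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for m, (a, b, _) in enumerate(self.merges[: n - k]):
            node = n + m
            parent[find(a)] = node
            parent[find(b)] = node
        roots = {}
        out = np.empty(n, dtype=int)
        for leaf in range(n):
            r = find(leaf)
            out[leaf] = roots.setdefault(r, len(roots))
        return out

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge heights between leaves."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        C = np.zeros((n, n))
        for m, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    C[i, j] = C[j, i] = h
            members[n + m] = members.pop(a) + members.pop(b)
        return C

    def to_newick(self) -> str:
        """Newick string with branch lengths as merge-height differences
        (an ultrametric tree: leaf-to-root path length = root height / 2)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for m, (a, b, h) in enumerate(self.merges):
            node = n + m
            la = (h - height[a]) / 2.0
            lb = (h - height[b]) / 2.0
            text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            height[node] = h
        return text[n + len(self.merges) - 1] + ";"


def upgma(D: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Inter-cluster distance is the arithmetic mean over all cross pairs, so
    merge heights are nondecreasing. Ties between candidate merges go to
    the lexicographically smallest (label_a, label_b) pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("D must be symmetric with zero diagonal")
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    active: dict[int, dict] = {
        i: {"size": 1, "label": labels[i]} for i in range(n)
    }
    dist = {}
    ids = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]

    def get(a, b):
        return dist[(a, b) if a < b else (b, a)]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    last_h = -np.inf
    while len(active) > 1:
        # closest pair; ties by lexicographically smallest sorted label pair
        best = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                d = get(i, j)
                key = tuple(sorted((active[i]["label"], active[j]["label"])))
                if best is None or d < best[0] - 1e-300 or (d == best[0] and key < best[1]):
                    best = (d, key, i, j)
        d, _, a, b = best
        assert d >= last_h - 1e-9, "UPGMA inversion (should be impossible)"
        last_h = max(last_h, d)
        sa, sb = active[a]["size"], active[b]["size"]
        new_label = min(active[a]["label"], active[b]["label"])
        for other in active:
            if other in (a, b):
                continue
            dn = (sa * get(a, other) + sb * get(b, other)) / (sa + sb)
            dist[(min(other, next_id), max(other, next_id))] = dn
        merges.append((a, b, d))
        del active[a], active[b]
        active[next_id] = {"size": sa + sb, "label": new_label}
        next_id += 1
    return Dendrogram(merges=merges, labels=list(labels))


def silhouette_width(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width over items given a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    i's own cluster (excluding i) and b(i) the smallest mean distance to
    another cluster; members of singleton clusters get s(i) = 0.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mask_own = (labels == own)
        size_own = mask_own.sum()
        if size_own == 1:
            s[i] = 0.0
            continue
        a = D[i, mask_own].sum() / (size_own - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != own)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


@dataclass
class Harmonization:
    """Cross-plot zone mapping with its silhouette profile."""

    k: int
    mapping: pd.DataFrame          # columns: plot, zone, label, final
    silhouettes: dict[int, float]  # candidate k -> mean silhouette
    dendrogram: Dendrogram
    median_table: pd.DataFrame


def harmonize(tables: dict, k_range=None) -> Harmonization:
    """UPGMA-harmonize zones across plots.

    Parameters
    ----------
    tables : dict mapping plot id -> zone-summary DataFrame with columns
        ``zone``, ``median_n_conc``, ``median_d15N``, ``median_d13C``.
    k_range : iterable of candidate cluster counts, default 2..n-1.

    The pooled (plot, zone) median rows are clustered on unscaled Euclidean
    distances; the cut with the highest mean silhouette wins; final cluster
    ids are 1..k ordered by ascending median N concentration. The result is
    invariant to plot input order and per-plot zone label permutations
    (rows are canonically sorted and ties broken lexicographically).
    """
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
             "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]
    rows = []
    for plot_id in sorted(tables, key=str):
        t = tables[plot_id]
        for _, r in t.sort_values("zone").iterrows():
            z = int(r["zone"])
            rows.append({
                "plot": plot_id, "zone": z,
                "label": f"{plot_id}.{roman[z - 1]}",
                "median_n_conc": float(r["median_n_conc"]),
                "median_d15N": float(r["median_d15N"]),
                "median_d13C": float(r["median_d13C"]),
            })
    tab = pd.DataFrame(rows)
    n = len(tab)
    if n < 3:
        raise ValueError(f"harmonization needs >= 3 pooled zones, got {n}")
    if tab["label"].duplicated().any():
        raise ValueError("duplicate plot.zone labels")
    M = tab[["median_n_conc", "median_d15N", "median_d13C"]].to_numpy()
    D = squareform(pdist(M))
    dend = upgma(D, list(tab["label"]))
    ks = list(k_range) if k_range is not None else list(range(2, n))
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("empty harmonization k_range")
    sils = {}
    cuts = {}
    for k in ks:
        labels_k = dend.cut(k)
        cuts[k] = labels_k
        sils[k] = silhouette_width(D, labels_k)
    k_best = max(ks, key=lambda k: (sils[k], -k))
    raw = cuts[k_best]
    # relabel final clusters by ascending median N concentration
    med_n = {c: float(np.median(M[raw == c, 0])) for c in np.unique(raw)}
    order = sorted(med_n, key=lambda c: (med_n[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    tab = tab.copy()
    tab["final"] = [remap[c] for c in raw]
    return Harmonization(
        k=k_best,
        mapping=tab[["plot", "zone", "label", "final"]],
        silhouettes=sils,
        dendrogram=dend,
        median_table=tab,
    )
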