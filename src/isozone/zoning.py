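"""Partition stacked tracer isoscapes into homogeneous zones.

The three kriged tracer surfaces (N concentration, d15N, d13C) of one plot
are stacked cell-wise into an n x 3 matrix, clustered with the constrained
Gaussian-mixture family, and the chosen partition is relabelled so zone 1
has the lowest median N concentration. Between-zone differences are tested
with a Kruskal-Wallis rank sum test and a mean-rank post-hoc comparison
with Bonferroni-type correction, summarised as compact letters.

Raster cells are treated as observations in these tests, which replicates
the pseudo-replicated inference of typical isoscape studies; spatial
autocorrelation inflates the effective significance and the results should
be read as descriptive, not confirmatory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import Raster, TRACERS
from .geostat import Isoscape
from .mixture import BICSurface, MixtureFit, classify, fit_family, select_model_plateau

log = logging.getLogger(__name__)


@dataclass
class IsoscapeStack:
    """Aligned tracer rasters as a row-per-cell matrix.

    ``rows`` holds only cells with all three layers present; ``cell_index``
    maps each row to its flat cell index on the grid.
    """

    grid: object
    rows: np.ndarray          # (n, 3) in layer order n_conc, d15N, d13C
    cell_index: np.ndarray    # (n,) flat indices into grid
    units: tuple[str, str, str]
    n_excluded: int = 0


def stack_isoscapes(iso_n: Isoscape, iso_15n: Isoscape, iso_13c: Isoscape) -> IsoscapeStack:
    """Stack the three tracer isoscapes; cells missing any layer are excluded."""
    g = iso_n.prediction.grid
    for iso in (iso_15n, iso_13c):
        if iso.prediction.grid.fingerprint() != g.fingerprint():
            raise ValueError(
                f"grid mismatch: {g.fingerprint()} vs {iso.prediction.grid.fingerprint()}"
            )
    layers = [iso_n.prediction.values.ravel(),
              iso_15n.prediction.values.ravel(),
              iso_13c.prediction.values.ravel()]
    M = np.column_stack(layers)
    good = ~np.isnan(M).any(axis=1)
    if (~good).any():
        log.info("stack_isoscapes: excluding %d cell(s) with missing layers", (~good).sum())
    return IsoscapeStack(
        grid=g,
        rows=M[good],
        cell_index=np.flatnonzero(good),
        units=(iso_n.units, iso_15n.units, iso_13c.units),
        n_excluded=int((~good).sum()),
    )


@dataclass
class ZoneMap:
    """Integer zone labels on the grid (0 = excluded cell), ordered so that
    median N concentration increases with the zone number."""

    labels: Raster
    fit: MixtureFit
    surface: BICSurface
    code: str
    k: int
    tau: float
    zone_sizes: dict[int, int]

    def zone_of_rows(self, stack: IsoscapeStack) -> np.ndarray:
        """Zone label (1..k) per stack row."""
        flat = self.labels.values.ravel()
        return flat[stack.cell_index].astype(int)


def cluster_plot(
    stack: IsoscapeStack,
    codes=None,
    k_range=range(1, 21),
    tau: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    standardize: bool = False,
) -> ZoneMap:
    """Cluster one plot's stacked isoscapes into zones.

    Variables enter unstandardized by default (all tracers are judged on a
    common, comparable scale downstream). The mixture family is fitted over
    ``codes`` x ``k_range``, the (code, k) is chosen by the BIC-plateau
    rule, and MAP labels are relabelled by ascending median N concentration.
    """
    from .mixture import CODES

    if codes is None:
        codes = CODES
    X = stack.rows
    if X.shape[0] < 10:
        raise ValueError("need at least 10 cells to cluster")
    if standardize:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    surface = fit_family(X, k_range=k_range, codes=codes, tol=tol,
                         max_iter=max_iter, seed=seed)
    code, k = select_model_plateau(surface, tau=tau)
    fit = surface.fits[(code, k)]
    raw = classify(fit)  # 0-based component ids
    # order zones by ascending median N concentration (layer 0)
    present = np.unique(raw)
    medians = {c: np.median(stack.rows[raw == c, 0]) for c in present}
    order = sorted(present, key=lambda c: (medians[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    zones = np.array([remap[c] for c in raw])
    flat = np.zeros(stack.grid.shape[0] * stack.grid.shape[1])
    flat[stack.cell_index] = zones
    labels = Raster(stack.grid, flat.reshape(stack.grid.shape), units="zone")
    sizes = {z: int((zones == z).sum()) for z in sorted(set(zones))}
    return ZoneMap(labels=labels, fit=fit, surface=surface, code=code,
                   k=len(present), tau=tau, zone_sizes=sizes)


def zone_summaries(
    zonemap: ZoneMap,
    stack: IsoscapeStack,
    distance: Raster | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-zone medians of the tracers (and canopy distance when available)
    plus compact post-hoc letters per variable.

    Distance medians are missing for uninvaded plots (no distance raster).
    """
    zones = zonemap.zone_of_rows(stack)
    zone_ids = sorted(set(zones))
    rec: dict[str, list] = {"zone": zone_ids}
    for li, name in enumerate(TRACERS):
        rec[f"median_{name}"] = [float(np.median(stack.rows[zones == z, li]))
                                 for z in zone_ids]
    if distance is not None:
        dvals = distance.values.ravel()[stack.cell_index]
        rec["median_dist"] = [float(np.nanmedian(dvals[zones == z])) for z in zone_ids]
    else:
        rec["median_dist"] = [np.nan] * len(zone_ids)
    rec["n_cells"] = [int((zones == z).sum()) for z in zone_ids]
    out = pd.DataFrame(rec)
    if len(zone_ids) > 1:
        for li, name in enumerate(TRACERS):
            letters = posthoc_mean_ranks(stack.rows[:, li], zones, alpha=alpha)[1]
            out[f"letters_{name}"] = [letters[z] for z in zone_ids]
    return out


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def kruskal_wallis(values: np.ndarray, labels: np.ndarray) -> tuple[float, int, float]:
    """Kruskal-Wallis rank sum test with midrank tie correction.

    Returns (H, df, p) with p from the chi-square approximation. All-equal
    values give H = 0, p = 1 (the tie-correction denominator would vanish).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = len(values)
    if np.ptp(values) == 0:
        log.warning("kruskal_wallis: all values identical; H = 0")
        return 0.0, len(groups) - 1, 1.0
    ranks = stats.rankdata(values)
    H = 0.0
    for g in groups:
        rg = ranks[labels == g]
        H += rg.sum() ** 2 / len(rg)
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    ties = np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n**3 - n)
    H /= denom
    df = len(groups) - 1
    p = float(stats.chi2.sf(H, df))
    return float(H), df, p


def posthoc_mean_ranks(
    values: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Pairwise mean-rank comparisons after Kruskal-Wallis, with compact letters.

    Pair (i, j) differs significantly iff

        |Rbar_i - Rbar_j| > z_{1 - alpha/(k(k-1))} * sqrt(n(n+1)/12 * (1/n_i + 1/n_j))

    (Bonferroni-type correction over the k(k-1)/2 two-sided comparisons).
    Letters are assigned greedily on zones sorted by mean rank so that zones
    sharing a letter are not significantly different.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(np.unique(labels))
    k = len(groups)
    if k < 2:
        raise ValueError("post-hoc comparison needs at least 2 groups")
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    zcrit = stats.norm.ppf(1.0 - alpha / (k * (k - 1)))
    rows = []
    sig = {}
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            ga, gb = groups[a_i], groups[b_i]
            diff = abs(mean_rank[ga] - mean_rank[gb])
            crit = zcrit * np.sqrt(n * (n + 1) / 12.0 * (1 / sizes[ga] + 1 / sizes[gb]))
            s = diff > crit
            sig[(ga, gb)] = sig[(gb, ga)] = s
            rows.append({"group_a": ga, "group_b": gb, "obs_diff": diff,
                         "critical_diff": crit, "significant": s})
    table = pd.DataFrame(rows)
    letters = _compact_letters(sorted(groups, key=lambda g: mean_rank[g]), sig)
    return table, letters


def _compact_letters(ordered_groups: list, sig: dict) -> dict:
    """Greedy insert-first-fit compact letter display."""
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letter_groups: list[list] = []
    for g in ordered_groups:
        placed = False
        for lg in letter_groups:
            if all(not sig[(g, other)] for other in lg):
                lg.append(g)
                placed = True
        if not placed:
            letter_groups.append([g])
    out = {g: "" for g in ordered_groups}
    for li, lg in enumerate(letter_groups):
        for g in lg:
            out[g] += alphabet[li % len(alphabet)]
    return out
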