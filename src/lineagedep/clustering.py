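"""Greedy correlation clustering of binary open-chromatin profiles.

Samples (cell types / tissues) are described by binary open(1)/closed(0)
calls over candidate cis-regulatory regions. After restricting to the
most variable regions, samples are clustered greedily on the pairwise
Pearson correlation matrix: repeatedly seed a cluster with the sample that
correlates (PCC above threshold) with the most remaining samples, absorb
every remaining sample correlated with that seed, and stop when a seeded
cluster falls below the minimum size. Cluster-specific regions are those
open in most (80%) of a cluster's samples and present, by the same rule,
in at most two other clusters; their association with differential-
accessibility regions is tested by strict summit-window containment and a
one-tailed hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ConsensusPeak


@dataclass
class ProfileMatrix:
    """Binary regions x samples accessibility matrix."""

    regions: pd.DataFrame            # columns chrom, start, end
    samples: list[str]
    values: np.ndarray               # uint8, shape (n_regions, n_samples)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("profile values must be binary 0/1")
        dup = self.regions.duplicated(subset=["chrom", "start", "end"])
        if dup.any():
            raise ValueError("duplicate region coordinates in profile matrix")


@dataclass
class ClusterResult:
    clusters: dict[str, list[str]]           # ordered: cluster_1, cluster_2, ...
    unassigned: list[str]
    seed_sample: dict[str, str] = field(default_factory=dict)


def select_variable_regions(matrix: ProfileMatrix, top_k: int) -> np.ndarray:
    """Indices of the ``top_k`` regions most variable across samples.

    For a binary row the across-sample variance is p(1-p) up to scaling,
    maximal at half-open rows. Ties are broken by region coordinate so the
    ranking is total.
    """
    if top_k > len(matrix.regions):
        raise ValueError(f"top_k={top_k} exceeds {len(matrix.regions)} regions")
    p = matrix.values.mean(axis=1)
    var = p * (1.0 - p)
    order = pd.DataFrame({
        "var": -var,
        "chrom": matrix.regions["chrom"].to_numpy(),
        "start": matrix.regions["start"].to_numpy(),
        "end": matrix.regions["end"].to_numpy(),
    }).sort_values(["var", "chrom", "start", "end"], kind="mergesort").index.to_numpy()
    return order[:top_k]


def sample_correlation(matrix: ProfileMatrix, region_subset=None):
    """Pairwise Pearson correlation between sample columns.

    Returns ``(pcc, constant)``: the symmetric correlation DataFrame
    (diagonal 1) and a boolean Series flagging constant columns, whose
    correlations are recorded as 0.
    """
    vals = matrix.values if region_subset is None else matrix.values[np.asarray(region_subset)]
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 regions to correlate samples")
    X = vals.astype(float)
    constant = X.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.corrcoef(X, rowvar=False)
    pcc = np.where(np.isnan(pcc), 0.0, pcc)
    np.fill_diagonal(pcc, 1.0)
    return (
        pd.DataFrame(pcc, index=matrix.samples, columns=matrix.samples),
        pd.Series(constant, index=matrix.samples),
    )


def greedy_cluster(pcc: pd.DataFrame, pcc_threshold: float = 0.6,
                   min_cluster_size: int = 5) -> ClusterResult:
    """Iterative seed-and-absorb clustering on the correlation matrix.

    Each round ranks the remaining samples by how many remaining partners
    they correlate with above the threshold (ties by sample id), seeds a
    cluster with the top sample plus everything correlated with *the
    seed*, and stops — without emitting — as soon as a seeded cluster is
    smaller than ``min_cluster_size``. Deterministic and invariant to the
    order samples appear in the matrix.
    """
    if list(pcc.index) != list(pcc.columns):
        raise ValueError("pcc must be square with matching index and columns")
    remaining = sorted(pcc.index)
    clusters: dict[str, list[str]] = {}
    seeds: dict[str, str] = {}
    k = 0
    while remaining:
        sub = pcc.loc[remaining, remaining]
        partners = (sub.to_numpy() > pcc_threshold).sum(axis=1) - 1  # exclude self
        # top rank = most partners, ties by lexicographic sample id
        seed = min(zip(-partners, remaining))[1]
        members = [s for s in remaining
                   if s == seed or pcc.loc[seed, s] > pcc_threshold]
        if len(members) < min_cluster_size:
            break
        k += 1
        cid = f"cluster_{k}"
        clusters[cid] = members
        seeds[cid] = seed
        remaining = [s for s in remaining if s not in set(members)]
    return ClusterResult(clusters=clusters, unassigned=remaining, seed_sample=seeds)


def cluster_specific_regions(
    matrix: ProfileMatrix,
    clusters: dict[str, list[str]],
    presence_fraction: float = 0.8,
    max_additional_clusters: int = 2,
) -> dict[str, np.ndarray]:
    """Region indices specific to each cluster.

    A region is *present in* a cluster when open in at least
    ``presence_fraction`` of its samples (the same rule for the home and
    the other clusters), and *specific to* a cluster when present there
    and in at most ``max_additional_clusters`` others.
    """
    sample_pos = {s: i for i, s in enumerate(matrix.samples)}
    ids = list(clusters)
    presence = np.zeros((len(matrix.regions), len(ids)), dtype=bool)
    for j, cid in enumerate(ids):
        cols = [sample_pos[s] for s in clusters[cid]]
        frac = matrix.values[:, cols].mean(axis=1)
        presence[:, j] = frac >= presence_fraction
    n_present = presence.sum(axis=1)
    out = {}
    for j, cid in enumerate(ids):
        specific = presence[:, j] & (n_present - 1 <= max_additional_clusters)
        out[cid] = np.where(specific)[0]
    return out


def _containment_lookup(regions: pd.DataFrame):
    """Per-chrom arrays for 'is [s, e) fully inside some region' queries."""
    lookup = {}
    for chrom, grp in regions.groupby("chrom"):
        srt = grp.sort_values("start")
        starts = srt["start"].to_numpy()
        ends = np.maximum.accumulate(srt["end"].to_numpy())
        lookup[chrom] = (starts, ends)
    return lookup


def _window_contained(lookup, chrom: str, start: int, end: int) -> bool:
    if chrom not in lookup:
        return False
    starts, ends = lookup[chrom]
    i = np.searchsorted(starts, start, side="right")
    return i > 0 and ends[i - 1] >= end


def overlap_enrichment(
    cluster_regions: dict[str, pd.DataFrame],
    da_peaks: list[ConsensusPeak] | pd.DataFrame,
    all_consensus: list[ConsensusPeak],
    summit_flank: int = 25,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of DA summit windows in cluster region sets.

    A peak *hits* a cluster set when its [summit - flank, summit + flank + 1)
    window is 100% contained in one of the cluster's regions. The test for
    each cluster draws |DA| peaks from the consensus universe with the
    consensus hit count as successes; the upper tail gives the p-value.
    Rows are ordered by increasing p.
    """
    def peak_tuples(peaks):
        if isinstance(peaks, pd.DataFrame):
            return list(zip(peaks["chrom"], peaks["summit"]))
        return [(p.chrom, p.summit) for p in peaks]

    def windows(peaks):
        out, n_oob = [], 0
        for chrom, summit in peak_tuples(peaks):
            s, e = summit - summit_flank, summit + summit_flank + 1
            if s < 0 or (chrom_sizes and e > chrom_sizes.get(chrom, np.inf)):
                n_oob += 1
                continue
            out.append((chrom, s, e))
        return out, n_oob

    cons_windows, n_excluded = windows(all_consensus)
    da_windows, n_excluded_da = windows(da_peaks)
    M = len(cons_windows)
    n_draws = len(da_windows)

    rows = []
    for cid, regions in cluster_regions.items():
        lookup = _containment_lookup(regions)
        K = sum(_window_contained(lookup, *wdw) for wdw in cons_windows)
        k = sum(_window_contained(lookup, *wdw) for wdw in da_windows)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_draws)) if n_draws else 1.0
        rows.append({"cluster": cid, "n_da_hits": k, "n_consensus_hits": K,
                     "n_da": n_draws, "n_consensus": M,
                     "n_excluded": n_excluded + n_excluded_da, "p_value": p})
    return (pd.DataFrame(rows)
            .sort_values("p_value", kind="mergesort")
            .reset_index(drop=True))
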