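"""Consensus peak construction, read counting and differential-accessibility calls.

The consensus list re-centres every called peak on its summit at a fixed
width (501 bp), ranks the candidates by -log10(q) and greedily keeps each
candidate that overlaps no already-kept interval, yielding the most
significant non-overlapping representative of every locus. Read counting
extends each read to the modal fragment length (250 bp) from its 5' end in
strand direction. Differential-accessibility (DA) calls simply threshold
an externally computed fold-change/padj table: |FC| >= 2 and padj < 0.001,
split into lower- (LA) and higher-accessibility (HA) regions.
"""

from __future__ import annotations

import bisect
import logging

import numpy as np
import pandas as pd

from .intervals import ConsensusPeak, GenomicInterval, Peak

logger = logging.getLogger(__name__)


def filter_peaks_by_q(peaks: list[Peak], threshold: float,
                      keep_significant: bool = True) -> list[Peak]:
    """Significance filter on -log10(q).

    The default keeps peaks with ``neg_log10_q >= threshold`` (boundary
    inclusive). ``keep_significant=False`` selects the complementary,
    literal "< threshold" set instead.
    """
    if keep_significant:
        return [p for p in peaks if p.neg_log10_q >= threshold]
    return [p for p in peaks if p.neg_log10_q < threshold]


def build_consensus(peaks: list[Peak], consensus_width: int = 501,
                    boundary: str = "drop") -> list[ConsensusPeak]:
    """Significance-ranked greedy selection of summit-centered windows.

    Each peak proposes the window [summit - w, summit + w + 1) with
    w = (consensus_width - 1) / 2. Candidates are ranked by -log10(q)
    descending (ties broken by (chrom, summit) ascending, making the
    result independent of input order) and kept iff they overlap no
    previously kept window. Output is coordinate-sorted.

    ``boundary`` controls windows that would start before base 0:
    ``"drop"`` discards them (default), ``"clip"`` anchors them at 0 with
    the full width preserved to the right.
    """
    if consensus_width % 2 != 1:
        raise ValueError("consensus_width must be odd so the summit is centered")
    if boundary not in ("drop", "clip"):
        raise ValueError(f"boundary must be 'drop' or 'clip', got {boundary!r}")
    w = (consensus_width - 1) // 2

    candidates = []
    n_dropped = 0
    for p in peaks:
        start = p.summit - w
        if start < 0:
            if boundary == "drop":
                n_dropped += 1
                continue
            start = 0
        candidates.append((p, start, start + consensus_width))
    if n_dropped:
        logger.warning("dropped %d peaks whose consensus window would start before 0",
                       n_dropped)

    candidates.sort(key=lambda c: (-c[0].neg_log10_q, c[0].chrom, c[0].summit))

    kept: list[ConsensusPeak] = []
    # per-chromosome sorted start positions of kept (non-overlapping) windows
    kept_starts: dict[str, list[int]] = {}
    kept_ends: dict[str, list[int]] = {}
    for p, start, end in candidates:
        starts = kept_starts.setdefault(p.chrom, [])
        ends = kept_ends.setdefault(p.chrom, [])
        i = bisect.bisect_right(starts, start)
        # kept windows are disjoint, so only the neighbours can overlap
        if i > 0 and ends[i - 1] > start:
            continue
        if i < len(starts) and starts[i] < end:
            continue
        starts.insert(i, start)
        ends.insert(i, end)
        kept.append(ConsensusPeak(
            interval=GenomicInterval(p.chrom, start, end),
            summit=p.summit, source_peak=p.name, neg_log10_q=p.neg_log10_q,
        ))
    kept.sort(key=lambda c: (c.chrom, c.interval.start))
    return kept


def count_reads(reads: pd.DataFrame, consensus: list[ConsensusPeak],
                read_extension: int = 250) -> np.ndarray:
    """Count strand-extended reads overlapping each consensus peak.

    Each read is extended from its 5' end to ``read_extension`` bases in
    strand direction ('+': [start, start+L), '-': [end-L, end), clipped at
    0); a read increments every (non-overlapping) peak its extension
    touches. Unstranded reads are treated as '+' with a warning.
    Returns counts aligned with ``consensus`` order.
    """
    counts = np.zeros(len(consensus), dtype=np.int64)
    if reads.empty or not consensus:
        return counts
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, cp in enumerate(consensus):
        by_chrom.setdefault(cp.chrom, []).append((cp.interval.start, cp.interval.end, idx))
    chrom_arrays = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples])
        ends = np.array([t[1] for t in triples])
        idxs = np.array([t[2] for t in triples])
        chrom_arrays[chrom] = (starts, ends, idxs)

    n_unstranded = int((reads["strand"] == ".").sum())
    if n_unstranded:
        logger.warning("%d unstranded reads treated as '+'", n_unstranded)

    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in chrom_arrays:
            continue
        starts, ends, idxs = chrom_arrays[chrom]
        rs = grp["start"].to_numpy()
        re_ = grp["end"].to_numpy()
        minus = (grp["strand"] == "-").to_numpy()
        ext_start = np.where(minus, np.maximum(re_ - read_extension, 0), rs)
        ext_end = np.where(minus, re_, rs + read_extension)
        # peaks overlapping [s, e): those with end > s and start < e
        lo = np.searchsorted(ends, ext_start, side="right")
        hi = np.searchsorted(starts, ext_end, side="left")
        delta = np.zeros(len(starts) + 1, dtype=np.int64)
        np.add.at(delta, lo, 1)
        np.add.at(delta, hi, -1)
        per_peak = np.cumsum(delta[:-1])
        counts[idxs] += per_peak
    return counts


def call_da(consensus: list[ConsensusPeak], differential_table: pd.DataFrame,
            da_fc: float = 2.0, da_padj: float = 0.001) -> pd.DataFrame:
    """Threshold a differential table into LA/HA regions.

    ``differential_table`` must carry columns ``name`` (matching each
    consensus peak's ``source_peak``), ``log2fc`` and ``padj``. A peak is
    HA iff log2fc >= log2(da_fc), LA iff log2fc <= -log2(da_fc), in either
    case requiring padj < da_padj; all other peaks are excluded. Consensus
    peaks missing from the table are excluded with a reported count.
    """
    if da_fc <= 1:
        raise ValueError("da_fc must exceed 1")
    lfc_cut = np.log2(da_fc)
    table = differential_table.set_index("name")
    rows = []
    n_missing = 0
    for cp in consensus:
        if cp.source_peak not in table.index:
            n_missing += 1
            continue
        rec = table.loc[cp.source_peak]
        lfc, padj = float(rec["log2fc"]), float(rec["padj"])
        if not padj < da_padj:
            continue
        if lfc >= lfc_cut:
            cls = "HA"
        elif lfc <= -lfc_cut:
            cls = "LA"
        else:
            continue
        rows.append({
            "chrom": cp.chrom, "start": cp.interval.start, "end": cp.interval.end,
            "name": cp.source_peak, "summit": cp.summit,
            "log2fc": lfc, "padj": padj, "da_class": cls,
        })
    if n_missing:
        logger.warning("%d consensus peaks absent from the differential table", n_missing)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "summit",
                                       "log2fc", "padj", "da_class"])


def matched_controls(consensus: list[ConsensusPeak], da_regions: pd.DataFrame,
                     n: int | None = None,
                     seed: int | np.random.Generator = 0) -> list[ConsensusPeak]:
    """Uniform sample (without replacement) of non-DA consensus peaks.

    ``n`` defaults to the DA set size, matching the heatmap-style
    comparison the control set exists for.
    """
    da_names = set(da_regions["name"]) if len(da_regions) else set()
    pool = [cp for cp in consensus if cp.source_peak not in da_names]
    if n is None:
        n = len(da_names)
    if n > len(pool):
        raise ValueError(f"requested {n} controls but only {len(pool)} non-DA peaks exist")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]
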