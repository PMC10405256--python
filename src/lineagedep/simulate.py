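"""Synthetic inputs with planted ground truth.

Two generators emulate the eight inputs the pipeline consumes. The
dependency generator plants lineage-specific TF dependencies (a mean CERES
shift in the sensitive lines of one lineage), pan-essential decoys (a
strong shift everywhere plus an extra in-lineage shift, so they pass the
effect filter but fail the pan-essential filter), resistant cell-line
subsets, acquired dependencies confined to resistant lines and
mutation-rate contrasts between the two groups. The regulatory generator
plants overlapping peak pairs (to exercise consensus de-overlap), reads
scattered around summits, spatial coupling between differential expression
and differential accessibility, and block-structured binary accessibility
profiles with bit-flip noise.

Every generated table parses back through the :mod:`lineagedep.io` readers,
and the ground-truth objects are sufficient to score every downstream
stage without re-reading generator parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ldio
from .clustering import ProfileMatrix
from .intervals import GenomicInterval, Peak
from .rng import stream

DEFAULT_GENOME = (("chr1", 40_000_000), ("chr2", 25_000_000))


# ---------------------------------------------------------------------------
# dependency bundle
# ---------------------------------------------------------------------------

@dataclass
class DependencySimParams:
    """Effect sizes and rates for the fitness-matrix generator.

    The background noise sd (0.15) keeps the planted shifts (|delta| >=
    0.45) well separated at 10-20 lines per lineage. Because resistant
    lines do not carry the lineage shift, a nonzero resistant fraction
    dilutes the observable LD score toward (1 - rho) * delta_ld; set
    ``resistant_fraction = 0`` to study pure dependency recovery. The
    mutation-rate contrast mirrors a 47% vs 28% mutant-fraction
    difference between resistant and sensitive lines.
    """

    sigma: float = 0.15                     # background CERES noise sd
    delta_ld: float = -1.5                  # planted in-lineage shift (sensitive lines)
    pan_essential_mean: float = -1.0        # shift applied everywhere for decoys
    n_pan_essential: int = 5
    tfs_per_ld_lineage: int = 1
    n_ld_lineages: int | None = None        # None = every lineage gets planted TFs
    resistant_fraction: float = 0.3         # rho: share of a lineage's lines
    acquired_shift: float = -0.8            # resistant-only shift
    n_acquired_per_lineage: int = 1
    mutation_background_rate: float = 0.05
    p_mut_resistant: float = 0.47           # enriched-gene mutation rate, resistant lines
    p_mut_sensitive: float = 0.28
    n_enriched_mutation_genes: int = 1      # per lineage
    plant_ccle_flags: bool = True           # emit VHL/SMARCB1/ARID1A scenarios


@dataclass
class DependencyGroundTruth:
    planted_ld: dict[str, list[tuple[str, float]]]
    pan_essential_genes: list[str]
    resistant_lines: dict[str, list[str]]
    acquired_dep_genes: dict[str, list[tuple[str, float]]]
    enriched_mutation_genes: dict[str, list[tuple[str, float, float]]]
    ccle_flags: dict[str, dict[str, bool]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DependencyBundle:
    ceres: pd.DataFrame
    annotations: pd.DataFrame
    tf_list: list[str]
    mutations: pd.DataFrame


def generate_dependency_bundle(
    n_lineages: int = 25,
    lines_per_lineage: int = 20,
    n_genes: int = 2000,
    n_tfs: int = 1600,
    params: DependencySimParams | None = None,
    seed: int = 0,
) -> tuple[DependencyBundle, DependencyGroundTruth]:
    """Simulate a CERES matrix plus annotations, TF list and mutation table.

    CERES_ij = Normal(0, sigma) + planted shifts. For a planted
    lineage-dependency TF, the *sensitive* lines of its lineage receive
    the mean shift ``delta_ld`` while the resistant lines receive none;
    acquired-dependency genes receive their shift in resistant lines only.
    """
    p = params or DependencySimParams()
    if n_tfs > n_genes:
        raise ValueError("n_tfs cannot exceed n_genes")
    n_resistant = int(round(p.resistant_fraction * lines_per_lineage))
    if p.n_acquired_per_lineage > 0 and p.resistant_fraction > 0 and n_resistant < 1:
        raise ValueError(
            "resistant_fraction * lines_per_lineage < 1: no resistant lines "
            "to carry the requested acquired dependencies"
        )

    rng = stream(seed, "dependency")
    lineages = [f"tissue{i:02d}_subtype{i:02d}" for i in range(n_lineages)]
    lines = [f"ACH-{i:06d}" for i in range(n_lineages * lines_per_lineage)]
    lineage_of = {
        line: lineages[i // lines_per_lineage] for i, line in enumerate(lines)
    }
    tf_names = [f"TF{i:04d}" for i in range(n_tfs)]
    other_names = [f"G{i:04d}" for i in range(n_genes - n_tfs)]
    genes = tf_names + other_names
    if p.plant_ccle_flags:
        genes = genes + ["VHL", "SMARCB1", "ARID1A"]

    X = rng.normal(0.0, p.sigma, size=(len(lines), len(genes)))
    ceres = pd.DataFrame(X, index=lines, columns=genes)

    ld_lineages = lineages if p.n_ld_lineages is None else lineages[: p.n_ld_lineages]
    need_tfs = len(ld_lineages) * p.tfs_per_ld_lineage + p.n_pan_essential
    if need_tfs > n_tfs:
        raise ValueError(f"need {need_tfs} TFs for planting but only {n_tfs} exist")

    planted_ld: dict[str, list[tuple[str, float]]] = {}
    resistant: dict[str, list[str]] = {}
    acquired: dict[str, list[tuple[str, float]]] = {}
    tf_cursor = 0
    for lin in ld_lineages:
        members = [l for l in lines if lineage_of[l] == lin]
        res = list(rng.choice(members, size=n_resistant, replace=False)) if n_resistant else []
        sens = [l for l in members if l not in set(res)]
        if res:
            resistant[lin] = sorted(res)
        planted_ld[lin] = []
        for _ in range(p.tfs_per_ld_lineage):
            tf = tf_names[tf_cursor]
            tf_cursor += 1
            ceres.loc[sens, tf] += p.delta_ld
            planted_ld[lin].append((tf, p.delta_ld))

    # pan-essential decoys: shifted everywhere AND extra-shifted in one
    # lineage so they clear the effect-size filter yet fail the
    # pan-essential median filter
    pan_essential: list[str] = []
    for j in range(p.n_pan_essential):
        tf = tf_names[tf_cursor]
        tf_cursor += 1
        ceres[tf] += p.pan_essential_mean
        lin = ld_lineages[j % len(ld_lineages)]
        members = [l for l in lines if lineage_of[l] == lin]
        ceres.loc[members, tf] += p.delta_ld
        pan_essential.append(tf)

    gene_cursor = 0
    if other_names:
        for lin in ld_lineages:
            if lin not in resistant or p.n_acquired_per_lineage == 0:
                continue
            acquired[lin] = []
            for _ in range(p.n_acquired_per_lineage):
                g = other_names[gene_cursor % len(other_names)]
                gene_cursor += 1
                ceres.loc[resistant[lin], g] += p.acquired_shift
                acquired[lin].append((g, p.acquired_shift))

    mut_rows, enriched = _simulate_mutations(
        p, rng, lines, lineage_of, resistant, other_names, gene_cursor
    )
    ccle_flags: dict[str, dict[str, bool]] = {}
    if p.plant_ccle_flags:
        ccle_flags = _plant_ccle_scenarios(p, rng, lines, ceres, mut_rows)

    mutations = pd.DataFrame(mut_rows, columns=ldio.MUTATION_COLUMNS)
    annotations = pd.DataFrame(
        {"cell_line": lines, "lineage": [lineage_of[l] for l in lines]}
    )
    bundle = DependencyBundle(
        ceres=ceres, annotations=annotations, tf_list=tf_names, mutations=mutations
    )
    truth = DependencyGroundTruth(
        planted_ld=planted_ld,
        pan_essential_genes=pan_essential,
        resistant_lines=resistant,
        acquired_dep_genes=acquired,
        enriched_mutation_genes=enriched,
        ccle_flags=ccle_flags,
    )
    return bundle, truth


def _simulate_mutations(p, rng, lines, lineage_of, resistant, other_names, gene_cursor):
    """Bernoulli mutation table: enriched genes contrast resistant vs
    sensitive rates; background mutations are class 'missense', no hotspot."""
    rows = []
    enriched: dict[str, list[tuple[str, float, float]]] = {}
    for lin, res_lines in resistant.items():
        res_set = set(res_lines)
        enriched[lin] = []
        for _ in range(p.n_enriched_mutation_genes):
            g = (other_names[gene_cursor % len(other_names)]
                 if other_names else f"MUT_{lin}")
            gene_cursor += 1
            enriched[lin].append((g, p.p_mut_resistant, p.p_mut_sensitive))
            for line in lines:
                if lineage_of[line] != lin:
                    continue
                rate = p.p_mut_resistant if line in res_set else p.p_mut_sensitive
                if rng.random() < rate:
                    rows.append({
                        "cell_line": line, "gene": g,
                        "variant_classification": "missense",
                        "is_deleterious": True,
                        "is_tcga_hotspot": False, "is_cosmic_hotspot": False,
                    })
    if p.mutation_background_rate > 0 and other_names:
        for line in lines:
            if rng.random() < p.mutation_background_rate:
                g = other_names[int(rng.integers(len(other_names)))]
                rows.append({
                    "cell_line": line, "gene": g,
                    "variant_classification": "missense",
                    "is_deleterious": False,
                    "is_tcga_hotspot": False, "is_cosmic_hotspot": False,
                })
    return rows, enriched


def _plant_ccle_scenarios(p, rng, lines, ceres, mut_rows):
    """Construct per-line mutation scenarios whose expected flags are known
    by construction (decided before the realizing record is drawn)."""
    flags = {}
    for line in lines:
        is_ccrcc = bool(rng.random() < 0.15)
        if is_ccrcc:
            mut_rows.append({
                "cell_line": line, "gene": "VHL",
                "variant_classification": rng.choice(["damaging", "other non-conserving"]),
                "is_deleterious": True,
                "is_tcga_hotspot": False, "is_cosmic_hotspot": False,
            })
            ceres.loc[line, "VHL"] = rng.uniform(-0.4, 0.2)
        elif rng.random() < 0.1:
            # disruptive VHL mutation but still VHL-dependent: not ccRCC
            mut_rows.append({
                "cell_line": line, "gene": "VHL",
                "variant_classification": "damaging",
                "is_deleterious": True,
                "is_tcga_hotspot": False, "is_cosmic_hotspot": False,
            })
            ceres.loc[line, "VHL"] = rng.uniform(-1.2, -0.6)
        line_flags = {"is_ccRCC": is_ccrcc}
        for gene in ("SMARCB1", "ARID1A"):
            functional = bool(rng.random() < 0.1)
            if functional:
                if rng.random() < 0.5:
                    rec = {"variant_classification": "damaging",
                           "is_tcga_hotspot": False, "is_cosmic_hotspot": False}
                else:
                    rec = {"variant_classification": "missense",
                           "is_tcga_hotspot": True, "is_cosmic_hotspot": False}
                mut_rows.append({"cell_line": line, "gene": gene,
                                 "is_deleterious": True, **rec})
            elif rng.random() < 0.1:
                # non-functional decoys: silent hotspot or plain missense
                rec = ({"variant_classification": "silent",
                        "is_tcga_hotspot": True, "is_cosmic_hotspot": False}
                       if rng.random() < 0.5 else
                       {"variant_classification": "missense",
                        "is_tcga_hotspot": False, "is_cosmic_hotspot": False})
                mut_rows.append({"cell_line": line, "gene": gene,
                                 "is_deleterious": False, **rec})
            line_flags[f"{gene.lower()}_functional"] = functional
        flags[line] = line_flags
    return flags


# ---------------------------------------------------------------------------
# regulatory bundle
# ---------------------------------------------------------------------------

@dataclass
class RegulatorySimParams:
    """Shapes and rates for the accessibility generator."""

    overlap_pair_fraction: float = 0.2   # planted overlapping peak pairs / n_peaks
    q_min: float = 1.0                   # -log10(q) floor
    q_pareto_alpha: float = 1.5          # heavy tail for -log10(q)
    q_pareto_scale: float = 8.0
    peak_width_min: int = 200
    peak_width_max: int = 1000
    la_fraction: float = 0.15            # ~3:1 lower- vs higher-accessibility split
    ha_fraction: float = 0.05
    read_dispersion: float = 80.0        # sd of read 5' ends around summits, bp
    read_length: int = 50
    coupling_odds: float = 5.0           # DE odds multiplier near a DA summit
    coupling_distance: int = 50_000
    frac_not_expressed: float = 0.3
    base_de_rate: float = 0.1            # per direction, away from DA peaks
    n_backbone_regions: int = 100        # shared open regions in profiles
    specific_regions_per_cluster: int = 50
    region_width: int = 300
    specific_region_da_overlap_frac: float = 0.5  # cluster_1 regions placed on LA summits
    flip_prob: float = 0.02              # epsilon: per-bit noise
    unassigned_fraction: float = 0.25    # samples outside any planted cluster


@dataclass
class RegulatoryGroundTruth:
    true_clusters: dict[str, list[str]]
    true_specific_regions: dict[str, list[int]]
    da_truth: dict[str, str]                 # peak name -> LA | HA | none
    de_da_coupling: float
    overlapping_pairs: list[tuple[str, str]]

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RegulatoryBundle:
    peaks: list[Peak]
    reads: pd.DataFrame
    genes: pd.DataFrame
    differential: pd.DataFrame               # name, log2fc, padj
    profiles: ProfileMatrix


def generate_regulatory_bundle(
    genome=DEFAULT_GENOME,
    n_peaks: int = 500,
    n_reads: int = 20_000,
    n_genes: int = 1000,
    n_samples: int = 60,
    n_clusters: int = 4,
    params: RegulatorySimParams | None = None,
    seed: int = 0,
) -> tuple[RegulatoryBundle, RegulatoryGroundTruth]:
    p = params or RegulatorySimParams()
    rng = stream(seed, "regulatory")
    genome = [(str(c), int(L)) for c, L in genome]
    margin = p.peak_width_max + 1000
    usable = [(c, L) for c, L in genome if L > 2 * margin]
    if not usable:
        raise ValueError("genome too small to place peaks within bounds")
    total = sum(L for _, L in usable)
    if n_peaks * 2 * p.peak_width_max > total:
        raise ValueError("genome too small to place the requested number of peaks")

    peaks, pairs = _simulate_peaks(p, rng, usable, total, margin, n_peaks)
    da_truth = _assign_da(p, rng, peaks)
    differential = _simulate_differential(p, rng, peaks, da_truth)
    reads = _simulate_reads(p, rng, peaks, dict(genome), n_reads)
    genes = _simulate_genes(p, rng, usable, total, peaks, da_truth, n_genes)
    profiles, clusters, specific = _simulate_profiles(
        p, rng, usable, peaks, da_truth, n_samples, n_clusters
    )
    bundle = RegulatoryBundle(peaks=peaks, reads=reads, genes=genes,
                              differential=differential, profiles=profiles)
    truth = RegulatoryGroundTruth(
        true_clusters=clusters,
        true_specific_regions={k: [int(i) for i in v] for k, v in specific.items()},
        da_truth=da_truth,
        de_da_coupling=p.coupling_odds,
        overlapping_pairs=pairs,
    )
    return bundle, truth


def _rand_positions(rng, usable, total, n, margin):
    out = []
    for _ in range(n):
        r = rng.random() * total
        for chrom, L in usable:
            if r < L:
                pos = margin + int(rng.integers(L - 2 * margin))
                out.append((chrom, pos))
                break
            r -= L
    return out


def _simulate_peaks(p, rng, usable, total, margin, n_peaks):
    n_pairs = int(round(p.overlap_pair_fraction * n_peaks))
    if 2 * n_pairs > n_peaks:
        raise ValueError("overlap_pair_fraction too large: pairs exceed peak count")
    n_single = n_peaks - n_pairs
    anchors = _rand_positions(rng, usable, total, n_single, margin)

    summits = list(anchors)
    pair_partners: list[tuple[int, int]] = []
    for i in range(n_pairs):
        chrom, pos = anchors[i]
        # partner summit < 501 bp away so the consensus windows collide
        delta = int(rng.integers(50, 450))
        summits.append((chrom, pos + delta))
        pair_partners.append((i, n_single + i))

    peaks = []
    for i, (chrom, summit) in enumerate(summits):
        width = int(rng.integers(p.peak_width_min, p.peak_width_max + 1))
        offset = int(rng.integers(width // 4, 3 * width // 4))
        start = max(summit - offset, 0)
        q = p.q_min + rng.pareto(p.q_pareto_alpha) * p.q_pareto_scale
        peaks.append(Peak(
            interval=GenomicInterval(chrom, start, start + width),
            summit=summit, neg_log10_q=float(q), name=f"peak{i:05d}",
            score=int(min(1000, 10 * q)), signal=float(q),
            neg_log10_p=float(q) + 1.0,
        ))
    pairs = [(peaks[a].name, peaks[b].name) for a, b in pair_partners]
    return peaks, pairs


def _assign_da(p, rng, peaks) -> dict[str, str]:
    labels = {}
    for pk in peaks:
        r = rng.random()
        if r < p.la_fraction:
            labels[pk.name] = "LA"
        elif r < p.la_fraction + p.ha_fraction:
            labels[pk.name] = "HA"
        else:
            labels[pk.name] = "none"
    return labels


def _simulate_differential(p, rng, peaks, da_truth) -> pd.DataFrame:
    rows = []
    for pk in peaks:
        label = da_truth[pk.name]
        if label == "LA":
            lfc = -(1.0 + abs(rng.normal(0, 1)))
            padj = 10.0 ** -rng.uniform(3.5, 10)
        elif label == "HA":
            lfc = 1.0 + abs(rng.normal(0, 1))
            padj = 10.0 ** -rng.uniform(3.5, 10)
        else:
            lfc = rng.normal(0, 0.3)
            padj = rng.uniform(0.0011, 1.0)  # always fails the padj cutoff
        rows.append({"name": pk.name, "log2fc": float(lfc), "padj": float(padj)})
    return pd.DataFrame(rows)


def _simulate_reads(p, rng, peaks, chrom_len, n_reads) -> pd.DataFrame:
    which = rng.integers(len(peaks), size=n_reads)
    rows = []
    for i, j in enumerate(which):
        pk = peaks[int(j)]
        L = chrom_len[pk.chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        five_prime = int(np.clip(round(rng.normal(pk.summit, p.read_dispersion)),
                                 p.read_length, L - p.read_length))
        if strand == "+":
            start, end = five_prime, five_prime + p.read_length
        else:
            start, end = five_prime - p.read_length, five_prime
        rows.append({"chrom": pk.chrom, "start": start, "end": end,
                     "name": f"read{i:06d}", "score": 0, "strand": strand})
    return pd.DataFrame(rows, columns=ldio.BED6_COLUMNS)


def _simulate_genes(p, rng, usable, total, peaks, da_truth, n_genes) -> pd.DataFrame:
    positions = _rand_positions(rng, usable, total, n_genes, 1000)
    da_summits = {"LA": {}, "HA": {}}
    for pk in peaks:
        lab = da_truth[pk.name]
        if lab in da_summits:
            da_summits[lab].setdefault(pk.chrom, []).append(pk.summit)
    for lab in da_summits:
        da_summits[lab] = {c: np.sort(v) for c, v in da_summits[lab].items()}

    def near_da(lab, chrom, tss) -> bool:
        arr = da_summits[lab].get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = np.searchsorted(arr, tss)
        best = min(
            abs(tss - arr[i - 1]) if i > 0 else np.inf,
            abs(arr[i] - tss) if i < len(arr) else np.inf,
        )
        return best <= p.coupling_distance

    base = p.base_de_rate
    base_odds = base / (1.0 - base)
    rows = []
    for i, (chrom, tss) in enumerate(positions):
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < p.frac_not_expressed:
            status, lfc, padj = "not_expressed", np.nan, np.nan
        else:
            status = "unchanged"
            for lab, direction in (("LA", "down"), ("HA", "up")):
                odds = base_odds * (p.coupling_odds if near_da(lab, chrom, tss) else 1.0)
                if rng.random() < odds / (1.0 + odds):
                    status = direction
                    break
            if status == "down":
                lfc, padj = -(0.5 + abs(rng.normal(0, 1))), 10.0 ** -rng.uniform(2, 8)
            elif status == "up":
                lfc, padj = 0.5 + abs(rng.normal(0, 1)), 10.0 ** -rng.uniform(2, 8)
            else:
                lfc, padj = float(rng.normal(0, 0.2)), rng.uniform(0.1, 1.0)
        rows.append({"gene_id": f"gene{i:05d}", "chrom": chrom, "tss": tss,
                     "strand": strand, "de_status": status,
                     "log2fc": lfc, "padj": padj})
    return pd.DataFrame(rows, columns=ldio.GENE_COLUMNS)


def _simulate_profiles(p, rng, usable, peaks, da_truth, n_samples, n_clusters):
    n_unassigned = int(round(p.unassigned_fraction * n_samples))
    n_assigned = n_samples - n_unassigned
    if n_assigned < n_clusters * 2:
        raise ValueError("too few samples for the requested number of clusters")
    samples = [f"sample{i:03d}" for i in range(n_samples)]
    block_sizes = [n_assigned // n_clusters] * n_clusters
    for i in range(n_assigned % n_clusters):
        block_sizes[i] += 1
    clusters: dict[str, list[str]] = {}
    cursor = 0
    for k, size in enumerate(block_sizes, start=1):
        clusters[f"cluster_{k}"] = samples[cursor: cursor + size]
        cursor += size
    unassigned = samples[cursor:]

    n_specific = n_clusters * p.specific_regions_per_cluster
    n_regions = p.n_backbone_regions + n_specific

    # non-overlapping tiles; a share of cluster_1's specific regions is
    # centered on LA summits so DA summit windows fall fully inside them
    la_summits = [(pk.chrom, pk.summit) for pk in peaks if da_truth[pk.name] == "LA"]
    regions: list[tuple[str, int, int]] = []
    chrom0, L0 = usable[0]
    stride = p.region_width + 200
    pos = 10_000
    specific: dict[str, list[int]] = {cid: [] for cid in clusters}
    region_rows = []
    idx = 0
    for b in range(p.n_backbone_regions):
        region_rows.append((chrom0, pos, pos + p.region_width))
        pos += stride
        idx += 1
    backbone_idx = list(range(p.n_backbone_regions))
    n_on_da = int(round(p.specific_region_da_overlap_frac
                        * p.specific_regions_per_cluster)) if la_summits else 0
    for k, cid in enumerate(clusters, start=1):
        for j in range(p.specific_regions_per_cluster):
            if cid == "cluster_1" and j < n_on_da and j < len(la_summits):
                chrom, summit = la_summits[j % len(la_summits)]
                half = p.region_width // 2
                start = max(summit - half, 0)
                region_rows.append((chrom, start, start + p.region_width))
            else:
                region_rows.append((chrom0, pos, pos + p.region_width))
                pos += stride
            specific[cid].append(idx)
            idx += 1
    if pos >= L0:
        raise ValueError("genome too small for the requested profile regions")

    regions_df = (pd.DataFrame(region_rows, columns=["chrom", "start", "end"])
                  .drop_duplicates(subset=["chrom", "start", "end"]))
    if len(regions_df) != n_regions:
        raise ValueError("region placement produced duplicate coordinates")

    values = np.zeros((n_regions, n_samples), dtype=np.uint8)
    values[backbone_idx, :] = 1
    pos_of = {s: i for i, s in enumerate(samples)}
    for cid, members in clusters.items():
        cols = [pos_of[s] for s in members]
        values[np.ix_(specific[cid], cols)] = 1
    if unassigned:
        # unassigned samples are unrelated profiles: every region open
        # with probability 1/2, uncorrelated with any planted block
        cols = [pos_of[s] for s in unassigned]
        noise = rng.random((n_regions, len(cols))) < 0.5
        values[:, cols] = noise
    if p.flip_prob > 0:
        flips = rng.random(values.shape) < p.flip_prob
        values = np.where(flips, 1 - values, values).astype(np.uint8)

    matrix = ProfileMatrix(regions=regions_df.reset_index(drop=True),
                           samples=samples, values=values)
    return matrix, clusters, specific


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_dependency_bundle(bundle: DependencyBundle, truth: DependencyGroundTruth,
                            outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ldio.write_dependency_csv(bundle.ceres, outdir / "ceres.csv")
    ldio.write_annotations(bundle.annotations, outdir / "annotations.csv")
    ldio.write_tf_list(bundle.tf_list, outdir / "tfs.txt")
    ldio.write_mutations(bundle.mutations, outdir / "mutations.csv")
    with open(outdir / "dependency_ground_truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)


def write_regulatory_bundle(bundle: RegulatoryBundle, truth: RegulatoryGroundTruth,
                            outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ldio.write_narrowpeak(bundle.peaks, outdir / "peaks.narrowPeak")
    ldio.write_bed6(bundle.reads, outdir / "reads.bed")
    ldio.write_gene_table(bundle.genes, outdir / "genes.tsv")
    bundle.differential.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    ldio.write_profile_matrix(bundle.profiles, outdir / "profile_regions.bed",
                              outdir / "profiles.tsv")
    with open(outdir / "regulatory_ground_truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
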