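"""Cohort consensus map construction and characterization.

The consensus map is the interval union of per-sample peak calls: the shared
coordinate frame for all downstream quantification.  This module also
computes the saturation curve (unique merged regions as samples are added in
random order), per-region sample support, genomic co-localization
enrichment, and nearest-TSS annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GenomicRegion, PeakSet, count_overlaps, merge_intervals

# Support-class boundaries: constitutive > 0.95, rare < 0.05, shared in between.
SUPPORT_BOUNDS = {"constitutive_gt": 0.95, "rare_lt": 0.05}


@dataclass
class ConsensusMap:
    """Union regions with stable IDs and per-region sample support."""

    regions: list[GenomicRegion]
    n_samples: int
    support: np.ndarray | None = None

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class SaturationResult:
    """Mean and 95% percentile band of unique-region counts per samples added."""

    mean_curve: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_iterations: int


def merge_peak_sets(peak_sets: list[PeakSet]) -> ConsensusMap:
    """Union of all samples' peaks; book-ended intervals merge.

    Every input peak is contained in exactly one consensus region; two peaks
    share a region iff a chain of overlapping-or-touching peaks connects them.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    all_regions = [r for ps in peak_sets for r in ps.regions]
    if not all_regions:
        raise ValueError("all peak sets are empty")
    return ConsensusMap(regions=merge_intervals(all_regions), n_samples=len(peak_sets))


def saturation_curve(
    peak_sets: list[PeakSet], n_iterations: int = 1000, seed: int = 0
) -> SaturationResult:
    """Unique merged-region count as samples are added in random order.

    For each of ``n_iterations`` random orderings, the value at step k is the
    number of merged regions over the first k samples.  Returns the mean and
    the 2.5/97.5 percentile band across orderings.  The final step equals the
    consensus size for every ordering (union is order-invariant).
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(peak_sets)
    curves = np.empty((n_iterations, n), dtype=np.int64)
    for it in range(n_iterations):
        order = rng.permutation(n)
        acc: list[GenomicRegion] = []
        for k, si in enumerate(order):
            acc = merge_intervals(acc + list(peak_sets[si].regions))
            curves[it, k] = len(acc)
    return SaturationResult(
        mean_curve=curves.mean(axis=0),
        ci_low=np.percentile(curves, 2.5, axis=0),
        ci_high=np.percentile(curves, 97.5, axis=0),
        n_iterations=n_iterations,
    )


def region_support(
    consensus: ConsensusMap, peak_sets: list[PeakSet]
) -> tuple[np.ndarray, dict]:
    """Fraction of samples with >=1 called peak overlapping each region.

    Returns the per-region support array and a breakdown dict with the
    fraction of regions in each class (constitutive / shared / rare) and the
    boundary convention used.
    """
    if consensus.n_samples != len(peak_sets):
        raise ValueError(
            f"consensus built from {consensus.n_samples} samples, got {len(peak_sets)}"
        )
    n = len(peak_sets)
    hit = np.zeros(len(consensus.regions), dtype=np.int64)
    for ps in peak_sets:
        hit += (count_overlaps(consensus.regions, ps.regions) > 0).astype(np.int64)
    support = hit / n
    consensus.support = support
    breakdown = {
        "constitutive": float(np.mean(support > SUPPORT_BOUNDS["constitutive_gt"])),
        "shared": float(
            np.mean(
                (support >= SUPPORT_BOUNDS["rare_lt"])
                & (support <= SUPPORT_BOUNDS["constitutive_gt"])
            )
        ),
        "rare": float(np.mean(support < SUPPORT_BOUNDS["rare_lt"])),
        "bounds": dict(SUPPORT_BOUNDS),
    }
    return support, breakdown


def co_localization(
    regions: list[GenomicRegion],
    features: dict[str, list[GenomicRegion]],
    genome: dict[str, int],
) -> pd.DataFrame:
    """Overlap frequency and base-pair fold enrichment per feature class.

    frequency: fraction of regions overlapping the class by >=1 bp.
    fold_change: (region bp inside class / total region bp) divided by
    (class bp / genome bp).
    """
    genome_bp = sum(genome.values())
    if genome_bp <= 0:
        raise ValueError("genome has zero total length")
    region_bp = sum(len(r) for r in regions)
    if region_bp <= 0:
        raise ValueError("regions have zero total length")
    rows = []
    for cls, feats in features.items():
        feats_merged = merge_intervals(feats)
        class_bp = sum(len(f) for f in feats_merged)
        if class_bp <= 0:
            raise ValueError(f"feature class {cls!r} has zero total length")
        n_overlap = int(np.sum(count_overlaps(regions, feats_merged) > 0))
        inside_bp = 0
        for r in regions:
            for f in feats_merged:
                if r.overlaps(f):
                    inside_bp += min(r.end, f.end) - max(r.start, f.start)
        fold = (inside_bp / region_bp) / (class_bp / genome_bp)
        rows.append(
            {
                "feature_class": cls,
                "frequency": n_overlap / len(regions),
                "fold_change": fold,
            }
        )
    return pd.DataFrame(rows)


def annotate_nearest_tss(
    regions: list[GenomicRegion], genes: pd.DataFrame
) -> pd.DataFrame:
    """Nearest gene per region by |region midpoint - TSS| (0 if TSS inside).

    Ties break to the lexicographically smallest gene_id.  Regions on
    chromosomes with no annotated gene get gene_id=None and NaN distance.
    """
    if genes.empty:
        raise ValueError("gene table is empty")
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values(["tss", "gene_id"]) for c, g in genes.groupby("chrom")
    }
    rows = []
    for r in regions:
        g = by_chrom.get(r.chrom)
        if g is None:
            rows.append({"region_id": r.region_id, "gene_id": None, "distance": np.nan})
            continue
        tss = g["tss"].to_numpy()
        inside = (tss >= r.start) & (tss < r.end)
        if inside.any():
            hits = g[inside]
            best = hits.sort_values("gene_id").iloc[0]
            rows.append({"region_id": r.region_id, "gene_id": best["gene_id"], "distance": 0.0})
            continue
        dist = np.abs(r.midpoint - tss)
        dmin = dist.min()
        hits = g[dist == dmin]
        best = hits.sort_values("gene_id").iloc[0]
        rows.append(
            {"region_id": r.region_id, "gene_id": best["gene_id"], "distance": float(dmin)}
        )
    return pd.DataFrame(rows)
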