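"""Per-region accessibility quantification, normalization, variability and
corridor tracks.

The accessibility matrix is regions x samples.  The raw layer counts
fragments overlapping each consensus region by >=1 bp; the normalized layer
is quantile-normalized across samples so every column shares one multiset of
values.  Cohort variability is summarized per region by mean, standard
deviation (n-1), variance-to-mean ratio and squared coefficient of
variation.  Corridor tracks summarize normalized per-base coverage across
the cohort by its mean and 5/25/75/95th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusMap
from .regions import GenomicRegion, count_overlaps


@dataclass
class AccessibilityMatrix:
    region_ids: list[str]
    sample_ids: list[str]
    raw: np.ndarray  # regions x samples, counts
    normalized: np.ndarray | None = None
    totals: np.ndarray | None = None  # per-sample filtered fragment totals
    qc: dict = field(default_factory=dict)

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=self.region_ids, columns=self.sample_ids)

    def normalized_frame(self) -> pd.DataFrame:
        if self.normalized is None:
            raise ValueError("normalized layer not computed")
        return pd.DataFrame(
            self.normalized, index=self.region_ids, columns=self.sample_ids
        )


def quantify_regions(
    consensus: ConsensusMap,
    fragments: dict[str, list[GenomicRegion]],
    totals: dict[str, int] | None = None,
) -> AccessibilityMatrix:
    """Count fragments overlapping each consensus region by >=1 bp (half-open).

    A fragment spanning several regions counts once in each.  Fragments on
    chromosomes absent from the consensus are skipped and tallied in the QC
    report.  ``totals`` overrides the per-sample filtered-fragment totals
    (defaults to the fragment-list lengths).
    """
    if not consensus.regions:
        raise ValueError("consensus map is empty")
    sample_ids = list(fragments)
    known_chroms = {r.chrom for r in consensus.regions}
    raw = np.zeros((len(consensus.regions), len(sample_ids)), dtype=np.int64)
    skipped = {}
    for j, sid in enumerate(sample_ids):
        frags = fragments[sid]
        raw[:, j] = count_overlaps(consensus.regions, frags)
        skipped[sid] = sum(1 for f in frags if f.chrom not in known_chroms)
    tot = np.array(
        [totals[sid] if totals else len(fragments[sid]) for sid in sample_ids],
        dtype=np.int64,
    )
    return AccessibilityMatrix(
        region_ids=consensus.region_ids,
        sample_ids=sample_ids,
        raw=raw,
        totals=tot,
        qc={"skipped_fragments": skipped},
    )


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile normalization across columns (samples).

    Each column's sorted values are replaced by the row-wise mean of all
    column-sorted values; ties within a column receive the mean of the
    reference values at their rank positions (the behaviour of the classic
    microarray implementation).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 samples (columns)")
    if (values < 0).any():
        raise ValueError("negative values not allowed")
    n_rows, n_cols = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n_rows, dtype=np.int64)
        ranks[order] = np.arange(n_rows)
        mapped = reference[ranks]
        # average reference values over tied input values
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=mapped, minlength=len(uniq))
        cnts = np.bincount(inv, minlength=len(uniq))
        out[:, j] = (sums / cnts)[inv]
    return out


def add_normalized_layer(matrix: AccessibilityMatrix) -> AccessibilityMatrix:
    matrix.normalized = quantile_normalize(matrix.raw)
    return matrix


def variability_metrics(matrix: AccessibilityMatrix) -> pd.DataFrame:
    """Per-region mean, sd (n-1), variance/mean and squared CV of the
    normalized layer.  Rows with mean 0 get NaN vmr/cv2 and a flag."""
    if matrix.normalized is None:
        raise ValueError("normalized layer not computed")
    x = matrix.normalized
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    var = sd**2
    with np.errstate(divide="ignore", invalid="ignore"):
        vmr = np.where(mean > 0, var / mean, np.where(sd == 0, 0.0, np.nan))
        cv2 = np.where(mean > 0, (sd / mean) ** 2, np.where(sd == 0, 0.0, np.nan))
    return pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "vmr": vmr,
            "cv2": cv2,
            "flag_zero_mean": mean == 0,
        },
        index=matrix.region_ids,
    )


PROMOTER_MAX_BP = 1000
DISTAL_MIN_BP = 2500


def summarize_by_gene(
    matrix: AccessibilityMatrix, tss_annotation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Gene-level promoter and distal accessibility per sample.

    promoter: value of the gene's closest region within 1,000 bp of its TSS.
    distal: mean over the gene's regions farther than 2,500 bp from its TSS.
    Regions between the two cutoffs belong to neither summary.  Genes with
    no qualifying region are absent from the respective table.
    """
    if matrix.normalized is None:
        raise ValueError("normalized layer not computed")
    values = matrix.normalized_frame()
    ann = tss_annotation.dropna(subset=["gene_id"]).set_index("region_id")
    ann = ann.loc[ann.index.intersection(values.index)]

    promoter_rows = {}
    distal_rows = {}
    for gene_id, sub in ann.groupby("gene_id"):
        prom = sub[sub["distance"] <= PROMOTER_MAX_BP]
        if not prom.empty:
            closest = prom["distance"].idxmin()
            promoter_rows[gene_id] = values.loc[closest]
        dist = sub[sub["distance"] > DISTAL_MIN_BP]
        if not dist.empty:
            distal_rows[gene_id] = values.loc[dist.index].mean(axis=0)
    promoter = pd.DataFrame(promoter_rows).T
    distal = pd.DataFrame(distal_rows).T
    return {"promoter": promoter, "distal": distal}


COVERAGE_SCALE = 1e7


def normalize_coverage(coverage: np.ndarray, total_filtered_reads: int) -> np.ndarray:
    """Scale per-base coverage to reads per total-filtered-reads x 1e7."""
    if total_filtered_reads <= 0:
        raise ValueError("total_filtered_reads must be > 0")
    return np.asarray(coverage, dtype=float) / total_filtered_reads * COVERAGE_SCALE


CORRIDOR_PERCENTILES = (5, 25, 75, 95)


@dataclass
class CorridorTrack:
    """Cohort coverage summary over one locus: per-base mean and percentiles."""

    chrom: str
    start: int
    mean: np.ndarray
    p5: np.ndarray
    p25: np.ndarray
    p75: np.ndarray
    p95: np.ndarray
    metadata: dict = field(default_factory=dict)


def corridor_tracks(
    coverages: dict[str, np.ndarray], chrom: str, start: int
) -> CorridorTrack:
    """Per-base mean and 5/25/75/95th percentiles across samples.

    All per-sample tracks must cover the same locus (equal length).
    Percentiles use linear interpolation between closest order statistics.
    """
    if len(coverages) < 2:
        raise ValueError("need >=2 samples")
    lengths = {len(v) for v in coverages.values()}
    if len(lengths) != 1:
        raise ValueError("per-sample tracks cover inconsistent loci")
    stack = np.vstack([np.asarray(v, dtype=float) for v in coverages.values()])
    pct = np.percentile(stack, CORRIDOR_PERCENTILES, axis=0, method="linear")
    return CorridorTrack(
        chrom=chrom,
        start=start,
        mean=stack.mean(axis=0),
        p5=pct[0],
        p25=pct[1],
        p75=pct[2],
        p95=pct[3],
        metadata={"percentile_method": "linear", "n_samples": len(coverages)},
    )
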