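#!/usr/bin/env python
"""Quantify accessibility, normalize, and summarize cohort variability.

Counts fragments per consensus region and sample, quantile-normalizes the
matrix, computes the four per-region variability metrics (mean, sd,
variance-to-mean ratio, squared CV), gene-level promoter/distal
summaries, and an accessibility-corridor track (cohort mean and
5/25/75/95th percentiles of normalized coverage) over an example locus.
"""

import json
from pathlib import Path

import numpy as np

import atacohort as a
import atacohort.io as aio

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    with open(SCRATCH / "manifest.json") as fh:
        manifest = json.load(fh)
    peak_sets = [
        aio.read_peak_set(p, sid) for sid, p in sorted(manifest["peaks"].items())
    ]
    fragments = {
        sid: aio.read_bed(p) for sid, p in sorted(manifest["fragments"].items())
    }
    consensus = a.merge_peak_sets(peak_sets)

    matrix = a.quantify_regions(consensus, fragments)
    a.add_normalized_layer(matrix)
    aio.write_matrix(matrix.raw_frame(), ROOT / "scratch" / "matrix_raw.tsv")
    aio.write_matrix(matrix.normalized_frame(), ROOT / "scratch" / "matrix_norm.tsv")

    stats = a.variability_metrics(matrix)
    stats.to_csv(ROOT / "scratch" / "variability.tsv", sep="\t")

    import pandas as pd

    tss = pd.read_csv(ROOT / "scratch" / "tss_annotation.tsv", sep="\t")
    gene_level = a.summarize_by_gene(matrix, tss)

    # corridor over the first consensus region, padded by 500 bp
    locus = consensus.regions[0]
    start, end = locus.start - 500, locus.end + 500
    covs = {}
    for sid, frags in fragments.items():
        cov = np.zeros(end - start)
        for f in frags:
            if f.chrom == locus.chrom and f.start < end and f.end > start:
                cov[max(f.start - start, 0) : f.end - start] += 1
        covs[sid] = a.normalize_coverage(cov, len(frags))
    track = a.corridor_tracks(covs, locus.chrom, start)

    summary = {
        "matrix_shape": list(matrix.raw.shape),
        "mean_accessibility": float(np.mean(matrix.normalized)),
        "median_cv2": float(stats["cv2"].median()),
        "n_genes_with_promoter_signal": int(len(gene_level["promoter"])),
        "n_genes_with_distal_signal": int(len(gene_level["distal"])),
        "corridor_locus": locus.region_id,
        "corridor_peak_p95": float(track.p95.max()),
        "corridor_peak_p5": float(track.p5.max()),
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "accessibility_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
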