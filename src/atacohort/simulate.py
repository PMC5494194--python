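"""Synthetic ATAC-seq cohort generator.

Generates a fully specified cohort — per-sample peak sets, fragment
intervals, a sample sheet with IGHV germline homology, gene models, and
transcription-factor footprint tables — with the statistical structure the
downstream stages assume, so every stage is testable without external data.

The emulated structure mirrors a leukemia cohort profiled by chromatin
accessibility: a core of regions open in every sample, a large shared
component open in a varying subset, and rare sample-specific regions; two
disease subtypes (IGHV-mutated / unmutated) separated by planted mean
shifts at signature regions; planted variance-ratio differences at
equal means (so differential variability is not confounded with mean
shifts); optional intermediate samples whose expected signal at signature
regions is the midpoint of the two subtype means; and footprint sites whose
purity and TSS distance make a known set of TF->gene edges recoverable
while decoy TFs stay below the edge threshold.

Counts are negative binomial in the mean/dispersion parameterization
(var = mu + dispersion * mu^2).  A single integer seed drives every stream;
regeneration with the same spec is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .regions import GenomicRegion, PeakSet

REGION_WIDTH = 500
SITE_WIDTH = 15
BACKGROUND_MEAN = 1.0
N_DECOY_ZONE_REGIONS = 10
N_FAR_GENES = 2  # genes anchored at the start of the last chromosome


class SizingError(ValueError):
    """Regions cannot be packed into the requested genome."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults are the desk-scale study
    conditions used throughout the analysis scripts and tests."""

    n_samples: int = 40
    n_patients: int = 25
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000),
        ("chr2", 20_000_000),
    )
    n_core_regions: int = 240
    n_variable_regions: int = 1160
    n_sample_specific_regions_per_sample: int = 15
    n_signature_regions: int = 50
    signature_log2_effect: float = 1.5
    n_diffvar_regions: int = 50
    diffvar_variance_ratio: float = 4.0
    baseline_mean: float = 30.0
    dispersion: float = 0.25
    subtype_fraction_mutated: float = 0.5
    intermediate_fraction: float = 0.0
    n_genes: int = 40
    footprint_spec: tuple[int, tuple[int, int], tuple[float, float]] = (
        8,
        (550, 700),
        (4.0, 1.5),
    )
    seed: int = 0

    @property
    def total_regions(self) -> int:
        return (
            self.n_core_regions
            + self.n_variable_regions
            + self.n_samples * self.n_sample_specific_regions_per_sample
        )

    def validate(self) -> None:
        if self.n_patients > self.n_samples:
            raise ValueError(
                f"n_patients ({self.n_patients}) > n_samples ({self.n_samples})"
            )
        if self.n_patients < 1 or self.n_samples < 1:
            raise ValueError("need >=1 sample and >=1 patient")
        if not 0 < self.subtype_fraction_mutated < 1:
            raise ValueError("subtype_fraction_mutated must be in (0,1)")
        if not 0 <= self.intermediate_fraction < 1:
            raise ValueError("intermediate_fraction must be in [0,1)")
        if self.diffvar_variance_ratio <= 1:
            raise ValueError("diffvar_variance_ratio must be > 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        n_tfs, sites_range, beta = self.footprint_spec
        n_planted = n_tfs - n_tfs // 2
        needed_core = (
            (self.n_genes - N_FAR_GENES)
            + N_FAR_GENES
            + N_DECOY_ZONE_REGIONS
            + self.n_signature_regions
            + self.n_diffvar_regions
        )
        if self.n_core_regions < needed_core:
            raise ValueError(
                f"n_core_regions ({self.n_core_regions}) too small for "
                f"{self.n_genes} gene anchors, {N_DECOY_ZONE_REGIONS} decoy-zone "
                f"regions, {self.n_signature_regions} signature and "
                f"{self.n_diffvar_regions} diff-var regions ({needed_core} needed)"
            )
        if n_planted + N_FAR_GENES > self.n_genes:
            raise ValueError("n_genes too small for the planted TF targets")


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    peak_sets: list[PeakSet]
    fragments: dict[str, list[GenomicRegion]]
    sample_sheet: pd.DataFrame
    gene_models: pd.DataFrame
    footprints: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        return {sid: len(frags) for sid, frags in self.fragments.items()}


def _place_regions(spec: CohortSpec) -> list[GenomicRegion]:
    """Evenly spaced fixed-width regions, allocated across chromosomes
    proportionally to length; raises SizingError if they cannot fit."""
    total = spec.total_regions
    genome_bp = sum(l for _, l in spec.genome)
    regions: list[GenomicRegion] = []
    allocated = 0
    for i, (chrom, length) in enumerate(spec.genome):
        if i == len(spec.genome) - 1:
            k = total - allocated
        else:
            k = int(round(total * length / genome_bp))
        allocated += k
        if k == 0:
            continue
        spacing = length // (k + 1)
        if spacing < REGION_WIDTH + 1000:
            raise SizingError(
                f"cannot pack {k} regions of {REGION_WIDTH} bp into {chrom} "
                f"({length} bp): spacing {spacing} bp too small"
            )
        for j in range(k):
            start = spacing * (j + 1)
            regions.append(GenomicRegion(chrom, start, start + REGION_WIDTH))
    return regions


def _assign_patients(spec: CohortSpec, rng: np.random.Generator):
    """Sample -> patient map; every patient gets >=1 sample, extras are
    spread over random patients (so some patients contribute several)."""
    sample_ids = [f"S{i+1:03d}" for i in range(spec.n_samples)]
    patient_ids = [f"P{i+1:03d}" for i in range(spec.n_patients)]
    assignment = {}
    for i, sid in enumerate(sample_ids):
        if i < spec.n_patients:
            assignment[sid] = patient_ids[i]
        else:
            assignment[sid] = patient_ids[rng.integers(0, spec.n_patients)]
    return sample_ids, patient_ids, assignment


def _assign_subtypes(spec: CohortSpec, patient_ids: list[str], rng: np.random.Generator):
    """Patient-level subtype labels (all samples of a patient agree)."""
    n = len(patient_ids)
    n_int = int(round(spec.intermediate_fraction * n))
    n_rest = n - n_int
    n_mut = int(round(spec.subtype_fraction_mutated * n_rest))
    n_mut = min(max(n_mut, 1), n_rest - 1)  # both subtypes represented
    order = rng.permutation(n)
    subtype = {}
    for rank, idx in enumerate(order):
        if rank < n_int:
            subtype[patient_ids[idx]] = "intermediate"
        elif rank < n_int + n_mut:
            subtype[patient_ids[idx]] = "mutated"
        else:
            subtype[patient_ids[idx]] = "unmutated"
    return subtype


def _nb_draw(rng: np.random.Generator, mu: float, alpha: float) -> int:
    """Negative binomial with mean mu and var mu + alpha*mu^2."""
    if mu <= 0:
        return 0
    size = 1.0 / alpha
    p = size / (size + mu)
    return int(rng.negative_binomial(size, p))


def diffvar_dispersion(mu: float, alpha: float, ratio: float) -> float:
    """Dispersion that multiplies the NB variance by ``ratio`` at fixed mean."""
    base_var = mu + alpha * mu * mu
    return (ratio * base_var - mu) / (mu * mu)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full synthetic cohort described by ``spec``.

    Deterministic: the same spec (including seed) yields identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    regions = _place_regions(spec)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    last_chrom = spec.genome[-1][0]
    first_chrom_idx = [
        i for c, ii in by_chrom.items() if c != last_chrom for i in ii
    ]
    last_chrom_idx = by_chrom.get(last_chrom, [])
    if len(last_chrom_idx) < N_FAR_GENES + N_DECOY_ZONE_REGIONS:
        raise SizingError(
            f"last chromosome holds only {len(last_chrom_idx)} regions; need "
            f">= {N_FAR_GENES + N_DECOY_ZONE_REGIONS} for gene/decoy anchors"
        )

    # --- structural roles -------------------------------------------------
    n_near_genes = spec.n_genes - N_FAR_GENES
    step = max(1, len(first_chrom_idx) // n_near_genes)
    near_anchor_idx = first_chrom_idx[::step][:n_near_genes]
    far_anchor_idx = last_chrom_idx[:N_FAR_GENES]
    decoy_idx = last_chrom_idx[-N_DECOY_ZONE_REGIONS:]
    fixed_core = set(near_anchor_idx) | set(far_anchor_idx) | set(decoy_idx)

    free = [i for i in range(len(regions)) if i not in fixed_core]
    free = list(rng.permutation(np.array(free)))
    n_extra_core = spec.n_core_regions - len(fixed_core)
    extra_core = free[:n_extra_core]
    rest = free[n_extra_core:]
    core_idx = sorted(fixed_core | set(int(i) for i in extra_core))

    sig_pool = [int(i) for i in extra_core]
    signature_idx = sig_pool[: spec.n_signature_regions]
    diffvar_idx = sig_pool[
        spec.n_signature_regions : spec.n_signature_regions + spec.n_diffvar_regions
    ]

    variable_idx = [int(i) for i in rest[: spec.n_variable_regions]]
    specific_pool = [int(i) for i in rest[spec.n_variable_regions :]]

    # --- samples, patients, subtypes -------------------------------------
    sample_ids, patient_ids, patient_of = _assign_patients(spec, rng)
    subtype_of_patient = _assign_subtypes(spec, patient_ids, rng)
    label_of = {s: subtype_of_patient[patient_of[s]] for s in sample_ids}

    homology = {}
    for s in sample_ids:
        lab = label_of[s]
        if lab == "mutated":
            homology[s] = float(rng.uniform(85.0, 97.9))
        elif lab == "unmutated":
            homology[s] = float(rng.uniform(98.1, 100.0))
        else:  # intermediate: homology straddles the 98% threshold
            homology[s] = float(rng.uniform(97.6, 98.4))

    # --- presence structure ----------------------------------------------
    n_spec_per = spec.n_sample_specific_regions_per_sample
    specific_of: dict[int, str] = {}
    for si, s in enumerate(sample_ids):
        for ridx in specific_pool[si * n_spec_per : (si + 1) * n_spec_per]:
            specific_of[ridx] = s

    presence_frac = {ridx: float(rng.uniform(0.1, 0.9)) for ridx in variable_idx}
    present = np.zeros((len(regions), len(sample_ids)), dtype=bool)
    present[core_idx, :] = True
    for ridx in variable_idx:
        row = rng.random(len(sample_ids)) < presence_frac[ridx]
        if not row.any():
            row[rng.integers(0, len(sample_ids))] = True
        present[ridx] = row
    for ridx, s in specific_of.items():
        present[ridx, sample_ids.index(s)] = True

    # --- expected counts ---------------------------------------------------
    # per-region baseline mean with lognormal spread around baseline_mean
    base_mu = spec.baseline_mean * np.exp(rng.normal(0.0, 0.4, size=len(regions)))
    half = spec.signature_log2_effect / 2
    sig_direction = {}  # region idx -> subtype with the higher mean
    for k, ridx in enumerate(signature_idx):
        sig_direction[ridx] = "mutated" if k % 2 == 0 else "unmutated"
    dv_direction = {}  # region idx -> subtype with the higher variance
    for k, ridx in enumerate(diffvar_idx):
        dv_direction[ridx] = "mutated" if k % 2 == 0 else "unmutated"

    def expected_mu(ridx: int, label: str) -> float:
        mu = base_mu[ridx]
        if ridx in sig_direction:
            up = sig_direction[ridx]
            mu_up = mu * 2**half
            mu_dn = mu * 2**-half
            if label == "intermediate":
                return (mu_up + mu_dn) / 2
            return mu_up if label == up else mu_dn
        return float(mu)

    def expected_alpha(ridx: int, label: str) -> float:
        if ridx in dv_direction and label == dv_direction[ridx]:
            return diffvar_dispersion(
                float(base_mu[ridx]), spec.dispersion, spec.diffvar_variance_ratio
            )
        return spec.dispersion

    # --- counts and fragments ----------------------------------------------
    frag_len = 100
    peak_sets: list[PeakSet] = []
    fragments: dict[str, list[GenomicRegion]] = {}
    for sj, s in enumerate(sample_ids):
        lab = label_of[s]
        frags: list[GenomicRegion] = []
        peaks = [regions[i] for i in range(len(regions)) if present[i, sj]]
        for ridx, r in enumerate(regions):
            if present[ridx, sj]:
                mu = expected_mu(ridx, lab)
                alpha = expected_alpha(ridx, lab)
            else:
                mu, alpha = BACKGROUND_MEAN, spec.dispersion
            c = _nb_draw(rng, mu, alpha)
            if c:
                starts = rng.integers(r.start, r.end - frag_len, size=c)
                frags.extend(
                    GenomicRegion(r.chrom, int(st), int(st) + frag_len)
                    for st in starts
                )
        peak_sets.append(PeakSet(sample_id=s, regions=peaks))
        fragments[s] = frags

    # --- gene models --------------------------------------------------------
    anchor_idx = list(near_anchor_idx) + list(far_anchor_idx)
    gene_rows = []
    for gi, ridx in enumerate(anchor_idx):
        r = regions[ridx]
        strand = "+" if gi % 2 == 0 else "-"
        body_len = int(rng.integers(2000, 8000))
        if strand == "+":
            start = r.start - 200
            end = start + body_len
        else:
            end = r.end + 200
            start = end - body_len
        gene_rows.append(
            {
                "gene_id": f"G{gi+1:03d}",
                "chrom": r.chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "anchor_region": r.region_id,
            }
        )
    gene_models = pd.DataFrame(gene_rows)
    gene_models["tss"] = np.where(
        gene_models["strand"] == "+", gene_models["start"], gene_models["end"] - 1
    )

    # --- footprints --------------------------------------------------------
    n_tfs, sites_range, (beta_a, beta_b) = spec.footprint_spec
    n_decoy = n_tfs // 2
    n_planted = n_tfs - n_decoy
    planted_edges = []
    fp_rows = []

    def draw_purity(n: int) -> np.ndarray:
        return 0.5 + 0.5 * rng.beta(beta_a, beta_b, size=n)

    for ti in range(n_planted):
        tf = f"TF{ti+1:02d}"
        gene = gene_rows[ti]  # anchored near-gene on the first chromosome
        target_region = regions[near_anchor_idx[ti]]
        n_sites = int(rng.integers(*sites_range))
        purities = draw_purity(n_sites)
        starts = rng.integers(
            target_region.start, target_region.end - SITE_WIDTH, size=n_sites
        )
        for st, pu in zip(starts, purities):
            fp_rows.append(
                {
                    "tf": tf,
                    "chrom": target_region.chrom,
                    "start": int(st),
                    "end": int(st) + SITE_WIDTH,
                    "purity": float(pu),
                }
            )
        planted_edges.append((tf, gene["gene_id"]))

    decoy_tfs = []
    for ti in range(n_decoy):
        tf = f"TF{n_planted+ti+1:02d}"
        decoy_tfs.append(tf)
        n_sites = int(rng.integers(*sites_range))
        purities = draw_purity(n_sites)
        region_pick = rng.integers(0, len(decoy_idx), size=n_sites)
        for k in range(n_sites):
            r = regions[decoy_idx[int(region_pick[k])]]
            st = int(rng.integers(r.start, r.end - SITE_WIDTH))
            fp_rows.append(
                {
                    "tf": tf,
                    "chrom": r.chrom,
                    "start": st,
                    "end": st + SITE_WIDTH,
                    "purity": float(purities[k]),
                }
            )
    footprints = pd.DataFrame(fp_rows)

    # --- assemble -----------------------------------------------------------
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": [patient_of[s] for s in sample_ids],
            "ighv_homology_percent": [round(homology[s], 2) for s in sample_ids],
        }
    )
    region_roles = {}
    for i, r in enumerate(regions):
        if i in specific_of:
            role = "sample_specific"
        elif i in set(variable_idx):
            role = "variable"
        else:
            role = "core"
        region_roles[r.region_id] = role

    expected_params = {}
    for ridx in sorted(set(signature_idx) | set(diffvar_idx)):
        rid = regions[ridx].region_id
        expected_params[rid] = {
            "mu_mutated": expected_mu(ridx, "mutated"),
            "mu_unmutated": expected_mu(ridx, "unmutated"),
            "mu_intermediate": expected_mu(ridx, "intermediate"),
            "disp_mutated": expected_alpha(ridx, "mutated"),
            "disp_unmutated": expected_alpha(ridx, "unmutated"),
        }

    ground_truth = {
        "labels": label_of,
        "patients": patient_of,
        "signature_regions": {
            regions[i].region_id: sig_direction[i] for i in signature_idx
        },
        "diffvar_regions": {
            regions[i].region_id: dv_direction[i] for i in diffvar_idx
        },
        "planted_edges": planted_edges,
        "decoy_tfs": decoy_tfs,
        "region_roles": region_roles,
        "expected_params": expected_params,
        "baseline_mean_per_region": {
            regions[i].region_id: float(base_mu[i]) for i in range(len(regions))
        },
        "background_mean": BACKGROUND_MEAN,
        "dispersion": spec.dispersion,
        "totals": {s: len(fragments[s]) for s in sample_ids},
    }
    return SyntheticCohort(
        spec=spec,
        peak_sets=peak_sets,
        fragments=fragments,
        sample_sheet=sheet,
        gene_models=gene_models,
        footprints=footprints,
        ground_truth=ground_truth,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | os.PathLike) -> dict:
    """Write all cohort artifacts as plain text; returns the file manifest.

    Peak and fragment BEDs are 0-based half-open; the sample sheet, gene
    models and footprint table are TSV with a header row; ground truth is
    JSON.
    """
    d = Path(directory)
    (d / "peaks").mkdir(parents=True, exist_ok=True)
    (d / "fragments").mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"peaks": {}, "fragments": {}}
    for ps in cohort.peak_sets:
        p = d / "peaks" / f"{ps.sample_id}.bed"
        aio.write_bed(ps.regions, p)
        manifest["peaks"][ps.sample_id] = str(p)
    for sid, frags in cohort.fragments.items():
        p = d / "fragments" / f"{sid}.bed"
        aio.write_bed(frags, p)
        manifest["fragments"][sid] = str(p)
    sheet_path = d / "sample_sheet.tsv"
    aio.write_sample_sheet(cohort.sample_sheet, sheet_path)
    genes_path = d / "genes.tsv"
    aio.write_gene_models(cohort.gene_models, genes_path)
    fp_path = d / "footprints.tsv"
    aio.write_footprints(cohort.footprints, fp_path)
    gt_path = d / "ground_truth.json"
    with open(gt_path, "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True)
    manifest.update(
        {
            "sample_sheet": str(sheet_path),
            "gene_models": str(genes_path),
            "footprints": str(fp_path),
            "ground_truth": str(gt_path),
        }
    )
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
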