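"""Disease-subtype analysis: IGHV labels, differential variability,
patient-aware cross-validated classification, signature extraction,
clustering and PCA.

Samples are labelled mutated/unmutated from IGHV germline homology (>98%
homology = unmutated).  Group-wise differential variability uses a
two-sided F test on per-region sample variances with Bonferroni control.
Subtype classification trains a random forest under leave-one-out
cross-validation in which every sample sharing the test sample's patient is
also withheld from training, so repeated samples from one patient can never
leak across the fold boundary.  Signature regions are those whose Gini
importance, averaged over folds, exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

IGHV_HOMOLOGY_THRESHOLD = 98.0
BONFERRONI_ALPHA = 0.05
MEAN_CUTOFF = 1.0
IMPORTANCE_THRESHOLD = 1e-4

DEFAULT_MODEL_CONFIG = {
    "n_estimators": 500,
    "max_depth": None,
    "max_features": "sqrt",
}


def ighv_labels(
    sheet: pd.DataFrame, threshold: float = IGHV_HOMOLOGY_THRESHOLD
) -> pd.Series:
    """Label samples mutated/unmutated/unknown from IGHV germline homology.

    Homology strictly above the threshold (default 98%) means the gene is
    close to germline, i.e. unmutated; at or below means mutated; missing
    values give 'unknown' and are excluded downstream.
    """
    hom = sheet.set_index("sample_id")["ighv_homology_percent"]
    present = hom.dropna()
    if ((present < 0) | (present > 100)).any():
        bad = present[(present < 0) | (present > 100)]
        raise ValueError(f"homology values outside [0,100]: {bad.to_dict()}")
    labels = pd.Series("unknown", index=hom.index, name="label")
    labels[present.index[present > threshold]] = "unmutated"
    labels[present.index[present <= threshold]] = "mutated"
    return labels


@dataclass
class DifferentialVariabilityResult:
    table: pd.DataFrame  # per-region F, p, p_bonferroni, variances, mean, flags
    n_tested: int
    group_names: tuple[str, str]

    def significant(self, group: str) -> pd.Index:
        """Regions significantly more variable in ``group``."""
        t = self.table
        higher = t["higher_variance_group"] == group
        return t.index[t["significant"] & higher]


def differential_variability(
    values: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "mutated",
    group_b: str = "unmutated",
    alpha: float = BONFERRONI_ALPHA,
    mean_cutoff: float = MEAN_CUTOFF,
) -> DifferentialVariabilityResult:
    """Two-sided F test of per-region variance between two sample groups.

    F = s_a^2 / s_b^2 with (n_a-1, n_b-1) df; p = 2*min(P(F>=f), P(F<=f))
    capped at 1; Bonferroni over regions actually tested.  Significant
    regions require adjusted p < alpha AND overall mean > mean_cutoff, and
    are attributed to the group with the larger variance.  Regions with zero
    variance in both groups are skipped (flagged); zero variance in one
    group gives the limiting p (0) with a flag.
    """
    a_samples = labels.index[labels == group_a]
    b_samples = labels.index[labels == group_b]
    a_samples = [s for s in a_samples if s in values.columns]
    b_samples = [s for s in b_samples if s in values.columns]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("both groups need >=2 samples")
    xa = values[a_samples].to_numpy(dtype=float)
    xb = values[b_samples].to_numpy(dtype=float)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    overall_mean = values[a_samples + b_samples].mean(axis=1).to_numpy()

    both_zero = (va == 0) & (vb == 0)
    one_zero = ((va == 0) | (vb == 0)) & ~both_zero
    dfa, dfb = len(a_samples) - 1, len(b_samples) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = va / vb
    p = np.full(len(values), np.nan)
    ok = ~both_zero & ~one_zero
    fdist = scipy.stats.f(dfa, dfb)
    p[ok] = np.minimum(1.0, 2 * np.minimum(fdist.sf(f[ok]), fdist.cdf(f[ok])))
    p[one_zero] = 0.0  # limiting value of the two-sided tail
    n_tested = int(np.sum(~both_zero))
    p_bonf = np.minimum(1.0, p * n_tested)

    higher = np.where(va > vb, group_a, group_b)
    significant = (~both_zero) & (p_bonf < alpha) & (overall_mean > mean_cutoff)
    table = pd.DataFrame(
        {
            "F": f,
            "p_value": p,
            "p_bonferroni": p_bonf,
            f"var_{group_a}": va,
            f"var_{group_b}": vb,
            "mean": overall_mean,
            "higher_variance_group": higher,
            "significant": significant,
            "flag_both_zero": both_zero,
            "flag_one_zero": one_zero,
        },
        index=values.index,
    )
    return DifferentialVariabilityResult(
        table=table, n_tested=n_tested, group_names=(group_a, group_b)
    )


@dataclass
class ClassifierResult:
    scores: pd.Series  # out-of-fold probability of the positive class
    labels: pd.Series  # true labels of scored samples
    positive_label: str
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    operating_point: dict  # sensitivity, specificity at top-left-closest point
    importances: pd.Series  # per-region mean Gini importance over folds
    fold_map: dict[str, list[str]]  # test sample -> training samples
    model_config: dict = field(default_factory=dict)


class SmallCohortError(ValueError):
    """A cross-validation fold lost one of the two classes from training."""


def _loocv_scores(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: list[str],
    patients: pd.Series,
    positive_label: str,
    model_config: dict,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, dict[str, list[str]]]:
    """One pass of patient-aware LOOCV; returns scores, mean importances,
    and the fold map (test sample -> training sample IDs).

    The out-of-fold score is the positive-class probability centered on the
    training fold's positive-class prior (then mapped affinely into [0,1]):
    leaving a sample out leaves the training class balance anti-correlated
    with its own label, which at small cohort sizes biases raw-probability
    scores — and shuffled-label null AUCs — below chance.  Centering removes
    that composition component while leaving within-fold ranks untouched.
    """
    n = len(sample_ids)
    scores = np.empty(n)
    importances = np.zeros((n, X.shape[1]))
    fold_map: dict[str, list[str]] = {}
    pat = patients.reindex(sample_ids).to_numpy()
    for i in range(n):
        train = np.array([j for j in range(n) if pat[j] != pat[i]])
        classes = set(y[train])
        if len(classes) < 2:
            raise SmallCohortError(
                f"training fold for sample {sample_ids[i]} has classes {classes}"
            )
        clf = RandomForestClassifier(random_state=seed + i, **model_config)
        clf.fit(X[train], y[train])
        pos_col = list(clf.classes_).index(positive_label)
        proba = clf.predict_proba(X[i : i + 1])[0, pos_col]
        prior = float(np.mean(y[train] == positive_label))
        scores[i] = 0.5 + (proba - prior) / 2
        importances[i] = clf.feature_importances_
        fold_map[sample_ids[i]] = [sample_ids[j] for j in train]
    return scores, importances.mean(axis=0), fold_map


def roc_and_auc(
    scores: pd.Series, labels: pd.Series, positive_label: str = "unmutated"
) -> tuple[pd.DataFrame, float, dict]:
    """ROC by threshold sweep; AUC by trapezoidal integration (equal to the
    Mann-Whitney concordance probability with ties counted 1/2); operating
    point closest to (FPR 0, TPR 1) in Euclidean distance."""
    y = labels.reindex(scores.index)
    pos = scores[y == positive_label].to_numpy()
    neg = scores[y != positive_label].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        tpr[k] = np.mean(pos >= t)
        fpr[k] = np.mean(neg >= t)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    # trapezoidal area under the sweep curve; ties produce diagonal segments,
    # so this equals the Mann-Whitney probability with ties counted 1/2
    auc = np.trapezoid(tpr, fpr)
    d = np.sqrt(fpr**2 + (1 - tpr) ** 2)
    k = int(np.argmin(d))
    operating = {
        "sensitivity": float(tpr[k]),
        "specificity": float(1 - fpr[k]),
        "threshold": float(thresholds[k]),
    }
    return roc, float(auc), operating


def patient_aware_loocv(
    values: pd.DataFrame,
    labels: pd.Series,
    patients: pd.Series,
    model_config: dict | None = None,
    seed: int = 0,
    positive_label: str = "unmutated",
) -> ClassifierResult:
    """Leave-one-out cross-validation excluding the test sample's patient.

    For each labelled sample a random forest is trained on all labelled
    samples except those sharing the test sample's patient_id; out-of-fold
    class probabilities give the ROC/AUC, and Gini importances are averaged
    over folds.
    """
    config = dict(DEFAULT_MODEL_CONFIG if model_config is None else model_config)
    labelled = [
        s for s in values.columns if labels.get(s) in ("mutated", "unmutated")
    ]
    y = labels.reindex(labelled).to_numpy()
    for cls in ("mutated", "unmutated"):
        if np.sum(y == cls) < 2:
            raise ValueError(f"need >=2 samples of class {cls!r}")
    X = values[labelled].to_numpy(dtype=float).T  # samples x regions
    s, imp, fold_map = _loocv_scores(
        X, y, labelled, patients, positive_label, config, seed
    )
    scores = pd.Series(s, index=labelled, name="score")
    roc, auc, operating = roc_and_auc(scores, labels, positive_label)
    return ClassifierResult(
        scores=scores,
        labels=labels.reindex(labelled),
        positive_label=positive_label,
        roc=roc,
        auc=auc,
        operating_point=operating,
        importances=pd.Series(imp, index=values.index, name="importance"),
        fold_map=fold_map,
        model_config=config,
    )


@dataclass
class NullDistribution:
    auc_values: np.ndarray
    n_permutations: int
    seed: int
    failures: list[str] = field(default_factory=list)


def shuffled_label_null(
    values: pd.DataFrame,
    labels: pd.Series,
    patients: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
    model_config: dict | None = None,
    positive_label: str = "unmutated",
) -> NullDistribution:
    """AUC distribution under label shuffling.

    Labels are permuted across samples before each repetition (the patient
    structure is kept for fold exclusion) and the full patient-aware LOOCV
    is rerun.  Folds that lose a class under some permutation are recorded
    as failures and the remaining permutations continue.
    """
    config = dict(DEFAULT_MODEL_CONFIG if model_config is None else model_config)
    labelled = [
        s for s in values.columns if labels.get(s) in ("mutated", "unmutated")
    ]
    X = values[labelled].to_numpy(dtype=float).T
    y0 = labels.reindex(labelled).to_numpy()
    rng = np.random.default_rng(seed)
    aucs = []
    failures = []
    for perm in range(n_permutations):
        y = y0[rng.permutation(len(y0))]
        try:
            s, _, _ = _loocv_scores(
                X, y, labelled, patients, positive_label, config, seed + 1000 + perm
            )
        except SmallCohortError as exc:
            failures.append(f"permutation {perm}: {exc}")
            continue
        pos = s[y == positive_label]
        neg = s[y != positive_label]
        gt = (pos[:, None] > neg[None, :]).sum()
        eq = (pos[:, None] == neg[None, :]).sum()
        aucs.append((gt + 0.5 * eq) / (len(pos) * len(neg)))
    return NullDistribution(
        auc_values=np.array(aucs),
        n_permutations=n_permutations,
        seed=seed,
        failures=failures,
    )


@dataclass
class SignatureRegions:
    region_ids: pd.Index
    directions: pd.Series  # which subtype has the higher group mean
    clusters: pd.Series  # 1 = mutated-accessible, 2 = unmutated-accessible
    threshold: float


def extract_signature(
    result: ClassifierResult,
    values: pd.DataFrame,
    labels: pd.Series,
    importance_threshold: float = IMPORTANCE_THRESHOLD,
) -> SignatureRegions:
    """Regions with fold-averaged Gini importance above the threshold,
    directed by comparing group means on the normalized layer."""
    keep = result.importances.index[result.importances > importance_threshold]
    mut = [s for s in values.columns if labels.get(s) == "mutated"]
    unmut = [s for s in values.columns if labels.get(s) == "unmutated"]
    mean_mut = values.loc[keep, mut].mean(axis=1)
    mean_unmut = values.loc[keep, unmut].mean(axis=1)
    directions = pd.Series(
        np.where(mean_mut >= mean_unmut, "mutated", "unmutated"),
        index=keep,
        name="direction",
    )
    clusters = pd.Series(
        np.where(directions == "mutated", 1, 2), index=keep, name="cluster"
    )
    return SignatureRegions(
        region_ids=keep,
        directions=directions,
        clusters=clusters,
        threshold=importance_threshold,
    )


def cluster_samples(
    values: pd.DataFrame, k: int = 4
) -> tuple[pd.Series, list[str]]:
    """Average-linkage hierarchical clustering of samples on 1 - Pearson
    correlation over the supplied (signature) regions; cut to k clusters.

    Returns the per-sample cluster assignment and the dendrogram leaf order.
    """
    if values.shape[1] < k:
        raise ValueError(f"need >= k={k} samples")
    if values.empty:
        raise ValueError("empty region set")
    sds = values.std(axis=0, ddof=0)
    constant = sds.index[sds == 0]
    if len(constant):
        raise ValueError(
            f"constant profile (undefined correlation) for samples: {list(constant)}"
        )
    corr = np.corrcoef(values.to_numpy(dtype=float).T)
    dist = 1 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=k, criterion="maxclust")
    order = [values.columns[i] for i in leaves_list(Z)]
    return pd.Series(assign, index=values.columns, name="cluster"), order


def pca_projection(
    values: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples over regions.

    Returns per-sample coordinates (samples x components) and the
    explained-variance fractions.
    """
    X = values.to_numpy(dtype=float).T  # samples x regions
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >=2 samples and >=2 regions")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: no variance across samples")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_
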