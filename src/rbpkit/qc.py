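"""Experiment-level quality control: features, classifier, triage.

An experiment is summarized by an 83-dimensional feature vector built
from its Set A / Set B 7-mer Z-score tables and motifs: the A-vs-B
Z-score correlation, the top-ten overlap, the individual top-ten Z-scores
of each set, skewness and kurtosis of the two Z distributions, the
highest merged-set Z, per-artifact counts of top-ten 7-mers containing
each of 26 recurrent artifact k-mers (plus their sum), the information
content of each set's motif, and the similarity between the two motifs.

A logistic regression with L1 (LASSO) regularization is trained on
labeled pass/fail collections; its probability is triaged with the
0.35/0.65 band: <= 0.35 fail, >= 0.65 pass, anything between routed to
manual review.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .kmers import KmerUniverse, default_universe
from .motifs import PFM, build_motif, compare_motifs, information_content
from .pool import ProbePool
from .scoring import (
    IntensityProfile,
    KmerTable,
    ab_diagnostics,
    compute_kmer_zscores,
    normalize_intensities,
)

# Recurrent artifact k-mers (lengths 4-7).  The canonical artifact list is
# not published; this is a synthetic placeholder assembled from the usual
# suspects (G-rich runs, GA-rich repeats, homopolymers, UG repeats, and
# SapI-site-derived fragments).  Supply your own list for real data.
ARTIFACT_KMERS: tuple[str, ...] = (
    "GGGG", "GGGGG", "GGGGGG", "GGGGGGG",
    "GGAG", "GAGG", "GGAGG", "GAGGA", "GAAGA", "AGGAGG",
    "UUUU", "UUUUU", "UUUUUU", "UUUUUUU",
    "AAAA", "AAAAA", "AAAAAA", "AAAAAAA",
    "UGUG", "GUGU", "UGUGUGU",
    "GCUCUUC", "CGAGAAG", "CUCUUC", "GAGAAG", "UCUUC",
)
assert len(ARTIFACT_KMERS) == 26

FAIL_MAX = 0.35
PASS_MIN = 0.65


def _validate_artifacts(artifacts) -> list[str]:
    artifacts = list(artifacts)
    for a in artifacts:
        if not 4 <= len(a) <= 7:
            raise ValueError(f"artifact k-mer {a!r} must have length 4-7")
    return artifacts


def feature_names(artifacts=ARTIFACT_KMERS) -> list[str]:
    names = ["ab_pearson", "top10_overlap"]
    names += [f"top_z_a_{i + 1}" for i in range(10)]
    names += [f"top_z_b_{i + 1}" for i in range(10)]
    names += ["skew_a", "skew_b", "kurt_a", "kurt_b", "max_merged_z"]
    names += [f"artifact_{a}_a" for a in artifacts]
    names += [f"artifact_{a}_b" for a in artifacts]
    names += ["artifact_sum", "ic_a", "ic_b", "motif_similarity"]
    return names


@dataclass
class ExperimentFeatures:
    """The classifier's feature vector for one experiment."""

    ab_pearson: float
    top10_overlap: int
    top10_z_a: np.ndarray
    top10_z_b: np.ndarray
    skew_a: float
    skew_b: float
    kurt_a: float
    kurt_b: float
    max_merged_z: float
    artifact_counts: np.ndarray  # (n_artifacts, 2): per k-mer, set A and B
    artifact_sum: int
    ic_a: float
    ic_b: float
    motif_similarity: float
    artifacts: tuple[str, ...] = ARTIFACT_KMERS

    def __post_init__(self) -> None:
        self.top10_z_a = np.asarray(self.top10_z_a, dtype=float)
        self.top10_z_b = np.asarray(self.top10_z_b, dtype=float)
        self.artifact_counts = np.asarray(self.artifact_counts, dtype=int)
        if self.top10_z_a.size != 10 or self.top10_z_b.size != 10:
            raise ValueError("top10 Z vectors must have length 10")
        if self.artifact_counts.shape != (len(self.artifacts), 2):
            raise ValueError("artifact_counts must be (n_artifacts, 2)")
        if (self.artifact_counts < 0).any() or (self.artifact_counts > 10).any():
            raise ValueError("artifact counts must lie in [0, 10]")
        if self.artifact_sum != int(self.artifact_counts.sum()):
            raise ValueError("artifact_sum must equal artifact_counts.sum()")

    def names(self) -> list[str]:
        return feature_names(self.artifacts)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.ab_pearson, self.top10_overlap],
                self.top10_z_a,
                self.top10_z_b,
                [self.skew_a, self.skew_b, self.kurt_a, self.kurt_b, self.max_merged_z],
                self.artifact_counts[:, 0],
                self.artifact_counts[:, 1],
                [self.artifact_sum, self.ic_a, self.ic_b, self.motif_similarity],
            ]
        ).astype(float)


def extract_features(
    table_a: KmerTable,
    table_b: KmerTable,
    table_merged: KmerTable,
    motif_a: PFM,
    motif_b: PFM,
    artifacts=ARTIFACT_KMERS,
    compare_seed: int = 0,
) -> ExperimentFeatures:
    """Compute the feature vector from per-set tables and motifs."""
    artifacts = _validate_artifacts(artifacts)
    r, overlap = ab_diagnostics(table_a, table_b)
    top_a, z_a = table_a.top(10)
    top_b, z_b = table_b.top(10)
    counts = np.zeros((len(artifacts), 2), dtype=int)
    for i, art in enumerate(artifacts):
        counts[i, 0] = sum(art in w for w in top_a)
        counts[i, 1] = sum(art in w for w in top_b)
    sim, _, _ = compare_motifs(motif_a, motif_b, n_null=0, seed=compare_seed)
    return ExperimentFeatures(
        ab_pearson=r,
        top10_overlap=overlap,
        top10_z_a=z_a,
        top10_z_b=z_b,
        skew_a=float(stats.skew(table_a.zscores)),
        skew_b=float(stats.skew(table_b.zscores)),
        kurt_a=float(stats.kurtosis(table_a.zscores)),
        kurt_b=float(stats.kurtosis(table_b.zscores)),
        max_merged_z=float(table_merged.zscores.max()),
        artifact_counts=counts,
        artifact_sum=int(counts.sum()),
        ic_a=information_content(motif_a)[0],
        ic_b=information_content(motif_b)[0],
        motif_similarity=sim,
        artifacts=tuple(artifacts),
    )


def profile_features(
    pool: ProbePool,
    profile: IntensityProfile,
    universe: KmerUniverse | None = None,
    artifacts=ARTIFACT_KMERS,
    trim_fraction: float = 0.025,
) -> ExperimentFeatures:
    """Full pipeline from a raw intensity profile to classifier features."""
    if universe is None:
        universe = default_universe(7)
    norm = normalize_intensities(profile)
    t_a = compute_kmer_zscores(norm, pool, "A", universe, trim_fraction)
    t_b = compute_kmer_zscores(norm, pool, "B", universe, trim_fraction)
    t_m = compute_kmer_zscores(norm, pool, "merged", universe, trim_fraction)
    m_a = build_motif(t_a, name="setA")
    m_b = build_motif(t_b, name="setB")
    return extract_features(t_a, t_b, t_m, m_a, m_b, artifacts)


# ---------------------------------------------------------------------------
# classifier


def auroc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the Mann-Whitney rank statistic (midranks for ties)."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes")
    r = stats.rankdata(scores)
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class TrainedClassifier:
    """A fitted L1 logistic model with its scaler and triage thresholds."""

    feature_names_all: list[str]
    kept_features: list[str]
    weights: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    l1_strength: float  # sklearn C (inverse regularization strength)
    triage_band: tuple[float, float] = (FAIL_MAX, PASS_MIN)
    training_meta: dict = field(default_factory=dict)
    version: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=float)
        self.scaler_scale = np.asarray(self.scaler_scale, dtype=float)
        if not (
            len(self.kept_features)
            == self.weights.size
            == self.scaler_mean.size
            == self.scaler_scale.size
        ):
            raise ValueError("kept feature names and weight/scaler sizes differ")
        if not self.triage_band[0] <= self.triage_band[1]:
            raise ValueError("triage band must be ordered")

    def predict_proba(self, features: "ExperimentFeatures") -> float:
        names = features.names()
        if names != self.feature_names_all:
            raise ValueError("feature names do not match the trained model")
        vec = features.to_vector()
        idx = [names.index(f) for f in self.kept_features]
        x = (vec[idx] - self.scaler_mean) / self.scaler_scale
        logit = float(self.weights @ x + self.intercept)
        return 1.0 / (1.0 + np.exp(-logit))

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "feature_names_all": self.feature_names_all,
            "kept_features": self.kept_features,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "l1_strength": self.l1_strength,
            "triage_band": list(self.triage_band),
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrainedClassifier":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names_all=d["feature_names_all"],
            kept_features=d["kept_features"],
            weights=np.array(d["weights"]),
            intercept=d["intercept"],
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_scale=np.array(d["scaler_scale"]),
            l1_strength=d["l1_strength"],
            triage_band=tuple(d["triage_band"]),
            training_meta=d.get("training_meta", {}),
            version=d.get("version", 1),
        )


def _fit_l1(X: np.ndarray, y: np.ndarray, C: float, seed: int) -> LogisticRegression:
    return LogisticRegression(
        penalty="l1", C=C, solver="liblinear", max_iter=1000, tol=1e-6,
        random_state=seed,
    ).fit(X, y)


def train_classifier(
    collection,
    holdout_fraction: float = 40 / 471,
    seed: int = 0,
    c_grid: np.ndarray | None = None,
    n_folds: int = 5,
) -> tuple[TrainedClassifier, float]:
    """Train the pass/fail model and report held-out AUROC.

    ``collection`` is a sequence of ``(ExperimentFeatures, label)`` with
    labels in {"pass", "fail"}.  A class-balanced holdout (by default 40
    experiments, 20 per class, mirroring the curated split) is set aside
    before any fitting or selection; the L1 strength is chosen by seeded
    stratified 5-fold cross-validation on the remainder, maximizing mean
    validation AUROC (ties prefer the stronger regularization).  Features
    are z-scaled with training-set statistics only; constant features are
    dropped with a warning.
    """
    feats, labels = zip(*collection)
    bad = set(labels) - {"pass", "fail"}
    if bad:
        raise ValueError(f"labels must be 'pass' or 'fail', got {sorted(bad)}")
    y = np.array([1 if l == "pass" else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("training collection must contain both classes")
    names = feats[0].names()
    for f in feats:
        if f.names() != names:
            raise ValueError("inconsistent feature definitions in collection")
    X = np.stack([f.to_vector() for f in feats])

    rng = np.random.default_rng(seed)
    n_hold_pc = int(round(holdout_fraction * y.size / 2))
    hold_idx: list[int] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        if n_hold_pc >= cls_idx.size:
            raise ValueError("holdout would consume an entire class")
        hold_idx.extend(rng.permutation(cls_idx)[:n_hold_pc].tolist())
    hold = np.zeros(y.size, dtype=bool)
    hold[hold_idx] = True
    X_tr, y_tr = X[~hold], y[~hold]
    X_ho, y_ho = X[hold], y[hold]

    sd = X_tr.std(axis=0)
    kept = sd > 0
    if not kept.all():
        dropped = [n for n, k in zip(names, kept) if not k]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    kept_names = [n for n, k in zip(names, kept) if k]
    X_tr = X_tr[:, kept]
    X_ho = X_ho[:, kept]

    if c_grid is None:
        c_grid = np.logspace(-3, 3, 13)
    sk_seed = seed % (2**31)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=sk_seed)
    folds = list(skf.split(X_tr, y_tr))
    mean_auc = []
    for C in c_grid:
        aucs = []
        for tr, va in folds:
            mu, sig = X_tr[tr].mean(axis=0), X_tr[tr].std(axis=0)
            sig = np.where(sig > 0, sig, 1.0)
            model = _fit_l1((X_tr[tr] - mu) / sig, y_tr[tr], C, sk_seed)
            p = model.predict_proba((X_tr[va] - mu) / sig)[:, 1]
            aucs.append(auroc_rank(y_tr[va], p))
        mean_auc.append(np.mean(aucs))
    mean_auc = np.asarray(mean_auc)
    best_c = float(c_grid[int(np.argmax(mean_auc))])  # argmax: first = smallest C

    mu, sig = X_tr.mean(axis=0), X_tr.std(axis=0)
    sig = np.where(sig > 0, sig, 1.0)
    final = _fit_l1((X_tr - mu) / sig, y_tr, best_c, sk_seed)
    p_ho = final.predict_proba((X_ho - mu) / sig)[:, 1]
    auroc = auroc_rank(y_ho, p_ho)

    model = TrainedClassifier(
        feature_names_all=names,
        kept_features=kept_names,
        weights=final.coef_[0],
        intercept=float(final.intercept_[0]),
        scaler_mean=mu,
        scaler_scale=sig,
        l1_strength=best_c,
        training_meta={
            "n_pass": int(y.sum()),
            "n_fail": int((1 - y).sum()),
            "n_holdout": int(hold.sum()),
            "seed": seed,
            "cv_mean_auroc": mean_auc.tolist(),
            "c_grid": np.asarray(c_grid).tolist(),
            "similarity_metric": "mean column Pearson at best ungapped offset",
        },
    )
    return model, auroc


# ---------------------------------------------------------------------------
# triage


@dataclass
class TriageResult:
    probability: float
    label: str  # pass / fail / uncertain

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


def triage(probability: float, fail_max: float = FAIL_MAX, pass_min: float = PASS_MIN) -> TriageResult:
    """Map a classifier probability to pass / fail / uncertain.

    Exact threshold hits follow the band's closed ends: <= fail_max is a
    fail, >= pass_min a pass.
    """
    if probability <= fail_max:
        label = "fail"
    elif probability >= pass_min:
        label = "pass"
    else:
        label = "uncertain"
    return TriageResult(probability, label)


def classify(model: TrainedClassifier, features: ExperimentFeatures) -> TriageResult:
    """Apply a trained model and triage the probability."""
    p = model.predict_proba(features)
    return triage(p, *model.triage_band)


def resolve_replicates(results) -> str:
    """Consensus over replicate triage calls for one protein.

    Unanimous pass or fail resolves automatically; any disagreement, or
    any uncertain call, is flagged for manual review rather than silently
    auto-resolved.
    """
    labels = [r.label for r in results]
    if not labels:
        raise ValueError("need at least one replicate result")
    if all(l == labels[0] for l in labels) and labels[0] in ("pass", "fail"):
        return labels[0]
    return "manual_review"
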