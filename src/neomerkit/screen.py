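"""Liquid-biopsy screening: panel k-mer counting and stacked-ensemble CV.

Reads (cfDNA/cfRNA FASTQ) are scanned for panel k-mers; occurrence counts are
CPM-normalized, control-noisy features are removed (a feature is dropped when
more than 40% of control samples exceed a raw-count threshold — 20 for RNA,
500 for DNA), the minority class is SMOTE-oversampled inside each training
fold, and a stacked ensemble is trained: per-modality base learners (RNA:
class-balanced logistic regression + gradient-boosted trees; DNA: random
forest + gradient-boosted trees) feed out-of-fold probabilities into a
logistic-regression meta-learner.  Performance is reported as stratified
5-fold cross-validated ROC-AUC and PR-AUC.

All preprocessing (filtering, scaling, oversampling) is fitted strictly
inside training folds; held-out samples are only ever transformed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MaxAbsScaler, StandardScaler

from . import kmers
from .errors import ConfigurationError, FormatError, ParameterError
from .panel import NeomerPanel
from .provenance import read_tsv_with_header, write_tsv_with_header

logger = logging.getLogger(__name__)

MODALITIES = ("DNA", "RNA")


@dataclass
class SampleMeta:
    sample_id: str
    label: str  # "case" | "control"
    modality: str  # "DNA" | "RNA"

    def __post_init__(self) -> None:
        if self.label not in ("case", "control"):
            raise ParameterError(f"label must be case/control, got {self.label!r}")
        if self.modality not in MODALITIES:
            raise ParameterError(f"modality must be DNA/RNA, got {self.modality!r}")


@dataclass
class FeatureFilterSpec:
    """Control-based noise filter: drop features that controls express.

    A feature is removed iff strictly more than ``control_fraction`` of the
    control samples have a raw count strictly above ``count_threshold``.
    """

    count_threshold: int
    control_fraction: float = 0.40

    RNA_DEFAULT_THRESHOLD = 20
    DNA_DEFAULT_THRESHOLD = 500

    @classmethod
    def for_rna(cls) -> "FeatureFilterSpec":
        return cls(cls.RNA_DEFAULT_THRESHOLD)

    @classmethod
    def for_dna(cls) -> "FeatureFilterSpec":
        return cls(cls.DNA_DEFAULT_THRESHOLD)

    def __post_init__(self) -> None:
        if self.count_threshold < 0:
            raise ParameterError("count_threshold must be >= 0")
        if not 0.0 <= self.control_fraction <= 1.0:
            raise ParameterError("control_fraction must lie in [0, 1]")


@dataclass
class CountMatrix:
    """Samples x panel-k-mers occurrence counts for one modality."""

    modality: str
    samples: list[SampleMeta]
    features: list[str]
    counts: np.ndarray  # int, shape (n_samples, n_features)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.features)):
            raise ParameterError("count matrix dimensions are inconsistent")
        if (self.counts < 0).any():
            raise ParameterError("counts must be nonnegative")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate sample_id within a modality")

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if s.label == "case" else 0 for s in self.samples])

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_tsv(self, path: str | Path, provenance: dict | None = None) -> None:
        df = pd.DataFrame(self.counts, columns=self.features)
        df.insert(0, "sample_id", [s.sample_id for s in self.samples])
        df.insert(1, "label", [s.label for s in self.samples])
        meta = {"modality": self.modality}
        meta.update(provenance or {})
        write_tsv_with_header(df, path, meta)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df, meta = read_tsv_with_header(path)
        modality = meta.get("modality", "DNA")
        samples = [
            SampleMeta(str(sid), str(lab), modality)
            for sid, lab in zip(df["sample_id"], df["label"])
        ]
        features = [c for c in df.columns if c not in ("sample_id", "label")]
        counts = df[features].to_numpy(dtype=np.int64)
        return cls(modality, samples, features, counts)


def panel_features(panel: NeomerPanel) -> list[str]:
    """Deterministic feature order for a panel: sorted k-mer strings."""
    return sorted(panel.entries)


def _reads_iter(reads):
    if isinstance(reads, (str, Path)):
        path = str(reads)

        def gen():
            try:
                with pysam.FastxFile(path) as fh:
                    for i, rec in enumerate(fh):
                        yield rec.sequence or ""
            except OSError as exc:
                raise FormatError(f"unreadable FASTQ {path}: {exc}") from exc

        return gen()
    return iter(reads)


def count_panel_kmers(
    reads,
    features: list[str],
    k: int,
    canonical: bool = True,
    batch_bases: int = 4_000_000,
) -> np.ndarray:
    """Occurrence counts of panel k-mers in one read set.

    ``reads`` is a FASTQ path (plain or gzipped) or an iterable of read
    strings.  Every k-window of every read that matches a panel k-mer (up to
    reverse complement in canonical mode) increments that k-mer's count;
    windows containing N are skipped.  Occurrences are counted, not per-read
    presence.
    """
    if not features:
        raise ParameterError("panel is empty")
    codes = kmers.encode_kmers(features, k, canonicalize=canonical)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    if len(np.unique(sorted_codes)) != len(sorted_codes):
        raise ParameterError(
            "panel contains k-mers that collide under canonical encoding"
        )
    counts_sorted = np.zeros(len(features), dtype=np.int64)

    def flush(buf: list[str]) -> None:
        nonlocal counts_sorted
        if not buf:
            return
        # single N separators prevent windows from spanning read boundaries
        chunk = "N".join(buf)
        window_codes, valid = kmers.kmer_codes(chunk, k)
        c = window_codes[valid]
        if canonical and len(c):
            c = kmers.canonical_codes(c, k)
        pos = np.searchsorted(sorted_codes, c)
        inb = pos < len(sorted_codes)
        hit = np.zeros(len(c), dtype=bool)
        hit[inb] = sorted_codes[pos[inb]] == c[inb]
        if hit.any():
            counts_sorted += np.bincount(pos[hit], minlength=len(features))

    buf: list[str] = []
    size = 0
    for seq in _reads_iter(reads):
        buf.append(seq.upper())
        size += len(seq) + 1
        if size >= batch_bases:
            flush(buf)
            buf, size = [], 0
    flush(buf)
    counts = np.zeros(len(features), dtype=np.int64)
    counts[order] = counts_sorted
    return counts


def count_readsets(
    readsets: dict[str, object],
    sample_meta: list[SampleMeta],
    features: list[str],
    k: int,
    canonical: bool = True,
) -> CountMatrix:
    """Count panel k-mers across many samples into one CountMatrix."""
    rows = []
    for meta in sample_meta:
        rows.append(
            count_panel_kmers(readsets[meta.sample_id], features, k, canonical)
        )
    modality = sample_meta[0].modality if sample_meta else "DNA"
    return CountMatrix(modality, list(sample_meta), list(features), np.vstack(rows))


def cpm_normalize(counts: np.ndarray | CountMatrix) -> np.ndarray:
    """Counts-per-million: each row scaled to sum to 1e6.

    All-zero rows are emitted as zeros with a warning (no reads hit the
    panel), so downstream maths never divides by zero.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        logger.warning("cpm_normalize: %d sample(s) with zero total counts", zero.sum())
    safe = np.where(totals == 0, 1.0, totals)
    return counts / safe * 1e6


def filter_features(
    counts: np.ndarray,
    control_mask: np.ndarray,
    spec: FeatureFilterSpec,
) -> np.ndarray:
    """Boolean mask of retained features under the control-noise rule.

    Operates on raw counts; callers pass training-fold rows only so held-out
    samples never influence the filter.
    """
    counts = np.asarray(counts)
    control_mask = np.asarray(control_mask, dtype=bool)
    n_controls = int(control_mask.sum())
    if n_controls == 0:
        raise ConfigurationError("feature filter needs at least one control sample")
    exceed = (counts[control_mask] > spec.count_threshold).sum(axis=0) / n_controls
    return ~(exceed > spec.control_fraction)


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    duplicate_fallback: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance binary classes by SMOTE interpolation of the minority class.

    Synthetic points are convex combinations of a minority sample and one of
    its min(5, minority-1) nearest minority neighbors; originals come first
    in the output.  Deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ParameterError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(class_counts)]
    n_min, n_maj = class_counts.min(), class_counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    Xmin = X[y == minority]
    n_new = int(n_maj - n_min)
    if n_min == 1:
        if not duplicate_fallback:
            raise ParameterError(
                "minority class has a single sample; SMOTE cannot interpolate "
                "(pass duplicate_fallback=True to duplicate it instead)"
            )
        synth = np.repeat(Xmin, n_new, axis=0)
    else:
        k_nn = min(5, n_min - 1)
        nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(Xmin)
        _, nbr = nn.kneighbors(Xmin)
        base = rng.integers(0, n_min, size=n_new)
        pick = rng.integers(0, k_nn, size=n_new)
        gaps = rng.random(n_new)
        neighbors = nbr[base, 1 + pick]
        synth = Xmin[base] + gaps[:, None] * (Xmin[neighbors] - Xmin[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def _base_learners(seed: int) -> list[tuple[str, object, str]]:
    """(name, estimator, modality) triples for the four base models."""
    return [
        (
            "rna_logreg",
            LogisticRegression(class_weight="balanced", max_iter=5000, random_state=seed),
            "RNA",
        ),
        ("rna_gbdt", HistGradientBoostingClassifier(random_state=seed), "RNA"),
        ("dna_rf", RandomForestClassifier(random_state=seed, n_jobs=1), "DNA"),
        ("dna_gbdt", HistGradientBoostingClassifier(random_state=seed), "DNA"),
    ]


class StackedEnsemble:
    """Two-modality stacking classifier.

    RNA features are max-abs scaled, DNA features z-scored (both fitted on the
    training data).  The four base learners produce out-of-fold probabilities
    via an internal stratified 5-fold split; a logistic-regression meta-learner
    is fitted on those four probability columns, then the base learners are
    refitted on the full training data.
    """

    def __init__(self, seed: int = 0, inner_folds: int = 5):
        self.seed = int(seed)
        self.inner_folds = int(inner_folds)

    def fit(self, rna: np.ndarray, dna: np.ndarray, y: np.ndarray) -> "StackedEnsemble":
        rna, dna, y = np.asarray(rna, float), np.asarray(dna, float), np.asarray(y)
        if not (len(rna) == len(dna) == len(y)):
            raise ConfigurationError("RNA/DNA/label sample counts differ")
        if len(np.unique(y)) != 2:
            raise ConfigurationError("training labels must contain both classes")
        self.rna_scaler_ = MaxAbsScaler().fit(rna)
        self.dna_scaler_ = StandardScaler().fit(dna)
        scaled = {"RNA": self.rna_scaler_.transform(rna), "DNA": self.dna_scaler_.transform(dna)}
        inner = min(self.inner_folds, int(np.bincount(y).min()))
        cv = StratifiedKFold(n_splits=max(2, inner), shuffle=True, random_state=self.seed)
        self.base_ = _base_learners(self.seed)
        oof = np.column_stack(
            [
                cross_val_predict(
                    clone(est), scaled[mod], y, cv=cv, method="predict_proba"
                )[:, 1]
                for _, est, mod in self.base_
            ]
        )
        self.meta_ = LogisticRegression(max_iter=5000, random_state=self.seed).fit(oof, y)
        self.fitted_base_ = [
            (name, clone(est).fit(scaled[mod], y), mod) for name, est, mod in self.base_
        ]
        return self

    def _base_probabilities(self, rna: np.ndarray, dna: np.ndarray) -> np.ndarray:
        scaled = {
            "RNA": self.rna_scaler_.transform(np.asarray(rna, float)),
            "DNA": self.dna_scaler_.transform(np.asarray(dna, float)),
        }
        return np.column_stack(
            [est.predict_proba(scaled[mod])[:, 1] for _, est, mod in self.fitted_base_]
        )

    def predict_proba(self, rna: np.ndarray, dna: np.ndarray) -> np.ndarray:
        return self.meta_.predict_proba(self._base_probabilities(rna, dna))

    def base_learner_params(self) -> dict:
        return {
            name: {"class": type(est).__name__, "modality": mod, **_short_params(est)}
            for name, est, mod in _base_learners(self.seed)
        }


def _short_params(est) -> dict:
    keep = ("n_estimators", "max_iter", "learning_rate", "class_weight", "max_depth")
    return {k: v for k, v in est.get_params().items() if k in keep}


def train_stacked_ensemble(
    rna: np.ndarray, dna: np.ndarray, y: np.ndarray, seed: int = 0
) -> StackedEnsemble:
    """Fit the two-modality stacking classifier on preprocessed features."""
    return StackedEnsemble(seed=seed).fit(rna, dna, y)


@dataclass
class CVResult:
    """Stratified cross-validation metrics for the stacked ensemble."""

    roc_aucs: list[float]
    pr_aucs: list[float]
    fold_assignments: list[int]  # fold index per sample
    seed: int
    folds: int
    config: dict = field(default_factory=dict)
    fold_details: list[dict] = field(default_factory=list)

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self.roc_aucs))

    @property
    def std_roc_auc(self) -> float:
        return float(np.std(self.roc_aucs))

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.pr_aucs))

    @property
    def std_pr_auc(self) -> float:
        return float(np.std(self.pr_aucs))

    def to_dict(self) -> dict:
        return {
            "roc_auc_per_fold": self.roc_aucs,
            "pr_auc_per_fold": self.pr_aucs,
            "roc_auc_mean": self.mean_roc_auc,
            "roc_auc_std": self.std_roc_auc,
            "pr_auc_mean": self.mean_pr_auc,
            "pr_auc_std": self.std_pr_auc,
            "fold_assignments": self.fold_assignments,
            "seed": self.seed,
            "folds": self.folds,
            "config": self.config,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _check_matched(rna: CountMatrix, dna: CountMatrix) -> None:
    rna_ids = [(s.sample_id, s.label) for s in rna.samples]
    dna_ids = [(s.sample_id, s.label) for s in dna.samples]
    if rna_ids != dna_ids:
        raise ConfigurationError(
            "RNA and DNA matrices must cover the same samples in the same order"
        )


def cross_validate(
    rna: CountMatrix,
    dna: CountMatrix,
    folds: int = 5,
    seed: int = 0,
    rna_filter: FeatureFilterSpec | None = None,
    dna_filter: FeatureFilterSpec | None = None,
    use_smote: bool = True,
) -> CVResult:
    """Stratified k-fold evaluation of the full screening pipeline.

    Per fold: the control-noise filter is computed from training-fold raw
    counts, CPM values of retained features form the design matrices, SMOTE
    balances the training classes (jointly over the concatenated modalities so
    synthetic samples stay paired), and the stacked ensemble is fitted on the
    training fold only.  Held-out ROC-AUC and PR-AUC are recorded per fold.
    """
    _check_matched(rna, dna)
    rna_filter = rna_filter or FeatureFilterSpec.for_rna()
    dna_filter = dna_filter or FeatureFilterSpec.for_dna()
    y = rna.labels
    class_sizes = np.bincount(y, minlength=2)
    if class_sizes.min() < folds:
        raise ParameterError(
            f"smallest class has {class_sizes.min()} samples < {folds} folds; "
            "use fewer folds"
        )
    cpm_rna = cpm_normalize(rna.counts)
    cpm_dna = cpm_normalize(dna.counts)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignments = np.full(len(y), -1, dtype=int)
    roc_aucs, pr_aucs, details = [], [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignments[te] = fold
        controls_tr = y[tr] == 0
        if not controls_tr.any():
            raise ConfigurationError(f"fold {fold}: no control samples in training split")
        keep_r = filter_features(rna.counts[tr], controls_tr, rna_filter)
        keep_d = filter_features(dna.counts[tr], controls_tr, dna_filter)
        if not keep_r.any() or not keep_d.any():
            raise ConfigurationError(f"fold {fold}: feature filter removed every feature")
        Xr, Xd = cpm_rna[:, keep_r], cpm_dna[:, keep_d]
        Xr_tr, Xd_tr, y_tr = Xr[tr], Xd[tr], y[tr]
        fold_seed = (seed * 1009 + fold) % (2**31)
        if use_smote:
            joint = np.hstack([Xr_tr, Xd_tr])
            joint_aug, y_aug = smote_oversample(joint, y_tr, seed=fold_seed)
            Xr_tr = joint_aug[:, : Xr_tr.shape[1]]
            Xd_tr = joint_aug[:, Xr_tr.shape[1] :]
            y_tr = y_aug
        model = StackedEnsemble(seed=fold_seed).fit(Xr_tr, Xd_tr, y_tr)
        prob = model.predict_proba(Xr[te], Xd[te])[:, 1]
        roc_aucs.append(float(roc_auc_score(y[te], prob)))
        pr_aucs.append(float(average_precision_score(y[te], prob)))
        details.append(
            {
                "test_indices": te.tolist(),
                "train_indices": tr.tolist(),
                "filter_control_indices": tr[controls_tr].tolist(),
                "n_features_rna": int(keep_r.sum()),
                "n_features_dna": int(keep_d.sum()),
            }
        )
    config = {
        "rna_filter": {"count_threshold": rna_filter.count_threshold, "control_fraction": rna_filter.control_fraction},
        "dna_filter": {"count_threshold": dna_filter.count_threshold, "control_fraction": dna_filter.control_fraction},
        "use_smote": use_smote,
        "base_learners": StackedEnsemble(seed=seed).base_learner_params(),
    }
    return CVResult(
        roc_aucs=roc_aucs,
        pr_aucs=pr_aucs,
        fold_assignments=assignments.tolist(),
        seed=seed,
        folds=folds,
        config=config,
        fold_details=details,
    )


def write_labels_tsv(samples: list[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "label": [s.label for s in samples],
            "modality": [s.modality for s in samples],
        }
    )
    write_tsv_with_header(df, path, {})


def read_labels_tsv(path: str | Path) -> list[SampleMeta]:
    df, _ = read_tsv_with_header(path, dtype=str)
    return [
        SampleMeta(r.sample_id, r.label, r.modality) for r in df.itertuples(index=False)
    ]
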