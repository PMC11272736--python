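"""Copy-number feature engineering and the cluster-4 Naïve Bayes predictor.

The CN-high arm of the TCGA-analogue cascade is a supervised prediction of
membership in the TCGA serous-like copy-number cluster 4, made from WES-based
segment calls. Features per sample: gain/loss counts overall, per chromosome
(1-22, X) and per gene for the 25 most frequently altered genes, plus ploidy
(length-weighted mean copy number) and total altered megabases. A Gaussian
Naïve Bayes model with empirical class priors is trained on a cohort with the
cluster-4 label binarized (cluster 4 vs clusters 1-3) and evaluated by
stratified 5-fold cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import (
    accuracy_score, f1_score, precision_score, recall_score, roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.utils.validation import check_is_fitted

from .genes import CN_FEATURE_CHROMS, synthetic_gene_model

DEFAULT_GAIN_CUTOFF = 2.5
DEFAULT_LOSS_CUTOFF = 1.5
N_SELECTED_GENES = 25


@dataclass(frozen=True)
class CNFeatureVector:
    """Per-sample copy-number features for cluster-4 prediction."""

    n_gains: int
    n_losses: int
    gains_per_chrom: dict[str, int]
    losses_per_chrom: dict[str, int]
    gene_alteration_counts: dict[str, int]
    ploidy: float
    altered_mb: float
    alterations_per_mb: float = 0.0  # alternative normalization, not a model feature


@dataclass(frozen=True)
class CVMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float
    fold_count: int = 5
    seed: int = 0


def canonicalize_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Sort one sample's segments and merge adjacent equal-copy-number runs.

    Alteration counts are defined on maximal runs, so splitting a segment in
    two at the same copy number must not change any feature.
    """
    if segments.empty:
        return segments
    seg = segments.sort_values(["chrom", "start"], ignore_index=True)
    merged: list[list] = []
    for row in seg.itertuples(index=False):
        if row.start >= row.end:
            raise ValueError(f"segment with start >= end on {row.chrom}")
        if (merged and merged[-1][0] == row.chrom
                and merged[-1][2] == row.start
                and np.isclose(merged[-1][3], row.copy_number)):
            merged[-1][2] = row.end
        else:
            if merged and merged[-1][0] == row.chrom and row.start < merged[-1][2]:
                raise ValueError(f"overlapping segments on {row.chrom}")
            merged.append([row.chrom, row.start, row.end, row.copy_number])
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "copy_number"])


def gene_alteration_table(
    segments: pd.DataFrame,
    gene_model: pd.DataFrame,
    gain_cutoff: float = DEFAULT_GAIN_CUTOFF,
    loss_cutoff: float = DEFAULT_LOSS_CUTOFF,
) -> dict[str, int]:
    """Count altered segments overlapping each model gene by >= 1 base."""
    counts = dict.fromkeys(gene_model["gene"], 0)
    if segments.empty:
        return counts
    seg = canonicalize_segments(segments)
    altered = seg[(seg["copy_number"] > gain_cutoff) | (seg["copy_number"] < loss_cutoff)]
    for g in gene_model.itertuples(index=False):
        on_chrom = altered[altered["chrom"] == g.chrom]
        overlap = (on_chrom["start"] < g.end) & (on_chrom["end"] > g.start)
        counts[g.gene] = int(overlap.sum())
    return counts


def extract_cn_features(
    segments: pd.DataFrame,
    gene_model: pd.DataFrame,
    selected_genes: list[str],
    gain_cutoff: float = DEFAULT_GAIN_CUTOFF,
    loss_cutoff: float = DEFAULT_LOSS_CUTOFF,
) -> CNFeatureVector:
    """Compute the feature vector for one sample's segment calls.

    A sample with zero segments yields all-zero counts and default ploidy 2.0
    (with a warning): a missing CN profile is treated as a quiet genome.
    """
    gains_pc = dict.fromkeys(CN_FEATURE_CHROMS, 0)
    losses_pc = dict.fromkeys(CN_FEATURE_CHROMS, 0)
    if segments.empty:
        warnings.warn("sample has no CN segments; using quiet-genome defaults")
        return CNFeatureVector(
            n_gains=0, n_losses=0, gains_per_chrom=gains_pc,
            losses_per_chrom=losses_pc,
            gene_alteration_counts=dict.fromkeys(selected_genes, 0),
            ploidy=2.0, altered_mb=0.0, alterations_per_mb=0.0,
        )
    seg = canonicalize_segments(segments)
    length = (seg["end"] - seg["start"]).astype(float)
    is_gain = seg["copy_number"] > gain_cutoff
    is_loss = seg["copy_number"] < loss_cutoff
    for chrom, sub_gain, sub_loss in zip(seg["chrom"], is_gain, is_loss):
        if chrom not in gains_pc:
            gains_pc[chrom] = 0
            losses_pc[chrom] = 0
        gains_pc[chrom] += int(sub_gain)
        losses_pc[chrom] += int(sub_loss)
    ploidy = float((length * seg["copy_number"]).sum() / length.sum())
    altered_len = float(length[is_gain | is_loss].sum())
    altered_mb = altered_len / 1e6
    genome_mb = float(length.sum()) / 1e6
    gene_counts = gene_alteration_table(seg, gene_model, gain_cutoff, loss_cutoff)
    return CNFeatureVector(
        n_gains=int(is_gain.sum()), n_losses=int(is_loss.sum()),
        gains_per_chrom=gains_pc, losses_per_chrom=losses_pc,
        gene_alteration_counts={g: gene_counts.get(g, 0) for g in selected_genes},
        ploidy=ploidy, altered_mb=altered_mb,
        alterations_per_mb=(int(is_gain.sum()) + int(is_loss.sum())) / genome_mb
        if genome_mb > 0 else 0.0,
    )


def feature_row(fv: CNFeatureVector, selected_genes: list[str]) -> pd.Series:
    """Flatten a feature vector into the model's numeric feature row."""
    data: dict[str, float] = {"n_gains": fv.n_gains, "n_losses": fv.n_losses}
    for c in CN_FEATURE_CHROMS:
        data[f"gains_{c}"] = fv.gains_per_chrom.get(c, 0)
    for c in CN_FEATURE_CHROMS:
        data[f"losses_{c}"] = fv.losses_per_chrom.get(c, 0)
    for g in selected_genes:
        data[f"alt_{g}"] = fv.gene_alteration_counts.get(g, 0)
    data["ploidy"] = fv.ploidy
    data["altered_mb"] = fv.altered_mb
    return pd.Series(data)


def select_top_genes(
    gene_incidence: pd.DataFrame, k: int = N_SELECTED_GENES
) -> list[str]:
    """Pick the k genes altered in the most training samples.

    ``gene_incidence`` is a samples x genes table of per-sample alteration
    counts. Ties at rank k break lexicographically; if fewer than k genes are
    ever altered the list is padded (with a warning) by the lexicographically
    first unaltered genes so the feature layout stays fixed.
    """
    n_samples_altered = (gene_incidence > 0).sum(axis=0)
    # stable sort on a lexicographically pre-sorted index implements the tie rule
    ranked = n_samples_altered.loc[sorted(n_samples_altered.index)].sort_values(
        ascending=False, kind="mergesort")
    altered = [g for g in ranked.index if n_samples_altered[g] > 0]
    if len(altered) >= k:
        return altered[:k]
    warnings.warn(f"only {len(altered)} genes altered in training; padding to {k}")
    pad = [g for g in sorted(gene_incidence.columns) if g not in altered]
    return altered + pad[: k - len(altered)]


class CnFeaturizer(BaseEstimator, TransformerMixin):
    """Turn long-format segment tables into the model's feature matrix.

    fit() learns the 25-gene selection from the training cohort and freezes
    it; transform() produces one numeric row per sample. Input is a DataFrame
    with columns ``sample, chrom, start, end, copy_number``.
    """

    def __init__(self, gene_model: pd.DataFrame | None = None,
                 n_genes: int = N_SELECTED_GENES,
                 gain_cutoff: float = DEFAULT_GAIN_CUTOFF,
                 loss_cutoff: float = DEFAULT_LOSS_CUTOFF):
        self.gene_model = gene_model
        self.n_genes = n_genes
        self.gain_cutoff = gain_cutoff
        self.loss_cutoff = loss_cutoff

    def _model(self) -> pd.DataFrame:
        return self.gene_model if self.gene_model is not None else synthetic_gene_model()

    def fit(self, X: pd.DataFrame, y=None) -> "CnFeaturizer":
        gm = self._model()
        incidence = pd.DataFrame({
            sid: gene_alteration_table(grp, gm, self.gain_cutoff, self.loss_cutoff)
            for sid, grp in X.groupby("sample")
        }).T
        self.selected_genes_ = select_top_genes(incidence, self.n_genes)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_genes_")
        gm = self._model()
        rows = {}
        for sid, grp in X.groupby("sample"):
            fv = extract_cn_features(
                grp, gm, self.selected_genes_, self.gain_cutoff, self.loss_cutoff)
            rows[sid] = feature_row(fv, self.selected_genes_)
        return pd.DataFrame(rows).T.sort_index()


class CNCluster4Classifier(BaseEstimator, ClassifierMixin):
    """Gaussian Naïve Bayes cluster-4 predictor on the CN feature matrix.

    Class-conditional Gaussians with per-feature mean/variance (variance floor
    1e-9 x the largest feature variance), empirical class priors, posterior by
    Bayes' rule; the cluster-4 flag is posterior > 0.5. Cluster-4 is the
    positive class (label 1).
    """

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing

    def fit(self, X, y) -> "CNCluster4Classifier":
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class; refusing to train")
        if counts.min() < 2:
            raise ValueError("need at least 2 training samples per class")
        self.feature_names_ = (
            list(X.columns) if isinstance(X, pd.DataFrame) else None)
        self.nb_ = GaussianNB(var_smoothing=self.var_smoothing)
        self.nb_.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.nb_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "nb_")
        return self.nb_.predict_proba(np.asarray(X, dtype=float))

    def posterior_cluster4(self, X) -> np.ndarray:
        pos = int(np.where(self.classes_ == 1)[0][0])
        return self.predict_proba(X)[:, pos]

    def predict(self, X) -> np.ndarray:
        return (self.posterior_cluster4(X) > 0.5).astype(int)

    def to_dict(self) -> dict:
        check_is_fitted(self, "nb_")
        return {
            "var_smoothing": self.var_smoothing,
            "classes": self.nb_.classes_.tolist(),
            "class_prior": self.nb_.class_prior_.tolist(),
            "class_count": self.nb_.class_count_.tolist(),
            "theta": self.nb_.theta_.tolist(),
            "var": self.nb_.var_.tolist(),
            "epsilon": float(self.nb_.epsilon_),
            "feature_names": self.feature_names_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CNCluster4Classifier":
        clf = cls(var_smoothing=d["var_smoothing"])
        nb = GaussianNB(var_smoothing=d["var_smoothing"])
        nb.classes_ = np.asarray(d["classes"])
        nb.class_prior_ = np.asarray(d["class_prior"])
        nb.class_count_ = np.asarray(d["class_count"])
        nb.theta_ = np.asarray(d["theta"])
        nb.var_ = np.asarray(d["var"])
        nb.epsilon_ = d["epsilon"]
        clf.nb_ = nb
        clf.classes_ = nb.classes_
        clf.feature_names_ = d["feature_names"]
        return clf


@dataclass
class Cluster4Model:
    """A trained cluster-4 predictor with its frozen feature layout."""

    featurizer: CnFeaturizer
    classifier: CNCluster4Classifier

    def predict_sample(self, segments: pd.DataFrame) -> tuple[bool, float]:
        """Flag + posterior for one sample's segment table (no 'sample' column needed)."""
        seg = segments.copy()
        if "sample" not in seg.columns:
            seg["sample"] = "_one"
        X = self.featurizer.transform(seg)
        post = float(self.classifier.posterior_cluster4(X)[0])
        return post > 0.5, post

    def save(self, path) -> None:
        d = {
            "featurizer": {
                "n_genes": self.featurizer.n_genes,
                "gain_cutoff": self.featurizer.gain_cutoff,
                "loss_cutoff": self.featurizer.loss_cutoff,
                "selected_genes": self.featurizer.selected_genes_,
            },
            "classifier": self.classifier.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def load(cls, path, gene_model: pd.DataFrame | None = None) -> "Cluster4Model":
        with open(path) as fh:
            d = json.load(fh)
        fz = CnFeaturizer(
            gene_model=gene_model, n_genes=d["featurizer"]["n_genes"],
            gain_cutoff=d["featurizer"]["gain_cutoff"],
            loss_cutoff=d["featurizer"]["loss_cutoff"])
        fz.selected_genes_ = d["featurizer"]["selected_genes"]
        return cls(featurizer=fz, classifier=CNCluster4Classifier.from_dict(d["classifier"]))


def train_cluster4_model(
    segments: pd.DataFrame,
    labels: pd.Series,
    gene_model: pd.DataFrame | None = None,
    **featurizer_kwargs,
) -> Cluster4Model:
    """Fit featurizer + classifier on a labeled training cohort.

    ``labels`` is indexed by sample id with values 1 (cluster 4) / 0 (other).
    """
    fz = CnFeaturizer(gene_model=gene_model, **featurizer_kwargs)
    X = fz.fit(segments).transform(segments)
    y = labels.loc[X.index].to_numpy()
    clf = CNCluster4Classifier().fit(X, y)
    return Cluster4Model(featurizer=fz, classifier=clf)


def cross_validate(
    X: pd.DataFrame, y, folds: int = 5, seed: int = 0
) -> CVMetrics:
    """Stratified k-fold CV of the cluster-4 predictor (cluster 4 positive).

    Metrics are computed per fold on held-out data and averaged unweighted;
    ROC-AUC uses the cluster-4 posterior as the score.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` members for stratified CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Xa = np.asarray(X, dtype=float)
    accs, precs, recs, f1s, aucs = [], [], [], [], []
    for train_idx, test_idx in skf.split(Xa, y):
        assert len(np.unique(y[test_idx])) == 2, "stratified fold lost a class"
        clf = CNCluster4Classifier().fit(Xa[train_idx], y[train_idx])
        pred = clf.predict(Xa[test_idx])
        post = clf.posterior_cluster4(Xa[test_idx])
        accs.append(accuracy_score(y[test_idx], pred))
        precs.append(precision_score(y[test_idx], pred, zero_division=0))
        recs.append(recall_score(y[test_idx], pred, zero_division=0))
        f1s.append(f1_score(y[test_idx], pred, zero_division=0))
        aucs.append(roc_auc_score(y[test_idx], post))
    return CVMetrics(
        accuracy=float(np.mean(accs)), precision=float(np.mean(precs)),
        recall=float(np.mean(recs)), f1=float(np.mean(f1s)),
        roc_auc=float(np.mean(aucs)), fold_count=folds, seed=seed,
    )
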