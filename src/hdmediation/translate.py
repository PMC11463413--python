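"""Transfer of transcript loadings to an independent population.

The loadings learned in the discovery population encode the direction and
relative importance of each transcript for the composite metabolic-disease
index (MDI). They are transferred to a new population by scoring each
individual as the loading-weighted sum of per-gene standardized expression —
either measured expression, or expression imputed from local genotype via
per-gene founder-effect models at the marker nearest the TSS. Comparing the
two predictions separates the contribution of local genetic regulation from
everything else that shapes expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_io import HaplotypeDosages, OmicsMatrix
from .mediation import LoadingVector

__all__ = [
    "LocalModel",
    "PredictionReport",
    "ScorePrediction",
    "LocalExpressionImputer",
    "CompositeScorePredictor",
    "fit_local_models",
    "impute_expression",
    "predict_scores",
    "evaluate_prediction",
]


@dataclass
class LocalModel:
    """Founder-effect regression of one gene on its nearest marker."""

    gene_id: str
    marker_id: str
    founder_effects: np.ndarray
    intercept: float
    training_r2: float


@dataclass
class ScorePrediction:
    """Predicted composite scores with the gene accounting behind them."""

    scores: pd.Series
    n_genes: int
    dropped: list = field(default_factory=list)


@dataclass
class PredictionReport:
    predicted: pd.Series
    observed: pd.Series
    r: float = np.nan
    p: float = np.nan
    kind: str = "continuous"  # or "groups"
    group_stats: pd.DataFrame = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "r": self.r, "p": self.p, "n": int(len(self.predicted))}


class LocalExpressionImputer(BaseEstimator):
    """Per-gene local-genotype models: expression ~ founder dosages at the TSS marker.

    For each gene, ordinary least squares of training expression on the
    founder-dosage columns of the single marker nearest its TSS (plus an
    intercept), solved with a pseudoinverse to absorb the dosages' sum-to-two
    collinearity. :meth:`predict` imputes expression in a new population from
    its dosages at the same markers.
    """

    def fit(self, expression: OmicsMatrix, dosages: HaplotypeDosages, annotations=None):
        ann = annotations if annotations is not None else expression.feature_annotations
        if ann is None or not {"chrom", "tss_bp"} <= set(ann.columns):
            raise ValueError("need feature annotations with chrom and tss_bp")
        if expression.individual_ids != dosages.individual_ids:
            raise ValueError("expression and dosages must share aligned individuals")
        mm = dosages.marker_map
        models = []
        skipped = []
        for gene in expression.feature_ids:
            if gene not in ann.index:
                skipped.append(gene)
                continue
            chrom = str(ann.loc[gene, "chrom"])
            tss = float(ann.loc[gene, "tss_bp"])
            on_chrom = np.flatnonzero(mm["chrom"].astype(str).to_numpy() == chrom)
            if on_chrom.size == 0:
                skipped.append(gene)
                continue
            pos = mm["pos_bp"].to_numpy()[on_chrom]
            j = on_chrom[int(np.argmin(np.abs(pos - tss)))]
            D = dosages.dosages[:, j, :]
            y = expression.values[gene].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(y)), D])
            beta = np.linalg.pinv(X) @ y
            fitted = X @ beta
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - np.sum((y - fitted) ** 2) / ss_tot if ss_tot > 0 else 0.0
            models.append(
                LocalModel(
                    gene_id=gene,
                    marker_id=str(mm["marker_id"].iloc[j]),
                    founder_effects=beta[1:],
                    intercept=float(beta[0]),
                    training_r2=float(max(0.0, r2)),
                )
            )
        if skipped:
            warnings.warn(f"{len(skipped)} genes skipped (no usable local marker)")
        self.models_ = models
        self.skipped_ = skipped
        return self

    def predict(self, dosages_new: HaplotypeDosages) -> OmicsMatrix:
        marker_pos = {m: i for i, m in enumerate(dosages_new.marker_map["marker_id"])}
        cols, names, dropped = [], [], []
        for model in self.models_:
            j = marker_pos.get(model.marker_id)
            if j is None:
                dropped.append(model.gene_id)
                continue
            D = dosages_new.dosages[:, j, :]
            cols.append(model.intercept + D @ model.founder_effects)
            names.append(model.gene_id)
        if dropped:
            warnings.warn(f"{len(dropped)} genes dropped (marker absent in new population)")
        if not cols:
            raise ValueError("no model markers present in the new population")
        values = pd.DataFrame(
            np.column_stack(cols), index=dosages_new.individual_ids, columns=names
        )
        return OmicsMatrix(values=values, name="imputed")


class CompositeScorePredictor(BaseEstimator):
    """Score new individuals with discovery-population transcript loadings.

    Each mapped gene is standardized within the new population (the loadings
    carry direction and relative importance, not absolute scale) and summed
    with its loading as weight.

    Parameters
    ----------
    loadings : LoadingVector or Series of per-feature loadings.
    gene_map : optional mapping (dict or two-column DataFrame) from loading
        feature ids to new-population feature ids (e.g. mouse -> human
        orthologs). Unmapped genes are dropped and counted.
    """

    def __init__(self, loadings=None, gene_map=None):
        self.loadings = loadings
        self.gene_map = gene_map

    def _loading_series(self) -> pd.Series:
        if isinstance(self.loadings, LoadingVector):
            return self.loadings.loadings
        return pd.Series(self.loadings)

    def predict(self, expression_new: OmicsMatrix) -> ScorePrediction:
        load = self._loading_series()
        if self.gene_map is not None:
            gm = self.gene_map
            if isinstance(gm, pd.DataFrame):
                gm = dict(zip(gm.iloc[:, 0], gm.iloc[:, 1]))
            load = load.rename(index=gm)
            load = load[~load.index.duplicated(keep="first")]
        shared = [g for g in load.index if g in set(expression_new.feature_ids)]
        if not shared:
            raise ValueError("no genes shared between loadings and new expression")
        X = expression_new.values[shared].to_numpy(dtype=float)
        usable = np.ptp(X, axis=0) > 0
        dropped = [g for g, u in zip(shared, usable) if not u]
        if dropped:
            warnings.warn(f"{len(dropped)} zero-variance genes dropped from score")
        if not usable.any():
            raise ValueError("all mapped genes have zero variance in the new population")
        Zc = X[:, usable] - X[:, usable].mean(axis=0)
        Z = Zc / Zc.std(axis=0)
        w = load.loc[[g for g, u in zip(shared, usable) if u]].to_numpy(dtype=float)
        scores = pd.Series(Z @ w, index=expression_new.individual_ids, name="predicted_score")
        return ScorePrediction(scores=scores, n_genes=int(usable.sum()), dropped=dropped)


def fit_local_models(expression_train, dosages_train, annotations=None):
    """Functional wrapper over :class:`LocalExpressionImputer`."""
    return LocalExpressionImputer().fit(expression_train, dosages_train, annotations).models_


def impute_expression(dosages_new: HaplotypeDosages, models) -> OmicsMatrix:
    imp = LocalExpressionImputer()
    imp.models_ = list(models)
    return imp.predict(dosages_new)


def predict_scores(expression_new, loadings, gene_map=None) -> ScorePrediction:
    return CompositeScorePredictor(loadings=loadings, gene_map=gene_map).predict(expression_new)


def evaluate_prediction(predicted, observed, groups=None, strain=None) -> PredictionReport:
    """Evaluate predicted scores against a continuous trait or binary groups.

    Continuous: Pearson r with two-sided p. Binary groups: difference of group
    means with a two-sided Wilcoxon rank-sum p. ``strain`` optionally labels
    individuals for per-strain mean/sd summaries.
    """
    predicted = pd.Series(predicted)
    if groups is not None:
        groups = pd.Series(groups, index=predicted.index)
        levels = groups.unique()
        if len(levels) < 2:
            raise ValueError("need at least two groups")
        if len(levels) != 2:
            raise ValueError(f"expected two groups, got {len(levels)}")
        a = predicted[groups == levels[0]].to_numpy()
        b = predicted[groups == levels[1]].to_numpy()
        if min(len(a), len(b)) < 2:
            raise ValueError("need at least 2 individuals per group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        report = PredictionReport(
            predicted=predicted,
            observed=groups,
            r=float(np.mean(b) - np.mean(a)),
            p=float(res.pvalue),
            kind="groups",
        )
    else:
        observed = pd.Series(observed, index=predicted.index)
        r, p = stats.pearsonr(predicted.to_numpy(), observed.to_numpy(dtype=float))
        report = PredictionReport(
            predicted=predicted, observed=observed, r=float(r), p=float(p), kind="continuous"
        )
    if strain is not None:
        strain = pd.Series(strain, index=predicted.index)
        grp = pd.DataFrame({"predicted": predicted, "strain": strain}).groupby("strain")
        report.group_stats = grp["predicted"].agg(["mean", "std", "count"])
    return report
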