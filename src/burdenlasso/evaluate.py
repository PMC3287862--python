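"""Method comparison: selection consistency, cross-replicate prediction, ROC.

Three complementary views of a collapsing method's performance:

* **Consistency** — how stable the set of selected features is across
  phenotype replicates, scored as total selection instability
  C = sum_{j in F} n_j (R - n_j) / R over the features F selected in at
  least one replicate (n_j = number of replicates selecting j).  C = 0 when
  every replicate selects the identical set; lower is more consistent.
* **Cross-replicate prediction** — each replicate's fitted model predicts
  the trait in every other replicate; improvement is measured against a
  covariates-only baseline (MSE reduction for quantitative traits, average
  AUC gain for disease).
* **ROC against the truth set** — features are ranked by the number of
  replicates in which they receive a nonzero coefficient; sweeping a count
  threshold traces sensitivity/specificity against the known causal set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .collapse import (
    COVARIATE,
    GENE_SCORE,
    CollapseConfig,
    covariates_only_design,
)
from .errors import ConfigurationError, PipelineError
from .lasso import DISEASE_TRAIT, FitResult, IDENTITY, LOGIT, fit_all_replicates
from .types import GenotypeSet, ReplicateSet, TruthSet


@dataclass
class SelectionMatrix:
    """Binary replicate x feature selection-indicator matrix.

    Restricted to features selected in at least one replicate, so every
    column has at least one 1.
    """

    s: np.ndarray
    features: list[str]

    @property
    def R(self) -> int:
        return self.s.shape[0]

    def counts(self) -> np.ndarray:
        return self.s.sum(axis=0)


def selection_matrix(fits: list[FitResult], genetic_only: bool = True) -> SelectionMatrix:
    """Build the selection-indicator matrix from per-replicate fits.

    With ``genetic_only`` (default) covariate columns are excluded: they are
    unpenalized, hence always selected, and contribute zero instability.
    """
    if not fits:
        raise ConfigurationError("no fits provided")
    cols = fits[0].design_columns
    names = list(fits[0].selected.index)
    if genetic_only:
        keep = [n for n, k in zip(names, cols["kind"]) if k != COVARIATE]
    else:
        keep = names
    mat = np.array([[bool(f.selected.get(n, False)) for n in keep] for f in fits], dtype=int)
    ever = mat.any(axis=0)
    return SelectionMatrix(
        s=mat[:, ever], features=[n for n, e in zip(keep, ever) if e]
    )


def consistency_score(sel: SelectionMatrix, normalize_by_size: bool = False) -> float:
    """Selection instability C = sum_j n_j (R - n_j) / R over F.

    ``normalize_by_size`` divides by |F| for a per-feature average; the
    default keeps the raw sum (lower = more consistent either way).
    """
    if sel.R < 2:
        raise ConfigurationError("consistency needs at least 2 replicates")
    if sel.s.shape[1] == 0:
        raise ConfigurationError("empty feature set F")
    n_j = sel.counts()
    c = float((n_j * (sel.R - n_j)).sum() / sel.R)
    if normalize_by_size:
        c /= sel.s.shape[1]
    return c


def fit_baselines(
    g: GenotypeSet, reps: ReplicateSet, trait: str
) -> list[FitResult]:
    """Covariates-only ordinary fits (OLS / logistic), one per replicate."""
    design = covariates_only_design(g, reps.covariates)
    X = design.values
    link = LOGIT if trait == DISEASE_TRAIT else IDENTITY
    Xa = np.hstack([X, np.ones((X.shape[0], 1))])
    fits = []
    for r in range(reps.R):
        y = reps.trait_replicate(trait, r)
        if link == IDENTITY:
            beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            coef, b0 = beta[:-1], float(beta[-1])
        else:
            clf = LogisticRegression(C=np.inf, max_iter=1000)  # unpenalized
            clf.fit(X, y)
            coef, b0 = clf.coef_[0], float(clf.intercept_[0])
        lp = b0 + X @ coef
        fits.append(
            FitResult(
                coefficients=pd.Series(coef, index=design.feature_names),
                intercept=b0,
                selected=pd.Series(coef != 0.0, index=design.feature_names),
                link=link,
                chosen_penalties=None,
                cv_error=None,
                linear_predictor=lp,
                design_columns=design.columns,
            )
        )
    return fits


def cross_replicate_prediction(
    fits: list[FitResult],
    reps: ReplicateSet,
    trait: str,
    baseline: list[FitResult],
) -> float:
    """Mean prediction improvement of the full model over covariates-only.

    Each replicate's model predicts the trait in all other replicates (the
    genotypes and covariates are fixed, so a model's predictions are one
    vector).  Quantitative traits: improvement = baseline MSE - full MSE
    (positive means the genetic features help).  Disease: improvement =
    full average AUC - baseline average AUC.
    """
    if len(fits) != reps.R or len(baseline) != reps.R:
        raise ConfigurationError("need one fit and one baseline per replicate")
    link = LOGIT if trait == DISEASE_TRAIT else IDENTITY
    for f in fits + baseline:
        if f.link != link:
            raise ConfigurationError(f"fit link {f.link} does not match trait {trait}")
    Y = reps.traits[trait]
    R = reps.R
    improvements = []
    for i in range(R):
        others = [k for k in range(R) if k != i]
        pred_full = fits[i].predict()
        pred_base = baseline[i].predict()
        if link == IDENTITY:
            mse_full = np.mean((Y[:, others] - pred_full[:, None]) ** 2)
            mse_base = np.mean((Y[:, others] - pred_base[:, None]) ** 2)
            improvements.append(mse_base - mse_full)
        else:
            auc_full = np.mean([_safe_auc(Y[:, k], pred_full) for k in others])
            auc_base = np.mean([_safe_auc(Y[:, k], pred_base) for k in others])
            improvements.append(auc_full - auc_base)
    return float(np.mean(improvements))


def _safe_auc(y: np.ndarray, score: np.ndarray) -> float:
    if len(np.unique(y)) < 2:
        return 0.5
    return roc_auc_score(y, score)


# ---------------------------------------------------------------------------
# ROC against the truth set


@dataclass
class RocResult:
    points: pd.DataFrame  # threshold, sensitivity, specificity
    auc: float
    top_features: pd.DataFrame  # feature, count


def feature_counts(fits: list[FitResult], genetic_only: bool = True) -> pd.Series:
    """Replicate selection counts over the full candidate feature space."""
    cols = fits[0].design_columns
    names = list(fits[0].selected.index)
    if genetic_only:
        keep = [n for n, k in zip(names, cols["kind"]) if k != COVARIATE]
    else:
        keep = names
    counts = pd.Series(0, index=keep, dtype=int)
    for f in fits:
        counts += f.selected.reindex(keep).fillna(False).astype(int)
    return counts


def _truth_labels(
    fits: list[FitResult], truth: TruthSet, trait: str, granularity: str
) -> tuple[pd.Series, pd.Series]:
    """(counts, labels) per evaluation entity at the requested granularity."""
    cols = fits[0].design_columns.set_index("feature")
    counts = feature_counts(fits, genetic_only=True)
    causal_vars = truth.causal_variants.get(trait, set())
    causal_genes = truth.causal_genes.get(trait, set())
    if granularity == "gene":
        # every feature maps to its gene; entity count = max over its columns
        gene_counts: dict[str, int] = {}
        for name, cnt in counts.items():
            gene = cols.loc[name, "gene"]
            if not gene:
                continue
            gene_counts[gene] = max(gene_counts.get(gene, 0), int(cnt))
        ent = pd.Series(gene_counts).sort_index()
        labels = pd.Series({g: g in causal_genes for g in ent.index})
    elif granularity == "variant+gene":
        labels_d: dict[str, bool] = {}
        for name in counts.index:
            kind = cols.loc[name, "kind"]
            if kind == GENE_SCORE:
                labels_d[name] = cols.loc[name, "gene"] in causal_genes
            else:  # common variant column: the variant itself must be causal
                labels_d[name] = name in causal_vars
        ent = counts.sort_index()
        labels = pd.Series(labels_d).reindex(ent.index)
    else:
        raise ConfigurationError(f"unknown granularity {granularity!r}")
    return ent, labels


def rank_and_roc(
    fits: list[FitResult],
    truth: TruthSet,
    trait: str,
    granularity: str = "gene",
) -> RocResult:
    """Rank features by replicate selection count and trace ROC vs. truth.

    For each threshold t in {0..R+1}, features with count >= t are declared
    positive; sensitivity/specificity are computed against the causal truth
    set and the AUC by the trapezoid rule (equal to the tie-corrected
    Mann-Whitney statistic of the count ranking).
    """
    counts, labels = _truth_labels(fits, truth, trait, granularity)
    if labels.sum() == 0:
        raise ConfigurationError(f"truth set for {trait!r} is empty at this granularity")
    R = len(fits)
    pos = labels.to_numpy(dtype=bool)
    cnt = counts.to_numpy()
    P, N = int(pos.sum()), int((~pos).sum())
    rows = []
    for t in range(R + 1, -1, -1):
        declared = cnt >= t
        tp = int((declared & pos).sum())
        fp = int((declared & ~pos).sum())
        sens = tp / P
        spec = 1.0 - fp / N if N else 1.0
        rows.append((t, sens, spec))
    points = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])
    fpr = 1.0 - points["specificity"].to_numpy()
    tpr = points["sensitivity"].to_numpy()
    auc = float(np.trapezoid(tpr, fpr))
    order = sorted(counts.index, key=lambda f: (-counts[f], f))
    top = pd.DataFrame(
        {"feature": order, "count": [int(counts[f]) for f in order]}
    )
    return RocResult(points=points, auc=auc, top_features=top)


@dataclass
class EvaluationReport:
    """Assembled comparison across collapsing methods and traits."""

    consistency: pd.DataFrame  # method x trait
    prediction_improvement: pd.DataFrame  # method x trait
    auc: pd.DataFrame  # method x trait (gene-level truth ROC)
    roc: dict = field(default_factory=dict)  # (method, trait) -> RocResult
    top_features: dict = field(default_factory=dict)  # (method, trait) -> DataFrame


def compare_methods(
    g: GenotypeSet,
    reps: ReplicateSet,
    truth: TruthSet,
    methods: tuple = ("PROP", "DAS", "WS"),
    traits: tuple = ("Q1", "Q2", "Q4", "disease"),
    base_config: CollapseConfig = CollapseConfig(),
    protocol: str = "single",
    k_folds: int = 5,
    n_lambda: int = 50,
    seed: int = 0,
    granularity: str = "gene",
    with_prediction: bool = True,
) -> EvaluationReport:
    """Run the full pipeline for every method x trait and assemble the report."""
    cons = pd.DataFrame(index=list(methods), columns=list(traits), dtype=float)
    impr = pd.DataFrame(index=list(methods), columns=list(traits), dtype=float)
    auc = pd.DataFrame(index=list(methods), columns=list(traits), dtype=float)
    roc: dict = {}
    tops: dict = {}
    baselines = {t: fit_baselines(g, reps, t) if with_prediction else None for t in traits}
    for method in methods:
        config = CollapseConfig(
            rare_maf_threshold=base_config.rare_maf_threshold,
            method=method,
            das_alpha0=base_config.das_alpha0,
            ws_frequency_source=(
                "unaffected_only" if method == "WS" else base_config.ws_frequency_source
            ),
            split_by_annotation=base_config.split_by_annotation,
        )
        for trait in traits:
            try:
                cfg = config
                if method == "WS":
                    cfg = CollapseConfig(
                        rare_maf_threshold=config.rare_maf_threshold,
                        method="WS",
                        das_alpha0=config.das_alpha0,
                        ws_frequency_source=(
                            "unaffected_only" if trait == DISEASE_TRAIT else "all_samples"
                        ),
                        split_by_annotation=config.split_by_annotation,
                    )
                fits = fit_all_replicates(
                    g, reps, trait, cfg,
                    protocol=protocol, k_folds=k_folds, n_lambda=n_lambda, seed=seed,
                )
                cons.loc[method, trait] = consistency_score(selection_matrix(fits))
                if with_prediction:
                    impr.loc[method, trait] = cross_replicate_prediction(
                        fits, reps, trait, baselines[trait]
                    )
                if truth.causal_genes.get(trait):
                    rr = rank_and_roc(fits, truth, trait, granularity)
                    auc.loc[method, trait] = rr.auc
                    roc[(method, trait)] = rr
                    tops[(method, trait)] = rr.top_features
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(
                    "evaluate", str(exc), method=method, trait=trait
                ) from exc
    return EvaluationReport(
        consistency=cons,
        prediction_improvement=impr,
        auc=auc,
        roc=roc,
        top_features=tops,
    )


def plot_roc(report: EvaluationReport, trait: str, path=None):
    """ROC curves with AUC annotations for one trait (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (method, tr), rr in report.roc.items():
        if tr != trait:
            continue
        fpr = 1.0 - rr.points["specificity"]
        ax.plot(fpr, rr.points["sensitivity"], label=f"{method} (AUC={rr.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC vs. truth set — {trait}")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
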