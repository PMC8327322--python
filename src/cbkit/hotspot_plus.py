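"""Hotspot+ models: the positional GAM plus in-silico predictor scores.

The hotspot model captures gene burden and positional clustering; adding
per-variant predictor scores (dbNSFP-style columns) as unpenalized linear
terms — interacted with carrier status so they vanish for non-carriers —
yields per-variant odds ratios that can stratify risk between variants at
the same residue:

    log OR(variant) = beta1 + f(position) + sum_j gamma_j * score_j

Feature entry is guarded by a strict two-stage selection: stage 1 screens
each candidate marginally inside the hotspot model at a Bonferroni
threshold of 0.05 / n_candidates; stage 2 fits the surviving features
jointly and backward-eliminates the least significant until all clear
0.05 / (stage-1 count).  An empty selection is a legitimate outcome for
sparsely observed genes.  Relative model performance is summarised by the
AUC over repeated stratified 80/20 train/test splits of the carrier rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from scipy.special import expit

from .hotspot_gam import (
    GamFrame,
    HotspotModel,
    fit_hotspot,
    predict_log_or,
)
from .simulator import SimulatedDataset

__all__ = [
    "FeatureMatrix",
    "SelectionReport",
    "AucSummary",
    "generate_synthetic_scores",
    "select_features",
    "fit_hotspot_plus",
    "crossfold_auc",
]

#: Default number of candidate predictor columns (dbNSFP-like panel size).
DEFAULT_N_FEATURES = 24


@dataclass
class FeatureMatrix:
    """Carrier-row-aligned matrix of predictor scores.

    One row per carrier row of the :class:`GamFrame` (dataset order,
    carrier-count expanded).  Missing entries are NaN; selected features
    are mean-imputed within gene at fit time.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.names = tuple(self.names)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (n_rows, n_features)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def columns(self, names: Sequence[str], impute: bool = True) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        out = self.values[:, idx].copy()
        if impute:
            for j in range(out.shape[1]):
                col = out[:, j]
                miss = np.isnan(col)
                if miss.any():
                    fill = np.nanmean(col) if not miss.all() else 0.0
                    col[miss] = fill
        return out


@dataclass
class SelectionReport:
    """Audit trail of the two-stage feature selection."""

    stage1_pvalues: dict[str, float]
    stage1_selected: list[str]
    elimination_path: list[tuple[str, float]]
    final_features: list[str]
    stage1_alpha: float
    stage2_alpha: float


@dataclass
class AucSummary:
    """AUC over repeated stratified train/test splits."""

    mean_auc: float
    sd_auc: float
    per_split_auc: np.ndarray
    split_ratio: float = 0.8
    n_splits: int = 10

    def __post_init__(self) -> None:
        self.per_split_auc = np.asarray(self.per_split_auc, dtype=float)


def generate_synthetic_scores(
    sim: SimulatedDataset,
    n_features: int = DEFAULT_N_FEATURES,
    informative: Sequence[tuple[int, float]] = (),
    seed: int | None = None,
) -> FeatureMatrix:
    """Synthetic predictor panel aligned with a simulated gene's carriers.

    Informative columns are ``effect_size * z + N(0,1)`` where z is the
    standardized true per-variant log OR; the rest are pure standard
    normal noise.  With all effect sizes 0 every column is independent of
    the truth.  Rows follow the canonical carrier-row order (dataset
    order, carrier-count expanded), matching ``assemble_gam_frame``.
    """
    if n_features < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    log_or = np.log(np.repeat(
        sim.truth_or, [v.carrier_count for v in sim.dataset.variants]
    ))
    sd = log_or.std()
    z = (log_or - log_or.mean()) / sd if sd > 0 else np.zeros_like(log_or)
    n = z.shape[0]
    X = rng.standard_normal((n, n_features))
    for j, effect in informative:
        X[:, j] += effect * z
    names = tuple(f"score_{j:02d}" for j in range(n_features))
    return FeatureMatrix(names=names, values=X)


def _wald_pvalues(model: HotspotModel) -> dict[str, float]:
    """Two-sided Wald p-values of the model's feature coefficients."""
    q = len(model.feature_names)
    out: dict[str, float] = {}
    for j, name in enumerate(model.feature_names):
        idx = len(model.beta) - q + j
        se = math.sqrt(model.cov[idx, idx])
        zstat = model.beta[idx] / se if se > 0 else 0.0
        out[name] = float(2.0 * stats.norm.sf(abs(zstat)))
    return out


def select_features(
    frame: GamFrame,
    X: FeatureMatrix,
    basis_dim: int = 10,
    alpha_family: float = 0.05,
) -> SelectionReport:
    """Two-stage Bonferroni screen + backwards elimination.

    Stage 1 tests each candidate as a single added linear term in the
    hotspot model (Wald test) against ``alpha_family / n_candidates``.
    Stage 2 fits all stage-1 survivors jointly and repeatedly removes the
    feature with the largest p-value until every remaining one clears
    ``alpha_family / n_stage1``.  The smoothing parameter is estimated
    once on the feature-free hotspot model and held fixed during the
    screen; the production hotspot+ fit re-estimates it.
    """
    base = fit_hotspot(frame, basis_dim=basis_dim)
    lam = base.lam
    n_cand = X.n_features
    stage1_alpha = alpha_family / n_cand

    stage1_pvalues: dict[str, float] = {}
    for name in X.names:
        m = fit_hotspot(
            frame, basis_dim=basis_dim, lam=lam,
            features=X.columns([name]), feature_names=[name],
        )
        stage1_pvalues[name] = _wald_pvalues(m)[name]
    stage1_selected = [n for n in X.names if stage1_pvalues[n] < stage1_alpha]

    stage2_alpha = alpha_family / max(len(stage1_selected), 1)
    current = list(stage1_selected)
    path: list[tuple[str, float]] = []
    while current:
        m = fit_hotspot(
            frame, basis_dim=basis_dim, lam=lam,
            features=X.columns(current), feature_names=current,
        )
        pvals = _wald_pvalues(m)
        worst = max(current, key=lambda n: pvals[n])
        if pvals[worst] < stage2_alpha:
            break
        path.append((worst, pvals[worst]))
        current.remove(worst)
    return SelectionReport(
        stage1_pvalues=stage1_pvalues,
        stage1_selected=stage1_selected,
        elimination_path=path,
        final_features=current,
        stage1_alpha=stage1_alpha,
        stage2_alpha=stage2_alpha,
    )


def fit_hotspot_plus(
    frame: GamFrame,
    X: FeatureMatrix,
    features: Sequence[str],
    basis_dim: int = 10,
    smoothing: str = "REML",
    lam: float | None = None,
) -> HotspotModel:
    """Fit the hotspot model extended with the named score columns.

    With an empty feature list this is numerically the hotspot model.
    """
    features = list(features)
    if not features:
        return fit_hotspot(frame, basis_dim=basis_dim, smoothing=smoothing, lam=lam)
    return fit_hotspot(
        frame, basis_dim=basis_dim, smoothing=smoothing, lam=lam,
        features=X.columns(features), feature_names=features,
    )


def _predict_case_probability(
    model: HotspotModel,
    positions: np.ndarray,
    scores: np.ndarray | None,
) -> np.ndarray:
    """Fitted P(case) for carrier rows at the given positions/scores."""
    log_or, _ = predict_log_or(model, positions, scores)
    return expit(model.beta0 + log_or)


def crossfold_auc(
    frame: GamFrame,
    X: FeatureMatrix | None,
    features: Sequence[str] = (),
    n_splits: int = 10,
    ratio: float = 0.8,
    seed: int = 0,
    basis_dim: int = 10,
    max_redraws: int = 20,
) -> AucSummary:
    """Held-out AUC over repeated stratified 80/20 splits of carrier rows.

    Each split trains the requested model (hotspot when ``features`` is
    empty) on 80% of carriers plus the two non-carrier aggregate rows and
    scores the held-out carriers by predicted case probability.  Splits
    with a single-class test set are redrawn (stratification makes this
    rare).
    """
    carriers = frame.carrier_mask()
    n_car = int(carriers.sum())
    y = frame.is_case[carriers]
    if (y == 1).sum() < 10 or (y == 0).sum() < 10:
        raise ValueError("need >= 10 carriers per cohort for split evaluation")
    pos_car = frame.position[carriers]
    w_car = frame.weight[carriers]
    feats = list(features)
    Xv = X.columns(feats) if feats else None
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_splits):
        for _try in range(max_redraws):
            train_idx, test_idx = _stratified_split(y, ratio, rng)
            if len(np.unique(y[test_idx])) == 2 and len(np.unique(y[train_idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class test split")
        sub_frame = GamFrame(
            is_case=np.concatenate([y[train_idx], frame.is_case[~carriers]]),
            carrier=np.concatenate(
                [np.ones(len(train_idx)), np.zeros((~carriers).sum())]
            ),
            position=np.concatenate([pos_car[train_idx], frame.position[~carriers]]),
            weight=np.concatenate([w_car[train_idx], frame.weight[~carriers]]),
            gene=frame.gene, L=frame.L,
        )
        if feats:
            model = fit_hotspot(
                sub_frame, basis_dim=basis_dim,
                features=Xv[train_idx], feature_names=feats,
            )
            prob = _predict_case_probability(model, pos_car[test_idx], Xv[test_idx])
        else:
            model = fit_hotspot(sub_frame, basis_dim=basis_dim)
            prob = _predict_case_probability(model, pos_car[test_idx], None)
        aucs.append(float(roc_auc_score(y[test_idx], prob)))
    aucs = np.asarray(aucs)
    return AucSummary(
        mean_auc=float(aucs.mean()), sd_auc=float(aucs.std(ddof=1)),
        per_split_auc=aucs, split_ratio=ratio, n_splits=n_splits,
    )


def _stratified_split(
    y: np.ndarray, ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_parts, test_parts = [], []
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = int(round(ratio * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return np.concatenate(train_parts), np.concatenate(test_parts)
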