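"""Random-forest disease classification and directional biomarker scores.

Protocol: equal-size disease and healthy groups (seeded subsampling of
the larger group), a 70/30 train/test split, per-feature
standardization fit on the training split, a 500-tree random forest,
AUROC on the untouched test split. Feature importance is reported as
the directional mean absolute attribution

    D(f) = sign(Spearman(feature values, attributions)) * mean|attribution|

so a positive D means higher relative abundance pushes the model toward
the disease class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from ._seeds import subseed, substream
from .attribution import forest_attributions
from .datatypes import AbundanceMatrix, SampleMetadata

logger = logging.getLogger("panmgas")

__all__ = [
    "ClassifierSpec",
    "ModelHandle",
    "balanced_cohort",
    "train_evaluate",
    "directional_shap",
    "cross_cohort_validate",
]


@dataclass
class ClassifierSpec:
    n_trees: int = 500
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def balanced_cohort(
    abundance: AbundanceMatrix,
    metadata: SampleMetadata,
    disease_label: str,
    seed: int = 0,
    countries: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Equal-size case/control feature matrix for one disease.

    Cases are all samples with the given disease label; controls are
    healthy samples from the same countries. The larger group is
    subsampled (seeded) to the size of the smaller. Features are the
    relative abundances of all MSPs (samples x MSPs).
    """
    md = metadata.table.loc[list(abundance.sample_ids)]
    cases = md.index[(md["status"] == "diseased") & (md["disease_label"] == disease_label)]
    if countries is None:
        countries = sorted(md.loc[cases, "country"].unique())
    controls = md.index[
        (md["status"] == "healthy") & (md["country"].isin(countries))
    ]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError(
            f"disease {disease_label!r}: need both cases ({len(cases)}) and "
            f"matched healthy controls ({len(controls)})"
        )
    if min(len(cases), len(controls)) < 10:
        logger.warning(
            "disease %s: group of < 10 samples; model prone to overfitting",
            disease_label,
        )
    rng = substream(seed, "balance", disease_label)
    k = min(len(cases), len(controls))
    cases = sorted(rng.choice(sorted(cases), size=k, replace=False))
    controls = sorted(rng.choice(sorted(controls), size=k, replace=False))
    samples = cases + controls
    X = abundance.values[samples].T
    y = pd.Series([1] * len(cases) + [0] * len(controls), index=samples, name="label")
    return X, y


@dataclass
class ModelHandle:
    model: RandomForestClassifier
    scaler: StandardScaler
    feature_ids: list[str]
    auroc_train: float
    auroc_test: float
    X_scaled: np.ndarray  # full cohort, scaled (train statistics)
    X_raw: pd.DataFrame
    y: pd.Series
    test_index: list[str] = field(default_factory=list)


def train_evaluate(
    features: pd.DataFrame, labels: pd.Series, spec: ClassifierSpec
) -> ModelHandle:
    """Fit the forest on a stratified 70% split and score AUROC on the
    held-out 30%. Standardization statistics come from the training
    split only."""
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=y,
        random_state=subseed(spec.seed, "split"),
    )
    if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
        raise ValueError("a split ended up single-class; increase sample size")
    scaler = StandardScaler().fit(X[train_idx])
    Xs = scaler.transform(X)
    model = RandomForestClassifier(
        n_estimators=spec.n_trees,
        bootstrap=True,
        max_depth=None,
        max_features="sqrt",
        min_samples_leaf=1,
        min_samples_split=2,
        n_jobs=1,
        random_state=subseed(spec.seed, "forest"),
    )
    model.fit(Xs[train_idx], y[train_idx])
    p_train = model.predict_proba(Xs[train_idx])[:, 1]
    p_test = model.predict_proba(Xs[test_idx])[:, 1]
    return ModelHandle(
        model=model,
        scaler=scaler,
        feature_ids=list(features.columns),
        auroc_train=float(roc_auc_score(y[train_idx], p_train)),
        auroc_test=float(roc_auc_score(y[test_idx], p_test)),
        X_scaled=Xs,
        X_raw=features,
        y=labels,
        test_index=[features.index[i] for i in test_idx],
    )


def directional_shap(handle: ModelHandle, features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Directional mean-absolute attribution per MSP.

    Attributions are computed for the disease-class probability over the
    full cohort (or over ``features`` if given, aligned to the model's
    feature set). Sign 0 when the Spearman correlation is undefined
    (constant vectors) or exactly zero.
    """
    if features is None:
        X_raw = handle.X_raw
        Xs = handle.X_scaled
    else:
        X_raw = features[handle.feature_ids]
        Xs = handle.scaler.transform(X_raw.to_numpy(dtype=float))
    attr, base = forest_attributions(handle.model, Xs)
    rows = []
    for j, f in enumerate(handle.feature_ids):
        a = attr[:, j]
        v = X_raw[f].to_numpy(dtype=float)
        magnitude = float(np.abs(a).mean())
        if np.ptp(v) == 0 or np.ptp(a) == 0:
            sign = 0
            if np.ptp(v) == 0:
                logger.debug("constant feature %s: D = 0", f)
        else:
            r = stats.spearmanr(v, a).statistic
            sign = 0 if (np.isnan(r) or r == 0) else int(np.sign(r))
        rows.append(
            {
                "msp_id": f,
                "D": sign * magnitude,
                "mean_abs_attribution": magnitude,
                "sign": sign,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "mean_abs_attribution", ascending=False, kind="mergesort"
    )
    out.attrs["base_value"] = base
    return out.reset_index(drop=True)


def cross_cohort_validate(
    handle: ModelHandle,
    external_features: pd.DataFrame,
    external_labels: pd.Series,
    repeats: int = 0,
    group_size: int | None = None,
    seed: int = 0,
) -> dict:
    """Score the frozen model on an external cohort.

    Feature spaces are aligned by MSP id; MSPs unseen in the external
    cohort are imputed as 0 (logged). With ``repeats`` > 0, the repeated
    design draws ``repeats`` random balanced case/control subsets and
    reports mean ± sd AUROC alongside the full-cohort AUROC.
    """
    shared = [f for f in handle.feature_ids if f in external_features.columns]
    if not shared:
        raise ValueError("no shared features between model and external cohort")
    missing = [f for f in handle.feature_ids if f not in external_features.columns]
    if missing:
        logger.warning("%d model feature(s) absent externally; imputed 0", len(missing))
    X = pd.DataFrame(
        0.0, index=external_features.index, columns=handle.feature_ids
    )
    X[shared] = external_features[shared]
    Xs = handle.scaler.transform(X.to_numpy(dtype=float))
    y = external_labels.loc[X.index].to_numpy()
    p = handle.model.predict_proba(Xs)[:, 1]
    out = {"auroc": float(roc_auc_score(y, p))}
    if repeats > 0:
        cases = np.flatnonzero(y == 1)
        ctrls = np.flatnonzero(y == 0)
        size = group_size or min(len(cases), len(ctrls))
        scores = []
        for r in range(repeats):
            rng = substream(seed, "cross-cohort", r)
            pick = np.concatenate(
                [
                    rng.choice(cases, size=min(size, len(cases)), replace=False),
                    rng.choice(ctrls, size=min(size, len(ctrls)), replace=False),
                ]
            )
            scores.append(roc_auc_score(y[pick], p[pick]))
        out["auroc_mean"] = float(np.mean(scores))
        out["auroc_sd"] = float(np.std(scores, ddof=1)) if repeats > 1 else 0.0
    return out
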