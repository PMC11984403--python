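"""Correlation, cross-validated Ki67 prediction, entropy, group tests.

The prediction task mirrors the in vivo evaluation: biopsy-level MRI
metrics predict the histological Ki67+ fraction under five-fold
cross-validation (R^2 and RMS error on pooled out-of-fold predictions),
and voxelwise Ki67+ maps are produced under a leave-one-patient-out
scheme so a patient's own biopsies never train their map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import GroupKFold, KFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "CVReport",
    "FEATURE_SETS",
    "pearson",
    "cv_predict",
    "predict_map",
    "histogram_entropy",
    "group_compare",
]

#: The four biopsy feature sets compared in the prediction study.
FEATURE_SETS: Mapping[str, tuple[str, ...]] = {
    "kio_only": ("k_io",),
    "standard_mri": ("t2w", "dwi", "adc", "ce_t1w"),
    "dce_without_kio": ("Ktrans", "k_bo", "p_b", "p_o"),
    "dce_with_kio": ("Ktrans", "k_bo", "p_b", "p_o", "k_io"),
}

#: Random-forest defaults (hyperparameters exposed, seed-controlled).
RF_N_ESTIMATORS = 500


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome on pooled out-of-fold predictions."""

    r_squared: float
    rms_error: float
    fold_assignments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.r_squared > 1.0:
            raise ValueError("r_squared cannot exceed 1")


def pearson(x, y) -> tuple[float, float, tuple[float, float]]:
    """Pearson correlation with two-sided p and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    ci = (float(np.tanh(z - 1.959963985 * se)), float(np.tanh(z + 1.959963985 * se)))
    return float(r), float(p), ci


def _make_model(model: str, seed: int):
    if model == "rf":
        return RandomForestRegressor(n_estimators=RF_N_ESTIMATORS, random_state=seed)
    if model == "linear":
        return LinearRegression()
    if model == "tree":
        return DecisionTreeRegressor(random_state=seed)
    if model == "svm":
        return SVR()
    raise ValueError(f"unknown model {model!r}")


def cv_predict(
    table: pd.DataFrame,
    feature_set: Sequence[str],
    model: str = "rf",
    k_folds: int = 5,
    seed: int = 0,
    target: str = "ki67",
    grouped: bool = False,
) -> tuple[CVReport, np.ndarray]:
    """K-fold cross-validated prediction of the histology target.

    Row-level fold assignment by default (the biopsy dataset is split
    almost equally regardless of patient); set ``grouped=True`` for
    patient-grouped folds.  In row-level mode a warning is raised when a
    patient's biopsies span folds, making the leakage explicit.

    Returns the :class:`CVReport` (R^2 and RMS error computed on pooled
    out-of-fold predictions only) and the out-of-fold prediction vector.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    missing = [f for f in feature_set if f not in table.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    x = table[list(feature_set)].to_numpy(float)
    y = table[target].to_numpy(float)
    n = len(table)
    folds = np.empty(n, dtype=int)
    preds = np.empty(n, dtype=float)

    if grouped:
        if "patient_id" not in table.columns:
            raise ValueError("grouped CV requires a patient_id column")
        splitter = GroupKFold(n_splits=k_folds)
        split = splitter.split(x, y, groups=table["patient_id"].to_numpy())
    else:
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        split = splitter.split(x, y)

    for fold_id, (train, test) in enumerate(split):
        est = _make_model(model, seed)
        est.fit(x[train], y[train])
        preds[test] = est.predict(x[test])
        folds[test] = fold_id

    if not grouped and "patient_id" in table.columns:
        pid = table["patient_id"].to_numpy()
        spans = pd.DataFrame({"pid": pid, "fold": folds}).groupby("pid")["fold"].nunique()
        if (spans > 1).any():
            warnings.warn(
                "row-level CV splits some patients across folds "
                "(use grouped=True for patient-independent folds)",
                stacklevel=2,
            )

    report = CVReport(
        r_squared=float(r2_score(y, preds)),
        rms_error=float(np.sqrt(np.mean((y - preds) ** 2))),
        fold_assignments=folds,
        seed=seed,
    )
    return report, preds


def predict_map(
    feature_maps: Mapping[str, np.ndarray],
    mask: np.ndarray,
    training_table: pd.DataFrame,
    held_out_patient,
    feature_set: Sequence[str],
    model: str = "rf",
    seed: int = 0,
    target: str = "ki67",
) -> np.ndarray:
    """Voxelwise Ki67+ prediction under leave-one-patient-out training.

    The model is trained on every biopsy row except those of
    ``held_out_patient`` and applied to that patient's feature maps over
    the tumor mask; predictions are clipped to [0, 1].
    """
    missing = [f for f in feature_set if f not in feature_maps]
    if missing:
        raise ValueError(f"missing feature maps: {missing}")
    mask = np.asarray(mask, dtype=bool)
    train = training_table[training_table["patient_id"] != held_out_patient]
    if len(train) == len(training_table):
        raise ValueError(f"held-out patient {held_out_patient!r} not in table")
    est = _make_model(model, seed)
    est.fit(train[list(feature_set)].to_numpy(float), train[target].to_numpy(float))
    x_vox = np.column_stack([np.asarray(feature_maps[f], float)[mask] for f in feature_set])
    out = np.full(mask.shape, np.nan)
    out[mask] = np.clip(est.predict(x_vox), 0.0, 1.0)
    return out


def histogram_entropy(map_data: np.ndarray, mask: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the masked voxel histogram.

    The map is min-max normalized over the mask before binning into
    ``n_bins`` equal bins (mirroring 8-bit grayscale histogram entropy),
    so the result is invariant to affine intensity rescaling; a constant
    map has zero entropy.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(map_data, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite voxels under mask")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return 0.0
    norm = (vals - lo) / (hi - lo)
    counts, _ = np.histogram(norm, bins=n_bins, range=(0.0, 1.0))
    f = counts[counts > 0] / vals.size
    return float(-(f * np.log2(f)).sum())


def group_compare(groups: Sequence[np.ndarray], test: str = "t", **kwargs):
    """Group comparison delegating to standard tests.

    ``test``: ``t`` (unpaired two-sample), ``mannwhitney``, ``anova_tukey``
    (one-way ANOVA + Tukey HSD pairwise set), or ``two_way_anova`` (pass
    ``data``, ``dv``, ``factors`` instead of groups).

    Returns a dict with the statistic, p-value, the test used, and for
    ANOVA the pairwise Tukey table.
    """
    if test == "two_way_anova":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        data, dv, factors = kwargs["data"], kwargs["dv"], kwargs["factors"]
        formula = f"{dv} ~ C({factors[0]}) * C({factors[1]})"
        table = sm.stats.anova_lm(ols(formula, data=data).fit(), typ=2)
        return {"test": test, "anova_table": table}

    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    if test == "t":
        stat, p = stats.ttest_ind(groups[0], groups[1])
        return {"test": "t", "statistic": float(stat), "p": float(p)}
    if test == "mannwhitney":
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return {"test": "mannwhitney", "statistic": float(stat), "p": float(p)}
    if test == "anova_tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        stat, p = stats.f_oneway(*groups)
        values = np.concatenate(groups)
        labels = np.concatenate(
            [np.full(g.size, i) for i, g in enumerate(groups)]
        )
        tukey = pairwise_tukeyhsd(values, labels)
        return {
            "test": "anova_tukey",
            "statistic": float(stat),
            "p": float(p),
            "tukey": tukey.summary(),
            "tukey_pvalues": np.asarray(tukey.pvalues, dtype=float),
        }
    raise ValueError(f"unknown test {test!r}")
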