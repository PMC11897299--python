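"""Covariate residualisation and control-referenced z-scoring.

ROI volumes carry strong age, sex and total-brain-volume effects that are
nuisance variation for diagnosis.  Following standard practice in imaging
cohorts, each ROI feature is regressed on the covariates **using control
subjects only**; every subject (controls and patients alike) is then
residualised with that control model and z-scored by the controls'
residual mean and standard deviation.  Fitting on controls only means
disease-associated shifts in the patient groups survive the adjustment.

SNP genotypes are ordinal allele counts and are passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from dataclasses import replace as _dc_replace

import numpy as np

from ._common import ContractError
from .cohort import Cohort

__all__ = ["ResidualizationModel", "fit_residualizer", "apply_residualize_zscore"]

_COVARIATES = ("age", "sex", "brain_volume")


@dataclass
class ResidualizationModel:
    """Per-ROI linear covariate model plus control residual statistics."""

    coef: np.ndarray  # (n_roi, 3): age, sex, brain_volume slopes
    intercept: np.ndarray  # (n_roi,)
    resid_mean: np.ndarray  # (n_roi,) control residual mean (0 by construction)
    resid_sd: np.ndarray  # (n_roi,) control residual sd
    roi_columns: np.ndarray  # column indices the model applies to
    control_label: str
    n_controls: int

    def predict(self, covariates: np.ndarray) -> np.ndarray:
        """Expected ROI values (n, n_roi) from covariates (n, 3)."""
        return covariates @ self.coef.T + self.intercept


def fit_residualizer(cohort: Cohort, control_label: str = "CN") -> ResidualizationModel:
    """Fit one OLS model per ROI feature on control rows only.

    Raises
    ------
    ContractError
        If fewer than 2 control rows exist, or the control design matrix
        (intercept + covariates) is rank-deficient.
    """
    mask = cohort.labels == control_label
    n_controls = int(mask.sum())
    if n_controls < 2:
        raise ContractError(
            f"need >= 2 rows labelled {control_label!r}, found {n_controls}"
        )
    roi_cols = cohort.roi_columns()
    C = cohort.covariates.loc[mask, list(_COVARIATES)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n_controls), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ContractError(
            "degenerate covariate matrix among controls (rank-deficient); "
            "cannot residualise"
        )
    Y = cohort.features[np.ix_(mask, roi_cols)]
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)  # (4, n_roi)
    fitted = design @ beta
    resid = Y - fitted
    sd = resid.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = roi_cols[np.flatnonzero(sd <= 0)]
        raise ContractError(f"zero residual variance in ROI columns {bad.tolist()}")
    return ResidualizationModel(
        coef=beta[1:].T,
        intercept=beta[0],
        resid_mean=resid.mean(axis=0),  # ~0 up to float rounding
        resid_sd=sd,
        roi_columns=roi_cols,
        control_label=control_label,
        n_controls=n_controls,
    )


def apply_residualize_zscore(model: ResidualizationModel, cohort: Cohort) -> Cohort:
    """Residualise and z-score ROI columns of every subject; SNPs untouched.

    Transformed ROI value = (raw - predicted-from-covariates - control
    residual mean) / control residual sd.  Patients are transformed with the
    controls' model — no refit — so class shifts are preserved.
    """
    if cohort.features.shape[1] <= int(model.roi_columns.max(initial=-1)):
        raise ContractError("cohort feature matrix does not match fitted model schema")
    kinds = [cohort.feature_kinds[i] for i in model.roi_columns]
    if any(k != "roi" for k in kinds):
        raise ContractError("model ROI columns do not align with cohort feature kinds")
    C = cohort.covariates[list(_COVARIATES)].to_numpy(dtype=float)
    X = cohort.features.copy()
    raw = X[:, model.roi_columns]
    z = (raw - model.predict(C) - model.resid_mean) / model.resid_sd
    X[:, model.roi_columns] = z
    return _dc_replace(cohort, features=X)
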