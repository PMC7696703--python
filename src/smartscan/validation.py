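"""Latent-biomarker construction and independent-cohort validation.

The scan identifies a panel of co-varying significant variables — the
*latent biomarker*.  A one-component OPLS-EP model trained on the
discovery cohort's region-of-interest differences projects any new
case-minus-control difference vector onto the panel, yielding a single
score per pair.  On an independent single-time-point cohort the scores
are evaluated with a dependent t-test inside the detection window
(pairs sampled less than ``window_years`` before diagnosis) and with
ROC analysis treating that window as the positive condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from smartscan.data_model import PairedCohort
from smartscan.errors import SampleSizeError, SmartError
from smartscan.opls import OPLSModel, fit_opls_ep, predict


@dataclass
class LatentBiomarker:
    """A variable panel plus the OPLS-EP projection that scores it."""

    panel: list[str]
    model: OPLSModel
    window_years: float = 8.0


@dataclass
class ValidationResult:
    """ROC and dependent-t evaluation of latent-biomarker scores."""

    scores: np.ndarray
    positive: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    p_rank: float
    rank_test: str
    t_window: float
    p_window: float
    n_window: int
    n_pos: int
    n_neg: int

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "p_rank": self.p_rank,
            "rank_test": self.rank_test,
            "t_window": self.t_window,
            "p_window": self.p_window,
            "n_window": self.n_window,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def _panel_matrix(cohort: PairedCohort, panel: list[str]) -> np.ndarray:
    missing = [v for v in panel if v not in cohort.variable_ids]
    if missing:
        raise SmartError(f"panel variable(s) missing from cohort: {missing}")
    cols = [cohort.variable_ids.index(v) for v in panel]
    return cohort.d_matrix[:, cols]


def train_biomarker(
    discovery: PairedCohort,
    roi: tuple[float, float],
    panel: list[str],
    window_years: float = 8.0,
) -> LatentBiomarker:
    """One-component OPLS-EP on the panel, trained inside the ROI.

    ``roi = (ttd_max, tbs_max)`` restricts the discovery pairs exactly
    as the region-of-interest model does; the component count is fixed
    at one to limit overfitting.
    """
    mask = (discovery.ttd < roi[0]) & (discovery.tbs < roi[1])
    if mask.sum() < 3:
        raise SampleSizeError(f"only {int(mask.sum())} discovery pair(s) inside roi {roi}")
    ids = [pid for pid, m in zip(discovery.pair_ids, mask) if m]
    sub = discovery.subset(ids)
    model = fit_opls_ep(_panel_matrix(sub, panel), n_ortho=0, variable_ids=list(panel))
    return LatentBiomarker(panel=list(panel), model=model, window_years=window_years)


def score_validation(biomarker: LatentBiomarker, validation: PairedCohort) -> np.ndarray:
    """Predicted latent-biomarker response for each validation pair."""
    D = _panel_matrix(validation, biomarker.panel)
    y_hat, _ = predict(biomarker.model, D)
    return y_hat


def window_ttest(
    scores: np.ndarray, ttd: np.ndarray, window_years: float = 8.0
) -> tuple[float, float, int]:
    """Dependent t-test of the scores for pairs inside the window.

    The scores are case-minus-control projections, so a one-sample t
    against zero is the dependent (paired) t-test.  Returns (t, p, n).
    """
    scores = np.asarray(scores, dtype=float)
    ttd = np.asarray(ttd, dtype=float)
    in_window = ttd < window_years
    n = int(in_window.sum())
    if n < 2:
        raise SampleSizeError(f"fewer than 2 pairs with ttd < {window_years}")
    s = scores[in_window]
    sd = np.std(s, ddof=1)
    if sd <= 1e-12:
        return (np.nan, np.nan, n)
    t = s.mean() / (sd / np.sqrt(n))
    return float(t), float(2 * stats.t.sf(abs(t), df=n - 1)), n


def roc_auc(
    scores: np.ndarray,
    positive: np.ndarray,
    rank_test: str = "mannwhitney",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Empirical ROC, trapezoidal AUC, and a rank test of AUC = 0.5.

    Ties are handled by midranks, so the AUC equals the Mann-Whitney
    U statistic divided by n₁·n₂.  ``rank_test`` selects the
    significance test: "mannwhitney" (rank-sum between the two groups,
    the test matching the two-independent-group comparison) or
    "wilcoxon" (signed-rank of the positive-condition scores against
    zero, the alternative reading).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise SmartError("ROC needs both positive and negative pairs")
    fpr, tpr, thr = roc_curve(positive.astype(int), scores)
    # midrank AUC == Mann-Whitney U / (n1*n2)
    u_stat = stats.mannwhitneyu(scores[positive], scores[~positive]).statistic
    auc = float(u_stat / (n_pos * n_neg))
    if rank_test == "mannwhitney":
        p_rank = float(stats.mannwhitneyu(scores[positive], scores[~positive],
                                          alternative="two-sided").pvalue)
    elif rank_test == "wilcoxon":
        p_rank = float(stats.wilcoxon(scores[positive]).pvalue)
    else:
        raise ValueError(f"unknown rank_test {rank_test!r}")
    return fpr, tpr, thr, auc, p_rank


def validate_biomarker(
    biomarker: LatentBiomarker,
    validation: PairedCohort,
    rank_test: str = "mannwhitney",
) -> ValidationResult:
    """Full evaluation on an independent single-time-point cohort."""
    scores = score_validation(biomarker, validation)
    ttd = validation.ttd
    t_w, p_w, n_w = window_ttest(scores, ttd, biomarker.window_years)
    positive = ttd < biomarker.window_years
    fpr, tpr, thr, auc, p_rank = roc_auc(scores, positive, rank_test=rank_test)
    return ValidationResult(
        scores=scores, positive=positive, fpr=fpr, tpr=tpr, thresholds=thr,
        auc=auc, p_rank=p_rank, rank_test=rank_test,
        t_window=t_w, p_window=p_w, n_window=n_w,
        n_pos=int(positive.sum()), n_neg=int((~positive).sum()),
    )
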