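"""Binary Caco-2 permeability classification and qualitative statistics.

Compounds are labelled Caco-2 permeable (positive) when their apparent
permeability P_app reaches 8e-6 cm/s, i.e. log10 P_app >= log10(8e-6)
~ -5.0969.  From a confusion matrix the Cooper statistics (sensitivity,
specificity, accuracy, positive/negative predictivity), Matthews
correlation, Kubat's G-mean, F1 and Cohen's kappa are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import errors

#: classification threshold: linear P_app in cm/s
DEFAULT_THRESHOLD_PAPP = 8e-6


def binarize(
    log_papp,
    threshold_papp: float = DEFAULT_THRESHOLD_PAPP,
    boundary_positive: bool = True,
) -> np.ndarray | bool:
    """Label log10 P_app values Caco-2 permeable (True) / impermeable (False).

    The boundary value is assigned positive by default (configurable).
    """
    arr = np.asarray(log_papp, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise errors.ValidationError("non-finite log_papp value in binarize")
    cut = math.log10(threshold_papp)
    labels = arr >= cut if boundary_positive else arr > cut
    if np.ndim(log_papp) == 0:
        return bool(labels)
    return labels


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise errors.ValidationError(f"{name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise errors.ValidationError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, observed, predicted) -> "ConfusionMatrix":
        obs = np.asarray(observed, bool)
        pred = np.asarray(predicted, bool)
        if obs.shape != pred.shape:
            raise errors.ValidationError("label vectors differ in length")
        return cls(
            tp=int(np.sum(obs & pred)),
            fp=int(np.sum(~obs & pred)),
            tn=int(np.sum(~obs & ~pred)),
            fn=int(np.sum(obs & ~pred)),
        )


def cooper_stats(m: ConfusionMatrix) -> dict[str, float | None]:
    """Cooper statistics plus MCC, G-mean, F1 and Cohen's kappa.

    A statistic whose denominator is zero is reported as ``None``
    (undefined) rather than raising; MCC with a fully zero marginal is
    reported as 0.0 by the usual convention.
    """
    tp, fp, tn, fn = m.tp, m.fp, m.tn, m.fn
    total = m.total

    def ratio(num, den):
        return num / den if den else None

    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    acc = (tp + tn) / total
    pp = ratio(tp, tp + fp)
    np_ = ratio(tn, tn + fn)

    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den else 0.0

    g_mean = math.sqrt(se * sp) if se is not None and sp is not None else None
    f_measure = (
        2.0 * pp * se / (pp + se) if pp is not None and se is not None and (pp + se) else None
    )

    # Cohen's kappa: chance agreement from the marginals
    p_yes = ((tp + fp) / total) * ((tp + fn) / total)
    p_no = ((tn + fn) / total) * ((tn + fp) / total)
    p_e = p_yes + p_no
    kappa = (acc - p_e) / (1.0 - p_e) if p_e != 1.0 else None

    return {
        "se": se,
        "sp": sp,
        "acc": acc,
        "pp": pp,
        "np": np_,
        "mcc": mcc,
        "g_mean": g_mean,
        "f_measure": f_measure,
        "kappa": kappa,
    }


def classify_predictions(
    observed_log_papp,
    predicted_log_papp,
    threshold_papp: float = DEFAULT_THRESHOLD_PAPP,
) -> dict:
    """End-to-end qualitative evaluation of a quantitative model.

    Binarizes observed and predicted log P_app at the threshold, builds the
    confusion matrix (observed label = truth) and returns the matrix counts
    together with the full statistics report.
    """
    obs = binarize(observed_log_papp, threshold_papp)
    pred = binarize(predicted_log_papp, threshold_papp)
    m = ConfusionMatrix.from_labels(obs, pred)
    report = cooper_stats(m)
    report.update({"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn})
    return report
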