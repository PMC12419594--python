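"""Evaluation metrics and decision thresholds for presence/background models.

AUC is the Mann-Whitney pair statistic (probability a random presence
outscores a random background point, ties counted half).  The Continuous
Boyce Index (CBI) is the Spearman correlation between predicted-to-expected
presence ratios and suitability rank over sliding score windows; it targets
presence-only evaluation.  Binarization uses the score maximizing
sensitivity + specificity with the background as pseudoabsences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr

from .errors import DegenerateInputError

#: models with AUC above this are conventionally considered acceptable
AUC_ACCEPTABLE = 0.7


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: mean over presence x background pairs of
    1[p > b] + 0.5 * 1[p == b], computed via average ranks."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise DegenerateInputError("both presence and background scores are required")
    ranks = rankdata(np.concatenate([p, b]))
    rp = ranks[: p.size].sum()
    return float((rp - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


def boyce_index(
    presence_scores,
    evaluation_scores,
    n_windows: int = 101,
    window_width: float = 0.1,
) -> float:
    """Continuous Boyce Index over sliding windows of the score range.

    Windows of width ``window_width * (score range)`` are centred at
    ``n_windows`` evenly spaced midpoints.  In each window, P is the fraction
    of presence scores inside and E the fraction of evaluation scores inside;
    windows with E = 0 are skipped.  The index is the Spearman correlation
    between P/E and the window midpoint.
    """
    p = np.asarray(presence_scores, dtype=float)
    e = np.asarray(evaluation_scores, dtype=float)
    if p.size == 0 or e.size == 0:
        raise DegenerateInputError("presence and evaluation scores are required")
    lo, hi = float(e.min()), float(e.max())
    if hi == lo:
        raise DegenerateInputError("evaluation scores are constant; CBI undefined")
    width = window_width * (hi - lo)
    mids = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
    ratios, kept_mids = [], []
    for mid in mids:
        a, b = mid - width / 2.0, mid + width / 2.0
        e_frac = np.mean((e >= a) & (e <= b))
        if e_frac == 0.0:
            continue
        p_frac = np.mean((p >= a) & (p <= b))
        ratios.append(p_frac / e_frac)
        kept_mids.append(mid)
    if len(ratios) < 2:
        raise DegenerateInputError("fewer than two usable windows; CBI undefined")
    rho = spearmanr(ratios, kept_mids).statistic
    return float(rho)


def max_sens_spec_threshold(presence_scores, background_scores) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the unique pooled scores.  At threshold t, sensitivity is
    the fraction of presences with score >= t (a presence at the threshold
    counts as predicted present) and specificity the fraction of background
    with score < t.  Ties in the objective resolve to the smallest t, the
    most inclusive cut.  Returns (threshold, sensitivity, specificity).
    """
    p = np.sort(np.asarray(presence_scores, dtype=float))
    b = np.sort(np.asarray(background_scores, dtype=float))
    if p.size == 0 or b.size == 0:
        raise DegenerateInputError("both presence and background scores are required")
    cand = np.unique(np.concatenate([p, b]))
    sens = 1.0 - np.searchsorted(p, cand, side="left") / p.size
    spec = np.searchsorted(b, cand, side="left") / b.size
    total = sens + spec
    i = int(np.argmax(total))  # argmax returns the first (smallest t) maximizer
    return float(cand[i]), float(sens[i]), float(spec[i])


def classification_bookkeeping(
    predicted_present: set, presence_catchments: set
) -> tuple[int, int]:
    """(false negatives, possible new catchments).

    False negatives are recorded-presence catchments the binary map calls
    absent; possible-new catchments are predicted-present catchments with no
    record.
    """
    fn = len(presence_catchments - predicted_present)
    new = len(predicted_present - presence_catchments)
    return fn, new


@dataclass
class EvaluationReport:
    """Per-species model evaluation mirroring the summary-table layout."""

    species_id: str
    auc: float
    cbi: float
    threshold: float
    sensitivity: float
    specificity: float
    n_false_negative: int
    n_possible_new: int
    pct_predicted_present: float
    auc_acceptable: bool

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "auc": self.auc,
            "cbi": self.cbi,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_false_negative": self.n_false_negative,
            "n_possible_new": self.n_possible_new,
            "pct_predicted_present": self.pct_predicted_present,
            "auc_acceptable": self.auc_acceptable,
        }


def evaluate_model(
    species_id: str,
    presence_scores,
    background_scores,
    landscape_scores,
    presence_catchments: set,
    catchment_ids,
    n_windows: int = 101,
    window_width: float = 0.1,
) -> tuple[EvaluationReport, "np.ndarray"]:
    """Full per-species evaluation: AUC, CBI, threshold, and the bookkeeping
    counts computed over the whole landscape.

    Returns the report and the binary (0/1) landscape map aligned with
    ``catchment_ids``.
    """
    a = auc(presence_scores, background_scores)
    cbi = boyce_index(presence_scores, landscape_scores, n_windows, window_width)
    thr, sens, spec = max_sens_spec_threshold(presence_scores, background_scores)
    scores = np.asarray(landscape_scores, dtype=float)
    binary = (scores >= thr).astype(int)
    ids = np.asarray(catchment_ids, dtype=object)
    predicted_present = set(ids[binary == 1])
    fn, new = classification_bookkeeping(predicted_present, presence_catchments)
    report = EvaluationReport(
        species_id=species_id,
        auc=a,
        cbi=cbi,
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        n_false_negative=fn,
        n_possible_new=new,
        pct_predicted_present=100.0 * float(binary.mean()),
        auc_acceptable=a > AUC_ACCEPTABLE,
    )
    return report, binary
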