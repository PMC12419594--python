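"""Survey-effort-weighted background point selection.

Presence/background modelling assumes every site had an equal chance of
being surveyed; consolidated agency data violate that badly.  The remedy
implemented here: represent each catchment by its centroid (one candidate
point per catchment), drop every catchment inside a HUC10 with no survey
records at all, drop the focal species' presence catchments, then draw up
to ``n_background`` catchments with probability proportional to survey
effort.  When the candidate pool is already at or under the cap, the whole
pool is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CatchmentFrame
from .errors import DegenerateInputError, InvalidConfigError

WEIGHT_MODES = ("catchment_share", "huc10_share")


@dataclass(frozen=True)
class BackgroundConfig:
    """Settings for background selection.

    ``weight_mode`` chooses the effort weighting: ``catchment_share`` uses
    each catchment's share of all survey events; ``huc10_share`` spreads the
    encompassing HUC10's share evenly over its candidate catchments.
    ``floor_frac`` keeps eligible-but-unsurveyed catchments selectable under
    catchment_share: zero weights are replaced by ``floor_frac / n_candidates``
    before renormalisation (set 0 to disable).
    """

    n_background: int = 10_000
    weight_mode: str = "catchment_share"
    floor_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 1:
            raise InvalidConfigError("n_background must be >= 1")
        if self.weight_mode not in WEIGHT_MODES:
            raise InvalidConfigError(
                f"weight_mode must be one of {WEIGHT_MODES}, got {self.weight_mode!r}"
            )
        if self.floor_frac < 0:
            raise InvalidConfigError("floor_frac must be nonnegative")


def eligible_background(frame: CatchmentFrame, presences: set) -> list[str]:
    """Candidate catchments after both exclusion rules.

    Removes (1) every catchment whose HUC10 had zero survey events across all
    species, and (2) every focal-species presence catchment.  Each survivor
    is one candidate point (its centroid).
    """
    totals = frame.huc10_survey_totals()
    surveyed_huc10 = set(totals.index[totals > 0])
    df = frame.data
    mask = df["huc10"].isin(surveyed_huc10) & ~df["catchment_id"].isin(presences)
    candidates = df.loc[mask, "catchment_id"].tolist()
    if not candidates:
        raise DegenerateInputError(
            "no eligible background catchments remain after excluding "
            "unsurveyed HUC10s and focal-species presence catchments"
        )
    return candidates


def selection_weights(
    candidates: list[str],
    frame: CatchmentFrame,
    mode: str = "catchment_share",
    floor_frac: float = 0.1,
) -> np.ndarray:
    """Per-candidate selection probabilities, summing to one.

    catchment_share: proportional to the catchment's share of all survey
    events (zero shares floored, see :class:`BackgroundConfig`).
    huc10_share: the encompassing HUC10's share of all survey events divided
    evenly among that HUC10's candidates.
    """
    if not candidates:
        raise DegenerateInputError("candidate set is empty")
    if mode not in WEIGHT_MODES:
        raise InvalidConfigError(f"unknown weight mode {mode!r}")
    df = frame.data.set_index("catchment_id")
    total = float(frame.data["survey_count"].sum())
    if total == 0:
        raise DegenerateInputError("no survey events on the frame; weights undefined")
    if mode == "catchment_share":
        w = df.loc[candidates, "survey_count"].to_numpy(dtype=float) / total
        if floor_frac > 0:
            eps = floor_frac / len(candidates)
            w[w == 0.0] = eps
    else:
        huc10_totals = frame.huc10_survey_totals()
        cand_huc10 = df.loc[candidates, "huc10"]
        members_per_huc10 = cand_huc10.value_counts()
        share = huc10_totals.reindex(cand_huc10).to_numpy(dtype=float) / total
        w = share / members_per_huc10.reindex(cand_huc10).to_numpy(dtype=float)
    s = w.sum()
    if s <= 0:
        raise DegenerateInputError("all candidate weights are zero")
    return w / s


def sample_background(
    candidates: list[str],
    weights: np.ndarray,
    config: BackgroundConfig,
) -> list[str]:
    """Weighted sample of catchments without replacement, capped at
    ``n_background``.

    If the pool is at or under the cap, all candidates are used (the rule the
    widest-ranging species triggers in practice).  Otherwise sampling follows
    the successive draw-and-remove scheme, realised by the Gumbel top-k
    equivalence so it is vectorised and reproducible.  Output is sorted by
    catchment id.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(candidates):
        raise InvalidConfigError("weights and candidates must align")
    if len(candidates) <= config.n_background:
        return sorted(candidates)
    rng = np.random.default_rng(config.seed)
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    keys = logw + rng.gumbel(size=len(weights))
    top = np.argpartition(-keys, config.n_background)[: config.n_background]
    return sorted(np.asarray(candidates, dtype=object)[top].tolist())


def background_audit(
    candidates: list[str], weights: np.ndarray, selected: list[str]
) -> pd.DataFrame:
    """Audit table: candidate id, selection weight, selected flag."""
    sel = set(selected)
    return pd.DataFrame(
        {
            "catchment_id": candidates,
            "weight": weights,
            "selected": [c in sel for c in candidates],
        }
    )
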