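"""Synthetic catchment landscapes with known truth.

Real analyses of this kind consume multi-agency survey records joined to
regional GIS layers.  Neither is redistributable, so this module builds a
stand-in landscape from first principles: a nested HUC8 > HUC10 > HUC12 >
catchment hierarchy laid out in abstract projected coordinates, spatially
autocorrelated environmental covariates, per-species "true" occupancy
probabilities generated from known coefficient vectors through a logistic
link, spatially uneven survey effort, and an imperfect-detection,
presence-only observation process.  Because the truth is known, every
downstream stage (background sampling, maximum-entropy fitting, thresholding,
richness stacking, prioritization) can be tested for recovery rather than
merely for not crashing.

Spatial autocorrelation is produced by Gaussian-kernel smoothing of white
noise sampled at the catchment centroids themselves: each covariate value is
a kernel-weighted combination of per-catchment standard normals with weights
normalised so the marginal variance is one.  As the kernel range goes to zero
the field degenerates to i.i.d. noise; as it exceeds the landscape extent the
field becomes nearly constant.  Only the rank structure of the covariates
matters downstream, so a full Gaussian-process simulator would buy nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, DataError

RSGCN_RANKS = ("very_high", "high", "moderate", "not_listed")

#: state labels cycled over HUC8s; six units mirror a six-state study region
STATE_LABELS = ("CT", "RI", "MA", "VT", "NH", "ME")


@dataclass(frozen=True)
class LandscapeConfig:
    """Size and spatial-structure knobs for a synthetic landscape.

    The default nesting (6 x 4 x 5 x 42) yields 5,040 catchments in 24 HUC10s
    -- the study's species count at roughly 1/13 of its catchment count, which
    keeps a full multi-species run at desk scale while leaving every level of
    the hierarchy populated enough to matter.
    """

    n_huc8: int = 6
    n_huc10_per_huc8: int = 4
    n_huc12_per_huc10: int = 5
    n_catchments_per_huc12: int = 42
    n_covariates: int = 8
    autocorrelation_range: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_huc8,
            self.n_huc10_per_huc8,
            self.n_huc12_per_huc10,
            self.n_catchments_per_huc12,
        )
        if any(int(c) != c or c < 1 for c in counts):
            raise InvalidConfigError(f"all hierarchy counts must be >= 1, got {counts}")
        if self.n_covariates < 1:
            raise InvalidConfigError("n_covariates must be >= 1")
        if self.autocorrelation_range < 0:
            raise InvalidConfigError("autocorrelation_range must be nonnegative")

    @property
    def n_catchments(self) -> int:
        return (
            self.n_huc8
            * self.n_huc10_per_huc8
            * self.n_huc12_per_huc10
            * self.n_catchments_per_huc12
        )


@dataclass(frozen=True)
class TrueSpecies:
    """Data-generating parameters for one species.

    ``coefficients`` act on the covariate columns through a logistic link;
    the intercept is re-calibrated by :func:`true_suitability` so that the
    landscape-mean occupancy probability equals ``prevalence_target``.
    """

    species_id: str
    coefficients: Mapping[str, float]
    intercept: float = 0.0
    prevalence_target: float = 0.2
    rsgcn_rank: str = "not_listed"

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_target < 1.0):
            raise InvalidConfigError(
                f"prevalence_target must lie strictly in (0,1), got {self.prevalence_target}"
            )
        if self.rsgcn_rank not in RSGCN_RANKS:
            raise InvalidConfigError(
                f"rsgcn_rank must be one of {RSGCN_RANKS}, got {self.rsgcn_rank!r}"
            )


@dataclass(frozen=True)
class SurveyModel:
    """Spatially uneven survey effort with imperfect detection.

    Effort is allocated to HUC10s by a symmetric Dirichlet draw with
    concentration ``effort_concentration``: small values concentrate surveys
    in a few HUC10s and leave others entirely unsurveyed, large values spread
    effort near-uniformly.  Within a HUC10 the surveyed catchment is chosen
    uniformly.
    """

    effort_concentration: float = 1.0
    n_surveys: int = 8000
    detection_prob: float = 0.7
    seed: int = 0
    year_range: tuple[int, int] = (1970, 2022)

    def __post_init__(self) -> None:
        if self.n_surveys < 1:
            raise InvalidConfigError("n_surveys must be >= 1")
        if not (0.0 < self.detection_prob <= 1.0):
            raise InvalidConfigError(
                f"detection_prob must lie in (0,1], got {self.detection_prob}"
            )
        if self.effort_concentration < 0:
            raise InvalidConfigError("effort_concentration must be nonnegative")


def _grid_side(n: int) -> int:
    return int(np.ceil(np.sqrt(n)))


def _grid_centers(n: int, extent: float) -> np.ndarray:
    """Centers of the first n cells of a square grid filling [0, extent]^2."""
    side = _grid_side(n)
    cell = extent / side
    idx = np.arange(n)
    cx = (idx % side + 0.5) * cell
    cy = (idx // side + 0.5) * cell
    return np.column_stack([cx, cy])


def generate_hierarchy(config: LandscapeConfig) -> pd.DataFrame:
    """Build the nested catchment table.

    HUC8 blocks tile a square region; HUC10s tile each HUC8 block, HUC12s
    each HUC10 block, and catchment centroids are jittered uniformly inside
    their HUC12 cell, so members of the same hydrologic unit are spatially
    contiguous.  Codes follow the digit-string convention: a HUC10 code
    extends its HUC8 code, a HUC12 its HUC10.
    """
    rng = np.random.default_rng(config.seed)
    huc8_extent = 100.0
    side8 = _grid_side(config.n_huc8)
    region = huc8_extent * side8
    huc8_origin = _grid_centers(config.n_huc8, region) - huc8_extent / 2.0

    huc10_cell = huc8_extent / _grid_side(config.n_huc10_per_huc8)
    huc12_cell = huc10_cell / _grid_side(config.n_huc12_per_huc10)

    rows = []
    for i8 in range(config.n_huc8):
        huc8 = f"{i8 + 1:08d}"
        state = STATE_LABELS[i8 % len(STATE_LABELS)]
        o10 = (
            _grid_centers(config.n_huc10_per_huc8, huc8_extent)
            - huc10_cell / 2.0
            + huc8_origin[i8]
        )
        for i10 in range(config.n_huc10_per_huc8):
            huc10 = huc8 + f"{i10:02d}"
            o12 = (
                _grid_centers(config.n_huc12_per_huc10, huc10_cell)
                - huc12_cell / 2.0
                + o10[i10]
            )
            for i12 in range(config.n_huc12_per_huc10):
                huc12 = huc10 + f"{i12:02d}"
                jitter = rng.uniform(
                    0.0, huc12_cell, size=(config.n_catchments_per_huc12, 2)
                )
                for ic in range(config.n_catchments_per_huc12):
                    rows.append(
                        (
                            huc12,
                            huc10,
                            huc8,
                            state,
                            o12[i12, 0] + jitter[ic, 0],
                            o12[i12, 1] + jitter[ic, 1],
                        )
                    )
    frame = pd.DataFrame(
        rows, columns=["huc12", "huc10", "huc8", "state", "centroid_x", "centroid_y"]
    )
    frame.insert(0, "catchment_id", [f"C{i:06d}" for i in range(len(frame))])
    frame["survey_count"] = 0
    return frame


def _kernel_weights(xy: np.ndarray, length_scale: float) -> np.ndarray:
    """Row-normalised Gaussian smoothing weights over catchment centroids.

    Rows are scaled so the smoothed field has unit marginal variance when
    applied to standard-normal noise.
    """
    d2 = (
        np.sum(xy**2, axis=1)[:, None]
        + np.sum(xy**2, axis=1)[None, :]
        - 2.0 * (xy @ xy.T)
    )
    np.maximum(d2, 0.0, out=d2)
    w = np.exp(-0.5 * d2 / length_scale**2)
    w /= np.sqrt(np.sum(w**2, axis=1))[:, None]
    return w


def generate_covariates(
    frame: pd.DataFrame, config: LandscapeConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw spatially autocorrelated covariates at the catchment centroids.

    Returns the covariate table (indexed like ``frame``, first column
    ``catchment_id``) and a mapping column -> ``"continuous"``/``"binary"``.
    Continuous columns are named ``env_01`` ... ; the single binary column,
    ``tidal``, flags catchments in the southern coastal strip (lowest decile
    of y), emulating a tidal-influence indicator.
    """
    if frame.empty:
        raise DataError("catchment frame is empty")
    rng = np.random.default_rng(config.seed + 1)
    xy = frame[["centroid_x", "centroid_y"]].to_numpy(dtype=np.float32)
    n = len(frame)
    noise = rng.standard_normal((n, config.n_covariates))
    if config.autocorrelation_range == 0.0:
        values = noise
    else:
        w = _kernel_weights(xy, np.float32(config.autocorrelation_range))
        values = w @ noise.astype(np.float32)
    cols = {f"env_{j + 1:02d}": values[:, j].astype(float) for j in range(config.n_covariates)}
    kinds = {name: "continuous" for name in cols}
    y = frame["centroid_y"].to_numpy()
    cols["tidal"] = (y <= np.quantile(y, 0.10)).astype(float)
    kinds["tidal"] = "binary"
    table = pd.DataFrame(cols)
    table.insert(0, "catchment_id", frame["catchment_id"].to_numpy())
    return table, kinds


def generate_priority_covariates(
    frame: pd.DataFrame, config: LandscapeConfig
) -> pd.DataFrame:
    """Auxiliary prioritization inputs: protected land, forest, wetland,
    projected land-use change (all percent of catchment, 0-100) and a
    climate-resilience score in [0,1].

    Each is a monotone transform of an independent autocorrelated field, so
    the columns carry spatial structure but are unrelated to the species
    truth -- mirroring external GIS layers that arrive precomputed.
    """
    rng = np.random.default_rng(config.seed + 2)
    xy = frame[["centroid_x", "centroid_y"]].to_numpy(dtype=np.float32)
    n = len(frame)
    noise = rng.standard_normal((n, 5))
    if config.autocorrelation_range == 0.0:
        fields = noise
    else:
        w = _kernel_weights(xy, np.float32(config.autocorrelation_range))
        fields = (w @ noise.astype(np.float32)).astype(float)
    from scipy.special import expit

    out = pd.DataFrame(
        {
            "catchment_id": frame["catchment_id"].to_numpy(),
            # protected land is rare and right-skewed
            "percent_protected": 100.0 * expit(fields[:, 0] - 1.5),
            "percent_forest": 100.0 * expit(0.8 * fields[:, 1] + 0.5),
            "percent_wetland": 100.0 * expit(fields[:, 2] - 1.0),
            "landuse_change_pct": 100.0 * expit(fields[:, 3] - 2.0),
            "resilience": expit(fields[:, 4]),
        }
    )
    return out


def true_suitability(
    covariates: pd.DataFrame, species: TrueSpecies
) -> pd.Series:
    """Per-catchment occupancy probability under the species' logistic truth.

    The intercept is found by a 1-D root solve (Brent) so the landscape mean
    equals ``prevalence_target`` to within 1e-9.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    missing = [k for k in species.coefficients if k not in covariates.columns]
    if missing:
        raise KeyError(f"coefficients reference unknown covariates: {missing}")
    eta = np.zeros(len(covariates))
    for name, coef in species.coefficients.items():
        eta = eta + coef * covariates[name].to_numpy(dtype=float)

    def gap(b: float) -> float:
        return float(np.mean(expit(b + eta))) - species.prevalence_target

    intercept = brentq(gap, -500.0, 500.0, xtol=1e-12)
    suit = expit(intercept + eta)
    return pd.Series(suit, index=covariates["catchment_id"].to_numpy(), name=species.species_id)


def simulate_surveys(frame: pd.DataFrame, model: SurveyModel) -> pd.DataFrame:
    """Allocate survey events over catchments with HUC10-level unevenness.

    Returns a table of (catchment_id, year) events.  Use
    :func:`attach_survey_counts` to record per-catchment totals on the frame.
    """
    rng = np.random.default_rng(model.seed)
    huc10s = np.sort(frame["huc10"].unique())
    conc = model.effort_concentration if model.effort_concentration > 0 else 1e-3
    weights = rng.dirichlet(np.full(len(huc10s), conc))
    counts = rng.multinomial(model.n_surveys, weights)
    groups = {h: g["catchment_id"].to_numpy() for h, g in frame.groupby("huc10")}
    events = []
    for h, c in zip(huc10s, counts):
        if c == 0:
            continue
        members = groups[h]
        picks = members[rng.integers(0, len(members), size=c)]
        events.append(picks)
    catchments = np.concatenate(events) if events else np.array([], dtype=object)
    years = rng.integers(model.year_range[0], model.year_range[1] + 1, size=len(catchments))
    return pd.DataFrame({"catchment_id": catchments, "year": years})


def attach_survey_counts(frame: pd.DataFrame, surveys: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``frame`` with ``survey_count`` set from the events."""
    counts = surveys["catchment_id"].value_counts()
    out = frame.copy()
    out["survey_count"] = (
        out["catchment_id"].map(counts).fillna(0).astype(int)
    )
    return out


def sample_occurrences(
    truth: pd.Series,
    surveys: pd.DataFrame,
    detection_prob: float,
    seed: int,
    species_id: str | None = None,
) -> pd.DataFrame:
    """Presence-only occurrence records under imperfect detection.

    Latent occupancy is one Bernoulli(suitability) draw per catchment; each
    survey event in an occupied catchment then yields a record with
    probability ``detection_prob``.  Only detections are returned -- there
    are no absence records, matching field datasets consolidated to
    presence-only form.
    """
    if not (0.0 < detection_prob <= 1.0):
        raise InvalidConfigError(
            f"detection_prob must lie in (0,1], got {detection_prob}"
        )
    if species_id is None:
        species_id = str(truth.name)
    rng = np.random.default_rng(seed)
    occupied = rng.random(len(truth)) < truth.to_numpy()
    occupied_ids = set(truth.index[occupied])
    in_occ = surveys["catchment_id"].isin(occupied_ids).to_numpy()
    detected = in_occ & (rng.random(len(surveys)) < detection_prob)
    recs = surveys.loc[detected, ["catchment_id", "year"]].copy()
    recs.insert(0, "species_id", species_id)
    recs["habitat"] = np.where(
        rng.random(len(recs)) < 0.8, "lotic", "lentic"
    )
    return recs.reset_index(drop=True)


# ---------------------------------------------------------------------------
# default multi-species study

#: RSGCN ranks in the order species are generated: 2 very-high, 3 high,
#: 2 moderate, 5 not listed -- the composition of the 12-species study.
DEFAULT_RANKS = (
    "very_high", "moderate", "very_high", "high", "not_listed", "high",
    "not_listed", "moderate", "not_listed", "high", "not_listed", "not_listed",
)

#: target landscape prevalences; the spread (0.04-0.35) matches the reported
#: range of percent-of-catchments occupancy across the twelve modelled species
DEFAULT_PREVALENCES = (
    0.04, 0.19, 0.11, 0.08, 0.35, 0.12, 0.20, 0.17, 0.31, 0.06, 0.15, 0.16,
)


def default_species(
    covariate_names: Sequence[str], seed: int, n_species: int = 12
) -> list[TrueSpecies]:
    """Twelve species with sparse random responses to the covariates.

    Each species responds to 3-5 covariates with coefficients of magnitude
    0.8-2.5 and random sign, strong enough that ranks are recoverable yet
    far from deterministic occupancy.
    """
    rng = np.random.default_rng(seed)
    species = []
    names = list(covariate_names)
    for i in range(n_species):
        k = int(rng.integers(3, min(6, len(names) + 1)))
        chosen = rng.choice(len(names), size=k, replace=False)
        coefs = {
            names[j]: float(rng.uniform(0.8, 2.5) * rng.choice([-1.0, 1.0]))
            for j in chosen
        }
        species.append(
            TrueSpecies(
                species_id=f"species_{i + 1:02d}",
                coefficients=coefs,
                prevalence_target=DEFAULT_PREVALENCES[i % len(DEFAULT_PREVALENCES)],
                rsgcn_rank=DEFAULT_RANKS[i % len(DEFAULT_RANKS)],
            )
        )
    return species


@dataclass
class SyntheticDataset:
    """All tables produced for one synthetic study, plus the truth."""

    catchments: pd.DataFrame
    covariates: pd.DataFrame
    covariate_kinds: dict[str, str]
    priority_covariates: pd.DataFrame
    surveys: pd.DataFrame
    occurrences: pd.DataFrame
    truth: pd.DataFrame  # catchment_id x species suitability
    species: list[TrueSpecies] = field(default_factory=list)

    def species_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": [sp.species_id for sp in self.species],
                "rsgcn_rank": [sp.rsgcn_rank for sp in self.species],
                "prevalence_target": [sp.prevalence_target for sp in self.species],
            }
        )

    def write_csvs(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.catchments.to_csv(out / "catchments.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.priority_covariates.to_csv(out / "priority_covariates.csv", index=False)
        self.surveys.to_csv(out / "surveys.csv", index=False)
        self.occurrences.to_csv(out / "occurrences.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.species_table().to_csv(out / "species.csv", index=False)


def simulate_dataset(
    landscape: LandscapeConfig | None = None,
    survey_model: SurveyModel | None = None,
    species: list[TrueSpecies] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a complete study: landscape, covariates, surveys, occurrences.

    ``seed`` drives every stage through independent child streams; explicit
    config objects override the derived seeds with their own.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(4, dtype=np.uint32)
    if landscape is None:
        landscape = LandscapeConfig(seed=int(child[0]) % (2**31))
    if survey_model is None:
        survey_model = SurveyModel(seed=int(child[1]) % (2**31))
    frame = generate_hierarchy(landscape)
    covariates, kinds = generate_covariates(frame, landscape)
    aux = generate_priority_covariates(frame, landscape)
    if species is None:
        env_names = [c for c in covariates.columns if c != "catchment_id"]
        species = default_species(env_names, seed=int(child[2]) % (2**31))
    surveys = simulate_surveys(frame, survey_model)
    frame = attach_survey_counts(frame, surveys)
    truth = pd.DataFrame({"catchment_id": covariates["catchment_id"].to_numpy()})
    occ_parts = []
    occ_seed0 = int(child[3]) % (2**30)
    for i, sp in enumerate(species):
        suit = true_suitability(covariates, sp)
        truth[sp.species_id] = suit.to_numpy()
        occ_parts.append(
            sample_occurrences(
                suit, surveys, survey_model.detection_prob, seed=occ_seed0 + i
            )
        )
    occurrences = (
        pd.concat(occ_parts, ignore_index=True)
        if occ_parts
        else pd.DataFrame(columns=["species_id", "catchment_id", "year", "habitat"])
    )
    return SyntheticDataset(
        catchments=frame,
        covariates=covariates,
        covariate_kinds=kinds,
        priority_covariates=aux,
        surveys=surveys,
        occurrences=occurrences,
        truth=truth,
        species=species,
    )
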