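"""Catchment data model, record filters, and covariate screening.

The analysis unit is the catchment: the land area draining directly to one
stream segment, nested inside HUC12 < HUC10 < HUC8 hydrologic units.
Occurrence records are consolidated to presence-only catchment sets; the
candidate covariates are screened for redundancy with Spearman rank
correlations (drop one of each pair with |rho| above a threshold) and a
variance-inflation-factor check on the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateInputError, InvalidConfigError

CATCHMENT_COLUMNS = ["catchment_id", "huc12", "huc10", "huc8", "centroid_x", "centroid_y"]

SCALE_LABELS = ("catchment", "watershed", "riparian", "huc12", "huc8")


class CatchmentFrame:
    """Validated table of catchments with their HUC nesting and centroids.

    Wraps a DataFrame with columns ``catchment_id, huc12, huc10, huc8,
    state (optional), centroid_x, centroid_y, survey_count``.  Construction
    checks id uniqueness and that the nesting is a proper tree: every HUC12
    belongs to exactly one HUC10 and every HUC10 to exactly one HUC8.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in CATCHMENT_COLUMNS if c not in data.columns]
        if missing:
            raise DataError(f"catchment table missing columns: {missing}")
        data = data.copy()
        if "survey_count" not in data.columns:
            data["survey_count"] = 0
        if "state" not in data.columns:
            data["state"] = None
        if data["catchment_id"].duplicated().any():
            dupes = data.loc[data["catchment_id"].duplicated(), "catchment_id"]
            raise DataError(f"duplicate catchment ids: {sorted(set(dupes))[:5]} ...")
        if (data["survey_count"] < 0).any():
            raise DataError("survey_count must be nonnegative")
        for child, parent in (("huc12", "huc10"), ("huc10", "huc8")):
            parents = data.groupby(child)[parent].nunique()
            bad = parents[parents > 1]
            if len(bad):
                raise DataError(
                    f"nesting violated: {child} codes {list(bad.index)[:5]} map to multiple {parent}s"
                )
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.data["catchment_id"])

    def huc10_survey_totals(self) -> pd.Series:
        """Total survey events per HUC10, summed over all catchments."""
        return self.data.groupby("huc10")["survey_count"].sum()

    def with_survey_counts(self, surveys: pd.DataFrame) -> "CatchmentFrame":
        counts = surveys["catchment_id"].value_counts()
        out = self.data.copy()
        out["survey_count"] = out["catchment_id"].map(counts).fillna(0).astype(int)
        return CatchmentFrame(out)

    @classmethod
    def from_csv(cls, path) -> "CatchmentFrame":
        return cls(pd.read_csv(path, dtype={"huc12": str, "huc10": str, "huc8": str}))


class CovariateTable:
    """Per-catchment environmental values with kind and scale metadata.

    ``kinds`` tags each column continuous or binary; ``scales`` declares the
    spatial scale the value was computed at (catchment, watershed, riparian,
    huc12, huc8) -- metadata only, the numbers arrive precomputed.  Constant
    columns are rejected at load: they carry no information and silently
    break rank correlations.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        kinds: dict[str, str] | None = None,
        scales: dict[str, str] | None = None,
    ):
        if "catchment_id" not in data.columns:
            raise DataError("covariate table must have a catchment_id column")
        if data["catchment_id"].duplicated().any():
            raise DataError("duplicate catchment ids in covariate table")
        values = data.drop(columns=["catchment_id"])
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise DataError("covariate values must be finite")
        names = list(values.columns)
        if kinds is None:
            kinds = {
                c: "binary" if set(np.unique(values[c])) <= {0.0, 1.0} else "continuous"
                for c in names
            }
        for c in names:
            if kinds.get(c) == "binary" and not set(np.unique(values[c])) <= {0.0, 1.0}:
                raise DataError(f"binary covariate {c!r} has values outside {{0,1}}")
            if values[c].nunique() == 1:
                raise DataError(f"covariate {c!r} is constant; remove it from the input")
        self.data = data.reset_index(drop=True)
        self.kinds = dict(kinds)
        self.scales = dict(scales) if scales else {c: "catchment" for c in names}

    @property
    def names(self) -> list[str]:
        return [c for c in self.data.columns if c != "catchment_id"]

    @property
    def continuous(self) -> list[str]:
        return [c for c in self.names if self.kinds[c] == "continuous"]

    def values(self, columns: list[str] | None = None) -> pd.DataFrame:
        cols = columns if columns is not None else self.names
        return self.data.set_index("catchment_id")[cols]

    def subset(self, columns: list[str]) -> "CovariateTable":
        keep = ["catchment_id"] + list(columns)
        return CovariateTable(
            self.data[keep],
            {c: self.kinds[c] for c in columns},
            {c: self.scales[c] for c in columns},
        )

    def with_column(self, name: str, values: pd.Series, kind: str, scale: str) -> "CovariateTable":
        out = self.data.copy()
        out[name] = out["catchment_id"].map(values)
        tbl = CovariateTable.__new__(CovariateTable)
        tbl.data = out
        tbl.kinds = {**self.kinds, name: kind}
        tbl.scales = {**self.scales, name: scale}
        return tbl


# ---------------------------------------------------------------------------
# record filters


def filter_records_by_year(records: pd.DataFrame, cutoff_year: int) -> pd.DataFrame:
    """Keep records with ``year >= cutoff_year``.

    The modelling dataset uses a 1952 cutoff; the survey-priority binary uses
    1992 (records from the last thirty years).  Both are plain parameters.
    """
    return records.loc[records["year"] >= cutoff_year].reset_index(drop=True)


def consolidate_presences(
    records: pd.DataFrame, frame: CatchmentFrame
) -> dict[str, set]:
    """Collapse occurrence records to one presence-only catchment set per species."""
    known = set(frame.ids)
    unknown = set(records["catchment_id"]) - known
    if unknown:
        raise DataError(
            f"occurrence records reference unknown catchments: {sorted(unknown)[:5]}"
        )
    out: dict[str, set] = {}
    for sp, grp in records.groupby("species_id"):
        out[str(sp)] = set(grp["catchment_id"])
    return out


# ---------------------------------------------------------------------------
# covariate screening


def spearman_matrix(covariates: CovariateTable | pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix (average ranks on ties).

    Computed as the Pearson correlation of the rank-transformed columns.
    Pairs involving a constant column come back NaN.
    """
    df = covariates.values() if isinstance(covariates, CovariateTable) else df_no_id(covariates)
    if len(df) < 3:
        raise DataError("need at least 3 rows for rank correlations")
    ranks = df.rank(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def df_no_id(df: pd.DataFrame) -> pd.DataFrame:
    return df.drop(columns=["catchment_id"]) if "catchment_id" in df.columns else df


@dataclass
class ScreeningReport:
    """Outcome of the collinearity screen."""

    spearman: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    dropped: list[str]
    retained: list[str]
    vif: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.70
    notes: list[str] = field(default_factory=list)

    def log_text(self) -> str:
        lines = [f"collinearity screen at |rho| > {self.threshold}"]
        for a, b, r in self.flagged_pairs:
            lines.append(f"flagged: {a} ~ {b} (rho={r:.3f})")
        for name in self.dropped:
            lines.append(f"dropped: {name}")
        for name, v in self.vif.items():
            lines.append(f"vif: {name} = {v:.4f}")
        lines.extend(self.notes)
        return "\n".join(lines)


def screen_collinear(
    matrix: pd.DataFrame,
    threshold: float = 0.70,
    keep_priority: list[str] | None = None,
) -> ScreeningReport:
    """Drop covariates until no retained pair has |rho| strictly above threshold.

    Candidates are considered in ``keep_priority`` order (a reproducible
    stand-in for the expert choice among correlated variables): a covariate is
    retained unless it correlates above the threshold with one already
    retained.  Ties at exactly the threshold are not flagged.
    """
    if not (0.0 < threshold < 1.0):
        raise InvalidConfigError(f"threshold must lie in (0,1), got {threshold}")
    names = list(matrix.columns)
    flagged = [
        (a, b, float(matrix.loc[a, b]))
        for i, a in enumerate(names)
        for b in names[i + 1 :]
        if np.isfinite(matrix.loc[a, b]) and abs(matrix.loc[a, b]) > threshold
    ]
    involved = {n for a, b, _ in flagged for n in (a, b)}
    if keep_priority is None:
        keep_priority = names
    missing = involved - set(keep_priority)
    if missing:
        raise InvalidConfigError(
            f"keep_priority must cover all flagged covariates; missing {sorted(missing)}"
        )
    order = [n for n in keep_priority if n in names]
    order += [n for n in names if n not in order]
    retained: list[str] = []
    dropped: list[str] = []
    for name in order:
        conflict = any(
            np.isfinite(matrix.loc[name, r]) and abs(matrix.loc[name, r]) > threshold
            for r in retained
        )
        (dropped if conflict else retained).append(name)
    retained = [n for n in names if n in set(retained)]  # restore input order
    notes = []
    nan_pairs = int(np.isnan(matrix.to_numpy()).sum() // 2)
    if nan_pairs:
        notes.append(f"{nan_pairs} covariate pair(s) had undefined rho (constant ranks)")
    return ScreeningReport(
        spearman=matrix,
        flagged_pairs=flagged,
        dropped=dropped,
        retained=retained,
        threshold=threshold,
        notes=notes,
    )


def compute_vif(covariates: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from an ordinary least-squares regression of column j on the
    remaining columns plus an intercept.  Exact collinearity is reported as
    ``inf`` rather than raised.
    """
    df = df_no_id(covariates)
    names = list(df.columns)
    x = df.to_numpy(dtype=float)
    n, p = x.shape
    if n < p + 1:
        raise DataError(f"need at least {p + 1} rows for {p} covariates, got {n}")
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        if p == 1:
            out[name] = 1.0
            continue
        y = x[:, j]
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0.0:
            raise DataError(f"covariate {name!r} is constant")
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[name] = float("inf") if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return out


def huc8_occurrence_layer(
    presences: dict[str, set], frame: CatchmentFrame, species_id: str
) -> pd.Series:
    """Binary covariate: 1 for every catchment whose HUC8 holds >= 1 record
    of the focal species.

    Accounts for historical distribution and dispersal limits; being
    species-specific it is excluded from the collinearity screen.
    """
    present = presences.get(species_id, set())
    id_to_huc8 = frame.data.set_index("catchment_id")["huc8"]
    occupied_huc8 = set(id_to_huc8.loc[list(present)]) if present else set()
    values = frame.data["huc8"].isin(occupied_huc8).astype(float)
    return pd.Series(values.to_numpy(), index=frame.ids, name=f"huc8_occurrence_{species_id}")
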