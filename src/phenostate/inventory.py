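"""Core data model for two-census forest inventories.

Trees carry a leaf-phenology label (evergreen / deciduous / unknown), the
stem diameters at the two censuses and their fate over the interval; plots
carry coordinates, area, environmental principal components and the seven
key climate/soil determinants.  Plot summaries expose the two flavours of
relative evergreen abundance,

    relEV_area    = BA_EV / (BA_EV + BA_DE)
    relEV_density =  n_EV / (n_EV  + n_DE)

both in [0, 1], computed over known-phenology trees only.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: the seven key drivers used in the determinant (variable-importance) analysis
DETERMINANT_NAMES: tuple[str, ...] = (
    "mat_c",
    "annual_precip_mm",
    "coldest_quarter_c",
    "driest_quarter_mm",
    "soil_ph",
    "soil_n_density",
    "soil_cn_ratio",
)

N_ENV_PCS = 10


class Phenology(str, enum.Enum):
    EV = "EV"
    DE = "DE"
    UNKNOWN = "UNKNOWN"


class Fate(str, enum.Enum):
    SURVIVOR = "survivor"
    DIED = "died"
    RECRUIT = "recruit"


@dataclasses.dataclass(frozen=True)
class TreeRecord:
    """One tree followed across a census interval."""

    tree_id: str
    plot_id: str
    species_id: str
    phenology: Phenology
    dbh_prev: float | None  # cm at first census; None for recruits
    dbh_curr: float | None  # cm at second census; None if died
    fate: Fate

    def __post_init__(self) -> None:
        if self.fate is Fate.RECRUIT:
            if self.dbh_prev is not None or self.dbh_curr is None:
                raise ValueError(f"recruit {self.tree_id}: needs dbh_curr only")
        elif self.fate is Fate.DIED:
            if self.dbh_prev is None or self.dbh_curr is not None:
                raise ValueError(f"dead tree {self.tree_id}: needs dbh_prev only")
        else:
            if self.dbh_prev is None or self.dbh_curr is None:
                raise ValueError(f"survivor {self.tree_id}: needs both diameters")
        for d in (self.dbh_prev, self.dbh_curr):
            if d is not None and d < 0:
                raise ValueError(f"negative diameter on tree {self.tree_id}")

    @property
    def dbh_reference(self) -> float:
        """Diameter defining basal area: start-of-interval state when
        available, entry size for recruits."""
        return self.dbh_prev if self.dbh_prev is not None else self.dbh_curr  # type: ignore[return-value]


@dataclasses.dataclass
class PlotRecord:
    """A forest plot with its trees and environmental context."""

    plot_id: str
    lon: float
    lat: float
    area: float  # hectares
    interval: float = 5.0  # census interval, years
    env_pcs: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(N_ENV_PCS)
    )
    mat: float = 10.0  # mean annual temperature, deg C
    determinants: dict[str, float] = dataclasses.field(default_factory=dict)
    trees: list[TreeRecord] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.env_pcs = np.asarray(self.env_pcs, dtype=float)
        if self.env_pcs.shape != (N_ENV_PCS,):
            raise ValueError(
                f"plot {self.plot_id}: expected {N_ENV_PCS} environmental PCs"
            )
        if self.area <= 0:
            raise ValueError(f"plot {self.plot_id}: area must be positive")
        if self.interval <= 0:
            raise ValueError(f"plot {self.plot_id}: interval must be positive")
        if not -90 <= self.lat <= 90:
            raise ValueError(f"plot {self.plot_id}: latitude outside [-90, 90]")
        # normalize longitude to [-180, 180)
        self.lon = ((self.lon + 180.0) % 360.0) - 180.0


@dataclasses.dataclass(frozen=True)
class PlotSummary:
    n_ev: int
    n_de: int
    ba_ev: float  # m^2
    ba_de: float  # m^2
    relev_area: float | None
    relev_density: float | None
    n_species: int
    unknown_ba_frac: float
    mortality_frac: float


def basal_area_m2(dbh_cm: float) -> float:
    """Basal area of one stem, m^2, from its diameter in cm."""
    return math.pi * (dbh_cm / 200.0) ** 2


def compute_plot_summary(plot: PlotRecord) -> PlotSummary:
    """Stem counts, basal areas and relEV of one plot.

    Basal area uses the first-census diameter when present (state at the
    start of the exposure interval); recruits contribute via their current
    diameter.  UNKNOWN-phenology trees never enter the relEV numerator or
    denominator but are tracked through ``unknown_ba_frac``.  If every tree
    is UNKNOWN, relEV is undefined (``None``), not zero.
    """
    n = {Phenology.EV: 0, Phenology.DE: 0}
    ba = {Phenology.EV: 0.0, Phenology.DE: 0.0}
    ba_unknown = 0.0
    n_first = 0
    n_died = 0
    species: set[str] = set()
    for t in plot.trees:
        species.add(t.species_id)
        a = basal_area_m2(t.dbh_reference)
        if t.phenology is Phenology.UNKNOWN:
            ba_unknown += a
        else:
            n[t.phenology] += 1
            ba[t.phenology] += a
        if t.fate is not Fate.RECRUIT:
            n_first += 1
            if t.fate is Fate.DIED:
                n_died += 1
    ba_total = ba[Phenology.EV] + ba[Phenology.DE] + ba_unknown
    n_known = n[Phenology.EV] + n[Phenology.DE]
    relev_area = (
        ba[Phenology.EV] / (ba[Phenology.EV] + ba[Phenology.DE])
        if (ba[Phenology.EV] + ba[Phenology.DE]) > 0
        else None
    )
    relev_density = n[Phenology.EV] / n_known if n_known > 0 else None
    return PlotSummary(
        n_ev=n[Phenology.EV],
        n_de=n[Phenology.DE],
        ba_ev=ba[Phenology.EV],
        ba_de=ba[Phenology.DE],
        relev_area=relev_area,
        relev_density=relev_density,
        n_species=len(species),
        unknown_ba_frac=ba_unknown / ba_total if ba_total > 0 else 0.0,
        mortality_frac=n_died / n_first if n_first > 0 else 0.0,
    )


@dataclasses.dataclass
class FilterCriteria:
    """Plot inclusion rules mirroring the inventory preprocessing filters.

    Each rule can be toggled independently to accommodate dataset dialects
    (e.g. the species rules apply to inventories lacking management flags).
    """

    min_trees: int = 10
    max_unknown_ba_frac: float = 0.10
    max_mortality_frac: float = 0.50
    min_species: int = 2
    max_single_species_ba_frac: float = 0.90
    enable_min_trees: bool = True
    enable_unknown_ba: bool = True
    enable_mortality: bool = True
    enable_min_species: bool = True
    enable_single_species_ba: bool = True

    def __post_init__(self) -> None:
        for name in ("max_unknown_ba_frac", "max_mortality_frac",
                     "max_single_species_ba_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


#: fixed audit order: a rejected plot is counted once, under the first rule
#: it fails
_RULE_ORDER = ("min_trees", "unknown_ba", "mortality", "min_species",
               "single_species_ba")


def _single_species_ba_frac(plot: PlotRecord) -> float:
    ba_by_sp: dict[str, float] = {}
    total = 0.0
    for t in plot.trees:
        a = basal_area_m2(t.dbh_reference)
        ba_by_sp[t.species_id] = ba_by_sp.get(t.species_id, 0.0) + a
        total += a
    return max(ba_by_sp.values()) / total if total > 0 else 0.0


def _first_failed_rule(plot: PlotRecord, summary: PlotSummary,
                       criteria: FilterCriteria) -> str | None:
    if criteria.enable_min_trees and len(plot.trees) < criteria.min_trees:
        return "min_trees"
    if criteria.enable_unknown_ba and summary.unknown_ba_frac > criteria.max_unknown_ba_frac:
        return "unknown_ba"
    if criteria.enable_mortality and summary.mortality_frac > criteria.max_mortality_frac:
        return "mortality"
    if criteria.enable_min_species and summary.n_species < criteria.min_species:
        return "min_species"
    if (criteria.enable_single_species_ba
            and _single_species_ba_frac(plot) > criteria.max_single_species_ba_frac):
        return "single_species_ba"
    return None


def apply_inclusion_filters(
    plots: Iterable[PlotRecord],
    criteria: FilterCriteria | None = None,
) -> tuple[list[PlotRecord], pd.DataFrame]:
    """Keep plots passing every enabled rule; audit exclusions per rule.

    Returns the kept plots and an audit table with one row per rule in the
    documented fixed order plus a ``kept`` row; each excluded plot counts
    once, under the first rule it fails.
    """
    criteria = criteria or FilterCriteria()
    kept: list[PlotRecord] = []
    counts = {rule: 0 for rule in _RULE_ORDER}
    for plot in plots:
        summary = compute_plot_summary(plot) if plot.trees else PlotSummary(
            0, 0, 0.0, 0.0, None, None, 0, 0.0, 0.0)
        rule = _first_failed_rule(plot, summary, criteria)
        if rule is None:
            kept.append(plot)
        else:
            counts[rule] += 1
    audit = pd.DataFrame(
        {"rule": list(_RULE_ORDER) + ["kept"],
         "n_plots": [counts[r] for r in _RULE_ORDER] + [len(kept)]}
    )
    return kept, audit


def env_pca(
    covariate_table: pd.DataFrame | np.ndarray,
    n_components: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of a plots x covariates table.

    Covariates are standardized (zero mean, unit variance) first; constant
    columns are dropped with a warning.  Returns the component scores and
    the fractions of variance explained, in decreasing order.
    """
    import warnings

    from sklearn.decomposition import PCA

    X = np.asarray(covariate_table, dtype=float)
    if X.ndim != 2:
        raise ValueError("covariate table must be 2-d")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        warnings.warn(
            f"dropping {int((sd == 0).sum())} constant covariate column(s) "
            "before standardization",
            stacklevel=2,
        )
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    Z = (X - X.mean(axis=0)) / sd
    rank = min(Z.shape)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    return scores, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# delimited-text I/O (the documented generic schema)

TREE_COLUMNS = ["tree_id", "plot_id", "species_id", "phenology",
                "dbh_prev_cm", "dbh_curr_cm", "fate"]
PLOT_COLUMNS = (
    ["plot_id", "lon", "lat", "area_ha", "interval_yr"]
    + [f"env_pc{i}" for i in range(1, N_ENV_PCS + 1)]
    + list(DETERMINANT_NAMES)
)


def plots_to_frames(plots: Sequence[PlotRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten plots (and their trees) to the two CSV-ready tables."""
    prow = []
    trow = []
    for p in plots:
        rec = {"plot_id": p.plot_id, "lon": p.lon, "lat": p.lat,
               "area_ha": p.area, "interval_yr": p.interval}
        rec.update({f"env_pc{i + 1}": v for i, v in enumerate(p.env_pcs)})
        rec.update({k: p.determinants.get(k, np.nan) for k in DETERMINANT_NAMES})
        rec["mat_c"] = p.mat
        prow.append(rec)
        for t in p.trees:
            trow.append({
                "tree_id": t.tree_id, "plot_id": t.plot_id,
                "species_id": t.species_id, "phenology": t.phenology.value,
                "dbh_prev_cm": np.nan if t.dbh_prev is None else t.dbh_prev,
                "dbh_curr_cm": np.nan if t.dbh_curr is None else t.dbh_curr,
                "fate": t.fate.value,
            })
    return (pd.DataFrame(prow, columns=PLOT_COLUMNS),
            pd.DataFrame(trow, columns=TREE_COLUMNS))


def frames_to_plots(plot_table: pd.DataFrame, tree_table: pd.DataFrame) -> list[PlotRecord]:
    """Rebuild PlotRecords from the two generic tables."""
    trees_by_plot: dict[str, list[TreeRecord]] = {}
    for r in tree_table.itertuples(index=False):
        t = TreeRecord(
            tree_id=str(r.tree_id), plot_id=str(r.plot_id),
            species_id=str(r.species_id), phenology=Phenology(r.phenology),
            dbh_prev=None if pd.isna(r.dbh_prev_cm) else float(r.dbh_prev_cm),
            dbh_curr=None if pd.isna(r.dbh_curr_cm) else float(r.dbh_curr_cm),
            fate=Fate(r.fate),
        )
        trees_by_plot.setdefault(t.plot_id, []).append(t)
    plots = []
    pc_cols = [f"env_pc{i}" for i in range(1, N_ENV_PCS + 1)]
    for r in plot_table.itertuples(index=False):
        rd = r._asdict()
        plots.append(PlotRecord(
            plot_id=str(rd["plot_id"]), lon=float(rd["lon"]), lat=float(rd["lat"]),
            area=float(rd["area_ha"]), interval=float(rd["interval_yr"]),
            env_pcs=np.array([rd[c] for c in pc_cols], dtype=float),
            mat=float(rd.get("mat_c", np.nan)),
            determinants={k: float(rd[k]) for k in DETERMINANT_NAMES if k in rd},
            trees=trees_by_plot.get(str(rd["plot_id"]), []),
        ))
    return plots


def write_inventory_csv(plots: Sequence[PlotRecord], plot_path, tree_path) -> None:
    ptab, ttab = plots_to_frames(plots)
    ptab.to_csv(plot_path, index=False)
    ttab.to_csv(tree_path, index=False)


def read_inventory_csv(plot_path, tree_path) -> list[PlotRecord]:
    return frames_to_plots(pd.read_csv(plot_path), pd.read_csv(tree_path))
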