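"""Con-phenological feedback estimation from two-census inventories.

Fits per-phenology generalized additive models for the three vital rates:

* survival — tree level, binomial/logit, smooth terms for previous
  diameter and the feedback predictor relEV (basal-area based), linear
  terms for stand basal area, stem density and the 10 environmental PCs;
* growth — tree level (survivors), Gaussian, response current diameter,
  same predictors;
* recruitment — plot level, Poisson/log, recruits of the focal phenology
  per census interval, with the con-phenological basal area retained in
  both the feedback and the null variant (only relEV is the feedback
  term).

Headline contrasts mirror the way the effects are reported: predicted
con- minus hetero-phenological performance at relEV = 0 and 1 (survival,
growth) or rate ratios at relEV = 0.1 and 0.9 (recruitment), holding all
other predictors at training means, with uncertainty from 100
multivariate-normal draws of the coefficient vector.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .inventory import Fate, Phenology, PlotRecord, basal_area_m2

MIN_TREES_PER_FIT = 500
SPLINE_DF = 5
SPLINE_DEGREE = 3
#: smoothing weights tried when ``alpha="aic"`` (the default): the fit with
#: the lowest effective-df-corrected AIC wins, so near-linear relationships
#: get a heavy penalty and genuinely curved ones keep their wiggle room.
#: The grid starts at a moderate weight: boundary regions of the feedback
#: smooth are data-sparse, and an essentially unpenalized fit chases local
#: noise there.
ALPHA_GRID = (1e2, 1e4, 1e6)
DEFAULT_ALPHA: float | str = "aic"
N_CONTRAST_DRAWS = 100


# ---------------------------------------------------------------------------
# data preparation

def demography_tables(plots: list[PlotRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tree-level and plot-level model tables from a two-census inventory.

    Stand predictors (basal area, stem density, relEV) describe the state
    at the start of the interval: they are computed from first-census
    trees only, using previous diameters.
    """
    trows, prows = [], []
    for pl in plots:
        init = [t for t in pl.trees if t.fate is not Fate.RECRUIT]
        if not init:
            continue
        ba = {Phenology.EV: 0.0, Phenology.DE: 0.0, Phenology.UNKNOWN: 0.0}
        for t in init:
            ba[t.phenology] += basal_area_m2(t.dbh_prev)
        ba_known = ba[Phenology.EV] + ba[Phenology.DE]
        if ba_known <= 0:
            continue
        relev = ba[Phenology.EV] / ba_known
        ba_ha = sum(ba.values()) / pl.area
        dens_ha = len(init) / pl.area
        env = {f"pc{i + 1}": v for i, v in enumerate(pl.env_pcs)}
        base = dict(plot_id=pl.plot_id, ba_ha=ba_ha, dens_ha=dens_ha,
                    relev=relev, mat=pl.mat, interval=pl.interval, **env)
        for t in init:
            trows.append(dict(
                base, phenology=t.phenology.value, dbh_prev=t.dbh_prev,
                survived=1.0 if t.fate is Fate.SURVIVOR else 0.0,
                dbh_curr=t.dbh_curr if t.fate is Fate.SURVIVOR else np.nan,
            ))
        rec = {Phenology.EV: 0, Phenology.DE: 0}
        for t in pl.trees:
            if t.fate is Fate.RECRUIT and t.phenology in rec:
                rec[t.phenology] += 1
        for ph in (Phenology.EV, Phenology.DE):
            prows.append(dict(
                base, phenology=ph.value, recruits=rec[ph],
                con_ba_ha=ba[ph] / pl.area,
            ))
    return pd.DataFrame(trows), pd.DataFrame(prows)


# ---------------------------------------------------------------------------
# fitted-model container

@dataclasses.dataclass
class VitalRateModel:
    """One fitted vital-rate GAM with everything needed for prediction."""

    rate: str                      # 'survival' | 'growth' | 'recruitment'
    phenology: Phenology
    feedback: bool
    params: np.ndarray
    cov_params: np.ndarray
    smoother: BSplines
    smooth_names: list[str]
    linear_names: list[str]        # excluding the constant
    linear_means: np.ndarray
    smooth_means: np.ndarray
    family_link: str               # 'logit' | 'identity' | 'log'
    llf: float
    scale: float                   # residual variance (growth); else 1.0
    interval_yr: float
    converged: bool
    smooth_lo: np.ndarray = dataclasses.field(default=None)  # training range
    smooth_hi: np.ndarray = dataclasses.field(default=None)

    def _basis(self, smooth: np.ndarray) -> np.ndarray:
        # constant extrapolation outside the training range of each smooth
        # covariate (predictions at relEV 0/1 and simulator states can sit
        # just outside the fitted knots)
        x = np.clip(np.asarray(smooth, float), self.smooth_lo, self.smooth_hi)
        return self.smoother.transform(x)

    def design_row(self, overrides: dict[str, float]) -> np.ndarray:
        """One design row at training means, with named overrides."""
        lin = self.linear_means.copy()
        for k, v in overrides.items():
            if k in self.linear_names:
                lin[self.linear_names.index(k)] = v
        smo = self.smooth_means.copy()
        for k, v in overrides.items():
            if k in self.smooth_names:
                smo[self.smooth_names.index(k)] = v
        basis = self._basis(smo[None, :])
        return np.concatenate([[1.0], lin, np.ravel(basis)])

    def _inv_link(self, eta: np.ndarray) -> np.ndarray:
        if self.family_link == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        if self.family_link == "log":
            return np.exp(eta)
        return eta

    def predict_at(self, overrides: dict[str, float],
                   params: np.ndarray | None = None) -> float:
        row = self.design_row(overrides)
        beta = self.params if params is None else params
        return float(self._inv_link(row @ beta))

    def predict_rows(self, linear: np.ndarray, smooth: np.ndarray) -> np.ndarray:
        """Vectorized prediction on raw covariate arrays (simulator use)."""
        basis = self._basis(smooth)
        X = np.column_stack([np.ones(len(basis)), np.asarray(linear, float), basis])
        return self._inv_link(X @ self.params)

    def draw_params(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.multivariate_normal(self.params, self.cov_params, size=n,
                                       method="svd")


def _fit_gam(
    y: np.ndarray,
    table: pd.DataFrame,
    smooth_names: list[str],
    linear_names: list[str],
    family,
    family_link: str,
    rate: str,
    phenology: Phenology,
    feedback: bool,
    alpha: float | str,
) -> VitalRateModel:
    smooth = table[smooth_names].to_numpy(float)
    linear = table[linear_names].to_numpy(float)
    # relEV knots span the full composition range so contrasts at 0 / 1 are
    # evaluated inside the basis for both phenologies
    kwds = [dict(lower_bound=0.0, upper_bound=1.0) if nm == "relev" else {}
            for nm in smooth_names]
    bs = BSplines(smooth, df=[SPLINE_DF] * len(smooth_names),
                  degree=[SPLINE_DEGREE] * len(smooth_names),
                  knot_kwds=kwds)
    exog = sm.add_constant(linear, has_constant="add")
    alphas = ALPHA_GRID if alpha == "aic" else (float(alpha),)
    res = best = None
    for a in alphas:
        model = GLMGam(y, exog=exog, smoother=bs,
                       alpha=[a] * len(smooth_names), family=family)
        r = model.fit()
        if best is None or r.aic < best:
            best, res = r.aic, r
    return VitalRateModel(
        rate=rate, phenology=phenology, feedback=feedback,
        params=np.asarray(res.params), cov_params=np.asarray(res.cov_params()),
        smoother=bs, smooth_names=smooth_names, linear_names=linear_names,
        linear_means=linear.mean(axis=0), smooth_means=smooth.mean(axis=0),
        family_link=family_link, llf=float(res.llf), scale=float(res.scale),
        interval_yr=float(table["interval"].mean()), converged=bool(res.converged),
        smooth_lo=np.where([nm == "relev" for nm in smooth_names],
                           0.0, smooth.min(axis=0)),
        smooth_hi=np.where([nm == "relev" for nm in smooth_names],
                           1.0, smooth.max(axis=0)),
    )


def _pc_names(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("pc")]


def fit_survival(
    tree_table: pd.DataFrame,
    phenology: Phenology,
    feedback: bool = True,
    mat_term: bool = False,
    alpha: float = DEFAULT_ALPHA,
) -> VitalRateModel:
    """Binomial GAM for per-interval tree survival of one phenology.

    Reported on the survival scale (1 - mortality).  ``feedback=False``
    drops the relEV smooth (the null variant).
    """
    t = tree_table[tree_table["phenology"] == phenology.value]
    if len(t) < MIN_TREES_PER_FIT:
        raise ValueError(
            f"survival fit needs >= {MIN_TREES_PER_FIT} trees, got {len(t)}")
    smooth = ["dbh_prev"] + (["relev"] if feedback else [])
    linear = ["ba_ha", "dens_ha"] + _pc_names(t) + (["mat"] if mat_term else [])
    return _fit_gam(t["survived"].to_numpy(float), t, smooth, linear,
                    sm.families.Binomial(), "logit", "survival", phenology,
                    feedback, alpha)


def fit_growth(
    tree_table: pd.DataFrame,
    phenology: Phenology,
    feedback: bool = True,
    mat_term: bool = False,
    alpha: float = DEFAULT_ALPHA,
) -> VitalRateModel:
    """Gaussian GAM for current diameter of surviving trees.

    Growth is reported downstream as (predicted dbh_curr - dbh_prev) /
    interval, in cm per year.
    """
    t = tree_table[(tree_table["phenology"] == phenology.value)
                   & tree_table["dbh_curr"].notna()]
    if len(t) < MIN_TREES_PER_FIT:
        raise ValueError(
            f"growth fit needs >= {MIN_TREES_PER_FIT} survivors, got {len(t)}")
    if (t["interval"] <= 0).any():
        raise ValueError("census interval must be positive")
    smooth = ["dbh_prev"] + (["relev"] if feedback else [])
    linear = ["ba_ha", "dens_ha"] + _pc_names(t) + (["mat"] if mat_term else [])
    return _fit_gam(t["dbh_curr"].to_numpy(float), t, smooth, linear,
                    sm.families.Gaussian(), "identity", "growth", phenology,
                    feedback, alpha)


def fit_recruitment(
    recruit_table: pd.DataFrame,
    phenology: Phenology,
    feedback: bool = True,
    mat_term: bool = False,
    alpha: float = DEFAULT_ALPHA,
) -> VitalRateModel:
    """Poisson GAM for plot-level recruit counts of one phenology.

    The con-phenological basal area stays in both variants; only relEV is
    the feedback term.
    """
    t = recruit_table[recruit_table["phenology"] == phenology.value]
    if len(t) == 0 or t["recruits"].sum() == 0:
        raise ValueError("recruitment fit needs non-zero recruit counts")
    smooth = ["relev"] if feedback else ["ba_ha"]
    linear = (["ba_ha"] if feedback else []) + ["dens_ha", "con_ba_ha"] \
        + _pc_names(t) + (["mat"] if mat_term else [])
    if not feedback:
        # keep one smooth term so both variants exercise the same machinery
        linear = ["dens_ha", "con_ba_ha"] + _pc_names(t) + (["mat"] if mat_term else [])
    return _fit_gam(t["recruits"].to_numpy(float), t, smooth, linear,
                    sm.families.Poisson(), "log", "recruitment", phenology,
                    feedback, alpha)


# ---------------------------------------------------------------------------
# contrasts

@dataclasses.dataclass(frozen=True)
class ContrastResult:
    """Con vs hetero performance at one stand composition."""

    rate: str
    relev_point: float
    con_phenology: Phenology
    con_value: float
    hetero_value: float
    contrast: float          # relative % difference, or ratio for recruitment
    ci_low: float
    ci_high: float
    kind: str                # 'relative_pct' | 'ratio'
    unstable: bool = False


def _pooled_means(m_ev: VitalRateModel, m_de: VitalRateModel) -> dict[str, float]:
    out: dict[str, float] = {}
    for names, attr in (("linear_names", "linear_means"),
                        ("smooth_names", "smooth_means")):
        for k in getattr(m_ev, names):
            i, j = getattr(m_ev, names).index(k), getattr(m_de, names).index(k)
            out[k] = 0.5 * (getattr(m_ev, attr)[i] + getattr(m_de, attr)[j])
    return out


def _contrast_at(
    m_ev: VitalRateModel,
    m_de: VitalRateModel,
    relev: float,
    transform,
    kind: str,
    rate: str,
    rng: np.random.Generator,
    n_draws: int = N_CONTRAST_DRAWS,
    extra: dict[str, float] | None = None,
) -> ContrastResult:
    if not (m_ev.feedback and m_de.feedback):
        raise ValueError("contrasts need feedback-variant models (with relEV)")
    means = _pooled_means(m_ev, m_de)
    means.update(extra or {})
    means["relev"] = relev
    con_is_ev = relev >= 0.5
    v_ev = transform(m_ev.predict_at(means), m_ev, means)
    v_de = transform(m_de.predict_at(means), m_de, means)
    con, het = (v_ev, v_de) if con_is_ev else (v_de, v_ev)

    draws_ev = m_ev.draw_params(rng, n_draws)
    draws_de = m_de.draw_params(rng, n_draws)
    samples = []
    for be, bd in zip(draws_ev, draws_de):
        ve = transform(m_ev.predict_at(means, be), m_ev, means)
        vd = transform(m_de.predict_at(means, bd), m_de, means)
        c, h = (ve, vd) if con_is_ev else (vd, ve)
        samples.append(_combine(c, h, kind))
    lo, hi = np.percentile(samples, [2.5, 97.5])
    unstable = kind == "ratio" and het < 1e-8
    return ContrastResult(
        rate=rate, relev_point=relev,
        con_phenology=Phenology.EV if con_is_ev else Phenology.DE,
        con_value=con, hetero_value=het, contrast=_combine(con, het, kind),
        ci_low=float(lo), ci_high=float(hi), kind=kind, unstable=unstable,
    )


def _combine(con: float, het: float, kind: str) -> float:
    if kind == "ratio":
        return con / max(het, 1e-12)
    return 100.0 * (con - het) / het


def predict_survival_growth_contrast(
    model_ev: VitalRateModel,
    model_de: VitalRateModel,
    relev_points: tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | None = None,
) -> list[ContrastResult]:
    """Relative % survival or growth advantage of the con-phenological tree.

    At relEV = 1 the con-phenological tree is evergreen, at relEV = 0
    deciduous.  Growth models are contrasted on diameter increments per
    year; survival models on the per-interval survival probability.
    """
    rng = rng or np.random.default_rng()
    rate = model_ev.rate
    if rate != model_de.rate or rate not in ("survival", "growth"):
        raise ValueError("expected a matching survival or growth model pair")

    if rate == "growth":
        def transform(pred, model, means):
            return (pred - means["dbh_prev"]) / model.interval_yr
    else:
        def transform(pred, model, means):
            return pred

    return [
        _contrast_at(model_ev, model_de, r, transform, "relative_pct", rate, rng)
        for r in relev_points
    ]


def predict_recruitment_ratio(
    model_ev: VitalRateModel,
    model_de: VitalRateModel,
    relev_points: tuple[float, float] = (0.1, 0.9),
    rng: np.random.Generator | None = None,
) -> list[ContrastResult]:
    """Con:hetero recruitment-rate ratio at deciduous- and evergreen-
    dominated compositions (relEV = 0.1 and 0.9 by default)."""
    rng = rng or np.random.default_rng()
    if model_ev.rate != "recruitment" or model_de.rate != "recruitment":
        raise ValueError("expected recruitment models")

    def transform(pred, model, means):
        return pred

    return [
        _contrast_at(model_ev, model_de, r, transform, "ratio", "recruitment", rng)
        for r in relev_points
    ]


@dataclasses.dataclass
class VitalRateModelSet:
    """The six fitted GAMs of one variant (feedback or null)."""

    survival: dict[Phenology, VitalRateModel]
    growth: dict[Phenology, VitalRateModel]
    recruitment: dict[Phenology, VitalRateModel]
    feedback: bool

    @classmethod
    def fit(cls, plots: list[PlotRecord], feedback: bool = True,
            mat_term: bool = False, alpha: float = DEFAULT_ALPHA) -> "VitalRateModelSet":
        ttab, rtab = demography_tables(plots)
        kw = dict(feedback=feedback, mat_term=mat_term, alpha=alpha)
        return cls(
            survival={ph: fit_survival(ttab, ph, **kw)
                      for ph in (Phenology.EV, Phenology.DE)},
            growth={ph: fit_growth(ttab, ph, **kw)
                    for ph in (Phenology.EV, Phenology.DE)},
            recruitment={ph: fit_recruitment(rtab, ph, **kw)
                         for ph in (Phenology.EV, Phenology.DE)},
            feedback=feedback,
        )
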