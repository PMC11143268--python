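"""Stochastic forest succession simulator driven by vital-rate models.

Each plot carries a list of trees (phenology, diameter).  A 5-year step
applies, in fixed order: stand-replacing disturbance (annual probability
compounded to the step), survival, growth (predicted increment plus
Gaussian residual, floored at zero — no shrinkage), and Poisson
recruitment per phenology with entry at 12.7 cm.  Plot covariates are
frozen at the start of the step.  Post-disturbance regeneration resets the
stand to 20 trees whose phenologies are Bernoulli draws at the plot's
relEV immediately before the disturbance.

The simulator accepts either the generator's closed-form truth
(:class:`TrueRateAdapter`) or fitted GAMs (:class:`FittedRateAdapter`);
the ``null`` variant of either removes frequency dependence, which is the
control for whether feedbacks are needed to generate and maintain
bimodality and hysteresis.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .generator import RECRUIT_DBH_CM, GeneratorParams, TrueVitalRates
from .inventory import Phenology, PlotRecord


class InitScheme(str, enum.Enum):
    UNIFORM = "uniform"              # initial relEV ~ U[0, 1]
    BIMODAL_HALF = "bimodal_half"    # 500 pure EV + 500 pure DE
    HYSTERESIS_EV = "hysteresis_ev"  # 80% pure EV + 20% pure DE
    HYSTERESIS_DE = "hysteresis_de"  # 80% pure DE + 20% pure EV


@dataclasses.dataclass
class SimConfig:
    n_plots: int = 1000
    horizon_years: float = 2000.0
    step_years: float = 5.0
    p_disturb_annual: float = 0.0036  # natural stand-replacing rate
    init_scheme: InitScheme = InitScheme.UNIFORM
    init_trees: int = 20
    init_dbh: float = RECRUIT_DBH_CM
    plot_area_ha: float = 0.1
    variant: str = "feedback"        # 'feedback' | 'null'
    seed: int = 0
    record_every_steps: int = 10
    # hysteresis MAT grid
    mat_range: tuple[float, float] = (-2.0, 23.0)
    mat_sections: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_disturb_annual <= 1.0:
            raise ValueError("disturbance probability must lie in [0, 1]")
        n_steps = self.horizon_years / self.step_years
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("step_years must divide horizon_years")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_years / self.step_years))

    @property
    def p_disturb_step(self) -> float:
        return 1.0 - (1.0 - self.p_disturb_annual) ** self.step_years


def natural_disturbance_rate(overall: float = 0.009, management: float = 0.0054) -> float:
    """Natural annual stand-replacing probability: the overall North American
    rate minus the share attributable to management."""
    return overall - management


# ---------------------------------------------------------------------------
# rate adapters

class TrueRateAdapter:
    """Simulator interface over the generator's closed-form truth."""

    def __init__(self, params: GeneratorParams, variant: str = "feedback"):
        self.rates = TrueVitalRates(params, variant=variant)
        self.growth_sigma = params.growth_sigma_cm
        self.uses_mat = params.mat_effect

    def survival(self, is_ev, dbh, ba_ha, dens_ha, env, relev, mat):
        out = np.empty(dbh.shape)
        for ev, ph in ((True, Phenology.EV), (False, Phenology.DE)):
            m = is_ev == ev
            if m.any():
                out[m] = self.rates.survival_prob(ph, dbh[m], ba_ha[m], dens_ha[m],
                                                  env[m], relev[m])
        return out

    def growth(self, is_ev, dbh, ba_ha, dens_ha, env, relev, mat):
        out = np.empty(dbh.shape)
        for ev, ph in ((True, Phenology.EV), (False, Phenology.DE)):
            m = is_ev == ev
            if m.any():
                out[m] = self.rates.growth_increment(ph, dbh[m], ba_ha[m], dens_ha[m],
                                                     env[m], relev[m])
        return out

    def recruitment(self, phenology, ba_ha, con_ba_ha, dens_ha, env, relev, mat):
        return self.rates.recruitment_rate(
            phenology, ba_ha, con_ba_ha, dens_ha, env, relev,
            mat=mat if self.uses_mat else None)


class FittedRateAdapter:
    """Simulator interface over a fitted :class:`VitalRateModelSet`."""

    def __init__(self, model_set):
        self.models = model_set
        self.growth_sigma = float(
            np.sqrt(np.mean([m.scale for m in model_set.growth.values()])))

    def _predict(self, model, cov: dict[str, np.ndarray]) -> np.ndarray:
        linear = np.column_stack([cov[k] for k in model.linear_names])
        smooth = np.column_stack([cov[k] for k in model.smooth_names])
        return model.predict_rows(linear, smooth)

    def _cov(self, dbh, ba_ha, dens_ha, env, relev, mat):
        cov = {"dbh_prev": dbh, "ba_ha": ba_ha, "dens_ha": dens_ha,
               "relev": relev}
        if mat is not None:
            cov["mat"] = mat
        for i in range(env.shape[1]):
            cov[f"pc{i + 1}"] = env[:, i]
        return cov

    def survival(self, is_ev, dbh, ba_ha, dens_ha, env, relev, mat):
        cov = self._cov(dbh, ba_ha, dens_ha, env, relev, mat)
        out = np.empty(dbh.shape)
        for ev, ph in ((True, Phenology.EV), (False, Phenology.DE)):
            m = is_ev == ev
            if m.any():
                sub = {k: v[m] for k, v in cov.items()}
                out[m] = self._predict(self.models.survival[ph], sub)
        return out

    def growth(self, is_ev, dbh, ba_ha, dens_ha, env, relev, mat):
        cov = self._cov(dbh, ba_ha, dens_ha, env, relev, mat)
        out = np.empty(dbh.shape)
        for ev, ph in ((True, Phenology.EV), (False, Phenology.DE)):
            m = is_ev == ev
            if m.any():
                sub = {k: v[m] for k, v in cov.items()}
                pred = self._predict(self.models.growth[ph], sub)
                out[m] = pred - dbh[m]  # response is dbh_curr
        return out

    def recruitment(self, phenology, ba_ha, con_ba_ha, dens_ha, env, relev, mat):
        cov = self._cov(np.zeros_like(ba_ha), ba_ha, dens_ha, env, relev, mat)
        cov["con_ba_ha"] = con_ba_ha
        model = self.models.recruitment[phenology]
        cov["dbh_prev"] = np.zeros_like(ba_ha)
        return self._predict(model, cov)


# ---------------------------------------------------------------------------
# state

@dataclasses.dataclass
class SimState:
    """Flat tree arrays plus per-plot context; fully vectorised."""

    dbh: np.ndarray        # cm, one entry per living tree
    is_ev: np.ndarray      # bool per tree
    plot_idx: np.ndarray   # int per tree
    env: np.ndarray        # n_plots x 10
    mat: np.ndarray        # n_plots
    area_ha: float
    relev_last: np.ndarray   # last defined basal-area relEV per plot
    init_relev: np.ndarray
    time_yr: float = 0.0

    @property
    def n_plots(self) -> int:
        return self.env.shape[0]

    def plot_stats(self):
        """Per-plot basal area (m^2/ha, total and EV), density and relEV."""
        n = self.n_plots
        ba_tree = np.pi * (self.dbh / 200.0) ** 2
        ba_all = np.bincount(self.plot_idx, weights=ba_tree, minlength=n)
        ba_ev = np.bincount(self.plot_idx[self.is_ev],
                            weights=ba_tree[self.is_ev], minlength=n)
        count = np.bincount(self.plot_idx, minlength=n)
        relev = np.where(ba_all > 0, ba_ev / np.maximum(ba_all, 1e-300),
                         self.relev_last)
        return ba_all / self.area_ha, ba_ev / self.area_ha, count / self.area_ha, relev


def _target_relev(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_plots
    s = config.init_scheme
    if s is InitScheme.UNIFORM:
        return rng.random(n)
    if s is InitScheme.BIMODAL_HALF:
        half = n // 2
        return np.concatenate([np.ones(half), np.zeros(n - half)])
    n_major = int(round(0.8 * n))
    if s is InitScheme.HYSTERESIS_EV:
        return np.concatenate([np.ones(n_major), np.zeros(n - n_major)])
    if s is InitScheme.HYSTERESIS_DE:
        return np.concatenate([np.zeros(n_major), np.ones(n - n_major)])
    raise ValueError(f"unknown init scheme {s!r}")


def init_plots(
    config: SimConfig,
    rng: np.random.Generator,
    ref_plots: list[PlotRecord] | None = None,
    mat_override: np.ndarray | None = None,
    target_override: np.ndarray | None = None,
) -> SimState:
    """Initial state: 20 trees per plot at 12.7 cm, phenology Bernoulli at
    the plot's target relEV; environments drawn with replacement from a
    reference plot table (iid standard normal PCs if none is given)."""
    n = config.n_plots
    if ref_plots:
        pick = rng.integers(0, len(ref_plots), size=n)
        env = np.array([ref_plots[i].env_pcs for i in pick])
        mat = np.array([ref_plots[i].mat for i in pick])
    else:
        env = rng.standard_normal((n, 10))
        from .generator import mat_from_pc1
        mat = mat_from_pc1(env[:, 0])
    if mat_override is not None:
        mat = np.asarray(mat_override, float)
    target = (np.asarray(target_override, float) if target_override is not None
              else _target_relev(config, rng))
    k = config.init_trees
    is_ev = (rng.random((n, k)) < target[:, None]).ravel()
    plot_idx = np.repeat(np.arange(n), k)
    dbh = np.full(n * k, float(config.init_dbh))
    state = SimState(dbh=dbh, is_ev=is_ev, plot_idx=plot_idx, env=env, mat=mat,
                     area_ha=config.plot_area_ha, relev_last=target.copy(),
                     init_relev=target.copy())
    return state


def step(state: SimState, rates, config: SimConfig, rng: np.random.Generator) -> SimState:
    """Advance one step: disturbance -> survival -> growth -> recruitment."""
    n = state.n_plots
    ba_ha, ba_ev_ha, dens_ha, relev = state.plot_stats()
    state.relev_last = relev

    disturbed = rng.random(n) < config.p_disturb_step

    # survival & growth for trees on non-disturbed plots
    keep_tree = ~disturbed[state.plot_idx]
    dbh = state.dbh[keep_tree]
    is_ev = state.is_ev[keep_tree]
    pidx = state.plot_idx[keep_tree]
    if dbh.size:
        tree_env = state.env[pidx]
        s = rates.survival(is_ev, dbh, ba_ha[pidx], dens_ha[pidx], tree_env,
                           relev[pidx], state.mat[pidx])
        if not np.all(np.isfinite(s)):
            raise FloatingPointError(
                f"non-finite survival prediction at t={state.time_yr}; "
                f"covariates: ba={ba_ha[pidx][~np.isfinite(s)][:3]}")
        alive = rng.random(dbh.size) < s
        dbh, is_ev, pidx = dbh[alive], is_ev[alive], pidx[alive]
        if dbh.size:
            inc = rates.growth(is_ev, dbh, ba_ha[pidx], dens_ha[pidx],
                               state.env[pidx], relev[pidx], state.mat[pidx])
            if not np.all(np.isfinite(inc)):
                raise FloatingPointError("non-finite growth prediction")
            inc = inc + rng.normal(0.0, rates.growth_sigma, dbh.size)
            dbh = dbh + np.maximum(inc, 0.0)  # no shrinkage

    # recruitment on non-disturbed plots
    live = ~disturbed
    new_dbh = [dbh]
    new_ev = [is_ev]
    new_idx = [pidx]
    if live.any():
        ids = np.flatnonzero(live)
        for ph, ev_flag in ((Phenology.EV, True), (Phenology.DE, False)):
            con_ba = ba_ev_ha[ids] if ev_flag else ba_ha[ids] - ba_ev_ha[ids]
            lam = rates.recruitment(ph, ba_ha[ids], con_ba, dens_ha[ids],
                                    state.env[ids], relev[ids], state.mat[ids])
            if not np.all(np.isfinite(lam)):
                raise FloatingPointError("non-finite recruitment prediction")
            counts = rng.poisson(lam)
            tot = int(counts.sum())
            if tot:
                new_dbh.append(np.full(tot, float(config.init_dbh)))
                new_ev.append(np.full(tot, ev_flag))
                new_idx.append(np.repeat(ids, counts))

    # disturbance reset: 20 fresh trees, phenology at pre-disturbance relEV
    if disturbed.any():
        ids = np.flatnonzero(disturbed)
        k = config.init_trees
        draws = rng.random((ids.size, k)) < relev[ids][:, None]
        new_dbh.append(np.full(ids.size * k, float(config.init_dbh)))
        new_ev.append(draws.ravel())
        new_idx.append(np.repeat(ids, k))

    state.dbh = np.concatenate(new_dbh) if new_dbh else np.empty(0)
    state.is_ev = np.concatenate(new_ev) if new_ev else np.empty(0, bool)
    state.plot_idx = np.concatenate(new_idx).astype(int) if new_idx else np.empty(0, int)
    state.time_yr += config.step_years
    return state


@dataclasses.dataclass
class SimResult:
    times_yr: np.ndarray
    relev_traj: np.ndarray    # len(times) x n_plots
    final_relev: np.ndarray
    init_relev: np.ndarray
    config: SimConfig


def run_simulation(
    config: SimConfig,
    rates,
    ref_plots: list[PlotRecord] | None = None,
    mat_override: np.ndarray | None = None,
    target_override: np.ndarray | None = None,
) -> SimResult:
    """Run the simulator to the horizon, recording thinned relEV snapshots."""
    rng = np.random.default_rng(config.seed)
    state = init_plots(config, rng, ref_plots=ref_plots,
                       mat_override=mat_override, target_override=target_override)
    times = [0.0]
    traj = [state.relev_last.copy()]
    for istep in range(1, config.n_steps + 1):
        step(state, rates, config, rng)
        if istep % config.record_every_steps == 0 or istep == config.n_steps:
            _, _, _, relev = state.plot_stats()
            times.append(state.time_yr)
            traj.append(relev.copy())
    _, _, _, final = state.plot_stats()
    return SimResult(times_yr=np.array(times), relev_traj=np.array(traj),
                     final_relev=final, init_relev=state.init_relev,
                     config=config)


# ---------------------------------------------------------------------------
# hysteresis experiment

@dataclasses.dataclass
class HysteresisResult:
    mat_mid: np.ndarray            # section midpoints, deg C
    mean_ev_init: np.ndarray
    mean_de_init: np.ndarray
    se_ev_init: np.ndarray
    se_de_init: np.ndarray
    gap: np.ndarray                # EV-init minus DE-init mean final relEV
    gap_ci_low: np.ndarray         # 95% normal band of the gap
    gap_ci_high: np.ndarray
    variant: str


def hysteresis_experiment(
    config: SimConfig,
    rates,
    plots_per_section: int | None = None,
) -> HysteresisResult:
    """Mean final relEV per MAT section for EV- and DE-dominated inits.

    The MAT gradient is split into equal sections; every plot in a section
    gets the section's MAT (drawn uniformly within it) while the remaining
    environmental PCs stay iid.  The initialisation-dependence gap per
    section, with its 95% band, is the hysteresis signal.
    """
    lo, hi = config.mat_range
    k = config.mat_sections
    edges = np.linspace(lo, hi, k + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    npl = plots_per_section or max(config.n_plots // k, 10)
    if npl <= 0:
        raise ValueError("every MAT section needs at least one plot")
    width = edges[1] - edges[0]
    section_of_plot = np.repeat(np.arange(k), npl)
    n_major = int(round(0.8 * npl))

    means, ses = {}, {}
    for tag, major_ev in (("ev", True), ("de", False)):
        cfg = dataclasses.replace(
            config, n_plots=npl * k,
            init_scheme=InitScheme.HYSTERESIS_EV if major_ev else InitScheme.HYSTERESIS_DE,
            seed=config.seed + (0 if major_ev else 1))
        rng = np.random.default_rng(cfg.seed)
        mat = np.repeat(mids, npl) + rng.uniform(-0.5, 0.5, npl * k) * width
        # 80% majority / 20% minority within every section
        per = np.concatenate([np.ones(n_major), np.zeros(npl - n_major)])
        target = np.tile(per if major_ev else 1.0 - per, k)
        res = run_simulation(cfg, rates, mat_override=mat, target_override=target)
        m = np.empty(k)
        s = np.empty(k)
        for j in range(k):
            vals = res.final_relev[section_of_plot == j]
            if vals.size == 0:
                raise ValueError(f"MAT section {j} has no plots")
            m[j] = vals.mean()
            s[j] = vals.std(ddof=1) / np.sqrt(vals.size)
        means[tag], ses[tag] = m, s

    gap = means["ev"] - means["de"]
    gap_se = np.sqrt(ses["ev"] ** 2 + ses["de"] ** 2)
    return HysteresisResult(
        mat_mid=mids,
        mean_ev_init=means["ev"], mean_de_init=means["de"],
        se_ev_init=ses["ev"], se_de_init=ses["de"],
        gap=gap, gap_ci_low=gap - 1.96 * gap_se, gap_ci_high=gap + 1.96 * gap_se,
        variant=config.variant,
    )
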