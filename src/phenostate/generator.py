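"""Synthetic two-census forest inventories with controllable feedbacks.

The generator emulates the statistical structure of a remeasured forest
inventory: plots with iid environmental principal components, an initial
stand of trees with lognormal diameters and a mixture-designed initial
evergreen share, and a census transition driven by *true* vital-rate
functions (logit-linear survival, linear growth, log-linear recruitment).

Con-phenological feedbacks are planted as relative percentage contrasts at
the reference compositions used throughout the analysis: survival and
growth advantages at relEV = 0 and 1, and a con:hetero recruitment-rate
ratio between relEV = 0.9 and 0.1.  The truth coefficients are resolved
from these knobs in closed form, so the planted effect sizes are exact at
the reference covariates and recoverable by downstream model fits.
Setting every knob to zero (ratio to 1) makes the two phenologies
exchangeable up to labels.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import expit, logit

from .inventory import N_ENV_PCS, Fate, Phenology, PlotRecord, TreeRecord

RECRUIT_DBH_CM = 12.7  # smallest measured tree; entry diameter of recruits


class CalibrationError(ValueError):
    """A feedback knob implies a vital rate outside its valid range."""


@dataclasses.dataclass
class GeneratorParams:
    """Study conditions for the synthetic inventory.

    The feedback knobs default to the planted effect sizes used across the
    analysis: 14 % / 17 % survival advantages, 43 % / 4 % growth
    advantages, and a 5-fold con:hetero recruitment ratio.
    """

    n_plots: int = 3000
    seed: int = 20240531
    plot_area_ha: float = 0.1
    interval_yr: float = 5.0

    # initial stand: size is 10 + Poisson with a gamma-mixed mean, giving
    # realistic between-plot density spread (which also spreads basal area,
    # the handle that separates stand-size effects from composition effects)
    stand_size_min: int = 10
    stand_size_mean: float = 25.0
    stand_size_gamma_shape: float = 3.0   # 0 disables the gamma mixing
    dbh_lognormal_mu: float = 2.3   # of the (dbh - 12.7) lognormal, cm
    dbh_lognormal_sigma: float = 0.45
    # initial composition mixture: point masses at 0 and 1, near-pure mixed
    # components (hetero-phenology trees must exist in strongly dominated
    # stands for the boundary contrasts to be identifiable), and a uniform
    # body
    frac_pure_de: float = 0.10
    frac_pure_ev: float = 0.10
    frac_near_pure: float = 0.15    # each side, Beta(30, 2) / Beta(2, 30)
    near_pure_beta: tuple[float, float] = (30.0, 2.0)

    # feedback knobs (relative %, except the recruitment ratio)
    target_survival_advantage_de: float = 14.0  # DE over EV at relEV = 0
    target_survival_advantage_ev: float = 17.0  # EV over DE at relEV = 1
    target_growth_advantage_ev: float = 43.0    # EV over DE at relEV = 1
    target_growth_advantage_de: float = 4.0     # DE over EV at relEV = 0
    target_recruitment_ratio: float = 5.0       # con:hetero, relEV 0.9 vs 0.1

    # baseline demography (per census interval; ~2 %/yr baseline mortality)
    survival_base: float = 0.90       # con-phenological survival in own stand
    growth_base_cm: float = 1.4       # con-phenological increment in own stand
    growth_sigma_cm: float = 0.6
    recruit_log_rate: float = math.log(1.3)  # per phenology at relEV = 0.5

    # nuisance covariate effects (standardized scales, see _std); kept
    # modest so the contrast evaluated at training means stays close to
    # its value at the calibration reference
    surv_dbh: float = 0.12
    surv_ba: float = -0.25
    surv_density: float = -0.05
    surv_env: tuple[float, ...] = (0.08, 0.04, 0.02)
    growth_dbh: float = 0.05
    growth_ba: float = -0.12
    growth_env: tuple[float, ...] = (0.04, 0.02)
    recruit_ba: float = -0.50
    recruit_con_ba: float = 0.0
    recruit_env: tuple[float, ...] = (0.10, 0.05)

    # optional MAT-dependent asymmetry (evergreen favoured cold): the
    # recruitment log-rates gain -/+ mat_asymmetry * mat_std for EV / DE
    mat_effect: bool = False
    mat_asymmetry: float = 1.8

    # zero-adjusted abundance model (plot-level counts per leaf type)
    abundance_zero_intercept: float = -1.2
    abundance_zero_env: float = 0.9
    abundance_log_mean: float = 3.0
    abundance_env: float = 0.55
    abundance_coupling: float = 0.0   # rho <= 0; negative couples EV down, DE up

    def __post_init__(self) -> None:
        if not -1.0 <= self.abundance_coupling <= 0.0:
            raise ValueError("abundance_coupling must lie in [-1, 0]")
        if self.target_recruitment_ratio <= 0:
            raise CalibrationError("target_recruitment_ratio must be positive")

    # -- reference (calibration) covariate values -------------------------
    @property
    def dbh_ref(self) -> float:
        ln_mean = math.exp(self.dbh_lognormal_mu + self.dbh_lognormal_sigma**2 / 2)
        return RECRUIT_DBH_CM + ln_mean

    @property
    def tree_ba_ref_m2(self) -> float:
        mu, sg = self.dbh_lognormal_mu, self.dbh_lognormal_sigma
        e1 = math.exp(mu + sg**2 / 2)
        e2 = math.exp(2 * mu + 2 * sg**2)
        mean_sq = RECRUIT_DBH_CM**2 + 2 * RECRUIT_DBH_CM * e1 + e2
        return math.pi / 4.0 * mean_sq * 1e-4

    @property
    def ba_ref(self) -> float:
        """Expected initial basal area, m^2 per hectare."""
        return self.stand_size_mean * self.tree_ba_ref_m2 / self.plot_area_ha

    @property
    def density_ref(self) -> float:
        """Expected initial stem density per hectare."""
        return self.stand_size_mean / self.plot_area_ha


def _env_coef(short: tuple[float, ...]) -> np.ndarray:
    g = np.zeros(N_ENV_PCS)
    g[: len(short)] = short
    return g


def mat_from_pc1(pc1: np.ndarray) -> np.ndarray:
    """Mean annual temperature as an affine map of PC1 onto [-2, 23] C.

    PC1 is clipped at +-2.5 sd so the affine image spans the empirical
    forest MAT range without exceeding it.
    """
    return 10.5 + 12.5 * np.clip(np.asarray(pc1, float) / 2.5, -1.0, 1.0)


def mat_std(mat: np.ndarray) -> np.ndarray:
    """MAT standardized to [-1, 1] over the forest range [-2, 23] C."""
    return (np.asarray(mat, float) - 10.5) / 12.5


class TrueVitalRates:
    """Closed-form vital-rate truth resolved from the feedback knobs.

    Survival is logit-linear, growth linear and recruitment log-linear in
    the predictors, matching the link functions of the fitted models.

    ``variant="feedback"`` uses the plot's relative evergreen abundance;
    ``variant="null"`` freezes the composition terms at relEV = 0.5,
    removing frequency dependence while keeping all other structure.
    """

    def __init__(self, params: GeneratorParams, variant: str = "feedback"):
        if variant not in ("feedback", "null"):
            raise ValueError("variant must be 'feedback' or 'null'")
        self.params = params
        self.variant = variant
        p = params

        def _check_prob(v: float, knob: str) -> float:
            if not 0.0 < v < 1.0:
                raise CalibrationError(
                    f"knob {knob!r} implies survival probability {v:.4f} "
                    "outside (0, 1) at the reference covariates")
            return v

        def _check_pos(v: float, knob: str) -> float:
            if v <= 0:
                raise CalibrationError(
                    f"knob {knob!r} implies non-positive growth increment "
                    f"{v:.4f} cm at the reference covariates")
            return v

        s = _check_prob(p.survival_base, "survival_base")
        s_ev0 = _check_prob(s / (1 + p.target_survival_advantage_de / 100.0),
                            "target_survival_advantage_de")
        s_de1 = _check_prob(s / (1 + p.target_survival_advantage_ev / 100.0),
                            "target_survival_advantage_ev")
        self.surv_a = {Phenology.EV: float(logit(s_ev0)), Phenology.DE: float(logit(s))}
        self.surv_c = {Phenology.EV: float(logit(s) - logit(s_ev0)),
                       Phenology.DE: float(logit(s_de1) - logit(s))}

        g = _check_pos(p.growth_base_cm, "growth_base_cm")
        g_ev0 = _check_pos(g / (1 + p.target_growth_advantage_de / 100.0),
                           "target_growth_advantage_de")
        g_de1 = _check_pos(g / (1 + p.target_growth_advantage_ev / 100.0),
                           "target_growth_advantage_ev")
        self.growth_a = {Phenology.EV: g_ev0, Phenology.DE: g}
        self.growth_c = {Phenology.EV: g - g_ev0, Phenology.DE: g_de1 - g}

        # exp(0.8 * c_r) = target ratio  (contrast between relEV 0.9 and 0.1)
        self.recruit_c = math.log(p.target_recruitment_ratio) / 0.8

        self.surv_env = _env_coef(p.surv_env)
        self.growth_env = _env_coef(p.growth_env)
        self.recruit_env = _env_coef(p.recruit_env)

    # -- standardized covariates -----------------------------------------
    def _std(self, dbh, ba_ha, dens_ha):
        p = self.params
        dbh_s = (np.asarray(dbh, float) - p.dbh_ref) / 15.0
        ba_s = (np.asarray(ba_ha, float) - p.ba_ref) / 15.0
        dens_s = (np.asarray(dens_ha, float) - p.density_ref) / 300.0
        return dbh_s, ba_s, dens_s

    def _relev_term(self, relev):
        if self.variant == "null":
            return np.full_like(np.asarray(relev, float), 0.5)
        return np.asarray(relev, float)

    def survival_prob(self, phenology, dbh, ba_ha, dens_ha, env, relev):
        """Per-interval survival probability of a tree."""
        dbh_s, ba_s, dens_s = self._std(dbh, ba_ha, dens_ha)
        r = self._relev_term(relev)
        p = self.params
        lin = (self.surv_a[phenology] + self.surv_c[phenology] * r
               + p.surv_dbh * dbh_s + p.surv_ba * ba_s + p.surv_density * dens_s
               + np.asarray(env, float) @ self.surv_env)
        return expit(lin)

    def growth_increment(self, phenology, dbh, ba_ha, dens_ha, env, relev):
        """Expected diameter increment per interval, cm (noise excluded)."""
        dbh_s, ba_s, dens_s = self._std(dbh, ba_ha, dens_ha)
        r = self._relev_term(relev)
        p = self.params
        return (self.growth_a[phenology] + self.growth_c[phenology] * r
                + p.growth_dbh * dbh_s + p.growth_ba * ba_s
                + np.asarray(env, float) @ self.growth_env)

    def recruitment_rate(self, phenology, ba_ha, con_ba_ha, dens_ha, env, relev,
                         mat=None):
        """Expected recruits per plot per interval."""
        _, ba_s, _ = self._std(self.params.dbh_ref, ba_ha, dens_ha)
        con_s = (np.asarray(con_ba_ha, float) - self.params.ba_ref / 2.0) / 15.0
        r = self._relev_term(relev)
        con_rel = r if phenology is Phenology.EV else 1.0 - r
        p = self.params
        lin = (p.recruit_log_rate + self.recruit_c * (con_rel - 0.5)
               + p.recruit_ba * ba_s + p.recruit_con_ba * con_s
               + np.asarray(env, float) @ self.recruit_env)
        if p.mat_effect:
            if mat is None:
                raise ValueError("mat required when mat_effect is enabled")
            sgn = -1.0 if phenology is Phenology.EV else 1.0
            lin = lin + sgn * p.mat_asymmetry * mat_std(mat)
        return np.exp(lin)


# ---------------------------------------------------------------------------
# environment

def _determinants(rng: np.random.Generator, pcs: np.ndarray, mat: float) -> dict:
    """Plausible values of the seven key drivers, loaded on the leading PCs."""
    pc2 = pcs[1]
    pc3 = pcs[2]
    e = rng.normal(0, 0.3, size=5)
    return {
        "mat_c": float(mat),
        "annual_precip_mm": float(900 + 280 * pc2 + 90 * e[0]),
        "coldest_quarter_c": float(mat - 12 + 2.0 * pc3 + e[1]),
        "driest_quarter_mm": float(140 + 55 * pc2 + 18 * e[2]),
        "soil_ph": float(np.clip(5.8 + 0.55 * pc3 + 0.25 * e[3], 3.5, 8.5)),
        "soil_n_density": float(np.exp(0.6 + 0.3 * pc3 + 0.15 * e[4])),
        "soil_cn_ratio": float(np.clip(14 - 2.2 * pc3 + e[1], 5, 40)),
    }


def generate_environment(params: GeneratorParams) -> list[PlotRecord]:
    """Plots with environments but no trees; reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    plots = []
    for i in range(params.n_plots):
        pcs = rng.standard_normal(N_ENV_PCS)
        mat = float(mat_from_pc1(pcs[0]))
        plots.append(PlotRecord(
            plot_id=f"P{i:06d}",
            lon=float(rng.uniform(-100.0, -70.0)),
            lat=float(rng.uniform(35.0, 48.0)),
            area=params.plot_area_ha,
            interval=params.interval_yr,
            env_pcs=pcs,
            mat=mat,
            determinants=_determinants(rng, pcs, mat),
        ))
    return plots


# ---------------------------------------------------------------------------
# two-census inventory

_SPECIES_P = np.array([0.4, 0.3, 0.2, 0.1])


def _species(rng: np.random.Generator, pheno: Phenology, size: int) -> np.ndarray:
    k = rng.choice(4, size=size, p=_SPECIES_P)
    tag = "EV" if pheno is Phenology.EV else "DE"
    return np.array([f"{tag}_sp{j}" for j in k])


def generate_two_census_inventory(
    env_plots: list[PlotRecord],
    params: GeneratorParams,
    rates: TrueVitalRates | None = None,
) -> list[PlotRecord]:
    """Populate plots with an initial stand and simulate one census interval.

    Every tree survives with its true survival probability; survivors grow
    by the true increment plus Gaussian noise; recruits arrive Poisson at
    the true rate and enter at 12.7 cm.  The initial evergreen share is a
    mixture of pure-deciduous, pure-evergreen and uniform plots.
    """
    rates = rates or TrueVitalRates(params)
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    out = []
    p = params
    for plot in env_plots:
        extra = max(p.stand_size_mean - p.stand_size_min, 0.0)
        if p.stand_size_gamma_shape > 0:
            lam = rng.gamma(p.stand_size_gamma_shape,
                            extra / p.stand_size_gamma_shape)
        else:
            lam = extra
        n0 = p.stand_size_min + rng.poisson(lam)
        u = rng.random()
        a_np, b_np = p.near_pure_beta
        if u < p.frac_pure_de:
            target = 0.0
        elif u < p.frac_pure_de + p.frac_pure_ev:
            target = 1.0
        elif u < p.frac_pure_de + p.frac_pure_ev + p.frac_near_pure:
            target = rng.beta(b_np, a_np)   # deciduous-dominated, near 0
        elif u < p.frac_pure_de + p.frac_pure_ev + 2 * p.frac_near_pure:
            target = rng.beta(a_np, b_np)   # evergreen-dominated, near 1
        else:
            target = rng.random()
        is_ev = rng.random(n0) < target
        dbh = RECRUIT_DBH_CM + rng.lognormal(p.dbh_lognormal_mu, p.dbh_lognormal_sigma, n0)
        ba_tree = np.pi * (dbh / 200.0) ** 2
        ba_ev = float(ba_tree[is_ev].sum())
        ba_de = float(ba_tree[~is_ev].sum())
        relev = ba_ev / (ba_ev + ba_de) if (ba_ev + ba_de) > 0 else 0.5
        ba_ha = (ba_ev + ba_de) / plot.area
        dens_ha = n0 / plot.area

        trees: list[TreeRecord] = []
        for pheno, mask in ((Phenology.EV, is_ev), (Phenology.DE, ~is_ev)):
            d = dbh[mask]
            if d.size:
                s = rates.survival_prob(pheno, d, ba_ha, dens_ha, plot.env_pcs, relev)
                alive = rng.random(d.size) < s
                inc = rates.growth_increment(pheno, d, ba_ha, dens_ha, plot.env_pcs, relev)
                inc = inc + rng.normal(0.0, p.growth_sigma_cm, d.size)
                sp = _species(rng, pheno, d.size)
                for j in range(d.size):
                    if alive[j]:
                        trees.append(TreeRecord(
                            tree_id=f"{plot.plot_id}t{len(trees)}", plot_id=plot.plot_id,
                            species_id=str(sp[j]), phenology=pheno,
                            dbh_prev=float(d[j]), dbh_curr=float(d[j] + inc[j]),
                            fate=Fate.SURVIVOR))
                    else:
                        trees.append(TreeRecord(
                            tree_id=f"{plot.plot_id}t{len(trees)}", plot_id=plot.plot_id,
                            species_id=str(sp[j]), phenology=pheno,
                            dbh_prev=float(d[j]), dbh_curr=None, fate=Fate.DIED))
            con_ba = (ba_ev if pheno is Phenology.EV else ba_de) / plot.area
            lam = rates.recruitment_rate(pheno, ba_ha, con_ba, dens_ha,
                                         plot.env_pcs, relev,
                                         mat=plot.mat if p.mat_effect else None)
            n_rec = rng.poisson(lam)
            sp = _species(rng, pheno, n_rec)
            for j in range(n_rec):
                trees.append(TreeRecord(
                    tree_id=f"{plot.plot_id}t{len(trees)}", plot_id=plot.plot_id,
                    species_id=str(sp[j]), phenology=pheno,
                    dbh_prev=None, dbh_curr=RECRUIT_DBH_CM, fate=Fate.RECRUIT))
        new_plot = dataclasses.replace(plot, trees=trees)
        out.append(new_plot)
    return out


# ---------------------------------------------------------------------------
# zero-adjusted abundance table

def abundance_zap_params(params: GeneratorParams, env_pcs: np.ndarray):
    """True (pi0, mu) per leaf type for an array of environments.

    The positive-part means are modulated by a shared plot-level latent
    factor entering the two types with opposite signs, which induces
    environment-independent negative dependence when the coupling knob is
    negative (its strength is sqrt(-rho)); the latent contribution is
    mean-corrected so the marginal mu is unchanged.
    """
    p = params
    pc1 = np.asarray(env_pcs)[:, 0]
    pc2 = np.asarray(env_pcs)[:, 1]
    pi0_ev = expit(p.abundance_zero_intercept + p.abundance_zero_env * pc1)
    pi0_de = expit(p.abundance_zero_intercept - p.abundance_zero_env * pc1)
    log_mu_ev = p.abundance_log_mean - p.abundance_env * pc1 + 0.2 * pc2
    log_mu_de = p.abundance_log_mean + p.abundance_env * pc1 + 0.2 * pc2
    return pi0_ev, pi0_de, log_mu_ev, log_mu_de


def _sample_ztp(rng: np.random.Generator, mu: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson draws by masked resampling."""
    mu = np.asarray(mu, float)
    out = rng.poisson(mu)
    todo = out == 0
    while np.any(todo):
        out[todo] = rng.poisson(mu[todo])
        todo = out == 0
    return out


def generate_abundance_table(env_plots: list[PlotRecord], params: GeneratorParams):
    """Plot-level (ev_count, de_count) pairs from the zero-adjusted model.

    With ``abundance_coupling = 0`` the two counts are conditionally
    independent given the environment; negative coupling enriches the
    outer relEV bins beyond what environment alone produces.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 2)))
    pcs = np.array([pl.env_pcs for pl in env_plots])
    pi0_ev, pi0_de, log_mu_ev, log_mu_de = abundance_zap_params(params, pcs)
    s = 1.4 * math.sqrt(-params.abundance_coupling)
    z = rng.standard_normal(len(env_plots))
    mu_ev = np.exp(log_mu_ev + s * z - s**2 / 2.0)
    mu_de = np.exp(log_mu_de - s * z - s**2 / 2.0)
    ev = np.where(rng.random(len(env_plots)) < pi0_ev, 0, _sample_ztp(rng, mu_ev))
    de = np.where(rng.random(len(env_plots)) < pi0_de, 0, _sample_ztp(rng, mu_de))
    return pd.DataFrame({
        "plot_id": [pl.plot_id for pl in env_plots],
        "ev_count": ev.astype(int),
        "de_count": de.astype(int),
    })


# ---------------------------------------------------------------------------
# relEV mixture samples for the bimodality-index machinery

RELEV_PRESETS: dict[str, list[tuple[float, float, float]]] = {
    # (weight, alpha, beta)
    "unimodal_left": [(1.0, 1.6, 7.0)],    # deciduous-heavy, right-skewed
    "unimodal_right": [(1.0, 7.0, 1.6)],   # evergreen-heavy, left-skewed
    "bimodal": [(0.5, 2.0, 11.0), (0.5, 11.0, 2.0)],
}


def generate_relev_samples(
    spec: str | list[tuple[float, float, float]],
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw relEV values from a named preset or a beta-mixture spec.

    A spec is a list of ``(weight, alpha, beta)`` components; the weights
    must sum to 1.
    """
    comps = RELEV_PRESETS[spec] if isinstance(spec, str) else spec
    w = np.array([c[0] for c in comps], dtype=float)
    if w.size == 0 or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(comps), size=n, p=w)
    out = np.empty(n)
    for i, (_, a, b) in enumerate(comps):
        m = which == i
        out[m] = rng.beta(a, b, size=int(m.sum()))
    return out
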