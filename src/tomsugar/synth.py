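"""Study-shaped synthetic data with known ground truth.

Emulates the structure of a two-genotype glasshouse study: a cherry-type and
a large-fruited tomato, each grown under five treatments (a reference season,
high/low crop load, well-watered and water-deficit), with

* an hourly temperature series (diurnal cycle plus day-to-day AR(1) noise),
* Gompertz fresh- and dry-weight growth observed with multiplicative noise,
* a saturating water-content trajectory per treatment below a genotype-level
  upper boundary, and
* sugar/starch observations produced by the forward carbon-balance model from
  known "true" parameters plus multiplicative lognormal noise with replicates.

Treatments perturb the growth asymptote and the water content the way crop
load and irrigation do (lower load = bigger, slightly drier fruit; water
deficit = smaller, drier fruit), so every downstream stage — growth fitting,
empirical rate diagnostics, calibration, model comparison, cross-validation —
can be scored against the generating truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ObservationSet, pooled_variances
from .core import (
    FruitTrajectory,
    ModelParameters,
    Variant,
    initial_state,
    integrate,
)
from .constants import C_SOL, C_STA
from .growth import (
    GompertzParameters,
    WcBoundary,
    build_trajectory,
    degree_days,
    fit_gompertz,
    fit_wcmax,
    water_content,
)

__all__ = [
    "ClimateConfig",
    "GenotypeTemplate",
    "TreatmentSpec",
    "StudyConfig",
    "StudyData",
    "cherry_template",
    "large_template",
    "default_config",
    "apply_treatment",
    "generate_temperature",
    "true_trajectory",
    "generate_growth",
    "generate_observations",
    "generate_study",
    "assemble_datasets",
    "write_study",
]


@dataclass(frozen=True)
class ClimateConfig:
    """Hourly glasshouse temperature: mean + diurnal sine + AR(1) daily noise."""

    mean_c: float = 20.0
    diurnal_amplitude_c: float = 6.0
    daily_sd_c: float = 1.5
    daily_ar: float = 0.7
    season_days: int = 70


@dataclass(frozen=True)
class GenotypeTemplate:
    """Ground-truth curves and parameters of one genotype."""

    name: str
    fw: GompertzParameters
    dw: GompertzParameters
    wc_boundary: WcBoundary
    true_params: ModelParameters
    sample_ages_d: tuple
    growth_ages_d: tuple
    init_ss: float
    init_st: float

    @property
    def first_age_d(self) -> float:
        return float(self.sample_ages_d[0])

    @property
    def last_age_d(self) -> float:
        return float(self.sample_ages_d[-1])


@dataclass(frozen=True)
class TreatmentSpec:
    """Template perturbation: scale on the weight asymptotes, WC shift (pct pts)."""

    name: str
    a_scale: float = 1.0
    wc_offset: float = 0.0


@dataclass(frozen=True)
class StudyConfig:
    """Design of the synthetic study (genotypes x treatments x sampling)."""

    genotypes: tuple
    treatments: tuple
    replicates: int = 4
    cv: float = 0.05
    climate: ClimateConfig = field(default_factory=ClimateConfig)

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


# Published best-estimate parameter sets for a cherry-type and a large-fruited
# genotype (water-content variant) serve as the generating truth.
CHERRY_TRUE = ModelParameters(
    lam=4.324, alpha=1.620, beta=0.187, k2=0.461, k30=1.018, gamma=0.035,
    u=478.64, tau=53.53, variant=Variant.SUGAR_WC,
)
LARGE_TRUE = ModelParameters(
    lam=2.642, alpha=0.305, beta=0.029, k2=0.234, k30=0.125, gamma=0.517,
    u=413.02, tau=225.73, variant=Variant.SUGAR_WC,
)


def cherry_template() -> GenotypeTemplate:
    """Cherry-type genotype: ~8 g fruit, 45-day season, starch-rich early."""
    return GenotypeTemplate(
        name="cherry",
        fw=GompertzParameters(a=8.0, b=11.9, c=0.165 / 24.0),
        dw=GompertzParameters(a=0.48, b=9.81, c=0.165 / 24.0),
        wc_boundary=WcBoundary(p_inf=94.55, delta=23.37, r=0.01442),
        true_params=CHERRY_TRUE,
        sample_ages_d=(5, 8, 12, 16, 20, 25, 30, 35, 40, 45),
        growth_ages_d=(5, 8, 11, 14, 17, 20, 24, 28, 32, 36, 40, 45),
        init_ss=10.0,
        init_st=12.0,
    )


def large_template() -> GenotypeTemplate:
    """Large-fruited genotype: ~110 g fruit, 60-day season, water-sensitive starch."""
    return GenotypeTemplate(
        name="large",
        fw=GompertzParameters(a=110.0, b=11.0, c=0.12 / 24.0),
        dw=GompertzParameters(a=6.05, b=8.91, c=0.12 / 24.0),
        wc_boundary=WcBoundary(p_inf=95.07, delta=20.81, r=0.01028),
        true_params=LARGE_TRUE,
        sample_ages_d=(9, 14, 20, 26, 32, 38, 45, 52, 60),
        growth_ages_d=(9, 13, 17, 21, 26, 31, 36, 42, 48, 54, 60),
        init_ss=18.0,
        init_st=10.0,
    )


def default_treatments(genotype: str) -> tuple:
    """Five treatments mirroring the study contrasts.

    Lower crop load: larger and slightly drier fruit; water deficit: smaller
    fruit, drier for the large-fruited genotype but barely so for the cherry
    (matching the observed genotype dependence of the water-content response).
    """
    if genotype == "cherry":
        return (
            TreatmentSpec("2003", 1.00, 0.0),
            TreatmentSpec("2007_HL", 0.85, 0.0),
            TreatmentSpec("2007_LL", 1.15, -0.4),
            TreatmentSpec("2014_WW", 1.05, 0.0),
            TreatmentSpec("2014_WD", 0.75, -0.2),
        )
    return (
        TreatmentSpec("2003", 1.00, 0.0),
        TreatmentSpec("2007_HL", 0.85, 0.0),
        TreatmentSpec("2007_LL", 1.15, -0.8),
        TreatmentSpec("2014_WW", 1.05, 0.0),
        TreatmentSpec("2014_WD", 0.70, -1.0),
    )


def default_config() -> StudyConfig:
    return StudyConfig(
        genotypes=(cherry_template(), large_template()),
        treatments=(),  # resolved per genotype via default_treatments
    )


def apply_treatment(
    template: GenotypeTemplate, treatment: TreatmentSpec
) -> GenotypeTemplate:
    """Perturb the truth curves for one treatment.

    The asymptote scale acts on both FW and DW; the water-content offset is
    realised by raising the DW/FW asymptote ratio so the whole WC trajectory
    shifts down by about that many percentage points.
    """
    fw_a = template.fw.a * treatment.a_scale
    ratio = template.dw.a / template.fw.a - treatment.wc_offset / 100.0
    if not 0 < ratio < 1:
        raise ValueError("treatment drives the DW/FW ratio out of (0, 1)")
    fw = replace(template.fw, a=fw_a)
    dw = replace(template.dw, a=fw_a * ratio)
    return replace(template, fw=fw, dw=dw)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_temperature(
    config: ClimateConfig, seed=0
) -> np.ndarray:
    """Hourly temperature series from anthesis (length season_days * 24)."""
    rng = np.random.default_rng(seed)
    n = config.season_days * 24
    hours = np.arange(n)
    diurnal = config.diurnal_amplitude_c * np.sin(2 * np.pi * (hours % 24 - 9) / 24.0)
    daily = np.empty(config.season_days)
    noise = rng.normal(0.0, config.daily_sd_c, size=config.season_days)
    level = 0.0
    for d in range(config.season_days):
        level = config.daily_ar * level + np.sqrt(1 - config.daily_ar**2) * noise[d]
        daily[d] = level
    return config.mean_c + diurnal + np.repeat(daily, 24)


def true_trajectory(
    template: GenotypeTemplate, temp_hourly: np.ndarray, dt: float = 1.0
) -> FruitTrajectory:
    """Model-input trajectory from the genotype's true curves and boundary."""
    return build_trajectory(
        template.dw,
        template.fw,
        temp_hourly,
        template.wc_boundary,
        t_start_h=template.first_age_d * 24.0,
        t_end_h=template.last_age_d * 24.0,
        dt=dt,
    )


def generate_growth(
    template: GenotypeTemplate,
    cv: float,
    replicates: int,
    seed=0,
) -> pd.DataFrame:
    """Sampled FW/DW observations around the true growth curves.

    Multiplicative lognormal noise per fruit.  FW and DW of one fruit share
    the fruit-size error (both are measured on the same sampled fruit), with
    a smaller independent residual on the dry-matter ratio, so the derived
    water content carries a realistically small error; the dry weight never
    exceeds the fresh weight.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for age in template.growth_ages_d:
        t_h = age * 24.0
        fw_true = float(template.fw.weight(t_h))
        dw_true = float(template.dw.weight(t_h))
        size_err = _lognormal_factors(rng, cv, replicates)
        ratio_err = _lognormal_factors(rng, cv * 0.5, replicates)
        fw_obs = fw_true * size_err
        dw_obs = dw_true * size_err * ratio_err
        dw_obs = np.minimum(dw_obs, fw_obs * 0.999)
        for r in range(replicates):
            rows.append(
                {
                    "age_d": float(age),
                    "replicate": r,
                    "fw_g": fw_obs[r],
                    "dw_g": dw_obs[r],
                }
            )
    return pd.DataFrame(rows)


def generate_observations(
    template: GenotypeTemplate,
    traj: FruitTrajectory,
    cv: float,
    replicates: int,
    seed=0,
    name: str = "",
) -> ObservationSet:
    """Forward-simulate the truth and sample noisy SS/ST observations.

    The fresh-weight-basis values carry the same multiplicative noise scaled
    by the (true) DW/FW ratio, as they would when derived from the same
    sampled fruits.  Variances are left at a placeholder and must be pooled
    per genotype before calibration (see :func:`generate_study`).
    """
    rng = np.random.default_rng(seed)
    init = initial_state(
        template.init_ss,
        template.init_st,
        float(traj.interp("dw", template.first_age_d * 24.0)),
    )
    sim = integrate(traj, template.true_params, init)
    ages = np.repeat(np.asarray(template.sample_ages_d, dtype=float), replicates)
    t_obs = ages * 24.0
    csol = np.interp(t_obs, sim.t, sim.csol)
    csta = np.interp(t_obs, sim.t, sim.csta)
    dw = traj.interp("dw", t_obs)
    fw = traj.interp("fw", t_obs)
    ss_true = 100.0 * csol / (C_SOL * dw)
    st_true = 100.0 * csta / (C_STA * dw)
    ss = ss_true * _lognormal_factors(rng, cv, ages.size)
    st = st_true * _lognormal_factors(rng, cv, ages.size)
    ratio = dw / fw
    return ObservationSet(
        age_d=ages,
        ss=ss,
        st=st,
        var_ss=1.0,
        var_st=1.0,
        ssc=ss * ratio,
        stc=st * ratio,
        name=name,
    )


@dataclass
class TreatmentData:
    """Everything generated for one genotype x treatment."""

    spec: TreatmentSpec
    template: GenotypeTemplate  # treatment-adjusted truth
    growth_obs: pd.DataFrame
    observations: ObservationSet
    true_trajectory: FruitTrajectory


@dataclass
class GenotypeStudy:
    template: GenotypeTemplate
    treatments: dict


@dataclass
class StudyData:
    """Full synthetic study bundle plus the truth record."""

    config: StudyConfig
    seed: int
    temp_hourly: np.ndarray
    genotypes: dict

    def truth_record(self) -> dict:
        out = {"seed": self.seed}
        for gname, gen in self.genotypes.items():
            gdict = {"true_params": dataclasses.asdict(gen.template.true_params)}
            gdict["true_params"]["variant"] = gen.template.true_params.variant.value
            gdict["treatments"] = {}
            for tname, tdata in gen.treatments.items():
                tpl = tdata.template
                gdict["treatments"][tname] = {
                    "fw": dataclasses.asdict(tpl.fw),
                    "dw": dataclasses.asdict(tpl.dw),
                    "wc_boundary": dataclasses.asdict(tpl.wc_boundary),
                    "init_ss": tpl.init_ss,
                    "init_st": tpl.init_st,
                }
            out[gname] = gdict
        return out


def generate_study(
    config: StudyConfig | None = None, seed: int = 0
) -> StudyData:
    """Generate the whole study: climate, growth, water content, sugars/starch.

    Deterministic for a given seed; the per-genotype criterion variances are
    the pooled sample variances of the replicate SS and ST observations, the
    exact quantities the calibration criterion divides by.
    """
    config = config or default_config()
    root = np.random.SeedSequence(seed)
    temp = generate_temperature(config.climate, seed=np.random.SeedSequence([seed, 7]))
    genotypes = {}
    for g_index, template in enumerate(config.genotypes):
        treatments = config.treatments or default_treatments(template.name)
        tdata = {}
        for t_index, spec in enumerate(treatments):
            adjusted = apply_treatment(template, spec)
            traj = true_trajectory(adjusted, temp)
            growth = generate_growth(
                adjusted,
                config.cv,
                config.replicates,
                seed=np.random.SeedSequence([seed, 11, g_index, t_index]),
            )
            obs = generate_observations(
                adjusted,
                traj,
                config.cv,
                config.replicates,
                seed=np.random.SeedSequence([seed, 13, g_index, t_index]),
                name=spec.name,
            )
            tdata[spec.name] = TreatmentData(
                spec=spec,
                template=adjusted,
                growth_obs=growth,
                observations=obs,
                true_trajectory=traj,
            )
        var_ss, var_st = pooled_variances(
            [td.observations for td in tdata.values()]
        )
        for td in tdata.values():
            td.observations.var_ss = var_ss
            td.observations.var_st = var_st
        genotypes[template.name] = GenotypeStudy(template=template, treatments=tdata)
    return StudyData(config=config, seed=seed, temp_hourly=temp, genotypes=genotypes)


def assemble_datasets(
    study: StudyData,
    genotype: str,
    use_fitted_growth: bool = True,
    dt: float = 1.0,
):
    """Build the calibration inputs for one genotype from the generated study.

    With ``use_fitted_growth`` the pipeline is exercised end to end: Gompertz
    curves are refitted to the noisy growth observations, the water-content
    boundary is refitted to the pooled per-date maxima, and trajectories are
    rebuilt from those fits.  Otherwise the true curves are used (isolates
    calibration from input-fitting error).

    Returns ``(datasets, trajectories)``: a list of (ObservationSet,
    FruitTrajectory) pairs in treatment order and the same trajectories keyed
    by treatment.
    """
    gen = study.genotypes[genotype]
    temp = study.temp_hourly
    trajectories = {}
    datasets = []
    if use_fitted_growth:
        dd_hourly = degree_days(temp)
        ages = np.asarray(gen.template.growth_ages_d, dtype=float)
        pooled_wc = [[] for _ in ages]
        fits = {}
        for tname, tdata in gen.treatments.items():
            obs = tdata.growth_obs
            t_h = obs["age_d"].to_numpy() * 24.0
            fw_fit = fit_gompertz(t_h, obs["fw_g"].to_numpy())
            dw_fit = fit_gompertz(t_h, obs["dw_g"].to_numpy())
            fits[tname] = (dw_fit, fw_fit)
            wc_obs = water_content(obs["fw_g"].to_numpy(), obs["dw_g"].to_numpy())
            for i, age in enumerate(ages):
                pooled_wc[i].extend(wc_obs[obs["age_d"].to_numpy() == age])
        dd_dates = np.interp(ages * 24.0, np.arange(temp.size, dtype=float), dd_hourly)
        boundary = fit_wcmax(dd_dates, pooled_wc)
    for tname, tdata in gen.treatments.items():
        if use_fitted_growth:
            dw_fit, fw_fit = fits[tname]
            traj = build_trajectory(
                dw_fit,
                fw_fit,
                temp,
                boundary,
                t_start_h=gen.template.first_age_d * 24.0,
                t_end_h=gen.template.last_age_d * 24.0,
                dt=dt,
            )
        else:
            traj = tdata.true_trajectory
        trajectories[tname] = traj
        datasets.append((tdata.observations, traj))
    return datasets, trajectories


def write_study(study: StudyData, outdir) -> dict:
    """Write the study as plain-text files: climate, observations, truth.

    ``climate.csv`` (hour, temp_c), ``growth.csv`` and ``observations.csv``
    (tidy, one row per replicate measurement) and ``truth.json``.  Returns
    the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    climate = pd.DataFrame(
        {"hour": np.arange(study.temp_hourly.size), "temp_c": study.temp_hourly}
    )
    climate_path = outdir / "climate.csv"
    climate.to_csv(climate_path, index=False)
    growth_rows, obs_rows = [], []
    for gname, gen in study.genotypes.items():
        for tname, tdata in gen.treatments.items():
            g = tdata.growth_obs.copy()
            g.insert(0, "genotype", gname)
            g.insert(1, "treatment", tname)
            growth_rows.append(g)
            o = tdata.observations
            obs_rows.append(
                pd.DataFrame(
                    {
                        "genotype": gname,
                        "treatment": tname,
                        "age_d": o.age_d,
                        "ss_gdw": o.ss,
                        "st_gdw": o.st,
                        "ssc_gfw": o.ssc,
                        "stc_gfw": o.stc,
                    }
                )
            )
    growth_path = outdir / "growth.csv"
    obs_path = outdir / "observations.csv"
    truth_path = outdir / "truth.json"
    pd.concat(growth_rows).to_csv(growth_path, index=False)
    pd.concat(obs_rows).to_csv(obs_path, index=False)
    truth_path.write_text(json.dumps(study.truth_record(), indent=2))
    return {
        "climate": climate_path,
        "growth": growth_path,
        "observations": obs_path,
        "truth": truth_path,
    }
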