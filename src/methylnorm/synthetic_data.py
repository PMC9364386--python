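"""Synthetic methylation-array intensity data with known ground truth.

The generator emulates the statistical structure that makes mixed-sex
quantile normalization biased:

* autosomal CpGs with bimodal betas (a three-component Beta mixture:
  unmethylated, intermediate, methylated) shared across samples up to
  logit-normal biological jitter;
* female X CpGs at intermediate methylation (X inactivation: one silenced,
  hypermethylated copy averaged with one active copy), male X CpGs bimodal
  like autosomes;
* male Y CpGs bimodal; female Y probes carrying only background-scale signal
  (non-specific hybridization) — tiny total intensity, noisy betas;
* per-sample multiplicative technical factors per channel (between-array
  variation that normalization should remove);
* an additive Type I intensity offset (the two Infinium chemistries sit on
  different intensity scales).

Intensities invert the beta formula: M = beta * T + noise and
U = (1 - beta) * T + noise with a shared per-cell total intensity T, floored
at zero.  All randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .io_tables import IntensityMatrix, ProbeAnnotation, SampleSheet
from .normalize_core import BetaMatrix


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulator.

    Probe counts default to a desk-scale array keeping the real platforms'
    ~2.4% sex-chromosome share (50k autosomal, 1.2k X, 120 Y).
    """

    n_female: int = 10
    n_male: int = 10
    n_auto: int = 50_000
    n_x: int = 1_200
    n_y: int = 120
    type2_fraction: float = 0.72
    # Autosomal beta mixture: unmethylated / intermediate / methylated modes.
    auto_mixture_weights: tuple[float, ...] = (0.44, 0.12, 0.44)
    auto_mixture_means: tuple[float, ...] = (0.10, 0.50, 0.88)
    auto_mixture_concentrations: tuple[float, ...] = (25.0, 15.0, 25.0)
    # Female X: intermediate via X inactivation (one active bimodal copy
    # averaged with one silenced, largely methylated copy); centered at the
    # autosomal median so the cluster sits above roughly half the autosomal
    # values, as on real arrays.
    female_x_mean: float = 0.50
    female_x_concentration: float = 20.0
    # Male X: one chromosome copy, so roughly half the total intensity.
    male_x_intensity_scale: float = 0.5
    # Female Y probes see only background: total intensity scaled way down.
    female_y_intensity_scale: float = 0.05
    # Per-sample multiplicative technical factor, log-normal sigma per channel.
    technical_sd_meth: float = 0.15
    technical_sd_unmeth: float = 0.15
    # Additive Type I intensity offset (chemistry scale difference).
    type1_intensity_shift: float = 2000.0
    # Per-probe total intensity, log-normal.
    total_intensity_median: float = 5000.0
    total_intensity_sigma: float = 0.5
    # Additive measurement noise on each channel.
    background_noise_sd: float = 50.0
    # Biological between-sample jitter on betas, logit scale.
    biological_logit_sd: float = 0.1
    # Planted autosomal sex effect.
    n_sex_effect_auto: int = 0
    sex_effect_delta: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for name in ("n_female", "n_male", "n_auto", "n_x", "n_y", "n_sex_effect_auto"):
            if getattr(self, name) < 0:
                bad.append(name)
        if not 0 <= self.type2_fraction <= 1:
            bad.append("type2_fraction")
        if abs(sum(self.auto_mixture_weights) - 1.0) > 1e-9:
            bad.append("auto_mixture_weights")
        if not (len(self.auto_mixture_weights) == len(self.auto_mixture_means)
                == len(self.auto_mixture_concentrations)):
            bad.append("auto_mixture_means/concentrations")
        if not -1 < self.sex_effect_delta < 1:
            bad.append("sex_effect_delta")
        if self.n_sex_effect_auto > self.n_auto:
            bad.append("n_sex_effect_auto")
        for name in ("female_y_intensity_scale", "male_x_intensity_scale",
                     "technical_sd_meth", "technical_sd_unmeth",
                     "total_intensity_median", "total_intensity_sigma",
                     "background_noise_sd", "biological_logit_sd",
                     "female_x_concentration"):
            if getattr(self, name) < 0:
                bad.append(name)
        if bad:
            raise ConfigError(f"invalid SimConfig fields: {sorted(set(bad))}")


@dataclass(frozen=True)
class SimulatedDataset:
    intensities: IntensityMatrix
    annotation: ProbeAnnotation
    sheet: SampleSheet
    true_beta: BetaMatrix
    technical_factors: pd.DataFrame  # samples x {meth, unmeth}
    config: SimConfig


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def _draw_mixture(rng: np.random.Generator, n: int, weights, means, concs) -> np.ndarray:
    comp = rng.choice(len(weights), size=n, p=np.asarray(weights, dtype=float))
    out = np.empty(n)
    for c, (mu, kappa) in enumerate(zip(means, concs)):
        sel = comp == c
        a, b = _beta_params(mu, kappa)
        out[sel] = rng.beta(a, b, size=int(sel.sum()))
    return out


def _logit_jitter(rng: np.random.Generator, base: np.ndarray, sd: float,
                  n_samples: int) -> np.ndarray:
    """Per-sample logit-normal jitter around per-probe base betas."""
    base = np.clip(base, 1e-6, 1 - 1e-6)
    logit = np.log(base / (1 - base))[:, None]
    if sd > 0:
        logit = logit + rng.normal(0.0, sd, size=(len(base), n_samples))
    return 1.0 / (1.0 + np.exp(-logit)) * np.ones((1, n_samples))


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Draw a full dataset (intensities + annotation + sheet + truth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_female + cfg.n_male
    if n_samples == 0:
        raise ConfigError("need at least one sample")

    probe_ids = (
        [f"cgA{i:07d}" for i in range(cfg.n_auto)]
        + [f"cgX{i:05d}" for i in range(cfg.n_x)]
        + [f"cgY{i:05d}" for i in range(cfg.n_y)]
    )
    chroms = (
        [str(1 + i % 22) for i in range(cfg.n_auto)]
        + ["X"] * cfg.n_x + ["Y"] * cfg.n_y
    )
    n_probes = len(probe_ids)
    design = np.where(rng.random(n_probes) < cfg.type2_fraction, "II", "I")
    annotation = ProbeAnnotation(pd.DataFrame(
        {"chromosome": chroms, "design_type": design},
        index=pd.Index(probe_ids, name="probe_id"),
    ))

    sample_ids = [f"F{i:03d}" for i in range(cfg.n_female)] + \
                 [f"M{i:03d}" for i in range(cfg.n_male)]
    sexes = ["female"] * cfg.n_female + ["male"] * cfg.n_male
    chip_rows = 1 + rng.integers(0, 8, size=n_samples)
    sheet = SampleSheet(pd.DataFrame(
        {"sex": sexes, "chip_row": chip_rows},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    female_cols = np.array([s == "female" for s in sexes])

    w, mu, kp = cfg.auto_mixture_weights, cfg.auto_mixture_means, cfg.auto_mixture_concentrations
    base_auto = _draw_mixture(rng, cfg.n_auto, w, mu, kp)
    base_x_male = _draw_mixture(rng, cfg.n_x, w, mu, kp)
    ax, bx = _beta_params(cfg.female_x_mean, cfg.female_x_concentration)
    base_x_female = rng.beta(ax, bx, size=cfg.n_x)
    base_y_male = _draw_mixture(rng, cfg.n_y, w, mu, kp)

    # True betas per probe x sample.
    beta = np.empty((n_probes, n_samples))
    sl_auto = slice(0, cfg.n_auto)
    sl_x = slice(cfg.n_auto, cfg.n_auto + cfg.n_x)
    sl_y = slice(cfg.n_auto + cfg.n_x, n_probes)

    beta[sl_auto] = _logit_jitter(rng, base_auto, cfg.biological_logit_sd, n_samples)
    # Planted autosomal sex effects: +/- delta added to female means.
    effect_idx = rng.choice(cfg.n_auto, size=cfg.n_sex_effect_auto, replace=False)
    effect_sign = rng.choice([-1.0, 1.0], size=cfg.n_sex_effect_auto)
    if cfg.n_sex_effect_auto:
        shift = np.zeros((cfg.n_auto, n_samples))
        shift[effect_idx[:, None], np.flatnonzero(female_cols)[None, :]] = \
            (effect_sign * cfg.sex_effect_delta)[:, None]
        beta[sl_auto] = np.clip(beta[sl_auto] + shift, 0.005, 0.995)

    bx_mat = np.empty((cfg.n_x, n_samples))
    bx_mat[:, female_cols] = _logit_jitter(rng, base_x_female, cfg.biological_logit_sd,
                                           int(female_cols.sum()))
    bx_mat[:, ~female_cols] = _logit_jitter(rng, base_x_male, cfg.biological_logit_sd,
                                            int((~female_cols).sum()))
    beta[sl_x] = bx_mat

    by_mat = np.empty((cfg.n_y, n_samples))
    by_mat[:, ~female_cols] = _logit_jitter(rng, base_y_male, cfg.biological_logit_sd,
                                            int((~female_cols).sum()))
    # Female Y "betas" are background: the probes measure nothing specific.
    by_mat[:, female_cols] = rng.beta(2.0, 2.0, size=(cfg.n_y, int(female_cols.sum())))
    beta[sl_y] = by_mat

    # Total intensity per probe, scaled per sample/channel, Type I shifted.
    log_t = rng.normal(np.log(cfg.total_intensity_median), cfg.total_intensity_sigma,
                       size=n_probes)
    t_probe = np.exp(log_t)
    auto_median_t = float(np.median(t_probe[sl_auto]))
    t_cell = np.repeat(t_probe[:, None], n_samples, axis=1)
    # Male X: single-copy chromosome, reduced total intensity.
    t_x = t_cell[sl_x].copy()
    t_x[:, ~female_cols] *= cfg.male_x_intensity_scale
    t_cell[sl_x] = t_x
    # Female Y: background-scale total intensity.
    t_y = t_cell[sl_y].copy()
    t_y[:, female_cols] = cfg.female_y_intensity_scale * auto_median_t
    t_cell[sl_y] = t_y

    fac_m = np.exp(rng.normal(0.0, cfg.technical_sd_meth, size=n_samples)) \
        if cfg.technical_sd_meth > 0 else np.ones(n_samples)
    fac_u = np.exp(rng.normal(0.0, cfg.technical_sd_unmeth, size=n_samples)) \
        if cfg.technical_sd_unmeth > 0 else np.ones(n_samples)

    type1 = (design == "I")[:, None]
    shift = cfg.type1_intensity_shift * type1

    meth = beta * t_cell * fac_m[None, :] + shift
    unmeth = (1.0 - beta) * t_cell * fac_u[None, :] + shift
    if cfg.background_noise_sd > 0:
        meth = meth + rng.normal(0.0, cfg.background_noise_sd, size=meth.shape)
        unmeth = unmeth + rng.normal(0.0, cfg.background_noise_sd, size=unmeth.shape)
    meth = np.maximum(meth, 0.0)
    unmeth = np.maximum(unmeth, 0.0)

    idx = pd.Index(probe_ids, name="probe_id")
    cols = pd.Index(sample_ids, name="sample_id")
    intensities = IntensityMatrix(
        pd.DataFrame(meth, index=idx, columns=cols),
        pd.DataFrame(unmeth, index=idx, columns=cols),
    )
    true_beta = BetaMatrix(pd.DataFrame(np.clip(beta, 0.0, np.nextafter(1.0, 0.0)),
                                        index=idx, columns=cols))
    tech = pd.DataFrame({"meth": fac_m, "unmeth": fac_u}, index=cols)
    return SimulatedDataset(intensities=intensities, annotation=annotation, sheet=sheet,
                            true_beta=true_beta, technical_factors=tech, config=cfg)


def make_single_sex_subsets(d: SimulatedDataset) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Split a dataset into its (female, male) single-sex column subsets."""
    sex = d.sheet.sex()
    out = []
    for label in ("female", "male"):
        ids = sex.index[sex == label]
        if len(ids) == 0:
            warnings.warn(f"no {label} samples; subset is empty")
        cfg = replace(d.config,
                      n_female=len(ids) if label == "female" else 0,
                      n_male=len(ids) if label == "male" else 0)
        out.append(SimulatedDataset(
            intensities=d.intensities.subset_samples(ids),
            annotation=d.annotation,
            sheet=d.sheet.subset(ids),
            true_beta=BetaMatrix(d.true_beta.values_frame[ids], d.true_beta.offset_used),
            technical_factors=d.technical_factors.loc[ids],
            config=cfg,
        ))
    return out[0], out[1]


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
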