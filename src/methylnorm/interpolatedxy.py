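"""Rank-interpolation correction of sex-chromosome probes (interpolatedXY).

Quantile-based between-array normalization assumes every sample shares one
underlying intensity distribution.  X-chromosome probes break that assumption
in mixed-sex cohorts: X inactivation leaves female X CpGs at intermediate
methylation while male X CpGs stay bimodal, so pooling them with autosomes
shifts autosomal quantiles in opposite directions in the two sexes.  The fix
implemented here normalizes autosomes alone and then assigns every
sex-chromosome probe the corrected value interpolated at its fractional rank
within the autosomal raw-intensity distribution:

1. rank the autosomal raw values (average ranks for ties);
2. give each sex-probe raw value a fractional rank by piecewise-linear
   interpolation between the bracketing autosomal values (clamped at the
   extremes);
3. read the sorted corrected autosomal values at that fractional rank.

This runs independently per sample, per channel (M, U) and per Infinium
design type, and never consults the sex of any sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_tables import AUTOSOMES, DESIGN_TYPES, IntensityMatrix, ProbeAnnotation, SampleSheet
from .normalize_core import (
    DEFAULT_BETA_OFFSET,
    NormalizationError,
    NormalizationResult,
    compute_beta,
    dasen,
    quantile_normalize,
)

DEFAULT_STRATUM_FLOOR = 1000

NormalizerId = Literal["dasen", "quantile", "plugin"]


@dataclass(frozen=True)
class RankEstimate:
    """Fractional ranks of query values within a reference value->rank map."""

    fractional_rank: np.ndarray
    clamped_low: np.ndarray
    clamped_high: np.ndarray


@dataclass(frozen=True)
class QuantileFunction:
    """F(rank) -> corrected value: linear interpolation of the sorted
    corrected autosomal values at a fractional rank in [1, k]."""

    sorted_corrected: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.sorted_corrected, dtype=float)
        if v.ndim != 1 or len(v) < 2:
            raise NormalizationError("quantile function needs >= 2 corrected values")
        if np.any(np.diff(v) < 0):
            raise NormalizationError("corrected values must be sorted ascending")
        object.__setattr__(self, "sorted_corrected", v)

    @property
    def k(self) -> int:
        return len(self.sorted_corrected)

    def __call__(self, rank) -> np.ndarray:
        r = np.asarray(rank, dtype=float)
        return np.interp(r, np.arange(1, self.k + 1, dtype=float), self.sorted_corrected)


def estimate_ranks(raw_autosomal, raw_sex) -> RankEstimate:
    """Fractional ranks of sex-probe raw values within the autosomal raw
    distribution.

    Ties among autosomal values take average ranks; queries outside the
    autosomal range clamp to rank 1 / rank k with the corresponding flag set.
    Missing queries yield missing ranks.
    """
    a = np.asarray(raw_autosomal, dtype=float)
    a = a[~np.isnan(a)]
    if len(a) < 2:
        raise NormalizationError("need >= 2 non-missing autosomal values to rank against")
    q = np.asarray(raw_sex, dtype=float)
    ranks = rankdata(a, method="average")
    uniq, inv = np.unique(a, return_inverse=True)
    rank_of_uniq = np.bincount(inv, weights=ranks) / np.bincount(inv)
    with np.errstate(invalid="ignore"):
        fr = np.interp(q, uniq, rank_of_uniq)
        clamped_low = q < uniq[0]
        clamped_high = q > uniq[-1]
    fr = np.where(np.isnan(q), np.nan, fr)
    # NaN comparisons are False, so missing queries are never flagged clamped.
    return RankEstimate(fractional_rank=fr, clamped_low=clamped_low, clamped_high=clamped_high)


def build_quantile_function(corrected_autosomal) -> QuantileFunction:
    """Sort the corrected autosomal values into a rank -> value map F."""
    v = np.asarray(corrected_autosomal, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise NormalizationError("need >= 2 non-missing corrected values")
    return QuantileFunction(np.sort(v))


def interpolate_sex_values(raw_autosomal, corrected_autosomal, raw_sex) -> np.ndarray:
    """Corrected sex-probe values: F(estimate_ranks(raw_sex)).

    ``raw_autosomal`` and ``corrected_autosomal`` must be pairwise aligned by
    probe; pairs with a missing value in either vector are dropped so the rank
    map and the quantile function cover the same k probes.
    """
    ra = np.asarray(raw_autosomal, dtype=float)
    ca = np.asarray(corrected_autosomal, dtype=float)
    if ra.shape != ca.shape:
        raise NormalizationError("raw and corrected autosomal vectors differ in length")
    keep = ~(np.isnan(ra) | np.isnan(ca))
    ra, ca = ra[keep], ca[keep]
    est = estimate_ranks(ra, raw_sex)
    qf = build_quantile_function(ca)
    return qf(est.fractional_rank)


def _run_step_one(x: IntensityMatrix, annotation: ProbeAnnotation,
                  normalizer_id: str, sample_sheet, offset: float,
                  plugin: Callable | None) -> tuple[IntensityMatrix, pd.Series]:
    ann = annotation.table.loc[x.probe_index]
    auto_ids = x.probe_index[ann["chromosome"].isin(AUTOSOMES)]
    if normalizer_id in ("dasen", "quantile"):
        res = dasen(x, annotation, probe_scope="autosomes_only",
                    sample_sheet=sample_sheet, offset=offset,
                    align_types=(normalizer_id == "dasen"))
        return res.corrected, ann.loc[auto_ids, "design_type"]
    if normalizer_id == "plugin":
        if plugin is None:
            raise NormalizationError("normalizer_id='plugin' requires a plugin callable")
        sub = x.subset_probes(auto_ids)
        dt = ann.loc[auto_ids, "design_type"]
        corr_m = plugin(sub.meth, dt)
        corr_u = plugin(sub.unmeth, dt)
        return IntensityMatrix(pd.DataFrame(np.asarray(corr_m, dtype=float),
                                            index=sub.probe_index, columns=sub.sample_index),
                               pd.DataFrame(np.asarray(corr_u, dtype=float),
                                            index=sub.probe_index, columns=sub.sample_index)), dt
    raise NormalizationError(f"unknown normalizer_id {normalizer_id!r}")


def adjusted_normalize(x: IntensityMatrix, annotation: ProbeAnnotation,
                       normalizer_id: NormalizerId = "dasen",
                       sample_sheet: SampleSheet | None = None,
                       offset: float = DEFAULT_BETA_OFFSET,
                       stratum_floor: int = DEFAULT_STRATUM_FLOOR,
                       plugin: Callable | None = None) -> NormalizationResult:
    """Two-step sex-unbiased normalization (interpolatedXY adjusted normalizer).

    Step one runs the named normalizer on autosomal probes only; step two
    rank-interpolates every sex-chromosome probe against the autosomal
    raw -> corrected mapping, independently within each (channel, design type)
    stratum and each sample.  Betas are recomputed from the corrected
    intensities.  The sample sheet (if any) is used only for chip-row passing;
    sample sexes are never consulted.
    """
    ann = annotation.table.loc[x.probe_index]
    is_auto = ann["chromosome"].isin(AUTOSOMES)
    sex_ids = x.probe_index[~is_auto]
    auto_ids = x.probe_index[is_auto]
    # Stratum floor check before any heavy work.
    for dt in DESIGN_TYPES:
        n_sex = int(((~is_auto) & (ann["design_type"] == dt)).sum())
        n_auto = int((is_auto & (ann["design_type"] == dt)).sum())
        if n_sex > 0 and n_auto < stratum_floor:
            raise NormalizationError(
                f"design type {dt}: {n_auto} autosomal probes < stratum floor "
                f"{stratum_floor}; lower stratum_floor or use normalizer_id='quantile'"
            )
    corrected_auto, auto_dt = _run_step_one(x, annotation, normalizer_id,
                                            sample_sheet, offset, plugin)
    n_samples = len(x.sample_index)
    out_channels = {}
    for name in ("meth", "unmeth"):
        raw = getattr(x, name)
        corr_auto_frame = getattr(corrected_auto, name)
        full = pd.DataFrame(np.nan, index=x.probe_index, columns=x.sample_index)
        full.loc[corr_auto_frame.index] = corr_auto_frame
        for dt in DESIGN_TYPES:
            stratum_auto = auto_dt.index[auto_dt == dt]
            stratum_sex = sex_ids[ann.loc[sex_ids, "design_type"] == dt]
            if len(stratum_sex) == 0:
                continue
            raw_auto = raw.loc[stratum_auto].to_numpy()
            corr_auto = corr_auto_frame.loc[stratum_auto].to_numpy()
            raw_sex = raw.loc[stratum_sex].to_numpy()
            sex_out = np.empty_like(raw_sex)
            for j in range(n_samples):
                sex_out[:, j] = interpolate_sex_values(raw_auto[:, j], corr_auto[:, j],
                                                       raw_sex[:, j])
            full.loc[stratum_sex] = sex_out
        out_channels[name] = full
    corrected = IntensityMatrix(out_channels["meth"], out_channels["unmeth"])
    beta = compute_beta(corrected, offset=offset)
    return NormalizationResult(
        corrected=corrected,
        beta=beta,
        method_id=f"adjusted-{normalizer_id}",
        interpolated_probes=frozenset(sex_ids),
        parameters={"normalizer_id": normalizer_id, "offset": offset,
                    "stratum_floor": stratum_floor},
    )


def interpolate_sex_betas(beta_frame: pd.DataFrame, annotation: ProbeAnnotation,
                          corrected_auto_beta: pd.DataFrame) -> pd.DataFrame:
    """Beta-space fallback for matrices lacking channel intensities.

    Interpolates sex-probe betas against the autosomal raw-beta ->
    corrected-beta mapping directly.  Non-canonical: the reference procedure
    operates on intensities, with betas derived afterwards; use only when M/U
    channels are unavailable.
    """
    ann = annotation.table.loc[beta_frame.index]
    is_auto = ann["chromosome"].isin(AUTOSOMES)
    auto_ids = beta_frame.index[is_auto]
    sex_ids = beta_frame.index[~is_auto]
    out = pd.DataFrame(np.nan, index=beta_frame.index, columns=beta_frame.columns)
    out.loc[auto_ids] = corrected_auto_beta.loc[auto_ids]
    raw_auto = beta_frame.loc[auto_ids].to_numpy()
    corr_auto = corrected_auto_beta.loc[auto_ids].to_numpy()
    raw_sex = beta_frame.loc[sex_ids].to_numpy()
    sex_out = np.empty_like(raw_sex)
    for j in range(beta_frame.shape[1]):
        sex_out[:, j] = interpolate_sex_values(raw_auto[:, j], corr_auto[:, j], raw_sex[:, j])
    out.loc[sex_ids] = sex_out
    return out
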