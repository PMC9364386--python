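"""Quantitative yardsticks: RMSE, total variance and the sex-explained
fraction of variance.

Total variance of a beta matrix is the per-probe population variance
(divisor n, not n-1) averaged over probes,

    V_total = (1/n)(1/m) sum_i sum_j (beta_ij - mean_j)^2 .

The sex-explained fraction compares the sample-size-weighted within-sex
variances against the pooled total:

    F_sex = 1 - (n_f * V_f + n_m * V_m) / ((n_f + n_m) * V_total) ,

where V_f and V_m use within-sex per-probe means.  With divisor-n variances
this is exactly the between-group fraction of a one-way ANOVA decomposition,
so F_sex always lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import ProbeAnnotation, SampleSheet
from .normalize_core import BetaMatrix


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class VarianceReport:
    group: str
    v_total: float
    v_total_females: float
    v_total_males: float
    f_sex: float
    n_females: int
    n_males: int
    n_probes: int
    per_cpg_variance_females: np.ndarray = field(repr=False, default=None)
    per_cpg_variance_males: np.ndarray = field(repr=False, default=None)


def rmse(beta, beta_ref) -> float:
    """Root mean squared elementwise difference; missing pairs are dropped."""
    a = np.asarray(beta, dtype=float).ravel()
    b = np.asarray(beta_ref, dtype=float).ravel()
    if a.shape != b.shape:
        raise MetricsError("vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    if not keep.any():
        raise MetricsError("no overlapping non-missing pairs")
    d = a[keep] - b[keep]
    return float(np.sqrt(np.mean(d * d)))


def _per_probe_variance(mat: np.ndarray) -> np.ndarray:
    """Population (divisor-n) variance per row, NaN-aware; rows with < 2
    non-missing samples come back NaN."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = np.nanvar(mat, axis=1, ddof=0)
    counts = np.sum(~np.isnan(mat), axis=1)
    v[counts < 2] = np.nan
    return v


def total_variance(beta) -> float:
    """Per-probe population variance averaged over probes (rows = probes)."""
    mat = _as_probe_matrix(beta)
    if mat.shape[1] < 2:
        raise MetricsError("total variance needs >= 2 samples")
    v = _per_probe_variance(mat)
    if np.isnan(v).all():
        raise MetricsError("no probe has >= 2 non-missing samples")
    return float(np.nanmean(v))


def _as_probe_matrix(beta) -> np.ndarray:
    if isinstance(beta, BetaMatrix):
        return beta.values_frame.to_numpy(dtype=float)
    if isinstance(beta, pd.DataFrame):
        return beta.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(beta, dtype=float))


def sex_explained_fraction(beta, sex, group: str = "all") -> VarianceReport:
    """F_sex for one probes x samples matrix and per-sample sex labels.

    Probes lacking >= 2 non-missing samples in either sex group are dropped
    from all three variance terms so the decomposition stays consistent.
    """
    mat = _as_probe_matrix(beta)
    sex = np.asarray(sex)
    if sex.shape[0] != mat.shape[1]:
        raise MetricsError("one sex label per sample required")
    f_mask = sex == "female"
    m_mask = sex == "male"
    n_f, n_m = int(f_mask.sum()), int(m_mask.sum())
    if n_f < 2 or n_m < 2:
        raise MetricsError(
            "both sexes need >= 2 samples; for a single-sex matrix use total_variance"
        )
    v_f = _per_probe_variance(mat[:, f_mask])
    v_m = _per_probe_variance(mat[:, m_mask])
    v_all = _per_probe_variance(mat)
    keep = ~(np.isnan(v_f) | np.isnan(v_m) | np.isnan(v_all))
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} probes with < 2 non-missing samples in a group")
    if not keep.any():
        raise MetricsError("no probe usable in both sex groups")
    v_total = float(np.mean(v_all[keep]))
    v_total_f = float(np.mean(v_f[keep]))
    v_total_m = float(np.mean(v_m[keep]))
    if v_total == 0:
        raise MetricsError("V_total is zero; sex-explained fraction undefined")
    f_sex = 1.0 - (n_f * v_total_f + n_m * v_total_m) / ((n_f + n_m) * v_total)
    return VarianceReport(
        group=group,
        v_total=v_total,
        v_total_females=v_total_f,
        v_total_males=v_total_m,
        f_sex=float(f_sex),
        n_females=n_f,
        n_males=n_m,
        n_probes=int(keep.sum()),
        per_cpg_variance_females=v_f[keep],
        per_cpg_variance_males=v_m[keep],
    )


def variance_report(beta: BetaMatrix | pd.DataFrame, annotation: ProbeAnnotation,
                    sheet: SampleSheet) -> dict[str, VarianceReport]:
    """F_sex and variance components per chromosome group
    (autosomes / X / Y); empty groups are omitted with a warning."""
    frame = beta.values_frame if isinstance(beta, BetaMatrix) else beta
    groups = annotation.chromosome_group().loc[frame.index]
    sex = sheet.sex().loc[frame.columns].to_numpy()
    out: dict[str, VarianceReport] = {}
    for g in ("autosomes", "X", "Y"):
        ids = frame.index[groups == g]
        if len(ids) == 0:
            warnings.warn(f"chromosome group {g!r} empty; omitted from report")
            continue
        out[g] = sex_explained_fraction(frame.loc[ids], sex, group=g)
    return out


def report_to_frame(reports: dict[str, VarianceReport]) -> pd.DataFrame:
    """Flatten group reports to a tidy frame (rows = chromosome groups)."""
    rows = []
    for g, r in reports.items():
        rows.append({
            "group": g, "n_probes": r.n_probes,
            "n_females": r.n_females, "n_males": r.n_males,
            "v_total": r.v_total,
            "v_total_females": r.v_total_females, "v_total_males": r.v_total_males,
            "f_sex": r.f_sex, "f_sex_percent": 100.0 * r.f_sex,
        })
    return pd.DataFrame(rows).set_index("group")
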