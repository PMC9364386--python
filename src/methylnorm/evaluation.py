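"""Evaluation protocols: the single-sex gold standard for interpolation
accuracy, a per-CpG sex EWAS with Bonferroni correction, and saDMP overlap
summaries.

Gold standard: in a single-sex cohort, sex-chromosome probes can legitimately
join the quantile pool (every sample shares the same karyotype), so running
the base normalizer with sex chromosomes treated as ordinary autosomes gives
reference corrected values.  The rank-interpolated values from the adjusted
normalizer are scored against that reference by per-sample RMSE, separately
for X- and Y-linked probes in each sex.

The sex EWAS is a per-probe two-group linear model (beta ~ sex) with an
F-test on 1 and n-2 degrees of freedom — the same statistic a per-probe OLS
fit with a binary covariate yields — with Bonferroni-adjusted significance
at alpha and directions taken from the sign of mean(female) - mean(male).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import IntensityMatrix, ProbeAnnotation, SampleSheet
from .interpolatedxy import adjusted_normalize
from .metrics import MetricsError, rmse
from .normalize_core import BetaMatrix, dasen


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EvaluationReport:
    """Per-sample interpolation RMSEs grouped in four categories
    (female X / male X / female Y / male Y) with per-category summaries."""

    per_sample: pd.DataFrame  # columns: sample_id, sex, category, rmse
    summary: pd.DataFrame     # index: category; columns: mean, sd, n
    method_id: str


@dataclass(frozen=True)
class EwasResult:
    """Per-probe sex-association test results.

    ``table`` is indexed by probe with columns f_statistic, p_value, tested,
    significant (Bonferroni), direction; ``n_tested`` excludes zero-variance
    probes.
    """

    table: pd.DataFrame
    alpha: float
    n_tested: int

    @property
    def significant_probes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    @property
    def direction_counts(self) -> dict[str, int]:
        sig = self.table[self.table["significant"]]
        return {
            "higher_in_females": int((sig["direction"] == "higher_in_females").sum()),
            "higher_in_males": int((sig["direction"] == "higher_in_males").sum()),
        }


def _category_rmses(candidate: BetaMatrix, reference: BetaMatrix,
                    annotation: ProbeAnnotation, sex_label: str) -> list[dict]:
    groups = annotation.chromosome_group().loc[candidate.probe_index]
    rows = []
    for chrom in ("X", "Y"):
        ids = candidate.probe_index[groups == chrom]
        if len(ids) == 0:
            continue
        cand = candidate.values_frame.loc[ids]
        ref = reference.values_frame.loc[ids]
        for s in cand.columns:
            rows.append({
                "sample_id": s,
                "sex": sex_label,
                "category": f"{sex_label} {chrom}",
                "rmse": rmse(cand[s], ref[s]),
            })
    return rows


def single_sex_gold_standard(x: IntensityMatrix, annotation: ProbeAnnotation,
                             sheet: SampleSheet, normalizer_id: str = "dasen",
                             **normalize_kwargs) -> EvaluationReport:
    """Score interpolated sex-probe betas against single-sex references.

    The input is split by sex; each single-sex group (>= 2 samples) is
    normalized twice: once with sex chromosomes pooled as ordinary autosomes
    (the reference) and once by the adjusted two-step normalizer (the
    candidate).  Per-sample RMSEs over X- and Y-linked betas populate the
    four sex x chromosome categories.
    """
    sex = sheet.sex().loc[x.sample_index]
    rows: list[dict] = []
    for label in ("female", "male"):
        ids = sex.index[sex == label]
        if len(ids) == 0:
            continue
        if len(ids) < 2:
            raise EvaluationError(f"{label} group has {len(ids)} sample(s); need >= 2")
        rows.extend(_single_group_rmses(x.subset_samples(ids), annotation, label,
                                        normalizer_id, normalize_kwargs))
    if not rows:
        raise EvaluationError("no usable single-sex group in input")
    per_sample = pd.DataFrame(rows)
    summary = (per_sample.groupby("category")["rmse"]
               .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    n="size"))
    return EvaluationReport(per_sample=per_sample, summary=summary,
                            method_id=f"adjusted-{normalizer_id}")


def _single_group_rmses(group: IntensityMatrix, annotation: ProbeAnnotation,
                        sex_label: str, normalizer_id: str, normalize_kwargs) -> list[dict]:
    if sex_label not in ("female", "male"):
        raise EvaluationError("gold-standard groups must be single-sex (female or male)")
    align = normalizer_id == "dasen"
    reference = dasen(group, annotation, probe_scope="all", align_types=align)
    candidate = adjusted_normalize(group, annotation, normalizer_id=normalizer_id,
                                   **normalize_kwargs)
    return _category_rmses(candidate.beta, reference.beta, annotation, sex_label)


def sex_ewas(beta: BetaMatrix | pd.DataFrame, sheet: SampleSheet, alpha: float = 0.05,
             scope: str = "autosomes", annotation: ProbeAnnotation | None = None) -> EwasResult:
    """Per-probe sex EWAS: two-group F-test with Bonferroni correction.

    ``scope="autosomes"`` (requires ``annotation``) restricts testing to
    autosomal probes; ``scope="all"`` tests everything.  Zero-variance probes
    are skipped (tested=False) and never significant.  No covariates are
    modelled.
    """
    frame = beta.values_frame if isinstance(beta, BetaMatrix) else beta
    if scope == "autosomes":
        if annotation is None:
            raise EvaluationError("scope='autosomes' requires a probe annotation")
        keep = annotation.table.loc[frame.index, "chromosome"].isin(
            [str(i) for i in range(1, 23)])
        frame = frame.loc[keep]
    elif scope != "all":
        raise EvaluationError(f"unknown scope {scope!r}")
    sex = sheet.sex().loc[frame.columns].to_numpy()
    f_mask = sex == "female"
    m_mask = sex == "male"
    if f_mask.sum() < 2 or m_mask.sum() < 2:
        raise EvaluationError("sex EWAS needs >= 2 samples of each sex")

    mat = frame.to_numpy(dtype=float)
    nf = np.sum(~np.isnan(mat[:, f_mask]), axis=1).astype(float)
    nm = np.sum(~np.isnan(mat[:, m_mask]), axis=1).astype(float)
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_f = np.nanmean(mat[:, f_mask], axis=1)
        mean_m = np.nanmean(mat[:, m_mask], axis=1)
    n = nf + nm
    grand = (nf * mean_f + nm * mean_m) / n
    ss_between = nf * (mean_f - grand) ** 2 + nm * (mean_m - grand) ** 2
    centered = mat.copy()
    centered[:, f_mask] = centered[:, f_mask] - mean_f[:, None]
    centered[:, m_mask] = centered[:, m_mask] - mean_m[:, None]
    ss_within = np.nansum(centered ** 2, axis=1)
    df2 = n - 2
    total_var = ss_between + ss_within
    tested = (nf >= 2) & (nm >= 2) & (total_var > 0) & (df2 > 0)
    f_stat = np.full(mat.shape[0], np.nan)
    p_val = np.full(mat.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_raw = (ss_between / 1.0) / (ss_within / df2)
    zero_resid = tested & (ss_within == 0)
    f_stat[tested] = f_raw[tested]
    f_stat[zero_resid] = np.inf
    p_val[tested] = stats.f.sf(f_stat[tested], 1, df2[tested])
    p_val[zero_resid] = 0.0

    n_tested = int(tested.sum())
    threshold = alpha / max(n_tested, 1)
    significant = tested & (p_val < threshold)
    direction = np.where(mean_f > mean_m, "higher_in_females", "higher_in_males")
    table = pd.DataFrame({
        "f_statistic": f_stat,
        "p_value": p_val,
        "mean_female": mean_f,
        "mean_male": mean_m,
        "tested": tested,
        "significant": significant,
        "direction": direction,
    }, index=frame.index)
    return EwasResult(table=table, alpha=alpha, n_tested=n_tested)


@dataclass(frozen=True)
class OverlapSummary:
    """Shared / method-specific saDMP counts with direction breakdowns."""

    shared: int
    a_only: int
    b_only: int
    by_direction: pd.DataFrame  # index subset, columns higher_in_females/males


def compare_saDMPs(a: EwasResult, b: EwasResult) -> OverlapSummary:
    """Overlap of significant probes between two EWAS runs on one universe."""
    if not a.table.index.sort_values().equals(b.table.index.sort_values()):
        raise EvaluationError("EWAS results cover different probe universes")
    sig_a = set(a.significant_probes)
    sig_b = set(b.significant_probes)
    shared = sig_a & sig_b
    a_only = sig_a - sig_b
    b_only = sig_b - sig_a

    def count_directions(probes: set, source: EwasResult) -> dict[str, int]:
        if not probes:
            return {"higher_in_females": 0, "higher_in_males": 0}
        d = source.table.loc[list(probes), "direction"]
        return {
            "higher_in_females": int((d == "higher_in_females").sum()),
            "higher_in_males": int((d == "higher_in_males").sum()),
        }

    by_dir = pd.DataFrame({
        "shared": count_directions(shared, a),
        "a_only": count_directions(a_only, a),
        "b_only": count_directions(b_only, b),
    }).T
    return OverlapSummary(shared=len(shared), a_only=len(a_only), b_only=len(b_only),
                          by_direction=by_dir)
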