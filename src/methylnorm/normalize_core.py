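"""Beta computation and dasen-style between-array normalization.

The dasen composite normalizer works on methylated and unmethylated
intensities separately: first an additive per-sample alignment of the Type I
intensity distribution onto the Type II one (the two Infinium chemistries
have systematically different intensity scales), then quantile normalization
across samples within each design type.  Betas are recomputed from the
corrected intensities as M / (M + U + offset).

``probe_scope="autosomes_only"`` restricts the whole pipeline to autosomal
probes; it is step one of the interpolatedXY adjusted normalizer.
``probe_scope="all"`` is the classical mixed behaviour in which sex-chromosome
probes take part in the quantile pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .io_tables import (
    AUTOSOMES,
    DESIGN_TYPES,
    IntensityMatrix,
    ProbeAnnotation,
    SampleSheet,
)

DEFAULT_BETA_OFFSET = 100.0
MIN_TYPE_PROBES = 50

ProbeScope = Literal["all", "autosomes_only"]


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class BetaMatrix:
    """Methylation fractions in [0, 1) on a probes x samples grid."""

    values_frame: pd.DataFrame
    offset_used: float = DEFAULT_BETA_OFFSET

    def __post_init__(self) -> None:
        vals = self.values_frame.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() >= 1):
            raise NormalizationError("beta values must lie in [0, 1)")

    @property
    def probe_index(self) -> pd.Index:
        return self.values_frame.index

    @property
    def sample_index(self) -> pd.Index:
        return self.values_frame.columns

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values_frame.loc[pd.Index(probe_ids)], self.offset_used)


@dataclass(frozen=True)
class NormalizationResult:
    """Corrected intensities, recomputed betas and run provenance."""

    corrected: IntensityMatrix
    beta: BetaMatrix
    method_id: str
    interpolated_probes: frozenset[str] = frozenset()
    parameters: Mapping[str, object] = field(default_factory=dict)


def compute_beta(x: IntensityMatrix, offset: float = DEFAULT_BETA_OFFSET) -> BetaMatrix:
    """Elementwise beta = M / (M + U + offset); missing in either channel -> missing.

    With ``offset=0`` a cell where M = U = 0 has no defined methylation
    fraction and becomes missing.
    """
    if offset < 0:
        raise NormalizationError("beta offset must be non-negative")
    m = x.meth.to_numpy(dtype=float)
    u = x.unmeth.to_numpy(dtype=float)
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / denom, np.nan)
    beta[np.isnan(m) | np.isnan(u)] = np.nan
    return BetaMatrix(
        pd.DataFrame(beta, index=x.probe_index, columns=x.sample_index), offset_used=offset
    )


def quantile_normalize(m, reference: np.ndarray | None = None):
    """Between-array quantile normalization of a probes x samples matrix.

    Without an explicit reference, the reference distribution is the per-rank
    mean of the column-sorted values, computed over rows that are complete
    across all samples.  Each column's non-missing values are then replaced by
    the reference read at their within-column (average) ranks; tied values all
    receive the mean of the reference values over the tied span.  Columns with
    fewer non-missing values than the reference length are mapped through
    fractional ranks scaled to the reference length.

    Accepts and returns either a DataFrame or ndarray.
    """
    is_frame = isinstance(m, pd.DataFrame)
    A = m.to_numpy(dtype=float) if is_frame else np.asarray(m, dtype=float)
    if A.ndim != 2:
        raise NormalizationError("expected a 2-d probes x samples matrix")
    n_probes, n_samples = A.shape
    all_missing = np.isnan(A).all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        name = m.columns[j] if is_frame else j
        raise NormalizationError(f"sample {name!r} has no non-missing values")
    if reference is None:
        if n_samples < 2:
            raise NormalizationError("quantile normalization needs >= 2 samples")
        complete = ~np.isnan(A).any(axis=1)
        if not complete.any():
            raise NormalizationError("no rows complete across all samples; cannot build reference")
        ref = np.sort(A[complete], axis=0).mean(axis=1)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.ndim != 1 or len(ref) < 1 or np.any(np.diff(ref) < 0):
            raise NormalizationError("reference must be a sorted 1-d vector")
    k = len(ref)
    out = np.full_like(A, np.nan)
    ref_positions = np.arange(1, k + 1, dtype=float)
    for j in range(n_samples):
        col = A[:, j]
        mask = ~np.isnan(col)
        v = int(mask.sum())
        if v == 0:
            name = m.columns[j] if is_frame else j
            raise NormalizationError(f"sample {name!r} has no non-missing values")
        vals = col[mask]
        order = np.argsort(vals, kind="mergesort")
        # Reference value attached to each sorted slot (scaled when v != k).
        if v == k:
            slot_vals = ref.copy()
        elif v == 1:
            slot_vals = np.interp(np.array([(k + 1) / 2.0]), ref_positions, ref)
        else:
            slot_pos = (np.arange(v) / (v - 1)) * (k - 1) + 1
            slot_vals = np.interp(slot_pos, ref_positions, ref)
        mapped = np.empty(v)
        mapped[order] = slot_vals
        # Ties share the mean of the reference values over the tied span.
        sorted_vals = vals[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [v]))
        if len(starts) < v:  # at least one tie group
            group_means = np.add.reduceat(slot_vals, starts) / (ends - starts)
            group_of_slot = np.repeat(np.arange(len(starts)), ends - starts)
            tied_vals = np.empty(v)
            tied_vals[order] = group_means[group_of_slot]
            mapped = tied_vals
        out[mask, j] = mapped
    if is_frame:
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out


def _first_density_mode(values: np.ndarray, grid_points: int = 512,
                        rel_height: float = 0.01, hist_bins: int = 4096) -> float:
    """Lowest-intensity mode of a Gaussian KDE (Silverman bandwidth).

    The mode is the first local maximum of the density above ``rel_height`` of
    the global maximum; falls back to the global argmax for monotone densities.
    The kernel sum is evaluated from a ``hist_bins``-bin discretization of the
    data (bin width is far below the bandwidth, so the discretization error is
    negligible next to the kernel smoothing).
    """
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise NormalizationError("cannot estimate density of an empty vector")
    if np.ptp(values) == 0:
        return float(values[0])
    n = values.size
    sigma = float(np.std(values, ddof=1))
    if sigma == 0:
        return float(values[0])
    bandwidth = sigma * (3.0 * n / 4.0) ** (-0.2)  # Silverman factor, 1-d
    counts, edges = np.histogram(values, bins=hist_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nz = counts > 0
    centers, weights = centers[nz], counts[nz].astype(float)
    grid = np.linspace(values.min(), values.max(), grid_points)
    z = (grid[:, None] - centers[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z) @ weights
    # Prominence guard: a "mode" must stand clearly above its surroundings,
    # not be a sampling ripple on the density's shoulder.
    peaks, _ = find_peaks(dens, height=rel_height * dens.max(),
                          prominence=0.05 * dens.max())
    i = int(peaks[0]) if len(peaks) else int(np.argmax(dens))
    # Parabolic apex refinement removes the grid-origin sensitivity of the
    # discrete argmax (grid spacing is comparable to mode shifts of interest).
    if 0 < i < len(grid) - 1:
        denom = dens[i - 1] - 2.0 * dens[i] + dens[i + 1]
        if denom < 0:
            step = 0.5 * (dens[i - 1] - dens[i + 1]) / denom
            return float(grid[i] + step * (grid[1] - grid[0]))
    return float(grid[i])


def align_type_distributions(m, design_type, chip_row=None,
                             min_probes: int = MIN_TYPE_PROBES,
                             force: bool = False,
                             return_offsets: bool = False):
    """Additively align Type I intensities onto Type II, per sample.

    For every sample, the offset moving the lowest-intensity density mode of
    the Type I values onto that of the Type II values is applied to the Type I
    probes (output floored at 0).  When ``chip_row`` supplies a position for
    every sample, the per-sample offsets are first smoothed by their
    least-squares linear fit against chip row, mirroring the regression step
    of the dasen background-alignment procedure.
    """
    is_frame = isinstance(m, pd.DataFrame)
    A = m.to_numpy(dtype=float) if is_frame else np.asarray(m, dtype=float)
    dt = np.asarray(design_type)
    if dt.shape[0] != A.shape[0]:
        raise NormalizationError("design_type length must match probe count")
    mask_i = dt == "I"
    mask_ii = dt == "II"
    if not force and (mask_i.sum() < min_probes or mask_ii.sum() < min_probes):
        raise NormalizationError(
            f"need >= {min_probes} probes of each design type for a stable density "
            "estimate (pass force=True to override)"
        )
    n_samples = A.shape[1]
    offsets = np.empty(n_samples)
    for j in range(n_samples):
        mode_i = _first_density_mode(A[mask_i, j])
        mode_ii = _first_density_mode(A[mask_ii, j])
        offsets[j] = mode_ii - mode_i
    if chip_row is not None:
        rows = np.asarray(chip_row, dtype=float)
        if rows.shape[0] != n_samples or np.isnan(rows).any():
            raise NormalizationError("chip_row must provide one finite value per sample")
        X = np.column_stack([np.ones(n_samples), rows])
        coef, *_ = np.linalg.lstsq(X, offsets, rcond=None)
        offsets = X @ coef
    out = A.copy()
    out[mask_i, :] = np.maximum(out[mask_i, :] + offsets[np.newaxis, :], 0.0)
    result = pd.DataFrame(out, index=m.index, columns=m.columns) if is_frame else out
    if return_offsets:
        return result, offsets
    return result


def _scope_probes(x: IntensityMatrix, annotation: ProbeAnnotation, probe_scope: ProbeScope):
    ann = annotation.table.loc[x.probe_index]
    if probe_scope == "all":
        keep = pd.Series(True, index=x.probe_index)
    elif probe_scope == "autosomes_only":
        keep = ann["chromosome"].isin(AUTOSOMES)
    else:
        raise NormalizationError(f"unknown probe_scope {probe_scope!r}")
    return x.probe_index[keep], ann.loc[keep, "design_type"]


def _normalize_channels(x: IntensityMatrix, design_type: pd.Series,
                        align_types: bool, chip_row, min_type_probes: int) -> IntensityMatrix:
    dt = design_type.to_numpy()
    corrected = {}
    for name, frame in (("meth", x.meth), ("unmeth", x.unmeth)):
        mat = frame
        if align_types:
            mat = align_type_distributions(mat, dt, chip_row=chip_row,
                                           min_probes=min_type_probes)
        out = mat.copy()
        for t in DESIGN_TYPES:
            sel = dt == t
            if sel.sum() == 0:
                continue
            out.loc[sel] = quantile_normalize(mat.loc[sel])
        corrected[name] = out
    return IntensityMatrix(corrected["meth"], corrected["unmeth"])


def dasen(x: IntensityMatrix, annotation: ProbeAnnotation,
          probe_scope: ProbeScope = "all",
          sample_sheet: SampleSheet | None = None,
          offset: float = DEFAULT_BETA_OFFSET,
          align_types: bool = True,
          min_type_probes: int = MIN_TYPE_PROBES) -> NormalizationResult:
    """dasen composite normalizer: Type I/II alignment then per-type quantile
    normalization of M and U independently.

    ``align_types=False`` gives the plain per-type quantile normalizer
    (method id ``quantile``), used as an alternative step-one normalizer.
    """
    probe_ids, design_type = _scope_probes(x, annotation, probe_scope)
    if len(probe_ids) == 0:
        raise NormalizationError(f"probe_scope={probe_scope!r} selects no probes")
    sub = x.subset_probes(probe_ids)
    chip_row = None
    if sample_sheet is not None:
        rows = sample_sheet.chip_row()
        if rows is not None:
            chip_row = rows.loc[sub.sample_index].to_numpy()
    corrected = _normalize_channels(sub, design_type, align_types, chip_row, min_type_probes)
    beta = compute_beta(corrected, offset=offset)
    base = "dasen" if align_types else "quantile"
    return NormalizationResult(
        corrected=corrected,
        beta=beta,
        method_id=f"{base}[{probe_scope}]",
        parameters={"probe_scope": probe_scope, "offset": offset,
                    "align_types": align_types},
    )


def quantile_only(x: IntensityMatrix, annotation: ProbeAnnotation,
                  probe_scope: ProbeScope = "all",
                  sample_sheet: SampleSheet | None = None,
                  offset: float = DEFAULT_BETA_OFFSET) -> NormalizationResult:
    """Per-design-type quantile normalization without the Type I/II alignment."""
    return dasen(x, annotation, probe_scope=probe_scope, sample_sheet=sample_sheet,
                 offset=offset, align_types=False)
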