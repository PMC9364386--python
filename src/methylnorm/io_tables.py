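"""Delimited-table I/O and the core domain containers.

All on-disk formats are tab-separated text with ``NA`` as the missing-value
token: one table per intensity channel (probes x samples, probe_id first
column), a probe annotation table (probe_id, chromosome, design_type) and a
sample sheet (sample_id, sex, chip_row).  Chromosome labels are canonicalized
to bare ``1``..``22``, ``X``, ``Y`` (a leading ``chr`` is accepted and
stripped on input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NA_TOKEN = "NA"
DELIMITER = "\t"

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
VALID_CHROMOSOMES = AUTOSOMES | {"X", "Y"}
DESIGN_TYPES = ("I", "II")
SEXES = ("female", "male")


class TableFormatError(ValueError):
    """A delimited table violates the expected layout or value domain."""


class AlignmentError(ValueError):
    """Two tables that must share indices do not."""


def canonicalize_chromosome(label: str) -> str:
    """Map a chromosome label to canonical form: 'chrX' -> 'X', '07' -> '7'."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        s = str(int(s))
    return s


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe chromosome and Infinium design type.

    ``table`` is indexed by unique probe_id with columns ``chromosome``
    (canonical ``1``..``22``/``X``/``Y``) and ``design_type`` (``I``/``II``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate probe_id in annotation: {dups[:10]}")
        missing_cols = {"chromosome", "design_type"} - set(t.columns)
        if missing_cols:
            raise TableFormatError(f"annotation missing columns: {sorted(missing_cols)}")
        bad_chrom = set(t["chromosome"]) - VALID_CHROMOSOMES
        if bad_chrom:
            raise TableFormatError(f"invalid chromosome labels: {sorted(bad_chrom)[:10]}")
        bad_dt = set(t["design_type"]) - set(DESIGN_TYPES)
        if bad_dt:
            raise TableFormatError(f"unknown design_type values: {sorted(bad_dt)}")
        if t[["chromosome", "design_type"]].isna().any().any():
            raise TableFormatError("annotation contains missing chromosome/design_type")
        # Interpolation needs autosomal anchors in every design type that
        # carries sex probes.
        for dt in DESIGN_TYPES:
            sub = t[t["design_type"] == dt]
            has_sex = sub["chromosome"].isin(["X", "Y"]).any()
            has_auto = sub["chromosome"].isin(AUTOSOMES).any()
            if has_sex and not has_auto:
                raise TableFormatError(
                    f"design type {dt} has sex-chromosome probes but no autosomal probes"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def chromosome_group(self) -> pd.Series:
        """Per-probe group label: 'autosomes', 'X' or 'Y'."""
        chrom = self.table["chromosome"]
        return pd.Series(
            np.where(chrom == "X", "X", np.where(chrom == "Y", "Y", "autosomes")),
            index=self.table.index,
            name="group",
        )

    def is_autosomal(self) -> pd.Series:
        return self.table["chromosome"].isin(AUTOSOMES)

    def design_type(self) -> pd.Series:
        return self.table["design_type"]

    def subset(self, probe_ids: Iterable[str]) -> "ProbeAnnotation":
        return ProbeAnnotation.__new_unchecked__(self.table.loc[list(probe_ids)])

    @classmethod
    def __new_unchecked__(cls, table: pd.DataFrame) -> "ProbeAnnotation":
        obj = object.__new__(cls)
        object.__setattr__(obj, "table", table)
        return obj


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: sex (``female``/``male``) and optional chip row.

    Sex is only required by the metrics/evaluation entry points; the adjusted
    normalization itself never consults it.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise TableFormatError("duplicate sample_id in sample sheet")
        if "sex" in t.columns:
            bad = set(t["sex"].dropna()) - set(SEXES)
            if bad:
                raise TableFormatError(f"invalid sex labels: {sorted(bad)}")
        if "chip_row" in t.columns:
            rows = t["chip_row"].dropna()
            if len(rows) and (rows < 1).any():
                raise TableFormatError("chip_row values must be >= 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def sex(self) -> pd.Series:
        if "sex" not in self.table.columns or self.table["sex"].isna().any():
            raise TableFormatError("sample sheet lacks complete sex annotation")
        return self.table["sex"]

    def chip_row(self) -> pd.Series | None:
        """Chip rows if present for every sample, else None."""
        if "chip_row" not in self.table.columns:
            return None
        rows = self.table["chip_row"]
        if rows.isna().any():
            return None
        return rows.astype(float)

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)])


@dataclass(frozen=True)
class IntensityMatrix:
    """Paired methylated (M) / unmethylated (U) intensities on one grid.

    Both frames are probes x samples with identical indices; values are
    finite non-negative reals, NaN marking missing cells.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise AlignmentError("meth and unmeth matrices have different indices")
        for name, df in (("meth", self.meth), ("unmeth", self.unmeth)):
            vals = df.to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise TableFormatError(f"{name} contains non-finite intensities")
            if np.nanmin(vals, initial=0.0) < 0:
                raise TableFormatError(f"{name} contains negative intensities")

    @property
    def probe_index(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_index(self) -> pd.Index:
        return self.meth.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.meth.shape

    def subset_probes(self, probe_ids: Sequence[str]) -> "IntensityMatrix":
        ids = pd.Index(probe_ids)
        return IntensityMatrix(self.meth.loc[ids], self.unmeth.loc[ids])

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        ids = pd.Index(sample_ids)
        return IntensityMatrix(self.meth[ids], self.unmeth[ids])


def _read_matrix_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=DELIMITER, index_col=0, na_values=[NA_TOKEN], comment="#")
    except FileNotFoundError:
        raise
    except (ValueError, pd.errors.ParserError) as exc:
        raise TableFormatError(f"{path}: cannot parse table: {exc}") from exc
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableFormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    return df.astype(float)


def read_intensity_pair(meth_path: str | Path, unmeth_path: str | Path) -> IntensityMatrix:
    """Read a methylated/unmethylated TSV pair into an aligned IntensityMatrix.

    The two tables must carry the same probe and sample sets in any order; the
    methylated table's ordering is taken as canonical and the unmethylated
    table is permuted to match.
    """
    meth = _read_matrix_table(meth_path)
    unmeth = _read_matrix_table(unmeth_path)
    for axis, kind in ((0, "probe"), (1, "sample")):
        a = meth.index if axis == 0 else meth.columns
        b = unmeth.index if axis == 0 else unmeth.columns
        only_m, only_u = set(a) - set(b), set(b) - set(a)
        if only_m or only_u:
            raise AlignmentError(
                f"{kind} sets differ between channels: "
                f"meth-only={sorted(only_m)[:10]}, unmeth-only={sorted(only_u)[:10]}"
            )
    unmeth = unmeth.loc[meth.index, meth.columns]
    return IntensityMatrix(meth, unmeth)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe annotation TSV; canonicalize chromosomes, drop off-target rows.

    Rows whose chromosome is outside 1..22/X/Y (e.g. contigs, mitochondria)
    are dropped; their count is recorded on the returned object as
    ``n_dropped`` via the function's second behaviour -- see return value.
    """
    df = pd.read_csv(path, sep=DELIMITER, dtype=str, na_values=[NA_TOKEN], comment="#")
    required = {"probe_id", "chromosome", "design_type"}
    if not required <= set(df.columns):
        raise TableFormatError(f"{path}: annotation needs columns {sorted(required)}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].unique().tolist()
        raise TableFormatError(f"{path}: duplicate probe_id: {dups[:10]}")
    df["chromosome"] = df["chromosome"].map(canonicalize_chromosome)
    keep = df["chromosome"].isin(VALID_CHROMOSOMES)
    n_dropped = int((~keep).sum())
    df = df[keep]
    ann = ProbeAnnotation(df.set_index("probe_id")[["chromosome", "design_type"]])
    object.__setattr__(ann, "n_dropped", n_dropped)
    return ann


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep=DELIMITER, na_values=[NA_TOKEN], comment="#")
    if "sample_id" not in df.columns:
        raise TableFormatError(f"{path}: sample sheet needs a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleSheet(df.set_index("sample_id"))


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "probe_id",
                 header_comment: str | None = None) -> None:
    """Write a probes x samples table as TSV with full float round-trip precision."""
    path = Path(path)
    out = df.copy()
    out.index.name = index_name
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep=DELIMITER, na_rep=NA_TOKEN, float_format="%.17g")


def read_beta(path: str | Path) -> pd.DataFrame:
    """Read a beta-value table written by :func:`write_beta`."""
    return _read_matrix_table(path)


def write_beta(beta, path: str | Path, header_comment: str | None = None) -> None:
    """Write a BetaMatrix (or bare DataFrame) of methylation fractions as TSV."""
    df = getattr(beta, "values_frame", None)
    if df is None:
        df = beta
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() >= 1):
        raise TableFormatError("beta values must lie in [0, 1)")
    write_matrix(df, path, header_comment=header_comment)
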