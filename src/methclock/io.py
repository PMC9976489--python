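"""Reading, writing, validation and preprocessing of methylation data.

The interchange formats are plain delimited text (tab by default, comma
accepted):

* methylation matrix — one header row of CpG ids, first column sample ids,
  samples as rows;
* phenotype sheet — one row per sample with the canonical column names
  (``sample_id``, ``age``, ``sex``, ``cohort``, ``batch``, ``set``,
  ``smoking_status``, ``pack_years``, cell proportions, ``tte``, ``event``);
* weight table — three columns (feature, transform, weight) plus a single
  ``(Intercept)`` row, mirroring the layout of published clock coefficient
  files, with model metadata in leading ``#`` comment lines.

Methylation is carried either as beta values (proportions in [0, 1]) or
M-values (log2(beta / (1 - beta))); the two scales are linked exactly by
:func:`beta_to_m` / :func:`m_to_beta`.  Sex is coded female=1 / male=0 and
that mapping is written into every serialized model header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ImputationError, ValidationError

logger = logging.getLogger(__name__)

#: clipping bound applied to beta values before the M-value transform
BETA_CLIP = 1e-3

#: documented sex coding, written into serialized model headers
SEX_CODING = "female=1,male=0"

SMOKING_LEVELS = ("never", "current", "quit<1y", "quit>1y", "unknown")

PHENOTYPE_COLUMNS = (
    "sample_id",
    "age",
    "sex",
    "cohort",
    "batch",
    "set",
    "smoking_status",
    "pack_years",
    "tte",
    "event",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MethylationMatrix:
    """Samples x CpGs methylation values with ids and a scale tag.

    ``data`` is a float DataFrame indexed by sample id with CpG ids as
    columns.  ``scale`` is ``"beta"`` or ``"mvalue"``.  Missing values are
    permitted before imputation.
    """

    data: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "mvalue"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate CpG ids: {dups[:5]}")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric methylation values: {exc}") from exc
        if self.scale == "beta":
            vals = self.data.to_numpy()
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                rows, cols = np.nonzero(bad)
                cells = [
                    (self.data.index[r], self.data.columns[c], vals[r, c])
                    for r, c in zip(rows[:10], cols[:10])
                ]
                raise ValidationError(
                    f"beta values outside [0, 1] in {bad.sum()} cells, e.g. {cells}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def cpg_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_mvalues(self) -> "MethylationMatrix":
        if self.scale == "mvalue":
            return self
        return MethylationMatrix(
            pd.DataFrame(
                beta_to_m(self.data.to_numpy()),
                index=self.data.index,
                columns=self.data.columns,
            ),
            scale="mvalue",
        )


@dataclass
class WeightTable:
    """Named intercept + sparse feature weights with per-feature transform.

    ``entries`` has columns ``feature`` (CpG or covariate id), ``transform``
    (``linear`` or ``squared``) and ``weight``.
    """

    name: str
    intercept: float
    entries: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"feature", "transform", "weight"}
        if not required.issubset(self.entries.columns):
            raise FormatError(f"weight table needs columns {sorted(required)}")
        key = self.entries["feature"].astype(str) + "|" + self.entries["transform"].astype(str)
        if key.duplicated().any():
            raise FormatError("duplicate (feature, transform) rows in weight table")
        if not np.isfinite(self.entries["weight"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite weights in weight table")
        if not np.isfinite(self.intercept):
            raise ValidationError("non-finite intercept in weight table")


# ---------------------------------------------------------------------------
# delimited IO
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: empty file")


def read_methylation(path, scale: str = "beta") -> MethylationMatrix:
    """Read a delimited samples x CpGs matrix (header = CpG ids)."""
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no CpG columns found")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"{path}: malformed numeric cells in column {col!r}: {bad.head(3).tolist()}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MethylationMatrix(df, scale=scale)


def write_methylation(matrix: MethylationMatrix, path, sep: str = "\t") -> None:
    matrix.data.to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype sheet; returns a DataFrame indexed by sample_id."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: phenotype sheet lacks a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in phenotype sheet")
    df = df.set_index("sample_id")
    validate_phenotypes(df)
    return df


def write_phenotypes(pheno: pd.DataFrame, path, sep: str = "\t") -> None:
    pheno.to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def validate_phenotypes(pheno: pd.DataFrame, matrix: MethylationMatrix | None = None) -> None:
    """Check phenotype invariants; raise :class:`ValidationError` on failure."""
    if "age" in pheno.columns and (pheno["age"] <= 0).any():
        raise ValidationError("non-positive ages in phenotype sheet")
    if "sex" in pheno.columns:
        codes = set(pd.unique(pheno["sex"].dropna()))
        if not codes <= {0, 1}:
            raise ValidationError(f"sex must be coded {SEX_CODING}; saw {sorted(codes)}")
    if "pack_years" in pheno.columns and (pheno["pack_years"].dropna() < 0).any():
        raise ValidationError("negative pack_years")
    if "tte" in pheno.columns or "event" in pheno.columns:
        tte_na = pheno.get("tte", pd.Series(np.nan, index=pheno.index)).isna()
        ev_na = pheno.get("event", pd.Series(np.nan, index=pheno.index)).isna()
        if not tte_na.equals(ev_na):
            raise ValidationError("tte and event must be missing together")
        if (pheno.get("tte", pd.Series(dtype=float)).dropna() < 0).any():
            raise ValidationError("negative time-to-event")
    if matrix is not None:
        missing = set(matrix.sample_ids) - set(pheno.index)
        if missing:
            raise ValidationError(
                f"{len(missing)} matrix samples missing from phenotype sheet, "
                f"e.g. {sorted(missing)[:5]}"
            )


def read_weight_table(path) -> WeightTable:
    """Read a weight table (feature, transform, weight + ``(Intercept)`` row)."""
    metadata: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                metadata[k.strip()] = v.strip()
        else:
            break
    if body_start >= len(lines):
        raise FormatError(f"{path}: weight table has no body")
    sep = "\t" if "\t" in lines[body_start] else ","
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep=sep, float_precision="round_trip")
    if not {"feature", "transform", "weight"}.issubset(df.columns):
        raise FormatError(f"{path}: weight table needs feature/transform/weight columns")
    mask = df["feature"] == "(Intercept)"
    if mask.sum() != 1:
        raise FormatError(f"{path}: expected exactly one (Intercept) row, found {mask.sum()}")
    intercept = float(df.loc[mask, "weight"].iloc[0])
    entries = df.loc[~mask].reset_index(drop=True)
    entries["weight"] = entries["weight"].astype(float)
    return WeightTable(
        name=metadata.get("name", "model"),
        intercept=intercept,
        entries=entries,
        metadata=metadata,
    )


def write_weight_table(table: WeightTable, path, sep: str = "\t") -> None:
    meta = dict(table.metadata)
    meta.setdefault("name", table.name)
    meta.setdefault("sex_coding", SEX_CODING)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(sep.join(["feature", "transform", "weight"]) + "\n")
        fh.write(sep.join(["(Intercept)", "linear", repr(float(table.intercept))]) + "\n")
        for _, row in table.entries.iterrows():
            fh.write(sep.join([str(row["feature"]), str(row["transform"]), repr(float(row["weight"]))]) + "\n")


# ---------------------------------------------------------------------------
# scale transforms
# ---------------------------------------------------------------------------

def clip_beta(beta, bound: float = BETA_CLIP):
    """Clip beta values into [bound, 1 - bound], warning if any move."""
    arr = np.asarray(beta, dtype=float)
    n_clipped = int(((arr < bound) | (arr > 1 - bound)).sum())
    if n_clipped:
        logger.warning("clipped %d beta values to [%g, %g]", n_clipped, bound, 1 - bound)
    return np.clip(arr, bound, 1 - bound)


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)); betas outside the clip bound are clipped."""
    b = clip_beta(beta)
    return np.log2(b / (1.0 - b))


def m_to_beta(mvalue):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(mvalue, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def impute_mean_per_cpg(matrix: MethylationMatrix, cohort_labels) -> MethylationMatrix:
    """Mean-impute missing values per CpG and per cohort.

    Non-missing entries are left untouched; each missing cell receives the
    arithmetic mean of the observed values for that CpG within that sample's
    cohort.  A (cohort, CpG) group with no observed values is an error.
    """
    labels = pd.Series(np.asarray(cohort_labels), index=matrix.data.index)
    if len(labels) != len(matrix.data):
        raise ValidationError("cohort_labels length does not match sample count")
    if not matrix.data.isna().any().any():
        return matrix
    out = matrix.data.copy()
    for cohort, block in out.groupby(labels, sort=False):
        miss_cols = block.columns[block.isna().any()]
        if len(miss_cols) == 0:
            continue
        means = block[miss_cols].mean()
        dead = means.index[means.isna()]
        if len(dead):
            raise ImputationError(
                f"cohort {cohort!r}: CpG {dead[0]!r} has no observed values to impute from"
            )
        out.loc[block.index, miss_cols] = block[miss_cols].fillna(means)
    return MethylationMatrix(out, scale=matrix.scale)


def intersect_cpgs(matrices) -> list:
    """Restrict every matrix to the sorted intersection of their CpG sets."""
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValidationError("intersect_cpgs needs at least two matrices")
    common = set(matrices[0].cpg_ids)
    for m in matrices[1:]:
        common &= set(m.cpg_ids)
    if not common:
        raise ValidationError("no CpGs shared across all matrices")
    order = sorted(common)
    return [MethylationMatrix(m.data[order], scale=m.scale) for m in matrices]


def standardize_columns(X):
    """Scale columns to mean 0 and sample sd 1 (n-1 denominator).

    Accepts a DataFrame or 2-D array; returns ``(standardized, means, sds)``
    so the transform can be inverted exactly.
    """
    is_df = isinstance(X, pd.DataFrame)
    arr = X.to_numpy(dtype=float) if is_df else np.asarray(X, dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [X.columns[i] for i in zero[:10]] if is_df else zero[:10].tolist()
        raise ValidationError(f"zero-variance columns cannot be standardized: {names}")
    Z = (arr - means) / sds
    if is_df:
        Z = pd.DataFrame(Z, index=X.index, columns=X.columns)
        means = pd.Series(means, index=X.columns)
        sds = pd.Series(sds, index=X.columns)
    return Z, means, sds


def smoking_design(status, reference: str = "never") -> pd.DataFrame:
    """Dummy-code smoking status with ``never`` as the reference level.

    ``unknown`` is its own level, not treated as missing.
    """
    s = pd.Series(status).astype(str)
    bad = set(s.unique()) - set(SMOKING_LEVELS)
    if bad:
        raise ValidationError(f"unknown smoking levels {sorted(bad)}; expected {SMOKING_LEVELS}")
    levels = [lv for lv in SMOKING_LEVELS if lv != reference]
    out = pd.DataFrame(
        {f"smoking_{lv}": (s == lv).astype(float).to_numpy() for lv in levels},
        index=s.index,
    )
    return out
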