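"""Reading, validation, harmonization and imputation of methylation data.

Beta matrices are handled internally in samples x probes orientation; file
orientation is an explicit flag because GEO-style exports are commonly
probes x samples.  Values are methylation proportions in [0, 1]; small
float round-off outside the unit interval (within ``CLAMP_TOL``) is clamped
with a warning, anything larger is treated as corrupt data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: betas within this distance outside [0, 1] are clamped; beyond it, error
CLAMP_TOL = 1e-6

SEX_LEVELS = ("female", "male")
CHROMOSOME_LEVELS = tuple(str(c) for c in range(1, 23)) + ("X", "Y")

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "age",
    "sex",
    "region",
    "neuron_proportion",
    "dx_clinical",
    "cerad",
    "braak",
    "nia_reagan",
    "apoe_e4",
)


@dataclass
class BetaMatrix:
    """Samples x probes matrix of methylation beta values.

    Parameters
    ----------
    sample_ids : sequence of unique str
    probe_ids : sequence of unique str
    values : ndarray of shape (n_samples, n_probes)
        Methylation proportions in [0, 1]; NaN marks missing entries.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match id lists "
                f"({len(self.sample_ids)} samples, {len(self.probe_ids)} probes)"
            )
        if self.values.size == 0:
            raise ValueError("empty beta matrix")
        for name, ids in (("sample", self.sample_ids), ("probe", self.probe_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        self.values = _clamp_unit_interval(self.values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return BetaMatrix(list(sample_ids), list(self.probe_ids), self.values[idx, :])

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        pos = {p: j for j, p in enumerate(self.probe_ids)}
        idx = [pos[p] for p in probe_ids]
        return BetaMatrix(list(self.sample_ids), list(probe_ids), self.values[:, idx])


def _clamp_unit_interval(values: np.ndarray, tol: float = CLAMP_TOL) -> np.ndarray:
    finite = np.isfinite(values)
    bad = finite & ((values < -tol) | (values > 1.0 + tol))
    if bad.any():
        worst = values[bad]
        raise ValueError(
            f"{bad.sum()} beta values outside [0, 1] beyond tolerance {tol} "
            f"(e.g. {worst.flat[0]!r})"
        )
    clip_mask = finite & ((values < 0.0) | (values > 1.0))
    if clip_mask.any():
        warnings.warn(
            f"clamped {clip_mask.sum()} beta values within {tol} of the unit interval",
            stacklevel=3,
        )
        values = np.clip(values, 0.0, 1.0)
    return values


def read_beta_matrix(
    path, orientation: str = "samples_by_probes", sep: str | None = None
) -> BetaMatrix:
    """Read a delimited beta matrix and normalize to samples x probes.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row and an id first column.
    orientation : {"samples_by_probes", "probes_by_samples"}
        Layout of the file; the returned matrix is always samples x probes.
    sep : str, optional
        Field delimiter; inferred from the filename (.csv -> ",", else tab)
        when omitted.
    """
    if orientation not in ("samples_by_probes", "probes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    if frame.empty:
        raise ValueError(f"empty beta matrix in {path}")
    body = frame.apply(pd.to_numeric, errors="coerce")
    introduced_nan = body.isna() & frame.notna()
    if introduced_nan.to_numpy().any():
        offender = frame.to_numpy()[introduced_nan.to_numpy()][0]
        raise ValueError(f"non-numeric cell {offender!r} in {path}")
    if orientation == "probes_by_samples":
        body = body.T
    body.index = body.index.astype(str)
    body.columns = body.columns.astype(str)
    return BetaMatrix.from_frame(body)


def write_beta_matrix(
    matrix: BetaMatrix, path, orientation: str = "samples_by_probes", sep: str | None = None
) -> None:
    """Write a beta matrix as delimited text (missing entries as ``NA``)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    frame = matrix.to_frame()
    if orientation == "probes_by_samples":
        frame = frame.T
    elif orientation != "samples_by_probes":
        raise ValueError(f"unknown orientation {orientation!r}")
    frame.to_csv(path, sep=sep, na_rep="NA", index_label="id")


def read_sample_sheet(path, sep: str | None = None) -> pd.DataFrame:
    """Read a sample sheet (one row per sample) and validate core columns.

    Expected columns: ``sample_id`` (required), ``age`` (years), ``sex``
    (female/male), ``region``, ``neuron_proportion`` (fraction in [0, 1]),
    and optional categorical phenotype columns (``dx_clinical``, ``cerad``,
    ``braak``, ``nia_reagan``, ``apoe_e4``).
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    sheet = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" not in sheet.columns:
        raise ValueError("sample sheet must have a 'sample_id' column")
    sheet = sheet.copy()
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in sample sheet")
    if "age" in sheet.columns:
        age = pd.to_numeric(sheet["age"], errors="raise")
        if ((age < 0) | np.isinf(age)).any():
            raise ValueError("ages must be finite and non-negative")
        sheet["age"] = age
    if "sex" in sheet.columns:
        present = sheet["sex"].dropna()
        bad = set(present.astype(str).str.lower()) - set(SEX_LEVELS)
        if bad:
            raise ValueError(f"unknown sex labels {sorted(bad)}; expected {SEX_LEVELS}")
        sheet["sex"] = sheet["sex"].astype(str).str.lower().where(sheet["sex"].notna())
    if "neuron_proportion" in sheet.columns:
        npn = pd.to_numeric(sheet["neuron_proportion"], errors="raise")
        out = npn.notna() & ((npn < 0) | (npn > 1))
        if out.any():
            raise ValueError("neuron_proportion must lie in [0, 1]")
        sheet["neuron_proportion"] = npn
    return sheet


def read_probe_annotation(path, sep: str | None = None) -> pd.DataFrame:
    """Read a probe annotation table (probe_id, chromosome, gene)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    ann = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return validate_probe_annotation(ann)


def validate_probe_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    required = {"probe_id", "chromosome"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"probe annotation missing columns {sorted(missing)}")
    annotation = annotation.copy()
    annotation["probe_id"] = annotation["probe_id"].astype(str)
    if annotation["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_id in annotation")
    chrom = annotation["chromosome"].astype(str).str.removeprefix("chr")
    bad = set(chrom) - set(CHROMOSOME_LEVELS)
    if bad:
        raise ValueError(f"unknown chromosome labels {sorted(bad)}")
    annotation["chromosome"] = chrom
    if "gene" not in annotation.columns:
        annotation["gene"] = ""
    annotation["gene"] = annotation["gene"].fillna("").astype(str)
    return annotation


def harmonize_probes(
    matrices: BetaMatrix | Iterable[BetaMatrix],
    annotation: pd.DataFrame,
    exclude_chromosomes: Iterable[str] = ("X", "Y"),
) -> list[BetaMatrix]:
    """Restrict matrices to the shared, annotated, autosome-by-default probe set.

    The retained set is the intersection of all input probe sets, minus
    probes on ``exclude_chromosomes`` and probes absent from the annotation
    (their count is logged).  Output probe ordering is lexicographic so that
    downstream projection and serialization are deterministic.
    """
    if isinstance(matrices, BetaMatrix):
        matrices = [matrices]
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices given")
    annotation = validate_probe_annotation(annotation)
    exclude = {str(c).removeprefix("chr") for c in exclude_chromosomes}
    shared: set[str] = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        shared &= set(m.probe_ids)
    annotated = annotation.set_index("probe_id")["chromosome"]
    unannotated = shared - set(annotated.index)
    if unannotated:
        logger.info("dropping %d unannotated probes", len(unannotated))
    kept = sorted(
        p for p in shared - unannotated if annotated[p] not in exclude
    )
    if not kept:
        raise ValueError("empty probe intersection after harmonization")
    logger.info("retained %d shared probes", len(kept))
    return [m.select_probes(kept) for m in matrices]


def impute_missing(matrix: BetaMatrix) -> BetaMatrix:
    """Mean-impute missing betas per probe across samples.

    Each missing entry is replaced by the mean of the non-missing values of
    that probe; probes with no observed value at all are an error.
    """
    values = matrix.values
    if not np.isnan(values).any():
        return matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_means = np.nanmean(values, axis=0)
    all_missing = np.isnan(col_means)
    if all_missing.any():
        bad = [matrix.probe_ids[j] for j in np.flatnonzero(all_missing)[:5]]
        raise ValueError(f"probes with all values missing: {bad}")
    out = values.copy()
    rows, cols = np.nonzero(np.isnan(out))
    out[rows, cols] = col_means[cols]
    return BetaMatrix(matrix.sample_ids, matrix.probe_ids, out)


def filter_samples(
    sheet: pd.DataFrame,
    matrix: BetaMatrix,
    min_age: float = 20.0,
    required_fields: Sequence[str] = (),
) -> tuple[pd.DataFrame, BetaMatrix]:
    """Drop samples below ``min_age`` or missing any required field.

    Mirrors the standard clock-training exclusion of developmental-age
    samples (default cut at 20 years, boundary inclusive).  Exclusion
    counts are logged per criterion.
    """
    sheet = validate_sample_sheet(sheet)
    shared = [s for s in sheet["sample_id"] if s in set(matrix.sample_ids)]
    if not shared:
        raise ValueError("sheet and matrix share no sample ids")
    sub = sheet.set_index("sample_id").loc[shared]
    keep = pd.Series(True, index=sub.index)
    if "age" in sub.columns:
        young = sub["age"].isna() | (sub["age"] < min_age)
        logger.info("excluding %d samples with age < %s", int(young.sum()), min_age)
        keep &= ~young
    for fieldname in required_fields:
        if fieldname not in sub.columns:
            raise ValueError(f"required field {fieldname!r} absent from sheet")
        miss = sub[fieldname].isna()
        logger.info("excluding %d samples missing %s", int(miss.sum()), fieldname)
        keep &= ~miss
    kept_ids = list(sub.index[keep])
    if not kept_ids:
        raise ValueError("no samples remain after filtering")
    out_sheet = sheet[sheet["sample_id"].isin(kept_ids)].reset_index(drop=True)
    return out_sheet, matrix.select_samples(list(out_sheet["sample_id"]))
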