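"""Array data model and TSV I/O.

Beta values are methylation proportions in the closed interval [0, 1]
(0 = unmethylated, 1 = fully methylated); each measurement may carry a
detection p-value quantifying its confidence.  Matrices are stored
probes x samples throughout the package; any orientation change needed by a
downstream algorithm is internal to that algorithm.

Two on-disk dialects are supported:

``paired-columns``
    Each sample contributes two adjacent data columns, ``<sample>.beta`` and
    ``<sample>.pval`` (suffixes configurable), after a leading probe-id
    column.  This mirrors how GEO series-matrix supplements commonly ship
    450K data.
``beta-only``
    One data column per sample; no detection p-values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: The seven molecular subgroups, in canonical encoding order.
SUBGROUP_LABELS: tuple[str, ...] = (
    "WNT",
    "SHH-Infant",
    "SHH-Child",
    "Group3-LowRisk",
    "Group3-HighRisk",
    "Group4-LowRisk",
    "Group4-HighRisk",
)

NON_CLASSIFIABLE = "Non-classifiable"

#: Closed label vocabulary for sample sheets.
LABEL_VOCABULARY: tuple[str, ...] = SUBGROUP_LABELS + (NON_CLASSIFIABLE,)

SEX_CHROMOSOMES = frozenset({"X", "Y"})

#: NA tokens accepted when reading; missing values are written as "".
NA_TOKENS = ("", "NA", "NaN")


class FormatError(ValueError):
    """Raised when an input file violates the expected table layout."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class BetaMatrix:
    """Probes x samples beta values with optional paired detection p-values.

    Parameters
    ----------
    probe_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    beta
        Float array of shape ``(n_probes, n_samples)``; values in [0, 1]
        or NaN for missing.
    detection_p
        Optional float array of the same shape; values in [0, 1] or NaN.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    beta: np.ndarray
    detection_p: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        self.beta = np.asarray(self.beta, dtype=float)
        expected = (len(self.probe_ids), len(self.sample_ids))
        if self.beta.shape != expected:
            raise ValidationError(
                f"beta shape {self.beta.shape} != (n_probes, n_samples) {expected}"
            )
        _check_unit_interval(self.beta, "beta")
        if self.detection_p is not None:
            self.detection_p = np.asarray(self.detection_p, dtype=float)
            if self.detection_p.shape != expected:
                raise ValidationError(
                    f"detection_p shape {self.detection_p.shape} != beta shape {expected}"
                )
            _check_unit_interval(self.detection_p, "detection_p")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_probes, self.n_samples)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.beta)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            probe_ids=list(self.probe_ids),
            sample_ids=list(self.sample_ids),
            beta=self.beta.copy(),
            detection_p=None if self.detection_p is None else self.detection_p.copy(),
        )

    def select_probes(self, indices: Sequence[int]) -> "BetaMatrix":
        """Row subset, preserving the given order."""
        idx = list(indices)
        return BetaMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            beta=self.beta[idx, :],
            detection_p=None if self.detection_p is None else self.detection_p[idx, :],
        )

    def select_samples(self, indices: Sequence[int]) -> "BetaMatrix":
        """Column subset, preserving the given order."""
        idx = list(indices)
        return BetaMatrix(
            probe_ids=list(self.probe_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            beta=self.beta[:, idx],
            detection_p=None if self.detection_p is None else self.detection_p[:, idx],
        )

    def equals(self, other: "BetaMatrix") -> bool:
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        if not _nan_equal(self.beta, other.beta):
            return False
        if (self.detection_p is None) != (other.detection_p is None):
            return False
        if self.detection_p is not None and not _nan_equal(
            self.detection_p, other.detection_p
        ):
            return False
        return True


def _nan_equal(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and bool(
        np.all((a == b) | (np.isnan(a) & np.isnan(b)))
    )


def _check_unit_interval(arr: np.ndarray, what: str) -> None:
    finite = arr[~np.isnan(arr)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        bad = finite[(finite < 0.0) | (finite > 1.0)][0]
        raise ValidationError(f"{what} value {bad} outside [0, 1]")


@dataclass
class ProbeAnnotation:
    """Per-probe annotation table used by QC filtering.

    ``max_maf_within_50bp`` is the largest minor allele frequency of any SNP
    within 50 bp of the target CpG (0 if none); minor allele frequencies are
    by definition at most 0.5.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("probe_id", "chromosome", "cross_reactive", "max_maf_within_50bp")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        t = self.table
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id in annotation: {dup!r}")
        maf = t["max_maf_within_50bp"].to_numpy(dtype=float)
        if np.isnan(maf).any() or maf.min() < 0 or maf.max() > 0.5:
            raise ValidationError("max_maf_within_50bp must lie in [0, 0.5]")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("probe_id")


@dataclass
class SampleSheet:
    """Sample-to-subgroup mapping with optional age and sex columns."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns or "label" not in self.table.columns:
            raise ValidationError("sample sheet requires 'sample_id' and 'label' columns")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id in sheet: {dup!r}")
        bad = sorted(set(t["label"]) - set(LABEL_VOCABULARY))
        if bad:
            raise ValidationError(
                f"unknown subgroup label(s) {bad}; allowed: {list(LABEL_VOCABULARY)}"
            )
        if "age_years" in t.columns:
            age = pd.to_numeric(t["age_years"], errors="coerce")
            if (age.dropna() < 0).any():
                raise ValidationError("age_years must be nonnegative")
        if "sex" in t.columns:
            bad_sex = sorted(set(t["sex"].dropna()) - {"M", "F", "unknown"})
            if bad_sex:
                raise ValidationError(f"unknown sex value(s): {bad_sex}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        """Labels in the order of ``sample_ids``; error on unknown sample."""
        mapping = dict(zip(self.table["sample_id"], self.table["label"]))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValidationError(f"samples absent from sheet: {missing[:5]}")
        return [mapping[s] for s in sample_ids]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        order = {s: i for i, s in enumerate(sample_ids)}
        keep = keep.sort_values("sample_id", key=lambda s: s.map(order))
        return SampleSheet(keep.reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers / writers


def _format_float(x: float) -> str:
    # repr-based shortest round-trip rendering keeps write->read bit-stable
    return "" if np.isnan(x) else repr(float(x))


def read_beta_table(
    path,
    dialect: str = "paired-columns",
    beta_suffix: str = ".beta",
    pval_suffix: str = ".pval",
) -> BetaMatrix:
    """Read a TSV beta-value table.

    In the ``paired-columns`` dialect each sample contributes exactly two
    adjacent columns named ``<sample><beta_suffix>`` and
    ``<sample><pval_suffix>``; in ``beta-only`` every data column is one
    sample's beta values.  Empty cells and the tokens NA/NaN become missing.
    Values outside [0, 1] are rejected, never clipped.
    """
    if dialect not in ("paired-columns", "beta-only"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )
    if df.shape[1] < 2:
        raise FormatError("expected a probe-id column plus at least one data column")
    probe_col = df.columns[0]
    probe_ids = df[probe_col].tolist()
    _check_unique(probe_ids, "probe id")
    data_cols = list(df.columns[1:])

    def parse_column(col: str) -> np.ndarray:
        raw = df[col].to_numpy()
        out = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw):
            s = cell.strip()
            if s in NA_TOKENS:
                out[i] = np.nan
                continue
            try:
                out[i] = float(s)
            except ValueError:
                raise FormatError(
                    f"non-numeric cell {cell!r} at row {probe_ids[i]!r}, column {col!r}"
                ) from None
        return out

    if dialect == "beta-only":
        sample_ids = data_cols
        beta = np.column_stack([parse_column(c) for c in data_cols])
        return BetaMatrix(probe_ids, sample_ids, beta, None)

    if len(data_cols) % 2 != 0:
        raise FormatError(
            f"paired-columns dialect requires an even number of data columns, got {len(data_cols)}"
        )
    sample_ids = []
    beta_cols, pval_cols = [], []
    for i in range(0, len(data_cols), 2):
        bcol, pcol = data_cols[i], data_cols[i + 1]
        if not bcol.endswith(beta_suffix):
            raise FormatError(f"expected column ending {beta_suffix!r}, got {bcol!r}")
        if not pcol.endswith(pval_suffix):
            raise FormatError(f"expected column ending {pval_suffix!r}, got {pcol!r}")
        sample = bcol[: -len(beta_suffix)]
        if pcol[: -len(pval_suffix)] != sample:
            raise FormatError(f"column pair mismatch: {bcol!r} vs {pcol!r}")
        sample_ids.append(sample)
        beta_cols.append(parse_column(bcol))
        pval_cols.append(parse_column(pcol))
    beta = np.column_stack(beta_cols)
    detection_p = np.column_stack(pval_cols)
    return BetaMatrix(probe_ids, sample_ids, beta, detection_p)


def write_beta_table(
    bm: BetaMatrix,
    path,
    dialect: str = "paired-columns",
    beta_suffix: str = ".beta",
    pval_suffix: str = ".pval",
) -> None:
    """Write ``bm`` as TSV; inverse of :func:`read_beta_table`.

    Missing values are written as empty cells.  The beta-only dialect drops
    the detection-p block.  Writing paired-columns requires detection_p.
    """
    if dialect not in ("paired-columns", "beta-only"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "paired-columns" and bm.detection_p is None:
        raise ValidationError("paired-columns dialect requires detection_p")
    buf = io.StringIO()
    if dialect == "beta-only":
        header = ["probe_id"] + list(bm.sample_ids)
        buf.write("\t".join(header) + "\n")
        for i, pid in enumerate(bm.probe_ids):
            row = [pid] + [_format_float(x) for x in bm.beta[i]]
            buf.write("\t".join(row) + "\n")
    else:
        header = ["probe_id"]
        for s in bm.sample_ids:
            header += [f"{s}{beta_suffix}", f"{s}{pval_suffix}"]
        buf.write("\t".join(header) + "\n")
        for i, pid in enumerate(bm.probe_ids):
            row = [pid]
            for j in range(bm.n_samples):
                row.append(_format_float(bm.beta[i, j]))
                row.append(_format_float(bm.detection_p[i, j]))
            buf.write("\t".join(row) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_annotation(path) -> ProbeAnnotation:
    """Read a probe annotation TSV (probe_id, chromosome, cross_reactive,
    max_maf_within_50bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    if "cross_reactive" in df.columns:
        df["cross_reactive"] = df["cross_reactive"].map(_parse_bool)
    return ProbeAnnotation(df)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean value {x!r}")


def write_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    """Read a sample sheet TSV (sample_id, label[, age_years, sex])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "label": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)
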