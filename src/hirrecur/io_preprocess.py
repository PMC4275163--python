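"""Expression/clinical table I/O and preprocessing.

Readers accept plain TSV (and gzip thereof) plus a minimal GEO
series-matrix dialect.  Preprocessing covers quantile normalization,
signature matching by gene symbol and per-cohort median centering.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "CohortClinical",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "quantile_normalize",
    "match_and_center",
]

#: clinical covariates carried alongside time/event, when present
CLINICAL_COVARIATES = (
    "sex",
    "age",
    "afp_gt_300",
    "hbv",
    "cirrhosis",
    "tumor_gt_5cm",
    "multinodular",
    "vascular_invasion",
    "bclc",
)

_BCLC_LEVELS = {"0", "A", "B", "C"}


@dataclass
class ExpressionMatrix:
    """log2-scale genes x samples matrix with feature/sample annotation.

    ``feature_ids`` are unique probe-level identifiers; ``gene_symbols``
    may repeat across features (several probes per gene).
    """

    feature_ids: np.ndarray
    gene_symbols: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat or len(self.gene_symbols) != n_feat:
            raise ValueError("feature annotation length does not match value rows")
        if len(self.sample_ids) != n_samp:
            raise ValueError("sample_ids length does not match value columns")
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.sample_ids == sample_id)
        if idx.size == 0:
            raise KeyError(f"sample {sample_id!r} not present")
        return int(idx[0])

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample_id)]

    def subset_features(self, row_idx: Sequence[int]) -> "ExpressionMatrix":
        row_idx = np.asarray(row_idx, dtype=int)
        return ExpressionMatrix(
            feature_ids=self.feature_ids[row_idx],
            gene_symbols=self.gene_symbols[row_idx],
            sample_ids=self.sample_ids,
            values=self.values[row_idx, :],
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        cols = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=self.feature_ids,
            gene_symbols=self.gene_symbols,
            sample_ids=self.sample_ids[cols],
            values=self.values[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class CohortClinical:
    """Per-patient recurrence time, event flag and baseline covariates.

    Backed by a :class:`pandas.DataFrame` indexed by ``patient_id`` with
    required columns ``time_months`` and ``event``; an optional ``entry``
    column (delayed-entry / landmark time) plus any covariates.  BCLC
    stage may be missing (NaN) for a subset of patients.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time_months", "event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if df.index.has_duplicates:
            raise ValueError("duplicate patient IDs")
        if (df["time_months"] < 0).any():
            raise ValueError("negative time_months")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if "bclc" in df.columns:
            bad = df["bclc"].dropna().astype(str).pipe(lambda s: s[~s.isin(_BCLC_LEVELS)])
            if len(bad):
                raise ValueError(f"invalid BCLC stage values: {sorted(set(bad))}")

    @property
    def patient_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def copy(self) -> "CohortClinical":
        return CohortClinical(self.data.copy())


# ---------------------------------------------------------------------------
# readers / writers


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}: {v}" for k, v in provenance.items()]


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV or GEO series-matrix text.

    TSV layout: header row, first column feature ID, second column gene
    symbol, remaining columns one per sample.  Lines starting with ``#``
    are provenance comments and skipped.  The series-matrix dialect
    parses the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` (feature ID only; symbols default to the
    feature ID).
    """
    if format == "tsv":
        return _read_expression_tsv(path)
    if format == "series_matrix":
        return _read_expression_series_matrix(path)
    raise ValueError(f"unknown expression format {format!r}")


def _read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    with _open_text(path) as fh:
        header = None
        rows: list[list[str]] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if len(header) < 3:
                    raise ValueError(
                        f"{path}: malformed header (need feature ID, gene symbol and >=1 sample)"
                    )
                continue
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})")
            rows.append(parts)
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    feature_ids = [r[0] for r in rows]
    symbols = [r[1] for r in rows]
    values = np.empty((len(rows), len(header) - 2), dtype=float)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[2:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at feature {r[0]!r}, column {header[j + 2]!r}"
                ) from None
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"{path}: duplicate feature IDs")
    return ExpressionMatrix(
        feature_ids=np.array(feature_ids, dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
        sample_ids=np.array(header[2:], dtype=object),
        values=values,
    )


def _read_expression_series_matrix(path: str | Path) -> ExpressionMatrix:
    in_table = False
    header = None
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                break
            if not in_table or not line:
                continue
            parts = [p.strip().strip('"') for p in line.split("\t")]
            if header is None:
                header = parts
                continue
            feature_ids.append(parts[0])
            try:
                rows.append([float(c) for c in parts[1:]])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric cell in series-matrix table") from None
    if header is None or not rows:
        raise ValueError(f"{path}: no series-matrix table found")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"{path}: duplicate feature IDs")
    symbols = np.array(feature_ids, dtype=object)
    return ExpressionMatrix(
        feature_ids=np.array(feature_ids, dtype=object),
        gene_symbols=symbols,
        sample_ids=np.array(header[1:], dtype=object),
        values=np.asarray(rows, dtype=float),
    )


def write_expression(m: ExpressionMatrix, path: str | Path, provenance: dict | None = None) -> None:
    """Write TSV: feature_id, gene_symbol, then one column per sample."""
    with _open_text(path, "wt") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write("feature_id\tgene_symbol\t" + "\t".join(map(str, m.sample_ids)) + "\n")
        for i in range(m.n_features):
            vals = "\t".join(repr(float(v)) for v in m.values[i])
            fh.write(f"{m.feature_ids[i]}\t{m.gene_symbols[i]}\t{vals}\n")


def read_clinical(path: str | Path) -> CohortClinical:
    """Read a clinical TSV (patient_id, time_months, event, covariates)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"bclc": "string"})
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: missing patient_id column")
    df = df.set_index("patient_id")
    return CohortClinical(df)


def write_clinical(c: CohortClinical, path: str | Path, provenance: dict | None = None) -> None:
    with _open_text(path, "wt") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        c.data.rename_axis("patient_id").reset_index().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common empirical distribution.

    Each column's sorted values are replaced by the across-column means
    of the order statistics; ties within a column receive the mean of
    the tied rank values (``rankdata`` average ranks interpolated on the
    reference distribution).
    """
    if m.n_samples == 1:
        warnings.warn("quantile_normalize: single-sample matrix returned unchanged")
        return m
    x = m.values
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        r = rankdata(x[:, j], method="average")  # 1..n, halves on ties
        lo = np.floor(r).astype(int) - 1
        hi = np.ceil(r).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return ExpressionMatrix(
        feature_ids=m.feature_ids,
        gene_symbols=m.gene_symbols,
        sample_ids=m.sample_ids,
        values=out,
    )


def match_and_center(
    m: ExpressionMatrix, symbols: Sequence[str]
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict to signature genes (matched by symbol) and median-center rows.

    Duplicate symbols collapse to the highest-variance feature.  Returns
    the centered matrix (rows in the order of ``symbols``, absent genes
    dropped) and the list of absent symbols.
    """
    if hasattr(symbols, "symbols"):  # Signature object
        symbols = symbols.symbols
    wanted = list(dict.fromkeys(str(s) for s in symbols))  # preserve order, dedupe
    by_symbol: dict[str, int] = {}
    variances = m.values.var(axis=1, ddof=0)
    for i, sym in enumerate(m.gene_symbols):
        sym = str(sym)
        if sym not in by_symbol or variances[i] > variances[by_symbol[sym]]:
            by_symbol[sym] = i
    rows = [by_symbol[s] for s in wanted if s in by_symbol]
    absent = [s for s in wanted if s not in by_symbol]
    if not rows:
        raise ValueError("no signature genes present in matrix")
    sub = m.subset_features(rows)
    centered = sub.values - np.median(sub.values, axis=1, keepdims=True)
    out = ExpressionMatrix(
        feature_ids=sub.feature_ids,
        gene_symbols=sub.gene_symbols,
        sample_ids=sub.sample_ids,
        values=centered,
    )
    return out, absent
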