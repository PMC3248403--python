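"""Expression-matrix, annotation, signature and metagene I/O plus per-array
normalization transforms.

All expression data live in an :class:`ExpressionMatrix`: a probeset-major
:class:`pandas.DataFrame` (rows = probesets, columns = samples) with a
per-sample dataset label.  Sample order is authoritative and preserved by
every transform in the package.

Normalization follows the standard per-array convention for pooled Affymetrix
cohorts: log2 transform, median-centring of each array, and scaling each
array to unit magnitude (sum of squared values = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as missing during load.
MISSING_TOKENS = frozenset({"", "na", "nan", "null", "n/a", "none"})

ENDPOINT_TYPES = ("RFS", "DMFS", "none")


class ExpressionIOError(ValueError):
    """Raised for malformed expression, annotation or signature files."""


@dataclass
class ExpressionMatrix:
    """Probeset x sample log2-scale expression with per-sample dataset labels.

    Parameters
    ----------
    values
        DataFrame with unique probeset ids as index and unique sample ids as
        columns; all entries finite.
    dataset_labels
        Series mapping every sample id to a non-empty dataset label, in the
        same order as ``values.columns``.
    """

    values: pd.DataFrame
    dataset_labels: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate probeset ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample ids: {dups}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ExpressionIOError("expression values must be finite")
        self.dataset_labels = pd.Series(self.dataset_labels, dtype=object)
        self.dataset_labels = self.dataset_labels.reindex(cols)
        if self.dataset_labels.isna().any() or (self.dataset_labels == "").any():
            missing = self.dataset_labels.index[
                self.dataset_labels.isna() | (self.dataset_labels == "")
            ].tolist()
            raise ExpressionIOError(f"samples without dataset label: {missing}")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_probesets(self) -> int:
        return self.values.shape[0]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)],
            self.dataset_labels.loc[list(sample_ids)],
        )

    def subset_probesets(self, probeset_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(probeset_ids)], self.dataset_labels
        )


@dataclass
class SampleRecord:
    """Clinical annotation for one sample.

    ``endpoint_type`` is RFS, DMFS or "none"; when "none", ``time`` and
    ``event`` are absent.  Covariate class fields are nullable and excluded
    from complete-case analyses downstream.
    """

    sample_id: str
    dataset_id: str
    endpoint_type: str = "none"
    time: float | None = None
    event: int | None = None
    age_class: str | None = None      # "<=50" / ">50"
    size_class: str | None = None     # "<=2cm" / ">2cm"
    node_class: str | None = None     # "LNN" / "LNP"
    grade_class: str | None = None    # "G1&2" / "G3"
    pcr: int | None = None

    def __post_init__(self) -> None:
        if self.endpoint_type not in ENDPOINT_TYPES:
            raise ExpressionIOError(
                f"{self.sample_id}: endpoint_type must be one of {ENDPOINT_TYPES}"
            )
        if self.endpoint_type == "none":
            if self.time is not None or self.event is not None:
                raise ExpressionIOError(
                    f"{self.sample_id}: time/event given without an endpoint"
                )
        else:
            if self.time is None or self.event is None:
                raise ExpressionIOError(
                    f"{self.sample_id}: endpoint {self.endpoint_type} needs time and event"
                )
            if self.time < 0:
                raise ExpressionIOError(f"{self.sample_id}: negative survival time")
            if self.event not in (0, 1):
                raise ExpressionIOError(f"{self.sample_id}: event must be 0/1")
            if self.event == 1 and self.time <= 0:
                raise ExpressionIOError(
                    f"{self.sample_id}: event requires a positive time"
                )


ANNOTATION_COLUMNS = [
    "sample_id",
    "dataset_id",
    "endpoint_type",
    "time",
    "event",
    "age_class",
    "size_class",
    "node_class",
    "grade_class",
    "pcr",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


def _attach_labels(
    frame: pd.DataFrame,
    datasets: Mapping[str, str] | pd.Series | str | None,
) -> pd.Series:
    if datasets is None:
        labels = pd.Series("unspecified", index=frame.columns, dtype=object)
    elif isinstance(datasets, str):
        side = pd.read_csv(datasets, sep="\t", dtype=str)
        labels = side.set_index(side.columns[0])[side.columns[1]].reindex(frame.columns)
    else:
        labels = pd.Series(dict(datasets), dtype=object).reindex(frame.columns)
    return labels


def read_expression_matrix(
    path: str,
    dialect: str = "tsv",
    datasets: Mapping[str, str] | pd.Series | str | None = None,
) -> ExpressionMatrix:
    """Read a probeset x sample expression matrix.

    ``dialect="tsv"`` expects a header row of sample ids and a first column
    of probeset ids.  ``dialect="series_matrix"`` reads only the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` block of a
    GEO series-matrix file; metadata lines are ignored.

    Probesets containing a missing token or a non-numeric cell are dropped
    with a logged count (complete-row policy).  Duplicate probeset ids are a
    hard error.  ``datasets`` maps sample id -> dataset label (mapping,
    Series, or path to a two-column TSV sidecar).
    """
    if dialect == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "series_matrix":
        raw = _read_series_matrix_block(path)
    else:
        raise ExpressionIOError(f"unknown dialect {dialect!r}")

    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ExpressionIOError(f"duplicate probeset ids: {dups}")

    cleaned = raw.apply(
        lambda col: pd.to_numeric(
            col.map(lambda v: np.nan if isinstance(v, str) and _is_missing(v) else v),
            errors="coerce",
        )
    )
    bad = cleaned.isna().any(axis=1)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info(
            "read_expression_matrix: dropped %d probeset(s) with missing or "
            "non-numeric values",
            n_dropped,
        )
    cleaned = cleaned.loc[~bad].astype(float)
    return ExpressionMatrix(cleaned, _attach_labels(cleaned, datasets))


def _read_series_matrix_block(path: str) -> pd.DataFrame:
    rows: list[list[str]] = []
    inside = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                break
            if inside:
                rows.append([f.strip().strip('"') for f in stripped.split("\t")])
    if not rows:
        raise ExpressionIOError(f"{path}: no series_matrix table block found")
    header, *body = rows
    frame = pd.DataFrame(body, columns=header).set_index(header[0])
    frame.index.name = None
    return frame


def write_expression_matrix(m: ExpressionMatrix, path: str) -> None:
    m.values.to_csv(path, sep="\t", index_label="probeset_id", float_format="%.10g")


def read_annotations(path: str) -> list[SampleRecord]:
    """Read a sample-annotation TSV (one row per sample) into records."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(["sample_id", "dataset_id"]) - set(frame.columns)
    if missing_cols:
        raise ExpressionIOError(f"annotation file lacks columns {sorted(missing_cols)}")
    records = []
    for _, row in frame.iterrows():
        get = lambda key: None if key not in row or pd.isna(row[key]) or _is_missing(str(row[key])) else str(row[key])
        time = get("time")
        event = get("event")
        pcr = get("pcr")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                dataset_id=str(row["dataset_id"]),
                endpoint_type=get("endpoint_type") or "none",
                time=None if time is None else float(time),
                event=None if event is None else int(float(event)),
                age_class=get("age_class"),
                size_class=get("size_class"),
                node_class=get("node_class"),
                grade_class=get("grade_class"),
                pcr=None if pcr is None else int(float(pcr)),
            )
        )
    return records


def annotations_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records], columns=ANNOTATION_COLUMNS)
    return frame.set_index("sample_id", drop=False)


def write_annotations(records: Iterable[SampleRecord], path: str) -> None:
    annotations_to_frame(records).to_csv(path, sep="\t", index=False)


def read_signature_file(path: str) -> pd.DataFrame:
    """Read a 3-column signature TSV (probeset_id, weight, direction).

    POOR entries must have positive weight, GOOD negative.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"probeset_id": str})
    expected = ["probeset_id", "weight", "direction"]
    if list(frame.columns[:3]) != expected:
        raise ExpressionIOError(f"signature file must have columns {expected}")
    if frame["probeset_id"].duplicated().any():
        dups = frame.loc[frame["probeset_id"].duplicated(), "probeset_id"].tolist()
        raise ExpressionIOError(f"duplicate probesets in signature: {dups}")
    frame["weight"] = frame["weight"].astype(float)
    sign_ok = np.where(frame["direction"] == "POOR", frame["weight"] > 0, frame["weight"] < 0)
    if not sign_ok.all():
        bad = frame.loc[~sign_ok, "probeset_id"].tolist()
        raise ExpressionIOError(f"weight sign inconsistent with direction for: {bad}")
    return frame


def write_signature_file(frame: pd.DataFrame, path: str) -> None:
    frame.loc[:, ["probeset_id", "weight", "direction"]].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_metagene_definitions(path: str) -> dict[str, list[str]]:
    """Read 2-column TSV (metagene_name, probeset_id) into name -> members."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ExpressionIOError("metagene definition file needs 2 columns")
    name_col, probe_col = frame.columns[:2]
    out: dict[str, list[str]] = {}
    for name, grp in frame.groupby(name_col, sort=False):
        out[str(name)] = grp[probe_col].astype(str).tolist()
    if not all(out.values()):
        raise ExpressionIOError("metagene with empty member list")
    return out


def write_metagene_definitions(mg: Mapping[str, Sequence[str]], path: str) -> None:
    rows = [(name, p) for name, members in mg.items() for p in members]
    pd.DataFrame(rows, columns=["metagene_name", "probeset_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# per-array normalization
# ---------------------------------------------------------------------------

def log2_median_center(m: ExpressionMatrix, already_log: bool = False) -> ExpressionMatrix:
    """Log2-transform (unless already on log scale) and median-centre each array.

    Every output column has median exactly 0.
    """
    vals = m.values.to_numpy(dtype=float)
    if not already_log:
        if (vals <= 0).any():
            bad = m.values.columns[(vals <= 0).any(axis=0)].tolist()
            raise ExpressionIOError(
                f"non-positive values on linear scale in sample(s) {bad}"
            )
        vals = np.log2(vals)
    vals = vals - np.median(vals, axis=0, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.values.index, columns=m.values.columns),
        m.dataset_labels,
    )


def unit_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each array by S so its sum of squared values equals 1."""
    vals = m.values.to_numpy(dtype=float)
    norms = np.sqrt((vals**2).sum(axis=0))
    zero = norms == 0
    if zero.any():
        bad = m.values.columns[zero].tolist()
        raise ExpressionIOError(f"all-zero sample column(s): {bad}")
    return ExpressionMatrix(
        pd.DataFrame(vals / norms, index=m.values.index, columns=m.values.columns),
        m.dataset_labels,
    )
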