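"""Reading, writing and preparation of two-assay IC50 compound tables.

A compound record is one measurement from either the old or the new assay:
a compound identifier, sparse signature-descriptor counts, an IC50 in μM
with an optional censoring qualifier (">" / "<"), a test date and the assay
tag. Records are read from CSV (optionally with a companion libsvm sparse
feature file), filtered with the standard preparation rules (experimental
range cap at 100 μM, optional removal of a known artifact concentration,
per-compound deduplication) and turned into a :class:`LabeledDataset` for
either classification (active/nonactive at a 10 μM threshold) or regression
(pIC50 target, qualifier-free records only).
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

ACTIVE = "A"
NONACTIVE = "N"
UNDETERMINED = "undetermined"

CLASSIFICATION = "classification"
REGRESSION = "regression"

#: column order of the CSV interchange format (features may instead live in
#: a companion libsvm file, in which case the column is absent).
CSV_COLUMNS = ("id", "ic50_um", "qualifier", "date", "assay", "features")


class DataFormatError(ValueError):
    """The input file violates the expected tabular format."""


class EmptyDatasetError(ValueError):
    """Every record was filtered out; no dataset can be built."""


class Qualifier(str, Enum):
    EXACT = "exact"
    GREATER = "greater"
    LESS = "less"

    @classmethod
    def parse(cls, text: str) -> "Qualifier":
        text = (text or "").strip()
        if text in ("", "=", "exact"):
            return cls.EXACT
        if text in (">", "greater"):
            return cls.GREATER
        if text in ("<", "less"):
            return cls.LESS
        raise ValueError(f"unknown qualifier {text!r}")

    def symbol(self) -> str:
        return {"exact": "", "greater": ">", "less": "<"}[self.value]


class Assay(str, Enum):
    OLD = "old"
    NEW = "new"


@dataclass(frozen=True)
class CompoundRecord:
    """One assay measurement of one compound."""

    compound_id: str
    ic50_um: float
    qualifier: Qualifier
    test_date: dt.date
    assay: Assay
    features: dict[int, int]

    def __post_init__(self) -> None:
        if not (self.ic50_um > 0 and math.isfinite(self.ic50_um)):
            raise ValueError(f"non-positive IC50 for {self.compound_id!r}")
        for idx, count in self.features.items():
            if idx < 0:
                raise ValueError(f"negative feature index {idx}")
            if count < 0:
                raise ValueError(f"negative feature count at index {idx}")

    @property
    def pic50(self) -> float:
        return ic50_to_pic50(self.ic50_um)


def ic50_to_pic50(ic50_um):
    """Convert an IC50 in μM to pIC50 (negative log molar): 6 − log10(IC50).

    Accepts scalars or arrays; raises for non-positive input.
    """
    arr = np.asarray(ic50_um, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("IC50 must be positive and finite")
    out = 6.0 - np.log10(arr)
    return float(out) if np.isscalar(ic50_um) else out


def pic50_to_ic50(pic50):
    """Inverse of :func:`ic50_to_pic50` (result in μM)."""
    arr = np.asarray(pic50, dtype=float)
    out = np.power(10.0, 6.0 - arr)
    return float(out) if np.isscalar(pic50) else out


def label_activity(record: CompoundRecord, threshold_um: float = 10.0) -> str:
    """Categorize a measurement as active/nonactive at an IC50 threshold.

    Exact values: active iff IC50 ≤ threshold. A ">" qualifier can only
    certify nonactivity (IC50 ≥ threshold), a "<" qualifier only activity
    (IC50 ≤ threshold); otherwise the label is undetermined.
    """
    return _label_value(record.ic50_um, record.qualifier, threshold_um)


def _label_value(ic50_um: float, qualifier: Qualifier, threshold_um: float) -> str:
    if qualifier is Qualifier.EXACT:
        return ACTIVE if ic50_um <= threshold_um else NONACTIVE
    if qualifier is Qualifier.GREATER:
        return NONACTIVE if ic50_um >= threshold_um else UNDETERMINED
    return ACTIVE if ic50_um <= threshold_um else UNDETERMINED


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Feature matrix with per-row target, assay provenance and task kind.

    ``y`` holds pIC50 values (regression) or "A"/"N" labels (classification);
    ``assay_tag`` holds "old"/"new" per row.
    """

    X: sp.csr_matrix
    y: np.ndarray
    assay_tag: np.ndarray
    task: str
    compound_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown task {self.task!r}")
        self.X = sp.csr_matrix(self.X)
        self.y = np.asarray(self.y)
        self.assay_tag = np.asarray(self.assay_tag, dtype=object)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.assay_tag) == n):
            raise ValueError("X, y and assay_tag disagree on row count")
        if self.compound_ids is not None:
            self.compound_ids = np.asarray(self.compound_ids, dtype=object)
            if len(self.compound_ids) != n:
                raise ValueError("compound_ids length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def __len__(self) -> int:
        return self.n

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            assay_tag=self.assay_tag[idx],
            task=self.task,
            compound_ids=None if self.compound_ids is None else self.compound_ids[idx],
        )

    @staticmethod
    def concat(parts: Sequence["LabeledDataset"]) -> "LabeledDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        tasks = {p.task for p in parts}
        if len(tasks) != 1:
            raise ValueError("cannot concatenate datasets of different tasks")
        d = max(p.X.shape[1] for p in parts)
        mats = [_pad_columns(p.X, d) for p in parts]
        ids = None
        if all(p.compound_ids is not None for p in parts):
            ids = np.concatenate([p.compound_ids for p in parts])
        return LabeledDataset(
            X=sp.vstack(mats, format="csr"),
            y=np.concatenate([p.y for p in parts]),
            assay_tag=np.concatenate([p.assay_tag for p in parts]),
            task=parts[0].task,
            compound_ids=ids,
        )


def _pad_columns(X: sp.csr_matrix, d: int) -> sp.csr_matrix:
    if X.shape[1] == d:
        return X
    pad = sp.csr_matrix((X.shape[0], d - X.shape[1]), dtype=X.dtype)
    return sp.hstack([X, pad], format="csr")


# ---------------------------------------------------------------------------
# CSV / libsvm I/O
# ---------------------------------------------------------------------------


def _parse_inline_features(text: str) -> dict[int, int]:
    feats: dict[int, int] = {}
    for token in text.split():
        idx_s, _, cnt_s = token.partition(":")
        idx, cnt = int(idx_s), int(cnt_s)
        if idx in feats:
            raise ValueError(f"duplicate feature index {idx}")
        feats[idx] = cnt
    return feats


def _format_inline_features(features: dict[int, int]) -> str:
    return " ".join(f"{i}:{c}" for i, c in sorted(features.items()))


def read_records(path, features_path=None):
    """Read compound records from CSV, returning ``(records, rejections)``.

    Each well-formed row becomes a :class:`CompoundRecord`; malformed rows
    are reported as ``(line_number, reason)`` pairs instead of aborting the
    whole read. Features come either from an inline "idx:count ..." column
    (0-based indices) or from a companion libsvm file (1-based indices,
    aligned with the CSV data rows).

    Raises :class:`DataFormatError` if a mandatory column is missing.
    """
    ext_features = None
    if features_path is not None:
        Xf, _ = load_svmlight_file(str(features_path), zero_based=False)
        ext_features = sp.csr_matrix(Xf)

    records: list[CompoundRecord] = []
    rejections: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        mandatory = ["id", "ic50_um", "qualifier", "date", "assay"]
        missing = [c for c in mandatory if c not in header]
        if missing:
            raise DataFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        if "features" not in header and ext_features is None:
            raise DataFormatError(
                "no 'features' column and no companion libsvm file given"
            )
        for row_i, row in enumerate(reader):
            line_no = row_i + 2  # 1-based, after the header line
            try:
                ic50 = float(row["ic50_um"])
                if not ic50 > 0:
                    raise ValueError("non-positive IC50")
                if "features" in header:
                    feats = _parse_inline_features(row["features"] or "")
                else:
                    if row_i >= ext_features.shape[0]:
                        raise ValueError("no matching row in the features file")
                    sl = ext_features[row_i]
                    feats = {int(i): int(v) for i, v in zip(sl.indices, sl.data)}
                rec = CompoundRecord(
                    compound_id=row["id"],
                    ic50_um=ic50,
                    qualifier=Qualifier.parse(row["qualifier"]),
                    test_date=dt.date.fromisoformat(row["date"]),
                    assay=Assay(row["assay"]),
                    features=feats,
                )
            except (ValueError, KeyError, TypeError) as exc:
                reason = str(exc) or exc.__class__.__name__
                if "could not convert" in reason or "float" in reason:
                    reason = "non-positive or unparseable IC50"
                rejections.append((line_no, reason))
                continue
            records.append(rec)
    return records, rejections


def write_records(records: Iterable[CompoundRecord], path) -> None:
    """Write records to the CSV interchange format with inline features."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.compound_id,
                    repr(r.ic50_um),
                    r.qualifier.symbol(),
                    r.test_date.isoformat(),
                    r.assay.value,
                    _format_inline_features(r.features),
                ]
            )


def save_dataset(ds: LabeledDataset, csv_path, libsvm_path) -> None:
    """Serialize a prepared dataset as a CSV table plus a libsvm feature file.

    The libsvm file (1-based indices) carries the numeric target: pIC50 for
    regression, 1/0 for active/nonactive.
    """
    if ds.task == REGRESSION:
        y_num = ds.y.astype(float)
    else:
        y_num = (ds.y == ACTIVE).astype(float)
    with open(libsvm_path, "wb") as fh:
        dump_svmlight_file(ds.X, y_num, fh, zero_based=False)
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "y", "assay"])
        ids = ds.compound_ids
        for i in range(ds.n):
            writer.writerow(
                [ids[i] if ids is not None else f"row{i}", ds.y[i], ds.assay_tag[i]]
            )


def load_dataset(csv_path, libsvm_path, task: str) -> LabeledDataset:
    """Inverse of :func:`save_dataset`."""
    X, y_num = load_svmlight_file(str(libsvm_path), zero_based=False)
    ids, assays = [], []
    with open(csv_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ids.append(row["id"])
            assays.append(row["assay"])
    if task == CLASSIFICATION:
        y = np.where(y_num > 0.5, ACTIVE, NONACTIVE).astype(object)
    else:
        y = y_num.astype(float)
    return LabeledDataset(
        X=sp.csr_matrix(X),
        y=y,
        assay_tag=np.asarray(assays, dtype=object),
        task=task,
        compound_ids=np.asarray(ids, dtype=object),
    )


# ---------------------------------------------------------------------------
# preparation rules
# ---------------------------------------------------------------------------


@dataclass
class PrepConfig:
    """Toggles for the preparation pipeline.

    ``max_ic50_um`` drops measurements above the experimental range (None
    disables the cap); ``artifact_ic50_um`` drops an over-represented
    artifact concentration such as 33.3 μM (None disables); ``dedup_policy``
    is one of "most_recent" (default), "median" or "keep_all" applied per
    (compound, assay) group.
    """

    activity_threshold_um: float = 10.0
    max_ic50_um: float | None = 100.0
    artifact_ic50_um: float | None = None
    dedup_policy: str = "most_recent"
    artifact_rel_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.activity_threshold_um <= 0:
            raise ValueError("activity threshold must be positive")
        if self.max_ic50_um is not None and not (
            self.activity_threshold_um < self.max_ic50_um
        ):
            raise ValueError("activity threshold must be below the IC50 cap")
        if self.dedup_policy not in ("most_recent", "median", "keep_all"):
            raise ValueError(f"unknown dedup policy {self.dedup_policy!r}")


def apply_filters(records, cfg: PrepConfig, task: str):
    """Apply the preparation rules in order; return ``(kept, audit)``.

    The audit is a list of ``(rule, compound_id)`` pairs, one entry per
    dropped record, so every drop is attributable to exactly one rule.
    Rules, in order: (1) IC50 above the experimental cap; (2) the artifact
    concentration; (3) deduplication per (compound, assay); (4) the task
    rule — regression keeps qualifier-free records only, classification
    drops records whose label is undetermined at the threshold.
    """
    audit: list[tuple[str, str]] = []
    kept = list(records)

    if cfg.max_ic50_um is not None:
        survivors = []
        for r in kept:
            if r.ic50_um > cfg.max_ic50_um:
                audit.append(("over_max_ic50", r.compound_id))
            else:
                survivors.append(r)
        kept = survivors

    if cfg.artifact_ic50_um is not None:
        tol = cfg.artifact_rel_tol * cfg.artifact_ic50_um
        survivors = []
        for r in kept:
            if abs(r.ic50_um - cfg.artifact_ic50_um) <= tol:
                audit.append(("artifact_ic50", r.compound_id))
            else:
                survivors.append(r)
        kept = survivors

    if cfg.dedup_policy != "keep_all":
        groups: dict[tuple[str, str], list[CompoundRecord]] = {}
        order: list[tuple[str, str]] = []
        for r in kept:
            key = (r.compound_id, r.assay.value)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(r)
        survivors = []
        for key in order:
            group = groups[key]
            if len(group) == 1:
                survivors.append(group[0])
                continue
            if cfg.dedup_policy == "most_recent":
                chosen = max(enumerate(group), key=lambda t: (t[1].test_date, t[0]))[1]
            else:  # median: lower-middle record by IC50
                chosen = sorted(group, key=lambda r: r.ic50_um)[(len(group) - 1) // 2]
            for r in group:
                if r is not chosen:
                    audit.append(("duplicate", r.compound_id))
            survivors.append(chosen)
        kept = survivors

    survivors = []
    for r in kept:
        if task == REGRESSION:
            if r.qualifier is not Qualifier.EXACT:
                audit.append(("qualifier_in_regression", r.compound_id))
                continue
        else:
            if label_activity(r, cfg.activity_threshold_um) == UNDETERMINED:
                audit.append(("undetermined_label", r.compound_id))
                continue
        survivors.append(r)
    return survivors, audit


def records_to_dataset(
    records: Sequence[CompoundRecord],
    task: str,
    threshold_um: float = 10.0,
    n_features: int | None = None,
) -> LabeledDataset:
    """Assemble already-filtered records into a :class:`LabeledDataset`."""
    if not records:
        raise EmptyDatasetError("no records to assemble")
    if n_features is None:
        n_features = 1 + max(
            (max(r.features) for r in records if r.features), default=-1
        )
    rows, cols, data = [], [], []
    for i, r in enumerate(records):
        for j, c in r.features.items():
            if c != 0:
                rows.append(i)
                cols.append(j)
                data.append(c)
    X = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(records), max(n_features, 1)), dtype=float
    )
    if task == REGRESSION:
        y = np.array([r.pic50 for r in records], dtype=float)
    else:
        y = np.array(
            [label_activity(r, threshold_um) for r in records], dtype=object
        )
    return LabeledDataset(
        X=X,
        y=y,
        assay_tag=np.array([r.assay.value for r in records], dtype=object),
        task=task,
        compound_ids=np.array([r.compound_id for r in records], dtype=object),
    )


def prepare_dataset(records, cfg: PrepConfig, task: str, n_features=None):
    """Filter records and build the labeled dataset; return ``(ds, audit)``.

    Raises :class:`EmptyDatasetError` if every record is filtered out.
    """
    kept, audit = apply_filters(records, cfg, task)
    if not kept:
        raise EmptyDatasetError("all records removed by the preparation rules")
    ds = records_to_dataset(kept, task, cfg.activity_threshold_um, n_features)
    return ds, audit


def format_audit(audit: Sequence[tuple[str, str]]) -> str:
    """Render the audit as plain text, one line per dropped record."""
    lines = [f"{rule}\t{cid}" for rule, cid in audit]
    counts: dict[str, int] = {}
    for rule, _ in audit:
        counts[rule] = counts.get(rule, 0) + 1
    summary = ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "none"
    return "\n".join(lines + [f"# dropped: {summary}"])
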