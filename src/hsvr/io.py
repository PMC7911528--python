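"""Data model, compound-table readers/writers, and model serialization.

Compound tables are plain CSV (comma-separated, UTF-8, header row, decimal
point).  The modeled response is log10 of the apparent permeability
coefficient P_app in cm/s; a schema flag converts a linear P_app column on
ingest.  Any extra numeric column of the table is retained as a precomputed
descriptor (DFT-derived quantities such as the dipole moment are expected to
arrive this way).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import joblib
import numpy as np
import pandas as pd

from . import errors
from ._version import FORMAT_VERSION, PACKAGE_VERSION

ROLES = ("train", "test", "outlier", "unassigned")
ION_CLASSES = ("acid", "base", "neutral", "zwitterion", "unknown")

REQUIRED_COLUMNS = ("id", "smiles", "log_papp")


@dataclass
class CompoundRecord:
    """One compound: identifier, structure, observed activity, bookkeeping."""

    id: str
    smiles: str | None = None
    log_papp: float | None = None
    cas: str | None = None
    role: str = "unassigned"
    ion_class: str = "unknown"

    def __post_init__(self):
        if self.role not in ROLES:
            raise errors.ValidationError(f"unknown role {self.role!r} for compound {self.id!r}")
        if self.ion_class not in ION_CLASSES:
            raise errors.ValidationError(
                f"unknown ion class {self.ion_class!r} for compound {self.id!r}"
            )
        if self.log_papp is not None and not np.isfinite(self.log_papp):
            raise errors.ValidationError(f"non-finite log_papp for compound {self.id!r}")


@dataclass
class CompoundSet:
    """Ordered collection of compounds plus any precomputed descriptor columns."""

    records: list[CompoundRecord]
    descriptors: pd.DataFrame | None = None
    provenance: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dupes:
            raise errors.ValidationError(f"duplicate compound id(s): {dupes}")
        if self.descriptors is not None:
            self.descriptors = self.descriptors.loc[ids]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def response(self) -> pd.Series:
        return pd.Series(
            [r.log_papp for r in self.records], index=self.ids, name="log_papp", dtype=float
        )

    def roles(self) -> pd.Series:
        return pd.Series([r.role for r in self.records], index=self.ids, name="role")

    def with_roles(self, role_map: Mapping[str, str]) -> "CompoundSet":
        recs = [
            CompoundRecord(
                id=r.id,
                smiles=r.smiles,
                log_papp=r.log_papp,
                cas=r.cas,
                role=role_map.get(r.id, r.role),
                ion_class=r.ion_class,
            )
            for r in self.records
        ]
        return CompoundSet(recs, descriptors=self.descriptors, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame(
            {
                "id": self.ids,
                "smiles": [r.smiles for r in self.records],
                "log_papp": [r.log_papp for r in self.records],
                "cas": [r.cas for r in self.records],
                "role": [r.role for r in self.records],
                "ion_class": [r.ion_class for r in self.records],
            }
        )
        if self.descriptors is not None and len(self.descriptors.columns):
            base = base.join(self.descriptors.reset_index(drop=True))
        return base


@dataclass
class PredictionSet:
    """Observed/predicted pairs for one dataset, with the training references
    needed by the external-validation coefficients."""

    observed: np.ndarray
    predicted: np.ndarray
    ids: list[str] | None = None
    label: str = ""
    train_mean: float | None = None  # <y_TR>, for qF1/qF3
    n_train: int | None = None  # n_TR, for qF3
    train_ss: float | None = None  # sum((y_TR - <y_TR>)^2), for qF3

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != self.predicted.shape:
            raise errors.ValidationError("observed and predicted vectors differ in length")

    def __len__(self) -> int:
        return len(self.observed)


def _as_buffer(source) -> IO | Path:
    if isinstance(source, (str, Path)):
        return Path(source)
    return source


def read_compound_table(
    source,
    schema: Mapping[str, str] | None = None,
    linear_papp: bool = False,
) -> CompoundSet:
    """Read a compound CSV into a :class:`CompoundSet`.

    ``schema`` maps canonical names (``id``, ``smiles``, ``log_papp``,
    ``cas``, ``role``, ``ion_class``) to the column names actually present.
    With ``linear_papp=True`` the response column holds linear P_app in cm/s
    and is converted to log10 on ingest.  Extra numeric columns are retained
    as precomputed descriptors; rows with unparsable response values raise
    with their row index rather than being dropped silently.
    """
    schema = dict(schema or {})
    frame = pd.read_csv(_as_buffer(source))
    rename = {v: k for k, v in schema.items() if v in frame.columns}
    frame = frame.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise errors.SchemaError(f"missing required column(s): {missing}")

    ids = frame["id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise errors.ValidationError(f"duplicate compound id(s): {dupes}")

    y = pd.to_numeric(frame["log_papp"], errors="coerce")
    bad = frame.index[frame["log_papp"].notna() & y.isna()].tolist()
    if bad:
        raise errors.ValidationError(f"non-numeric log_papp at row index(es) {bad}")
    if linear_papp:
        if (y.dropna() <= 0).any():
            raise errors.ValidationError("linear P_app values must be positive for log conversion")
        y = np.log10(y)

    known = set(REQUIRED_COLUMNS) | {"cas", "role", "ion_class"}
    extra = [c for c in frame.columns if c not in known]
    numeric_extra = []
    for c in extra:
        converted = pd.to_numeric(frame[c], errors="coerce")
        if converted.notna().any():
            numeric_extra.append(c)
    descriptors = None
    if numeric_extra:
        descriptors = frame[numeric_extra].apply(pd.to_numeric, errors="coerce")
        descriptors.index = pd.Index(ids, name="id")

    records = []
    for i in range(len(frame)):
        row = frame.iloc[i]
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                smiles=None if pd.isna(row["smiles"]) else str(row["smiles"]),
                log_papp=None if pd.isna(y.iloc[i]) else float(y.iloc[i]),
                cas=None if "cas" not in frame.columns or pd.isna(row.get("cas")) else str(row["cas"]),
                role=str(row["role"]) if "role" in frame.columns and not pd.isna(row.get("role")) else "unassigned",
                ion_class=str(row["ion_class"])
                if "ion_class" in frame.columns and not pd.isna(row.get("ion_class"))
                else "unknown",
            )
        )
    provenance = getattr(source, "name", str(source))
    return CompoundSet(records, descriptors=descriptors, provenance=f"read from {provenance}")


def write_compound_table(cset: CompoundSet, target) -> None:
    """Write a CompoundSet back to CSV (inverse of :func:`read_compound_table`)."""
    frame = cset.to_frame()
    frame.to_csv(_as_buffer(target), index=False)


def read_prediction_table(
    source, observed_col: str = "observed", predicted_col: str = "predicted"
) -> PredictionSet:
    """Read an observed/predicted CSV into a PredictionSet."""
    frame = pd.read_csv(_as_buffer(source))
    for col in (observed_col, predicted_col):
        if col not in frame.columns:
            raise errors.SchemaError(f"missing column {col!r} in prediction table")
    ids = frame["id"].astype(str).tolist() if "id" in frame.columns else None
    return PredictionSet(
        observed=frame[observed_col].to_numpy(float),
        predicted=frame[predicted_col].to_numpy(float),
        ids=ids,
    )


def save_model(model, path) -> None:
    """Serialize a fitted model with its normalization parameters and seed."""
    payload = {
        "format": "hsvr-model",
        "format_version": FORMAT_VERSION,
        "package_version": PACKAGE_VERSION,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path):
    """Load a model saved by :func:`save_model`; version-checked."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated / foreign file
        raise errors.IncompatibleModelError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "hsvr-model":
        raise errors.IncompatibleModelError(f"{path} is not an hsvr model artifact")
    if payload.get("format_version") != FORMAT_VERSION:
        raise errors.IncompatibleModelError(
            f"model format version {payload.get('format_version')} "
            f"incompatible with supported version {FORMAT_VERSION}"
        )
    return payload["model"]
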