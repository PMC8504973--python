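"""Titration series container and delimited-text input/output.

A :class:`TitrationSeries` holds one construct / modality / replicate's
ordered (pH, response) points.  Fluorescence series carry the denatured-
protein fluorescence ``F_SDS`` used for normalization; current series carry
per-application reference flags used for rundown correction.

The on-disk schema is a flat CSV/TSV with columns
``construct, modality, replicate, order, pH, response, is_reference, f_sds``;
validation errors report 1-based file line numbers (header on line 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TitrationSeries", "SchemaError", "read_titration_csv", "write_titration_csv"]

COLUMNS = ["construct", "modality", "replicate", "order", "pH", "response", "is_reference", "f_sds"]
MODALITIES = ("fluorescence", "current")


class SchemaError(ValueError):
    """A titration table violates the input schema."""


@dataclass
class TitrationSeries:
    construct: str
    modality: str
    replicate: str
    order: np.ndarray          # application index, ordered
    ph: np.ndarray
    response: np.ndarray
    is_reference: np.ndarray   # current only; all False for fluorescence
    f_sds: float | None = None  # fluorescence only, arbitrary units
    normalized: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.ph = np.asarray(self.ph, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.is_reference = np.asarray(self.is_reference, dtype=bool)
        n = self.ph.size
        if not (self.order.size == self.response.size == self.is_reference.size == n):
            raise ValueError("per-point arrays must have equal length")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if np.any(self.ph < 0) or np.any(self.ph > 14):
            raise ValueError("pH values must lie in [0, 14]")
        if self.modality == "fluorescence":
            if self.f_sds is not None and self.f_sds <= 0:
                raise ValueError("F_SDS must be positive")
            if self.is_reference.any():
                raise ValueError("reference flags apply to current series only")
        if int(np.sum(~self.is_reference)) < 4:
            raise ValueError("at least 4 non-reference points are required for fitting")

    @property
    def n_points(self) -> int:
        return int(self.ph.size)

    def test_points(self) -> "TitrationSeries":
        """Series restricted to non-reference applications."""
        keep = ~self.is_reference
        return replace(
            self,
            order=self.order[keep],
            ph=self.ph[keep],
            response=self.response[keep],
            is_reference=self.is_reference[keep],
            provenance=list(self.provenance),
        )

    def with_note(self, note: str) -> "TitrationSeries":
        out = replace(self, provenance=list(self.provenance) + [note])
        return out


def _fail(line: int, message: str) -> None:
    raise SchemaError(f"line {line}: {message}")


def read_titration_csv(path, sep: str | None = None) -> list[TitrationSeries]:
    """Read a titration table, validating the schema row by row.

    The delimiter is sniffed from the extension (``.tsv`` -> tab) unless
    given.  Returns one series per (construct, modality, replicate), points
    sorted by application order.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    lines = df.index.to_numpy() + 2  # header is line 1
    for i, line in enumerate(lines):
        row = df.iloc[i]
        if row["modality"] not in MODALITIES:
            _fail(line, f"modality must be one of {MODALITIES}, got {row['modality']!r}")
        ph = row["pH"]
        if not np.isfinite(ph) or not (0 <= ph <= 14):
            _fail(line, f"pH out of range [0, 14]: {ph!r}")
        if not np.isfinite(row["response"]):
            _fail(line, f"non-finite response: {row['response']!r}")
        if row["modality"] == "fluorescence":
            f_sds = row["f_sds"]
            if not np.isfinite(f_sds) or f_sds <= 0:
                _fail(line, f"fluorescence rows need f_sds > 0, got {f_sds!r}")

    out: list[TitrationSeries] = []
    for (construct, modality, replicate), grp in df.groupby(
        ["construct", "modality", "replicate"], sort=False
    ):
        grp = grp.sort_values("order")
        f_sds = None
        if modality == "fluorescence":
            values = grp["f_sds"].unique()
            if len(values) != 1:
                raise SchemaError(
                    f"series {construct}/{modality}/{replicate}: f_sds must be constant "
                    f"within a series, found {values!r}"
                )
            f_sds = float(values[0])
        is_ref = grp["is_reference"].fillna(False).astype(bool).to_numpy()
        try:
            out.append(
                TitrationSeries(
                    construct=str(construct),
                    modality=str(modality),
                    replicate=str(replicate),
                    order=grp["order"].to_numpy(),
                    ph=grp["pH"].to_numpy(),
                    response=grp["response"].to_numpy(),
                    is_reference=is_ref,
                    f_sds=f_sds,
                    provenance=[f"read from {path.name}"],
                )
            )
        except ValueError as exc:
            first = int(grp.index[0]) + 2
            raise SchemaError(
                f"series {construct}/{modality}/{replicate} (starting line {first}): {exc}"
            ) from exc
    return out


def write_titration_csv(series: list[TitrationSeries], path, sep: str = ",") -> None:
    """Write series back to the flat schema (one row per application)."""
    rows = []
    for s in series:
        for k in range(s.n_points):
            rows.append(
                {
                    "construct": s.construct,
                    "modality": s.modality,
                    "replicate": s.replicate,
                    "order": int(s.order[k]),
                    "pH": float(s.ph[k]),
                    "response": float(s.response[k]),
                    "is_reference": bool(s.is_reference[k]),
                    "f_sds": s.f_sds if s.f_sds is not None else np.nan,
                }
            )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep=sep, index=False)
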