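"""Tabular schema for the barley regenerant dataset.

Each row describes one anther-culture-derived regenerant: two integrated
mid-infrared absorbance areas (the 710-690 and 1010-940 cm^-1 windows, plus
their sum), the metAFLP quantitative characteristics (total demethylation DMV
and its CG/CHG context components, sequence variation SV, all percentages),
the culture trial (M1-M9) and the culture duration in days.

The 35-regenerant study table ships with the package and is returned by
:func:`load_fixture`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "COLUMNS",
    "TRIALS",
    "TIME_LEVELS",
    "RegenerantRecord",
    "Dataset",
    "SchemaError",
    "TableValidationError",
    "load_fixture",
    "read_table",
    "write_table",
]

COLUMNS = (
    "sample_no",
    "trial",
    "f710_690",
    "f1010_940",
    "f_combined",
    "dmv",
    "cg_dmv",
    "chg_dmv",
    "sv",
    "time_days",
)

TRIALS = frozenset(f"M{i}" for i in range(1, 10))
TIME_LEVELS = (21, 28, 35)

#: |f_combined - (f710_690 + f1010_940)| must not exceed this (inclusive).
F_SUM_TOL = 1e-4
#: |dmv - (cg_dmv + chg_dmv)| must not exceed this.
DMV_SUM_TOL = 5e-3


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class TableValidationError(ValueError):
    """One or more rows violate the record invariants."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class RegenerantRecord:
    """One regenerant: spectral integrals, metAFLP characteristics, design."""

    sample_no: int
    trial: str
    f710_690: float
    f1010_940: float
    f_combined: float
    dmv: float
    cg_dmv: float
    chg_dmv: float
    sv: float
    time_days: int

    def problems(self) -> list[str]:
        """Return a human-readable list of invariant violations (empty if valid)."""
        out: list[str] = []
        if self.sample_no <= 0:
            out.append(f"sample_no must be positive, got {self.sample_no}")
        if self.trial not in TRIALS:
            out.append(f"trial {self.trial!r} not in M1..M9")
        if self.time_days not in TIME_LEVELS:
            out.append(f"time_days {self.time_days} not in {TIME_LEVELS}")
        if abs(self.f_combined - (self.f710_690 + self.f1010_940)) > F_SUM_TOL + 1e-12:
            out.append(
                f"f_combined {self.f_combined} != f710_690 + f1010_940 "
                f"= {self.f710_690 + self.f1010_940:.6g} (tol {F_SUM_TOL})"
            )
        if abs(self.dmv - (self.cg_dmv + self.chg_dmv)) > DMV_SUM_TOL + 1e-12:
            out.append(
                f"dmv {self.dmv} != cg_dmv + chg_dmv "
                f"= {self.cg_dmv + self.chg_dmv:.6g} (tol {DMV_SUM_TOL})"
            )
        for name in ("f710_690", "f1010_940", "f_combined", "dmv", "cg_dmv", "chg_dmv", "sv"):
            if getattr(self, name) < 0:
                out.append(f"{name} must be >= 0, got {getattr(self, name)}")
        return out


@dataclass(frozen=True)
class Dataset:
    """An ordered, validated collection of :class:`RegenerantRecord`."""

    records: tuple[RegenerantRecord, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        """Raise :class:`TableValidationError` listing every offending row."""
        problems: list[str] = []
        seen: set[int] = set()
        for i, rec in enumerate(self.records, start=1):
            for p in rec.problems():
                problems.append(f"row {i}: {p}")
            if rec.sample_no in seen:
                problems.append(f"row {i}: duplicate sample_no {rec.sample_no}")
            seen.add(rec.sample_no)
        if problems:
            raise TableValidationError(problems)

    def to_frame(self) -> pd.DataFrame:
        """Return the dataset as a DataFrame in canonical column order."""
        return pd.DataFrame([vars(r) for r in self.records], columns=list(COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "Dataset":
        """Build and validate a Dataset from a DataFrame with the canonical columns."""
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        records = []
        for idx, row in enumerate(frame.itertuples(index=False), start=1):
            try:
                records.append(
                    RegenerantRecord(
                        sample_no=int(row.sample_no),
                        trial=str(row.trial),
                        f710_690=float(row.f710_690),
                        f1010_940=float(row.f1010_940),
                        f_combined=float(row.f_combined),
                        dmv=float(row.dmv),
                        cg_dmv=float(row.cg_dmv),
                        chg_dmv=float(row.chg_dmv),
                        sv=float(row.sv),
                        time_days=int(row.time_days),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"row {idx}: cannot parse cell ({exc})") from exc
        ds = cls(records=tuple(records), provenance=provenance)
        ds.validate()
        return ds


def load_fixture() -> Dataset:
    """Load the packaged 35-regenerant study table.

    The printed row-35 total demethylation value carries an obvious
    typographic space ("2.0 940"); it is stored as 2.0940, consistent with
    the column's fixed-point format and the context-additivity invariant.
    """
    text = resources.files("specmed.data").joinpath("table1.csv").read_text()
    frame = pd.read_csv(io.StringIO(text))
    return Dataset.from_frame(frame, provenance="packaged 35-regenerant study table")


def read_table(path, schema: dict[str, str] | None = None) -> Dataset:
    """Read a validated Dataset from a CSV file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row, comma separator, "." decimals.
    schema : dict, optional
        Mapping from canonical column names to the names used in the file,
        for files whose headers differ from the canonical schema.
    """
    frame = pd.read_csv(path)
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    for col in COLUMNS:
        if col == "trial":
            continue
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            rows = [str(i + 1) for i in frame.index[bad]]
            raise SchemaError(f"non-numeric cell(s) in column {col!r}, row(s) {', '.join(rows)}")
    return Dataset.from_frame(frame, provenance=str(path))


def write_table(dataset: Dataset, path) -> None:
    """Write a Dataset as CSV with deterministic column order and full precision."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")
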