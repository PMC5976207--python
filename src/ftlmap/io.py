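"""Table readers/writers and run configuration.

All tables are one record per row with a mandatory header, mirroring how
tetrad, foci and qPCR data are shared as supplementary spreadsheets.
Delimited text (comma or tab, auto-detected) and ``.xlsx`` workbooks are both
accepted.  Grain phenotypes are encoded as concatenated single-letter channel
labels (``"CY"``, ``"C"``, ``"-"`` for none), order-normalised on read.

Tetrad tables come in two mutually exclusive schemas:

* **grain schema** — columns ``grain1..grain4`` (plus ``tetrad_id``,
  ``genotype``, ``temperature``), one scored tetrad per row;
* **count schema** — columns ``PD``, ``T``, ``NPD`` (optional ``OTHER``,
  ``interval``, ``condition``), one pre-tabulated class table per row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from .classify import ClassCounts
from .synthetic import (
    FociRecord,
    MarkerMap,
    QpcrRecord,
    SimConfig,
    Tetrad,
    TetradDataset,
)

__all__ = [
    "TableFormatError",
    "read_tetrad_table",
    "write_tetrad_table",
    "read_class_counts",
    "write_class_counts",
    "read_foci_table",
    "write_foci_table",
    "read_qpcr_table",
    "write_qpcr_table",
    "RunConfig",
    "load_run_config",
]

_GRAIN_COLS = ("grain1", "grain2", "grain3", "grain4")
_COUNT_COLS = ("PD", "T", "NPD")
_GRAIN_RE = re.compile(r"^grain(\d+)$")
_PHENOTYPE_RE = re.compile(r"^(-|[A-Za-z]+)$")


class TableFormatError(ValueError):
    """Malformed or mixed-schema input table."""


def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path)
    # sep=None sniffs comma vs tab from the header line
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def _write_frame(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        frame.to_excel(path, index=False)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        frame.to_csv(path, index=False, sep=sep)


# ---------------------------------------------------------------------------
# Tetrad tables
# ---------------------------------------------------------------------------


def _parse_grain(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if not _PHENOTYPE_RE.match(cell):
        raise ValueError(f"bad grain phenotype {cell!r}")
    if cell == "-":
        return frozenset()
    letters = list(cell)
    if len(set(letters)) != len(letters):
        raise ValueError(f"repeated channel letter in {cell!r}")
    return frozenset(letters)


def _encode_grain(grain: frozenset[str], channel_order: Sequence[str]) -> str:
    if not grain:
        return "-"
    for ch in grain:
        if len(ch) != 1:
            raise TableFormatError(
                f"grain tables need single-letter channel labels, got {ch!r}"
            )
    ordered = [ch for ch in channel_order if ch in grain]
    extras = sorted(grain - set(channel_order))
    return "".join(ordered + extras)


def read_tetrad_table(path) -> list[Tetrad] | list[ClassCounts]:
    """Read a tetrad table, returning tetrads or pre-tabulated class counts.

    The schema is detected from the header.  Files mixing grain and count
    columns, or carrying a grain column beyond ``grain4``, are rejected with
    a :class:`TableFormatError`; malformed rows are rejected with their line
    numbers.
    """
    frame = _read_frame(path)
    cols = list(frame.columns)
    grain_cols = [c for c in cols if _GRAIN_RE.match(str(c))]
    has_counts = all(c in cols for c in _COUNT_COLS)
    extra = [c for c in grain_cols if int(_GRAIN_RE.match(str(c)).group(1)) > 4]
    if extra:
        raise TableFormatError(
            f"unexpected grain column(s) {extra}: a tetrad has exactly 4 grains"
        )
    if grain_cols and has_counts:
        raise TableFormatError(
            "mixed schema: table has both grain columns and PD/T/NPD columns"
        )
    if has_counts:
        return _counts_from_frame(frame)
    if sorted(grain_cols) != sorted(_GRAIN_COLS):
        raise TableFormatError(
            f"tetrad table needs columns {_GRAIN_COLS} or {_COUNT_COLS}; "
            f"got {cols}"
        )
    tetrads: list[Tetrad] = []
    bad_lines: list[int] = []
    for i, row in frame.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            grains = tuple(_parse_grain(str(row[c])) for c in _GRAIN_COLS)
        except ValueError:
            bad_lines.append(line_no)
            continue
        tetrads.append(
            Tetrad(
                grains=grains,
                genotype=str(row.get("genotype", "WT")),
                temperature=str(row.get("temperature", "")),
                tetrad_id=int(row["tetrad_id"]) if "tetrad_id" in frame.columns else line_no - 2,
            )
        )
    if bad_lines:
        raise TableFormatError(f"malformed grain phenotypes at lines {bad_lines}")
    return tetrads


def _counts_from_frame(frame: pd.DataFrame) -> list[ClassCounts]:
    out: list[ClassCounts] = []
    bad_lines: list[int] = []
    for i, row in frame.iterrows():
        try:
            out.append(
                ClassCounts(
                    PD=int(row["PD"]),
                    T=int(row["T"]),
                    NPD=int(row["NPD"]),
                    OTHER=int(row["OTHER"]) if "OTHER" in frame.columns and str(row["OTHER"]).strip() else 0,
                    interval=str(row.get("interval", "")),
                    condition=str(row.get("condition", "")),
                )
            )
        except (ValueError, TypeError):
            bad_lines.append(int(i) + 2)
    if bad_lines:
        raise TableFormatError(f"malformed count rows at lines {bad_lines}")
    return out


def write_tetrad_table(dataset, path, marker_map: MarkerMap | None = None) -> None:
    """Write tetrads in the grain schema (round-trips with the reader)."""
    if marker_map is None and isinstance(dataset, TetradDataset):
        marker_map = dataset.marker_map
    channel_order: Sequence[str] = marker_map.channels if marker_map else ()
    rows = []
    for t in dataset:
        order = channel_order or sorted(set().union(*t.grains))
        rows.append(
            {
                "tetrad_id": t.tetrad_id,
                "genotype": t.genotype,
                "temperature": t.temperature,
                **{
                    col: _encode_grain(g, order)
                    for col, g in zip(_GRAIN_COLS, t.grains)
                },
            }
        )
    frame = pd.DataFrame(
        rows, columns=["tetrad_id", "genotype", "temperature", *_GRAIN_COLS]
    )
    _write_frame(frame, path)


def read_class_counts(path) -> list[ClassCounts]:
    """Read a count-schema table (thin wrapper over :func:`read_tetrad_table`)."""
    result = read_tetrad_table(path)
    if result and not isinstance(result[0], ClassCounts):
        raise TableFormatError("expected a count-schema table (PD/T/NPD columns)")
    return result  # type: ignore[return-value]


def write_class_counts(counts: Iterable[ClassCounts], path) -> None:
    rows = [
        {
            "interval": c.interval,
            "condition": c.condition,
            "PD": c.PD,
            "T": c.T,
            "NPD": c.NPD,
            "OTHER": c.OTHER,
            "n": c.n,
        }
        for c in counts
    ]
    frame = pd.DataFrame(
        rows, columns=["interval", "condition", "PD", "T", "NPD", "OTHER", "n"]
    )
    _write_frame(frame, path)


# ---------------------------------------------------------------------------
# Foci and qPCR tables
# ---------------------------------------------------------------------------

_FOCI_COLS = ("cell_id", "genotype", "temperature", "antibody", "count")
_QPCR_COLS = ("sample_id", "treatment", "gene", "ct", "tech_rep")


def read_foci_table(path) -> list[FociRecord]:
    """Read per-cell focus counts (columns: cell_id, genotype, temperature,
    antibody, count)."""
    frame = _read_frame(path)
    missing = [c for c in _FOCI_COLS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"foci table missing column(s) {missing}")
    records: list[FociRecord] = []
    bad_lines: list[int] = []
    for i, row in frame.iterrows():
        try:
            records.append(
                FociRecord(
                    cell_id=int(row["cell_id"]),
                    genotype=str(row["genotype"]),
                    temperature=str(row["temperature"]),
                    antibody=str(row["antibody"]),
                    count=int(row["count"]),
                )
            )
        except (ValueError, TypeError):
            bad_lines.append(int(i) + 2)
    if bad_lines:
        raise TableFormatError(f"malformed foci rows at lines {bad_lines}")
    return records


def write_foci_table(records: Iterable[FociRecord], path) -> None:
    rows = [
        {
            "cell_id": r.cell_id,
            "genotype": r.genotype,
            "temperature": r.temperature,
            "antibody": r.antibody,
            "count": r.count,
        }
        for r in records
    ]
    _write_frame(pd.DataFrame(rows, columns=list(_FOCI_COLS)), path)


def read_qpcr_table(path) -> list[QpcrRecord]:
    """Read raw CT wells (columns: sample_id, treatment, gene, ct, tech_rep)."""
    frame = _read_frame(path)
    missing = [c for c in _QPCR_COLS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"qPCR table missing column(s) {missing}")
    records: list[QpcrRecord] = []
    bad_lines: list[int] = []
    for i, row in frame.iterrows():
        try:
            records.append(
                QpcrRecord(
                    sample_id=str(row["sample_id"]),
                    treatment=str(row["treatment"]),
                    gene=str(row["gene"]),
                    ct=float(row["ct"]),
                    tech_rep=int(row["tech_rep"]),
                )
            )
        except (ValueError, TypeError):
            bad_lines.append(int(i) + 2)
    if bad_lines:
        raise TableFormatError(f"malformed qPCR rows at lines {bad_lines}")
    return records


def write_qpcr_table(records: Iterable[QpcrRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "treatment": r.treatment,
            "gene": r.gene,
            "ct": r.ct,
            "tech_rep": r.tech_rep,
        }
        for r in records
    ]
    _write_frame(pd.DataFrame(rows, columns=list(_QPCR_COLS)), path)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a pipeline run.

    ``scenarios`` drive the simulator (one genotype × temperature cell each);
    ``sim`` holds :class:`SimConfig` overrides shared by all scenarios.
    Temperatures and treatments are opaque labels — nothing ever computes on
    the numeric value of a condition.
    """

    marker_map: MarkerMap
    mode: str = "two-color"
    conditions: tuple[str, ...] = ("20C", "28C")
    scenarios: tuple[dict, ...] = ()
    sim: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("two-color", "three-color"):
            raise ValueError("mode must be 'two-color' or 'three-color'")
        need = 2 if self.mode == "two-color" else 3
        if len(self.marker_map.markers) != need:
            raise ValueError(
                f"{self.mode} mode needs {need} markers, "
                f"got {len(self.marker_map.markers)}"
            )
        if not self.conditions:
            raise ValueError("at least one condition label is required")
        unknown = set(self.sim) - set(SimConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown sim option(s): {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    try:
        markers = raw["markers"]
    except KeyError:
        raise ValueError("config must define 'markers'") from None
    marker_map = MarkerMap.from_tuples(
        (m["name"], m["channel"], float(m["position_cM"])) for m in markers
    )
    return RunConfig(
        marker_map=marker_map,
        mode=raw.get("mode", "two-color" if len(markers) == 2 else "three-color"),
        conditions=tuple(raw.get("conditions", ("20C", "28C"))),
        scenarios=tuple(raw.get("scenarios", ())),
        sim=dict(raw.get("sim", {})),
        qpcr=dict(raw.get("qpcr", {})),
        seed=int(raw.get("seed", 0)),
    )
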