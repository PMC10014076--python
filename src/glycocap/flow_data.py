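"""Reading, transforming and assembling single-cell fluorescence data.

The entry point for a real experiment is a set of acquisition files (FCS 3.0/3.1
list-mode or per-cell CSV) plus a sample sheet mapping each file to a condition
(receptor genotype, ligand, dose, replicate).  :func:`assemble_dataset` turns
those into one :class:`DoseResponseDataset` per (receptor, ligand, replicate) —
the central object consumed by the capacity, noise and dose-response stages.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    DuplicationError,
    FormatError,
    LinkageError,
    SampleSizeError,
    SchemaError,
    UnsupportedVersionError,
)

__all__ = [
    "EventTable",
    "SampleSheet",
    "DoseResponseDataset",
    "BeadCalibration",
    "read_fcs",
    "read_events_csv",
    "read_sample_sheet",
    "transform_intensity",
    "assemble_dataset",
    "summarize_population",
    "fit_bead_calibration",
    "calibrate_fi_to_molecules",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "receptor",
    "ligand",
    "dose",
    "dose_unit",
    "replicate",
    "stimulation_hours",
    "output_channel",
]

# Minimum cells per dose for capacity estimation (enforced downstream).
MIN_CELLS_FOR_CAPACITY = 50


@dataclass
class EventTable:
    """Per-cell channel intensities for one acquired sample.

    ``events`` is an (n_cells, n_channels) float array in arbitrary
    fluorescence units; no transform is applied at read time.
    """

    sample_id: str
    channels: list[str]
    events: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise DomainError("events must be a 2-D (cells x channels) array")
        if self.events.shape[1] != len(self.channels):
            raise DomainError(
                f"events has {self.events.shape[1]} columns but "
                f"{len(self.channels)} channel names were given"
            )

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the intensity column for one named channel."""
        try:
            j = self.channels.index(name)
        except ValueError:
            raise SchemaError(
                f"channel {name!r} not in sample {self.sample_id!r}: "
                f"available {self.channels}"
            ) from None
        return self.events[:, j]


@dataclass
class SampleSheet:
    """Experimental design table linking samples to conditions and doses."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"sample sheet missing columns: {missing}")
        t = self.table
        if (t["dose"] < 0).any():
            raise DomainError("doses must be non-negative")
        if (t["replicate"] < 1).any():
            raise DomainError("replicate indices must be >= 1")
        if (t["stimulation_hours"] <= 0).any():
            raise DomainError("stimulation_hours must be positive")
        key = t[["receptor", "ligand", "replicate", "dose"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise DuplicationError(
                "duplicate (receptor, ligand, replicate, dose): "
                f"{tuple(dup)}"
            )
        # at most one zero dose per condition
        zeros = t[t["dose"] == 0].groupby(["receptor", "ligand", "replicate"]).size()
        if (zeros > 1).any():
            raise DuplicationError("more than one zero dose in a condition")

    def conditions(self) -> list[tuple[str, str, int]]:
        seen: list[tuple[str, str, int]] = []
        for _, row in self.table.iterrows():
            c = (row["receptor"], row["ligand"], int(row["replicate"]))
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class DoseResponseDataset:
    """Ordered dose series with per-cell transformed outputs at each dose.

    This is the communication-channel view of one condition: ``doses`` is the
    input alphabet X (including the unstimulated dose 0 when measured) and
    ``outputs_per_dose[i]`` holds the single-cell output values Y at dose i,
    already on the transform scale recorded in ``transform_tag``.
    """

    condition: tuple[str, str, int]
    doses: np.ndarray
    outputs_per_dose: list[np.ndarray]
    transform_tag: str = "identity"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.ndim != 1 or len(self.doses) != len(self.outputs_per_dose):
            raise DomainError("doses and outputs_per_dose lengths differ")
        if np.any(np.diff(self.doses) <= 0):
            raise DomainError("doses must be strictly increasing")
        if np.any(self.doses < 0):
            raise DomainError("doses must be non-negative")
        cleaned = []
        for d, y in zip(self.doses, self.outputs_per_dose):
            y = np.asarray(y, dtype=float)
            if y.size < 1:
                raise SampleSizeError(f"dose {d} has no cells")
            if not np.all(np.isfinite(y)):
                raise DomainError(f"non-finite output values at dose {d}")
            cleaned.append(y)
        self.outputs_per_dose = cleaned

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @property
    def cells_per_dose(self) -> np.ndarray:
        return np.array([len(y) for y in self.outputs_per_dose])

    def pooled_outputs(self) -> np.ndarray:
        return np.concatenate(self.outputs_per_dose)

    def restrict_to_prefix(self, k: int) -> "DoseResponseDataset":
        """Dataset truncated to the first ``k`` doses (lowest concentrations)."""
        if not 2 <= k <= self.n_doses:
            raise DomainError(f"prefix length {k} outside [2, {self.n_doses}]")
        return DoseResponseDataset(
            condition=self.condition,
            doses=self.doses[:k],
            outputs_per_dose=self.outputs_per_dose[:k],
            transform_tag=self.transform_tag,
        )


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 reading (list-mode, datatypes F/D/I)
# ---------------------------------------------------------------------------

_SUPPORTED_FCS_VERSIONS = (b"FCS3.0", b"FCS3.1")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    parts = raw[1:].split(delim)
    # trailing delimiter leaves an empty last element
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    kw: dict[str, str] = {}
    for k, v in zip(parts[0::2], parts[1::2]):
        kw[k.decode("utf-8", "replace").strip()] = v.decode("utf-8", "replace")
    return kw


def read_fcs(path) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Supports float (F), double (D) and unsigned-integer (I) data segments.
    Log-amplified parameters (``$PnE = d,f`` with ``d > 0``) are converted to
    linear scale as ``f * 10**(d * x / $PnR)`` per the FCS keyword convention.
    TEXT-segment keywords are preserved in ``metadata``.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FormatError(f"file too short for an FCS header (byte offset {len(blob)})")
    version = blob[0:6]
    if not version.startswith(b"FCS"):
        raise FormatError("not an FCS file: missing 'FCS' magic at byte offset 0")
    if version not in _SUPPORTED_FCS_VERSIONS:
        raise UnsupportedVersionError(
            f"unsupported FCS version {version.decode('ascii', 'replace')!r}; "
            "only FCS3.0 and FCS3.1 are supported"
        )

    def _offset(a: int, b: int) -> int:
        txt = blob[a:b].strip()
        try:
            return int(txt) if txt else 0
        except ValueError:
            raise FormatError(f"bad header offset field at byte offset {a}") from None

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if text_end >= len(blob) or text_start >= text_end:
        raise FormatError(f"TEXT segment out of bounds at byte offset {text_start}")
    kw = _parse_text_segment(blob[text_start : text_end + 1])

    if data_start == 0 or data_end == 0:
        data_start = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise UnsupportedVersionError(f"only list-mode ($MODE=L) supported, got {mode!r}")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    endian = "<" if little else ">"

    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FormatError("$DATATYPE F requires 32-bit parameters")
        fmt = endian + "f"
        width = 4
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FormatError("$DATATYPE D requires 64-bit parameters")
        fmt = endian + "d"
        width = 8
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise UnsupportedVersionError(
                "integer data only supported with uniform 16- or 32-bit parameters"
            )
        fmt = endian + ("H" if bits[0] == 16 else "I")
        width = bits[0] // 8
    else:
        raise UnsupportedVersionError(f"unsupported $DATATYPE {datatype!r}")

    expected = n_tot * n_par * width
    raw = blob[data_start : data_end + 1]
    if len(raw) < expected:
        raise FormatError(
            f"DATA segment truncated: need {expected} bytes for $TOT={n_tot} events "
            f"but segment ending at byte offset {data_end} holds {len(raw)}"
        )
    flat = np.frombuffer(raw[:expected], dtype=np.dtype(fmt))
    events = flat.reshape(n_tot, n_par).astype(float)

    # de-log amplified parameters: $PnE = "decades,offset"
    for i in range(n_par):
        pne = kw.get(f"$P{i + 1}E", "0,0")
        try:
            decades, offset = (float(x) for x in pne.split(","))
        except ValueError:
            raise FormatError(f"malformed $P{i + 1}E keyword {pne!r}") from None
        if decades > 0:
            rng = float(kw.get(f"$P{i + 1}R", "1024"))
            if offset <= 0:
                offset = 1.0  # common writer quirk: f1>0 with f2=0 means f2=1
            events[:, i] = offset * 10.0 ** (decades * events[:, i] / rng)

    sample_id = kw.get("$FIL", str(path))
    return EventTable(sample_id=sample_id, channels=names, events=events, metadata=kw)


def read_events_csv(path, channel_columns: list[str]) -> EventTable:
    """Read a per-cell events CSV (header row, one row per cell)."""
    df = pd.read_csv(path)
    missing = [c for c in channel_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"events CSV missing columns: {missing}")
    cols = []
    for c in channel_columns:
        numeric = pd.to_numeric(df[c], errors="coerce")
        bad = numeric.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"non-numeric value {df[c].iloc[row]!r} in column {c!r} at data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise SchemaError(f"missing value in column {c!r} at data row {row}")
        cols.append(numeric.to_numpy(dtype=float))
    events = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return EventTable(
        sample_id=str(path), channels=list(channel_columns), events=events
    )


def read_sample_sheet(path) -> SampleSheet:
    """Read and validate a sample-sheet CSV."""
    return SampleSheet(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Transforms and assembly
# ---------------------------------------------------------------------------


def transform_intensity(values, method: str = "log10_floor", cofactor: float | None = None):
    """Transform raw fluorescence intensities onto an analysis scale.

    ``log10_floor`` replaces values <= 0 by half the smallest positive value in
    the collection before taking log10 (fluorescence spans decades and baseline
    subtraction can produce non-positive events).  ``arcsinh`` applies
    asinh(v / cofactor).  ``identity`` returns the values unchanged.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DomainError("input intensities must be finite")
    if method == "identity":
        return v.copy()
    if method == "arcsinh":
        if cofactor is None or cofactor <= 0:
            raise DomainError("arcsinh requires a positive cofactor")
        return np.arcsinh(v / cofactor)
    if method == "log10_floor":
        positive = v[v > 0]
        if positive.size == 0:
            raise DomainError("log10_floor: no positive values in input")
        floor = positive.min() / 2.0
        return np.log10(np.where(v > 0, v, floor))
    raise DomainError(f"unknown transform method {method!r}")


def _transform_tag(method: str, cofactor: float | None) -> str:
    if method == "arcsinh":
        return f"arcsinh(cofactor={cofactor:g})"
    return method


def assemble_dataset(
    sheet: SampleSheet,
    tables: dict[str, EventTable],
    transform: str = "log10_floor",
    cofactor: float | None = None,
) -> list[DoseResponseDataset]:
    """Build one :class:`DoseResponseDataset` per (receptor, ligand, replicate).

    The transform is applied per condition on the pooled values across doses,
    so the ``log10_floor`` floor is a single per-dataset constant.
    """
    datasets = []
    t = sheet.table
    for (receptor, ligand, replicate), grp in t.groupby(
        ["receptor", "ligand", "replicate"], sort=False
    ):
        grp = grp.sort_values("dose")
        raw_per_dose = []
        for _, row in grp.iterrows():
            sid = row["sample_id"]
            if sid not in tables:
                raise LinkageError(
                    f"sample sheet references {sid!r} but no such table was provided"
                )
            table = tables[sid]
            if table.n_events == 0:
                raise SampleSizeError(f"sample {sid!r} has no events")
            raw_per_dose.append(table.channel(row["output_channel"]))
        pooled = np.concatenate(raw_per_dose)
        transformed = transform_intensity(pooled, transform, cofactor)
        splits = np.cumsum([len(v) for v in raw_per_dose])[:-1]
        outputs = np.split(transformed, splits)
        datasets.append(
            DoseResponseDataset(
                condition=(receptor, ligand, int(replicate)),
                doses=grp["dose"].to_numpy(dtype=float),
                outputs_per_dose=outputs,
                transform_tag=_transform_tag(transform, cofactor),
            )
        )
    return datasets


def summarize_population(values) -> tuple[float, float]:
    """Geometric mean and robust SD of a positive-valued cell population.

    The robust SD is the scaled median absolute deviation (MAD x 1.4826) of
    ln(values), reported as a multiplicative factor exp(.), so
    (gm / factor, gm * factor) brackets the bulk of the population.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise DomainError("summarize_population requires finite positive values")
    lv = np.log(v)
    gm = float(np.exp(lv.mean()))
    mad = float(np.median(np.abs(lv - np.median(lv))))
    return gm, float(np.exp(1.4826 * mad))


# ---------------------------------------------------------------------------
# Bead calibration (fluorescence intensity -> molecule counts)
# ---------------------------------------------------------------------------


@dataclass
class BeadCalibration:
    """Log-log linear calibration from measured FI to molecule counts."""

    standards: np.ndarray  # (k, 2): measured_fi, molecules
    slope: float
    intercept: float
    fit_scale: str = "log-log"


def fit_bead_calibration(standards) -> BeadCalibration:
    """Least-squares line of log10(molecules) on log10(measured FI)."""
    s = np.asarray(standards, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
        raise DomainError("calibration needs >= 2 (measured_fi, molecules) standards")
    if np.any(s <= 0):
        raise DomainError("calibration standards must be positive")
    x, y = np.log10(s[:, 0]), np.log10(s[:, 1])
    slope, intercept = np.polyfit(x, y, 1)
    if not np.isfinite(slope):
        raise DomainError("calibration fit produced a non-finite slope")
    return BeadCalibration(standards=s, slope=float(slope), intercept=float(intercept))


def calibrate_fi_to_molecules(cal: BeadCalibration, values):
    """Predict molecule counts from measured fluorescence intensities."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise DomainError("calibration applies to positive intensities only")
    return 10.0 ** (cal.intercept + cal.slope * np.log10(v))
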