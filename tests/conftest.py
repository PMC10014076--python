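"""Shared fixtures: programmatic FCS writing and small synthetic datasets."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from glycocap.flow_data import DoseResponseDataset


def write_fcs(
    path,
    channels: list[str],
    events: np.ndarray,
    version: bytes = b"FCS3.0",
    tot_override: int | None = None,
    extra_keywords: dict[str, str] | None = None,
    truncate_data: int = 0,
) -> None:
    """Write a minimal FCS 3.0/3.1 list-mode file (float32 data)."""
    events = np.asarray(events, dtype="<f4")
    n_tot, n_par = events.shape
    assert n_par == len(channels)
    kw = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(tot_override if tot_override is not None else n_tot),
    }
    for i, name in enumerate(channels, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"
    if extra_keywords:
        kw.update(extra_keywords)
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    text_bytes = text.encode("ascii")
    data_bytes = events.tobytes()
    if truncate_data:
        data_bytes = data_bytes[:-truncate_data]
    text_start = 58
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + len(data_bytes) - 1
    header = version + b" " * 4
    for off in (text_start, text_end, data_start, data_end, 0, 0):
        header += f"{off:>8d}".encode("ascii")
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header + text_bytes + data_bytes)


@pytest.fixture
def fcs_writer():
    return write_fcs


def make_dataset(outputs_per_dose, doses=None, tag="identity"):
    """DoseResponseDataset from a list of per-dose arrays."""
    if doses is None:
        doses = np.arange(len(outputs_per_dose), dtype=float)
    return DoseResponseDataset(
        condition=("test", "test", 1),
        doses=np.asarray(doses, dtype=float),
        outputs_per_dose=[np.asarray(y, dtype=float) for y in outputs_per_dose],
        transform_tag=tag,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
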