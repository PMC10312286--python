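"""Reading ROI time series, event tables, censor lists and atlas tables,
and extracting condition-specific trial epochs.

All on-disk formats are plain tab-separated text (UTF-8, decimal point):

* time-series TSV — one header row of ROI ids, one body row per TR;
* events TSV — columns ``onset_tr``, ``condition``, ``correct``;
* censor file — one censored TR index per line;
* atlas TSV — columns ``node_id``, ``label``, ``hemisphere``, ``x``,
  ``y``, ``z``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("neutral", "disgusted")


class InputFormatError(ValueError):
    """Raised when an on-disk input file violates the expected format."""


@dataclass
class RoiTimeSeries:
    """One subject's ROI-averaged signal matrix with censor metadata.

    Parameters
    ----------
    subject_id
        Identifier of the scanned subject.
    data
        Signal array of shape ``(n_trs, n_rois)`` in percent-signal-change
        units.
    tr_seconds
        Repetition time of the acquisition, in seconds.
    roi_ids
        Ordered atlas node identifiers, one per column of ``data``.
    censored_trs
        TR indices flagged for motion (dropped from epochs, never
        interpolated).
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0
    roi_ids: Sequence[str] = ()
    censored_trs: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("time-series data must be a 2-D array with >= 1 TR")
        if not self.roi_ids:
            self.roi_ids = [f"roi{j}" for j in range(self.data.shape[1])]
        self.roi_ids = list(self.roi_ids)
        if len(self.roi_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.roi_ids)} ROI ids for {self.data.shape[1]} columns"
            )
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("duplicate ROI ids")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.censored_trs = frozenset(int(t) for t in self.censored_trs)
        bad = [t for t in self.censored_trs if not 0 <= t < self.n_trs]
        if bad:
            raise ValueError(f"censored TR indices out of range: {sorted(bad)}")

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class EventTable:
    """Ordered trial events: ``(onset_tr, condition, correct)`` triples."""

    trials: list[tuple[int, str, bool]]

    def __post_init__(self) -> None:
        self.trials = [(int(t), str(c), bool(k)) for t, c, k in self.trials]
        onsets = [t for t, _, _ in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        bad = {c for _, c, _ in self.trials} - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class AtlasTable:
    """Atlas node table: id, label, hemisphere and coordinates per node."""

    nodes: list[tuple[str, str, str, float, float, float]]

    def __post_init__(self) -> None:
        ids = [n[0] for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atlas node ids")

    @property
    def node_ids(self) -> list[str]:
        return [n[0] for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)


def read_timeseries(
    path: str | Path,
    censor_path: str | Path | None = None,
    subject_id: str | None = None,
    tr_seconds: float = 2.0,
) -> RoiTimeSeries:
    """Read a TR x ROI time-series TSV, optionally with a censor list.

    The header row carries the ROI ids; every body row must have exactly
    one numeric value per ROI. Column order is preserved.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise InputFormatError(f"{path}: empty time-series table")
        roi_ids = header.split("\t")
        if len(set(roi_ids)) != len(roi_ids):
            dupes = sorted({c for c in roi_ids if roi_ids.count(c) > 1})
            raise InputFormatError(f"{path}: duplicate ROI headers {dupes}")
        for rowno, line in enumerate(fh):
            n_fields = line.rstrip("\n").count("\t") + 1
            if line.strip() and n_fields != len(roi_ids):
                raise InputFormatError(
                    f"{path}: row {rowno} has {n_fields} fields for "
                    f"{len(roi_ids)} header columns"
                )
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, names=roi_ids,
                     float_precision="round_trip")
    if df.shape[0] < 1:
        raise InputFormatError(f"{path}: empty time-series table")
    try:
        data = df.to_numpy(dtype=float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise InputFormatError(
                    f"{path}: non-numeric cell at row {row}, column {col!r}"
                ) from None
        raise
    if np.isnan(data).any():
        r, c = np.argwhere(np.isnan(data))[0]
        raise InputFormatError(
            f"{path}: missing value at row {int(r)}, column {roi_ids[int(c)]!r}"
        )
    censored: frozenset[int] = frozenset()
    if censor_path is not None:
        censored = frozenset(read_censor(censor_path))
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        data=data,
        tr_seconds=tr_seconds,
        roi_ids=roi_ids,
        censored_trs=censored,
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a time series back to the TSV format ``read_timeseries`` reads.

    Values are serialized with ``repr`` round-trip precision so a
    write -> read cycle is bitwise lossless.
    """
    df = pd.DataFrame(ts.data, columns=list(ts.roi_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_censor(path: str | Path) -> list[int]:
    """Read a censor file: one censored TR index per line (blank lines ok)."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            out.append(int(line))
        except ValueError:
            raise InputFormatError(
                f"{path}: line {lineno}: expected a TR index, got {line!r}"
            ) from None
    return out


def read_events(path: str | Path) -> EventTable:
    """Read a trial event TSV with columns onset_tr, condition, correct."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0)
    required = {"onset_tr", "condition", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    correct = df["correct"]
    if correct.dtype == object:
        correct = correct.astype(str).str.lower().isin(("1", "true", "yes"))
    trials = [
        (int(t), str(c), bool(k))
        for t, c, k in zip(df["onset_tr"], df["condition"], correct)
    ]
    return EventTable(trials=trials)


def write_events(events: EventTable, path: str | Path) -> None:
    df = pd.DataFrame(events.trials, columns=["onset_tr", "condition", "correct"])
    df["correct"] = df["correct"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_atlas(path: str | Path, expected_n: int | None = None) -> AtlasTable:
    """Read an atlas node TSV (node_id, label, hemisphere, x, y, z)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0)
    required = ["node_id", "label", "hemisphere", "x", "y", "z"]
    missing = set(required) - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    nodes = [
        (str(r.node_id), str(r.label), str(r.hemisphere), float(r.x), float(r.y), float(r.z))
        for r in df.itertuples()
    ]
    table = AtlasTable(nodes=nodes)
    if expected_n is not None and len(table) != expected_n:
        raise InputFormatError(
            f"{path}: expected {expected_n} atlas nodes, found {len(table)}"
        )
    return table


class EmptyEpochError(ValueError):
    """No trial of the requested condition survives epoch extraction."""


def extract_condition_epochs(
    ts: RoiTimeSeries,
    events: EventTable,
    condition: str,
    trs_per_trial: int = 4,
) -> np.ndarray:
    """Concatenate the per-trial TR windows of one condition.

    For every correct trial of ``condition`` the window
    ``[onset_tr, onset_tr + trs_per_trial - 1]`` is taken (the onset TR is
    the first TR acquired while the object is on screen), censored TRs
    inside the window are dropped without interpolation, and the surviving
    rows are concatenated in trial order.

    Returns
    -------
    numpy.ndarray
        Array of shape ``(n_surviving_trs, n_rois)``.

    Raises
    ------
    EmptyEpochError
        If no TR of any matching trial survives.
    IndexError
        If a selected trial's window extends past the end of the scan.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if trs_per_trial < 1:
        raise ValueError("trs_per_trial must be >= 1")
    trials = sorted(events.trials, key=lambda t: t[0])
    rows: list[int] = []
    for onset, cond, correct in trials:
        if cond != condition or not correct:
            continue
        stop = onset + trs_per_trial
        if onset < 0 or stop > ts.n_trs:
            raise IndexError(
                f"trial window [{onset}, {stop - 1}] exceeds scan of {ts.n_trs} TRs"
            )
        window = [t for t in range(onset, stop) if t not in ts.censored_trs]
        if not window:
            logger.warning(
                "subject %s: trial at TR %d lost all %d TRs to censoring; skipped",
                ts.subject_id, onset, trs_per_trial,
            )
            continue
        rows.extend(window)
    if not rows:
        raise EmptyEpochError(
            f"subject {ts.subject_id}: no surviving TRs for condition {condition!r}"
        )
    return ts.data[rows, :]
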