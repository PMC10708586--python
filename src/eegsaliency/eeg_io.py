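"""Reading, writing and preparing 14-channel Emotiv EPOC EEG records.

The on-disk dialect is the public MindBigData line format: one line per
(event, channel) with tab-separated fields

    id <TAB> event <TAB> device <TAB> channel <TAB> code <TAB> size <TAB> data

where ``data`` is a comma-separated list of voltage samples and ``code`` is
the digit shown during the recording (-1 for unlabeled).  Lines sharing an
event id are grouped into one record; the 14 channel rows are ordered
left-hemisphere then right (AF3...O1, AF4...O2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Emotiv EPOC electrode names, left hemisphere then right.
CHANNEL_NAMES = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "AF4", "F8", "F4", "FC6", "T8", "P8", "O2",
)

N_CHANNELS = 14
SAMPLING_RATE = 128.0
TARGET_SAMPLES = 250  # samples per channel used for processing
UNLABELED = "unlabeled"


class ParseError(ValueError):
    """A malformed line in a MindBigData-dialect file."""


@dataclass
class EEGRecord:
    """One labeled multichannel EEG trial.

    ``signal`` is (channels, time) in microvolts; ``label`` is a digit 0-9
    or the string "unlabeled"; ``synthetic`` marks generator-made records.
    """

    signal: np.ndarray
    label: int | str = UNLABELED
    record_id: str = ""
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    sampling_rate: float = SAMPLING_RATE
    synthetic: bool = False

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def validate(self, n_samples: int | None = None) -> "EEGRecord":
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"record {self.record_id!r}: {self.signal.shape[0]} signal rows "
                f"for {len(self.channel_names)} channel names"
            )
        if len(self.channel_names) != N_CHANNELS:
            raise ValueError(
                f"record {self.record_id!r}: expected {N_CHANNELS} channels, "
                f"got {len(self.channel_names)}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.label != UNLABELED and self.label not in range(10):
            raise ValueError(f"label must be 0..9 or {UNLABELED!r}, got {self.label!r}")
        if n_samples is not None and self.n_samples != n_samples:
            raise ValueError(
                f"record {self.record_id!r}: {self.n_samples} samples, "
                f"expected {n_samples}"
            )
        return self


@dataclass
class DatasetManifest:
    """Per-class record counts for a dataset."""

    counts: dict = field(default_factory=dict)
    source: str = "synthetic"

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_table(self) -> str:
        lines = ["class\tcount"]
        for cls in sorted(self.counts, key=str):
            lines.append(f"{cls}\t{self.counts[cls]}")
        lines.append(f"total\t{self.total}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# MindBigData dialect I/O
# ---------------------------------------------------------------------------

def read_mindbig_tsv(path) -> list[EEGRecord]:
    """Parse a MindBigData-dialect TSV into validated records.

    Lines are grouped by event id; events missing any of the 14 channels
    are dropped with a warning.  Unknown channel labels are skipped with a
    warning; structurally malformed lines raise :class:`ParseError`.
    """
    path = Path(path)
    events: dict[str, dict[str, np.ndarray]] = {}
    codes: dict[str, int] = {}
    flags: dict[str, bool] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, "
                    f"got {len(fields)}"
                )
            _id, event, device, channel, code, size, data = fields
            if channel not in CHANNEL_NAMES:
                logger.warning("%s:%d: unknown channel %r skipped", path, lineno, channel)
                continue
            try:
                code_i = int(code)
                samples = np.array([float(v) for v in data.split(",")], dtype=float)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if int(size) != samples.size:
                raise ParseError(
                    f"{path}:{lineno}: declared size {size} != {samples.size} samples"
                )
            if event not in events:
                events[event] = {}
                order.append(event)
            events[event][channel] = samples
            codes[event] = code_i
            flags[event] = flags.get(event, False) or device.endswith("-SYN")
    records = []
    for event in order:
        chans = events[event]
        missing = [c for c in CHANNEL_NAMES if c not in chans]
        if missing:
            logger.warning(
                "event %s dropped: missing channels %s", event, ",".join(missing)
            )
            continue
        lengths = {chans[c].size for c in CHANNEL_NAMES}
        n = min(lengths)
        signal = np.stack([chans[c][:n] for c in CHANNEL_NAMES])
        label = codes[event] if codes[event] >= 0 else UNLABELED
        records.append(
            EEGRecord(
                signal, label=label, record_id=event, synthetic=flags[event]
            ).validate()
        )
    return records


def write_mindbig_tsv(records: list[EEGRecord], path) -> Path:
    """Write records in the MindBigData dialect (full decimal precision).

    Synthetic records are flagged through a ``-SYN`` suffix on the device
    field so provenance survives a round trip.
    """
    path = Path(path)
    with open(path, "w") as fh:
        line_id = 0
        for rec in records:
            rec.validate()
            code = rec.label if rec.label != UNLABELED else -1
            device = "EP" + ("-SYN" if rec.synthetic else "")
            for ch_name, row in zip(rec.channel_names, rec.signal):
                data = ",".join(repr(float(v)) for v in row)
                fh.write(
                    f"{line_id}\t{rec.record_id}\t{device}\t{ch_name}\t{code}\t"
                    f"{row.size}\t{data}\n"
                )
                line_id += 1
    return path


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

def trim_record(record: EEGRecord, n_samples: int = TARGET_SAMPLES) -> EEGRecord:
    """Keep the first ``n_samples`` samples of every channel."""
    if record.n_samples < n_samples:
        raise ValueError(
            f"record {record.record_id!r} has {record.n_samples} samples, "
            f"needs >= {n_samples}"
        )
    return replace(record, signal=record.signal[:, :n_samples].copy())


def normalize_record(record: EEGRecord, eps: float = 1e-8) -> EEGRecord:
    """Standardise each channel to zero mean and unit variance.

    Constant channels (std below ``eps``) map to all-zeros.
    """
    mu = record.signal.mean(axis=1, keepdims=True)
    sd = record.signal.std(axis=1, keepdims=True)
    out = (record.signal - mu) / np.maximum(sd, eps)
    out[np.broadcast_to(sd < eps, out.shape)] = 0.0
    return replace(record, signal=out)


def build_manifest(records: list[EEGRecord], source: str = "synthetic") -> DatasetManifest:
    counts: dict = {}
    for rec in records:
        counts[rec.label] = counts.get(rec.label, 0) + 1
    return DatasetManifest(counts=counts, source=source)


def prepare(records: list[EEGRecord], n_samples: int = TARGET_SAMPLES) -> list[EEGRecord]:
    """Validate, trim and normalise a record list (the standard pipeline)."""
    return [normalize_record(trim_record(r.validate(), n_samples)) for r in records]
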