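"""Signal file plumbing: single-column CSV and optional EDF ingest."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError


def write_signal_csv(signal: np.ndarray, path: str | Path) -> None:
    """Write a sampled signal as a single-column CSV (header ``value``)."""
    pd.DataFrame({"value": np.asarray(signal, dtype=float)}).to_csv(path, index=False)


def read_signal_csv(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path)
    if "value" not in frame.columns:
        raise FormatError(f"signal CSV {path} is missing column 'value'")
    return frame["value"].to_numpy(dtype=float)


def read_signal_edf(path: str | Path, channel: int | str = 0) -> tuple[np.ndarray, float]:
    """Read one channel from an EDF file via mne (optional ``edf`` extra).

    Returns ``(signal, sample_rate_hz)``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extra
        raise ImportError("EDF ingest requires the 'mne' package (pip install sleepuq[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if isinstance(channel, int):
        channel = raw.ch_names[channel]
    data = raw.get_data(picks=[channel])[0]
    return np.asarray(data, dtype=float), float(raw.info["sfreq"])
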