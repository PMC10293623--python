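"""File export/import: EDF recordings, BIDS-style event tables and the
epochs container (compressed array + JSON sidecar).

The EDF writer emits plain EDF (16-bit samples, one data record per second)
with a fixed header date so that identical data produce byte-identical
files. It covers exactly what the simulator needs; annotations/EDF+ features
are out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Epochs
from .simulate import CUE_S, RawRecording


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, data: np.ndarray, fs: float, labels: list[str],
              physical_dim: str = "uV") -> Path:
    """Write (n_channels, n_samples) microvolt data as a plain EDF file.

    The last data record is zero-padded to a whole second. Sampling rate must
    be an integer number of samples per second.
    """
    path = Path(path)
    n_ch, n_samp = data.shape
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    same = pmax - pmin < 1e-12
    pmax[same] = pmin[same] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    header = b"".join([
        _edf_field(0, 8),                      # version
        _edf_field("X X X X", 80),             # patient id (anonymous)
        _edf_field("Startdate 01-JAN-2000", 80),
        _edf_field("01.01.00", 8),             # fixed date -> deterministic files
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_ch + 1), 8),       # header bytes
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),                      # record duration (s)
        _edf_field(n_ch, 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(lbl, 16) for lbl in labels),
        b"".join(_edf_field("simulated", 80) for _ in labels),
        b"".join(_edf_field(physical_dim, 8) for _ in labels),
        b"".join(_edf_field(f"{v:.6g}", 8) for v in pmin),
        b"".join(_edf_field(f"{v:.6g}", 8) for v in pmax),
        b"".join(_edf_field(dmin, 8) for _ in labels),
        b"".join(_edf_field(dmax, 8) for _ in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field(spr, 8) for _ in labels),
        b"".join(_edf_field("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        # records: per record, all samples of signal 1, then signal 2, ...
        fh.write(np.ascontiguousarray(
            digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        ).tobytes())
    return path


def export_recording(rec: RawRecording, outdir: str | Path) -> list[Path]:
    """Write one EDF + one events TSV per run, for a simulated recording."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = rec.meta.get("participant_id", "P000")
    run_starts = list(rec.meta.get("run_starts", [0])) + [rec.data.shape[1]]
    written = []
    for run in range(len(run_starts) - 1):
        a, b = run_starts[run], run_starts[run + 1]
        edf = outdir / f"{pid}_run{run + 1}.edf"
        write_edf(edf, rec.data[:, a:b], rec.fs, rec.channel_labels)
        events = pd.DataFrame(
            [
                {
                    "onset": (ev.sample_index - a) / rec.fs,
                    "duration": CUE_S,
                    "task": ev.task,
                    "condition": ev.condition,
                }
                for ev in rec.events
                if ev.run_index == run
            ]
        )
        tsv = outdir / f"{pid}_run{run + 1}_events.tsv"
        events.to_csv(tsv, sep="\t", index=False, float_format="%.6f")
        written += [edf, tsv]
    return written


def save_epochs(epochs: Epochs, path: str | Path) -> Path:
    """Persist epochs as <path>.npz plus a <path>.json sidecar."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        data=epochs.data,
        condition=np.asarray(epochs.condition, dtype=str),
        task=np.asarray(epochs.task, dtype=str),
        kept=epochs.kept,
    )
    sidecar = {
        "fs": epochs.fs,
        "tmin": epochs.tmin,
        "tmax": epochs.tmax,
        "channel_labels": epochs.channel_labels,
        "channel_kinds": epochs.channel_kinds,
        "montage": {k: list(v) for k, v in epochs.montage.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_epochs(path: str | Path) -> Epochs:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"), allow_pickle=False)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Epochs(
        data=arrays["data"],
        fs=meta["fs"], tmin=meta["tmin"], tmax=meta["tmax"],
        condition=arrays["condition"].astype(object),
        task=arrays["task"].astype(object),
        kept=arrays["kept"].astype(bool),
        channel_labels=list(meta["channel_labels"]),
        channel_kinds=list(meta["channel_kinds"]),
        montage={k: tuple(v) for k, v in meta["montage"].items()},
    )
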