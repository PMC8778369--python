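"""Reading and writing trial sets.

Two containers are supported:

* an internal compressed tensor container (NumPy ``.npz``) that round-trips
  a :class:`~neurofuse.simulate.TrialSet` exactly, and
* European Data Format (EDF+C) export/import, one data record per trial,
  with a cue annotation (``cue`` / ``class:<k>``) per record.  EDF stores
  samples as 16-bit integers, so the EDF round trip is exact only to the
  per-channel quantisation step.

Channel labels in EDF are prefixed with their modality (``EEG Fc3``,
``EMG flexor c...``) and truncated to the format's 16-character field.
"""

from __future__ import annotations

import os
import zipfile

import numpy as np
import pandas as pd

from neurofuse.simulate import TrialSet

__all__ = [
    "write_trialset",
    "read_trialset",
    "export_edf",
    "import_edf",
    "write_event_table",
    "read_event_table",
]


# --------------------------------------------------------------------------
# internal container
# --------------------------------------------------------------------------

def write_trialset(ts: TrialSet, path: str | os.PathLike) -> None:
    """Save a trial set to a compressed ``.npz`` container."""
    np.savez_compressed(
        path,
        eeg=ts.eeg,
        emg=ts.emg,
        labels=ts.labels,
        fs=np.asarray(ts.fs),
        cue_index=np.asarray(ts.cue_index),
        eeg_channel_names=np.asarray(ts.eeg_channel_names),
        emg_channel_names=np.asarray(ts.emg_channel_names),
    )


def read_trialset(path: str | os.PathLike) -> TrialSet:
    """Load a trial set written by :func:`write_trialset`.

    Raises ``ValueError`` naming the missing/corrupt field rather than
    returning partial data.
    """
    try:
        with np.load(path, allow_pickle=False) as z:
            required = ("eeg", "emg", "labels", "fs", "cue_index",
                        "eeg_channel_names", "emg_channel_names")
            missing = [k for k in required if k not in z.files]
            if missing:
                raise ValueError(f"trialset container missing fields: {missing}")
            return TrialSet(
                eeg=z["eeg"], emg=z["emg"], labels=z["labels"],
                fs=float(z["fs"]), cue_index=int(z["cue_index"]),
                eeg_channel_names=tuple(str(s) for s in z["eeg_channel_names"]),
                emg_channel_names=tuple(str(s) for s in z["emg_channel_names"]),
            )
    except (zipfile.BadZipFile, EOFError, OSError) as e:
        raise ValueError(f"corrupt or truncated trialset file {path}: {e}") from e


# --------------------------------------------------------------------------
# event tables
# --------------------------------------------------------------------------

def write_event_table(ts: TrialSet, path: str | os.PathLike) -> None:
    """Write the per-trial event table (trial, class, cue_sample) as CSV."""
    pd.DataFrame({
        "trial": np.arange(ts.n_trials),
        "class": ts.labels,
        "cue_sample": np.full(ts.n_trials, ts.cue_index),
    }).to_csv(path, index=False)


def read_event_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("trial", "class", "cue_sample"):
        if col not in df.columns:
            raise ValueError(f"event table missing column {col!r}")
    return df


# --------------------------------------------------------------------------
# EDF+C
# --------------------------------------------------------------------------

_ANNOT_BYTES = 64  # bytes reserved for the annotation signal per record


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def export_edf(ts: TrialSet, path: str | os.PathLike) -> None:
    """Export a trial set to EDF+C: one data record per trial.

    Signals are ordered EEG channels then EMG channels, followed by the
    mandatory ``EDF Annotations`` signal carrying, per record, the record
    onset and a cue annotation with the class label.
    """
    n_trials = ts.n_trials
    ns_per_rec = ts.n_samples
    duration = ns_per_rec / ts.fs
    data = np.concatenate([ts.eeg, ts.emg], axis=1)  # (trials, ch, samples)
    labels = [f"EEG {n}" for n in ts.eeg_channel_names] + \
             [f"EMG {n}" for n in ts.emg_channel_names]
    n_sig = data.shape[1] + 1  # + annotations

    # per-channel physical scaling
    pmin = data.min(axis=(0, 2))
    pmax = data.max(axis=(0, 2))
    flat = pmax - pmin < 1e-9
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767

    header = b"".join([
        _edf_field(0, 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_sig), 8),
        _edf_field("EDF+C", 44),
        _edf_field(n_trials, 8),
        _edf_field(f"{duration:g}", 8),
        _edf_field(n_sig, 4),
    ])

    sig_labels = labels + ["EDF Annotations"]
    transducers = [""] * n_sig
    phys_dim = ["uV"] * (n_sig - 1) + [""]
    phys_min = [f"{v:.6g}"[:8] for v in pmin] + ["-1"]
    phys_max = [f"{v:.6g}"[:8] for v in pmax] + ["1"]
    dig_min = [str(dmin)] * (n_sig - 1) + ["-32768"]
    dig_max = [str(dmax)] * (n_sig - 1) + ["32767"]
    prefilter = [""] * n_sig
    spr = [str(ns_per_rec)] * (n_sig - 1) + [str(_ANNOT_BYTES // 2)]

    def field_block(vals, width):
        return b"".join(_edf_field(v, width) for v in vals)

    header += field_block(sig_labels, 16)
    header += field_block(transducers, 80)
    header += field_block(phys_dim, 8)
    header += field_block(phys_min, 8)
    header += field_block(phys_max, 8)
    header += field_block(dig_min, 8)
    header += field_block(dig_max, 8)
    header += field_block(prefilter, 80)
    header += field_block(spr, 8)
    header += field_block([""] * n_sig, 32)

    pmin_f = np.array([float(v) for v in phys_min[:-1]])
    pmax_f = np.array([float(v) for v in phys_max[:-1]])
    scale = (dmax - dmin) / (pmax_f - pmin_f)

    with open(path, "wb") as fh:
        fh.write(header)
        for i in range(n_trials):
            for c in range(data.shape[1]):
                dig = np.round((data[i, c] - pmin_f[c]) * scale[c] + dmin)
                fh.write(np.clip(dig, dmin, dmax).astype("<i2").tobytes())
            onset = i * duration
            cue_t = onset + ts.cue_index / ts.fs
            tal = (f"+{onset:g}\x14\x14\x00"
                   f"+{cue_t:g}\x14cue\x14class:{int(ts.labels[i])}\x14\x00")
            raw = tal.encode("ascii")
            if len(raw) > _ANNOT_BYTES:
                raise ValueError("annotation text exceeds reserved bytes")
            fh.write(raw.ljust(_ANNOT_BYTES, b"\x00"))


def _parse_tals(raw: bytes) -> list[tuple[float, list[str]]]:
    out = []
    for tal in raw.split(b"\x00"):
        if not tal:
            continue
        parts = tal.split(b"\x14")
        try:
            onset = float(parts[0].replace(b"\x15", b"."))
        except ValueError:
            continue
        notes = [p.decode("ascii", "replace") for p in parts[1:] if p]
        out.append((onset, notes))
    return out


def import_edf(path: str | os.PathLike) -> TrialSet:
    """Read an EDF+C file written by :func:`export_edf` back into a TrialSet.

    Raises ``ValueError`` naming the offending field on malformed or
    truncated files.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF: fixed header shorter than 256 bytes")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            duration = float(head[244:252].decode("ascii").strip())
            n_sig = int(head[252:256].decode("ascii").strip())
        except ValueError as e:
            raise ValueError(f"malformed EDF fixed header: {e}") from e
        sig_head = fh.read(256 * n_sig)
        if len(sig_head) < 256 * n_sig:
            raise ValueError("truncated EDF: signal header incomplete")

        def block(offset, width):
            base = offset * n_sig
            return [sig_head[base + i * width: base + (i + 1) * width]
                    .decode("ascii").strip() for i in range(n_sig)]

        labels = block(0, 16)
        # field offsets within the signal header, in bytes per signal
        off = {"phys_min": 16 * n_sig + 80 * n_sig + 8 * n_sig,
               "phys_max": 16 * n_sig + 80 * n_sig + 8 * n_sig + 8 * n_sig,
               "dig_min": 16 * n_sig + 80 * n_sig + 8 * n_sig + 16 * n_sig,
               "dig_max": 16 * n_sig + 80 * n_sig + 8 * n_sig + 24 * n_sig,
               "spr": 16 * n_sig + 80 * n_sig + 8 * n_sig + 32 * n_sig + 80 * n_sig}

        def fblock(key):
            base = off[key]
            return [sig_head[base + i * 8: base + (i + 1) * 8].decode("ascii").strip()
                    for i in range(n_sig)]

        try:
            phys_min = np.array([float(v) for v in fblock("phys_min")])
            phys_max = np.array([float(v) for v in fblock("phys_max")])
            dig_min = np.array([float(v) for v in fblock("dig_min")])
            dig_max = np.array([float(v) for v in fblock("dig_max")])
            spr = [int(v) for v in fblock("spr")]
        except ValueError as e:
            raise ValueError(f"malformed EDF signal header field: {e}") from e

        annot_idx = [i for i, l in enumerate(labels) if l == "EDF Annotations"]
        data_idx = [i for i in range(n_sig) if i not in annot_idx]
        rec_bytes = sum(2 * s for s in spr)
        signals = [[] for _ in range(n_sig)]
        annots: list[tuple[float, list[str]]] = []
        for r in range(n_records):
            rec = fh.read(rec_bytes)
            if len(rec) < rec_bytes:
                raise ValueError(
                    f"truncated EDF: record {r} has {len(rec)} of {rec_bytes} bytes")
            pos = 0
            for i in range(n_sig):
                chunk = rec[pos: pos + 2 * spr[i]]
                pos += 2 * spr[i]
                if i in annot_idx:
                    annots.extend(_parse_tals(chunk))
                else:
                    signals[i].append(np.frombuffer(chunk, dtype="<i2"))

    gains = (phys_max - phys_min) / (dig_max - dig_min)
    chans = []
    for i in data_idx:
        arr = np.stack(signals[i]).astype(float)   # (records, samples)
        chans.append(arr * gains[i] + phys_min[i] - dig_min[i] * gains[i])
    data = np.stack(chans, axis=1)                 # (records, channels, samples)

    eeg_ix = [j for j, i in enumerate(data_idx) if labels[i].startswith("EEG ")]
    emg_ix = [j for j, i in enumerate(data_idx) if labels[i].startswith("EMG ")]
    if not eeg_ix or not emg_ix:
        raise ValueError("EDF file lacks EEG/EMG-labelled signals")

    fs = spr[data_idx[0]] / duration
    cue_annots = [(t, n) for t, n in annots if n and n[0] == "cue"]
    if len(cue_annots) != n_records:
        raise ValueError(
            f"expected one cue annotation per record, found {len(cue_annots)}")
    trial_labels = []
    cue_index = None
    for r, (t, notes) in enumerate(cue_annots):
        cls = [n for n in notes if n.startswith("class:")]
        if not cls:
            raise ValueError(f"cue annotation in record {r} lacks class note")
        trial_labels.append(int(cls[0].split(":", 1)[1]))
        cue_index = int(round((t - r * duration) * fs))

    return TrialSet(
        eeg=data[:, eeg_ix], emg=data[:, emg_ix],
        labels=np.asarray(trial_labels), fs=fs, cue_index=cue_index,
        eeg_channel_names=tuple(labels[data_idx[j]][4:] for j in eeg_ix),
        emg_channel_names=tuple(labels[data_idx[j]][4:] for j in emg_ix),
    )
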