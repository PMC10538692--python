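"""Audio and manifest I/O, sample-inclusion rules, and normalization.

Speech excerpts arrive as mono (or stereo, mixed down) PCM WAV files plus a
CSV manifest giving, per file: sample id, speaker role (questioner or
respondent), diagnostic group (AUT or NT), dyad id and topic.  Before
demodulation every waveform is z-scored (mean 0, SD 1, population divisor)
so that absolute intensity cannot leak into the modulation features, and
excerpts shorter than 10 s are excluded.

The direction label of a sample is a pure function of who is speaking and
to whom: a respondent's speech is ``AUT_speech`` or ``NT_speech`` according
to their own group; a questioner's speech is ``AUT_directed`` or
``NT_directed`` according to the partner's group.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile

ROLES = ("questioner", "respondent")
GROUPS = ("AUT", "NT")
DIRECTION_LABELS = ("AUT_speech", "NT_speech", "AUT_directed", "NT_directed")

MANIFEST_COLUMNS = ["file", "sample_id", "role", "group", "dyad_id", "topic"]

#: PCM full-scale divisors for integer WAV payloads by dtype itemsize.
_PCM_SCALE = {1: 128.0, 2: 32768.0, 4: 2147483648.0}


class AudioValidationError(ValueError):
    """Raised when a sample violates a precondition (empty, constant, ...)."""


def direction_label(role: str, group: str, partner_group: str) -> str:
    """Label a sample by speaker role and the groups of the two parties.

    Respondents speak in their own voice (``{group}_speech``); the
    neurotypical questioner's speech is labelled by whom it addresses
    (``{partner_group}_directed``).
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    if group not in GROUPS or partner_group not in GROUPS:
        raise ValueError(f"groups must be one of {GROUPS}")
    if role == "respondent":
        return f"{group}_speech"
    return f"{partner_group}_directed"


@dataclass(frozen=True)
class SpeechSample:
    """One speech excerpt: waveform + rate + role/group/dyad metadata."""

    sample_id: str
    waveform: np.ndarray
    rate_hz: float
    role: str
    group: str
    direction_label: str
    dyad_id: str
    topic: str = ""
    normalized: bool = False

    def __post_init__(self):
        w = np.asarray(self.waveform, dtype=np.float64)
        object.__setattr__(self, "waveform", w)
        if w.ndim != 1 or w.size == 0:
            raise AudioValidationError(
                f"sample {self.sample_id!r}: waveform must be 1-D and non-empty"
            )
        if self.rate_hz <= 0:
            raise AudioValidationError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.waveform.size / self.rate_hz

    def replace(self, **kw) -> "SpeechSample":
        return replace(self, **kw)


def load_sample(path: str | os.PathLike, meta: dict | pd.Series) -> SpeechSample:
    """Read a PCM/float WAV and attach manifest metadata.

    Stereo is mixed down by channel mean; integer PCM is rescaled to
    [-1, 1).  The waveform is returned raw (un-normalized).
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap with the offending path
        raise IOError(f"could not read WAV file {os.fspath(path)!r}: {exc}") from exc
    if rate < 8000:
        raise AudioValidationError(f"{path!r}: sample rate {rate} Hz < 8000 Hz")
    if data.size == 0:
        raise AudioValidationError(f"{path!r}: zero-length audio")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / _PCM_SCALE[data.dtype.itemsize]
    else:
        data = data.astype(np.float64)

    meta = dict(meta)
    partner = meta.get("partner_group")
    label = meta.get("direction_label")
    if label is None:
        if partner is None:
            raise ValueError("meta needs either direction_label or partner_group")
        label = direction_label(meta["role"], meta["group"], partner)
    return SpeechSample(
        sample_id=str(meta["sample_id"]),
        waveform=data,
        rate_hz=float(rate),
        role=meta["role"],
        group=meta["group"],
        direction_label=label,
        dyad_id=str(meta["dyad_id"]),
        topic=str(meta.get("topic", "")),
    )


def zscore_normalize(sample: SpeechSample) -> SpeechSample:
    """Standardize the waveform to mean 0, SD 1 (population divisor T)."""
    w = sample.waveform
    sd = w.std()  # ddof=0: population convention
    if sd == 0 or not np.isfinite(sd):
        raise AudioValidationError(
            f"sample {sample.sample_id!r}: zero variance, cannot z-score"
        )
    return sample.replace(waveform=(w - w.mean()) / sd, normalized=True)


def filter_samples(samples, min_duration_s: float = 10.0):
    """Keep samples with duration >= ``min_duration_s``, preserving order."""
    return [s for s in samples if s.duration_s >= min_duration_s]


def trim_silence(
    sample: SpeechSample,
    frame_s: float = 0.05,
    rms_fraction: float = 0.05,
) -> SpeechSample:
    """Optionally strip leading/trailing low-energy frames.

    Frames of ``frame_s`` whose RMS falls below ``rms_fraction`` of the
    global RMS are considered silent; only the contiguous silent runs at the
    two ends are removed.  Off by default in the pipeline: the recordings'
    2-s lead-in/lead-out silences are retained unless this is requested.
    """
    w = sample.waveform
    n_frame = max(1, int(round(frame_s * sample.rate_hz)))
    n_full = w.size // n_frame
    if n_full == 0:
        return sample
    frames = w[: n_full * n_frame].reshape(n_full, n_frame)
    rms = np.sqrt((frames**2).mean(axis=1))
    thresh = rms_fraction * np.sqrt((w**2).mean())
    keep = rms >= thresh
    if not keep.any():
        return sample
    first = int(np.argmax(keep))
    last = int(n_full - np.argmax(keep[::-1]))
    return sample.replace(waveform=w[first * n_frame : last * n_frame])


def write_wav(path: str | os.PathLike, sample: SpeechSample, float_format: bool = True):
    """Write a sample to WAV (IEEE float by default, else 16-bit PCM)."""
    w = sample.waveform
    if float_format:
        wavfile.write(os.fspath(path), int(round(sample.rate_hz)), w.astype(np.float32))
    else:
        scaled = np.clip(np.round(w * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(os.fspath(path), int(round(sample.rate_hz)), scaled)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a manifest CSV.

    Columns: file, sample_id, role, group, dyad_id, topic.  sample_id must
    be unique and each dyad must have exactly one questioner identity.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in manifest: {dupes}")
    bad_role = set(df["role"]) - set(ROLES)
    if bad_role:
        raise ValueError(f"unknown roles in manifest: {sorted(bad_role)}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups in manifest: {sorted(bad_group)}")
    return df


def manifest_with_labels(df: pd.DataFrame) -> pd.DataFrame:
    """Attach direction_label to manifest rows.

    The partner group of a questioner's sample is the group of the dyad's
    respondent; a respondent's partner is the (NT) questioner.
    """
    df = df.copy()
    resp_group = (
        df[df.role == "respondent"].drop_duplicates("dyad_id").set_index("dyad_id")["group"]
    )
    labels = []
    for _, row in df.iterrows():
        if row.role == "respondent":
            labels.append(direction_label(row.role, row.group, "NT"))
        else:
            partner = resp_group.get(row.dyad_id)
            if partner is None:
                raise ValueError(f"dyad {row.dyad_id!r} has no respondent row")
            labels.append(direction_label(row.role, row.group, partner))
    df["direction_label"] = labels
    return df
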