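"""Per-note feature construction for the Onset and Baseline regression models.

The Onset model codes note onsets as a binary impulse; the Baseline model
adds binary flags (very high / very low pitch relative to pooled stimulus
quantiles, composition onset, immediate pitch repetition) and continuous
acoustic descriptors averaged over each note span: RMS amplitude, spectral
flatness and the variance of the gammatone broad-band envelope (a proxy for
acoustic edges).  Features become impulse regressors on the neural sampling
grid, continuous columns z-scored over note entries.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .note_io import Corpus, NoteSequence
from .trf_core import ImpulseRegressors

__all__ = [
    "pitch_quantile_thresholds",
    "build_feature_table",
    "build_feature_tables",
    "rms_per_note",
    "flatness_per_note",
    "envelope_variance_per_note",
    "to_impulse_regressors",
    "BINARY_FEATURES",
    "CONTINUOUS_FEATURES",
]

BINARY_FEATURES = (
    "onset_flag",
    "high_pitch",
    "low_pitch",
    "composition_onset",
    "repetition",
)
CONTINUOUS_FEATURES = ("rms", "flatness", "envelope_variance")


def pitch_quantile_thresholds(
    corpus: Corpus, lo_q: float = 0.10, hi_q: float = 0.90
) -> tuple[float, float]:
    """(low, high) pitch thresholds pooled over all notes of the stimulus set."""
    pitches = np.concatenate([seq.pitches for seq in corpus])
    return float(np.quantile(pitches, lo_q)), float(np.quantile(pitches, hi_q))


def _note_spans(seq: NoteSequence, fs: float, n: int) -> list[slice]:
    spans = []
    for note in seq:
        a = int(round(note.onset * fs))
        b = int(round((note.onset + note.duration) * fs))
        if a >= n or b > n:
            raise ValueError(
                f"note span [{note.onset}, {note.onset + note.duration}) s "
                "outside audio"
            )
        spans.append(slice(a, max(b, a + 1)))
    return spans


def rms_per_note(audio: np.ndarray, fs: float, seq: NoteSequence) -> np.ndarray:
    """Root-mean-square of the audio within each note's [onset, onset+dur)."""
    audio = np.asarray(audio, dtype=float)
    return np.array(
        [np.sqrt(np.mean(audio[s] ** 2)) for s in _note_spans(seq, fs, len(audio))]
    )


def flatness_per_note(audio: np.ndarray, fs: float, seq: NoteSequence) -> np.ndarray:
    """Spectral flatness per note: geometric / arithmetic mean of the
    magnitude spectrum of the note window (1 = flat/noise-like, ->0 = tonal).
    An all-zero window is defined as 0."""
    audio = np.asarray(audio, dtype=float)
    out = []
    for s in _note_spans(seq, fs, len(audio)):
        mag = np.abs(np.fft.rfft(audio[s]))
        am = mag.mean()
        if am == 0:
            out.append(0.0)
            continue
        gm = np.exp(np.mean(np.log(mag + 1e-30)))
        out.append(float(gm / am))
    return np.array(out)


def _erb_space(lo: float, hi: float, n: int) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale."""
    ear_q, min_bw = 9.26449, 24.7

    def hz_to_erb(f):
        return ear_q * np.log(1 + f / (ear_q * min_bw))

    def erb_to_hz(e):
        return ear_q * min_bw * (np.exp(e / ear_q) - 1)

    return erb_to_hz(np.linspace(hz_to_erb(lo), hz_to_erb(hi), n))


def broadband_envelope(
    audio: np.ndarray,
    fs: float,
    n_bands: int = 64,
    f_lo: float = 50.0,
    f_hi: float = 8000.0,
) -> np.ndarray:
    """Gammatone broad-band envelope.

    The signal is passed through a bank of 4th-order gammatone filters with
    ERB-spaced centre frequencies, the Hilbert envelope is taken per band and
    averaged across bands.
    """
    audio = np.asarray(audio, dtype=float)
    f_hi = min(f_hi, 0.45 * fs)
    env = np.zeros_like(audio)
    for fc in _erb_space(f_lo, f_hi, n_bands):
        b, a = signal.gammatone(fc, "iir", fs=fs)
        band = signal.lfilter(b, a, audio)
        env += np.abs(signal.hilbert(band))
    return env / n_bands


def envelope_variance_per_note(
    audio: np.ndarray, fs: float, seq: NoteSequence, n_bands: int = 64
) -> np.ndarray:
    """Variance of the band-averaged envelope within each note span."""
    env = broadband_envelope(audio, fs, n_bands=n_bands)
    return np.array([float(np.var(env[s])) for s in _note_spans(seq, fs, len(env))])


def build_feature_table(
    seq: NoteSequence,
    pitch_thresholds: tuple[float, float],
    audio: tuple[np.ndarray, float] | None = None,
    acoustics: Mapping[str, Sequence[float]] | None = None,
    surprise: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One feature row per note of a composition.

    ``pitch_thresholds`` are the pooled (low, high) stimulus-set quantiles;
    flags use strict inequality, so at ties no note is flagged.  Acoustic
    columns come from ``audio`` (waveform, fs) when given, else from
    ``acoustics`` (synthetic per-note ground truth), else zeros.  ``surprise``
    may add surprise/uncertainty columns (must align one row per note).
    """
    lo_thr, hi_thr = pitch_thresholds
    pitches = np.array(seq.pitches)
    n = len(seq)
    table = pd.DataFrame(
        {
            "composition_id": seq.composition_id,
            "note_index": np.arange(n),
            "onset_time": seq.onsets,
            "pitch": pitches,
            "onset_flag": np.ones(n),
            "high_pitch": (pitches > hi_thr).astype(float),
            "low_pitch": (pitches < lo_thr).astype(float),
            "composition_onset": np.eye(1, n).ravel(),
            "repetition": np.concatenate([[0.0], (pitches[1:] == pitches[:-1])]),
        }
    )
    if audio is not None:
        wav, fs = audio
        table["rms"] = rms_per_note(wav, fs, seq)
        table["flatness"] = flatness_per_note(wav, fs, seq)
        table["envelope_variance"] = envelope_variance_per_note(wav, fs, seq)
    elif acoustics is not None:
        for name in CONTINUOUS_FEATURES:
            vals = np.asarray(acoustics.get(name, np.zeros(n)), dtype=float)
            if vals.shape != (n,):
                raise ValueError(f"acoustic column '{name}' needs one value per note")
            table[name] = vals
    else:
        for name in CONTINUOUS_FEATURES:
            table[name] = 0.0
    if surprise is not None:
        sub = surprise[surprise["composition_id"] == seq.composition_id]
        if len(sub) != n:
            raise ValueError(
                f"surprise table misaligned: {len(sub)} rows for {n} notes"
            )
        sub = sub.sort_values("note_index")
        table["surprise"] = sub["surprise"].to_numpy()
        table["uncertainty"] = sub["uncertainty"].to_numpy()
    return table


def build_feature_tables(
    corpus: Corpus,
    audio: Mapping[str, tuple[np.ndarray, float]] | None = None,
    acoustics: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    surprise: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Concatenated feature table for a whole stimulus set (pooled quantiles)."""
    thresholds = pitch_quantile_thresholds(corpus)
    tables = []
    for seq in corpus:
        tables.append(
            build_feature_table(
                seq,
                thresholds,
                audio=audio.get(seq.composition_id) if audio else None,
                acoustics=acoustics.get(seq.composition_id) if acoustics else None,
                surprise=surprise,
            )
        )
    return pd.concat(tables, ignore_index=True)


def to_impulse_regressors(
    table: pd.DataFrame,
    srate: float,
    n_samples: int,
    columns: Sequence[str] | None = None,
    onset_column: str = "onset_time",
) -> ImpulseRegressors:
    """Place per-note feature values as impulses on the neural time base.

    The onset sample is nearest-integer, half-up rounding of onset * srate.
    Continuous columns are z-scored over note entries *before* placement;
    binary columns are placed as-is.  Two notes mapping to the same sample
    raise (cannot occur at realistic note rates).
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c not in ("composition_id", "note_index", "onset_time", "pitch")
        ]
    onsets = table[onset_column].to_numpy(dtype=float)
    samples = np.floor(onsets * srate + 0.5).astype(int)  # round half-up
    if np.any(samples >= n_samples) or np.any(samples < 0):
        raise ValueError("note onset outside the recording")
    if len(np.unique(samples)) != len(samples):
        raise ValueError("two notes map to the same sample at this srate")
    mat = np.zeros((n_samples, len(columns)))
    for ci, name in enumerate(columns):
        vals = table[name].to_numpy(dtype=float)
        is_binary = set(np.unique(vals)) <= {0.0, 1.0}
        if not is_binary:
            sd = vals.std()
            vals = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        mat[samples, ci] = vals
    return ImpulseRegressors(matrix=mat, names=list(columns), srate=srate)
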