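"""Synthetic melodies and simulated neural recordings with known ground truth.

The melody generator samples from a key-constrained Markov process with a
Gaussian pitch-proximity bias and occasional verbatim motif reinsertion, so
that the true next-note distribution is available in closed form (see
:class:`MarkovPredictor`).  The neural simulator is the forward model that the
TRF estimator inverts: each channel is a sum of per-note impulse trains
convolved with known lag-resolved kernels, plus white or pink noise.  Every
generator takes an explicit seed and owns its RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .note_io import NoteEvent, NoteSequence, Corpus
from .trf_core import NeuralRecording

__all__ = [
    "MelodyGenConfig",
    "NeuralSimConfig",
    "generate_melody",
    "generate_corpus",
    "MarkovPredictor",
    "simulate_neural",
    "default_trf_kernel",
    "save_recording",
    "load_recording",
]

MAJOR_SCALE = (0, 2, 4, 5, 7, 9, 11)
MINOR_SCALE = (0, 2, 3, 5, 7, 8, 10)

# Pitch range of generated melodies (3 octaves around middle C).
PITCH_LO, PITCH_HI = 48, 84


@dataclass(frozen=True)
class MelodyGenConfig:
    """Parameters of the key-constrained Markov melody generator.

    ``markov_order`` 1 draws the next pitch around the previous one;
    order 2 adds interval momentum (the expected next interval continues a
    fraction ``momentum`` of the previous interval), making the process a
    genuine second-order chain.  ``interval_scale`` is the semitone SD of the
    proximity bias; ``tempo`` is in notes per second.
    """

    n_notes: int = 120
    tonic: int = 0  # pitch class 0-11 (0 = C)
    mode: str = "major"
    markov_order: int = 1
    interval_scale: float = 2.5
    momentum: float = 0.6
    motif_repeat_prob: float = 0.05
    tempo: float = 3.0
    rhythm: tuple[float, ...] = (0.5, 1.0, 1.0, 1.0, 1.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 2:
            raise ValueError("n_notes must be >= 2")
        if not 0 <= self.motif_repeat_prob <= 1:
            raise ValueError("motif_repeat_prob must be in [0, 1]")
        if self.markov_order not in (1, 2):
            raise ValueError("markov_order must be 1 or 2")
        if self.mode not in ("major", "minor"):
            raise ValueError("mode must be 'major' or 'minor'")
        if self.interval_scale < 0 or self.tempo <= 0:
            raise ValueError("interval_scale >= 0 and tempo > 0 required")


def _key_weights(cfg: MelodyGenConfig) -> np.ndarray:
    """Per-pitch weight over 0..127: in-scale pitch classes favoured 8:1."""
    scale = MAJOR_SCALE if cfg.mode == "major" else MINOR_SCALE
    pc_w = np.full(12, 1.0)
    for deg in scale:
        pc_w[(cfg.tonic + deg) % 12] = 8.0
    pc_w[cfg.tonic % 12] = 12.0  # tonic emphasis
    w = np.zeros(128)
    w[PITCH_LO : PITCH_HI + 1] = pc_w[np.arange(PITCH_LO, PITCH_HI + 1) % 12]
    return w


def conditional_distribution(
    cfg: MelodyGenConfig, prev: int, prev2: int | None = None
) -> np.ndarray:
    """Exact next-pitch distribution of the generator given its context.

    This is the generator's own transition law and serves as the matched
    predictor / brute-force oracle for everything downstream.
    """
    w = _key_weights(cfg)
    if cfg.interval_scale == 0:
        out = np.zeros(128)
        out[prev] = 1.0
        return out
    if cfg.markov_order == 2 and prev2 is not None:
        mean = prev + cfg.momentum * (prev - prev2)
    else:
        mean = float(prev)
    x = np.arange(128)
    p = w * np.exp(-((x - mean) ** 2) / (2 * cfg.interval_scale**2))
    total = p.sum()
    if total == 0:  # mean far outside range: fall back to key weights
        p = w.copy()
        total = p.sum()
    return p / total


def first_note_distribution(cfg: MelodyGenConfig) -> np.ndarray:
    w = _key_weights(cfg)
    x = np.arange(128)
    center = 60 + (cfg.tonic % 12)
    p = w * np.exp(-((x - center) ** 2) / (2 * 6.0**2))
    return p / p.sum()


def generate_melody(cfg: MelodyGenConfig, composition_id: str = "synthetic") -> NoteSequence:
    """Sample one melody; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    pitches: list[int] = [int(rng.choice(128, p=first_note_distribution(cfg)))]
    while len(pitches) < cfg.n_notes:
        if (
            cfg.motif_repeat_prob > 0
            and len(pitches) >= 8
            and rng.random() < cfg.motif_repeat_prob
        ):
            # verbatim reinsertion of an earlier motif (2-6 notes)
            length = int(rng.integers(2, 7))
            start = int(rng.integers(0, len(pitches) - length + 1))
            motif = pitches[start : start + length]
            pitches.extend(motif[: cfg.n_notes - len(pitches)])
            continue
        prev = pitches[-1]
        prev2 = pitches[-2] if len(pitches) >= 2 else None
        p = conditional_distribution(cfg, prev, prev2)
        pitches.append(int(rng.choice(128, p=p)))
    # rhythm: inter-onset intervals are note-value multiples of the base
    # period (mean IOI ~ 1/tempo); variable rhythm, as in real melodies,
    # also keeps the onset impulse train aperiodic
    base = 1.0 / cfg.tempo
    iois = base * rng.choice(cfg.rhythm, size=cfg.n_notes)
    onsets = np.concatenate([[0.0], np.cumsum(iois[:-1])])
    notes = [
        NoteEvent(p, float(t), float(0.8 * d))
        for p, t, d in zip(pitches[: cfg.n_notes], onsets, iois)
    ]
    return NoteSequence(notes, composition_id=composition_id, metadata={
        "tonic": cfg.tonic, "mode": cfg.mode})


def generate_corpus(
    cfg: MelodyGenConfig, n_sequences: int, name: str = "synthetic-corpus"
) -> Corpus:
    """Corpus of independent melodies; sequence i uses seed ``cfg.seed + i``."""
    seqs = []
    for i in range(n_sequences):
        c = MelodyGenConfig(**{**cfg.__dict__, "seed": cfg.seed + i})
        seqs.append(generate_melody(c, composition_id=f"{name}-{i:03d}"))
    return Corpus(seqs, name=name)


class MarkovPredictor:
    """The generator's own transition law exposed as a PitchPredictor.

    ``predict(context)`` returns the exact conditional distribution of the
    generating process given the most recent one or two context notes (the
    process has no longer memory).  With an empty context it returns the
    first-note distribution.
    """

    def __init__(self, cfg: MelodyGenConfig):
        self.cfg = cfg

    def predict(self, context) -> np.ndarray:
        context = list(context)
        if not context:
            return first_note_distribution(self.cfg)
        prev = context[-1]
        prev2 = context[-2] if len(context) >= 2 else None
        return conditional_distribution(self.cfg, prev, prev2)


# ---------------------------------------------------------------------------
# Neural simulation
# ---------------------------------------------------------------------------


@dataclass
class NeuralSimConfig:
    """Forward-model settings for simulated multichannel recordings."""

    n_channels: int = 8
    srate: float = 60.0
    lag_span: tuple[float, float] = (-0.2, 1.0)
    noise_sd: float = 1.0
    noise_type: str = "white"
    seed: int = 0
    pad: float = 1.5  # seconds appended after the last note
    channel_gains: np.ndarray | None = None  # (n_channels,) applied to all kernels

    def __post_init__(self) -> None:
        if self.srate <= 0:
            raise ValueError("srate must be > 0")
        if not (-0.2 - 1e-9 <= self.lag_span[0] < self.lag_span[1] <= 1.0 + 1e-9):
            raise ValueError("kernel lag span must lie within [-0.2, 1.0] s")
        if self.noise_type not in ("white", "pink"):
            raise ValueError("noise_type must be 'white' or 'pink'")

    def gains(self) -> np.ndarray:
        if self.channel_gains is not None:
            g = np.asarray(self.channel_gains, dtype=float)
            if g.shape != (self.n_channels,):
                raise ValueError("channel_gains must have shape (n_channels,)")
            return g
        # smooth deterministic gain profile across the channel array
        return 0.5 + np.cos(np.linspace(0, np.pi, self.n_channels)) ** 2


def default_trf_kernel(
    srate: float, t_min: float = -0.2, t_max: float = 1.0
) -> np.ndarray:
    """Difference-of-Gammas kernel with peaks near 75 ms and 200 ms and a
    sustained negative deflection over 0.3-0.6 s (auditory P1/P2/late
    negativity morphology); zero before onset; peak normalized to 1."""
    n_lags = round((t_max - t_min) * srate) + 1
    t = (np.arange(n_lags) + round(t_min * srate)) / srate
    k = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    k[pos] = (
        1.0 * stats.gamma.pdf(tp, a=4, scale=0.075 / 3)
        + 0.9 * stats.gamma.pdf(tp, a=6, scale=0.2 / 5)
        - 0.7 * stats.gamma.pdf(tp, a=8, scale=0.45 / 7)
    )
    return k / np.abs(k).max()


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    pink = np.fft.irfft(spec, n=shape[-1], axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def simulate_neural(
    seq: NoteSequence,
    regressors: Mapping[str, np.ndarray],
    cfg: NeuralSimConfig,
    true_trfs: Mapping[str, np.ndarray] | None = None,
) -> tuple[NeuralRecording, dict[str, np.ndarray]]:
    """Simulate a recording as impulse trains convolved with known kernels.

    Parameters
    ----------
    seq : the melody whose note onsets define the impulse times.
    regressors : per-note feature values, one array of length ``len(seq)``
        per named regressor.
    cfg : simulation settings; ``cfg.gains()`` scales each kernel per channel.
    true_trfs : optional mapping name -> kernel sampled on the lag grid
        ``round(lag_span[0]*srate) .. round(lag_span[1]*srate)``; defaults to
        :func:`default_trf_kernel` for every regressor.

    Returns
    -------
    (recording, truth) where ``truth[name]`` has shape (n_channels, n_lags):
    the exact per-channel kernels embedded in the data.
    """
    srate = cfg.srate
    t_min, t_max = cfg.lag_span
    lag0 = round(t_min * srate)
    n_lags = round((t_max - t_min) * srate) + 1
    n_samples = int(np.ceil((seq.notes[-1].onset + cfg.pad) * srate)) + n_lags
    kernels: dict[str, np.ndarray] = {}
    for name in regressors:
        k = None if true_trfs is None else true_trfs.get(name)
        k = default_trf_kernel(srate, t_min, t_max) if k is None else np.asarray(k, float)
        if len(k) != n_lags:
            raise ValueError(
                f"kernel for '{name}' has {len(k)} lags, expected {n_lags}"
            )
        if n_lags > n_samples:
            raise ValueError("TRF kernel longer than recording")
        kernels[name] = k
    onset_samples = np.array([round(n.onset * srate) for n in seq.notes])
    gains = cfg.gains()
    data = np.zeros((cfg.n_channels, n_samples))
    truth: dict[str, np.ndarray] = {}
    for name, values in regressors.items():
        values = np.asarray(values, dtype=float)
        if values.shape != (len(seq),):
            raise ValueError(f"regressor '{name}' needs one value per note")
        train = np.zeros(n_samples)
        np.add.at(train, onset_samples, values)
        full = np.convolve(train, kernels[name])  # index t-lag0-j
        sig = full[-lag0 : -lag0 + n_samples] if lag0 <= 0 else np.pad(
            full, (lag0, 0)
        )[:n_samples]
        data += gains[:, None] * sig[None, :]
        truth[name] = gains[:, None] * kernels[name][None, :]
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0:
        if cfg.noise_type == "white":
            noise = rng.standard_normal(data.shape)
        else:
            noise = _pink_noise(rng, data.shape)
        data = data + cfg.noise_sd * noise
    rec = NeuralRecording(
        data=data,
        srate=srate,
        bad_mask=np.zeros(n_samples, dtype=bool),
        channel_ids=[f"ch{c:02d}" for c in range(cfg.n_channels)],
    )
    return rec, truth


def save_recording(
    path, rec: NeuralRecording, truth: Mapping[str, np.ndarray] | None = None
) -> None:
    """Write a recording (and optional ground-truth kernels) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("bad_mask", data=rec.bad_mask)
        f.attrs["srate"] = rec.srate
        f.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
        if truth:
            g = f.create_group("truth")
            for name, k in truth.items():
                g.create_dataset(name, data=k)


def load_recording(path) -> tuple[NeuralRecording, dict[str, np.ndarray]]:
    import h5py

    with h5py.File(path, "r") as f:
        rec = NeuralRecording(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            bad_mask=f["bad_mask"][()].astype(bool),
            channel_ids=list(f.attrs["channel_ids"]),
        )
        truth = {}
        if "truth" in f:
            truth = {name: f["truth"][name][()] for name in f["truth"]}
    return rec, truth
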