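"""Probabilistic models of melodic expectation and their information measures.

Implements three families of next-note-pitch predictors over the 128-pitch
MIDI alphabet:

* a Bayesian Gestalt model (central-pitch tendency, pitch proximity, key
  profile; the three principles combined multiplicatively, with exact
  discrete marginalization over the latent central pitch and the 24 keys);
* variable-order n-gram models with interpolated PPM-style smoothing, in
  long-term (corpus-trained) and short-term (online, strictly causal)
  variants, plus their entropy-weighted combination;
* an adapter for externally computed per-note estimates.

From a predictive distribution two information measures are derived: the
surprise of the observed pitch, ``-ln P(x_t | context)``, and the uncertainty
(Shannon entropy) of the prediction.  All logarithms are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .note_io import Corpus, NoteSequence

__all__ = [
    "ALPHABET",
    "LN_ALPHABET",
    "uniform_distribution",
    "finalize_distribution",
    "surprise",
    "uncertainty",
    "TemperleyParams",
    "temperley_predict",
    "fit_temperley_params",
    "TemperleyPredictor",
    "NGramModel",
    "ngram_train",
    "ngram_predict",
    "raw_ngram_ratio",
    "NGramPredictor",
    "STMPredictor",
    "combine_both",
    "BothPredictor",
    "SurpriseTable",
    "evaluate_model",
    "save_surprise_table",
    "load_external_surprise",
]

ALPHABET = 128
LN_ALPHABET = math.log(ALPHABET)

#: Weight of the uniform floor mixed into every final distribution so that
#: zero-count events keep finite surprise (cap ~ ln(ALPHABET / FLOOR)).
FLOOR = 1e-6


def uniform_distribution() -> np.ndarray:
    return np.full(ALPHABET, 1.0 / ALPHABET)


def validate_distribution(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (ALPHABET,):
        raise ValueError(f"distribution must have shape ({ALPHABET},)")
    if np.any(dist < 0):
        raise ValueError("distribution has negative entries")
    if abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError(f"distribution sums to {dist.sum()}, not 1")
    return dist


def finalize_distribution(dist: np.ndarray) -> np.ndarray:
    """Mix with the uniform floor and renormalize (guards exact zeros)."""
    dist = np.asarray(dist, dtype=float)
    out = (1.0 - FLOOR) * dist / dist.sum() + FLOOR / ALPHABET
    return out / out.sum()


def surprise(dist: np.ndarray, observed: int) -> float:
    """Surprise of the observed pitch: -ln P(observed | context), in nats."""
    if not 0 <= observed < ALPHABET:
        raise ValueError(f"pitch {observed} out of range")
    dist = validate_distribution(dist)
    p = dist[observed]
    if p <= 0:
        return math.log(ALPHABET / FLOOR)  # cap for exact zeros
    return -math.log(p)


def uncertainty(dist: np.ndarray) -> float:
    """Shannon entropy of the predictive distribution in nats (0 ln 0 = 0)."""
    dist = validate_distribution(dist)
    nz = dist[dist > 0]
    return float(-(nz * np.log(nz)).sum())


@runtime_checkable
class PitchPredictor(Protocol):
    """Anything that maps a pitch context to a 128-way distribution."""

    def predict(self, context: Sequence[int]) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Bayesian Gestalt model
# ---------------------------------------------------------------------------


def _default_key_profiles() -> np.ndarray:
    """Flat scale-tone templates: uniform over the 7 diatonic scale degrees.

    Rows 0-11 are major keys (tonic = row index), rows 12-23 natural-minor
    keys.  Row k gives p(scale degree) indexed by (pitch - tonic) mod 12.
    Corpus-estimated profiles (fit_temperley_params) are preferred when key
    labels exist.
    """
    major = np.zeros(12)
    major[[0, 2, 4, 5, 7, 9, 11]] = 1.0 / 7
    minor = np.zeros(12)
    minor[[0, 2, 3, 5, 7, 8, 10]] = 1.0 / 7
    return np.vstack([np.tile(major, (12, 1)), np.tile(minor, (12, 1))])


@dataclass
class TemperleyParams:
    """Parameters of the Gestalt melody model.

    Defaults are the published corpus-moment estimates: central pitch prior
    mean 72 and variance 34.4, range-profile variance 83.2, proximity
    variance 18.2, and probability 0.81 of a major key.
    """

    c0: float = 72.0
    var_c0: float = 34.4
    v_r: float = 83.2
    v_x: float = 18.2
    p_maj: float = 0.81
    key_profiles: np.ndarray = field(default_factory=_default_key_profiles)

    def __post_init__(self) -> None:
        if self.var_c0 < 0 or self.v_r < 0 or self.v_x < 0:
            raise ValueError("variances must be non-negative")
        if not 0 <= self.p_maj <= 1:
            raise ValueError("p_maj must be in [0, 1]")
        self.key_profiles = np.asarray(self.key_profiles, dtype=float)
        if self.key_profiles.shape != (24, 12):
            raise ValueError("key_profiles must be 24 x 12")
        if np.any(self.key_profiles < 0) or np.any(
            np.abs(self.key_profiles.sum(axis=1) - 1) > 1e-6
        ):
            raise ValueError("each key-profile row must be a distribution")


def _discrete_normal(mean: float, var: float) -> np.ndarray:
    """Gaussian discretized over integer pitches 0..127 (delta when var=0)."""
    x = np.arange(ALPHABET, dtype=float)
    if var == 0:
        out = np.zeros(ALPHABET)
        out[int(np.clip(round(mean), 0, ALPHABET - 1))] = 1.0
        return out
    p = np.exp(-((x - mean) ** 2) / (2.0 * var))
    return p / p.sum()


def _key_term(params: TemperleyParams) -> np.ndarray:
    """(24, 128) profile value for each key and absolute pitch."""
    pitch_pc = np.arange(ALPHABET) % 12
    tonics = np.tile(np.arange(12), 2)
    degrees = (pitch_pc[None, :] - tonics[:, None]) % 12
    return np.take_along_axis(params.key_profiles, degrees, axis=1)


def _note_model(params: TemperleyParams) -> np.ndarray:
    """(128 c, 24 key, 128 x) unnormalized range x key term."""
    c_grid = np.arange(ALPHABET, dtype=float)
    x = np.arange(ALPHABET, dtype=float)
    if params.v_r == 0:
        rng_term = (x[None, :] == c_grid[:, None]).astype(float)
    else:
        rng_term = np.exp(-((x[None, :] - c_grid[:, None]) ** 2) / (2 * params.v_r))
    return rng_term[:, None, :] * _key_term(params)[None, :, :]


def _prox_term(prev: int | None, v_x: float) -> np.ndarray:
    if prev is None:
        return np.ones(ALPHABET)
    x = np.arange(ALPHABET, dtype=float)
    if v_x == 0:
        return (x == prev).astype(float)
    return np.exp(-((x - prev) ** 2) / (2 * v_x))


def temperley_predict(
    context: Sequence[int], params: TemperleyParams | None = None
) -> np.ndarray:
    """Predictive pitch distribution of the Gestalt model.

    The latent central pitch c (prior N(c0, var_c0) discretized on 0..127)
    and the key (prior p_maj/12 per major key, (1-p_maj)/12 per minor key)
    are marginalized exactly on the 128 x 24 grid, with their joint posterior
    updated from the context notes.  Per note, the unnormalized score of a
    candidate pitch is RangeTerm(x|c) * ProximityTerm(x|prev) * KeyTerm(x|key);
    the proximity term is omitted for the first note.
    """
    params = TemperleyParams() if params is None else params
    context = [int(p) for p in context]
    if any(not 0 <= p < ALPHABET for p in context):
        raise ValueError("context pitch out of range")
    post = np.outer(
        _discrete_normal(params.c0, params.var_c0),
        np.concatenate(
            [np.full(12, params.p_maj / 12), np.full(12, (1 - params.p_maj) / 12)]
        ),
    )
    base = _note_model(params)  # (c, key, x)
    prev: int | None = None
    for pitch in context:
        cond = base * _prox_term(prev, params.v_x)[None, None, :]
        z = cond.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            like = np.where(z > 0, cond[:, :, pitch] / np.where(z > 0, z, 1.0), 0.0)
        post = post * like
        total = post.sum()
        if total == 0:  # context impossible under every (c, key): reset prior
            post = np.outer(
                _discrete_normal(params.c0, params.var_c0),
                np.concatenate(
                    [np.full(12, params.p_maj / 12), np.full(12, (1 - params.p_maj) / 12)]
                ),
            )
        else:
            post = post / total
        prev = pitch
    cond = base * _prox_term(prev, params.v_x)[None, None, :]
    z = cond.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(z > 0, cond / np.where(z > 0, z, 1.0), 0.0)
    pred = np.einsum("ck,ckx->x", post, cond)
    return finalize_distribution(pred)


class TemperleyPredictor:
    """Gestalt model bound to a parameter set, as a PitchPredictor."""

    name = "temperley"

    def __init__(self, params: TemperleyParams | None = None):
        self.params = TemperleyParams() if params is None else params

    def predict(self, context: Sequence[int]) -> np.ndarray:
        return temperley_predict(context, self.params)


def fit_temperley_params(
    corpus: Corpus,
    key_labels: dict[str, tuple[int, str]] | None = None,
) -> TemperleyParams:
    """Moment estimates of the Gestalt parameters from a corpus.

    c0 / var_c0 = mean and (population) variance of compositions' mean pitch;
    v_r = variance of each melody's first note around its mean pitch;
    v_x = variance of pitches around the previous pitch, over notes whose
    predecessor equals the composition's central pitch (rounded mean);
    key profiles = scale-degree frequencies and p_maj = proportion of major
    pieces when ``key_labels`` (composition_id -> (tonic pc, mode)) is given,
    else the flat fallback templates and the default p_maj.
    """
    comp_means = np.array([np.mean(seq.pitches) for seq in corpus])
    c0 = float(comp_means.mean())
    var_c0 = float(comp_means.var())
    v_r = float(
        np.mean([(seq.pitches[0] - m) ** 2 for seq, m in zip(corpus, comp_means)])
    )
    sq_dev = []
    for seq, m in zip(corpus, comp_means):
        c = round(m)
        p = seq.pitches
        sq_dev.extend((p[t] - p[t - 1]) ** 2 for t in range(1, len(p)) if p[t - 1] == c)
    if not sq_dev:  # no note follows the central pitch: fall back to all intervals
        for seq in corpus:
            p = seq.pitches
            sq_dev.extend((p[t] - p[t - 1]) ** 2 for t in range(1, len(p)))
    v_x = float(np.mean(sq_dev)) if sq_dev else 0.0

    profiles = _default_key_profiles()
    p_maj = 0.81
    if key_labels is not None:
        missing = [s.composition_id for s in corpus if s.composition_id not in key_labels]
        if missing:
            raise ValueError(f"no key label for compositions {missing}")
        maj_counts = np.zeros(12)
        min_counts = np.zeros(12)
        n_major = 0
        for seq in corpus:
            tonic, mode = key_labels[seq.composition_id]
            degrees = (np.array(seq.pitches) - tonic) % 12
            target = maj_counts if mode == "major" else min_counts
            np.add.at(target, degrees, 1)
            n_major += mode == "major"
        if maj_counts.sum():
            profiles[:12] = np.tile(maj_counts / maj_counts.sum(), (12, 1))
        if min_counts.sum():
            profiles[12:] = np.tile(min_counts / min_counts.sum(), (12, 1))
        p_maj = n_major / len(corpus)
    return TemperleyParams(
        c0=c0, var_c0=var_c0, v_r=v_r, v_x=v_x, p_maj=p_maj, key_profiles=profiles
    )


# ---------------------------------------------------------------------------
# Variable-order n-gram models
# ---------------------------------------------------------------------------


class NGramModel:
    """Counts of all m-grams up to order_bound+1 over the pitch alphabet.

    ``counts[gram]`` is the occurrence count of the pitch tuple (length
    1..order_bound+1); ``continuations[ctx]`` maps each context (length
    0..order_bound) to the counts of the pitches that followed it.  Counting
    never crosses composition boundaries.
    """

    def __init__(self, order_bound: int, mode: str = "ltm"):
        if order_bound < 1:
            raise ValueError("order_bound must be >= 1")
        if mode not in ("ltm", "stm"):
            raise ValueError("mode must be 'ltm' or 'stm'")
        self.order_bound = order_bound
        self.mode = mode
        self.counts: dict[tuple[int, ...], int] = {}
        self.continuations: dict[tuple[int, ...], dict[int, int]] = {}
        self._history: list[int] = []  # stm running context within the piece

    def _add(self, context: tuple[int, ...], pitch: int) -> None:
        self.counts[context + (pitch,)] = self.counts.get(context + (pitch,), 0) + 1
        self.continuations.setdefault(context, {})
        self.continuations[context][pitch] = (
            self.continuations[context].get(pitch, 0) + 1
        )

    def add_sequence(self, pitches: Sequence[int]) -> None:
        pitches = [int(p) for p in pitches]
        for t, pitch in enumerate(pitches):
            for m in range(0, min(self.order_bound, t) + 1):
                self._add(tuple(pitches[t - m : t]), pitch)

    # --- stm interface -----------------------------------------------------
    def reset(self) -> None:
        """Start a new composition (stm counts are per-piece)."""
        if self.mode != "stm":
            raise ValueError("reset() applies to stm models")
        self.counts = {}
        self.continuations = {}
        self._history = []

    def observe(self, pitch: int) -> None:
        """Add one note: all m-grams ending at the note are incremented.

        Predictions for note t must be made *before* observing it, so the
        model is strictly causal.
        """
        if self.mode != "stm":
            raise ValueError("observe() applies to stm models")
        t = len(self._history)
        for m in range(0, min(self.order_bound, t) + 1):
            self._add(tuple(self._history[t - m : t]), pitch)
        self._history.append(int(pitch))


def ngram_train(corpus: Corpus, order_bound: int) -> NGramModel:
    """Long-term model: pooled m-gram counts (m <= order_bound+1) of a corpus."""
    model = NGramModel(order_bound, mode="ltm")
    for seq in corpus:
        model.add_sequence(seq.pitches)
    return model


def _ppm_distribution(model: NGramModel, context: tuple[int, ...]) -> np.ndarray:
    """Interpolated back-off (PPM escape-method-C style).

    At each order the maximum-likelihood estimate is blended with the
    next-lower order using escape mass d/(n+d), where n is the context count
    and d the number of distinct continuations; recursion bottoms out at the
    uniform 1/128 floor.
    """
    cont = model.continuations.get(context)
    if cont is None or not cont:
        if context:
            return _ppm_distribution(model, context[1:])
        return uniform_distribution()
    n = sum(cont.values())
    d = len(cont)
    ml = np.zeros(ALPHABET)
    for pitch, c in cont.items():
        ml[pitch] = c / n
    lower = (
        _ppm_distribution(model, context[1:]) if context else uniform_distribution()
    )
    escape = d / (n + d)
    return (1.0 - escape) * ml + escape * lower


def ngram_predict(model: NGramModel, context: Sequence[int]) -> np.ndarray:
    """Smoothed predictive distribution given the most recent context notes."""
    ctx = tuple(int(p) for p in context)[-model.order_bound :]
    return finalize_distribution(_ppm_distribution(model, ctx))


def raw_ngram_ratio(model: NGramModel, context: Sequence[int]) -> np.ndarray:
    """Unsmoothed relative n-gram frequency count(ctx+x)/count(ctx).

    Diagnostic view of the maximum-likelihood estimate at the full context
    order; NaN everywhere if the context was never seen.
    """
    ctx = tuple(int(p) for p in context)[-model.order_bound :]
    cont = model.continuations.get(ctx)
    if not cont:
        return np.full(ALPHABET, np.nan)
    n = sum(cont.values())
    out = np.zeros(ALPHABET)
    for pitch, c in cont.items():
        out[pitch] = c / n
    return out


class NGramPredictor:
    """Corpus-trained (ltm) n-gram model as a PitchPredictor."""

    name = "idyom-ltm"

    def __init__(self, model: NGramModel):
        self.model = model

    def predict(self, context: Sequence[int]) -> np.ndarray:
        return ngram_predict(self.model, context)


class STMPredictor:
    """Online short-term model: learns the current piece as it unfolds.

    ``begin_composition()`` resets the counts; ``observe()`` must be called
    after each prediction so that the prediction for note t only ever uses
    notes 1..t-1.
    """

    name = "idyom-stm"

    def __init__(self, order_bound: int):
        self.model = NGramModel(order_bound, mode="stm")

    def begin_composition(self) -> None:
        self.model.reset()

    def observe(self, pitch: int) -> None:
        self.model.observe(pitch)

    def predict(self, context: Sequence[int]) -> np.ndarray:
        return ngram_predict(self.model, context)


def combine_both(
    stm_dist: np.ndarray, ltm_dist: np.ndarray, bias: float = 1.0
) -> tuple[np.ndarray, tuple[float, float]]:
    """Entropy-weighted geometric combination of the stm and ltm predictions.

    Each model's weight is proportional to (H_m / ln 128)^(-bias): confident
    (low-entropy) models dominate.  The combined distribution is the weighted
    geometric mixture, renormalized.  Returns (distribution, (w_stm, w_ltm)).
    """
    stm_dist = validate_distribution(stm_dist)
    ltm_dist = validate_distribution(ltm_dist)
    ents = np.array([uncertainty(stm_dist), uncertainty(ltm_dist)]) / LN_ALPHABET
    if np.any(ents == 0):
        w = (ents == 0).astype(float)
        w /= w.sum()
    else:
        w = ents**-bias
        w = w / w.sum()
    log_mix = w[0] * np.log(np.maximum(stm_dist, 1e-300)) + w[1] * np.log(
        np.maximum(ltm_dist, 1e-300)
    )
    log_mix -= log_mix.max()
    mix = np.exp(log_mix)
    return finalize_distribution(mix), (float(w[0]), float(w[1]))


class BothPredictor:
    """stm + ltm combination with entropy-derived weights.

    Tracks the weights used at each prediction so their means can be
    reported alongside the evaluation summary.
    """

    name = "idyom-both"

    def __init__(self, ltm_model: NGramModel, order_bound: int, bias: float = 1.0):
        self.ltm = NGramPredictor(ltm_model)
        self.stm = STMPredictor(order_bound)
        self.bias = bias
        self.weights_log: list[tuple[float, float]] = []

    def begin_composition(self) -> None:
        self.stm.begin_composition()

    def observe(self, pitch: int) -> None:
        self.stm.observe(pitch)

    def predict(self, context: Sequence[int]) -> np.ndarray:
        dist, w = combine_both(
            self.stm.predict(context), self.ltm.predict(context), self.bias
        )
        self.weights_log.append(w)
        return dist


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class SurpriseTable:
    """Per-note surprise/uncertainty records for one model at one context."""

    records: pd.DataFrame
    model_name: str = "model"
    context_length: int = 0

    _COLUMNS = (
        "composition_id",
        "note_index",
        "surprise",
        "uncertainty",
        "predicted_pitch",
        "correct",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self._COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"SurpriseTable missing columns {missing}")
        if (self.records["surprise"] < 0).any():
            raise ValueError("surprise must be non-negative")
        u = self.records["uncertainty"]
        if (u < 0).any() or (u > LN_ALPHABET + 1e-9).any():
            raise ValueError("uncertainty must lie in [0, ln 128]")
        dup = self.records.duplicated(["composition_id", "note_index"])
        if dup.any():
            raise ValueError("duplicate (composition_id, note_index) records")

    def __len__(self) -> int:
        return len(self.records)


def evaluate_model(
    predictor: PitchPredictor, test: Corpus, k: int
) -> tuple[SurpriseTable, pd.DataFrame, dict]:
    """Evaluate a predictor on a test corpus at context length k.

    The context for note t is truncated to the most recent k notes of the
    same composition; the first note of every composition is scored against
    the uniform 1/128 prior.  Argmax ties resolve to the lowest pitch.

    Returns (table, per_composition, overall) where per_composition holds
    accuracy, median surprise and median uncertainty per piece, and overall
    holds their medians across compositions plus the cross-entropy (mean
    surprise across all notes).
    """
    if k < 1:
        raise ValueError("context length k must be >= 1")
    rows = []
    for seq in test:
        if hasattr(predictor, "begin_composition"):
            predictor.begin_composition()
        pitches = seq.pitches
        for t, pitch in enumerate(pitches):
            if t == 0:
                dist = uniform_distribution()
            else:
                dist = predictor.predict(pitches[max(0, t - k) : t])
            pred = int(np.argmax(dist))  # first max = lowest pitch
            rows.append(
                {
                    "composition_id": seq.composition_id,
                    "note_index": t,
                    "surprise": surprise(dist, pitch),
                    "uncertainty": uncertainty(dist),
                    "predicted_pitch": pred,
                    "correct": pred == pitch,
                }
            )
            if hasattr(predictor, "observe"):
                predictor.observe(pitch)
    records = pd.DataFrame(rows)
    name = getattr(predictor, "name", type(predictor).__name__)
    table = SurpriseTable(records, model_name=name, context_length=k)
    per_comp = (
        records.groupby("composition_id")
        .agg(
            accuracy=("correct", "mean"),
            median_surprise=("surprise", "median"),
            median_uncertainty=("uncertainty", "median"),
        )
        .reset_index()
    )
    overall = {
        "model": name,
        "context_length": k,
        "accuracy": float(per_comp["accuracy"].median()),
        "median_surprise": float(per_comp["median_surprise"].median()),
        "median_uncertainty": float(per_comp["median_uncertainty"].median()),
        "cross_entropy": float(records["surprise"].mean()),
    }
    return table, per_comp, overall


def save_surprise_table(table: SurpriseTable, path) -> None:
    table.records.to_csv(path, index=False)


def load_external_surprise(
    path, corpus: Corpus, model_name: str = "external", context_length: int = 0
) -> SurpriseTable:
    """Load per-note estimates produced outside the package (e.g. by a
    neural-network music model) and validate their alignment to a corpus."""
    df = pd.read_csv(path)
    required = ["composition_id", "note_index", "surprise", "uncertainty"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"external table missing columns {missing}")
    if "predicted_pitch" not in df.columns:
        df["predicted_pitch"] = -1
    if "correct" not in df.columns:
        df["correct"] = False
    for seq in corpus:
        sub = df[df["composition_id"] == seq.composition_id]
        if len(sub) != len(seq):
            raise ValueError(
                f"composition {seq.composition_id}: {len(sub)} rows for "
                f"{len(seq)} notes"
            )
        if sorted(sub["note_index"]) != list(range(len(seq))):
            raise ValueError(
                f"composition {seq.composition_id}: note_index not 0..n-1"
            )
    return SurpriseTable(df, model_name=model_name, context_length=context_length)
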