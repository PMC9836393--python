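"""Expectation models: information measures, Gestalt model vs brute-force
enumeration, n-gram smoothing vs an independent recursion, and evaluation."""

import math
from collections import Counter, defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melotrf.note_io import Corpus, NoteEvent, NoteSequence
from melotrf.expectation_models import (
    ALPHABET,
    LN_ALPHABET,
    BothPredictor,
    NGramPredictor,
    STMPredictor,
    SurpriseTable,
    TemperleyParams,
    TemperleyPredictor,
    combine_both,
    evaluate_model,
    fit_temperley_params,
    load_external_surprise,
    ngram_predict,
    ngram_train,
    raw_ngram_ratio,
    save_surprise_table,
    surprise,
    temperley_predict,
    uncertainty,
    uniform_distribution,
)

from conftest import make_seq

FLOOR = 1e-6


# ---------------------------------------------------------------------------
# surprise / uncertainty closed forms
# ---------------------------------------------------------------------------


def test_uniform_surprise_and_entropy():
    d = uniform_distribution()
    assert surprise(d, 64) == pytest.approx(math.log(128), abs=1e-12)
    assert uncertainty(d) == pytest.approx(4.852030263919617, abs=1e-12)


def test_surprise_closed_forms():
    onehot = np.zeros(ALPHABET)
    onehot[60] = 1.0
    assert surprise(onehot, 60) == 0.0
    half = np.zeros(ALPHABET)
    half[[60, 62]] = 0.5
    assert surprise(half, 60) == pytest.approx(math.log(2), abs=1e-12)
    assert uncertainty(half) == pytest.approx(math.log(2), abs=1e-12)
    assert uncertainty(onehot) == 0.0
    with pytest.raises(ValueError):
        surprise(uniform_distribution(), 128)


# ---------------------------------------------------------------------------
# Gestalt model vs naive (c, key, x) enumeration
# ---------------------------------------------------------------------------


def brute_force_gestalt(context, params):
    """Independent triple-loop enumeration of the Gestalt model."""
    c0, var_c0, v_r, v_x, p_maj = (
        params.c0, params.var_c0, params.v_r, params.v_x, params.p_maj,
    )
    prof = params.key_profiles

    def key_val(key, x):
        tonic = key % 12
        return prof[key, (x - tonic) % 12]

    pc = [math.exp(-((c - c0) ** 2) / (2 * var_c0)) for c in range(128)]
    s = sum(pc)
    pc = [v / s for v in pc]
    pk = [p_maj / 12] * 12 + [(1 - p_maj) / 12] * 12

    def cond(c, key, prev):
        u = []
        for x in range(128):
            r = math.exp(-((x - c) ** 2) / (2 * v_r))
            px = 1.0 if prev is None else math.exp(-((x - prev) ** 2) / (2 * v_x))
            u.append(r * px * key_val(key, x))
        z = sum(u)
        return [v / z for v in u] if z > 0 else u

    post = [[pc[c] * pk[k] for k in range(24)] for c in range(128)]
    prev = None
    for pitch in context:
        tot = 0.0
        for c in range(128):
            for k in range(24):
                post[c][k] *= cond(c, k, prev)[pitch]
                tot += post[c][k]
        post = [[post[c][k] / tot for k in range(24)] for c in range(128)]
        prev = pitch
    pred = np.zeros(128)
    for c in range(128):
        for k in range(24):
            pred += post[c][k] * np.array(cond(c, k, prev))
    pred = (1 - FLOOR) * pred / pred.sum() + FLOOR / 128
    return pred / pred.sum()


@pytest.mark.parametrize("context", [[], [60], [60, 62, 64]])
def test_gestalt_matches_enumeration_oracle(context):
    params = TemperleyParams()
    fast = temperley_predict(context, params)
    slow = brute_force_gestalt(context, params)
    assert np.abs(fast - slow).max() < 1e-10
    assert fast.sum() == pytest.approx(1.0, abs=1e-12)


def test_gestalt_empty_context_mode_at_central_pitch():
    uniform_profiles = np.full((24, 12), 1 / 12)
    params = TemperleyParams(key_profiles=uniform_profiles)
    dist = temperley_predict([], params)
    assert int(np.argmax(dist)) == 72


def test_gestalt_proximity_dominates_in_limit():
    uniform_profiles = np.full((24, 12), 1 / 12)
    params = TemperleyParams(v_x=0.25, key_profiles=uniform_profiles)
    dist = temperley_predict([60] * 10, params)
    assert int(np.argmax(dist)) == 60


def test_fit_params_degenerate_and_hand_computed():
    const = make_seq([70] * 10, composition_id="const")
    p = fit_temperley_params(Corpus([const]))
    assert p.c0 == 70 and p.var_c0 == 0

    a = make_seq([60] * 8, composition_id="a")
    b = make_seq([80] * 8, composition_id="b")
    p2 = fit_temperley_params(Corpus([a, b]))
    assert p2.c0 == pytest.approx(70)
    assert p2.var_c0 == pytest.approx(100)  # population variance of (60, 80)


def test_fit_key_profiles_from_labels():
    seq = make_seq([60, 62, 64, 60], composition_id="cmaj")
    p = fit_temperley_params(
        Corpus([seq]), key_labels={"cmaj": (0, "major")}
    )
    assert p.p_maj == 1.0
    # scale degrees 0,2,4 observed with frequencies 2/4, 1/4, 1/4
    assert p.key_profiles[0, 0] == pytest.approx(0.5)
    assert p.key_profiles[0, 2] == pytest.approx(0.25)
    with pytest.raises(ValueError):
        fit_temperley_params(Corpus([seq]), key_labels={})


# ---------------------------------------------------------------------------
# n-gram models
# ---------------------------------------------------------------------------


def test_ngram_counts_brute_force(tiny_seq):
    model = ngram_train(Corpus([tiny_seq]), 2)
    assert model.counts[(60,)] == 3
    assert model.counts[(60, 62)] == 2
    assert model.counts[(62, 60)] == 2
    assert (60, 62, 60) in model.counts


def test_ngram_order_bound_limits_gram_length(tiny_seq):
    model = ngram_train(Corpus([tiny_seq]), 1)
    assert max(len(g) for g in model.counts) == 2


def test_ngram_prefix_consistency_random_corpus(small_corpus):
    """Every (m+1)-gram count <= the occurrence count of its m-gram prefix,
    re-counted from scratch."""
    model = ngram_train(small_corpus, 3)
    # independent recount
    recount = Counter()
    for seq in small_corpus:
        p = seq.pitches
        for m in range(1, 5):
            for t in range(len(p) - m + 1):
                recount[tuple(p[t : t + m])] += 1
    for gram, c in model.counts.items():
        assert c == recount[gram]
        if len(gram) > 1:
            assert c <= recount[gram[:-1]]


def ppm_oracle(sequences, order_bound, context, x):
    """Independent recursion of the interpolated escape smoothing."""
    cont = defaultdict(Counter)
    for p in sequences:
        for t in range(len(p)):
            for m in range(0, min(order_bound, t) + 1):
                cont[tuple(p[t - m : t])][p[t]] += 1

    def prob(ctx):
        c = cont.get(tuple(ctx))
        if not c:
            return prob(ctx[1:]) if ctx else 1.0 / 128
        n = sum(c.values())
        d = len(c)
        lower = prob(ctx[1:]) if ctx else 1.0 / 128
        return (1 - d / (n + d)) * c[x] / n + (d / (n + d)) * lower

    p = prob(list(context)[-order_bound:])
    return (1 - FLOOR) * p + FLOOR / 128  # the uniform floor mix


def test_ngram_smoothing_matches_independent_recursion():
    train = [[60, 62, 60, 62]]
    model = ngram_train(
        Corpus([make_seq(train[0], composition_id="t")]), 2
    )
    dist = ngram_predict(model, [60])
    assert int(np.argmax(dist)) == 62
    for x in (62, 60, 64):
        assert dist[x] == pytest.approx(ppm_oracle(train, 2, [60], x), abs=1e-12)
    # raw relative frequency per the count-ratio definition
    raw = raw_ngram_ratio(ngram_train(Corpus([make_seq(train[0], composition_id="t")]), 1), [60])
    assert raw[62] == 1.0


def test_untrained_model_predicts_uniform():
    from melotrf.expectation_models import NGramModel

    model = NGramModel(2)
    np.testing.assert_allclose(ngram_predict(model, [60, 62]), 1 / 128)


def test_stm_counts_equal_batch_training_after_full_pass(tiny_seq):
    stm = STMPredictor(2)
    stm.begin_composition()
    for p in tiny_seq.pitches:
        stm.observe(p)
    batch = ngram_train(Corpus([tiny_seq]), 2)
    assert stm.model.counts == batch.counts


def test_stm_is_strictly_causal():
    """Permuting future notes never changes the prediction for note t."""
    base = [60, 62, 64, 65, 67, 60, 62]
    alt = base[:4] + [72, 71, 48]  # same first 4 notes, different future
    preds = {}
    for label, pitches in (("base", base), ("alt", alt)):
        stm = STMPredictor(3)
        stm.begin_composition()
        out = []
        for t, p in enumerate(pitches):
            out.append(stm.predict(pitches[max(0, t - 3) : t]))
            stm.observe(p)
        preds[label] = out
    for t in range(4):
        np.testing.assert_array_equal(preds["base"][t], preds["alt"][t])


def test_stm_surprise_nonincreasing_on_repetition():
    stm = STMPredictor(2)
    stm.begin_composition()
    vals = []
    for t in range(6):
        dist = stm.predict([60] * min(t, 2)) if t else uniform_distribution()
        vals.append(surprise(dist, 60))
        stm.observe(60)
    assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# stm + ltm combination
# ---------------------------------------------------------------------------


def test_combine_equal_entropies_symmetric():
    a = np.zeros(ALPHABET)
    a[[60, 62]] = 0.5
    b = np.zeros(ALPHABET)
    b[[64, 66]] = 0.5
    dist, (ws, wl) = combine_both(a, b)
    assert ws == pytest.approx(0.5) and wl == pytest.approx(0.5)
    # normalized geometric mean, then floored
    geo = np.sqrt(np.maximum(a, 1e-300) * np.maximum(b, 1e-300))
    expected = (1 - FLOOR) * geo / geo.sum() + FLOOR / ALPHABET
    np.testing.assert_allclose(dist, expected / expected.sum(), atol=1e-9)


def test_combine_onehot_takes_all_weight():
    onehot = np.zeros(ALPHABET)
    onehot[60] = 1.0
    dist, (ws, wl) = combine_both(onehot, uniform_distribution())
    assert ws == 1.0 and wl == 0.0
    assert int(np.argmax(dist)) == 60


def test_combine_matches_stated_formula(rng):
    a = rng.dirichlet(np.ones(ALPHABET))
    b = rng.dirichlet(np.ones(ALPHABET))
    dist, (ws, wl) = combine_both(a, b, bias=2.0)
    ha = uncertainty(a) / LN_ALPHABET
    hb = uncertainty(b) / LN_ALPHABET
    w = np.array([ha, hb]) ** -2.0
    w = w / w.sum()
    assert ws == pytest.approx(w[0], abs=1e-12)
    mix = a**w[0] * b**w[1]
    mix = (1 - FLOOR) * mix / mix.sum() + FLOOR / ALPHABET
    np.testing.assert_allclose(dist, mix / mix.sum(), atol=1e-9)
    assert dist.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


class UniformPredictor:
    name = "uniform"

    def predict(self, context):
        return uniform_distribution()


def test_uniform_predictor_surprise_and_chance_level(small_corpus):
    table, per_comp, overall = evaluate_model(UniformPredictor(), small_corpus, k=2)
    np.testing.assert_allclose(table.records["surprise"], LN_ALPHABET)
    # chance probability of a correct guess under the uniform distribution
    chance = float(uniform_distribution()[small_corpus.sequences[0].pitches[0]])
    assert chance == pytest.approx(1 / 128)
    assert overall["cross_entropy"] == pytest.approx(LN_ALPHABET)


def test_single_note_composition_scored_against_uniform_prior():
    seq = NoteSequence([NoteEvent(72, 0.0, 0.3)], composition_id="one")
    table, _, _ = evaluate_model(UniformPredictor(), Corpus([seq]), k=1)
    assert table.records["surprise"].iloc[0] == pytest.approx(4.852, abs=1e-3)
    assert table.records["uncertainty"].iloc[0] == pytest.approx(4.852, abs=1e-3)


def test_context_truncated_to_k(small_corpus):
    """A k=1 evaluation must give the ltm model 1-note contexts only."""
    model = ngram_train(small_corpus, 4)
    seen = []

    class Spy:
        name = "spy"

        def predict(self, context):
            seen.append(len(context))
            return ngram_predict(model, context)

    evaluate_model(Spy(), small_corpus, k=1)
    assert max(seen) == 1


def test_external_surprise_round_trip(tmp_path, small_corpus):
    model = ngram_train(small_corpus, 2)
    table, _, _ = evaluate_model(NGramPredictor(model), small_corpus, k=2)
    path = tmp_path / "ext.csv"
    save_surprise_table(table, path)
    back = load_external_surprise(path, small_corpus)
    np.testing.assert_allclose(
        back.records["surprise"].to_numpy(), table.records["surprise"].to_numpy()
    )


def test_external_surprise_alignment_errors(tmp_path, small_corpus):
    model = ngram_train(small_corpus, 2)
    table, _, _ = evaluate_model(NGramPredictor(model), small_corpus, k=2)
    df = table.records.iloc[:-1]  # drop one row
    path = tmp_path / "short.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="rows for"):
        load_external_surprise(path, small_corpus)
    bad = table.records.copy()
    bad.loc[0, "uncertainty"] = 5.0  # > ln 128
    path2 = tmp_path / "bad.csv"
    bad.to_csv(path2, index=False)
    with pytest.raises(ValueError):
        load_external_surprise(path2, small_corpus)


# ---------------------------------------------------------------------------
# distribution invariants (property tests)
# ---------------------------------------------------------------------------

contexts = st.lists(st.integers(0, 127), min_size=0, max_size=6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(context=contexts)
def test_ngram_predictions_are_distributions(context):
    seq = make_seq([60, 62, 64, 65, 67, 65, 64, 62, 60], composition_id="p")
    model = ngram_train(Corpus([seq]), 3)
    dist = ngram_predict(model, context)
    assert np.all(dist >= 0)
    assert dist.sum() == pytest.approx(1.0, abs=1e-9)
    obs = context[-1] if context else 60
    assert surprise(dist, obs) >= 0
    assert 0 <= uncertainty(dist) <= LN_ALPHABET + 1e-9


@settings(max_examples=10, deadline=None, derandomize=True)
@given(context=contexts)
def test_gestalt_predictions_are_distributions(context):
    dist = temperley_predict(context)
    assert np.all(dist >= 0)
    assert dist.sum() == pytest.approx(1.0, abs=1e-9)
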