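import numpy as np
import pytest

from melotrf.note_io import Corpus, NoteEvent, NoteSequence
from melotrf.synthetic_data import MelodyGenConfig, generate_corpus


def make_seq(pitches, ioi=0.25, composition_id="seq"):
    return NoteSequence(
        [NoteEvent(int(p), i * ioi, 0.8 * ioi) for i, p in enumerate(pitches)],
        composition_id=composition_id,
    )


@pytest.fixture
def tiny_seq():
    return make_seq([60, 62, 60, 62, 60], composition_id="tiny")


@pytest.fixture
def small_corpus():
    cfg = MelodyGenConfig(n_notes=60, seed=7, motif_repeat_prob=0.0)
    return generate_corpus(cfg, 3, name="small")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
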