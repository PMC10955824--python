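import os

# the suite runs many small linear-algebra problems; BLAS threading only
# adds contention at these sizes
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from chatthemes.corpus import Conversation, Corpus, LabelSet, Message


def make_conv(cid, year, month, texts, speakers=None, age=None):
    """Build a conversation from a list of message texts."""
    if speakers is None:
        speakers = ["user" if i % 2 == 0 else "volunteer" for i in range(len(texts))]
    msgs = tuple(Message(speaker=s, text=t, index=i) for i, (s, t) in enumerate(zip(speakers, texts)))
    return Conversation(id=cid, year=year, month=month, messages=msgs, age=age)


@pytest.fixture
def tiny_corpus():
    """Six hand-built conversations over two months with full labels."""
    convs = [
        make_conv("a1", 2020, 1, ["I hate my body", "tell me more", "so ugly"], age=18),
        make_conv("a2", 2020, 1, ["my mom and dad fight", "how does that feel"]),
        make_conv("a3", 2020, 1, ["exams and grades stress me", "I see"], age=22),
        make_conv("b1", 2020, 2, ["I feel alone", "who is around you", "my family ignores me"]),
        make_conv("b2", 2020, 2, ["panic attacks at night", "when did they start"]),
        make_conv("b3", 2020, 2, ["just wanted to talk", "I am here"]),
    ]
    labels = {
        "a1": LabelSet(themes={"self_image": 1, "violence": 0, "sexual_diversity": 0,
                               "relational": 0, "emotional_crisis": 0, "performance": 0}),
        "a2": LabelSet(themes={"self_image": 0, "violence": 0, "sexual_diversity": 0,
                               "relational": 1, "emotional_crisis": 0, "performance": 0}),
        "a3": LabelSet(themes={"self_image": 0, "violence": 0, "sexual_diversity": 0,
                               "relational": 0, "emotional_crisis": 0, "performance": 1}),
        "b1": LabelSet(themes={"self_image": 0, "violence": 0, "sexual_diversity": 0,
                               "relational": 1, "emotional_crisis": 0, "performance": 0}),
        "b2": LabelSet(themes={"self_image": 0, "violence": 0, "sexual_diversity": 0,
                               "relational": 0, "emotional_crisis": 1, "performance": 0}),
        "b3": LabelSet(themes={"self_image": 0, "violence": 0, "sexual_diversity": 0,
                               "relational": 0, "emotional_crisis": 0, "performance": 0}),
    }
    return Corpus(conversations=convs, labels=labels)


@pytest.fixture(scope="session")
def small_synth():
    """A 300-conversation synthetic corpus shared across tests (read-only)."""
    from chatthemes.synthetic import GeneratorConfig, generate_corpus

    cfg = GeneratorConfig(n_conversations=300, seed=13)
    corpus, truth = generate_corpus(cfg)
    return cfg, corpus, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
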