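import numpy as np
import pytest

from glycurate.splits import LabeledSet, encode_label
from glycurate.text_pipeline import Lexicons, load_default_lexicons


@pytest.fixture(scope="session")
def default_lexicons() -> Lexicons:
    return load_default_lexicons()


@pytest.fixture
def tiny_lexicons() -> Lexicons:
    """A small, fully hand-checkable lexicon set."""
    return Lexicons(
        word_lists={
            "biology": {"gene", "chromatin"},
            "methods": {"western blot", "immunoblot"},
        },
        regex_lists={
            "o-glcnac": [r"\boglcnac\w*\b"],
            "ser/thr": [r"\b(?:ser|thr|[st])\d{1,4}\b"],
        },
        protein_names={"tau", "ogt"},
        organism_names={"mouse", "human"},
        stop_words={"et al"},
        tag_symbols={"o-glcnac": "OGLCNAC", "ser/thr": "STSITES"},
    )


def make_labeled_set(n_pos: int, n_neg: int, prefix: str = "D") -> LabeledSet:
    ids = tuple(f"{prefix}{i:05d}" for i in range(n_pos + n_neg))
    labels = tuple(
        encode_label("positive" if i < n_pos else "negative") for i in range(n_pos + n_neg)
    )
    return LabeledSet(ids=ids, labels=labels)


@pytest.fixture
def balanced_pool_1340() -> LabeledSet:
    return make_labeled_set(670, 670)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
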