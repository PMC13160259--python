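"""Shared fixtures: small generated corpora and a trained cascade.

Everything is generated programmatically at test time; nothing is read from
fixture files.
"""

from __future__ import annotations

import pytest

from opnote.cascade import CascadeConfig, train_cascade
from opnote.parser import parse_corpus
from opnote.simulate import generate_corpus, tiny_config
from opnote.taxonomy import DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def tiny_notes():
    return generate_corpus(tiny_config(seed=11))


@pytest.fixture(scope="session")
def tiny_sections(tiny_notes):
    sectioned, _ = parse_corpus(tiny_notes, "operative details")
    return {s.note_id: s.target_text for s in sectioned if s.status == "parsed"}


@pytest.fixture(scope="session")
def fast_config():
    """Reduced tree count for unit tests; statistical contracts still hold."""
    return CascadeConfig(n_trees=60, seed=42)


@pytest.fixture(scope="session")
def tiny_cascade(tiny_notes, tiny_sections, fast_config):
    return train_cascade(tiny_notes, tiny_sections, DEFAULT_TAXONOMY, fast_config)
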