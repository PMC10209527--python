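import numpy as np
import pytest

from duore.datamodel import Document, EntitySpan, RelationSchema, SchemaEntry
from duore.encoding import CharTokenizer, EncoderConfig


def make_doc(text: str, doc_id: str = "d0", gold=None) -> Document:
    return Document(doc_id=doc_id, text=text, tokens=list(text), gold=gold or set())


def span(doc: Document, h: int, t: int) -> EntitySpan:
    return EntitySpan(h, t, "".join(doc.tokens[h : t + 1]))


@pytest.fixture
def schema2() -> RelationSchema:
    return RelationSchema(
        [
            SchemaEntry("treats", "treats", "drug", "disease"),
            SchemaEntry("prevents", "prevents", "drug", "disease"),
        ]
    )


@pytest.fixture
def tiny_enc_cfg() -> EncoderConfig:
    return EncoderConfig(layers=1, d=16, heads=2, d_ffn=32, dropout=0.1, max_len=64)


@pytest.fixture
def ascii_tokenizer() -> CharTokenizer:
    return CharTokenizer("abcdefghijklmnopqrstuvwxyz .")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
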