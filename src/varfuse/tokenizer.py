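"""Whitespace/punctuation tokenizer for desk-scale caption text.

Captions in this package are compact JSON strings whose values are single
word-tokens (``intron_variant``, ``G07``), so a regex split into word and
punctuation tokens is lossless and detokenization is plain concatenation.
A real decoder's tokenizer can be substituted wherever a ``Tokenizer`` is
accepted; only ``encode``/``decode`` and the special ids are used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+|[^\sA-Za-z0-9_]")

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = [PAD, BOS, EOS, UNK]


def split_text(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


@dataclass
class Tokenizer:
    vocab: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for tok in SPECIALS:
            self.vocab.setdefault(tok, len(self.vocab))
        self._inv = {i: t for t, i in self.vocab.items()}

    @classmethod
    def from_corpus(cls, texts: list[str], max_vocab: int | None = None) -> "Tokenizer":
        counts: dict[str, int] = {}
        for text in texts:
            for tok in split_text(text):
                counts[tok] = counts.get(tok, 0) + 1
        ordered = sorted(counts, key=lambda t: (-counts[t], t))
        if max_vocab is not None:
            ordered = ordered[: max_vocab - len(SPECIALS)]
        tok = cls()
        for t in ordered:
            tok.vocab.setdefault(t, len(tok.vocab))
        tok._inv = {i: t for t, i in tok.vocab.items()}
        return tok

    def __len__(self) -> int:
        return len(self.vocab)

    @property
    def pad_id(self) -> int:
        return self.vocab[PAD]

    @property
    def bos_id(self) -> int:
        return self.vocab[BOS]

    @property
    def eos_id(self) -> int:
        return self.vocab[EOS]

    def encode(self, text: str, add_special: bool = True) -> list[int]:
        unk = self.vocab[UNK]
        ids = [self.vocab.get(t, unk) for t in split_text(text)]
        if add_special:
            ids = [self.bos_id] + ids + [self.eos_id]
        return ids

    def decode(self, ids: list[int], strip_special: bool = True) -> str:
        toks = [self._inv.get(int(i), UNK) for i in ids]
        if strip_special:
            toks = [t for t in toks if t not in SPECIALS]
        return "".join(toks)
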