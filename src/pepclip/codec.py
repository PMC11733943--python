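"""Peptide sequence encodings.

Two representations are produced from the same 20-letter alphabet:

* an index encoding — each residue replaced by its position in the fixed
  alphabet ``ACDEFGHIKLMNPQRSTVWY`` (round-trippable);
* a language-model tokenization — one token per residue wrapped in
  classification/separator specials, right-padded, with an attention
  mask marking real tokens.

The built-in vocabulary ships with the package so no download is ever
required; ``load_vocab`` accepts any JSON token map with the same four
special tokens for plug-in compatibility with external models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
N_SPECIAL_PER_SEQUENCE = 2  # leading [CLS] + trailing [SEP]


def load_vocab(path=None) -> dict[str, int]:
    if path is None:
        text = resources.files("pepclip.data").joinpath("vocab.json").read_text()
    else:
        text = open(path).read()
    vocab = json.loads(text)
    for special in (PAD, UNK, CLS, SEP):
        if special not in vocab:
            raise ValueError(f"vocabulary is missing special token {special}")
    return vocab


@dataclass
class IndexEncoding:
    indices: list[int]
    alphabet: str = ALPHABET
    pad_index: int = field(default=-1)  # no padding by default


@dataclass
class TokenizedSequence:
    token_ids: list[int]
    attention_mask: list[int]

    def __post_init__(self):
        if len(self.token_ids) != len(self.attention_mask):
            raise ValueError("token ids and attention mask lengths differ")


def validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for pos, ch in enumerate(sequence):
        if ch not in _INDEX:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} (1-based {pos + 1})"
            )


def encode_indices(sequence: str) -> IndexEncoding:
    validate_sequence(sequence)
    return IndexEncoding(indices=[_INDEX[ch] for ch in sequence])


def decode_indices(encoding: IndexEncoding) -> str:
    chars = []
    for i, idx in enumerate(encoding.indices):
        if not 0 <= idx < len(encoding.alphabet):
            raise ValueError(f"index {idx} at position {i} is out of alphabet range")
        chars.append(encoding.alphabet[idx])
    return "".join(chars)


def tokenize_for_lm(
    sequence: str, max_length: int, vocab: dict[str, int] | None = None
) -> TokenizedSequence:
    vocab = vocab if vocab is not None else load_vocab()
    validate_sequence(sequence)
    needed = len(sequence) + N_SPECIAL_PER_SEQUENCE
    if needed > max_length:
        raise ValueError(
            f"sequence of length {len(sequence)} needs {needed} tokens "
            f"but max_length is {max_length}"
        )
    ids = [vocab[CLS]] + [vocab.get(ch, vocab[UNK]) for ch in sequence] + [vocab[SEP]]
    mask = [1] * len(ids)
    pad = max_length - len(ids)
    ids += [vocab[PAD]] * pad
    mask += [0] * pad
    return TokenizedSequence(token_ids=ids, attention_mask=mask)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
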