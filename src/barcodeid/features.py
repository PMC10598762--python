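"""k-mer count featurization of barcode sequences.

Sequences are tokenized into overlapping k-mers (stride 1) and counted
against a vocabulary frozen on the training corpus — the bag-of-words model
applied to DNA, with k-mers as words.  A length-L sequence yields L-k+1
tokens; the feature vector of a sample is the per-vocabulary-token count.

Ambiguous IUPAC letters (N, R, Y, ...) are kept verbatim inside tokens; they
simply become rare vocabulary entries.  At prediction time, tokens outside
the training vocabulary are silently dropped (fit-then-transform contract).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

__all__ = [
    "KmerVocabulary",
    "kmerize",
    "build_vocabulary",
    "vectorize",
    "encode_sequences",
    "save_count_matrix",
]

DEFAULT_K = 7


def kmerize(sequence: str, k: int) -> list[str]:
    """Overlapping k-mers of ``sequence``, left to right, uppercase.

    Returns exactly ``max(0, L - k + 1)`` tokens; a sequence shorter than
    ``k`` yields an empty list (the caller decides how to handle it).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


@dataclass(frozen=True)
class KmerVocabulary:
    """Ordered k-mer vocabulary with token -> column index mapping.

    Tokens are the distinct k-mers of the training corpus in lexicographic
    order, so the feature layout is a deterministic function of the corpus.
    """

    k: int
    tokens: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("vocabulary must contain at least one token")
        if any(len(t) != self.k for t in self.tokens):
            raise ValueError(f"all vocabulary tokens must have length k={self.k}")
        object.__setattr__(
            self, "index", {tok: j for j, tok in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def save(self, path: str | Path) -> None:
        """One token per line; k is recoverable from the token length."""
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerVocabulary":
        tokens = tuple(
            line.strip() for line in Path(path).read_text().splitlines() if line.strip()
        )
        if not tokens:
            raise ValueError(f"empty vocabulary file: {path}")
        return cls(k=len(tokens[0]), tokens=tokens)


def build_vocabulary(token_lists: Sequence[Sequence[str]]) -> KmerVocabulary:
    """Vocabulary = sorted distinct tokens of the training corpus.

    Raises ``ValueError`` when every token list is empty (no sequence reached
    length k), since an empty vocabulary cannot featurize anything.
    """
    distinct: set[str] = set()
    for tokens in token_lists:
        distinct.update(tokens)
    if not distinct:
        raise ValueError("cannot build a vocabulary from an all-empty corpus")
    ordered = tuple(sorted(distinct))
    return KmerVocabulary(k=len(ordered[0]), tokens=ordered)


def vectorize(
    token_lists: Sequence[Sequence[str]], vocab: KmerVocabulary
) -> sp.csr_matrix:
    """Count matrix: entry (i, j) = occurrences of vocabulary token j in sample i.

    Out-of-vocabulary tokens are dropped, so a sample sharing no k-mer with
    the training corpus becomes an all-zero row.  The result is CSR with
    shape ``(len(token_lists), len(vocab))``.
    """
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    index = vocab.index
    for tokens in token_lists:
        counts = Counter(tokens)
        cols = sorted(
            index[tok] for tok in counts.keys() & index.keys()
        )
        row_counts = Counter({index[tok]: n for tok, n in counts.items() if tok in index})
        indices.extend(cols)
        data.extend(row_counts[j] for j in cols)
        indptr.append(len(indices))
    matrix = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), indices, indptr),
        shape=(len(token_lists), len(vocab)),
    )
    return matrix


def encode_sequences(
    sequences: Iterable[str],
    k: int = DEFAULT_K,
    vocab: KmerVocabulary | None = None,
) -> tuple[sp.csr_matrix, KmerVocabulary]:
    """Tokenize and count in one step.

    When ``vocab`` is None it is built from ``sequences`` (training mode);
    otherwise the given vocabulary is used unchanged (prediction mode).
    """
    token_lists = [kmerize(seq, k) for seq in sequences]
    if vocab is None:
        vocab = build_vocabulary(token_lists)
    elif vocab.k != k:
        raise ValueError(f"vocabulary was built for k={vocab.k}, got k={k}")
    return vectorize(token_lists, vocab), vocab


def save_count_matrix(
    matrix: sp.spmatrix, vocab: KmerVocabulary, prefix: str | Path
) -> None:
    """Dump features as MatrixMarket plus a one-token-per-line vocabulary file."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), matrix)
    vocab.save(prefix.with_suffix(".vocab.txt"))
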