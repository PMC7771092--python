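"""Tokenization, word-embedding I/O and mention representations.

Mentions are represented two ways: as the arithmetic mean of their token
embeddings (for the feedforward branch) and as a zero-padded token-by-
dimension matrix (for the convolutional branch).
"""

from __future__ import annotations

import logging
import re
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from conceptnorm.errors import FormatError

__all__ = [
    "EmbeddingTable",
    "MentionMatrix",
    "load_embeddings",
    "save_embeddings",
    "normalize_unit",
    "tokenize_filter",
    "mention_average",
    "mention_matrix",
    "default_stopwords",
    "load_stopwords",
]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[0-9a-z]+")


@dataclass
class EmbeddingTable:
    """Token -> vector map with a fixed dimension."""

    dimension: int
    vectors: dict[str, np.ndarray]
    unit_normalized: bool = False

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def get(self, token: str) -> np.ndarray | None:
        return self.vectors.get(token)


@dataclass
class MentionMatrix:
    """Padded token-embedding matrix of one mention.

    ``rows`` is (pad_length, D); the first ``n_tokens`` rows hold real token
    vectors, the rest are zero.  ``flagged`` marks mentions with no
    in-vocabulary token.
    """

    rows: np.ndarray
    n_tokens: int
    flagged: bool = field(default=False)


def tokenize_filter(text: str, stopwords: set[str] | frozenset[str] = frozenset()) -> list[str]:
    """Lowercase, split into alphanumeric runs and drop stop-words.

    Punctuation never yields a token; order of the surviving tokens is
    preserved.  The empty string tokenizes to an empty list.
    """
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in stopwords]


def default_stopwords() -> frozenset[str]:
    """The English stop-word list shipped with the package."""
    data = resources.files("conceptnorm.data").joinpath("stopwords_en.txt")
    return frozenset(data.read_text(encoding="utf-8").split())


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stop-word file: one token per line, UTF-8."""
    return frozenset(Path(path).read_text(encoding="utf-8").split())


# ---------------------------------------------------------------------------
# word2vec I/O


def load_embeddings(path: str | Path, format: str = "word2vec-text") -> EmbeddingTable:
    """Load a word2vec table in text or binary serialization.

    Token casing is preserved exactly as stored.  A token stored twice keeps
    its last vector (a warning is logged).

    Parameters
    ----------
    path
        File to read.
    format
        ``"word2vec-text"`` (header ``"V D"`` then one ``token w1 .. wD``
        line per token) or ``"word2vec-binary"`` (same header, then
        ``token<SP>`` followed by D little-endian float32 values).
    """
    path = Path(path)
    if format == "word2vec-text":
        return _load_text(path)
    if format == "word2vec-binary":
        return _load_binary(path)
    raise ValueError(f"unknown embedding format {format!r}")


def _parse_header(header: str, path: Path) -> tuple[int, int]:
    parts = header.split()
    if len(parts) != 2:
        raise FormatError(f"{path}: unreadable word2vec header {header!r}")
    try:
        return int(parts[0]), int(parts[1])
    except ValueError:
        raise FormatError(f"{path}: unreadable word2vec header {header!r}") from None


def _load_text(path: Path) -> EmbeddingTable:
    with open(path, encoding="utf-8") as fh:
        n_tokens, dim = _parse_header(fh.readline(), path)
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(" ")
            token, values = fields[0], fields[1:]
            if len(values) != dim:
                raise FormatError(
                    f"{path}:{lineno}: expected {dim} weights for "
                    f"{token!r}, found {len(values)}"
                )
            if token in vectors:
                logger.warning("duplicate token %r; last occurrence wins", token)
            vectors[token] = np.asarray(values, dtype=np.float64)
    if len(vectors) != n_tokens:
        logger.warning(
            "%s: header declares %d tokens, read %d", path, n_tokens, len(vectors)
        )
    return EmbeddingTable(dimension=dim, vectors=vectors)


def _load_binary(path: Path) -> EmbeddingTable:
    with open(path, "rb") as fh:
        header = b""
        while not header.endswith(b"\n"):
            ch = fh.read(1)
            if not ch:
                raise FormatError(f"{path}: unreadable word2vec header")
            header += ch
        n_tokens, dim = _parse_header(header.decode("utf-8"), path)
        vectors: dict[str, np.ndarray] = {}
        row_size = 4 * dim
        for _ in range(n_tokens):
            token_bytes = b""
            while True:
                ch = fh.read(1)
                if not ch:
                    raise FormatError(f"{path}: truncated binary table")
                if ch == b" ":
                    break
                if ch != b"\n":  # tolerate newline between records
                    token_bytes += ch
            raw = fh.read(row_size)
            if len(raw) != row_size:
                raise FormatError(f"{path}: truncated vector for {token_bytes!r}")
            token = token_bytes.decode("utf-8")
            if token in vectors:
                logger.warning("duplicate token %r; last occurrence wins", token)
            vectors[token] = np.frombuffer(raw, dtype="<f4").astype(np.float64)
    return EmbeddingTable(dimension=dim, vectors=vectors)


def save_embeddings(
    table: EmbeddingTable, path: str | Path, format: str = "word2vec-text"
) -> None:
    """Write a table in word2vec text or binary serialization."""
    path = Path(path)
    if format == "word2vec-text":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(table.vectors)} {table.dimension}\n")
            for token, vec in table.vectors.items():
                weights = " ".join(repr(float(v)) for v in vec)
                fh.write(f"{token} {weights}\n")
    elif format == "word2vec-binary":
        with open(path, "wb") as fh:
            fh.write(f"{len(table.vectors)} {table.dimension}\n".encode("utf-8"))
            for token, vec in table.vectors.items():
                fh.write(token.encode("utf-8") + b" ")
                fh.write(struct.pack(f"<{table.dimension}f", *vec))
    else:
        raise ValueError(f"unknown embedding format {format!r}")


def normalize_unit(table: EmbeddingTable) -> EmbeddingTable:
    """Scale every non-zero vector to Euclidean norm 1.

    Zero vectors are kept as zero (with a warning); the operation is
    idempotent.
    """
    vectors: dict[str, np.ndarray] = {}
    for token, vec in table.vectors.items():
        norm = float(np.linalg.norm(vec))
        if norm == 0.0:
            logger.warning("token %r has a zero vector; left unnormalized", token)
            vectors[token] = vec.copy()
        else:
            vectors[token] = vec / norm
    return EmbeddingTable(
        dimension=table.dimension, vectors=vectors, unit_normalized=True
    )


# ---------------------------------------------------------------------------
# Mention representations


def mention_average(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Arithmetic mean of the vectors of the in-vocabulary tokens.

    Out-of-vocabulary tokens are skipped; with no in-vocabulary token the
    zero vector is returned and a warning logged.
    """
    hits = [table.vectors[t] for t in tokens if t in table.vectors]
    if not hits:
        logger.warning("mention %r has no in-vocabulary token", list(tokens))
        return np.zeros(table.dimension)
    return np.mean(hits, axis=0)


def mention_matrix(
    tokens: Sequence[str], table: EmbeddingTable, pad_length: int
) -> MentionMatrix:
    """Stack the first ``pad_length`` in-vocabulary token vectors, zero-padded.

    Tokens beyond ``pad_length`` are truncated with a warning.  A mention
    with no in-vocabulary token yields an all-zero matrix flagged as such.
    """
    if pad_length < 1:
        raise ValueError(f"pad_length must be >= 1, got {pad_length}")
    hits = [table.vectors[t] for t in tokens if t in table.vectors]
    if len(hits) > pad_length:
        logger.warning(
            "mention with %d in-vocabulary tokens truncated to %d",
            len(hits),
            pad_length,
        )
        hits = hits[:pad_length]
    rows = np.zeros((pad_length, table.dimension))
    for i, vec in enumerate(hits):
        rows[i] = vec
    return MentionMatrix(rows=rows, n_tokens=len(hits), flagged=not hits)


def batch_matrices(
    token_lists: Iterable[Sequence[str]], table: EmbeddingTable, pad_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack mention matrices into (B, L, D) plus a (B, L) validity mask."""
    mats = [mention_matrix(toks, table, pad_length) for toks in token_lists]
    batch = np.stack([m.rows for m in mats]) if mats else np.zeros((0, pad_length, table.dimension))
    mask = np.zeros((len(mats), pad_length), dtype=bool)
    for i, m in enumerate(mats):
        mask[i, : m.n_tokens] = True
    return batch, mask
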