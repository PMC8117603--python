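"""k-mer frequency features: the 84-dimensional baseline.

4 mononucleotide + 16 dinucleotide + 64 trinucleotide overlapping-window
relative frequencies, lexicographic within each k. No reverse-complement
canonicalization: transcripts are stranded, so AC and GT stay distinct.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .entropy import _encode, _word_counts

ALPHABET = "ACGT"

KMER_FEATURE_NAMES: tuple[str, ...] = tuple(
    "".join(w) for k in (1, 2, 3) for w in product(ALPHABET, repeat=k)
)


def kmer_frequencies(seq: str, k: int) -> dict[str, float]:
    """Relative frequencies of length-k words over overlapping windows.

    Windows containing N are skipped; frequencies sum to 1 over the
    observed words (empty dict when no valid window exists).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    counts = _word_counts(_encode(seq), k)
    total = counts.sum()
    if total == 0:
        return {}
    words = ["".join(w) for w in product(ALPHABET, repeat=k)]
    return {w: counts[i] / total for i, w in enumerate(words) if counts[i] > 0}


def kmer_feature_block(seq: str) -> np.ndarray:
    """The ordered 84-entry k-mer frequency vector (k = 1, 2, 3)."""
    if len(seq) < 3:
        raise ValueError(f"sequence length {len(seq)} < 3")
    blocks = []
    codes = _encode(seq)
    for k in (1, 2, 3):
        counts = _word_counts(codes, k)
        total = counts.sum()
        blocks.append(counts / total if total else counts.astype(float))
    return np.concatenate(blocks)
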