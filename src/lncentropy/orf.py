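"""Open-reading-frame detection and ORF-derived features.

Transcripts are treated as already oriented, so only the three forward
frames are scanned. An ORF is a maximal ATG..stop stretch: in each frame,
the first ATG after the previous stop opens a candidate and the next
in-frame stop (TAA/TAG/TGA) closes it. ORF length counts nucleotides of
both the start and the stop codon, so a transcript that is exactly one
ORF has relative length 1. Candidates with no downstream stop are dropped
unless ``allow_open_ended`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

ORF_FEATURE_NAMES: tuple[str, ...] = (
    "length",
    "orf_first_len",
    "orf_first_rel",
    "orf_longest_len",
    "orf_longest_rel",
)


@dataclass(frozen=True)
class Orf:
    """Half-open nucleotide interval [start, end) of an ATG..stop ORF."""

    start: int
    end: int
    frame: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def find_orfs(seq: str, allow_open_ended: bool = False) -> list[Orf]:
    """All maximal forward-strand ORFs, ordered by start position.

    Codons containing N never match a start or stop codon.
    """
    orfs: list[Orf] = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                orfs.append(Orf(start, pos + 3, frame))
                start = None
            pos += 3
        if start is not None and allow_open_ended:
            end = start + 3 * ((n - start) // 3)
            if end - start >= 6:
                orfs.append(Orf(start, end, frame))
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def orf_feature_block(seq: str, allow_open_ended: bool = False) -> np.ndarray:
    """[|seq|, first-ORF length, first-ORF relative length, longest-ORF
    length (ll), longest-ORF relative length (lp)].

    The first ORF is the one with the smallest start coordinate across
    frames (tie -> smaller frame); the longest is the one of maximal
    length (tie -> smaller start). All four ORF entries are 0 when no ORF
    exists.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    orfs = find_orfs(seq, allow_open_ended=allow_open_ended)
    if not orfs:
        return np.array([n, 0.0, 0.0, 0.0, 0.0])
    first = orfs[0]  # already sorted by (start, frame)
    longest = max(orfs, key=lambda o: (o.length_nt, -o.start))
    return np.array(
        [
            n,
            first.length_nt,
            first.length_nt / n,
            longest.length_nt,
            longest.length_nt / n,
        ],
        dtype=float,
    )


def write_orf_bed(seq_id: str, orfs: list[Orf], path: str | Path, append: bool = False) -> None:
    """Dump detected ORFs as BED-like TSV (0-based, half-open)."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for o in orfs:
            fh.write(f"{seq_id}\t{o.start}\t{o.end}\torf_frame{o.frame}\t{o.length_nt}\t+\n")
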