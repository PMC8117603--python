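"""Two-class synthetic transcript generator.

The generator emulates the statistical structure that separates
protein-coding transcripts (PCTs) from lncRNAs in real data, without
mimicking any particular genome:

* coding-like sequences carry one embedded ATG..stop ORF spanning a
  target fraction of the transcript, whose interior codons are drawn
  from a period-3-biased codon distribution (stop-free by construction);
  flanks are background. The periodic bias lowers subword richness, so
  the topological-entropy features separate the classes alongside the
  ORF features.
* noncoding-like sequences are a background Markov chain (order 0, 1 or
  2) with no deliberately embedded ORF.

All randomness flows from a single integer seed through
numpy's PCG64 generator, so a fixed spec reproduces the same dataset on
every run and platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_prep import LNCRNA, PCT, Dataset, Transcript

ALPHABET = "ACGT"
_STOP_CODON_IDS = tuple(
    16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2])
    for c in ("TAA", "TAG", "TGA")
)

# Codon-position nucleotide biases (A, C, G, T): purine/G-rich first
# position, A/T-leaning second, GC-leaning wobble — the broad shape of
# vertebrate coding frames, blended toward uniform by coding_codon_bias.
_POS_WEIGHTS = np.array(
    [
        [0.27, 0.20, 0.33, 0.20],
        [0.31, 0.22, 0.18, 0.29],
        [0.21, 0.29, 0.29, 0.21],
    ]
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class transcript generator.

    Lengths are log-uniform on [min_len, max_len]; min_len must be >= 200
    so every generated transcript passes the pipeline's length filter.
    coding_orf_rel is the (low, high) range of the target longest-ORF
    relative length for the coding class; noise is the fraction of
    class-swapped labels, applied last.
    """

    n_per_class: int = 500
    min_len: int = 200
    max_len: int = 3000
    coding_orf_rel: tuple[float, float] = (0.5, 0.9)
    coding_codon_bias: float = 0.5
    noncoding_markov_order: int = 0
    background_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.min_len < 200:
            raise ValueError("min_len must be >= 200 (pipeline length filter)")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        lo, hi = self.coding_orf_rel
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("coding_orf_rel must satisfy 0 < low <= high <= 1")
        if hi > 1.0 - 6.0 / self.min_len:
            raise ValueError(
                "coding_orf_rel too large for min_len: no room for flanking guard"
            )
        if not (0.0 <= self.coding_codon_bias <= 1.0):
            raise ValueError("coding_codon_bias must be in [0, 1]")
        if self.noncoding_markov_order not in (0, 1, 2):
            raise ValueError("noncoding_markov_order must be 0, 1 or 2")
        if abs(sum(self.background_probs) - 1.0) > 1e-9 or min(self.background_probs) < 0:
            raise ValueError("background_probs must be a probability vector")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must be in [0, 1]")


def _codon_distribution(bias: float) -> np.ndarray:
    """Probability over the 61 non-stop codons: per-position weights
    blended toward uniform by (1 - bias), product over positions."""
    w = bias * _POS_WEIGHTS + (1.0 - bias) * 0.25
    probs = np.einsum("i,j,k->ijk", w[0], w[1], w[2]).reshape(64).copy()
    probs[list(_STOP_CODON_IDS)] = 0.0
    return probs / probs.sum()


def _decode_codons(ids: np.ndarray) -> str:
    chars = np.empty((ids.size, 3), dtype="<U1")
    bases = np.array(list(ALPHABET))
    chars[:, 0] = bases[ids // 16]
    chars[:, 1] = bases[(ids // 4) % 4]
    chars[:, 2] = bases[ids % 4]
    return "".join(chars.ravel())


def _draw_length(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    lo, hi = np.log(spec.min_len), np.log(spec.max_len)
    return int(np.exp(rng.uniform(lo, hi)))


def _markov_transitions(spec: SyntheticSpec) -> np.ndarray | None:
    """Fixed per-spec transition table for order >= 1 backgrounds, drawn
    once from a Dirichlet centered on background_probs."""
    if spec.noncoding_markov_order == 0:
        return None
    rng = np.random.default_rng([spec.seed, 11])
    n_ctx = 4**spec.noncoding_markov_order
    alpha = 20.0 * np.asarray(spec.background_probs)
    return rng.dirichlet(np.maximum(alpha, 1e-3), size=n_ctx)


def _background(
    rng: np.random.Generator, length: int, spec: SyntheticSpec, trans: np.ndarray | None
) -> np.ndarray:
    probs = np.asarray(spec.background_probs)
    order = spec.noncoding_markov_order
    if trans is None or order == 0 or length <= order:
        return rng.choice(4, size=length, p=probs)
    out = np.empty(length, dtype=np.int64)
    out[:order] = rng.choice(4, size=order, p=probs)
    ctx = 0
    for i in range(order):
        ctx = ctx * 4 + out[i]
    mod = 4**order
    u = rng.random(length)
    cum = np.cumsum(trans, axis=1)
    for i in range(order, length):
        nxt = int(np.searchsorted(cum[ctx], u[i], side="right"))
        nxt = min(nxt, 3)
        out[i] = nxt
        ctx = (ctx * 4) % mod + nxt
    return out


_CODES_TO_CHAR = np.array(list(ALPHABET))


def generate_coding_like(spec: SyntheticSpec, count: int) -> Dataset:
    """Coding-like transcripts (labeled PCT): one embedded ORF covering
    roughly a coding_orf_rel fraction of the length, period-3 codon bias
    inside the ORF, in-frame guard stop just upstream so random flank
    sequence cannot extend the ORF."""
    rng = np.random.default_rng([spec.seed, 1])
    codon_probs = _codon_distribution(spec.coding_codon_bias)
    trans = _markov_transitions(spec)
    records = []
    for i in range(count):
        length = _draw_length(rng, spec)
        rel = rng.uniform(*spec.coding_orf_rel)
        n_codons = max(3, int(round(rel * length / 3)))
        orf_len = 3 * n_codons
        if orf_len > length - 3:
            n_codons = (length - 3) // 3
            orf_len = 3 * n_codons
        offset = int(rng.integers(0, length - orf_len + 1))
        inner_ids = rng.choice(64, size=n_codons - 2, p=codon_probs)
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        orf_seq = "ATG" + _decode_codons(inner_ids) + stop
        seq_codes = _background(rng, length, spec, trans)
        seq = list(_CODES_TO_CHAR[seq_codes])
        seq[offset : offset + orf_len] = orf_seq
        if offset >= 3:  # guard stop blocks in-frame upstream extension
            seq[offset - 3 : offset] = "TAA"
        records.append(Transcript(f"pct_{spec.seed}_{i:05d}", "".join(seq), PCT))
    ds = Dataset(records)
    ds.log("generate_coding_like", n=count, seed=spec.seed)
    return ds


def generate_noncoding_like(spec: SyntheticSpec, count: int) -> Dataset:
    """Noncoding-like transcripts (labeled lncRNA): pure background
    Markov chain of the configured order, no ORF deliberately embedded."""
    rng = np.random.default_rng([spec.seed, 2])
    trans = _markov_transitions(spec)
    records = []
    for i in range(count):
        length = _draw_length(rng, spec)
        codes = _background(rng, length, spec, trans)
        records.append(
            Transcript(f"lnc_{spec.seed}_{i:05d}", "".join(_CODES_TO_CHAR[codes]), LNCRNA)
        )
    ds = Dataset(records)
    ds.log("generate_noncoding_like", n=count, seed=spec.seed)
    return ds


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """n_per_class of each class, shuffled, label noise applied last
    (exactly round(noise * total) labels swapped)."""
    coding = generate_coding_like(spec, spec.n_per_class)
    noncoding = generate_noncoding_like(spec, spec.n_per_class)
    records = coding.records + noncoding.records
    rng = np.random.default_rng([spec.seed, 3])
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    n_flip = int(round(spec.noise * len(records)))
    if n_flip:
        flip = set(rng.choice(len(records), size=n_flip, replace=False).tolist())
        records = [
            Transcript(r.id, r.seq, (LNCRNA if r.label == PCT else PCT))
            if i in flip
            else r
            for i, r in enumerate(records)
        ]
    ds = Dataset(records)
    ds.log(
        "generate_dataset",
        spec={
            "n_per_class": spec.n_per_class,
            "min_len": spec.min_len,
            "max_len": spec.max_len,
            "coding_orf_rel": list(spec.coding_orf_rel),
            "coding_codon_bias": spec.coding_codon_bias,
            "noncoding_markov_order": spec.noncoding_markov_order,
            "background_probs": list(spec.background_probs),
            "noise": spec.noise,
            "seed": spec.seed,
        },
        n_flipped=n_flip,
    )
    return ds
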