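"""Unit and property tests for the information-theory feature block.

The topological-entropy implementations are checked against naive
substring-enumeration oracles written independently here (pure-python
dictionaries, no shared code paths).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncentropy.entropy import (
    ENTROPY_FEATURE_NAMES,
    EntropyConfig,
    entropy_feature_block,
    gapped_mutual_information,
    generalized_topological_entropy,
    kl_divergence_block,
    n_omega,
    shannon_block_entropy,
    subword_spectrum,
    distinct_count,
    topological_entropy,
)

from conftest import de_bruijn_b43, random_dna

UNMOD = EntropyConfig(modified=False)
MOD_LITERAL = EntropyConfig(modified=True, threshold_mode="literal")
MOD_PER_LENGTH = EntropyConfig(modified=True, threshold_mode="per_length")

dna = st.text(alphabet="ACGT", min_size=18, max_size=300)


# ---------------------------------------------------------------- oracles
def oracle_n_omega(length: int) -> int:
    best = None
    for n in range(1, 20):
        if 4**n + n - 1 <= length:
            best = n
    assert best is not None
    return best


def oracle_counts(seq: str, L: int, window: int) -> dict:
    region = seq[: min(window, len(seq))]
    counts = {}
    for i in range(len(region) - L + 1):
        w = region[i : i + L]
        if "N" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts


def oracle_p(seq: str, L: int, window: int, cfg: EntropyConfig) -> int:
    counts = oracle_counts(seq, L, window)
    if cfg.modified:
        if cfg.threshold_mode == "literal":
            thr = 4 ** oracle_n_omega(len(seq)) / len(seq)
        else:
            thr = 4**L / len(seq)
        counts = {w: c for w, c in counts.items() if c >= thr}
    return max(len(counts), 1)


def oracle_te(seq: str, n: int, cfg: EntropyConfig) -> float:
    window = min(4**n + n - 1, len(seq))
    return math.log(oracle_p(seq, n, window, cfg), 4) / n


def oracle_gte(seq: str, k: int, cfg: EntropyConfig) -> float:
    nw = oracle_n_omega(len(seq))
    k = min(k, nw)
    window = min(4**nw + nw - 1, len(seq))
    terms = [
        math.log(oracle_p(seq, i, window, cfg), 4) / i
        for i in range(nw - k + 1, nw + 1)
    ]
    return sum(terms) / k


# ----------------------------------------------------------------- n_omega
@pytest.mark.parametrize("length,expected", [(66, 3), (200, 3), (259, 4), (4, 1)])
def test_n_omega_values(length, expected):
    assert n_omega(length) == expected
    assert oracle_n_omega(length) == expected


def test_n_omega_matches_enumeration_everywhere():
    for length in range(4, 3000):
        assert n_omega(length) == oracle_n_omega(length)


def test_n_omega_too_short():
    with pytest.raises(ValueError):
        n_omega(3)


# --------------------------------------------------------------- spectrum
def test_spectrum_homopolymer():
    spec = subword_spectrum("AAAA", 3, 4)
    assert spec.counts == {"AAA": 2}


def test_spectrum_periodic_window66():
    seq = ("ACGT" * 20)[:80]
    spec = subword_spectrum(seq, 3, 66)
    assert set(spec.counts) == {"ACG", "CGT", "GTA", "TAC"}
    assert spec.total() == 64


def test_spectrum_skips_n_windows():
    spec = subword_spectrum("ACNGT", 2, 5)
    assert spec.counts == {"AC": 1, "GT": 1}


def test_distinct_count_threshold():
    spec = subword_spectrum("AAAA", 3, 4)
    assert distinct_count(spec, 0) == 1
    assert distinct_count(spec, 3) == 0
    spec2 = subword_spectrum("AACAACAAC", 3, 9)  # AAC:3? count real words
    assert distinct_count(spec2, 3) == sum(1 for c in spec2.counts.values() if c >= 3)


# ----------------------------------------------------- TE/GTE closed forms
def test_te_homopolymer_is_zero():
    assert topological_entropy("A" * 200, 3, UNMOD) == 0.0
    assert topological_entropy("A" * 200, 3, MOD_LITERAL) == 0.0


def test_te_de_bruijn_is_one():
    seq = de_bruijn_b43()
    assert len(seq) == 66
    assert topological_entropy(seq, 3, UNMOD) == pytest.approx(1.0, abs=1e-15)


def test_te_acgt_periodic_one_third():
    seq = "ACGT" * 50
    assert topological_entropy(seq, 3, UNMOD) == pytest.approx(1 / 3, abs=1e-15)


def test_gte_homopolymer_zero():
    for k in (1, 2, 3):
        assert generalized_topological_entropy("A" * 200, k, UNMOD) == 0.0


def test_gte_acgt66_is_11_18():
    seq = ("ACGT" * 17)[:66]
    got = generalized_topological_entropy(seq, 3, UNMOD)
    assert got == pytest.approx(11 / 18, abs=1e-12)


def test_gte_k1_equals_te_at_n_omega(rng):
    for _ in range(25):
        seq = random_dna(rng, int(rng.integers(200, 1200)))
        nw = n_omega(len(seq))
        gte = generalized_topological_entropy(seq, 1, UNMOD)
        # TE at n = n_omega uses the same window as GTE (4^n + n - 1 = the
        # n_omega window), so the two definitions coincide at k = 1
        te = topological_entropy(seq, nw, UNMOD)
        assert gte == pytest.approx(te, abs=1e-15)


def test_te_gte_match_oracle(rng):
    """Spot check against the enumeration oracle (the full 200-sequence
    suite runs in the acceptance tests)."""
    for _ in range(30):
        seq = random_dna(rng, int(rng.integers(200, 1500)), n_rate=0.01)
        for cfg in (UNMOD, MOD_LITERAL, MOD_PER_LENGTH):
            for n in (3, 4, 5):
                assert topological_entropy(seq, n, cfg) == pytest.approx(
                    oracle_te(seq, n, cfg), abs=1e-12
                )
            for k in (3, 4, 5):
                assert generalized_topological_entropy(seq, k, cfg) == pytest.approx(
                    oracle_gte(seq, k, cfg), abs=1e-12
                )


@given(dna)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_modification_never_increases_entropy(seq):
    for n in (2, 3):
        assert topological_entropy(seq, n, MOD_PER_LENGTH) <= topological_entropy(
            seq, n, UNMOD
        ) + 1e-15
    assert generalized_topological_entropy(seq, 3, MOD_PER_LENGTH) <= (
        generalized_topological_entropy(seq, 3, UNMOD) + 1e-15
    )


# ------------------------------------------------------------ SE, MI, KLD
@pytest.mark.parametrize(
    "seq,L,expected",
    [
        ("ACGTACGTACGT", 1, 1.0),
        ("AAAA", 2, 0.0),
        ("AACC", 1, 0.5),
    ],
)
def test_shannon_block_entropy_values(seq, L, expected):
    assert shannon_block_entropy(seq, L) == pytest.approx(expected, abs=1e-12)


def test_mi_homopolymer_zero():
    assert gapped_mutual_information("A" * 100, 5) == 0.0


def test_mi_alternating_half():
    assert gapped_mutual_information("AC" * 100, 1) == pytest.approx(0.5, abs=1e-3)


def test_mi_iid_tends_to_zero(rng):
    seq = random_dna(rng, 100_000)
    assert gapped_mutual_information(seq, 7) < 0.02


@given(dna)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_mi_reversal_invariant(seq):
    for g in (1, 5):
        assert gapped_mutual_information(seq, g) == pytest.approx(
            gapped_mutual_information(seq[::-1], g), abs=1e-12
        )


def test_kld_values():
    assert kl_divergence_block("A" * 100, 1) == pytest.approx(1.0, abs=1e-12)
    assert kl_divergence_block("A" * 100, 2) == pytest.approx(0.0, abs=1e-12)
    assert kl_divergence_block("ACGT" * 25, 1) == pytest.approx(0.0, abs=1e-12)


# -------------------------------------------------------------- the block
def test_block_order_and_dimension():
    vec = entropy_feature_block("ACGT" * 100)
    assert vec.shape == (30,)
    assert len(ENTROPY_FEATURE_NAMES) == 30
    assert ENTROPY_FEATURE_NAMES[0] == "se_1"
    assert ENTROPY_FEATURE_NAMES[4] == "te_3"
    assert ENTROPY_FEATURE_NAMES[7] == "gte_3"
    assert ENTROPY_FEATURE_NAMES[10] == "mi_1"
    assert ENTROPY_FEATURE_NAMES[27] == "kld_1"


def test_block_homopolymer_closed_form():
    vec = entropy_feature_block("A" * 1100)
    named = dict(zip(ENTROPY_FEATURE_NAMES, vec))
    for name, value in named.items():
        if name == "kld_1":
            assert value == pytest.approx(1.0, abs=1e-12)
        else:
            assert value == pytest.approx(0.0, abs=1e-12)


@given(dna)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_block_ranges(seq):
    vec = entropy_feature_block(seq)
    named = dict(zip(ENTROPY_FEATURE_NAMES, vec))
    assert np.all(np.isfinite(vec))
    for name, value in named.items():
        if name.startswith(("se_", "te_", "gte_")):
            assert -1e-12 <= value <= 1 + 1e-12
        else:
            assert value >= 0


def test_block_deterministic(rng):
    seq = random_dna(rng, 500)
    assert np.array_equal(entropy_feature_block(seq), entropy_feature_block(seq))


def test_block_too_short_lists_features():
    with pytest.raises(ValueError, match="mi_17"):
        entropy_feature_block("ACGT" * 4)
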