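import numpy as np
import pytest

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int, n_rate: float = 0.0) -> str:
    """Random sequence over {A,C,G,T}, optionally salted with N."""
    seq = BASES[rng.integers(0, 4, size=length)]
    if n_rate > 0:
        mask = rng.random(length) < n_rate
        seq = np.where(mask, "N", seq)
    return "".join(seq)


def de_bruijn_b43() -> str:
    """Linearized de Bruijn cycle B(4,3) plus a 2-character wrap: a
    66-character string whose 64 overlapping trinucleotides are exactly
    the 64 distinct ones (standard Lyndon-word construction)."""
    k, n = 4, 3
    alphabet = "ACGT"
    a = [0] * k * n
    sequence = []

    def db(t: int, p: int) -> None:
        if t > n:
            if n % p == 0:
                sequence.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    cycle = "".join(alphabet[i] for i in sequence)
    return cycle + cycle[:2]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261002)
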