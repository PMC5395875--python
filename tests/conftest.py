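import numpy as np
import pytest

from seqloop.odh import ODHConfig, kmer_index


@pytest.fixture
def cfg3():
    return ODHConfig(K=3, D=100)


def dense_odh_oracle(seq: str, cfg: ODHConfig) -> dict[int, int]:
    """Brute-force O(L^2) double-loop ODH transform used as the independent
    oracle: enumerate every ordered occurrence-position pair directly."""
    K, D, M = cfg.K, cfg.D, cfg.n_kmers
    P = len(seq) - K + 1
    valid = [all(c in "ACGT" for c in seq[p : p + K]) for p in range(P)]
    out: dict[int, int] = {}
    for p1 in range(P):
        for p2 in range(p1, min(P, p1 + D + 1)):
            if valid[p1] and valid[p2]:
                i = kmer_index(seq[p1 : p1 + K], cfg)
                j = kmer_index(seq[p2 : p2 + K], cfg)
                key = (i * M + j) * (D + 1) + (p2 - p1)
                out[key] = out.get(key, 0) + 1
    return out


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    if with_n:
        return "".join(
            rng.choice(list("ACGTN"), size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04])
        )
    return "".join(rng.choice(list("ACGT"), size=length))
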