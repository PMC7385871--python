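import numpy as np
import pytest

from augref.synthpop import ReferenceSequence, Variant, VariantPanel, generate_reference


@pytest.fixture(scope="session")
def toy_ref():
    return ReferenceSequence("t", "ACGTACGT")


@pytest.fixture(scope="session")
def small_ref():
    return generate_reference(30_000, 0.42, seed=101)


@pytest.fixture
def tiny_panel():
    """Four haplotypes (two diploids, one population), three variants."""
    ref = ReferenceSequence("t", "ACGTACGTACGTACGTACGT")
    variants = [
        Variant("t", 3, "T", "G"),
        Variant("t", 8, "A", "ACCT"),  # 3-bp insertion
        Variant("t", 13, "CGT", "C"),  # 2-bp deletion
    ]
    H = np.array(
        [
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 0],
        ],
        dtype=np.int8,
    )
    panel = VariantPanel(
        variants, [("s1", "A"), ("s2", "A")], H, ref_length=ref.length, chrom="t"
    )
    return ref, panel


def brute_force_pi(hap_matrix: np.ndarray) -> float:
    """Mean pairwise Hamming distance over all haplotype pairs (oracle)."""
    from fractions import Fraction
    from itertools import combinations

    n = hap_matrix.shape[0]
    total = Fraction(0)
    pairs = 0
    for i, j in combinations(range(n), 2):
        total += int(np.sum(hap_matrix[i] != hap_matrix[j]))
        pairs += 1
    return float(Fraction(total, pairs)) if pairs else 0.0
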