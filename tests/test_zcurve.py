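"""Encoder tests: phase decomposition, k-mer counting, Z-parameters.

The reference oracle here is deliberately naive: it counts k-mer windows
with a dictionary loop and applies the three axis definitions literally,
so any vectorisation mistake in the package shows up as a mismatch.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oriforge as of
from oriforge.sequences import InvalidSequenceError
from oriforge.zcurve import _FAMILY_DIM

from conftest import random_dna

DNA = st.text(alphabet="ACGT", min_size=1, max_size=300)


# ---------------------------------------------------------------- oracle
def oracle_counts(s: str, k: int) -> dict:
    out: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        out[s[i : i + k]] = out.get(s[i : i + k], 0) + 1
    return out


def oracle_z(s: str, k: int, normalize: bool) -> list[float]:
    counts = oracle_counts(s, k)
    n_windows = max(0, len(s) - k + 1)
    contexts = [""]
    for _ in range(k - 1):
        contexts = [c + b for c in contexts for b in "ACGT"]
    vals = []
    for c in contexts:
        a, cc, g, t = (counts.get(c + b, 0) for b in "ACGT")
        for v in ((a + g) - (cc + t), (a + cc) - (g + t), (a + t) - (g + cc)):
            vals.append(v / n_windows if normalize and n_windows else float(v))
    return vals


def oracle_encode(s: str, config: of.ZSpaceConfig) -> np.ndarray:
    phases = (s, s[0::3], s[1::3], s[2::3])
    vals: list[float] = []
    for k, active in zip((1, 2, 3), (config.include_mono, config.include_di, config.include_tri)):
        if active:
            for sub in phases:
                vals.extend(oracle_z(sub, k, config.normalize))
    return np.array(vals)


# ------------------------------------------------------- phase decomposition
@pytest.mark.parametrize(
    "seq, phases",
    [
        ("ACGTACGTA", ("ATG", "CAT", "GCA")),
        ("A", ("A", "", "")),
        ("AAAAAA", ("AA", "AA", "AA")),
    ],
)
def test_phase_decompose(seq, phases):
    dec = of.phase_decompose(seq)
    assert dec.phases == phases
    assert sum(map(len, dec.phases)) == len(seq)


def test_phase_decompose_reconstructs():
    rng = np.random.default_rng(0)
    s = random_dna(rng, 101)
    dec = of.phase_decompose(s)
    rebuilt = [""] * len(s)
    for phase, sub in enumerate(dec.phases):
        for j, base in enumerate(sub):
            rebuilt[phase + 3 * j] = base
    assert "".join(rebuilt) == s


def test_phase_decompose_empty_rejected():
    with pytest.raises(InvalidSequenceError):
        of.phase_decompose("")


# ------------------------------------------------------------- k-mer counts
@pytest.mark.parametrize(
    "seq, k, expected",
    [
        ("AACG", 1, {"A": 2, "C": 1, "G": 1}),
        ("AAAA", 2, {"AA": 3}),
        ("AC", 3, {}),
    ],
)
def test_count_kmers_examples(seq, k, expected):
    assert of.count_kmers(seq, k) == expected


def test_count_kmers_rejects_bad_k():
    with pytest.raises(ValueError):
        of.count_kmers("ACGT", 4)


@settings(deadline=None, derandomize=True)
@given(DNA, st.integers(1, 3))
def test_count_kmers_total(s, k):
    assert sum(of.count_kmers(s, k).values()) == max(0, len(s) - k + 1)


# ------------------------------------------------------------- mono / k-mer Z
@pytest.mark.parametrize(
    "seq, normalize, expected",
    [
        ("ACGT", True, (0, 0, 0)),
        ("AAAA", True, (1, 1, 1)),
        ("AACG", False, (2, 2, 0)),
    ],
)
def test_mono_z_examples(seq, normalize, expected):
    np.testing.assert_allclose(of.mono_z(seq, normalize), expected)


def test_kmer_z_homopolymer():
    v = of.kmer_z("AAAA", 2, normalize=True)
    expected = np.zeros(12)
    expected[:3] = 1.0  # only context A (first), axes x, y, z
    np.testing.assert_allclose(v, expected)


def test_kmer_z_acgt_unnormalized():
    # dinucleotides AC, CG, GT: one successor per context A, C, G
    expected = [-1, 1, -1, 1, -1, -1, -1, -1, 1, 0, 0, 0]
    np.testing.assert_allclose(of.kmer_z("ACGT", 2, normalize=False), expected)


def test_kmer_z_tri_length():
    assert of.kmer_z("ACGTACGTT", 3).shape == (48,)


# ------------------------------------------------------------ encode / dims
ALL_CONFIGS = [
    ((True, False, False), 12),
    ((False, True, False), 48),
    ((True, True, False), 60),
    ((False, False, True), 192),
    ((True, False, True), 204),
    ((False, True, True), 240),
    ((True, True, True), 252),
]


@pytest.mark.parametrize("flags, dim", ALL_CONFIGS)
def test_dimension_table(flags, dim):
    cfg = of.ZSpaceConfig(*flags)
    assert cfg.dim == dim
    rng = np.random.default_rng(dim)
    for length in (9, 300):
        assert of.encode(random_dna(rng, length), cfg).values.shape == (dim,)


def test_admissible_dims_match_configs():
    assert {dim for _, dim in ALL_CONFIGS} == set(of.ADMISSIBLE_DIMS)
    assert _FAMILY_DIM == {1: 12, 2: 48, 3: 192}


def test_encode_length_invariance():
    cfg = of.ZSpaceConfig()
    a = of.encode(random_dna(np.random.default_rng(1), 300), cfg)
    b = of.encode(random_dna(np.random.default_rng(2), 3000), cfg)
    assert a.values.shape == b.values.shape == (252,)


def test_encode_too_short_names_family():
    with pytest.raises(InvalidSequenceError, match="tri"):
        of.encode("ACGTACGT", of.ZSpaceConfig())  # 8 bp: phase 3 has < 3 bases


def test_encode_batch_shape_and_errors():
    rng = np.random.default_rng(3)
    seqs = [of.DnaSequence(f"s{i}", random_dna(rng, 300)) for i in range(10)]
    assert of.encode_batch(seqs).shape == (10, 252)
    assert of.encode_batch([]).shape == (0, 252)
    bad = seqs[:2] + [of.DnaSequence("shorty", "AC")]
    with pytest.raises(InvalidSequenceError, match="shorty"):
        of.encode_batch(bad)


def test_component_names_align_with_dim():
    for flags, dim in ALL_CONFIGS:
        assert len(of.component_names(of.ZSpaceConfig(*flags))) == dim
    names = of.component_names(of.ZSpaceConfig())
    assert names[0] == "mono.s0.x" and "tri.s2.GC.y" in names


# --------------------------------------------------------------- properties
def test_oracle_equivalence_200_random_sequences():
    """Every component of every Z-vector matches the brute-force oracle."""
    rng = np.random.default_rng(42)
    cfg_norm = of.ZSpaceConfig()
    cfg_raw = of.ZSpaceConfig(normalize=False)
    worst = 0.0
    for _ in range(200):
        s = random_dna(rng, int(rng.integers(30, 3001)))
        for cfg in (cfg_norm, cfg_raw):
            got = of.encode(s, cfg).values
            want = oracle_encode(s, cfg)
            worst = max(worst, float(np.max(np.abs(got - want))))
    assert worst < 1e-12


@settings(deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=500))
def test_mono_identities(s):
    """Unnormalized x + y = 2(A - T) and x - y = 2(G - C)."""
    x, y, _ = of.mono_z(s, normalize=False)
    assert x + y == 2 * (s.count("A") - s.count("T"))
    assert x - y == 2 * (s.count("G") - s.count("C"))


@settings(deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=500))
def test_complement_antisymmetry(s):
    """Complementing every base maps (x, y, z) -> (-x, -y, z)."""
    x, y, z = of.mono_z(s)
    xc, yc, zc = of.mono_z(of.DnaSequence("c", s).complement())
    np.testing.assert_allclose((xc, yc, zc), (-x, -y, z), atol=1e-15)


def test_normalized_bounds_and_homopolymer_extremes():
    rng = np.random.default_rng(9)
    for _ in range(50):
        v = of.encode(random_dna(rng, int(rng.integers(9, 500)))).values
        assert np.all(v >= -1 - 1e-12) and np.all(v <= 1 + 1e-12)
    allA = of.encode("A" * 60).values
    assert allA.max() == 1.0  # mono axes all hit +1 on poly-A
    allG = of.mono_z("G" * 60)
    np.testing.assert_allclose(allG, (1, -1, -1))
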