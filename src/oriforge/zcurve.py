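"""Phase-specific Z-curve encoding of DNA sequences.

The Z-curve maps base composition onto three axes: x separates purines from
pyrimidines, (A+G)-(C+T); y separates amino from keto bases, (A+C)-(G+T);
z separates weakly from strongly hydrogen-bonded pairs, (A+T)-(G+C).  For a
whole sequence these three count differences give a 3-vector; computing them
additionally on each of the three phase subsequences gives 3 + 9 = 12
mononucleotide parameters.  The k-mer generalisation conditions the same
three differences on a (k-1)-base context: for every context c the counts of
cA, cC, cG, cT are combined with the same +/- pattern, yielding 12 phase-free
dinucleotide parameters (4 contexts x 3 axes) and 48 trinucleotide ones
(16 x 3), each again computed phase-free and per phase.

Activating the mono / di / tri families therefore spans feature spaces of
dimension 12, 48, 192 alone and 60, 204, 240, 252 in combination — fixed
dimension regardless of sequence length, which is the point: sequences of any
length land in the same space.

Counts are normalised by the number of counted k-mer windows by default, so
every component lies in [-1, 1] and sequences of different lengths are
comparable; raw count differences remain available with ``normalize=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

from .sequences import DnaSequence, InvalidSequenceError, as_str, phase_decompose

BASES = "ACGT"
_CODE = {ord(b): i for i, b in enumerate(BASES)}
_LUT = np.full(128, 255, dtype=np.uint8)
for _b, _i in _CODE.items():
    _LUT[_b] = _i

#: admissible feature-space dimensions for the seven family combinations
ADMISSIBLE_DIMS = frozenset({12, 48, 60, 192, 204, 240, 252})

_FAMILY_DIM = {1: 12, 2: 48, 3: 192}  # 4 * 3 * 4**(k-1): phase-free + 3 phases
_FAMILY_NAME = {1: "mono", 2: "di", 3: "tri"}


class ZSpaceConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ZSpaceConfig:
    """Which k-mer parameter families are active, and count normalisation."""

    include_mono: bool = True
    include_di: bool = True
    include_tri: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (self.include_mono or self.include_di or self.include_tri):
            raise ZSpaceConfigError("at least one of mono/di/tri must be active")

    @property
    def active_ks(self) -> tuple[int, ...]:
        flags = (self.include_mono, self.include_di, self.include_tri)
        return tuple(k for k, on in zip((1, 2, 3), flags) if on)

    @property
    def dim(self) -> int:
        return sum(_FAMILY_DIM[k] for k in self.active_ks)

    @property
    def min_length(self) -> int:
        """Shortest sequence for which every phase admits one window of the largest active k."""
        return 3 * max(self.active_ks)

    @classmethod
    def from_string(cls, spec: str, normalize: bool = True) -> "ZSpaceConfig":
        """Parse a comma-separated family list, e.g. ``"mono,di,tri"``."""
        parts = {p.strip().lower() for p in spec.split(",") if p.strip()}
        unknown = parts - {"mono", "di", "tri"}
        if unknown:
            raise ZSpaceConfigError(f"unknown Z-parameter families: {sorted(unknown)}")
        return cls(
            include_mono="mono" in parts,
            include_di="di" in parts,
            include_tri="tri" in parts,
            normalize=normalize,
        )


@dataclass(frozen=True)
class ZVector:
    """One encoded sequence: a fixed-dimension real feature vector."""

    values: np.ndarray
    config: ZSpaceConfig
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.config.dim,):
            raise ValueError(
                f"ZVector for {self.source_id!r} has length {v.shape}, "
                f"config dimension is {self.config.dim}"
            )
        object.__setattr__(self, "values", v)


def _codes(s: str) -> np.ndarray:
    arr = _LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise InvalidSequenceError("sequence contains non-ACGT symbols")
    return arr.astype(np.int64)


def count_kmers(seq: "DnaSequence | str", k: int) -> dict[str, int]:
    """Counts of every overlapping k-mer window, k in {1, 2, 3}.

    Only observed k-mers appear in the result; the counts sum to
    max(0, len(seq) - k + 1).
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    vec = _kmer_count_vector(as_str(seq), k)
    kmers = ("".join(p) for p in product(BASES, repeat=k))
    return {km: int(c) for km, c in zip(kmers, vec) if c}


def _kmer_count_vector(s: str, k: int) -> np.ndarray:
    """Counts of all 4**k k-mers in lexicographic order."""
    c = _codes(s)
    if c.size < k:
        return np.zeros(4**k, dtype=np.int64)
    idx = c[: c.size - k + 1].copy()
    for j in range(1, k):
        idx = idx * 4 + c[j : c.size - k + 1 + j]
    return np.bincount(idx, minlength=4**k)


def _z_from_counts(counts: np.ndarray, k: int, n_windows: int, normalize: bool) -> np.ndarray:
    """Apply the x/y/z +/- pattern per context; context-major (x,y,z) order."""
    n = counts.reshape(4 ** (k - 1), 4).astype(np.float64)
    a, c, g, t = n[:, 0], n[:, 1], n[:, 2], n[:, 3]
    out = np.empty((4 ** (k - 1), 3))
    out[:, 0] = (a + g) - (c + t)
    out[:, 1] = (a + c) - (g + t)
    out[:, 2] = (a + t) - (g + c)
    if normalize and n_windows > 0:
        out /= n_windows
    return out.ravel()


def _z_params(s: str, k: int, normalize: bool) -> np.ndarray:
    n_windows = max(0, len(s) - k + 1)
    return _z_from_counts(_kmer_count_vector(s, k), k, n_windows, normalize)


def mono_z(seq: "DnaSequence | str", normalize: bool = True) -> np.ndarray:
    """Whole-sequence (phase-free) mononucleotide coordinates (x, y, z)."""
    s = as_str(seq)
    if not s:
        raise InvalidSequenceError("cannot encode an empty sequence")
    return _z_params(s, 1, normalize)


def kmer_z(seq: "DnaSequence | str", k: int, normalize: bool = True) -> np.ndarray:
    """Phase-free k-mer Z-parameters for k=2 (length 12) or k=3 (length 48).

    Sequences shorter than k yield an all-zero vector.
    """
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    s = as_str(seq)
    if len(s) < k:
        logging.getLogger(__name__).warning(
            "sequence shorter than k=%d: returning an all-zero vector", k
        )
    return _z_params(s, k, normalize)


def encode(seq: "DnaSequence | str", config: ZSpaceConfig | None = None) -> ZVector:
    """Encode one sequence into the configured Z-space.

    Layout: families in order mono -> di -> tri (active only); within a
    family the phase-free block on the whole sequence, then phases 1, 2, 3;
    within a block, contexts in lexicographic order with axes x, y, z.
    """
    config = config or ZSpaceConfig()
    s = as_str(seq)
    source_id = seq.id if isinstance(seq, DnaSequence) else ""
    if not s:
        raise InvalidSequenceError("cannot encode an empty sequence")
    dec = phase_decompose(s)
    subseqs = (dec.s0,) + dec.phases
    parts = []
    for k in config.active_ks:
        if len(dec.s3) < k:  # s3 is the shortest phase
            raise InvalidSequenceError(
                f"sequence {source_id!r} (length {len(s)}) is too short for the "
                f"{_FAMILY_NAME[k]} family: every phase needs >= {k} bases "
                f"(minimum length {3 * k})"
            )
        for sub in subseqs:
            parts.append(_z_params(sub, k, config.normalize))
    return ZVector(np.concatenate(parts), config, source_id)


def encode_batch(
    seqs: "list[DnaSequence] | list[str]", config: ZSpaceConfig | None = None
) -> np.ndarray:
    """Encode a list of sequences into an (n, dim) matrix, row order preserved."""
    config = config or ZSpaceConfig()
    rows = np.empty((len(seqs), config.dim))
    for i, seq in enumerate(seqs):
        try:
            rows[i] = encode(seq, config).values
        except InvalidSequenceError as exc:
            sid = seq.id if isinstance(seq, DnaSequence) else f"#{i}"
            raise InvalidSequenceError(f"while encoding {sid!r}: {exc}") from exc
    return rows


def component_names(config: ZSpaceConfig | None = None) -> list[str]:
    """Header names matching encode()'s layout, e.g. ``tri.s2.GC.y``."""
    config = config or ZSpaceConfig()
    names = []
    for k in config.active_ks:
        fam = _FAMILY_NAME[k]
        for sub in ("s0", "s1", "s2", "s3"):
            if k == 1:
                contexts = [""]
            else:
                contexts = ["".join(p) for p in product(BASES, repeat=k - 1)]
            for ctx in contexts:
                for axis in "xyz":
                    mid = f".{ctx}" if ctx else ""
                    names.append(f"{fam}.{sub}{mid}.{axis}")
    return names
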