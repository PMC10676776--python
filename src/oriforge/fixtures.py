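"""Synthetic labelled sequence sets with origin-like statistical structure.

The generators emulate the composition signals that separate replication
origins from background in the human benchmark: positives ("ORI-like") have
per-sequence GC content in the 50-60% band and carry planted GC-rich motifs;
negatives are either uniform-random (GC concentrated near 50%) or
"genome-like" with an AT-leaning per-sequence GC spread around 40%
(mass mostly in 30-50%).  Lengths vary (300-3000 bp by default) so the
length-invariance of the Z-space encoding is exercised throughout.

These fixtures carry only composition and planted-motif signal — none of the
positional, epigenetic or repeat structure of real origins — so results on
them demonstrate that the pipeline works, not that real origins are this
easy.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

from .sequences import DnaSequence

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_GC = np.frombuffer(b"GC", dtype="S1")
_AT = np.frombuffer(b"AT", dtype="S1")

#: concentration of the per-sequence GC Beta distribution for genome-like sets
#: (mean 0.40 -> sd ~0.054, so ~2 sd covers the 0.30-0.50 band)
GENOME_GC_CONCENTRATION = 80.0


@dataclass(frozen=True)
class FixtureSpec:
    n_pos: int = 1000
    n_neg: int = 1000
    length_range: tuple[int, int] = (300, 3000)
    pos_gc_range: tuple[float, float] = (0.50, 0.60)
    neg_mode: str = "genome-like"  # or "uniform"
    neg_gc_mean: float = 0.40
    motif: str = "GGGCGGGGC"
    motif_copies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neg_mode not in ("genome-like", "uniform"):
            raise ValueError("neg_mode must be 'genome-like' or 'uniform'")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range is not well-ordered")
        if not 0.0 < self.neg_gc_mean < 1.0:
            raise ValueError("neg_gc_mean must lie in (0, 1)")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")


def _random_lengths(n: int, length_range: tuple[int, int], rng) -> np.ndarray:
    return rng.integers(length_range[0], length_range[1] + 1, size=n)


def _exact_gc_sequence(length: int, n_gc: int, rng: np.random.Generator) -> str:
    """A shuffled sequence with exactly n_gc G/C bases (each strand-symmetric)."""
    strong = rng.choice(_GC, size=n_gc)
    weak = rng.choice(_AT, size=length - n_gc)
    arr = np.concatenate([strong, weak])
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def gen_uniform_random(
    n: int, length_range: tuple[int, int] = (300, 3000), seed: int = 0
) -> list[DnaSequence]:
    """i.i.d. uniform ACGT sequences with uniform lengths."""
    rng = np.random.default_rng(seed)
    out = []
    for i, L in enumerate(_random_lengths(n, length_range, rng)):
        s = rng.choice(_BASES, size=int(L)).tobytes().decode("ascii")
        out.append(DnaSequence(f"rand_{i:05d}", s))
    return out


def gen_genome_like(
    n: int,
    length_range: tuple[int, int] = (300, 3000),
    gc_mean: float = 0.40,
    seed: int = 0,
) -> list[DnaSequence]:
    """Background with genome-like GC heterogeneity.

    Per-sequence GC is drawn from a Beta distribution with the given mean
    (spread roughly +/-0.10), then bases are i.i.d. given that GC.
    """
    rng = np.random.default_rng(seed)
    a = gc_mean * GENOME_GC_CONCENTRATION
    b = (1.0 - gc_mean) * GENOME_GC_CONCENTRATION
    out = []
    for i, L in enumerate(_random_lengths(n, length_range, rng)):
        gc = float(rng.beta(a, b))
        strong = rng.random(int(L)) < gc
        arr = np.where(strong, rng.choice(_GC, size=int(L)), rng.choice(_AT, size=int(L)))
        out.append(DnaSequence(f"genome_{i:05d}", arr.tobytes().decode("ascii")))
    return out


def gen_ori_like(
    n: int,
    length_range: tuple[int, int] = (300, 3000),
    gc_range: tuple[float, float] = (0.50, 0.60),
    motif: str = "GGGCGGGGC",
    motif_copies: int = 1,
    seed: int = 0,
) -> list[DnaSequence]:
    """Origin-like positives: GC in the target band plus planted GC-rich motifs.

    Each sequence gets a GC target uniform in ``gc_range``, hit exactly by
    count construction; ``motif_copies`` copies of the motif are spliced in at
    random non-overlapping positions, with the background composition
    compensated so the total GC still matches the target.
    """
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over ACGT")
    if motif_copies * len(motif) > length_range[0]:
        raise ValueError("motif copies do not fit in the minimum length")
    rng = np.random.default_rng(seed)
    motif_gc = motif.count("G") + motif.count("C")
    out = []
    for i, L in enumerate(_random_lengths(n, length_range, rng)):
        L = int(L)
        target = float(rng.uniform(*gc_range))
        bg_len = L - motif_copies * len(motif)
        bg_gc = int(np.clip(round(target * L) - motif_copies * motif_gc, 0, bg_len))
        s = _exact_gc_sequence(bg_len, bg_gc, rng)
        for pos in sorted(rng.integers(0, bg_len + 1, size=motif_copies), reverse=True):
            s = s[:pos] + motif + s[pos:]
        out.append(DnaSequence(f"ori_{i:05d}", s))
    return out


def make_labeled_dataset(
    spec: FixtureSpec | None = None,
) -> tuple[list[DnaSequence], np.ndarray, dict]:
    """A shuffled labelled dataset (positives=1, negatives=0) plus provenance."""
    spec = spec or FixtureSpec()
    pos = gen_ori_like(
        spec.n_pos, spec.length_range, spec.pos_gc_range, spec.motif,
        spec.motif_copies, seed=spec.seed * 2 + 1,
    )
    if spec.neg_mode == "uniform":
        neg = gen_uniform_random(spec.n_neg, spec.length_range, seed=spec.seed * 2 + 2)
    else:
        neg = gen_genome_like(
            spec.n_neg, spec.length_range, spec.neg_gc_mean, seed=spec.seed * 2 + 2
        )
    seqs = pos + neg
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    order = np.random.default_rng(spec.seed * 2 + 3).permutation(len(seqs))
    seqs = [seqs[i] for i in order]
    labels = labels[order]
    return seqs, labels, {"spec": asdict(spec), "n_total": len(seqs)}


def make_cell_lines(
    spec: FixtureSpec | None = None, names: tuple[str, ...] = ("lineA", "lineB", "lineC")
) -> dict[str, tuple[list[DnaSequence], np.ndarray]]:
    """Pseudo-cell-line datasets drawn independently from ONE distribution.

    Because the lines share a single generating process, any attempt to
    classify sequences by line should score near chance, while pooling them
    should help a positive-vs-negative model.
    """
    spec = spec or FixtureSpec()
    out = {}
    for i, name in enumerate(names):
        sub = replace(spec, seed=(spec.seed * 1009 + 7919 * (i + 1)) % (2**31))
        seqs, labels, _ = make_labeled_dataset(sub)
        out[name] = (seqs, labels)
    return out
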