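"""Synthetic labelled protein sequence sets with controllable class signal.

The generator emulates the kind of data the classifier is built for: two
classes of protein sequences of realistic length (100-600 residues), the
positive class (cancerlectins) carrying degenerate conserved motifs and an
optional mild composition shift toward hydrophobic residues. The two knobs
are independent so tests can attribute classifier signal to order-sensitive
features (motifs -> conjoint triads, dipeptides) versus composition-
sensitive features (shift -> amino-acid composition).

Motif consensi use the bracketed-alternative syntax motif-discovery tools
print (``PTTS[VI][IV]I[TV]FHNE...``): a bracket lists interchangeable
residues, ``X`` draws from the background. The default motifs are
degenerate lectin-like consensi in that syntax.

Default class sizes are 178 positive / 226 negative training sequences and
20 / 20 test sequences; defaults plant one instance of each configured
motif per positive sequence (conserved blocks co-occur within a family)
with 5 % per-position substitution noise, plus a hydrophobic composition
shift of 0.02. The null configuration (``motif_prob=0``,
``composition_shift=0``) makes the two classes draws from one distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .physchem import AMINO_ACIDS
from .seqio import NEGATIVE, POSITIVE, ProteinRecord

#: Degenerate lectin-like consensus motifs planted in positive sequences.
#: Conserved blocks co-occur within a protein family, so every positive
#: sequence receives an instance of each configured motif (subject to
#: motif_prob), placed in disjoint segments of the sequence.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "FA[ED][RK]L[YH][KQ][AS]MKG[AL]GT[RD]D[KN][TV]LIRI[ML][VI]SR[SA]E[ITV]D"
    "[LM][LN]DI[RK][AS][EH][FY][KQR][KRE][KM]YGKSL[YS][SH][MD]I",
    "PTTS[VI][IV]I[TV]FHNE[AG][WR]STLLRT[VI]HSVL[KN]R[ST]P[PR]HL[LI][KA]EI[IV]LVDD",
)

#: Residues counted as hydrophobic for the composition shift.
HYDROPHOBIC = "CLVIMFW"

_TOKEN = re.compile(r"\[([A-Z]+)\]|(X)|([A-Z])")


class SimConfigError(ValueError):
    pass


def parse_consensus(pattern: str) -> list[Optional[str]]:
    """Parse a bracketed consensus into per-position alternative sets.

    Returns one entry per motif position: a string of allowed residues, or
    ``None`` for an ``X`` (background) position. Whitespace is ignored so
    line-wrapped consensi can be pasted as printed.
    """
    pattern = re.sub(r"\s+", "", pattern)
    positions: list[Optional[str]] = []
    pos = 0
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if not m:
            raise SimConfigError(f"cannot parse consensus at {pattern[pos:pos+8]!r}")
        if m.group(1):
            alts = m.group(1)
            if not set(alts) <= set(AMINO_ACIDS):
                raise SimConfigError(f"non-canonical residues in alternative set [{alts}]")
            positions.append(alts)
        elif m.group(2):
            positions.append(None)  # X: background draw
        else:
            if m.group(3) not in AMINO_ACIDS:
                raise SimConfigError(f"non-canonical residue {m.group(3)!r} in consensus")
            positions.append(m.group(3))
        pos = m.end()
    if not positions:
        raise SimConfigError("empty consensus")
    return positions


@dataclass
class SimConfig:
    n_pos: int = 178
    n_neg: int = 226
    n_test_pos: int = 20
    n_test_neg: int = 20
    length_range: tuple[int, int] = (100, 600)
    background: Optional[Sequence[float]] = None  # 20 probs, AMINO_ACIDS order
    motifs: Sequence[str] = DEFAULT_MOTIFS
    motif_prob: float = 1.0
    motif_noise: float = 0.05
    composition_shift: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.n_test_pos, self.n_test_neg) < 0:
            raise SimConfigError("class sizes must be >= 0")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise SimConfigError("length_range must satisfy 1 <= min <= max")
        for p in (self.motif_prob, self.motif_noise):
            if not 0.0 <= p <= 1.0:
                raise SimConfigError("probabilities must lie in [0, 1]")
        if self.composition_shift < 0:
            raise SimConfigError("composition_shift must be >= 0")
        if self.background is None:
            self.background = np.full(20, 1 / 20)
        else:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (20,) or (self.background < 0).any():
                raise SimConfigError("background must be 20 non-negative probabilities")
            if abs(self.background.sum() - 1.0) > 1e-9:
                raise SimConfigError("background must sum to 1")
        self._parsed_motifs = [parse_consensus(m) for m in self.motifs]
        if self.motif_prob > 0 and self._parsed_motifs:
            # every motif gets its own L/k segment, so each must fit there
            segment = lo // len(self._parsed_motifs)
            longest = max(len(m) for m in self._parsed_motifs)
            if longest > segment:
                raise SimConfigError(
                    f"longest motif ({longest}) exceeds the per-motif segment "
                    f"({segment} = min length {lo} / {len(self._parsed_motifs)} motifs)"
                )


def _positive_background(config: SimConfig) -> np.ndarray:
    """Background shifted by delta toward hydrophobic residues, renormalized."""
    bg = np.array(config.background, dtype=float)
    if config.composition_shift > 0:
        mask = np.array([aa in HYDROPHOBIC for aa in AMINO_ACIDS], dtype=float)
        bg = bg + config.composition_shift * mask
        bg = bg / bg.sum()
    return bg


def _sample_sequence(
    rng: np.random.Generator,
    config: SimConfig,
    background: np.ndarray,
    with_motif: bool,
) -> str:
    lo, hi = config.length_range
    L = int(rng.integers(lo, hi + 1))
    aa = np.array(list(AMINO_ACIDS))
    seq = rng.choice(aa, size=L, p=background)
    if with_motif and config._parsed_motifs:
        k = len(config._parsed_motifs)
        for i, motif in enumerate(config._parsed_motifs):
            if rng.uniform() >= config.motif_prob:
                continue
            # disjoint segment per motif so instances never overwrite each other
            seg_lo, seg_hi = i * L // k, (i + 1) * L // k
            start = int(rng.integers(seg_lo, seg_hi - len(motif) + 1))
            for off, alts in enumerate(motif):
                if alts is None:  # X position: background draw
                    residue = rng.choice(aa, p=np.asarray(config.background))
                else:
                    residue = alts[int(rng.integers(len(alts)))]
                if config.motif_noise > 0 and rng.uniform() < config.motif_noise:
                    residue = aa[int(rng.integers(20))]
                seq[start + off] = residue
    return "".join(seq)


def simulate_dataset(config: SimConfig = SimConfig()) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Generate (train_records, test_records), deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    pos_bg = _positive_background(config)
    neg_bg = np.asarray(config.background, dtype=float)
    train: list[ProteinRecord] = []
    test: list[ProteinRecord] = []
    for split, n_pos, n_neg, out in (
        ("train", config.n_pos, config.n_neg, train),
        ("test", config.n_test_pos, config.n_test_neg, test),
    ):
        for i in range(n_pos):
            out.append(
                ProteinRecord(
                    id=f"pos_{split}_{i + 1:04d}",
                    sequence=_sample_sequence(rng, config, pos_bg, with_motif=True),
                    label=POSITIVE,
                )
            )
        for i in range(n_neg):
            out.append(
                ProteinRecord(
                    id=f"neg_{split}_{i + 1:04d}",
                    sequence=_sample_sequence(rng, config, neg_bg, with_motif=False),
                    label=NEGATIVE,
                )
            )
    return train, test


def null_config(seed: int = 1, **overrides) -> SimConfig:
    """The no-signal configuration: both classes from the same distribution."""
    kwargs = dict(motif_prob=0.0, composition_shift=0.0, seed=seed)
    kwargs.update(overrides)
    return SimConfig(**kwargs)
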