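"""Protein sequence descriptor families.

Implements every feature family of the classification pipeline:

========================  ======================  =========
family                    function                dimension
========================  ======================  =========
Amino Acid Composition    :func:`aac`                    20
Dipeptide Composition     :func:`dpc`                   400
Conjoint Triad            :func:`ctf`                   343
Pse-AAC (type 1)          :func:`pseaac`             20 + l
Amphiphilic Pse-AAC       :func:`apseaac`           20 + 2l
Norm. Moreau-Broto        :func:`autocorrelation`  8 * nlag
Moran / Geary             :func:`autocorrelation`  8 * nlag
Seq.-order coupling nums  :func:`socn`             2 * nlag
Quasi-sequence-order      :func:`qso`         2 * (20+nlag)
188-dim physicochemical   :func:`d188`                  188
k-skip bigrams            :func:`skipgram`              400
========================  ======================  =========

Default parameters (lambda = nlag = 30, Pse-AAC weight 0.05, amphiphilic
weight 0.5, QSO weight 0.1, eight autocorrelation properties, two distance
matrices) give the dimensions in the right column: 20, 400, 343, 50, 80,
240, 60, 100, 188, 400.

Frequency-type vectors (AAC, DPC, CTF, skip-grams, each QSO block, the full
Pse-AAC vector) are normalized to sum to 1. Feature names follow
``<family>.<component>`` (e.g. ``ctf.3_1_5``, ``pseaac.theta7``) so that
concatenated tables keep unambiguous headers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import physchem
from .physchem import AMINO_ACIDS, AA_INDEX, CTF_CLASSES, CTD_PARTITIONS, PropertyTable
from .seqio import ProteinRecord


class DescriptorError(ValueError):
    """A record violates a descriptor family's precondition."""


@dataclass(frozen=True)
class DescriptorParams:
    """Tunable parameters shared by the lag/weight-parameterised families.

    lambda_ : correlation depth of (amphiphilic) Pse-AAC, default 30.
    weight_pse / weight_apse : the weight w balancing composition against
        sequence-order terms, defaults 0.05 and 0.5.
    nlag : maximum lag of the autocorrelation, coupling-number, and
        quasi-sequence-order families, default 30.
    weight_qso : quasi-sequence-order weight, default 0.1.
    skip : maximum gap of the skip-bigram family (0 reduces it to DPC).
    """

    lambda_: int = 30
    weight_pse: float = 0.05
    weight_apse: float = 0.5
    nlag: int = 30
    weight_qso: float = 0.1
    skip: int = 1

    def __post_init__(self) -> None:
        if self.lambda_ < 1 or self.nlag < 1:
            raise ValueError("lambda_ and nlag must be >= 1")
        if min(self.weight_pse, self.weight_apse, self.weight_qso) <= 0:
            raise ValueError("weights must be > 0")
        if self.skip < 0:
            raise ValueError("skip must be >= 0")


DEFAULT_PARAMS = DescriptorParams()


@dataclass
class DescriptorVector:
    """One sequence's feature vector for one descriptor family."""

    method: str
    params: dict
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique within a vector")

    @property
    def k(self) -> int:
        return self.values.shape[0]


def _indices(record: ProteinRecord) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in record.sequence], dtype=np.intp)
    except KeyError as exc:
        raise DescriptorError(
            f"record {record.id!r} contains non-canonical residue {exc.args[0]!r}; "
            "run seqio.validate_records first"
        ) from None


def _require_length(record: ProteinRecord, min_len: int, family: str) -> None:
    if record.length < min_len:
        raise DescriptorError(
            f"{family}: record {record.id!r} has length {record.length}, needs >= {min_len}"
        )


# ---------------------------------------------------------------------------
# composition families

_PAIR_NAMES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]


def aac(record: ProteinRecord) -> DescriptorVector:
    """Amino-acid composition: 20 residue frequencies summing to 1."""
    _require_length(record, 1, "aac")
    idx = _indices(record)
    counts = np.bincount(idx, minlength=20).astype(float)
    return DescriptorVector(
        "aac", {}, [f"aac.{a}" for a in AMINO_ACIDS], counts / record.length
    )


def dpc(record: ProteinRecord) -> DescriptorVector:
    """Dipeptide composition: 400 adjacent-pair frequencies summing to 1."""
    _require_length(record, 2, "dpc")
    idx = _indices(record)
    pair = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair, minlength=400).astype(float)
    return DescriptorVector(
        "dpc", {}, [f"dpc.{p}" for p in _PAIR_NAMES], counts / (record.length - 1)
    )


def ctf(record: ProteinRecord, alphabet: Optional[dict[str, int]] = None) -> DescriptorVector:
    """Conjoint-triad feature: 343 class-triad frequencies.

    Residues are mapped to seven physicochemical classes; every width-3
    window contributes one triad count; counts are divided by L - 2 so the
    vector is a frequency distribution over the 7 x 7 x 7 triads.
    """
    _require_length(record, 3, "ctf")
    classes = alphabet or CTF_CLASSES
    try:
        cls = np.array([classes[a] - 1 for a in record.sequence], dtype=np.intp)
    except KeyError as exc:
        raise DescriptorError(
            f"ctf: record {record.id!r} contains unmapped residue {exc.args[0]!r}"
        ) from None
    triad = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    counts = np.bincount(triad, minlength=343).astype(float)
    names = [f"ctf.{i}_{j}_{k}" for i in range(1, 8) for j in range(1, 8) for k in range(1, 8)]
    return DescriptorVector("ctf", {}, names, counts / (record.length - 2))


# ---------------------------------------------------------------------------
# pseudo-amino-acid composition

def pseaac(
    record: ProteinRecord,
    params: DescriptorParams = DEFAULT_PARAMS,
    props: PropertyTable = physchem.PSEAAC_PROPERTIES,
) -> DescriptorVector:
    """Type-1 pseudo-amino-acid composition: 20 + lambda components.

    The correlation factor at lag j averages, over all residue pairs at
    separation j, the mean squared difference of the three standardized
    properties (hydrophobicity, hydrophilicity, side-chain mass). The
    composition block and the weighted correlation block share one
    normalizing denominator, so the whole vector sums to 1.
    """
    lam, w = params.lambda_, params.weight_pse
    if record.length <= lam:
        raise DescriptorError(
            f"pseaac: record {record.id!r} has length {record.length}, needs > lambda={lam}"
        )
    idx = _indices(record)
    prop = props.standardized_matrix()[:, idx]  # (3, L)
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        diff = prop[:, j:] - prop[:, :-j]
        theta[j - 1] = (diff**2).mean(axis=0).mean()
    freqs = np.bincount(idx, minlength=20) / record.length
    denom = freqs.sum() + w * theta.sum()
    values = np.concatenate([freqs, w * theta]) / denom
    names = [f"pseaac.{a}" for a in AMINO_ACIDS] + [f"pseaac.theta{j}" for j in range(1, lam + 1)]
    return DescriptorVector("pseaac", {"lambda": lam, "weight": w}, names, values)


def apseaac(
    record: ProteinRecord,
    params: DescriptorParams = DEFAULT_PARAMS,
    props: PropertyTable = physchem.PSEAAC_PROPERTIES,
) -> DescriptorVector:
    """Type-2 (amphiphilic) pseudo-amino-acid composition: 20 + 2 lambda.

    Hydrophobicity and hydrophilicity contribute separate correlation terms
    per lag, each the mean product of the standardized property at the two
    positions; these can be negative, so only the relative normalization —
    not a simplex constraint — holds.
    """
    lam, w = params.lambda_, params.weight_apse
    if record.length <= lam:
        raise DescriptorError(
            f"apseaac: record {record.id!r} has length {record.length}, needs > lambda={lam}"
        )
    idx = _indices(record)
    h1 = props.standardized("hydrophobicity")[idx]
    h2 = props.standardized("hydrophilicity")[idx]
    tau = np.empty(2 * lam)
    for j in range(1, lam + 1):
        tau[2 * j - 2] = (h1[j:] * h1[:-j]).mean()
        tau[2 * j - 1] = (h2[j:] * h2[:-j]).mean()
    freqs = np.bincount(idx, minlength=20) / record.length
    denom = freqs.sum() + w * tau.sum()
    values = np.concatenate([freqs, w * tau]) / denom
    names = [f"apseaac.{a}" for a in AMINO_ACIDS] + [
        f"apseaac.tau{j}_{p}" for j in range(1, lam + 1) for p in ("hb", "hl")
    ]
    return DescriptorVector("apseaac", {"lambda": lam, "weight": w}, names, values)


# ---------------------------------------------------------------------------
# autocorrelation

AUTOCORR_KINDS = ("normalized-moreau-broto", "moran", "geary")


def autocorrelation(
    record: ProteinRecord,
    kind: str,
    params: DescriptorParams = DEFAULT_PARAMS,
    props: PropertyTable = physchem.AUTOCORR_PROPERTIES,
) -> DescriptorVector:
    """Autocorrelation descriptors over standardized property profiles.

    For each property P and lag d = 1..nlag:

    * normalized Moreau-Broto:  sum_i P_i P_{i+d} / (L - d)
    * Moran: covariance-type statistic normalized by the sequence variance
      of P (population, denominator L)
    * Geary: half mean squared lag difference over the sample variance
      (denominator L - 1)

    Sequences on which a property is constant have zero variance; the Moran
    and Geary terms are then defined as 0 rather than raising, so
    homopolymers remain processable.
    """
    if kind not in AUTOCORR_KINDS:
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    nlag = params.nlag
    if record.length <= nlag:
        raise DescriptorError(
            f"{kind}: record {record.id!r} has length {record.length}, needs > nlag={nlag}"
        )
    idx = _indices(record)
    L = record.length
    values = np.empty(len(props.names) * nlag)
    names: list[str] = []
    short = {"normalized-moreau-broto": "nmbroto", "moran": "moran", "geary": "geary"}[kind]
    pos = 0
    for pname in props.names:
        p = props.standardized(pname)[idx]
        pbar = p.mean()
        var_pop = ((p - pbar) ** 2).mean()
        var_samp = ((p - pbar) ** 2).sum() / (L - 1)
        # standardized properties are O(1); variance below 1e-12 is a
        # constant profile up to float rounding -> terms defined as 0
        degenerate = var_pop <= 1e-12
        for d in range(1, nlag + 1):
            a, b = p[:-d], p[d:]
            if kind == "normalized-moreau-broto":
                v = (a * b).sum() / (L - d)
            elif kind == "moran":
                v = 0.0 if degenerate else ((a - pbar) * (b - pbar)).mean() / var_pop
            else:  # geary
                v = 0.0 if degenerate else ((a - b) ** 2).sum() / (2 * (L - d)) / var_samp
            values[pos] = v
            names.append(f"{short}.{pname}.d{d}")
            pos += 1
    return DescriptorVector(short, {"nlag": nlag}, names, values)


# ---------------------------------------------------------------------------
# sequence-order descriptors

def _coupling_numbers(idx: np.ndarray, matrix: np.ndarray, nlag: int) -> np.ndarray:
    """tau_d = sum_i dist(A_i, A_{i+d})^2 for d = 1..nlag."""
    return np.array(
        [(matrix[idx[:-d], idx[d:]] ** 2).sum() for d in range(1, nlag + 1)]
    )


def socn(record: ProteinRecord, params: DescriptorParams = DEFAULT_PARAMS) -> DescriptorVector:
    """Sequence-order coupling numbers for both distance matrices (2 * nlag)."""
    nlag = params.nlag
    if record.length <= nlag:
        raise DescriptorError(
            f"socn: record {record.id!r} has length {record.length}, needs > nlag={nlag}"
        )
    idx = _indices(record)
    names: list[str] = []
    blocks = []
    for mname, matrix in physchem.get_distance_matrices().items():
        blocks.append(_coupling_numbers(idx, matrix, nlag))
        names += [f"socn.{mname}.d{d}" for d in range(1, nlag + 1)]
    return DescriptorVector("socn", {"nlag": nlag}, names, np.concatenate(blocks))


def qso(record: ProteinRecord, params: DescriptorParams = DEFAULT_PARAMS) -> DescriptorVector:
    """Quasi-sequence-order descriptors: per matrix, 20 composition-type and
    nlag order-type components sharing one denominator, so each
    (20 + nlag)-block sums to 1; k = 2 * (20 + nlag)."""
    nlag, w = params.nlag, params.weight_qso
    if record.length <= nlag:
        raise DescriptorError(
            f"qso: record {record.id!r} has length {record.length}, needs > nlag={nlag}"
        )
    idx = _indices(record)
    counts = np.bincount(idx, minlength=20).astype(float)
    names: list[str] = []
    blocks = []
    for mname, matrix in physchem.get_distance_matrices().items():
        tau = _coupling_numbers(idx, matrix, nlag)
        denom = counts.sum() + w * tau.sum()
        blocks.append(np.concatenate([counts, w * tau]) / denom)
        names += [f"qso.{mname}.{a}" for a in AMINO_ACIDS]
        names += [f"qso.{mname}.tau{d}" for d in range(1, nlag + 1)]
    return DescriptorVector("qso", {"nlag": nlag, "weight": w}, names, np.concatenate(blocks))


# ---------------------------------------------------------------------------
# 188-dimension physicochemical features (AAC + C/T/D over 8 partitions)

_D188_QUANTILES = (0.25, 0.50, 0.75)


def d188(record: ProteinRecord) -> DescriptorVector:
    """188-dimension physicochemical feature set.

    20 amino-acid composition components, then for each of the eight
    three-group alphabet partitions: 3 group compositions, 3 transition
    frequencies between distinct groups, and 15 distribution values — for
    each group the positions of its first, 25 %, 50 %, 75 %, and last
    occurrence as percentages of L (0 for an absent group).
    """
    _require_length(record, 2, "d188")
    idx = _indices(record)
    L = record.length
    values = [np.bincount(idx, minlength=20) / L]
    names = [f"d188.aac.{a}" for a in AMINO_ACIDS]
    for pname, groups in CTD_PARTITIONS.items():
        gmap = np.empty(20, dtype=np.intp)
        for g, letters in enumerate(groups):
            for aa in letters:
                gmap[AA_INDEX[aa]] = g
        gseq = gmap[idx]
        comp = np.bincount(gseq, minlength=3) / L
        names += [f"d188.{pname}.comp{g + 1}" for g in range(3)]
        pairs = {(0, 1): 0, (1, 0): 0, (0, 2): 1, (2, 0): 1, (1, 2): 2, (2, 1): 2}
        trans = np.zeros(3)
        for a, b in zip(gseq[:-1], gseq[1:]):
            if a != b:
                trans[pairs[(a, b)]] += 1
        trans /= L - 1
        names += ["d188.%s.trans%s" % (pname, t) for t in ("12", "13", "23")]
        distr = np.zeros(15)
        for g in range(3):
            positions = np.flatnonzero(gseq == g) + 1  # 1-based
            if positions.size:
                n = positions.size
                picks = [positions[0]]
                picks += [positions[max(1, int(np.ceil(q * n))) - 1] for q in _D188_QUANTILES]
                picks.append(positions[-1])
                distr[5 * g : 5 * g + 5] = 100.0 * np.array(picks) / L
            names += [f"d188.{pname}.distr{g + 1}.{p}" for p in ("first", "q25", "q50", "q75", "last")]
        values += [comp, trans, distr]
    return DescriptorVector("d188", {}, names, np.concatenate(values))


# ---------------------------------------------------------------------------
# k-skip bigrams

def skipgram(record: ProteinRecord, params: DescriptorParams = DEFAULT_PARAMS) -> DescriptorVector:
    """k-skip bigrams: ordered residue pairs with gap 0..skip, aggregated
    into one 400-component frequency vector (skip=0 equals DPC)."""
    skip = params.skip
    min_len = 2 + skip
    if record.length < min_len:
        raise DescriptorError(
            f"skipgram: record {record.id!r} has length {record.length}, needs >= {min_len}"
        )
    idx = _indices(record)
    counts = np.zeros(400)
    total = 0
    for g in range(skip + 1):
        step = g + 1
        pair = idx[:-step] * 20 + idx[step:]
        counts += np.bincount(pair, minlength=400)
        total += pair.size
    prefix = f"skip{skip}"
    return DescriptorVector(
        prefix, {"skip": skip}, [f"{prefix}.{p}" for p in _PAIR_NAMES], counts / total
    )


# ---------------------------------------------------------------------------
# registry

#: CLI/table method keys -> extractor taking (record, params).
METHODS = {
    "aac": lambda r, p: aac(r),
    "dpc": lambda r, p: dpc(r),
    "ctf": lambda r, p: ctf(r),
    "pseaac": lambda r, p: pseaac(r, p),
    "apseaac": lambda r, p: apseaac(r, p),
    "nmbroto": lambda r, p: autocorrelation(r, "normalized-moreau-broto", p),
    "moran": lambda r, p: autocorrelation(r, "moran", p),
    "geary": lambda r, p: autocorrelation(r, "geary", p),
    "socn": lambda r, p: socn(r, p),
    "qso": lambda r, p: qso(r, p),
    "d188": lambda r, p: d188(r),
    "skip1": lambda r, p: skipgram(r, replace(p, skip=1)),
    "skip2": lambda r, p: skipgram(r, replace(p, skip=2)),
}

#: Display names for reports, matching the conventional spellings.
DISPLAY_NAMES = {
    "aac": "Amino Acid Composition",
    "dpc": "Dipeptide Composition",
    "ctf": "Conjoint Triad",
    "pseaac": "Pseudo-Amino Acid Composition",
    "apseaac": "Amphiphilic Pseudo-Amino Acid Composition",
    "nmbroto": "Normalized Moreau-Broto Autocorrelation",
    "moran": "Moran Autocorrelation",
    "geary": "Geary autocorrelation",
    "socn": "Sequence-Order-Coupling Number",
    "qso": "Quasi-Sequence-Order Descriptors",
    "d188": "188 dimensions",
    "skip1": "1-skip",
    "skip2": "2-skip",
}

#: Minimum admissible sequence length per method at the given params.
def min_length(method: str, params: DescriptorParams = DEFAULT_PARAMS) -> int:
    if method in ("pseaac", "apseaac"):
        return params.lambda_ + 1
    if method in ("nmbroto", "moran", "geary", "socn", "qso"):
        return params.nlag + 1
    return {"aac": 1, "dpc": 2, "ctf": 3, "d188": 2, "skip1": 3, "skip2": 4}[method]


def extract(record: ProteinRecord, method: str, params: DescriptorParams = DEFAULT_PARAMS) -> DescriptorVector:
    """Dispatch one record through a named descriptor family."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(f"unknown descriptor method {method!r}; choose from {sorted(METHODS)}")
    return fn(record, params)
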