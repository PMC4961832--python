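"""Independent brute-force oracles for the descriptor and ranking math.

Everything here is written with explicit Python loops straight from the
textbook definitions, deliberately sharing no code path with the package
implementation. The property tables and alphabet orderings are shared
contracts (they are inputs, not computation) and are taken from
``cancerlect.physchem``.
"""

import math

from cancerlect.physchem import (
    AMINO_ACIDS,
    AUTOCORR_PROPERTIES,
    CTD_PARTITIONS,
    CTF_CLASSES,
    PSEAAC_PROPERTIES,
    get_distance_matrices,
)


def _standardize(values: dict) -> dict:
    mean = sum(values[a] for a in AMINO_ACIDS) / 20
    var = sum((values[a] - mean) ** 2 for a in AMINO_ACIDS) / 20
    sd = math.sqrt(var)
    return {a: (values[a] - mean) / sd for a in AMINO_ACIDS}


def oracle_aac(seq: str) -> list:
    return [seq.count(a) / len(seq) for a in AMINO_ACIDS]


def oracle_dpc(seq: str) -> list:
    out = []
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            count = sum(1 for i in range(len(seq) - 1) if seq[i] == a and seq[i + 1] == b)
            out.append(count / (len(seq) - 1))
    return out


def oracle_ctf(seq: str) -> list:
    cls = [CTF_CLASSES[a] for a in seq]
    out = []
    for i in range(1, 8):
        for j in range(1, 8):
            for k in range(1, 8):
                count = 0
                for p in range(len(seq) - 2):
                    if cls[p] == i and cls[p + 1] == j and cls[p + 2] == k:
                        count += 1
                out.append(count / (len(seq) - 2))
    return out


def oracle_pseaac(seq: str, lam: int = 30, w: float = 0.05) -> list:
    props = [_standardize(PSEAAC_PROPERTIES.properties[n]) for n in PSEAAC_PROPERTIES.names]
    L = len(seq)

    def theta_pair(a, b):
        return sum((p[b] - p[a]) ** 2 for p in props) / len(props)

    thetas = []
    for j in range(1, lam + 1):
        thetas.append(sum(theta_pair(seq[i], seq[i + j]) for i in range(L - j)) / (L - j))
    freqs = [seq.count(a) / L for a in AMINO_ACIDS]
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def oracle_apseaac(seq: str, lam: int = 30, w: float = 0.5) -> list:
    h1 = _standardize(PSEAAC_PROPERTIES.properties["hydrophobicity"])
    h2 = _standardize(PSEAAC_PROPERTIES.properties["hydrophilicity"])
    L = len(seq)
    taus = []
    for j in range(1, lam + 1):
        taus.append(sum(h1[seq[i]] * h1[seq[i + j]] for i in range(L - j)) / (L - j))
        taus.append(sum(h2[seq[i]] * h2[seq[i + j]] for i in range(L - j)) / (L - j))
    freqs = [seq.count(a) / L for a in AMINO_ACIDS]
    denom = sum(freqs) + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


def oracle_autocorrelation(seq: str, kind: str, nlag: int = 30) -> list:
    out = []
    L = len(seq)
    for name in AUTOCORR_PROPERTIES.names:
        table = _standardize(AUTOCORR_PROPERTIES.properties[name])
        p = [table[a] for a in seq]
        pbar = sum(p) / L
        var_pop = sum((x - pbar) ** 2 for x in p) / L
        var_samp = sum((x - pbar) ** 2 for x in p) / (L - 1)
        degenerate = var_pop <= 1e-12  # constant profile up to rounding
        for d in range(1, nlag + 1):
            if kind == "normalized-moreau-broto":
                out.append(sum(p[i] * p[i + d] for i in range(L - d)) / (L - d))
            elif kind == "moran":
                if degenerate:
                    out.append(0.0)
                else:
                    num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(L - d)) / (L - d)
                    out.append(num / var_pop)
            elif kind == "geary":
                if degenerate:
                    out.append(0.0)
                else:
                    num = sum((p[i] - p[i + d]) ** 2 for i in range(L - d)) / (2 * (L - d))
                    out.append(num / var_samp)
            else:
                raise ValueError(kind)
    return out


def _tau(seq: str, matrix, d: int) -> float:
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    return sum(matrix[idx[seq[i]], idx[seq[i + d]]] ** 2 for i in range(len(seq) - d))


def oracle_socn(seq: str, nlag: int = 30) -> list:
    out = []
    for matrix in get_distance_matrices().values():
        out.extend(_tau(seq, matrix, d) for d in range(1, nlag + 1))
    return out


def oracle_qso(seq: str, nlag: int = 30, w: float = 0.1) -> list:
    counts = [seq.count(a) for a in AMINO_ACIDS]
    out = []
    for matrix in get_distance_matrices().values():
        taus = [_tau(seq, matrix, d) for d in range(1, nlag + 1)]
        denom = sum(counts) + w * sum(taus)
        out.extend(c / denom for c in counts)
        out.extend(w * t / denom for t in taus)
    return out


def oracle_d188(seq: str) -> list:
    L = len(seq)
    out = [seq.count(a) / L for a in AMINO_ACIDS]
    for groups in CTD_PARTITIONS.values():
        which = []
        for a in seq:
            for g, letters in enumerate(groups):
                if a in letters:
                    which.append(g)
                    break
        for g in range(3):
            out.append(which.count(g) / L)
        for pair in ((0, 1), (0, 2), (1, 2)):
            count = 0
            for i in range(L - 1):
                if {which[i], which[i + 1]} == set(pair):
                    count += 1
            out.append(count / (L - 1))
        for g in range(3):
            positions = [i + 1 for i, x in enumerate(which) if x == g]
            if not positions:
                out.extend([0.0] * 5)
                continue
            n = len(positions)
            picks = [positions[0]]
            for q in (0.25, 0.50, 0.75):
                picks.append(positions[max(1, math.ceil(q * n)) - 1])
            picks.append(positions[-1])
            out.extend(100.0 * p / L for p in picks)
    return out


def oracle_skipgram(seq: str, skip: int) -> list:
    counts = {}
    total = 0
    for i in range(len(seq)):
        for g in range(skip + 1):
            j = i + g + 1
            if j < len(seq):
                counts[(seq[i], seq[j])] = counts.get((seq[i], seq[j]), 0) + 1
                total += 1
    return [counts.get((a, b), 0) / total for a in AMINO_ACIDS for b in AMINO_ACIDS]


def oracle_mrmd(X, y) -> tuple:
    """Relevance, distance, and combined MRMD scores from the definitions."""
    n = len(X)
    d = len(X[0])

    def pearson(col):
        xs = [row[col] for row in X]
        mx = sum(xs) / n
        my = sum(y) / n
        cov = sum((xs[i] - mx) * (y[i] - my) for i in range(n))
        vx = math.sqrt(sum((x - mx) ** 2 for x in xs))
        vy = math.sqrt(sum((v - my) ** 2 for v in y))
        if vx == 0 or vy == 0:
            return 0.0
        return abs(cov / (vx * vy))

    rel = [pearson(c) for c in range(d)]
    scaled = []
    for c in range(d):
        xs = [row[c] for row in X]
        lo, hi = min(xs), max(xs)
        scaled.append([0.0] * n if hi == lo else [(x - lo) / (hi - lo) for x in xs])
    means = []
    for c in range(d):
        dists = [
            math.sqrt(sum((scaled[c][i] - scaled[o][i]) ** 2 for i in range(n)))
            for o in range(d) if o != c
        ]
        means.append(sum(dists) / len(dists))
    top = max(means)
    dist = [m / top if top > 0 else 0.0 for m in means]
    combined = [rel[c] + dist[c] for c in range(d)]
    return rel, dist, combined
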