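"""Amino-acid property tables, alphabet partitions, and distance matrices.

Every descriptor family indexes the strict 20-letter alphabet through the
tables collected here:

* the hydrophobicity / hydrophilicity / side-chain-mass triple of Chou's
  pseudo-amino-acid composition (hydrophobicity after Tanford, hydrophilicity
  after Hopp & Woods, side-chain mass in daltons);
* eight AAindex properties conventionally used for sequence autocorrelation
  descriptors (accession numbers given per table);
* the seven-class reduced alphabet of the conjoint-triad feature, clustering
  residues by dipole and side-chain volume;
* the eight three-group partitions of the alphabet behind the 188-dimension
  composition/transition/distribution feature set;
* Grantham's amino-acid difference matrix, computed exactly from his
  composition/polarity/volume formula;
* a physicochemical distance matrix built from the standardized Chou triple.
  This matrix is a synthetic stand-in: it plays the structural role the
  Schneider-Wrede distance matrix plays in the classical quasi-sequence-order
  descriptors, but its entries are constructed here (Euclidean distance over
  the three standardized properties), not copied from that publication.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residues that invalidate a record (ambiguity codes, rare residues, stop).
NON_CANONICAL: frozenset[str] = frozenset("BJOUXZ*")


class PropertyTable:
    """A named set of per-amino-acid real values with a standardized view.

    The standardized view has zero mean and unit variance over the 20
    canonical residues (population variance, denominator 20), which is the
    normalization the pseudo-amino-acid and autocorrelation descriptors
    assume.
    """

    def __init__(self, properties: dict[str, dict[str, float]]):
        for name, vals in properties.items():
            missing = set(AMINO_ACIDS) - set(vals)
            if missing:
                raise ValueError(f"property {name!r} lacks values for {sorted(missing)}")
        self.properties = properties
        self.names = list(properties)

    def raw(self, name: str) -> np.ndarray:
        """Values in AMINO_ACIDS order."""
        vals = self.properties[name]
        return np.array([vals[aa] for aa in AMINO_ACIDS], dtype=float)

    def standardized(self, name: str) -> np.ndarray:
        v = self.raw(name)
        return (v - v.mean()) / v.std()  # population std over the 20 residues

    def standardized_matrix(self) -> np.ndarray:
        """(n_properties, 20) matrix of standardized values."""
        return np.vstack([self.standardized(n) for n in self.names])


def _table(order: str, values: list[float]) -> dict[str, float]:
    return dict(zip(order, values))


_ARNDC = "ARNDCQEGHILKMFPSTWYV"  # AAindex row order

# Chou's Pse-AAC property triple.
CHOU_HYDROPHOBICITY = _table(
    _ARNDC,
    [0.62, -2.53, -0.78, -0.90, 0.29, -0.85, -0.74, 0.48, -0.40, 1.38,
     1.06, -1.50, 0.64, 1.19, 0.12, -0.18, -0.05, 0.81, 0.26, 1.08],
)
CHOU_HYDROPHILICITY = _table(
    _ARNDC,
    [-0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
     -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5],
)
CHOU_SIDECHAIN_MASS = _table(
    _ARNDC,
    [15.0, 101.0, 58.0, 59.0, 47.0, 72.0, 73.0, 1.0, 82.0, 57.0,
     57.0, 73.0, 75.0, 91.0, 42.0, 31.0, 45.0, 130.0, 107.0, 43.0],
)

PSEAAC_PROPERTIES = PropertyTable(
    {
        "hydrophobicity": CHOU_HYDROPHOBICITY,
        "hydrophilicity": CHOU_HYDROPHILICITY,
        "sidechain_mass": CHOU_SIDECHAIN_MASS,
    }
)

# Eight AAindex properties for the autocorrelation descriptors.
AUTOCORR_PROPERTIES = PropertyTable(
    {
        # CIDH920105 normalized average hydrophobicity
        "CIDH920105": _table(
            _ARNDC,
            [0.02, -0.42, -0.77, -1.04, 0.77, -1.10, -1.14, -0.80, 0.26, 1.81,
             1.14, -0.41, 1.00, 1.35, -0.09, -0.97, -0.77, 1.71, 1.11, 1.13],
        ),
        # BHAR880101 average flexibility index
        "BHAR880101": _table(
            _ARNDC,
            [0.357, 0.529, 0.463, 0.511, 0.346, 0.493, 0.497, 0.544, 0.323, 0.462,
             0.365, 0.466, 0.295, 0.314, 0.509, 0.507, 0.444, 0.305, 0.420, 0.386],
        ),
        # CHAM820101 polarizability parameter
        "CHAM820101": _table(
            _ARNDC,
            [0.046, 0.291, 0.134, 0.105, 0.128, 0.180, 0.151, 0.000, 0.230, 0.186,
             0.186, 0.219, 0.221, 0.290, 0.131, 0.062, 0.108, 0.409, 0.298, 0.140],
        ),
        # CHAM820102 free energy of solution in water
        "CHAM820102": _table(
            _ARNDC,
            [-0.368, -1.03, 0.0, 2.06, 4.53, 0.731, 1.77, -0.525, 0.0, 0.791,
             1.07, 0.0, 0.656, 1.06, -2.24, -0.524, 0.0, 1.60, 4.91, 0.401],
        ),
        # CHOC760101 residue accessible surface area in tripeptide
        "CHOC760101": _table(
            _ARNDC,
            [115.0, 225.0, 160.0, 150.0, 135.0, 180.0, 190.0, 75.0, 195.0, 175.0,
             170.0, 200.0, 185.0, 210.0, 145.0, 115.0, 140.0, 255.0, 230.0, 155.0],
        ),
        # BIGC670101 residue volume
        "BIGC670101": _table(
            _ARNDC,
            [52.6, 109.1, 75.7, 68.4, 68.3, 89.7, 84.7, 36.3, 91.9, 102.0,
             102.0, 105.1, 97.7, 113.9, 73.6, 54.9, 71.2, 135.4, 116.2, 85.1],
        ),
        # CHAM810101 steric parameter
        "CHAM810101": _table(
            _ARNDC,
            [0.52, 0.68, 0.76, 0.76, 0.62, 0.68, 0.68, 0.00, 0.70, 1.02,
             0.98, 0.68, 0.78, 0.70, 0.36, 0.53, 0.50, 0.70, 0.70, 0.76],
        ),
        # DAYM780201 relative mutability
        "DAYM780201": _table(
            _ARNDC,
            [100.0, 65.0, 134.0, 106.0, 20.0, 93.0, 102.0, 49.0, 66.0, 96.0,
             40.0, 56.0, 94.0, 41.0, 56.0, 120.0, 97.0, 18.0, 41.0, 74.0],
        ),
    }
)

# Seven-class reduced alphabet of the conjoint-triad feature (dipole and
# side-chain volume clustering).
CTF_CLASSES: dict[str, int] = {}
for _cls, _letters in enumerate(["AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"], start=1):
    for _aa in _letters:
        CTF_CLASSES[_aa] = _cls

# Three-group partitions behind the 188-dimension C/T/D encoder. Each entry
# maps a property name to its (group1, group2, group3) residue sets.
CTD_PARTITIONS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "surface_tension": ("GQDNAHR", "KTSEC", "ILMFPWYV"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def _check_partitions() -> None:
    for name, groups in CTD_PARTITIONS.items():
        joined = "".join(groups)
        assert sorted(joined) == sorted(AMINO_ACIDS), name


_check_partitions()

# Grantham (1974) side-chain composition c, polarity p, and volume v.
_GRANTHAM_CPV: dict[str, tuple[float, float, float]] = {
    "A": (0.0, 8.1, 31.0), "R": (0.65, 10.5, 124.0), "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0), "C": (2.75, 5.5, 55.0), "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0), "G": (0.74, 9.0, 3.0), "H": (0.58, 10.4, 96.0),
    "I": (0.0, 5.2, 111.0), "L": (0.0, 4.9, 111.0), "K": (0.33, 11.3, 119.0),
    "M": (0.0, 5.7, 105.0), "F": (0.0, 5.2, 132.0), "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0), "T": (0.71, 8.6, 61.0), "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0), "V": (0.0, 5.9, 84.0),
}


def grantham_matrix() -> np.ndarray:
    """Grantham's 20x20 amino-acid difference matrix, AMINO_ACIDS order.

    D_ij = 50.723 * sqrt(1.833 (c_i-c_j)^2 + 0.1018 (p_i-p_j)^2
                          + 0.000399 (v_i-v_j)^2)
    which reproduces the published table up to the printed rounding
    (e.g. Leu-Ile 5, Trp-Cys 215).
    """
    cpv = np.array([_GRANTHAM_CPV[aa] for aa in AMINO_ACIDS])
    alpha, beta, gamma, rho = 1.833, 0.1018, 0.000399, 50.723
    diff = cpv[:, None, :] - cpv[None, :, :]
    return rho * np.sqrt(
        alpha * diff[:, :, 0] ** 2 + beta * diff[:, :, 1] ** 2 + gamma * diff[:, :, 2] ** 2
    )


def physchem_distance_matrix() -> np.ndarray:
    """Synthetic physicochemical distance matrix, AMINO_ACIDS order.

    Euclidean distance over the standardized Chou triple (hydrophobicity,
    hydrophilicity, side-chain mass), divided by sqrt(3) so a one-standard-
    deviation difference on every property gives distance 1. Constructed
    here as a stand-in for the Schneider-Wrede matrix of the classical
    quasi-sequence-order descriptor, whose entries are not bundled.
    """
    props = PSEAAC_PROPERTIES.standardized_matrix()  # (3, 20)
    diff = props[:, :, None] - props[:, None, :]
    return np.sqrt((diff**2).mean(axis=0))


#: Distance matrices available to SOCN/QSO, in feature order.
DISTANCE_MATRICES: dict[str, "np.ndarray"] = {}


def get_distance_matrices() -> dict[str, np.ndarray]:
    if not DISTANCE_MATRICES:
        DISTANCE_MATRICES["pcd"] = physchem_distance_matrix()
        DISTANCE_MATRICES["grantham"] = grantham_matrix()
    return DISTANCE_MATRICES
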