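import numpy as np
import pytest

import oracles
from cancerlect import descriptors as desc
from cancerlect.descriptors import DescriptorError, DescriptorParams
from cancerlect.physchem import AMINO_ACIDS, PSEAAC_PROPERTIES, AUTOCORR_PROPERTIES
from cancerlect.seqio import ProteinRecord

ALL20 = ProteinRecord("all20", AMINO_ACIDS)

EXPECTED_DIMS = {
    "aac": 20, "dpc": 400, "ctf": 343, "pseaac": 50, "apseaac": 80,
    "nmbroto": 240, "moran": 240, "geary": 240, "socn": 60, "qso": 100,
    "d188": 188, "skip1": 400, "skip2": 400,
}

FREQUENCY_METHODS = ["aac", "dpc", "ctf", "pseaac", "skip1", "skip2"]

ORACLES = {
    "aac": lambda s: oracles.oracle_aac(s),
    "dpc": lambda s: oracles.oracle_dpc(s),
    "ctf": lambda s: oracles.oracle_ctf(s),
    "pseaac": lambda s: oracles.oracle_pseaac(s),
    "apseaac": lambda s: oracles.oracle_apseaac(s),
    "nmbroto": lambda s: oracles.oracle_autocorrelation(s, "normalized-moreau-broto"),
    "moran": lambda s: oracles.oracle_autocorrelation(s, "moran"),
    "geary": lambda s: oracles.oracle_autocorrelation(s, "geary"),
    "socn": lambda s: oracles.oracle_socn(s),
    "qso": lambda s: oracles.oracle_qso(s),
    "d188": lambda s: oracles.oracle_d188(s),
    "skip1": lambda s: oracles.oracle_skipgram(s, 1),
    "skip2": lambda s: oracles.oracle_skipgram(s, 2),
}


@pytest.mark.parametrize("method,k", sorted(EXPECTED_DIMS.items()))
def test_dimension_contract(method, k):
    rec = ProteinRecord("x", AMINO_ACIDS * 4)
    vec = desc.extract(rec, method)
    assert vec.k == k
    assert len(vec.names) == len(set(vec.names)) == k


@pytest.mark.parametrize("method", sorted(EXPECTED_DIMS))
def test_oracle_equivalence_on_random_sequences(method, random_records):
    """Each family equals its brute-force direct-summation oracle to 1e-9."""
    for rec in random_records:
        got = desc.extract(rec, method).values
        want = np.array(ORACLES[method](rec.sequence))
        np.testing.assert_allclose(got, want, atol=1e-9, rtol=0)


@pytest.mark.parametrize("method", FREQUENCY_METHODS)
def test_frequency_vectors_on_simplex(method, random_records):
    for rec in random_records[:10]:
        v = desc.extract(rec, method).values
        assert (v >= 0).all()
        assert abs(v.sum() - 1.0) < 1e-9


def test_qso_blocks_each_sum_to_one(random_records):
    for rec in random_records[:5]:
        v = desc.extract(rec, "qso").values
        assert abs(v[:50].sum() - 1.0) < 1e-9
        assert abs(v[50:].sum() - 1.0) < 1e-9


def test_aac_uniform_and_homopolymer():
    v = desc.aac(ALL20).values
    np.testing.assert_allclose(v, 0.05)
    v3 = desc.aac(ProteinRecord("a3", "AAA")).values
    assert v3[0] == 1.0 and v3[1:].sum() == 0.0


def test_dpc_hand_example():
    vec = desc.dpc(ProteinRecord("x", "ACAC"))
    by_name = dict(zip(vec.names, vec.values))
    assert by_name["dpc.AC"] == pytest.approx(2 / 3)
    assert by_name["dpc.CA"] == pytest.approx(1 / 3)
    assert sum(v for k, v in by_name.items() if k not in ("dpc.AC", "dpc.CA")) == 0


def test_ctf_homopolymer_concentrates_on_one_triad():
    vec = desc.ctf(ProteinRecord("x", "AAAA"))  # A is class 1
    by_name = dict(zip(vec.names, vec.values))
    assert by_name["ctf.1_1_1"] == 1.0
    assert vec.values.sum() == 1.0


def test_pseaac_homopolymer_zero_correlation():
    vec = desc.pseaac(ProteinRecord("x", "A" * 40))
    by_name = dict(zip(vec.names, vec.values))
    assert by_name["pseaac.A"] == pytest.approx(1.0)
    assert all(v == 0 for k, v in by_name.items() if k != "pseaac.A")


def test_apseaac_lambda_one_dimension():
    vec = desc.apseaac(ProteinRecord("x", AMINO_ACIDS), DescriptorParams(lambda_=1))
    assert vec.k == 22


def test_moran_zero_variance_guard():
    vec = desc.autocorrelation(ProteinRecord("x", "A" * 50), "moran")
    assert (vec.values == 0).all()
    geary = desc.autocorrelation(ProteinRecord("x", "A" * 50), "geary")
    assert (geary.values == 0).all()


def test_socn_homopolymer_is_zero():
    assert (desc.socn(ProteinRecord("x", "A" * 40)).values == 0).all()


def test_skip0_equals_dpc(random_records):
    rec = random_records[0]
    skip0 = desc.skipgram(rec, DescriptorParams(skip=0)).values
    np.testing.assert_allclose(skip0, desc.dpc(rec).values, atol=1e-12)


def test_skipgram_hand_example():
    vec = desc.skipgram(ProteinRecord("x", "ACDE"), DescriptorParams(skip=1))
    by_name = dict(zip(vec.names, vec.values))
    expected = {"skip1.AC": 0.2, "skip1.CD": 0.2, "skip1.DE": 0.2,
                "skip1.AD": 0.2, "skip1.CE": 0.2}
    for name, val in expected.items():
        assert by_name[name] == pytest.approx(val)
    assert vec.values.sum() == pytest.approx(1.0)


def test_d188_single_group_sequence():
    # IVL are all in the hydrophobic group of the hydrophobicity partition
    vec = desc.d188(ProteinRecord("x", "IVLIVLIVL"))
    by_name = dict(zip(vec.names, vec.values))
    assert by_name["d188.hydrophobicity.comp3"] == 1.0
    assert by_name["d188.hydrophobicity.trans12"] == 0.0
    assert by_name["d188.hydrophobicity.trans13"] == 0.0
    assert by_name["d188.hydrophobicity.trans23"] == 0.0


def test_d188_distribution_values_bounded_and_monotone(random_records):
    rec = random_records[0]
    vec = desc.d188(rec)
    by_name = dict(zip(vec.names, vec.values))
    for pname in ("hydrophobicity", "charge"):
        for g in (1, 2, 3):
            vals = [by_name[f"d188.{pname}.distr{g}.{p}"] for p in ("first", "q25", "q50", "q75", "last")]
            assert all(0 <= v <= 100 for v in vals)
            assert vals == sorted(vals)


def test_permutation_changes_order_sensitive_families_only():
    a = ProteinRecord("a", "ACDEFGHIKLMNPQRSTVWY" * 3)
    b = ProteinRecord("b", a.sequence[::-1])
    np.testing.assert_allclose(desc.aac(a).values, desc.aac(b).values)
    assert not np.allclose(desc.dpc(a).values, desc.dpc(b).values)
    assert not np.allclose(desc.ctf(a).values, desc.ctf(b).values)


def test_determinism_bit_identical(random_records):
    rec = random_records[0]
    for method in ("ctf", "pseaac", "qso"):
        v1 = desc.extract(rec, method).values
        v2 = desc.extract(rec, method).values
        assert (v1 == v2).all()


@pytest.mark.parametrize(
    "method,length",
    [("pseaac", 30), ("apseaac", 30), ("nmbroto", 30), ("socn", 30),
     ("qso", 30), ("ctf", 2), ("dpc", 1), ("skip2", 3)],
)
def test_length_preconditions_raise(method, length):
    rec = ProteinRecord("short", ("ACDEFGHIKL" * 3)[:length])
    with pytest.raises(DescriptorError):
        desc.extract(rec, method)


def test_noncanonical_residue_raises_descriptor_error():
    with pytest.raises(DescriptorError, match="non-canonical"):
        desc.aac(ProteinRecord("x", "MKB"))


def test_property_tables_standardized_views():
    for table in (PSEAAC_PROPERTIES, AUTOCORR_PROPERTIES):
        for name in table.names:
            z = table.standardized(name)
            assert abs(z.mean()) < 1e-9
            assert abs(z.var() - 1.0) < 1e-9


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DescriptorParams(lambda_=0)
    with pytest.raises(ValueError):
        DescriptorParams(weight_pse=0)
    with pytest.raises(ValueError):
        desc.extract(ALL20, "no-such-method")
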