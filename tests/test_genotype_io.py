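"""Genotype table I/O, validation and allele-frequency estimation."""

import numpy as np
import pytest

from forensicstr.io_ import (
    read_frequency_table,
    read_genotype_table,
    validate_x_males,
    write_frequency_table,
    write_genotype_table,
)
from forensicstr.markers import (
    AlleleFrequencySpectrum,
    Linkage,
    MarkerDef,
    NoDataError,
    SchemaError,
    allele_sort_key,
    count_distinct_alleles,
    estimate_frequencies,
    normalize_allele,
)
from forensicstr.simulate import SimConfig, simulate_x_table

from conftest import make_table

A = MarkerDef("LOC1")
X1 = MarkerDef("XA", Linkage.X_LINKED)
X2 = MarkerDef("XB", Linkage.X_LINKED)


def test_allele_label_normalization_and_ordering():
    assert normalize_allele("10.0") == "10"
    assert normalize_allele(" 9.3 ") == "9.3"
    labels = sorted(["10", "9.3", "9", "28.2", "X"], key=allele_sort_key)
    assert labels == ["9", "9.3", "10", "28.2", "X"]


def test_hand_counted_frequencies():
    t = make_table([A], [
        ("s1", "female", "P", {"LOC1": ("10", "11")}),
        ("s2", "male", "P", {"LOC1": ("11", "11")}),
    ])
    sp = estimate_frequencies(t, "LOC1")
    assert sp.n_chrom == 4
    assert sp.freq("10") == 0.25
    assert sp.freq("11") == 0.75


def test_monomorphic_frequency():
    t = make_table([A], [("s1", "female", "P", {"LOC1": ("12", "12")})])
    sp = estimate_frequencies(t, "LOC1")
    assert sp.freq("12") == 1.0 and len(sp) == 1


def test_empty_stratum_is_an_error_not_silent_zero():
    t = make_table([A], [("s1", "female", "P", {"LOC1": ("10", "11")})])
    with pytest.raises(NoDataError):
        estimate_frequencies(t, "LOC1", "males")


def test_x_chromosome_accounting_pooled():
    # 3 females (2 chrom each) + 2 males (1 chrom) = 8 chromosomes
    rows = [(f"f{i}", "female", "P", {"XA": ("10", "11")}) for i in range(3)]
    rows += [("m1", "male", "P", {"XA": ("12", None)}),
             ("m2", "male", "P", {"XA": ("10", None)})]
    t = make_table([X1], rows)
    sp = estimate_frequencies(t, "XA", "pooled")
    assert sp.n_chrom == 8
    assert sp.freq("12") == 1 / 8  # male contributes exactly one copy
    males = estimate_frequencies(t, "XA", "males")
    assert males.n_chrom == 2


def test_study_shaped_pool_has_415_chromosomes():
    # 123 females + 169 males at an X locus -> 2*123 + 169 chromosomes,
    # so a single-copy allele sits at 1/415 ~ 0.0024
    rows = [(f"f{i}", "female", "P", {"XA": ("10", "10")}) for i in range(123)]
    rows += [(f"m{i}", "male", "P", {"XA": ("11", None)}) for i in range(168)]
    rows += [("m168", "male", "P", {"XA": ("12", None)})]
    t = make_table([X1], rows)
    sp = estimate_frequencies(t, "XA")
    assert sp.n_chrom == 415
    assert sp.freq("12") == pytest.approx(1 / 415)
    assert f"{sp.freq('12'):.4f}" == "0.0024"


def test_partial_autosomal_genotype_treated_as_missing(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text(
        "SampleID\tSex\tPopulation\tLOC1_1\tLOC1_2\n"
        "s1\tF\tP\t10\t\n"
        "s2\tM\tP\t10.0\t11\n")
    t = read_genotype_table(path, [A])
    assert t.data.loc[0, "LOC1_1"] is None
    assert t.data.loc[1, "LOC1_1"] == "10"  # ".0" stripped
    sp = estimate_frequencies(t, "LOC1")
    assert sp.n_chrom == 2


def test_read_rejects_unknown_locus(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text("SampleID\tSex\tPopulation\tZZZ_1\tZZZ_2\ns\tF\tP\t1\t2\n")
    with pytest.raises(SchemaError):
        read_genotype_table(path, [A])


def test_read_male_hemizygote_and_dropout(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text(
        "SampleID\tSex\tPopulation\tXA_1\tXA_2\tXB_1\tXB_2\n"
        "m1\tM\tP\t10\t10\t9\t\n"   # hom-looking male -> one chromosome
        "m2\tM\tP\t\t\t9\t\n")      # dropout at XA
    t = read_genotype_table(path, [X1, X2])
    assert t.data.loc[0, "XA_1"] == "10" and t.data.loc[0, "XA_2"] is None
    assert t.data.loc[1, "XA_1"] is None
    _, report = validate_x_males(t)
    assert report.removed_samples == [("m2", "dropout at XA")]


@pytest.fixture
def flawed_x_table():
    return make_table([X1, X2], [
        ("ok", "male", "P", {"XA": ("10", None), "XB": ("8", None)}),
        ("drop", "male", "P", {"XA": (None, None), "XB": ("8", None)}),
        ("het", "male", "P", {"XA": ("10", "11"), "XB": ("8", None)}),
        ("fem", "female", "P", {"XA": ("10", "11"), "XB": ("8", "9")}),
    ])


def test_x_male_policy_exclude_sample(flawed_x_table):
    clean, report = validate_x_males(flawed_x_table, "exclude_sample")
    assert clean.n_individuals == 2
    assert {s for s, _ in report.removed_samples} == {"drop", "het"}


def test_x_male_policy_exclude_locus_call(flawed_x_table):
    clean, report = validate_x_males(flawed_x_table, "exclude_locus_call")
    assert clean.n_individuals == 4
    assert {(s, l) for s, l, _ in report.removed_calls} == {
        ("drop", "XA"), ("het", "XA")}
    # the males' other locus survives
    sp = estimate_frequencies(clean, "XB", "males")
    assert sp.n_chrom == 3


def test_x_male_policy_error(flawed_x_table):
    with pytest.raises(ValueError):
        validate_x_males(flawed_x_table, "error")


def test_x_male_no_violations_is_identity():
    t = make_table([X1], [
        ("m", "male", "P", {"XA": ("10", None)}),
        ("f", "female", "P", {"XA": ("10", "11")}),
    ])
    clean, report = validate_x_males(t)
    assert not report
    assert clean.n_individuals == 2


def test_study_scale_dropout_exclusion():
    # 169 males, two with one missing X locus each -> 167 males retained
    rows = [(f"m{i}", "male", "P",
             {"XA": ("10", None), "XB": ("8", None)}) for i in range(167)]
    rows.append(("m167", "male", "P", {"XA": (None, None), "XB": ("8", None)}))
    rows.append(("m168", "male", "P", {"XA": ("10", None), "XB": (None, None)}))
    t = make_table([X1, X2], rows)
    clean, report = validate_x_males(t, "exclude_sample")
    assert clean.n_individuals == 167
    assert report.n_removed_samples == 2


def test_count_distinct_alleles():
    s1 = AlleleFrequencySpectrum("L1", {"10": 1, "11": 2, "12": 1})
    s2 = AlleleFrequencySpectrum("L2", {"8": 1, "9": 1})
    s3 = AlleleFrequencySpectrum("L3", {"9.3": 2, "10": 2})
    per, total = count_distinct_alleles([s1, s2, s3])
    assert per == {"L1": 3, "L2": 2, "L3": 2}
    assert total == 7


def test_frequency_table_round_trip(tmp_path, rng):
    spectra = [
        AlleleFrequencySpectrum("L1", {"9": 3, "9.3": 1, "10": 6}),
        AlleleFrequencySpectrum("L2", {"14": 414, "15": 1}),
    ]
    path = tmp_path / "freqs.csv"
    write_frequency_table(spectra, path)
    back = read_frequency_table(path)
    assert {sp.locus: sp.counts for sp in back} == {
        sp.locus: sp.counts for sp in spectra}
    # display formatting is fixed-point 4 decimals
    text = path.read_text()
    assert "0.0024" in text  # 1/415


def test_genotype_table_round_trip(tmp_path):
    cfg = SimConfig(seed=11, n_loci_x=3, alleles_min=4, alleles_max=8,
                    n_females_x=10, n_males_x=10,
                    subpopulations=(("P", 20, 0.05),))
    table, _ = simulate_x_table(cfg)
    path = tmp_path / "x.tsv"
    write_genotype_table(table, path)
    back = read_genotype_table(path, table.panel)
    assert back.data.equals(table.data)


def test_frequency_invariants_on_simulated_tables():
    cfg = SimConfig(seed=7, n_loci_x=4, alleles_min=4, alleles_max=10,
                    n_females_x=30, n_males_x=40,
                    subpopulations=(("P", 70, 0.02),), dropout_rate=0.0)
    table, _ = simulate_x_table(cfg)
    for m in table.panel:
        for stratum, expect in (("pooled", 100), ("females", 60),
                                ("males", 40)):
            sp = estimate_frequencies(table, m, stratum)
            assert sp.n_chrom == expect
            assert abs(sum(sp.as_dict().values()) - 1.0) < 1e-12
            for c in sp.counts.values():
                assert c >= 1  # p_i >= 1/n_chrom, counts integral
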