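import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popkit.dataio import (
    AlleleName,
    LocusGenotype,
    PopFileError,
    PopulationDataset,
    format_haplotype_name,
    parse_pop_file,
    write_pop_file,
)

from conftest import TWO_LOCUS_POP


def test_parse_basic_dataset(two_locus_dataset):
    ds = two_locus_dataset
    assert ds.n_individuals == 3
    assert ds.loci == ["A", "B"]
    assert ds.metadata == {"name": "demo", "region": "testland"}
    assert ds.individuals[1][0] == LocusGenotype(AlleleName("01:01"), AlleleName("02:01"))


def test_untyped_marker_makes_single_locus_incomplete():
    text = TWO_LOCUS_POP.replace("01:01\t02:01\t02:01\t03:01", "01:01\t****\t02:01\t03:01")
    ds = parse_pop_file(io.StringIO(text))
    assert not ds.individuals[1][0].complete  # locus A incomplete
    assert ds.individuals[1][1].complete  # locus B untouched
    assert all(g.complete for g in ds.individuals[0]) and all(
        g.complete for g in ds.individuals[2]
    )


def test_custom_untyped_marker():
    text = TWO_LOCUS_POP.replace("02:01\t02:01\t03:01\t03:01", "02:01\tNONE\t03:01\t03:01")
    ds = parse_pop_file(io.StringIO(text), untyped_marker="NONE")
    assert not ds.individuals[2][0].complete


@pytest.mark.parametrize(
    "mutation, fragment",
    [
        # a row with 5 allele fields instead of 4
        (lambda t: t.replace("02:01\t02:01\t03:01\t03:01", "02:01\t02:01\t03:01\t03:01\t09:99"), "line 6"),
        # odd number of header columns
        (lambda t: t.replace("A_1\tA_2\tB_1\tB_2", "A_1\tA_2\tB_1"), "odd"),
        # duplicate locus
        (lambda t: t.replace("B_1\tB_2", "A_1\tA_2"), "duplicate"),
        # bad header suffixes
        (lambda t: t.replace("A_1\tA_2", "A_x\tA_y"), "_1"),
    ],
)
def test_format_errors_name_the_problem(mutation, fragment):
    with pytest.raises(PopFileError) as err:
        parse_pop_file(io.StringIO(mutation(TWO_LOCUS_POP)))
    assert fragment in str(err.value)


@pytest.mark.parametrize("text", ["", "name: x\n", "name: x\nA_1\tA_2\n"])
def test_empty_body_rejected(text):
    with pytest.raises(PopFileError):
        parse_pop_file(io.StringIO(text))


def test_crlf_accepted():
    ds = parse_pop_file(io.StringIO(TWO_LOCUS_POP.replace("\n", "\r\n")))
    assert ds.n_individuals == 3


def test_round_trip_identity(two_locus_dataset):
    buf = io.StringIO()
    write_pop_file(two_locus_dataset, buf)
    again = parse_pop_file(io.StringIO(buf.getvalue()))
    assert again.metadata == two_locus_dataset.metadata
    assert again.loci == two_locus_dataset.loci
    assert again.individuals == two_locus_dataset.individuals


def test_round_trip_preserves_untyped():
    text = TWO_LOCUS_POP.replace("01:01\t02:01", "****\t02:01", 1)
    ds = parse_pop_file(io.StringIO(text))
    buf = io.StringIO()
    write_pop_file(ds, buf)
    assert "****" in buf.getvalue()
    assert parse_pop_file(io.StringIO(buf.getvalue())).individuals == ds.individuals


def test_genotype_pair_is_order_insensitive():
    a, b = AlleleName("01:01"), AlleleName("02:01")
    assert LocusGenotype(a, b) == LocusGenotype(b, a)
    assert hash(LocusGenotype(a, b)) == hash(LocusGenotype(b, a))


def test_long_colon_names_survive():
    text = TWO_LOCUS_POP.replace("01:01\t01:01\t02:01", "A*02:01:01:134Q\tDPB1*1372:01:01:02\t02:01")
    ds = parse_pop_file(io.StringIO(text))
    names = {ds.individuals[0][0].allele1.raw, ds.individuals[0][0].allele2.raw}
    assert names == {"A*02:01:01:134Q", "DPB1*1372:01:01:02"}


allele_names = st.text(
    alphabet=st.sampled_from("ABDQ*:0123456789"), min_size=1, max_size=12
).filter(lambda s: s != "****")


@settings(derandomize=True, max_examples=50)
@given(
    loci=st.lists(
        st.text(alphabet=st.sampled_from("ABCDQR"), min_size=1, max_size=4),
        min_size=1,
        max_size=4,
        unique=True,
    ),
    rows=st.integers(min_value=1, max_value=5),
    data=st.data(),
)
def test_round_trip_property(loci, rows, data):
    """Any dataset expressible in the dialect survives write -> parse intact."""
    individuals = []
    for _ in range(rows):
        genos = []
        for _ in loci:
            a1 = data.draw(st.one_of(allele_names, st.none()))
            a2 = data.draw(allele_names)
            genos.append(
                LocusGenotype(
                    AlleleName("", untyped=True) if a1 is None else AlleleName(a1),
                    AlleleName(a2),
                )
            )
        individuals.append(tuple(genos))
    ds = PopulationDataset(metadata={"name": "prop"}, loci=list(loci), individuals=individuals)
    buf = io.StringIO()
    write_pop_file(ds, buf)
    again = parse_pop_file(io.StringIO(buf.getvalue()))
    assert again.loci == ds.loci
    assert again.individuals == ds.individuals


class TestHaplotypeName:
    def test_pair_uses_tilde(self):
        assert format_haplotype_name(["A*01:01", "B*08:01"]) == "A*01:01~B*08:01"

    def test_single_element(self):
        assert format_haplotype_name([AlleleName("01:01")]) == "01:01"

    def test_five_alleles_four_separators(self):
        name = format_haplotype_name([f"{i:02d}:01" for i in range(5)])
        assert name.count("~") == 4

    def test_untyped_member_rejected(self):
        with pytest.raises(ValueError):
            format_haplotype_name([AlleleName("", untyped=True), AlleleName("01:01")])
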