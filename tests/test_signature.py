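"""Loop-receptor signature representation, distances, families, consensus."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tectofit import (
    LoopReceptorVariant,
    PairClass,
    SignatureAlignment,
    classify_pair,
    consensus,
    family_components,
    pairing_profile,
    parse_variant_name,
    point_mutation_distance,
)
from tectofit.positions import label_key, sort_labels
from tectofit.signature import read_fasta, signature_report, write_fasta


# --- construct-name grammar -------------------------------------------------

@pytest.mark.parametrize(
    "name, expected",
    [
        ("980_9", ("980", 9, None)),
        ("980", ("980", 11, None)),
        ("4LVV_9.1", ("4LVV", 9, "1")),
        ("980.2", ("980", 11, "2")),
        ("4LVV_10", ("4LVV", 10, None)),
    ],
)
def test_parse_variant_name(name, expected):
    assert parse_variant_name(name) == expected


def test_parse_variant_name_rejects_bad_stem():
    with pytest.raises(ValueError, match="_12"):
        parse_variant_name("980_12")


def test_parse_variant_name_rejects_empty():
    with pytest.raises(ValueError):
        parse_variant_name("")


# --- position-label ordering -------------------------------------------------

def test_insertion_labels_sort_between_flanking_positions():
    assert label_key("6") < label_key("6.1") < label_key("7")
    assert sort_labels(["7", "6.1", "6", "23", "10"]) == ["6", "6.1", "7", "10", "23"]


# --- pair classification ----------------------------------------------------

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@pytest.mark.parametrize("a, b", list(itertools.product("ACGU", repeat=2)))
def test_classify_pair_truth_table(a, b):
    expected = (
        PairClass.WATSON_CRICK
        if (a, b) in _WC
        else PairClass.WOBBLE
        if (a, b) in _WOBBLE
        else PairClass.MISMATCH
    )
    assert classify_pair(a, b) is expected


def test_classify_pair_deletion_and_bad_base():
    assert classify_pair(None, "A") is PairClass.UNPAIRED
    assert classify_pair("G", None) is PairClass.UNPAIRED
    with pytest.raises(ValueError):
        classify_pair("T", "A")


# --- pairing profile ----------------------------------------------------------

def test_pairing_profile_has_five_fixed_pairs(variants):
    for v in variants.values():
        prof = pairing_profile(v)
        assert [p for p, _ in prof.pairs] == [
            ("8", "22"), ("9", "21"), ("10", "20"), ("11", "19"), ("12", "18")
        ]


def test_pairing_profile_gc_counts(variants):
    assert pairing_profile(variants["980"]).gc_count == 4
    assert pairing_profile(variants["4LVV"]).gc_count == 3
    assert pairing_profile(variants["488.1"]).gc_count == 4


def test_593_carries_au_pair_at_10_20(variants):
    prof = dict(pairing_profile(variants["593"]).pairs)
    assert prof[("10", "20")] is PairClass.WATSON_CRICK
    assert variants["593"].residues["10"] == "A"
    assert variants["593"].residues["20"] == "U"


def test_deleted_position_yields_unpaired():
    v = LoopReceptorVariant(id="x", residues={"8": "G"})
    prof = dict(pairing_profile(v).pairs)
    assert prof[("9", "21")] is PairClass.UNPAIRED


# --- point-mutation distance --------------------------------------------------

def test_distance_examples(variants):
    v980 = variants["980"]
    assert point_mutation_distance(v980, v980) == 0
    assert point_mutation_distance(variants["3SUX"], v980) == 1
    assert point_mutation_distance(variants["593"], v980) == 2
    assert point_mutation_distance(variants["4LVV"], v980) == 8
    # deletion and insertion each count as one point mutation
    assert point_mutation_distance(variants["980.2"], v980) == 1
    assert point_mutation_distance(variants["894"], variants["593"]) == 1


@st.composite
def _short_variant(draw):
    labels = ["1", "2", "3", "4", "5"]
    residues = {
        l: draw(st.sampled_from("ACGU"))
        for l in labels
        if draw(st.booleans())
    }
    return LoopReceptorVariant(id="v", residues=residues)


@settings(max_examples=60, derandomize=True)
@given(_short_variant(), _short_variant(), _short_variant())
def test_distance_is_a_metric(a, b, c):
    assert point_mutation_distance(a, a) == 0
    assert point_mutation_distance(a, b) == point_mutation_distance(b, a)
    assert (
        point_mutation_distance(a, c)
        <= point_mutation_distance(a, b) + point_mutation_distance(b, c)
    )


# --- sequence families ----------------------------------------------------------

def test_single_variant_is_a_singleton_family(variants):
    assert family_components([variants["980"]]) == [["980"]]


def test_families_follow_the_two_mutation_rule(variants):
    far = LoopReceptorVariant(
        id="far", residues={str(i): "A" for i in range(1, 24)}
    )
    fams = family_components([variants["980"], variants["3SUX"], far])
    assert fams == [["3SUX", "980"], ["far"]]


def test_families_are_transitive_chains():
    base = {str(i): "A" for i in range(1, 24)}
    a = LoopReceptorVariant(id="a", residues=base)
    b = LoopReceptorVariant(id="b", residues={**base, "1": "C", "2": "C"})
    c = LoopReceptorVariant(id="c", residues={**base, "1": "C", "2": "C", "3": "G", "4": "G"})
    assert point_mutation_distance(a, c) == 4
    assert family_components([a, b, c]) == [["a", "b", "c"]]


def test_family_partition_and_order_invariance(variants):
    vs = list(variants.values())
    fams = family_components(vs)
    ids = sorted(v.id for v in vs)
    assert sorted(vid for fam in fams for vid in fam) == ids
    assert family_components(list(reversed(vs))) == fams


def test_curated_set_splits_into_two_families(variants):
    fams = family_components(list(variants.values()))
    assert len(fams) == 2
    assert "980" in fams[0] and "3SUX" in fams[0]
    assert "4LVV" in fams[1] and "488.1" in fams[1]


# --- consensus -------------------------------------------------------------------

def test_consensus_majority_and_degenerate_codes():
    assert consensus(["G", "G", "G"]) == "G"
    assert consensus(["A", "A", "A", "G"]) == "A"  # 0.75 is inclusive
    assert consensus(["A", "A", "G", "G"]) == "R"
    assert consensus(["C", "C", "U", "U"]) == "Y"
    assert consensus(["A", "A", "U", "U"]) == "W"
    assert consensus(["A", "C", "G", "U"]) == "N"


def test_consensus_gap_majority_emits_gap():
    assert consensus(["A-", "A-", "AG"]) == "A-"


def test_consensus_is_idempotent(variants):
    cons = consensus(SignatureAlignment(list(variants.values())))
    assert consensus([cons]) == cons


def test_consensus_of_curated_set_conserves_key_positions(variants):
    aln = SignatureAlignment(list(variants.values()))
    cons = dict(zip(aln.columns, consensus(aln)))
    assert cons["7"] == "G"  # highly conserved guanosine
    assert cons["13"] == "U"  # ligand-contacting uracil


# --- FASTA round trip and report ---------------------------------------------------

def test_fasta_round_trip(tmp_path, variants):
    path = tmp_path / "sig.fasta"
    write_fasta(variants.values(), str(path))
    back = {v.id: v for v in read_fasta(str(path))}
    assert set(back) == set(variants)
    for vid, v in variants.items():
        assert dict(back[vid].residues) == dict(v.residues)
        assert back[vid].stem_length_bp == v.stem_length_bp
        assert back[vid].source == v.source


def test_signature_report_columns_and_reference_distance(variants):
    df = signature_report(list(variants.values()), reference_id="4LVV")
    assert {"id", "family", "gc_count", "pair_8_22", "dist_to_4LVV"} <= set(df.columns)
    row = df[df["id"] == "980"].iloc[0]
    assert row["dist_to_4LVV"] == 8
    assert df[df["id"] == "4LVV"]["dist_to_4LVV"].iloc[0] == 0


def test_signature_report_unknown_reference(variants):
    with pytest.raises(ValueError):
        signature_report(list(variants.values()), reference_id="nope")
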