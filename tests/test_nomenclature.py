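"""Protein-HGVS parsing, canonicalization and cross-dialect equivalence."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqapt.nomenclature import (
    ONE_TO_THREE,
    THREE_TO_ONE,
    ChangeKind,
    HgvsParseError,
    ProteinChange,
    canonicalize,
    key_for,
    parse_protein_hgvs,
    variants_equivalent,
)
from eqapt.schemas import OrderedVariant, ReportedVariant
from eqapt.simulate import Dialect, render_dialect

AA3 = [a for a in THREE_TO_ONE if a != "Ter"]


@pytest.mark.parametrize(
    "text, kind, refs, alts",
    [
        ("p.V600R", ChangeKind.SUBSTITUTION, (("Val", 600),), ("Arg",)),
        ("p.(Val600Glu)", ChangeKind.SUBSTITUTION, (("Val", 600),), ("Glu",)),
        ("p(Val600Arg)", ChangeKind.SUBSTITUTION, (("Val", 600),), ("Arg",)),
        ("p.Val600Arg", ChangeKind.SUBSTITUTION, (("Val", 600),), ("Arg",)),
        ("p.(Arg1443*)", ChangeKind.NONSENSE, (("Arg", 1443),), ("Ter",)),
        ("p.(Glu171Ter)", ChangeKind.NONSENSE, (("Glu", 171),), ("Ter",)),
        (
            "p.(Glu746_Ala750delinsIlePro)",
            ChangeKind.DELINS,
            (("Glu", 746), ("Ala", 750)),
            ("Ile", "Pro"),
        ),
        (
            "p.(Glu746-Ala750del)",  # hyphen range separator dialect
            ChangeKind.DELETION,
            (("Glu", 746), ("Ala", 750)),
            (),
        ),
        ("p.(His195_Pro196dup)", ChangeKind.DUPLICATION,
         (("His", 195), ("Pro", 196)), ()),
        ("p.Val600delinsArg", ChangeKind.DELINS, (("Val", 600),), ("Arg",)),
        ("p.V600delinsR", ChangeKind.DELINS, (("Val", 600),), ("Arg",)),
    ],
)
def test_parse_dialects(text, kind, refs, alts):
    change = parse_protein_hgvs(text)
    assert change.kind is kind
    assert change.ref_residues == refs
    assert change.alt_residues == alts


def test_parse_frameshift_with_offset():
    change = parse_protein_hgvs("p.(Asn1784Thrfs*7)")
    assert change.kind is ChangeKind.FRAMESHIFT
    assert change.ref_residues == (("Asn", 1784),)
    assert change.fs_new_residue == "Thr"
    assert change.fs_term_offset == 7
    bare = parse_protein_hgvs("p.Val600fs")
    assert bare.fs_term_offset is None and bare.fs_new_residue is None


@pytest.mark.parametrize(
    "bad", ["", "p.()", "Val600", "p.600Val", "p.Xyz600Arg", "p.V600delins",
            "p.(Ala750_Glu746del)", "p.(Ter100Arg)", "c.1799T>A"],
)
def test_parse_failures(bad):
    with pytest.raises(HgvsParseError):
        parse_protein_hgvs(bad)


def test_canonicalize_reduces_single_residue_delins():
    assert canonicalize(parse_protein_hgvs("p.Val600delinsArg")) == "p.(Val600Arg)"
    assert canonicalize(parse_protein_hgvs("p.V600delinsR")) == "p.(Val600Arg)"
    # multi-residue delins is not a substitution and must not be reduced
    assert (
        canonicalize(parse_protein_hgvs("p.(Glu746_Ala750delinsIlePro)"))
        == "p.(Glu746_Ala750delinsIlePro)"
    )


def test_canonical_forms():
    assert canonicalize(parse_protein_hgvs("p.R1443*")) == "p.(Arg1443*)"
    assert canonicalize(parse_protein_hgvs("p.(Glu746-Ala750del)")) == "p.(Glu746_Ala750del)"
    assert canonicalize(parse_protein_hgvs("p.N1784Tfs*7")) == "p.(Asn1784Thrfs*7)"


def test_one_letter_round_trip_lossless():
    assert set(THREE_TO_ONE.values()) == set(ONE_TO_THREE)
    for three, one in THREE_TO_ONE.items():
        assert ONE_TO_THREE[one] == three


def _ordered(gene, p_hgvs, pos=1000):
    return OrderedVariant(
        sample_id="S1", gene=gene, p_hgvs=p_hgvs, chrom="chr1", pos=pos,
        expected_af=10.0,
    )


def _reported(gene, p_hgvs, pos=1000):
    return ReportedVariant(
        participant="LAB", sample_id="S1", replicate=1, gene=gene,
        chrom="chr1", pos=pos, p_hgvs_raw=p_hgvs, af=10.0,
    )


def test_equivalence_examples():
    assert variants_equivalent(_reported("BRAF", "p.V600R"), _ordered("BRAF", "p.(Val600Arg)"))
    # gene symbol mismatch is decisive even for identical protein changes
    assert not variants_equivalent(_reported("KRAS", "p.(Gly12Asp)"), _ordered("NRAS", "p.(Gly12Asp)"))
    # a deletion and a delins with different outcomes are distinct events
    assert not variants_equivalent(
        _reported("EGFR", "p.(Glu746_Ala750delinsIlePro)"),
        _ordered("EGFR", "p.(Glu746-Ala750del)"),
    )


def test_frameshift_offsets_conservative():
    assert not variants_equivalent(
        _reported("BRCA2", "p.(Asn1784Thrfs*7)"),
        _ordered("BRCA2", "p.(Asn1784Thrfs*9)"),
    )
    assert not variants_equivalent(
        _reported("BRCA2", "p.(Asn1784Thrfs)"),
        _ordered("BRCA2", "p.(Asn1784Thrfs*7)"),
    )


def test_genomic_fallback_never_mixes_levels():
    # unparseable protein string falls back to coordinate identity
    assert variants_equivalent(_reported("MET", "exon14skip", pos=77),
                               _ordered("MET", "p.(Val600Glu)", pos=77))
    assert not variants_equivalent(_reported("MET", "exon14skip", pos=78),
                                   _ordered("MET", "p.(Val600Glu)", pos=77))
    # parseable but different canonical forms never rescue via coordinates
    assert not variants_equivalent(_reported("MET", "p.(Val600Met)", pos=77),
                                   _ordered("MET", "p.(Val600Glu)", pos=77))


def test_all_six_renderings_collapse_to_one_key():
    renderings = ["p.(Val600Arg)", "p(Val600Arg)", "p.Val600Arg", "p.V600R",
                  "p.Val600delinsArg", "p.V600delinsR"]
    keys = {key_for("BRAF", r).label for r in renderings}
    assert keys == {"BRAF p.(Val600Arg)"}


@st.composite
def protein_changes(draw):
    kind = draw(st.sampled_from(list(ChangeKind)))
    pos = draw(st.integers(1, 5000))
    ref = draw(st.sampled_from(AA3))
    if kind in (ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE):
        alt = ("Ter",) if kind is ChangeKind.NONSENSE else (
            draw(st.sampled_from(AA3)),)
        return ProteinChange(kind=kind, ref_residues=((ref, pos),), alt_residues=alt)
    if kind is ChangeKind.FRAMESHIFT:
        return ProteinChange(
            kind=kind, ref_residues=((ref, pos),),
            fs_new_residue=draw(st.one_of(st.none(), st.sampled_from(AA3))),
            fs_term_offset=draw(st.one_of(st.none(), st.integers(1, 99))),
        )
    span = draw(st.booleans())
    refs = ((ref, pos), (draw(st.sampled_from(AA3)), pos + draw(st.integers(1, 50)))) \
        if span else ((ref, pos),)
    if kind in (ChangeKind.DELETION, ChangeKind.DUPLICATION):
        return ProteinChange(kind=kind, ref_residues=refs)
    if kind is ChangeKind.INSERTION and not span:
        refs = ((ref, pos), ("Ala", pos + 1))
    alts = tuple(draw(st.lists(st.sampled_from(AA3), min_size=1, max_size=4)))
    return ProteinChange(kind=kind, ref_residues=refs, alt_residues=alts)


@settings(max_examples=300, derandomize=True)
@given(protein_changes())
def test_canonicalize_parse_idempotent(change):
    canonical = canonicalize(change)
    assert canonicalize(parse_protein_hgvs(canonical)) == canonical


@settings(max_examples=200, derandomize=True)
@given(protein_changes(), st.sampled_from(list(Dialect)))
def test_dialect_rendering_preserves_identity(change, dialect):
    canonical = canonicalize(change)
    rendered = render_dialect(canonical, dialect)
    assert canonicalize(parse_protein_hgvs(rendered)) == canonical


@settings(max_examples=100, derandomize=True)
@given(st.sampled_from(AA3), st.integers(1, 2000),
       st.sampled_from(AA3), st.permutations(list(Dialect)))
def test_equivalence_is_equivalence_relation(ref, pos, alt, dialects):
    """Reflexive/symmetric/transitive across dialect renderings."""
    canonical = f"p.({ref}{pos}{alt})"
    rendered = [render_dialect(canonical, d) for d in dialects[:3]]
    reports = [_reported("BRAF", r) for r in rendered]
    ordered = [_ordered("BRAF", r) for r in rendered]
    for i in range(3):
        assert variants_equivalent(reports[i], ordered[i])
        for j in range(3):
            assert variants_equivalent(reports[i], ordered[j]) == variants_equivalent(
                reports[j], ordered[i]
            )
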