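"""Label grammars, site naming from CDS anchors, codon-engineering designs."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from ppredit.nomenclature import (
    CdsModel,
    LabelError,
    ProteinLabel,
    SiteLabel,
    Substitution,
    TargetVariant,
    apply_target_mutations,
    design_codon_edits,
    format_protein_label,
    name_site,
    name_site_from_annotation,
    parse_protein_label,
    parse_site_label,
    parse_target_label,
    read_cds_bed12,
    read_cds_gff3,
)
from ppredit.ppr_code import TargetWindow, reverse_complement


# -- protein-mutation labels -------------------------------------------------


def test_parse_dyw_point_mutation():
    label = parse_protein_label("PPR56|DYW:G3A")
    assert label.factor == "PPR56"
    (mut,) = label.mutations
    assert (mut.domain, mut.position, mut.from_aa, mut.to_aa) == ("DYW", 3, "G", "A")


def test_parse_double_ppr_mutation_preserves_order():
    label = parse_protein_label("PPR56|S-7TD>TN|S-4TN>TD")
    assert [m.motif_index for m in label.mutations] == [-7, -4]
    assert [m.from_pair for m in label.mutations] == ["TD", "TN"]


def test_parse_invalid_motif_class_fails():
    with pytest.raises(LabelError):
        parse_protein_label("PPR56|Q-3XX")


def test_format_e1_point_mutation():
    label = parse_protein_label("PPR56|E1:N34D")
    assert format_protein_label(label) == "PPR56|E1:N34D"


def test_bare_factor_round_trips():
    label = parse_protein_label("PPR56")
    assert label.mutations == ()
    assert format_protein_label(label) == "PPR56"


_protein_segments = st.one_of(
    st.builds(
        lambda d, f, p, t: f"{d}:{f}{p}{t}",
        st.sampled_from(["DYW", "E1", "E2"]),
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        st.integers(min_value=1, max_value=150),
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    ),
    st.builds(
        lambda k, i, a, b: f"{k}{i}{a}>{b}",
        st.sampled_from(["P", "L", "S", "P2", "L2", "S2"]),
        st.integers(min_value=-14, max_value=-1),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=2),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=2),
    ),
    st.builds(
        lambda k, i: f"trunc:{k}{i}",
        st.sampled_from(["P", "L", "S"]),
        st.integers(min_value=-14, max_value=-1),
    ),
)


@settings(max_examples=200, deadline=None)
@given(st.lists(_protein_segments, max_size=3))
def test_protein_label_round_trip(segments):
    label = "|".join(["PPR56", *segments])
    try:
        parsed = parse_protein_label(label)
    except LabelError:
        # duplicate addressing is legitimately rejected
        return
    assert format_protein_label(parsed) == label


# -- editing-site labels -----------------------------------------------------


@pytest.mark.parametrize(
    "text,locus,position,aa_from,aa_to",
    [
        ("nad4eU272SL", "nad4", 272, "S", "L"),
        ("nad3eU230SL", "nad3", 230, "S", "L"),
        ("fdhEeU403Q*", "fdhE", 403, "Q", "*"),
        ("folDeU-5", "folD", -5, None, None),
        ("cox3eU290SF", "cox3", 290, "S", "F"),
        ("yegHeU419SL", "yegH", 419, "S", "L"),
    ],
)
def test_parse_site_label(text, locus, position, aa_from, aa_to):
    site = parse_site_label(text)
    assert (site.locus, site.position) == (locus, position)
    assert (site.aa_from, site.aa_to) == (aa_from, aa_to)
    assert str(site) == text


def test_site_label_requires_eu_token():
    with pytest.raises(LabelError):
        parse_site_label("nad4272SL")


def test_site_label_position_zero_invalid():
    with pytest.raises(LabelError):
        SiteLabel("nad4", 0)


# -- target-variant labels ---------------------------------------------------


def test_parse_single_substitution():
    variant = parse_target_label("nad4eU272SL|u-4g")
    assert variant.substitutions == (Substitution(-4, "u", "g"),)


def test_parse_pre_edited_state():
    variant = parse_target_label("nad4eU272SL|c0u")
    assert variant.substitutions == (Substitution(0, "c", "u"),)


def test_parse_triple_substitution_order():
    variant = parse_target_label("nad3eU230SL|u-16a|u-9g|c-6u")
    assert [s.offset for s in variant.substitutions] == [-16, -9, -6]
    assert str(variant) == "nad3eU230SL|u-16a|u-9g|c-6u"


def test_parse_accepts_t_for_u():
    variant = parse_target_label("nad4eU272SL|t-4g")
    assert variant.substitutions == (Substitution(-4, "u", "g"),)


def test_downstream_substitution_keeps_plus_sign():
    variant = parse_target_label("nad4eU272SL|a+1u")
    assert str(variant) == "nad4eU272SL|a+1u"


# -- applying target mutations ----------------------------------------------


def test_apply_c_minus6_u(nad3_window):
    variant = parse_target_label("nad3eU230SL|c-6u")
    mutated = apply_target_mutations(nad3_window, variant)
    assert mutated[-6] == "U"
    assert nad3_window[-6] == "C"  # original untouched


def test_apply_mismatching_from_base_fails(nad4_window):
    variant = parse_target_label("nad4eU272SL|c-4g")  # -4 is U, not C
    with pytest.raises(LabelError, match="-4"):
        apply_target_mutations(nad4_window, variant)


def test_apply_empty_substitutions_is_identity(nad4_window):
    variant = parse_target_label("nad4eU272SL")
    assert apply_target_mutations(nad4_window, variant) == nad4_window


def test_apply_out_of_window_offset_fails(nad4_window):
    with pytest.raises(LabelError):
        apply_target_mutations(nad4_window, [Substitution(-19, "a", "g")])


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=-16, max_value=2),
            st.sampled_from("acgu"),
        ),
        max_size=5,
        unique_by=lambda t: t[0],
    )
)
def test_apply_then_reverse_restores_window(changes):
    from ppredit.builtin import NAD4_WINDOW

    subs = [
        Substitution(off, NAD4_WINDOW[off].lower(), to)
        for off, to in changes
        if NAD4_WINDOW[off].lower() != to
    ]
    mutated = apply_target_mutations(NAD4_WINDOW, subs)
    restored = apply_target_mutations(mutated, [s.inverse() for s in reversed(subs)])
    assert restored == NAD4_WINDOW


# -- site naming from a CDS anchor ------------------------------------------


def test_name_site_serine_to_leucine():
    # UCA at CDS positions 271-273; editing 272 gives UUA: S -> L
    cds = "AUG" + "GCU" * 89 + "UCA" + "GCU" * 5 + "UAA"
    label = name_site("nad4", cds, 1, 272)
    assert str(label) == "nad4eU272SL"


def test_name_site_glutamine_to_stop():
    # CAA starting at CDS position 403; editing 403 gives UAA: Q -> *
    cds = "AUG" + "GCU" * 133 + "CAA" + "GCU" * 3 + "UAA"
    label = name_site("fdhE", cds, 1, 403)
    assert str(label) == "fdhEeU403Q*"


def test_name_site_upstream_of_start():
    transcript = "AAACAAAA" + "AUGGCUGCUUAA"
    label = name_site("folD", transcript, 9, 4)
    assert str(label) == "folDeU-5"


def test_name_site_requires_cytidine():
    cds = "AUGGCUUAA"
    with pytest.raises(ValueError):
        name_site("x", cds, 1, 2)  # U, not C


@settings(max_examples=60, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_name_site_agrees_with_full_translation(seed):
    """Oracle: translate the whole CDS before/after the C->U substitution."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n_codons = int(rng.integers(5, 40))
    body = "".join(rng.choice(list("ACGU"), size=3 * n_codons))
    cds = "AUG" + body + "UAA"
    c_positions = [i + 1 for i, b in enumerate(cds) if b == "C"]
    if not c_positions:
        return
    pos = int(rng.choice(c_positions))
    label = name_site("x", cds, 1, pos)
    before = str(Seq(cds).translate())
    edited = cds[: pos - 1] + "U" + cds[pos:]
    after = str(Seq(edited).translate())
    codon_idx = (pos - 1) // 3
    assert label.aa_from == before[codon_idx]
    assert label.aa_to == after[codon_idx]
    assert label.position == pos


# -- codon-engineering designs ----------------------------------------------


def test_stop_and_start_designs_on_nad4(nad4_window):
    designs = design_codon_edits(nad4_window)
    stops = {d.codon: d.substitutions for d in designs if d.category == "stop"}
    assert set(stops) == {"UAA", "UAG", "UGA"}
    assert stops["UAA"] == (Substitution(2, "u", "a"),)
    assert stops["UAG"] == (Substitution(2, "u", "g"),)
    assert stops["UGA"] == (
        Substitution(1, "a", "g"),
        Substitution(2, "u", "a"),
    )
    (start,) = [d for d in designs if d.category == "start"]
    assert start.substitutions == (
        Substitution(-1, "u", "a"),
        Substitution(1, "a", "g"),
    )


def test_design_requires_central_cytidine():
    with pytest.raises(ValueError):
        design_codon_edits(TargetWindow("UUUAU", -2))


def test_already_stop_yields_empty_substitutions():
    window = TargetWindow("UCAA", -1)  # after editing: frame reads UAA
    designs = design_codon_edits(window)
    uaa = next(d for d in designs if d.codon == "UAA")
    assert uaa.substitutions == ()


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ACGU", min_size=4, max_size=4))
def test_designs_verify_by_translation(flanks):
    """Re-check every design by editing + reading the engineered frame."""
    seq = flanks[:2] + "C" + flanks[2:]
    window = TargetWindow(seq, -2)
    for design in design_codon_edits(window):
        engineered = apply_target_mutations(window, design.substitutions)
        edited = engineered.with_base(0, "U")
        if design.category == "stop":
            codon = edited[0] + edited[1] + edited[2]
            assert codon == design.codon
            assert str(Seq(codon).translate()) == "*"
        else:
            assert edited[-1] + edited[0] + edited[1] == "AUG"


# -- annotation-backed naming ------------------------------------------------


@pytest.fixture
def toy_genome():
    # gene A: forward CDS at 101..160 (UCA codon at CDS 271-273 impossible in
    # 60 nt; use a C inside); gene B: reverse CDS at 301..330
    fwd_cds = "ATG" + "GCT" * 8 + "TCA" + "GCT" * 9 + "TAA"  # 90 nt
    rev_cds = "ATG" + "GCT" * 3 + "CAA" + "GCT" * 4 + "TAA"  # 30 nt
    seq = ["A"] * 500
    seq[100: 100 + len(fwd_cds)] = list(fwd_cds)
    seq[300: 300 + len(rev_cds)] = list(reverse_complement(rev_cds))
    return {"chr": "".join(seq)}, len(fwd_cds), len(rev_cds)


def test_name_site_forward_cds_from_models(toy_genome):
    reference, fwd_len, _ = toy_genome
    models = [CdsModel("geneA", "chr", "+", ((101, 100 + fwd_len),))]
    # the C of the TCA codon (CDS 28-30): CDS position 29 -> genomic 129
    label = name_site_from_annotation("chr", 129, "+", models, reference)
    assert label == "geneAeU29SL"


def test_name_site_reverse_cds_from_models(toy_genome):
    reference, _, rev_len = toy_genome
    models = [CdsModel("geneB", "chr", "-", ((301, 300 + rev_len),))]
    # CAA codon at CDS 13-15; its C is CDS position 13 -> genomic 330-12=318
    label = name_site_from_annotation("chr", 318, "-", models, reference)
    assert label == "geneBeU13Q*"


def test_name_site_upstream_and_raw_fallback(toy_genome):
    reference, fwd_len, _ = toy_genome
    models = [CdsModel("geneA", "chr", "+", ((101, 100 + fwd_len),))]
    assert name_site_from_annotation("chr", 96, "+", models, reference) == "geneAeU-5"
    assert name_site_from_annotation("chr", 450, "+", models, reference) == "chr:450"


def test_gff3_and_bed12_readers_agree(tmp_path, toy_genome):
    reference, fwd_len, _ = toy_genome
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        f"chr\ttest\tgene\t101\t{100 + fwd_len}\t.\t+\t.\tID=geneA\n"
        f"chr\ttest\tmRNA\t101\t{100 + fwd_len}\t.\t+\t.\tID=mA;Parent=geneA\n"
        f"chr\ttest\tCDS\t101\t{100 + fwd_len}\t.\t+\t0\tID=cA;Parent=mA;gene=geneA\n"
    )
    bed = tmp_path / "ann.bed"
    bed.write_text(
        f"chr\t100\t{100 + fwd_len}\tgeneA\t0\t+\t100\t{100 + fwd_len}\t0\t1"
        f"\t{fwd_len},\t0,\n"
    )
    from_gff = read_cds_gff3(gff)
    from_bed = read_cds_bed12(bed)
    assert len(from_gff) == len(from_bed) == 1
    assert from_gff[0].blocks == from_bed[0].blocks == ((101, 100 + fwd_len),)
    assert from_gff[0].locus == from_bed[0].locus == "geneA"
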