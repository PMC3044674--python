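"""Variant grammar, variant calling, mutation classification, table I/O."""

import warnings

import pytest
from hypothesis import given, strategies as st

from islandlineages.core_io import (
    CODING_RHO,
    HVS1_RHO,
    AlignmentError,
    CoordinateError,
    GeneSpan,
    IntegrityError,
    MT_LENGTH,
    MutationClass,
    MutationKind,
    RegionSpec,
    SchemaError,
    TokenError,
    Variant,
    call_variants,
    classify_mutation,
    format_variant,
    is_hotspot,
    load_gene_map,
    normalize_token,
    parse_variant_token,
    read_genealogy,
    read_mt_samples,
    read_str_profiles,
    write_genealogy,
    write_mt_samples,
    write_str_profiles,
)
from islandlineages.core_io import _TRANSITION_PARTNER


# --------------------------------------------------------------------------
# Token grammar
# --------------------------------------------------------------------------

class TestVariantTokens:
    def test_transversion_with_explicit_base(self, reference):
        v = parse_variant_token("16360A")
        assert v == Variant(16360, "A", MutationKind.TRANSVERSION)
        # the reference carries a pyrimidine there, so A is a transversion
        assert reference[16359] in "CT"

    def test_bare_position_is_transition(self, reference):
        v = parse_variant_token("4025")
        assert v.kind is MutationKind.TRANSITION
        assert v.derived == _TRANSITION_PARTNER[reference[4024]]

    @pytest.mark.parametrize("token,kind", [
        ("310.1C", MutationKind.INSERTION),
        ("523d", MutationKind.DELETION),
    ])
    def test_indel_tokens(self, token, kind):
        assert parse_variant_token(token).kind is kind

    @pytest.mark.parametrize("bad", ["", "  ", "16360X", "abc", "310.C", "d", "-5A"])
    def test_malformed_tokens_raise(self, bad):
        with pytest.raises((TokenError, CoordinateError)):
            parse_variant_token(bad)

    def test_out_of_range_position(self):
        with pytest.raises(CoordinateError):
            parse_variant_token(str(MT_LENGTH + 1))

    def test_derived_equal_to_reference_rejected(self, reference):
        pos = 1000
        with pytest.raises(TokenError):
            parse_variant_token(f"{pos}{reference[pos - 1]}")

    @given(
        pos=st.integers(min_value=1, max_value=MT_LENGTH),
        flavour=st.sampled_from(["transition", "transversion", "deletion", "insertion"]),
        idx=st.integers(min_value=1, max_value=3),
        ins=st.text(alphabet="ACGT", min_size=1, max_size=3),
    )
    def test_token_round_trip(self, pos, flavour, idx, ins, reference):
        """format(parse(t)) == normalize(t) for every valid token."""
        ref_base = reference[pos - 1]
        if flavour == "transition":
            token = str(pos)
        elif flavour == "transversion":
            token = f"{pos}{'A' if ref_base in 'CT' else 'C'}"
        elif flavour == "deletion":
            token = f"{pos}d"
        else:
            token = f"{pos}.{idx}{ins}"
        assert format_variant(parse_variant_token(token)) == normalize_token(token)
        # and parsing the canonical form is a fixpoint
        canonical = normalize_token(token)
        assert normalize_token(canonical) == canonical


# --------------------------------------------------------------------------
# Variant calling
# --------------------------------------------------------------------------

class TestCallVariants:
    def test_identical_sequences_yield_nothing(self, reference):
        assert call_variants(reference, reference) == frozenset()

    def test_single_transition_in_toy_region(self):
        region = RegionSpec("toy", 1, 10)
        out = call_variants("ACGTACATAC", "ACGTACGTAC", region)
        assert out == {Variant(7, "A", MutationKind.TRANSITION)}

    def test_region_window_against_full_reference(self, reference):
        region = RegionSpec("w", 101, 110)
        window = list(reference[100:110])
        window[3] = "A" if window[3] != "A" else "G"
        out = call_variants("".join(window), reference, region)
        assert {v.position for v in out} == {104}

    def test_gapped_alignment_calls_indels(self):
        region = RegionSpec("toy", 1, 9)
        #       ref: ACG-TACGT   (insertion after 3), seq deletes position 6
        out = call_variants("ACGCTA-GT", "ACG-TACGT", region)
        assert Variant(3, "C", MutationKind.INSERTION, 1) in out
        assert Variant(6, "-", MutationKind.DELETION) in out

    def test_length_mismatch_raises(self, reference):
        with pytest.raises(AlignmentError):
            call_variants("ACGT", reference)

    def test_hotspots_are_dropped(self, reference):
        seq = list(reference)
        seq[16518] = _TRANSITION_PARTNER[reference[16518]]  # 16519 transition
        assert call_variants("".join(seq), reference) == frozenset()
        assert is_hotspot(parse_variant_token("16183C"))


# --------------------------------------------------------------------------
# Mutation classification
# --------------------------------------------------------------------------

def _toy_gene_setup():
    """A 60-bp gene on a synthetic molecule, plus the raw sequence."""
    ref = ("T" * 100) + "ATGACCCTAGGCGCATTCAAAGAACTTCGAGGATCTTGGAGAGTTCCTAATCTCGCGTAA" + ("T" * 100)
    gene = GeneSpan("TOY1", 101, 160, "+")
    return ref[:261], (gene,)


class TestClassifyMutation:
    def test_hvs1_transition(self):
        assert classify_mutation(parse_variant_token("16092")) is MutationClass.HVS1_TRANSITION

    def test_hvs1_transversion_is_other(self, reference):
        base = "A" if reference[16091] in "CT" else "C"
        v = parse_variant_token(f"16092{base}")
        assert classify_mutation(v) is MutationClass.OTHER

    def test_deletions_never_synonymous(self):
        v = Variant(8000, "-", MutationKind.DELETION)
        assert classify_mutation(v) is MutationClass.OTHER

    def test_out_of_range_raises(self):
        with pytest.raises(CoordinateError):
            classify_mutation(Variant(300, "A", MutationKind.TRANSITION), reference="ACGT" * 25)

    def test_toy_gene_matches_codon_translation_oracle(self):
        """Exhaustive check of every site and base of a 60-bp gene against
        explicit codon translation under the vertebrate mitochondrial code."""
        from Bio.Seq import Seq

        ref, gene_map = _toy_gene_setup()
        gene = gene_map[0]
        for pos in range(gene.start, gene.end + 1):
            ref_base = ref[pos - 1]
            off = pos - gene.start
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                v_kind = (
                    MutationKind.TRANSITION
                    if (alt in "AG") == (ref_base in "AG")
                    else MutationKind.TRANSVERSION
                )
                got = classify_mutation(Variant(pos, alt, v_kind), gene_map, ref)
                cds = ref[gene.start - 1 : gene.end]
                mutated = cds[:off] + alt + cds[off + 1 :]
                same_aa = Seq(cds).translate(table=2) == Seq(mutated).translate(table=2)
                expected = (
                    MutationClass.SYNONYMOUS_CODING if same_aa else MutationClass.NONSYNONYMOUS
                )
                assert got is expected, f"position {pos} {ref_base}>{alt}"

    def test_overlapping_genes_require_synonymy_in_every_frame(self):
        """On the packaged map, ATP8/ATP6 overlap: a change silent in one
        frame but not the other must not be called synonymous."""
        gene_map = load_gene_map()
        overlap = [p for p in range(8527, 8573)]
        assert overlap, "packaged map should keep the ATP8/ATP6 overlap"
        for pos in overlap:
            v = parse_variant_token(str(pos))
            got = classify_mutation(v)
            per_gene = [
                classify_mutation(v, (g,))
                for g in gene_map
                if g.start <= pos <= g.end
            ]
            if got is MutationClass.SYNONYMOUS_CODING:
                assert all(c is MutationClass.SYNONYMOUS_CODING for c in per_gene)


# --------------------------------------------------------------------------
# Tabular I/O
# --------------------------------------------------------------------------

class TestTableIO:
    def test_str_profile_round_trip(self, make_profile, tmp_path):
        profiles = [
            make_profile("YD05", {0: 15}, haplogroup="O1a*-M119", population="Yami"),
            make_profile("YD12", {3: 22}, haplogroup="O1a1*-P203", population="Yami"),
        ]
        path = tmp_path / "str.tsv"
        write_str_profiles(profiles, path)
        assert read_str_profiles(path) == profiles

    def test_header_only_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("sample_id\tvillage\tancestral_family\textended_family\n")
        with pytest.warns(UserWarning, match="header-only"):
            assert read_genealogy(path) == []

    def test_missing_column_raises_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tvillage\n")
        with pytest.raises(SchemaError):
            read_genealogy(path)

    def test_duplicate_sample_id_raises(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "sample_id\tpopulation\tvariants\nA\tYami\t4025\nA\tYami\t16092\n"
        )
        with pytest.raises(IntegrityError):
            read_mt_samples(path)

    def test_genealogy_record_and_family_consistency_warning(self, tmp_path):
        path = tmp_path / "gen.tsv"
        path.write_text(
            "sample_id\tvillage\tancestral_family\textended_family\n"
            "YD13\tIraralai\tIraralai-I\t46\n"
            "YD14\tYayu\tYayu-I\t46\n"
        )
        with pytest.warns(UserWarning, match="spans ancestral families"):
            records = read_genealogy(path)
        assert records[0].village == "Iraralai"
        assert records[0].extended_family == 46

    def test_unknown_village_warns(self, tmp_path):
        path = tmp_path / "gen.tsv"
        path.write_text(
            "sample_id\tvillage\tancestral_family\textended_family\n"
            "A\tAtlantis\tAtlantis-I\t1\n"
        )
        with pytest.warns(UserWarning, match="unknown village"):
            read_genealogy(path, known_villages=["Iraralai"])

    def test_mt_sample_round_trip_normalises_hotspots(self, tmp_path):
        path = tmp_path / "mt.tsv"
        path.write_text("sample_id\tpopulation\tvariants\nA\tYami\t4025 16519 16092\n")
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            samples = read_mt_samples(path)
        tokens = samples[0].tokens()
        assert "16519" not in tokens and set(tokens) == {"4025", "16092"}
        out = tmp_path / "mt2.tsv"
        write_mt_samples(samples, out)
        assert read_mt_samples(out) == samples
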