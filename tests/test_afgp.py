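"""Afgp locus analytics: gene validation, haplotype deltas, motifs."""

import itertools

import pytest

from notokit.afgp import (
    REASON_FRAME,
    REASON_NO_SIGNAL,
    REASON_NO_TERMINAL,
    REASON_NO_TLP,
    AfgpGeneModel,
    LocusLayout,
    LocusToken,
    compare_haplotype_loci,
    detect_alternating_arrays,
    detect_duplication_motif,
    validate_gene,
)
from notokit.intervals import GenomicInterval
from notokit.synthetic import simulate_afgp_locus


def _functional_gene(gid="g", strand="+", n_rep=30):
    from notokit.synthetic import _dna, _exon2

    return AfgpGeneModel(
        gene_id=gid, strand=strand, exon1_seq=_dna("M" + "LF" * 5), exon2_seq=_exon2(n_rep)
    )


class TestValidateGene:
    def test_intact_gene_functional(self):
        res = validate_gene(_functional_gene())
        assert res.status == "functional" and res.reasons == ()

    def test_missing_exon1_is_pseudogene(self):
        g = _functional_gene()
        g = AfgpGeneModel(gene_id="g", strand="+", exon1_seq=None, exon2_seq=g.exon2_seq)
        res = validate_gene(g)
        assert res.status == "pseudogene"
        assert REASON_NO_SIGNAL in res.reasons

    def test_stripped_terminal_motif(self):
        g = _functional_gene()
        trimmed = g.exon2_seq[:-12]  # drop the AARG codons
        res = validate_gene(AfgpGeneModel(gene_id="g", exon1_seq=g.exon1_seq, exon2_seq=trimmed))
        assert res.status == "pseudogene"
        assert REASON_NO_TERMINAL in res.reasons

    def test_one_bp_deletion_breaks_frame(self):
        g = _functional_gene()
        shifted = g.exon2_seq[:50] + g.exon2_seq[51:]
        res = validate_gene(AfgpGeneModel(gene_id="g", exon1_seq=g.exon1_seq, exon2_seq=shifted))
        assert res.status == "pseudogene"
        assert REASON_FRAME in res.reasons

    def test_chimeric_without_tlp_exons(self):
        g = _functional_gene()
        chi = AfgpGeneModel(
            gene_id="g", gene_type="afgp_tlp", exon1_seq=g.exon1_seq,
            exon2_seq=g.exon2_seq, tlp_exon_seqs=(),
        )
        res = validate_gene(chi)
        assert res.status == "pseudogene" and REASON_NO_TLP in res.reasons

    def test_flags_override_sequences(self):
        g = AfgpGeneModel(gene_id="g", flags={"has_terminal_motif": False})
        res = validate_gene(g)
        assert res.status == "pseudogene" and REASON_NO_TERMINAL in res.reasons

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            AfgpGeneModel(gene_id="g")

    def test_planted_events_all_detected_with_reasons(self):
        events = {
            "afgp1": "drop_exon1",
            "afgp3": "frameshift",
            "afgp5": "strip_terminal",
            "afgp_tlp1": "delete_tlp_exons",
        }
        sim = simulate_afgp_locus(n_units=2, pseudogene_events=events, n_chimeric=1, seed=9)
        expected_reason = {
            "drop_exon1": REASON_NO_SIGNAL,
            "frameshift": REASON_FRAME,
            "strip_terminal": REASON_NO_TERMINAL,
            "delete_tlp_exons": REASON_NO_TLP,
        }
        for g in sim.genes:
            res = validate_gene(g)
            if g.gene_id in events:
                assert res.status == "pseudogene", g.gene_id
                assert expected_reason[events[g.gene_id]] in res.reasons
            else:
                assert res.status == "functional", (g.gene_id, res.reasons)


class TestCompareHaplotypes:
    def test_identical_loci_all_matched(self):
        a = simulate_afgp_locus(n_units=2, seed=3)
        b = simulate_afgp_locus(n_units=2, seed=3)
        cmp = compare_haplotype_loci(a.genes, b.genes)
        assert cmp.unmatched_hap1 == cmp.unmatched_hap2 == ()
        assert cmp.variants == ()

    @pytest.mark.parametrize("delta,frame_ok", [(1224, True), (1, False), (51, True), (2, False)])
    def test_frame_flag(self, delta, frame_ok):
        g1 = _functional_gene("a", n_rep=200)
        base = g1.exon2_seq
        g2 = AfgpGeneModel(gene_id="b", exon1_seq=g1.exon1_seq, exon2_seq=base[: len(base) - delta])
        cmp = compare_haplotype_loci([g1], [g2])
        (v,) = cmp.variants
        assert v.delta_bp == delta
        assert v.frame_preserving is frame_ok

    def test_missing_gene_reported_presence_absence(self):
        a = simulate_afgp_locus(n_units=2, n_chimeric=0, seed=3)
        genes2 = [g for g in a.genes if g.gene_id != "afgp8"]
        cmp = compare_haplotype_loci(a.genes, genes2)
        assert "afgp8" in cmp.unmatched_hap1
        assert cmp.unmatched_hap2 == ()

    def test_symmetry_up_to_role_swap(self):
        a = simulate_afgp_locus(n_units=2, seed=5)
        genes2 = [g for g in a.genes if g.gene_id != "afgp3"]
        fwd = compare_haplotype_loci(a.genes, genes2)
        rev = compare_haplotype_loci(genes2, a.genes)
        assert fwd.unmatched_hap1 == rev.unmatched_hap2
        assert {p for p in fwd.matched} == {(b, a_) for a_, b in rev.matched}


def _gene_tok(name, strand, gtype="afgp"):
    return LocusToken(kind="gene", name=name, strand=strand, gene_type=gtype)


def _rep_tok(fam):
    return LocusToken(kind="repeat", name=fam)


class TestAlternatingArrays:
    def test_eight_alternating_genes_one_run(self):
        toks = [_gene_tok(f"g{i}", "+-"[i % 2]) for i in range(8)]
        (run,) = detect_alternating_arrays(LocusLayout(tuple(toks)))
        assert run.length == 8 and run.pairs_of_pairs == 2

    def test_all_plus_no_run(self):
        toks = [_gene_tok(f"g{i}", "+") for i in range(6)]
        assert detect_alternating_arrays(LocusLayout(tuple(toks))) == []

    def test_interleaved_repeats_do_not_break_runs(self):
        toks = []
        for i in range(4):
            toks.append(_gene_tok(f"g{i}", "+-"[i % 2]))
            toks.append(_rep_tok("L2"))
        (run,) = detect_alternating_arrays(LocusLayout(tuple(toks)))
        assert run.length == 4

    def test_agrees_with_enumeration_oracle(self):
        for n in range(1, 11):
            for strands in itertools.product("+-", repeat=n):
                toks = [_gene_tok(f"g{i}", s) for i, s in enumerate(strands)]
                runs = detect_alternating_arrays(LocusLayout(tuple(toks)))
                # oracle: all maximal alternating substrings of length >= 4
                expected = []
                i = 0
                while i < n:
                    j = i
                    while j + 1 < n and strands[j + 1] != strands[j]:
                        j += 1
                    if j - i + 1 >= 4:
                        expected.append((i, j - i + 1))
                    i = j + 1
                assert [(r.start_index, r.length) for r in runs] == expected


class TestDuplicationMotif:
    def test_three_copy_unit(self):
        unit = [_gene_tok("a", "+"), _gene_tok("b", "-"), _rep_tok("t1"), _rep_tok("t2")]
        toks = unit * 3
        res = detect_duplication_motif(LocusLayout(tuple(toks)))
        assert res.copies == 3
        assert len(res.unit) == 4
        assert res.unit == tuple(t.signature() for t in unit)

    def test_no_repetition_returns_none(self):
        toks = [_gene_tok("a", "+"), _rep_tok("x"), _gene_tok("b", "-"), _rep_tok("y")]
        # signatures: g+ rx g- ry -> unique pairs, no tandem repeat with 2 genes
        assert detect_duplication_motif(LocusLayout(tuple(toks))) is None

    def test_appending_mismatched_token_keeps_copies(self):
        unit = [_gene_tok("a", "+"), _gene_tok("b", "-")]
        toks = unit * 3 + [_rep_tok("zz")]
        res = detect_duplication_motif(LocusLayout(tuple(toks)))
        assert res.copies == 3 and len(res.unit) == 2

    def test_exhaustive_units_recovered(self):
        # U^k returns exactly (U, k) for unit lengths 2-6, copies 2-5
        pool = [
            _gene_tok("a", "+"),
            _gene_tok("b", "-"),
            _rep_tok("r1"),
            _rep_tok("r2"),
            _gene_tok("c", "+"),
            _rep_tok("r3"),
        ]
        for L in range(2, 7):
            unit = pool[:L]
            if sum(1 for t in unit if t.kind == "gene") < 2:
                continue
            for k in range(2, 6):
                layout = LocusLayout(tuple(unit * k))
                res = detect_duplication_motif(layout)
                assert res is not None, (L, k)
                assert res.unit == tuple(t.signature() for t in unit), (L, k)
                assert res.copies == k, (L, k)

    def test_genomic_span_attached(self):
        toks = []
        pos = 0
        for rep in range(2):
            for name, strand in (("a", "+"), ("b", "-")):
                toks.append(
                    LocusToken(
                        kind="gene", name=name, strand=strand,
                        interval=GenomicInterval("chr16", pos, pos + 100), gene_type="afgp",
                    )
                )
                pos += 150
        res = detect_duplication_motif(LocusLayout(tuple(toks)))
        assert res.span == GenomicInterval("chr16", 0, 550)

    def test_simulated_locus_unit_recovered(self):
        sim = simulate_afgp_locus(n_units=4, n_chimeric=0, seed=6)
        res = detect_duplication_motif(sim.layout)
        assert res.copies == 4
        assert len(res.unit) == sim.truth["unit_tokens"]
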