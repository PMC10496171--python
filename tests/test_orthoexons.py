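"""Orthologous-exon filters: identity/indel arithmetic, multimap
resolution, reciprocal validation and the reference builder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebcomp import io as eio
from ebcomp import simulate as sim
from ebcomp.orthoexons import (
    AlignmentHit,
    InvalidRecordError,
    OrthologySet,
    apply_forward_filters,
    build_reference,
    indel_fraction,
    reciprocal_validate,
    resolve_multimapping,
    run_filters,
    sequence_identity,
)


def hit(exon="e1", gene="g1", length=100, matches=90, mism=None, qgap=0,
        tgap=0, chrom="chrT", start=1000, end=None, strand="+",
        src=("chrQ", 500, 700)):
    if mism is None:
        mism = max(0, length - matches - qgap)
    return AlignmentHit(query_exon_id=exon, query_gene_id=gene,
                        query_length=length, matches=matches, mismatches=mism,
                        query_gap_bases=qgap, target_gap_bases=tgap,
                        target_chrom=chrom, target_start=start,
                        target_end=end if end is not None else start + length,
                        strand=strand, source_locus=src)


class TestIdentityAndIndels:
    @pytest.mark.parametrize("matches,length,expected", [
        (80, 100, 0.80), (100, 100, 1.0), (79, 100, 0.79)])
    def test_sequence_identity(self, matches, length, expected):
        assert sequence_identity(hit(matches=matches, length=length)) == \
            pytest.approx(expected)

    @pytest.mark.parametrize("qgap,tgap,expected", [
        (0, 0, 0.0), (15, 10, 0.25), (10, 10, 0.20)])
    def test_indel_fraction(self, qgap, tgap, expected):
        h = hit(matches=70, qgap=qgap, tgap=tgap)
        assert indel_fraction(h) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        h = hit(length=1, matches=1)
        object.__setattr__(h, "query_length", 0)
        object.__setattr__(h, "matches", 0)
        with pytest.raises(InvalidRecordError):
            sequence_identity(h)

    @given(matches=st.integers(0, 100), qgap=st.integers(0, 50),
           tgap=st.integers(0, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_fractions_bounded(self, matches, qgap, tgap):
        h = hit(length=200, matches=matches, qgap=qgap, tgap=tgap)
        assert 0 <= sequence_identity(h) <= 1
        assert indel_fraction(h) >= 0


def five_exon_gene(target_starts, chrom="chrT", identity=0.9, strand="+"):
    """Candidate map for a toy gene: exon i at target_starts[i]."""
    out = {}
    for i, s in enumerate(target_starts):
        out[f"e{i}"] = [hit(exon=f"e{i}", matches=int(identity * 100),
                            chrom=chrom, start=s, strand=strand)]
    return out


class TestMultimapResolution:
    def test_single_hit_returned(self):
        h = hit()
        assert resolve_multimapping([h], {"e1": [h]}) is h

    def test_empty_returns_none(self):
        assert resolve_multimapping([], {}) is None

    def test_neighbor_count_decides(self):
        # exon e0 maps to two loci: locus A near 3 same-gene exons (within
        # 100 kb), locus B near 1
        gene_map = five_exon_gene([0, 10_000, 20_000, 30_000, 5_000_000])
        a = hit(exon="e0", start=0)
        b = hit(exon="e0", start=5_050_000, matches=95)
        gene_map["e0"] = [a, b]
        chosen = resolve_multimapping([a, b], gene_map)
        assert chosen is a  # 3 neighbors beat 1 despite lower identity

    def test_tie_breaks_by_identity_then_locus(self):
        a = hit(exon="e0", start=0, matches=92)
        b = hit(exon="e0", chrom="chrU", start=0, matches=85)
        assert resolve_multimapping([a, b], {"e0": [a, b]}) is a
        c = hit(exon="e0", chrom="chrA", start=0, matches=92)
        # equal identity: lexicographically smallest (chrom, start, end)
        assert resolve_multimapping([a, c], {"e0": [a, c]}) is c

    def test_mixed_strand_neighbor_is_non_support(self):
        gene_map = five_exon_gene([0, 10_000])
        gene_map["e1"].append(hit(exon="e1", start=12_000, strand="-"))
        a = hit(exon="e0", start=0)                     # e1 mixed-strand
        b = hit(exon="e0", chrom="chrU", start=0, matches=95)  # no neighbors
        gene_map["e0"] = [a, b]
        # a's only potential neighbor has mixed-strand support -> 0 vs 0,
        # tie broken by b's higher identity
        assert resolve_multimapping([a, b], gene_map) is b


class TestReciprocalValidation:
    def _forward(self):
        return OrthologySet(retained={"e1": hit()})

    def test_identical_backmaps_retained(self):
        fwd = self._forward()
        back_h = [hit(chrom="chrQ", start=500, end=700)]
        back_c = [hit(chrom="chrT", start=1000, end=1100)]
        out = reciprocal_validate(fwd, back_h, back_c)
        assert "e1" in out.retained

    def test_wrong_chromosome_dropped(self):
        fwd = self._forward()
        back_h = [hit(chrom="chrZ", start=500, end=700)]
        back_c = [hit(chrom="chrT", start=1000, end=1100)]
        out = reciprocal_validate(fwd, back_h, back_c)
        assert out.dropped["e1"] == "reciprocal-human"

    def test_one_base_overlap_retained(self):
        fwd = self._forward()
        back_h = [hit(chrom="chrQ", start=699, end=899)]  # overlaps by 1
        back_c = [hit(chrom="chrT", start=1000, end=1100)]
        out = reciprocal_validate(fwd, back_h, back_c)
        assert "e1" in out.retained

    def test_missing_backmap_flagged(self):
        out = reciprocal_validate(self._forward(), [], [])
        assert out.dropped["e1"] == "no-reciprocal-hit"


class TestBuildReference:
    def test_exon_counts_conserved(self, tmp_path):
        retained = {f"e{i}": hit(exon=f"e{i}", start=1000 + i * 500)
                    for i in range(10)}
        ortho = OrthologySet(retained=retained)
        human_gtf, chimp_gtf, _ = build_reference(ortho, tmp_path)
        assert len(human_gtf.read_text().splitlines()) == 10
        assert len(chimp_gtf.read_text().splitlines()) == 10

    def test_empty_retained_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_reference(OrthologySet(), tmp_path)

    def test_gtf_coordinates_one_based_inclusive(self, tmp_path):
        ortho = OrthologySet(retained={"e1": hit(start=1000, end=1100)})
        _, chimp_gtf, _ = build_reference(ortho, tmp_path)
        fields = chimp_gtf.read_text().split("\t")
        assert fields[3] == "1001" and fields[4] == "1100"


class TestFixtureFidelity:
    def test_retained_set_matches_fixture_truth(self):
        fx = sim.simulate_psl_fixture(200, seed=4)
        ortho = run_filters(fx.forward, fx.back_to_human, fx.chimp_self)
        truth = fx.truth.set_index("exon_id")
        assert set(ortho.retained) == set(truth.index[truth["keep"]])
        for exon, reason in ortho.dropped.items():
            assert truth.at[exon, "reason"] == reason

    def test_order_invariance(self, rng):
        fx = sim.simulate_psl_fixture(150, seed=4)
        base = run_filters(fx.forward, fx.back_to_human, fx.chimp_self)
        for _ in range(3):
            fwd = list(fx.forward)
            rng.shuffle(fwd)
            again = run_filters(fwd, fx.back_to_human, fx.chimp_self)
            assert set(again.retained) == set(base.retained)
            assert again.dropped == base.dropped

    def test_reason_codes_partition_dropped(self):
        fx = sim.simulate_psl_fixture(300, seed=6)
        ortho = run_filters(fx.forward, fx.back_to_human, fx.chimp_self)
        assert set(ortho.retained) & set(ortho.dropped) == set()
        all_exons = set(fx.truth["exon_id"])
        assert set(ortho.retained) | set(ortho.dropped) == all_exons

    def test_psl_round_trip_preserves_decisions(self, tmp_path):
        fx = sim.simulate_psl_fixture(100, seed=5)
        for name, hits in [("fwd", fx.forward), ("back", fx.back_to_human),
                           ("self", fx.chimp_self)]:
            eio.write_psl(tmp_path / f"{name}.psl", hits)
        ortho = run_filters(eio.read_psl(tmp_path / "fwd.psl"),
                            eio.read_psl(tmp_path / "back.psl"),
                            eio.read_psl(tmp_path / "self.psl"))
        truth = fx.truth.set_index("exon_id")
        assert set(ortho.retained) == set(truth.index[truth["keep"]])

    def test_retained_loci_match_expectation(self):
        fx = sim.simulate_psl_fixture(200, seed=8)
        ortho = run_filters(fx.forward, fx.back_to_human, fx.chimp_self)
        truth = fx.truth.set_index("exon_id")
        for exon, h in ortho.retained.items():
            assert h.target_chrom == truth.at[exon, "expected_chrom"]
            assert h.target_start == truth.at[exon, "expected_start"]
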