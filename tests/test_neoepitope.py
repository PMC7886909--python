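"""Variant filter chain, 25-mer windows, 8–11mer enumeration, ranking."""

import numpy as np
import pytest

from tilkit.errors import DataError
from tilkit.neoepitope import (
    NeoepitopeCandidate,
    VariantRecord,
    build_window,
    caller_concordance,
    candidates_to_frame,
    enumerate_peptides,
    filter_variants,
    prioritize_fpkm,
    rank_candidates,
    read_variants_csv,
    stub_scorer,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def variant(
    context="M" * 25,
    position=13,
    alt="K",
    tumor_depth=50,
    normal_depth=50,
    tumor_vaf=0.4,
    normal_vaf=0.0,
    callers=("mutect", "strelka"),
    fpkm=10.0,
):
    return VariantRecord(
        gene="G",
        protein_context=context,
        position=position,
        ref_aa=context[position - 1],
        alt_aa=alt,
        tumor_depth=tumor_depth,
        normal_depth=normal_depth,
        tumor_vaf=tumor_vaf,
        normal_vaf=normal_vaf,
        callers=frozenset(callers),
        fpkm=fpkm,
    )


def brute_force_peptides(window: str, mut_index: int) -> set[str]:
    """All distinct 8–11mer substrings containing the 1-based mutated index."""
    out = set()
    for length in (8, 9, 10, 11):
        for start in range(1, len(window) - length + 2):
            if start <= mut_index <= start + length - 1:
                out.add(window[start - 1 : start + length - 1])
    return out


class TestRecordValidation:
    def test_ref_mismatch_rejected(self):
        with pytest.raises(DataError, match="ref_aa"):
            VariantRecord("G", "MAL", 2, "L", "K", 50, 50, 0.4, 0.0)

    def test_position_outside_context_rejected(self):
        with pytest.raises(DataError, match="position"):
            VariantRecord("G", "MAL", 4, "L", "K", 50, 50, 0.4, 0.0)

    def test_vaf_outside_unit_interval_rejected(self):
        with pytest.raises(DataError, match="tumor_vaf"):
            variant(tumor_vaf=1.4)

    def test_indels_out_of_scope(self):
        with pytest.raises(DataError, match="substitution"):
            VariantRecord("G", "MAL", 2, "A", "KK", 50, 50, 0.4, 0.0)

    def test_unknown_caller_rejected(self):
        with pytest.raises(DataError, match="caller"):
            variant(callers=("mutect", "gatk"))


class TestFilterChain:
    def test_depth_boundaries_are_strict(self):
        kept, rejected = filter_variants([variant(tumor_depth=10)])
        assert not kept and rejected[0] == ["tumor_depth<=10"]
        kept, _ = filter_variants([variant(tumor_depth=11)])
        assert len(kept) == 1

    def test_tumor_vaf_boundary_is_inclusive(self):
        kept, _ = filter_variants([variant(tumor_vaf=0.10)])
        assert len(kept) == 1
        _, rejected = filter_variants([variant(tumor_vaf=0.0999)])
        assert rejected[0] == ["tumor_vaf<0.10"]

    def test_vaf_ratio_rule(self):
        _, rejected = filter_variants([variant(tumor_vaf=0.4, normal_vaf=0.1)])
        assert rejected[0] == ["tumor_normal_vaf_ratio<5"]
        kept, _ = filter_variants([variant(tumor_vaf=0.5, normal_vaf=0.1)])
        assert len(kept) == 1

    def test_germline_clean_passes_ratio_by_definition(self):
        kept, _ = filter_variants([variant(tumor_vaf=0.12, normal_vaf=0.0)])
        assert len(kept) == 1

    def test_all_failed_criteria_enumerated(self):
        _, rejected = filter_variants(
            [variant(tumor_depth=5, normal_depth=5, tumor_vaf=0.05)]
        )
        assert rejected[0] == ["tumor_depth<=10", "normal_depth<=10", "tumor_vaf<0.10"]

    def test_caller_concordance_default_two(self):
        assert caller_concordance([variant(callers=("mutect",))]) == []
        assert len(caller_concordance([variant(callers=("mutect", "strelka"))])) == 1

    def test_caller_concordance_brute_force_fixture(self):
        rng = np.random.default_rng(1)
        names = ["mutect", "somaticsniper", "strelka", "varscan"]
        records = [
            variant(callers=tuple(rng.choice(names, size=k, replace=False)))
            for k in rng.integers(1, 5, size=10)
        ]
        for k in (1, 2, 3, 4):
            kept = caller_concordance(records, k=k)
            assert len(kept) == sum(1 for v in records if len(v.callers) >= k)

    def test_order_independence_of_filters(self):
        rng = np.random.default_rng(2)
        names = ["mutect", "somaticsniper", "strelka", "varscan"]
        records = [
            variant(
                tumor_depth=int(rng.integers(5, 30)),
                normal_depth=int(rng.integers(5, 30)),
                tumor_vaf=float(rng.uniform(0.05, 0.5)),
                normal_vaf=float(rng.choice([0.0, 0.05])),
                callers=tuple(rng.choice(names, size=int(rng.integers(1, 5)), replace=False)),
            )
            for _ in range(50)
        ]
        depth_then_callers = caller_concordance(filter_variants(records)[0])
        callers_then_depth = filter_variants(caller_concordance(records))[0]
        assert depth_then_callers == callers_then_depth


class TestWindow:
    def test_exact_fit_context(self):
        c = build_window(variant(context="A" * 25, position=13, alt="W"))
        assert len(c.window25) == 25
        assert c.mut_index_in_window == 13
        assert c.window25[12] == "W"

    def test_central_position_in_long_context(self):
        ctx = "".join(AA[i % 20] for i in range(100))
        v = variant(context=ctx, position=50, alt="A" if ctx[49] != "A" else "C")
        c = build_window(v)
        assert len(c.window25) == 25 and c.mut_index_in_window == 13

    def test_left_truncation_near_n_terminus(self):
        ctx = "".join(AA[i % 20] for i in range(100))
        v = variant(context=ctx, position=5, alt="A" if ctx[4] != "A" else "C")
        c = build_window(v)
        assert len(c.window25) == 17  # 4 left + 1 + 12 right
        assert c.mut_index_in_window == 5
        assert c.window25[4] == v.alt_aa

    def test_truncation_never_drops_mutation(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            length = int(rng.integers(8, 80))
            ctx = "".join(rng.choice(list(AA), size=length))
            pos = int(rng.integers(1, length + 1))
            alt = next(a for a in AA if a != ctx[pos - 1])
            c = build_window(variant(context=ctx, position=pos, alt=alt))
            assert c.window25[c.mut_index_in_window - 1] == alt


class TestEnumerate:
    def test_central_mutation_full_window_gives_38(self):
        c = enumerate_peptides(build_window(variant()))
        assert len(c.peptides) == 38
        assert all(length in (8, 9, 10, 11) for _, length, _ in c.peptides)

    def test_edge_mutation_gives_4(self):
        ctx = "M" + "A" * 99
        c = enumerate_peptides(build_window(variant(context=ctx, position=1, alt="K")))
        assert len(c.peptides) == 4
        assert sorted(length for _, length, _ in c.peptides) == [8, 9, 10, 11]

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            length = int(rng.integers(8, 120))
            ctx = "".join(rng.choice(list(AA), size=length))
            pos = int(rng.integers(1, length + 1))
            alt = next(a for a in AA if a != ctx[pos - 1])
            c = enumerate_peptides(build_window(variant(context=ctx, position=pos, alt=alt)))
            oracle = brute_force_peptides(c.window25, c.mut_index_in_window)
            assert {seq for seq, _, _ in c.peptides} == oracle
            assert len(c.peptides) == len({seq for seq, _, _ in c.peptides})

    def test_every_peptide_spans_mutation_and_differs_in_one_residue(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            length = int(rng.integers(25, 80))
            ctx = "".join(rng.choice(list(AA), size=length))
            pos = int(rng.integers(1, length + 1))
            alt = next(a for a in AA if a != ctx[pos - 1])
            v = variant(context=ctx, position=pos, alt=alt)
            c = enumerate_peptides(build_window(v))
            left = max(1, v.position - 12)
            for seq, length_, start in c.peptides:
                assert start <= c.mut_index_in_window <= start + length_ - 1
                ref_pep = ctx[left - 1 + start - 1 : left - 1 + start - 1 + length_]
                diffs = sum(a != b for a, b in zip(seq, ref_pep))
                assert diffs == 1

    def test_short_window_yields_empty_list(self):
        c = enumerate_peptides(
            NeoepitopeCandidate(variant(), window25="MAL", mut_index_in_window=2)
        )
        assert c.peptides == ()


class TestPrioritizeAndRank:
    def test_fpkm_boundary_is_strict(self):
        low = enumerate_peptides(build_window(variant(fpkm=100.0)))
        high = enumerate_peptides(build_window(variant(fpkm=250.0)))
        out = prioritize_fpkm([low, high])
        assert [c.prioritized for c in out] == [True, False]
        assert out[0].variant.fpkm == 250.0

    def test_ordering_matches_independent_sort(self):
        rng = np.random.default_rng(17)
        cands = [
            enumerate_peptides(build_window(variant(fpkm=float(f))))
            for f in rng.uniform(0, 400, size=12)
        ]
        out = prioritize_fpkm(cands)
        fpkms = [c.variant.fpkm for c in out]
        n_pri = sum(c.prioritized for c in out)
        assert fpkms[:n_pri] == sorted((f for f in fpkms if f > 100), reverse=True)
        assert fpkms[n_pri:] == sorted((f for f in fpkms if f <= 100), reverse=True)

    def test_inclusive_cutoff(self):
        c = enumerate_peptides(build_window(variant()))
        assert rank_candidates([c], scorer=lambda p: 0.5, cutoff=0.5) != []
        assert rank_candidates([c], scorer=lambda p: 1.5, cutoff=0.5) == []

    def test_stub_scorer_matches_exhaustive_evaluation(self):
        c = enumerate_peptides(build_window(variant(context="ACDEFGHIKLMNPQRSTVWYACDEF", position=13, alt="W")))
        survivors = rank_candidates([c], stub_scorer, cutoff=10.0)
        expected = any(stub_scorer(seq) <= 10.0 for seq, _, _ in c.peptides)
        assert bool(survivors) == expected
        if survivors:
            assert survivors[0].binding_scores == tuple(
                stub_scorer(seq) for seq, _, _ in c.peptides
            )

    def test_scorer_failure_names_peptide(self):
        c = enumerate_peptides(build_window(variant()))
        def bad(p):
            raise ValueError("boom")
        with pytest.raises(DataError, match=c.peptides[0][0]):
            rank_candidates([c], scorer=bad)


def test_csv_roundtrip_and_frame(tmp_path):
    path = tmp_path / "variants.csv"
    path.write_text(
        "gene,protein_context,position,ref_aa,alt_aa,tumor_depth,normal_depth,"
        "tumor_vaf,normal_vaf,callers,fpkm\n"
        f"G1,{'M' * 25},13,M,K,50,50,0.4,0.0,mutect;strelka,120.0\n"
    )
    records = read_variants_csv(path)
    assert records[0].callers == frozenset({"mutect", "strelka"})
    c = enumerate_peptides(build_window(records[0]))
    frame = candidates_to_frame([c])
    assert len(frame) == 38
    assert (frame["mutation"] == "M13K").all()
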