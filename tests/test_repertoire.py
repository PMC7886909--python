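"""Repertoire container, clonality, Morisita–Horn, top-N, tracking, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_repertoire, naive_clonality, naive_morisita_horn
from tilkit.errors import ConfigError, DataError, EmptyRepertoireError
from tilkit.repertoire import (
    CloneRecord,
    Repertoire,
    call_reactive_clones,
    clonality,
    filter_productive,
    morisita_horn,
    read_repertoire_tsv,
    top_n_clones,
    track_clones,
    write_repertoire_tsv,
)


class TestContainer:
    def test_frequencies_recomputed_and_normalized(self):
        rep = make_repertoire({"A": 8, "B": 2})
        assert [c.frequency for c in rep.clones] == [0.8, 0.2]
        assert rep.total_templates == 10
        assert rep.richness == 2

    def test_duplicate_nucleotide_sequences_rejected(self):
        clones = (CloneRecord("AAA", "K", 1), CloneRecord("AAA", "K", 2))
        with pytest.raises(DataError, match="duplicate"):
            Repertoire(clones=clones)

    def test_negative_count_rejected(self):
        with pytest.raises(DataError, match="count"):
            CloneRecord("AAA", "K", -1)

    def test_aa_grouping_aggregates_convergent_clones(self):
        rep = Repertoire(
            clones=(CloneRecord("AAA", "K", 3), CloneRecord("AAG", "K", 2))
        )
        assert rep.counts("cdr3_aa") == {"K": 5}
        assert rep.counts("cdr3_nt") == {"AAA": 3, "AAG": 2}


class TestProductiveFilter:
    def test_all_productive_identity(self):
        rep = make_repertoire({"A": 5, "B": 5})
        assert filter_productive(rep).counts() == rep.counts()

    def test_mixed_renormalizes(self):
        rep = Repertoire(
            clones=(
                CloneRecord("AAA", "K", 6, productive=True),
                CloneRecord("CCC", "P", 4, productive=False),
            )
        )
        filtered = filter_productive(rep)
        assert filtered.richness == 1
        assert filtered.clones[0].frequency == 1.0

    def test_empty_after_filter_is_explicit(self):
        rep = make_repertoire({"A": 5}, productive=False)
        with pytest.raises(EmptyRepertoireError):
            filter_productive(rep)


class TestClonality:
    def test_monoclonal_is_one(self):
        assert clonality(make_repertoire({"A": 42})) == 1.0

    def test_uniform_is_zero(self):
        rep = make_repertoire({f"C{i}": 7 for i in range(50)})
        assert clonality(rep) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case_two_clones(self):
        # counts {8,2}: H = 0.500402, ln 2 = 0.693147 -> C = 0.278072
        assert clonality(make_repertoire({"A": 8, "B": 2})) == pytest.approx(
            0.2780719051, abs=1e-9
        )

    def test_matches_naive_oracle_on_random_repertoires(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            counts = {f"C{i}": int(rng.integers(1, 1000)) for i in range(int(rng.integers(2, 60)))}
            rep = make_repertoire(counts)
            assert clonality(rep) == pytest.approx(
                naive_clonality(list(counts.values())), abs=1e-12
            )

    def test_relabeling_invariance_and_concentration_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = [int(c) for c in rng.integers(2, 200, size=int(rng.integers(3, 20)))]
            rep = make_repertoire({f"C{i}": c for i, c in enumerate(counts)})
            shuffled = list(counts)
            rng.shuffle(shuffled)
            relabeled = make_repertoire({f"Z{i}": c for i, c in enumerate(shuffled)})
            assert clonality(rep) == pytest.approx(clonality(relabeled), abs=1e-12)
            # move one template from a rarer clone to a more common one
            order = sorted(range(len(counts)), key=lambda i: counts[i])
            lo, hi = order[0], order[-1]
            if counts[lo] > 1 and counts[hi] > counts[lo]:
                moved = list(counts)
                moved[lo] -= 1
                moved[hi] += 1
                sharper = make_repertoire({f"C{i}": c for i, c in enumerate(moved)})
                assert clonality(sharper) > clonality(rep)

    def test_empty_errors(self):
        with pytest.raises(EmptyRepertoireError):
            clonality(Repertoire(clones=()))


class TestMorisitaHorn:
    def test_identical_repertoires_give_one(self):
        rep = make_repertoire({"A": 10, "B": 5, "C": 1})
        assert morisita_horn(rep, rep) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_repertoires_give_zero(self):
        a = make_repertoire({"A": 3, "B": 2})
        b = make_repertoire({"C": 4, "D": 1})
        assert morisita_horn(a, b) == 0.0

    def test_hand_case(self):
        a = make_repertoire({"A": 3, "B": 1})
        b = make_repertoire({"A": 1, "B": 3})
        assert morisita_horn(a, b) == pytest.approx(0.6, abs=1e-12)

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            na, nb = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            x = {f"C{i}": int(rng.integers(1, 300)) for i in rng.choice(50, na, replace=False)}
            y = {f"C{i}": int(rng.integers(1, 300)) for i in rng.choice(50, nb, replace=False)}
            got = morisita_horn(make_repertoire(x), make_repertoire(y))
            assert got == pytest.approx(naive_morisita_horn(x, y), abs=1e-12)

    @given(st.integers(1, 1000), st.integers(1, 1000), st.integers(1, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_scale_invariance(self, c1, c2, k):
        a = make_repertoire({"A": c1, "B": c2})
        b = make_repertoire({"A": c2, "C": c1})
        assert morisita_horn(a, b) == pytest.approx(morisita_horn(b, a), abs=1e-12)
        scaled = make_repertoire({"A": c1 * k, "B": c2 * k})
        assert morisita_horn(scaled, b) == pytest.approx(morisita_horn(a, b), abs=1e-9)

    def test_empty_errors(self):
        with pytest.raises(EmptyRepertoireError):
            morisita_horn(Repertoire(clones=()), make_repertoire({"A": 1}))


class TestTopN:
    def test_full_set_cumulative_frequency_is_one(self):
        rep = make_repertoire({"A": 5, "B": 3, "C": 2})
        _, cum = top_n_clones(rep, rep.richness)
        assert cum == pytest.approx(1.0, abs=1e-12)

    def test_top_one_of_8_2(self):
        top, cum = top_n_clones(make_repertoire({"A": 8, "B": 2}), 1)
        assert top[0].cdr3_nt == "A"
        assert cum == pytest.approx(0.8)

    def test_n_beyond_richness_returns_all(self):
        rep = make_repertoire({"A": 5, "B": 3})
        top, cum = top_n_clones(rep, 100)
        assert len(top) == 2 and cum == pytest.approx(1.0)

    def test_matches_brute_force_sort_on_powerlaw_fixture(self):
        rng = np.random.default_rng(7)
        counts = {f"C{i:04d}": int(c) for i, c in enumerate(
            rng.multinomial(10_000, (np.arange(1, 201.0) ** -2) / (np.arange(1, 201.0) ** -2).sum())
        ) if c > 0}
        rep = make_repertoire(counts)
        top, cum = top_n_clones(rep, 30)
        oracle = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:30]
        assert [(c.cdr3_nt, c.count) for c in top] == oracle
        total = sum(counts.values())
        assert cum == pytest.approx(sum(c for _, c in oracle) / total, abs=1e-12)

    def test_deterministic_tie_break(self):
        rep = make_repertoire({"B": 5, "A": 5, "C": 5})
        top, _ = top_n_clones(rep, 2)
        assert [c.cdr3_nt for c in top] == ["A", "B"]

    def test_invalid_n(self):
        with pytest.raises(ConfigError):
            top_n_clones(make_repertoire({"A": 1}), 0)


class TestTrackClones:
    def test_identical_comparator_shares_all(self):
        rep = make_repertoire({f"C{i}": 10 - i for i in range(10)})
        _, shared = track_clones(rep, {"self": rep}, n=5)
        assert shared == {"self": 5}

    def test_disjoint_comparator_shares_none(self):
        rep = make_repertoire({"A": 3, "B": 2})
        other = make_repertoire({"X": 4})
        table, shared = track_clones(rep, {"other": other}, n=2)
        assert shared == {"other": 0}
        assert (table["other"] == 0.0).all()

    def test_planted_injection_recovered_exactly(self):
        rng = np.random.default_rng(5)
        ref_counts = {f"R{i:02d}": int(rng.integers(50, 500)) for i in range(30)}
        injected = sorted(ref_counts, key=lambda k: -ref_counts[k])[:8]
        comp_counts = {k: 7 for k in injected}
        comp_counts.update({f"X{i}": int(rng.integers(1, 50)) for i in range(20)})
        _, shared = track_clones(
            make_repertoire(ref_counts), {"blood": make_repertoire(comp_counts)}, n=8
        )
        assert shared == {"blood": 8}


class TestReactiveClones:
    def test_uniform_at_exact_cutoff_is_empty(self):
        rep = make_repertoire({f"C{i:03d}": 1 for i in range(100)})
        assert call_reactive_clones(rep, 0.02) == []

    def test_hand_counts(self):
        rep = make_repertoire({"A": 40, "B": 30, "C": 20, "D": 10})
        assert len(call_reactive_clones(rep, 0.02)) == 4
        assert len(call_reactive_clones(rep, 0.35)) == 1

    def test_cutoff_validation(self):
        with pytest.raises(ConfigError):
            call_reactive_clones(make_repertoire({"A": 1}), 1.5)


class TestIO:
    def test_airr_roundtrip(self, tmp_path):
        rep = Repertoire(
            clones=(
                CloneRecord("TGTGCC", "CA", 7, True),
                CloneRecord("TGTGCG", "CA", 3, False),
            ),
            sample_id="s1",
        )
        path = tmp_path / "rep.tsv"
        write_repertoire_tsv(rep, path)
        back = read_repertoire_tsv(path, sample_id="s1")
        assert back.counts() == rep.counts()
        assert [c.productive for c in back.clones] == [True, False]

    def test_immunoseq_style_headers(self, tmp_path):
        path = tmp_path / "immunoseq.tsv"
        path.write_text(
            "nucleotide\taminoAcid\tcount (templates/reads)\tsequenceStatus\n"
            "TGTGCC\tCA\t12\tIn\n"
            "TGTAAA\tCK\t3\tOut\n"
        )
        rep = read_repertoire_tsv(path)
        assert rep.counts() == {"TGTGCC": 12, "TGTAAA": 3}
        productive = filter_productive(rep)
        assert productive.richness == 1

    def test_unknown_columns_need_explicit_map(self, tmp_path):
        path = tmp_path / "odd.tsv"
        path.write_text("seq\taa\tn\tok\nTGT\tC\t5\tT\n")
        with pytest.raises(DataError, match="column"):
            read_repertoire_tsv(path)
        rep = read_repertoire_tsv(
            path,
            column_map={"cdr3_nt": "seq", "cdr3_aa": "aa", "count": "n", "productive": "ok"},
        )
        assert rep.counts() == {"TGT": 5}
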