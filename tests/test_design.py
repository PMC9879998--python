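"""Joint design: coarse energy, merging, clusters, resolution, variants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldswitch import (
    DomainError,
    Embedding,
    EnergyModel,
    FoldTemplate,
    SecondaryElement,
    apply_variant,
    coarse_energy,
    find_conflict_clusters,
    graft_cterminal_tail,
    graft_design_tail,
    merge_initial,
    optimize_nonoverlap,
    percent_identity,
    resolve_cluster,
    score_conflicts,
    truncate_to_short,
)
from foldswitch.design import ENERGY_DECIMALS
from foldswitch.tables import AA_INDEX


class TestCoarseEnergy:
    def test_no_contacts_contact_only_weights_scores_zero(self):
        t = FoldTemplate(
            name="t", length=6, elements=(), contacts=frozenset(),
            ref_sequence="AAAAAA", burial=("surface",) * 6,
        )
        model = EnergyModel.default()
        model = EnergyModel(contact=model.contact, burial=model.burial, ss=model.ss,
                            weights=(1.0, 0.0, 0.0))
        assert coarse_energy("AAAAAA", t, model) == 0.0

    def test_equals_term_by_term_hand_sum(self):
        t = FoldTemplate(
            name="t", length=8,
            elements=(SecondaryElement("helix", 2, 5, "α1"),),
            contacts=frozenset({(1, 4), (2, 6), (4, 8)}),
            ref_sequence="LKAVGEFS",
            burial=("core", "surface", "boundary", "core", "surface",
                    "core", "boundary", "surface"),
        )
        model = EnergyModel.default()
        seq = "LKAVGEFS"
        w_c, w_b, w_s = model.weights
        expected = 0.0
        for i, j in [(1, 4), (2, 6), (4, 8)]:
            expected += w_c * model.contact[AA_INDEX[seq[i - 1]], AA_INDEX[seq[j - 1]]]
        for pos, cls in enumerate(t.burial, start=1):
            expected += w_b * model.burial[cls][AA_INDEX[seq[pos - 1]]]
        for pos in range(2, 6):
            expected += w_s * model.ss["helix"][AA_INDEX[seq[pos - 1]]]
        assert coarse_energy(seq, t, model) == pytest.approx(expected, abs=1e-12)

    def test_swapping_contact_free_equal_class_positions_preserves_score(self):
        t = FoldTemplate(
            name="t", length=8, elements=(), contacts=frozenset({(1, 4)}),
            ref_sequence="AAAAAAAA",
            burial=("core", "surface", "surface", "core",
                    "surface", "surface", "surface", "surface"),
        )
        a = "LLAVKEAS"
        b = "LLAVAEKS"  # swap positions 5 and 7 (both surface, no contacts, no ss)
        assert coarse_energy(a, t) == pytest.approx(coarse_energy(b, t), abs=1e-12)

    def test_nonstandard_residue_names_position(self):
        t = FoldTemplate(
            name="t", length=4, elements=(), contacts=frozenset(),
            ref_sequence="AAAA", burial=("surface",) * 4,
        )
        with pytest.raises(DomainError, match="position 3"):
            coarse_energy("AAXA", t)


class TestMergeInitial:
    def test_window_takes_short_reference(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        w0, w1 = truth.window
        assert d.long_sequence[w0 - 1 : w1] == short_t.ref_sequence
        assert d.long_sequence[: w0 - 1] == long_t.ref_sequence[: w0 - 1]
        assert d.long_sequence[w1:] == long_t.ref_sequence[w1:]
        assert d.mutation_log == ()

    def test_marker_alphabets_land_positionally(self):
        long_t = FoldTemplate(
            name="L", length=20, elements=(), contacts=frozenset(),
            ref_sequence="G" * 20, burial=("surface",) * 20,
        )
        short_t = FoldTemplate(
            name="G", length=8, elements=(), contacts=frozenset(),
            ref_sequence="A" * 8, burial=("surface",) * 8,
        )
        emb = Embedding(offset=5, short_len=8, anchor=("x", "x"))
        d = merge_initial(emb, long_t, short_t)
        assert d.long_sequence == "G" * 5 + "A" * 8 + "G" * 7

    def test_full_overlap_equals_short_reference(self):
        t = FoldTemplate(
            name="L", length=8, elements=(), contacts=frozenset(),
            ref_sequence="G" * 8, burial=("surface",) * 8,
        )
        s = FoldTemplate(
            name="G", length=8, elements=(), contacts=frozenset(),
            ref_sequence="AVAVAVAV", burial=("surface",) * 8,
        )
        emb = Embedding(offset=0, short_len=8, anchor=("x", "x"))
        assert merge_initial(emb, t, s).long_sequence == "AVAVAVAV"


class TestConflictClusters:
    def test_zero_conflicts_zero_clusters(self, planted_pair):
        long_t, short_t, truth = planted_pair
        from foldswitch import ConflictReport

        rep = ConflictReport(embedding=truth, conflicts=())
        assert find_conflict_clusters(rep, long_t) == []

    def test_contacting_conflicts_share_a_cluster(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        rep = score_conflicts(truth, long_t, short_t, d.long_sequence)
        assert rep.total_count > 0
        clusters = find_conflict_clusters(rep, long_t)
        covered = set().union(*clusters)
        assert {c.long_position for c in rep.conflicts} <= covered
        assert all(len(c) <= 6 for c in clusters)

    def test_large_components_split_under_size_bound(self):
        # 9 mutually contacting positions (star-ish graph), all conflicted
        from foldswitch import Conflict, ConflictReport

        positions = list(range(1, 10))
        contacts = {(i, j) for i in positions for j in positions if j - i >= 3}
        t = FoldTemplate(
            name="t", length=12, elements=(), contacts=frozenset(contacts),
            ref_sequence="A" * 12, burial=("surface",) * 12,
        )
        emb = Embedding(offset=0, short_len=12, anchor=("x", "x"))
        rep = ConflictReport(
            embedding=emb,
            conflicts=tuple(
                Conflict(long_position=p, kind="buried_polar", severity=1.0, detail="")
                for p in positions
            ),
        )
        clusters = find_conflict_clusters(rep, t)
        assert all(len(c) <= 6 for c in clusters)
        assert set(positions) <= set().union(*clusters)


def _micro_pair_for_resolution():
    """2-core-position toy where a single substitution fixes all conflicts."""
    burial = ["surface"] * 10
    burial[2] = burial[6] = "core"
    long_t = FoldTemplate(
        name="L", length=10, elements=(), contacts=frozenset({(3, 7)}),
        ref_sequence="LLLLLLLLLL", burial=tuple(burial),
    )
    short_t = FoldTemplate(
        name="G", length=10, elements=(), contacts=frozenset(),
        ref_sequence="LLKLLLLLLL", burial=("surface",) * 10,
    )
    emb = Embedding(offset=0, short_len=10, anchor=("x", "x"))
    return long_t, short_t, emb


class TestResolveCluster:
    ALPHABET6 = "AGLSKV"

    def test_conflict_free_cluster_is_left_unchanged(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        rep = score_conflicts(truth, long_t, short_t, d.long_sequence)
        conflicted = {c.long_position for c in rep.conflicts}
        clean = tuple(
            p for p in range(1, 4) if p not in conflicted
        )
        d2 = resolve_cluster(d, clean, long_t, short_t)
        assert d2.long_sequence == d.long_sequence
        assert d2.mutation_log == ()

    def test_single_substitution_preferred_over_double(self):
        long_t, short_t, emb = _micro_pair_for_resolution()
        d = merge_initial(emb, long_t, short_t)  # K at core position 3
        d2 = resolve_cluster(d, (3, 7), long_t, short_t,
                             candidate_alphabet=self.ALPHABET6)
        muts = [m for m in d2.mutation_log]
        assert len(muts) == 1 and muts[0].position == 3
        rep = score_conflicts(emb, long_t, short_t, d2.long_sequence)
        assert rep.total_count == 0

    @pytest.mark.parametrize("cluster_size", [1, 2, 3])
    def test_matches_exhaustive_assignment_oracle(self, planted_pair, cluster_size):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        rep = score_conflicts(truth, long_t, short_t, d.long_sequence)
        seed_pos = rep.conflicts[0].long_position
        cluster = tuple(range(seed_pos, seed_pos + cluster_size))
        model = EnergyModel.default()
        d2 = resolve_cluster(d, cluster, long_t, short_t, model,
                             candidate_alphabet=self.ALPHABET6)

        # independent oracle: full enumeration with full rescoring
        base = d.long_sequence
        w0, w1 = truth.window

        def full_eval(assign):
            seq = list(base)
            for p, aa in zip(cluster, assign):
                seq[p - 1] = aa
            seq = "".join(seq)
            r = score_conflicts(truth, long_t, short_t, seq)
            cset = set(cluster)
            n_conf = sum(
                1 for c in r.conflicts
                if c.long_position in cset
                or (c.kind == "overpacked_pair" and any(
                    f"({i}," in c.detail or f",{i})" in c.detail.replace(" ", "")
                    for i in cset))
            )
            n_mut = sum(1 for p, aa in zip(cluster, assign) if aa != base[p - 1])
            e = coarse_energy(seq, long_t, model) + coarse_energy(
                seq[w0 - 1 : w1], short_t, model
            )
            return (n_conf, n_mut, round(e, ENERGY_DECIMALS), assign)

        choices = []
        for p in cluster:
            cur = base[p - 1]
            choices.append([cur] + [a for a in self.ALPHABET6 if a != cur])
        best = min(full_eval(a) for a in itertools.product(*choices))
        expected_seq = list(base)
        for p, aa in zip(cluster, best[3]):
            expected_seq[p - 1] = aa
        assert d2.long_sequence == "".join(expected_seq)

    def test_oversized_cluster_is_a_domain_error(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        with pytest.raises(DomainError):
            resolve_cluster(d, tuple(range(1, 8)), long_t, short_t)

    def test_infeasible_cluster_warns_and_minimises(self, caplog):
        # core position whose every candidate is polar -> always conflicted
        burial = ["surface"] * 8
        burial[3] = "core"
        long_t = FoldTemplate(
            name="L", length=8, elements=(), contacts=frozenset(),
            ref_sequence="LLLKLLLL", burial=tuple(burial),
        )
        short_t = FoldTemplate(
            name="G", length=8, elements=(), contacts=frozenset(),
            ref_sequence="LLLKLLLL", burial=("surface",) * 8,
        )
        emb = Embedding(offset=0, short_len=8, anchor=("x", "x"))
        d = merge_initial(emb, long_t, short_t)
        import logging

        with caplog.at_level(logging.WARNING, logger="foldswitch.design"):
            d2 = resolve_cluster(d, (4,), long_t, short_t, candidate_alphabet="KRD")
        assert "infeasible" in caplog.text
        assert d2.long_sequence == d.long_sequence  # conservation among equals


class TestOptimizeNonoverlap:
    def test_full_overlap_leaves_sequence_unchanged(self):
        t = FoldTemplate(
            name="L", length=8, elements=(), contacts=frozenset(),
            ref_sequence="GGGGGGGG", burial=("core",) * 8,
        )
        emb = Embedding(offset=0, short_len=8, anchor=("x", "x"))
        d = merge_initial(emb, t, t)
        d2 = optimize_nonoverlap(d, t, t)
        assert d2.long_sequence == d.long_sequence

    def test_improves_core_glycine_outside_window(self):
        burial = ["surface"] * 10
        burial[8] = "core"
        long_t = FoldTemplate(
            name="L", length=10, elements=(), contacts=frozenset(),
            ref_sequence="LLLLLLLLGL", burial=tuple(burial),
        )
        short_t = FoldTemplate(
            name="G", length=5, elements=(), contacts=frozenset(),
            ref_sequence="LLLLL", burial=("surface",) * 5,
        )
        emb = Embedding(offset=0, short_len=5, anchor=("x", "x"))
        d = merge_initial(emb, long_t, short_t)
        e0 = coarse_energy(d.long_sequence, long_t)
        d2 = optimize_nonoverlap(d, long_t, short_t)
        assert coarse_energy(d2.long_sequence, long_t) < e0
        assert d2.long_sequence[8] != "G"
        # single-position enumeration oracle: the accepted residue is the
        # best single substitution at position 9
        cands = {
            aa: coarse_energy(d.long_sequence[:8] + aa + d.long_sequence[9:], long_t)
            for aa in "AGSTVLIFYDEKRNQ"
        }
        assert d2.long_sequence[8] == min(cands, key=lambda a: (cands[a], a))

    def test_idempotent_at_convergence(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        d1 = optimize_nonoverlap(d, long_t, short_t)
        d2 = optimize_nonoverlap(d1, long_t, short_t)
        assert d2.long_sequence == d1.long_sequence

    def test_never_edits_window_and_never_raises_energy(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        d2 = optimize_nonoverlap(d, long_t, short_t)
        w0, w1 = truth.window
        assert d2.long_sequence[w0 - 1 : w1] == d.long_sequence[w0 - 1 : w1]
        assert coarse_energy(d2.long_sequence, long_t) <= coarse_energy(d.long_sequence, long_t)
        assert all(not (w0 <= m.position <= w1) for m in d2.mutation_log)


class TestVariantsAndTruncation:
    def test_window_mutation_changes_both_constructs(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        w0, _ = truth.window
        frm = d.long_sequence[w0 - 1]
        to = "W" if frm != "W" else "F"
        d2, inside = apply_variant(d, [(w0, frm, to)])
        assert inside == (True,)
        assert d2.short_sequence != d.short_sequence
        assert d2.long_sequence[w0 - 1] == to

    def test_outside_mutation_leaves_short_construct_alone(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        _, w1 = truth.window
        pos = w1 + 1
        frm = d.long_sequence[pos - 1]
        d2, inside = apply_variant(d, [(pos, frm, "R")])
        assert inside == (False,)
        assert d2.short_sequence == d.short_sequence

    def test_empty_mutation_list_renames_only(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        d2, inside = apply_variant(d, [], name="renamed")
        assert d2.long_sequence == d.long_sequence
        assert d2.name == "renamed"
        assert inside == ()

    def test_stale_from_residue_is_a_domain_error(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        frm = d.long_sequence[0]
        wrong = "W" if frm != "W" else "F"
        with pytest.raises(DomainError, match="stale"):
            apply_variant(d, [(1, wrong, "A")])

    def test_truncation_returns_exactly_the_window(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        w0, w1 = truth.window
        assert truncate_to_short(d) == d.long_sequence[w0 - 1 : w1]
        assert len(truncate_to_short(d)) == short_t.length


class TestTailGraft:
    def test_replaces_terminal_residues(self):
        seq = "A" * 92 + "AAD"
        out = graft_cterminal_tail(seq, 3, "DKLYRAL")
        assert len(out) == 99
        assert out.endswith("DKLYRAL")
        assert out[:92] == "A" * 92

    def test_vte_to_inhibitor_tail(self):
        seq = "G" * 88 + "VTE"
        out = graft_cterminal_tail(seq, 3, "DKLYRAL")
        assert out.endswith("DKLYRAL") and len(out) == 95

    def test_zero_replacement_is_pure_append(self):
        assert graft_cterminal_tail("AAA", 0, "X") == "AAAX"

    def test_over_long_replacement_is_a_domain_error(self):
        with pytest.raises(DomainError):
            graft_cterminal_tail("AAA", 4, "X")

    def test_design_graft_respects_window_and_replays(self, planted_pair):
        long_t, short_t, truth = planted_pair
        d = merge_initial(truth, long_t, short_t)
        n_free = long_t.length - truth.window[1]
        d2 = graft_design_tail(d, min(3, n_free), "DKLYRAL")
        assert truncate_to_short(d2) == truncate_to_short(d)
        assert d2.replay() == d2.long_sequence
        with pytest.raises(DomainError):
            graft_design_tail(d, n_free + 1, "DKLYRAL")


class TestPercentIdentity:
    def test_one_substitution_in_56_rounds_to_98(self):
        a = "A" * 56
        b = "A" * 4 + "L" + "A" * 51
        ident = percent_identity(a, b)
        assert ident.percent == pytest.approx(98.214, abs=1e-3)
        assert ident.nearest == 98

    def test_identical_56mers_are_100(self):
        assert percent_identity("Q" * 56, "Q" * 56) == (100.0, 100)

    def test_disjoint_sequences_are_0(self):
        assert percent_identity("AAAA", "GGGG").percent == 0.0

    def test_length_mismatch_is_a_domain_error(self):
        with pytest.raises(DomainError):
            percent_identity("AA", "AAA")

    @settings(derandomize=True, max_examples=40)
    @given(st.text(alphabet="ACDEF", min_size=1, max_size=30),
           st.text(alphabet="ACDEF", min_size=1, max_size=30))
    def test_symmetry_and_relabel_invariance(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert percent_identity(a, b) == percent_identity(b, a)
        relabel = str.maketrans("ACDEF", "GHIKL")
        assert percent_identity(a.translate(relabel), b.translate(relabel)) == \
            percent_identity(a, b)


def test_mutation_log_replays_byte_for_byte(planted_pair):
    long_t, short_t, truth = planted_pair
    d = merge_initial(truth, long_t, short_t)
    rep = score_conflicts(truth, long_t, short_t, d.long_sequence)
    for cluster in find_conflict_clusters(rep, long_t):
        d = resolve_cluster(d, cluster, long_t, short_t)
    d = optimize_nonoverlap(d, long_t, short_t)
    n_free = long_t.length - truth.window[1]
    if n_free >= 2:
        d = graft_design_tail(d, 2, "DKLYRAL")
    assert d.replay() == d.long_sequence
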