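"""Alignment, distances, divergence tiers, flags, NJ and bootstrap."""

import itertools
import warnings

import numpy as np
import pytest
from Bio import Align

from monotax.seqdist import (
    DistanceMatrix,
    DivergenceSummary,
    SeqRecord,
    bootstrap_support,
    conspecificity_flags,
    count_differences,
    distance_matrix,
    global_align,
    group_divergence,
    nj_tree,
    trim_alignment,
)


# ---------------------------------------------------------------------------
# global alignment


def _enumerate_alignments(a: str, b: str, match, mismatch, gap):
    """Brute-force optimum over all global alignments of two short strings."""
    best = [float("-inf")]

    def rec(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            rec(i + 1, j, score + gap)
        if j < len(b):
            rec(i, j + 1, score + gap)

    rec(0, 0, 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.aligned1 == aln.aligned2 == "ACGT"
        assert aln.score == 4 * 1.0

    def test_single_mismatch_column(self):
        aln = global_align("A", "G", match=1, mismatch=-1, gap=-2)
        assert (aln.aligned1, aln.aligned2) == ("A", "G")
        assert aln.score == -1

    def test_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        bases = "ACGT"
        for _ in range(25):
            a = "".join(rng.choice(list(bases), size=rng.integers(1, 6)))
            b = "".join(rng.choice(list(bases), size=rng.integers(1, 6)))
            aln = global_align(a, b, match=1, mismatch=-1, gap=-2)
            assert aln.score == _enumerate_alignments(a, b, 1, -1, -2), (a, b)
            # degapping recovers the inputs
            assert aln.aligned1.replace("-", "") == a
            assert aln.aligned2.replace("-", "") == b

    def test_score_matches_biopython_aligner(self):
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1, gap_score=-2
        )
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 30)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 30)))
            assert global_align(a, b, 1, -1, -2).score == aligner.score(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


# ---------------------------------------------------------------------------
# trimming


class TestTrimAlignment:
    def test_full_length_unchanged(self):
        aln = [SeqRecord("a", "ACGTACGT"), SeqRecord("b", "ACGAACGT")]
        assert [r.residues for r in trim_alignment(aln)] == ["ACGTACGT", "ACGAACGT"]

    def test_leading_gap_columns_dropped_for_all(self):
        aln = [
            SeqRecord("a", "-" * 10 + "ACGTACGTAC"),
            SeqRecord("b", "ACGTACGTACGTACGTACGT"),
        ]
        trimmed = trim_alignment(aln)
        assert all(len(r) == 10 for r in trimmed)
        assert trimmed[0].residues == "ACGTACGTAC"
        assert trimmed[1].residues == "ACGTACGTACGTACGTACGT"[10:]

    def test_mixed_overhangs_keep_common_span(self):
        # 4×20 with mixed 5'/3' overhangs; common span is columns 5..14
        aln = [
            SeqRecord("a", "-----ACGTACGTACGTACG"),
            SeqRecord("b", "ACGTACGTACGTACG-----"),
            SeqRecord("c", "--GTACGTACGTACGTAC--"),
            SeqRecord("d", "NNGTACGTACGTACGTACNN"),
        ]
        trimmed = trim_alignment(aln)
        assert all(len(r) == 10 for r in trimmed)
        assert trimmed[1].residues == "ACGTACGTACGTACG-----"[5:15]
        # interior columns untouched: a gap inside stays
        gappy = [SeqRecord("a", "AC-TAC"), SeqRecord("b", "ACGTAC")]
        assert trim_alignment(gappy)[0].residues == "AC-TAC"

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            trim_alignment([SeqRecord("a", "ACGT"), SeqRecord("b", "ACG")])


# ---------------------------------------------------------------------------
# distances


class TestCountDifferences:
    def test_hand_counts(self):
        assert count_differences("ACGT", "ACGA") == (1, 4)
        assert count_differences("AC-GT", "ACAGT") == (0, 4)

    def test_self_distance_zero(self):
        s = "ACGTNNRAC-GT"
        d, n = count_differences(s, s)
        assert d == 0 and n == len("ACGTACGT")  # N/R and gaps excluded

    def test_ambiguity_excluded_by_default_intersection_behind_flag(self):
        assert count_differences("ACRGT", "ACAGT") == (0, 4)
        assert count_differences("ACRGT", "ACAGT", iupac=True) == (0, 5)
        assert count_differences("ACRGT", "ACTGT", iupac=True) == (1, 5)

    def test_complete_deletion_uses_whole_alignment(self):
        ctx = [
            SeqRecord("x", "AC-GTACG"),
            SeqRecord("y", "ACAGTACG"),
            SeqRecord("z", "ACAGTACN"),
        ]
        assert count_differences(ctx[1], ctx[2], deletion="complete", context=ctx) == (0, 6)

    def test_pairwise_never_compares_fewer_sites_than_complete(self):
        rng = np.random.default_rng(5)
        chars = list("ACGT-N")
        seqs = [
            SeqRecord(f"s{i}", "".join(rng.choice(chars, size=60))) for i in range(5)
        ]
        dm_p = distance_matrix(seqs, deletion="pairwise")
        dm_c = distance_matrix(seqs, deletion="complete")
        assert (dm_p.compared_sites >= dm_c.compared_sites).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_differences("ACGT", "ACG")


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        dm = distance_matrix([SeqRecord("a", "ACGTAC"), SeqRecord("b", "ACGTAC")])
        assert dm.nt_diffs.sum() == 0
        assert (dm.p_dist == 0).all()

    def test_three_sequence_hand_tally(self):
        # 12-nt fixture with hand-countable differences
        seqs = [
            SeqRecord("a", "ACGTACGTACGT"),
            SeqRecord("b", "ACGTACGAACGT"),  # 1 diff vs a (pos 8)
            SeqRecord("c", "ATGTACGAACTT"),  # vs a: pos 2, 8, 11 → 3; vs b: pos 2, 11 → 2
        ]
        dm = distance_matrix(seqs)
        assert dm.pair("a", "b") == (1, 12, pytest.approx(1 / 12))
        assert dm.pair("a", "c") == (3, 12, pytest.approx(3 / 12))
        assert dm.pair("b", "c") == (2, 12, pytest.approx(2 / 12))
        assert (dm.nt_diffs == dm.nt_diffs.T).all()
        assert (np.diag(dm.p_dist) == 0).all()

    def test_p_dist_zero_iff_identical_over_compared_sites(self):
        dm = distance_matrix([SeqRecord("a", "ACGT-C"), SeqRecord("b", "ACGTNC")])
        assert dm.pair("a", "b") == (0, 5, 0.0)


# ---------------------------------------------------------------------------
# divergence tiers and flags


def _engineered_family():
    """2 species × 2 isolates over 100 sites: every intraspecific pair has
    exactly 1 difference, every interspecific pair exactly 10."""
    base = list("ACGT" * 25)
    s1a = base.copy()
    s1b = base.copy()
    s2a = base.copy()
    s2b = base.copy()
    # interspecific block: sites 10–19 differ between the species
    for k in range(10, 20):
        s2a[k] = s2b[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[base[k]]
    # intraspecific variants placed inside the interspecific block with a
    # third base, so interspecific counts stay at 10
    s1b[10] = sorted({"A", "C", "G", "T"} - {base[10], s2a[10]})[0]
    s2b[11] = sorted({"A", "C", "G", "T"} - {base[11], s2a[11]})[0]
    recs = [
        SeqRecord("s1a", "".join(s1a)), SeqRecord("s1b", "".join(s1b)),
        SeqRecord("s2a", "".join(s2a)), SeqRecord("s2b", "".join(s2b)),
    ]
    labels = {
        "s1a": ("sp1", "G"), "s1b": ("sp1", "G"),
        "s2a": ("sp2", "G"), "s2b": ("sp2", "G"),
    }
    return recs, labels


class TestGroupDivergence:
    def test_identical_conspecific_pair(self):
        recs = [SeqRecord("a", "ACGT" * 10), SeqRecord("b", "ACGT" * 10)]
        [s] = group_divergence(distance_matrix(recs), {"a": ("sp", "G"), "b": ("sp", "G")})
        assert (s.tier, s.nt_min, s.nt_max, s.pct_min, s.pct_max) == (
            "intraspecific", 0, 0, 0.0, 0.0,
        )

    def test_engineered_two_species_family(self):
        recs, labels = _engineered_family()
        summaries = group_divergence(distance_matrix(recs), labels)
        for s in summaries:
            if s.tier == "intraspecific":
                assert (s.nt_min, s.nt_max) == (1, 1), s
                assert s.pct_max == pytest.approx(1.0)
            else:
                assert (s.tier, s.nt_min, s.nt_max) == ("interspecific", 10, 10)
                assert s.pct_min == pytest.approx(10.0)

    def test_exclusion_list_recomputes_ranges(self):
        recs, labels = _engineered_family()
        outlier = SeqRecord("s1c", "T" * 100)
        labels = {**labels, "s1c": ("sp1", "G")}
        dm = distance_matrix(recs + [outlier])
        with_outlier = {(s.tier, s.label): s for s in group_divergence(dm, labels)}
        without = {(s.tier, s.label): s for s in group_divergence(dm, labels, exclude=["s1c"])}
        assert with_outlier[("intraspecific", "sp1")].nt_max > 1
        assert without[("intraspecific", "sp1")].nt_max == 1

    def test_unlabelled_id_rejected(self):
        recs, labels = _engineered_family()
        labels.pop("s2b")
        with pytest.raises(ValueError, match="s2b"):
            group_divergence(distance_matrix(recs), labels)


class TestConspecificityFlags:
    def mk(self, lo_pct, hi_pct, tier="interspecific", label="A vs B"):
        return DivergenceSummary(tier, label, 1, int(lo_pct * 7), int(hi_pct * 7), lo_pct, hi_pct)

    def test_low_divergence_pair_flagged(self):
        flags = conspecificity_flags([self.mk(0.9, 1.2)], 5.1, 11.8)
        assert [f.kind for f in flags] == ["conspecificity_candidate"]

    def test_ordinary_pair_not_flagged(self):
        assert conspecificity_flags([self.mk(8.0, 8.0)], 5.1, 11.8) == []

    def test_excess_divergence_flags_misplacement(self):
        flags = conspecificity_flags([self.mk(20.6, 20.8)], 5.1, 11.8)
        assert [f.kind for f in flags] == ["generic_misplacement_candidate"]

    def test_reference_required(self):
        with pytest.raises(ValueError):
            conspecificity_flags([self.mk(1.0, 1.0)], None)


# ---------------------------------------------------------------------------
# neighbour joining


def _matrix(ids, d):
    d = np.asarray(d, dtype=float)
    n = len(ids)
    return DistanceMatrix(
        ids=tuple(ids),
        nt_diffs=(d * 1000).astype(int),
        compared_sites=np.full((n, n), 1000, dtype=int),
        p_dist=d,
    )


def _ls_best_quartet_topology(d):
    """Least-squares fit of all 3 unrooted 4-leaf topologies; returns the
    winning split as a frozenset of two leaf indices."""
    pairs = list(itertools.combinations(range(4), 2))
    best = None
    for split in ({0, 1}, {0, 2}, {0, 3}):
        other = set(range(4)) - split
        # params: 4 leaf edges + 1 internal edge
        rows, y = [], []
        for i, j in pairs:
            row = [0.0] * 5
            row[i] = row[j] = 1.0
            if (i in split) != (j in split):
                row[4] = 1.0
            rows.append(row)
            y.append(d[i, j])
        coef, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        rss = float(np.sum((np.array(rows) @ coef - np.array(y)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, frozenset(split))
    return best[1]


def _random_additive(rng, n):
    """Random binary tree with positive branch lengths; returns (ids, D, splits)."""
    ids = [f"L{i}" for i in range(n)]
    clusters = [({i}, {i: 0.0}) for i in range(n)]  # (leaf set, leaf → dist to root)
    d = np.zeros((n, n))
    true_splits = set()
    while len(clusters) > 1:
        a = int(rng.integers(len(clusters)))
        b = int(rng.integers(len(clusters) - 1))
        b = b if b < a else b + 1
        (sa, da), (sb, db) = clusters[a], clusters[b]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        for x, dx in da.items():
            for y, dy in db.items():
                d[x, y] = d[y, x] = dx + la + dy + lb
        merged = sa | sb
        if 2 <= len(merged) <= n - 2:
            true_splits.add(frozenset(ids[i] for i in merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(
            (merged, {**{x: v + la for x, v in da.items()}, **{y: v + lb for y, v in db.items()}})
        )
    canon = {
        min(s, frozenset(ids) - s, key=lambda t: (len(t), sorted(t)))
        for s in true_splits
    }
    return ids, d, canon


class TestNJTree:
    def test_three_taxa_closed_form(self):
        dm = _matrix("ABC", [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(dm)
        lengths = {ch.name: ch.length for ch in tree.root.children}
        assert lengths["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_additive_matches_least_squares_oracle(self):
        d = np.array([[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 5], [8, 7, 5, 0]]) / 10
        dm = _matrix("ABCD", d)
        tree = nj_tree(dm)
        [split] = tree.splits()
        want = _ls_best_quartet_topology(d)
        assert split == frozenset("ABCD"[i] for i in want)

    def test_tie_break_is_deterministic(self):
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]]) / 10
        dm = _matrix("ABCD", d)
        first = nj_tree(dm).to_newick()
        for _ in range(5):
            assert nj_tree(dm).to_newick() == first

    def test_recovers_random_additive_topologies(self):
        """NJ recovers the generating topology on additive data (≤8 leaves)."""
        rng = np.random.default_rng(2024)
        for trial in range(50):
            n = int(rng.integers(4, 9))
            ids, d, true_splits = _random_additive(rng, n)
            tree = nj_tree(_matrix(ids, d))
            assert tree.splits() == frozenset(true_splits), trial

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        ids, d, _ = _random_additive(rng, 7)
        ours = nj_tree(_matrix(ids, d)).splits()
        sk_tree = skbio_nj(SkbioDM(d, ids))
        leaves = frozenset(ids)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(leaves) - 2:
                theirs.add(min(below, leaves - below, key=lambda s: (len(s), sorted(s))))
        assert ours == frozenset(theirs)

    def test_fewer_than_three_rejected(self):
        dm = distance_matrix([SeqRecord("a", "ACGT"), SeqRecord("b", "ACGA")])
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_negative_branch_clamped_with_warning(self):
        d = np.array([[0, 0.1, 0.4, 0.4], [0.1, 0, 0.1, 0.4],
                      [0.4, 0.1, 0, 0.1], [0.4, 0.4, 0.1, 0]])
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(_matrix("ABCD", d))
        def all_lengths(node):
            yield node.length
            for ch in node.children:
                yield from all_lengths(ch)
        assert all(l >= 0 for l in all_lengths(tree.root))


class TestBootstrap:
    def _clade_family(self):
        # two clades 30 differences apart, 1 difference within each
        base = list("ACGT" * 50)
        other = base.copy()
        for k in range(30):
            other[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[base[k]]
        a1 = "".join(base)
        a2 = "".join(base[:-1] + ["A" if base[-1] != "A" else "C"])
        b1 = "".join(other)
        b2 = "".join(other[:-2] + ["A" if other[-2] != "A" else "C"] + other[-1:])
        return [SeqRecord("a1", a1), SeqRecord("a2", a2),
                SeqRecord("b1", b1), SeqRecord("b2", b2)]

    def test_strong_clade_gets_high_support(self):
        tree = bootstrap_support(self._clade_family(), n_reps=100, seed=1)
        supports = {frozenset(s): None for s in tree.splits()}
        def find_supports(node):
            out = []
            if node.support is not None:
                out.append(node.support)
            for ch in node.children:
                out.extend(find_supports(ch))
            return out
        values = find_supports(tree.root)
        assert values and max(values) >= 90

    def test_seeded_reproducibility(self):
        t1 = bootstrap_support(self._clade_family(), n_reps=50, seed=7)
        t2 = bootstrap_support(self._clade_family(), n_reps=50, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(self._clade_family(), n_reps=1, seed=3)
        def supports(node):
            if node.support is not None:
                yield node.support
            for ch in node.children:
                yield from supports(ch)
        assert set(supports(tree.root)) <= {0.0, 100.0}

    def test_identical_sequences_handled_gracefully(self):
        seqs = [SeqRecord(f"s{i}", "ACGT" * 25) for i in range(4)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = bootstrap_support(seqs, n_reps=10, seed=0)
        assert tree.leaf_names == {"s0", "s1", "s2", "s3"}
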