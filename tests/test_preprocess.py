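"""Translation, profile alignment, trimming, length filter, concatenation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloplace.likelihood import log_likelihood
from phyloplace.models import load_empirical_model, uniform_model
from phyloplace.msa import MSA
from phyloplace.preprocess import (
    PreprocessError,
    TrimParams,
    align_to_profile,
    align_to_reference,
    apply_trim_to_query,
    build_profile,
    concatenate_markers,
    detection_threshold,
    length_filter,
    select_frame,
    translate_frame,
    translate_six_frames,
    trim_columns,
)
from phyloplace.simulate import (
    back_translate,
    evolve_alignment,
    random_tree,
)
from phyloplace.tree import parse_newick

_NT = st.text(alphabet="ACGT", min_size=3, max_size=60)


class TestTranslation:
    def test_forward_frame(self):
        assert translate_frame("ATGGCC", 1) == "MA"

    def test_reverse_frame(self):
        assert translate_frame("GGCCAT", -1) == "MA"

    def test_ambiguity_becomes_x(self):
        assert translate_frame("ATGNCC", 1) == "MX"

    def test_internal_stop_kept(self):
        assert translate_frame("ATGTAAGCC", 1) == "M*A"

    def test_trailing_nucleotides_dropped(self):
        assert translate_frame("ATGGC", 1) == "M"
        assert translate_frame("ATGG", 1) == "M"

    def test_empty_sequence_rejected(self):
        with pytest.raises(PreprocessError):
            translate_six_frames("")

    @settings(derandomize=True, max_examples=40)
    @given(_NT)
    def test_reverse_complement_symmetry(self, nt):
        """frame -k of s equals frame +k of revcomp(s)."""
        from Bio.Seq import Seq

        rc = str(Seq(nt).reverse_complement())
        frames = translate_six_frames(nt)
        for k in (1, 2, 3):
            assert frames[-k] == translate_frame(rc, k)


class TestProfile:
    def test_columns_sum_to_one(self, sim_pkg):
        profile, _ = build_profile(sim_pkg.msa)
        np.testing.assert_allclose(profile.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_column_dominated_by_observed_residue(self):
        msa = MSA({f"s{i}": "AAAA" for i in range(10)})
        profile, _ = build_profile(msa)
        assert profile[0, 0] > 0.8

    def test_profile_tracks_generating_frequencies(self, wag):
        tree = parse_newick("((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05);")
        msa = evolve_alignment(tree, wag, 5000, seed=31)
        profile, _ = build_profile(msa)
        mean_freq = profile.mean(axis=0)
        rho = np.corrcoef(mean_freq, wag.pi)[0, 1]
        assert rho > 0.9


class TestFrameSelection:
    @pytest.mark.parametrize("trial", range(20))
    def test_embedded_frame_recovered(self, trial, sim_pkg):
        """Fragments cut from a real marker recover their frame."""
        rng = np.random.default_rng(trial)
        profile, bg = build_profile(sim_pkg.msa)
        leaf = sim_pkg.tree.leaf_labels[trial % sim_pkg.tree.n_leaves]
        pep = sim_pkg.msa[leaf].replace("-", "")[:100]
        cds = back_translate(pep, rng)
        offset = int(rng.integers(0, 3))
        nt = "".join("ACGT"[i] for i in rng.integers(0, 4, size=offset)) + cds
        frames = translate_six_frames(nt)
        best, score = select_frame(frames, profile, bg)
        assert best == offset + 1

    def test_reversed_fragment_selects_negative_frame(self, sim_pkg):
        from Bio.Seq import Seq

        rng = np.random.default_rng(7)
        profile, bg = build_profile(sim_pkg.msa)
        pep = sim_pkg.msa[sim_pkg.tree.leaf_labels[0]].replace("-", "")[:80]
        nt = back_translate(pep, rng)
        fwd, _ = select_frame(translate_six_frames(nt), profile, bg)
        rev, _ = select_frame(
            translate_six_frames(str(Seq(nt).reverse_complement())), profile, bg
        )
        assert fwd == 1 and rev == -1

    def test_random_sequence_scores_below_threshold(self, sim_pkg):
        rng = np.random.default_rng(13)
        profile, bg = build_profile(sim_pkg.msa)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        frames = translate_six_frames(junk)
        frame, score = select_frame(frames, profile, bg)
        thresh = detection_threshold(frames[frame], profile, bg, n_shuffles=50, seed=13)
        assert score <= thresh
        # while a genuine marker fragment clears it
        pep = sim_pkg.msa[sim_pkg.tree.leaf_labels[1]].replace("-", "")[:100]
        real = back_translate(pep, rng)
        rframes = translate_six_frames(real)
        rframe, rscore = select_frame(rframes, profile, bg)
        rthresh = detection_threshold(rframes[rframe], profile, bg, n_shuffles=50, seed=13)
        assert rscore > rthresh


def _oracle_dp(pep, profile, bg):
    """Exhaustive recursion over all (i, j, state) paths on tiny inputs."""
    from functools import lru_cache

    from phyloplace.preprocess import GAP_EXTEND, GAP_OPEN
    from phyloplace.alphabet import AA_INDEX

    logodds = np.log(profile / bg[None, :])
    n, m = len(pep), profile.shape[0]

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # best score of an alignment ENDING at (i residues, j columns, state)
        if state == "M":
            if i == 0 or j == 0:
                return -1e30
            e = logodds[j - 1, AA_INDEX[pep[i - 1]]]
            prev = max(best(i - 1, j - 1, s) for s in "MXY")
            return e + max(prev, 0.0)
        if state == "X":  # residue i unaligned (insertion)
            if i == 0:
                return -1e30
            return max(best(i - 1, j, "M") - GAP_OPEN, best(i - 1, j, "X") - GAP_EXTEND)
        if j == 0:
            return -1e30
        return max(best(i, j - 1, "M") - GAP_OPEN, best(i, j - 1, "Y") - GAP_EXTEND)

    sc = max(
        (best(i, j, "M") for i in range(1, n + 1) for j in range(1, m + 1)),
        default=0.0,
    )
    return max(sc, 0.0)


class TestAlignment:
    def test_self_alignment_recovers_columns(self, sim_pkg):
        profile, bg = build_profile(sim_pkg.msa)
        row = sim_pkg.msa[sim_pkg.tree.leaf_labels[0]]
        aligned = align_to_reference(row.replace("-", ""), profile, bg)
        assert aligned == row

    def test_partial_peptide_fills_matching_window(self, sim_pkg):
        profile, bg = build_profile(sim_pkg.msa)
        row = sim_pkg.msa[sim_pkg.tree.leaf_labels[3]]
        window = row[70:120].replace("-", "")
        aligned = align_to_reference(window, profile, bg)
        assert aligned[70:120] == row[70:120]
        assert set(aligned[:70]) | set(aligned[120:]) <= {"-"}

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_exhaustive_oracle_on_toys(self, seed):
        rng = np.random.default_rng(seed)
        from phyloplace.alphabet import AMINO_ACIDS

        n_cols = int(rng.integers(2, 10))
        profile = rng.dirichlet(np.ones(20) * 0.5, size=n_cols)
        bg = np.full(20, 0.05)
        pep = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 8))))
        assert align_to_profile(pep, profile, bg) == pytest.approx(
            _oracle_dp(pep, profile, bg), abs=1e-9
        )


class TestTrim:
    def test_identical_gap_free_rows_all_kept(self):
        msa = MSA({f"s{i}": "ACDEFGHIKL" for i in range(6)})
        assert trim_columns(msa).all()

    def test_majority_gap_column_removed(self):
        rows = {f"s{i}": "AAAA" for i in range(5)}
        for i in (0, 1, 2):  # 60% gaps in column 1
            rows[f"s{i}"] = "A-AA"
        msa = MSA(rows)
        mask = trim_columns(msa)
        assert not mask[1]

    def test_hand_traced_twelve_column_toy(self):
        """Fixture traced by hand with b1=3, b2=4, b3=3, b4=2.

        Columns: gappy flank | conserved | 2 highly conserved | a
        4-column nonconserved island | highly, conserved, highly |
        gappy flank.  The island exceeds b3 and is rejected; flanks
        trim back to highly conserved positions; survivors are columns
        {2, 3, 8, 9, 10}.
        """
        rows = {
            "s1": "AAADACWAKKRR",
            "s2": "-AADCDYEKKR-",
            "s3": "-AADDECGKKR-",
            "s4": "-CADEGDCKRR-",
        }
        msa = MSA(rows)
        params = TrimParams(n_rows=4, b2=4, b3=3, b4=2)
        mask = trim_columns(msa, params)
        expected = np.zeros(12, dtype=bool)
        expected[[2, 3, 8, 9, 10]] = True
        np.testing.assert_array_equal(mask, expected)

    def test_trimming_is_idempotent(self):
        rng = np.random.default_rng(17)
        from phyloplace.alphabet import AMINO_ACIDS

        for _ in range(10):
            rows = {}
            for i in range(6):
                chars = rng.choice(list(AMINO_ACIDS[:5]) + ["-"], size=40)
                rows[f"s{i}"] = "".join(chars)
            msa = MSA(rows)
            params = TrimParams(n_rows=6, b3=2, b4=2)
            mask1 = trim_columns(msa, params)
            if not mask1.any():
                continue
            trimmed = msa.select_columns(mask1)
            mask2 = trim_columns(trimmed, TrimParams(n_rows=6, b3=2, b4=2))
            assert mask2.all()

    def test_invalid_params_rejected(self):
        with pytest.raises(PreprocessError):
            TrimParams(n_rows=10, b4=0)
        with pytest.raises(PreprocessError):
            TrimParams(n_rows=10, b2=2)


class TestLengthFilter:
    def test_forty_nine_residues_dropped(self):
        assert not length_filter("A" * 49 + "-" * 10)

    def test_fifty_residues_kept(self):
        assert length_filter("A" * 50 + "-" * 10)

    def test_empty_row_dropped(self):
        assert not length_filter("-" * 60)


class TestConcatenation:
    def _refs(self, wag):
        t1 = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        m1 = evolve_alignment(t1, wag, 100, seed=41)
        m2 = evolve_alignment(t1, wag, 120, seed=42)
        return t1, m1, m2

    def test_lengths_add(self, wag):
        _, m1, m2 = self._refs(wag)
        row, cat = concatenate_markers(
            {"g1": "A" * 100, "g2": "C" * 120},
            {"g1": m1, "g2": m2},
            ["g1", "g2"],
        )
        assert len(row) == 220 and cat.n_cols == 220

    def test_single_marker_is_identity(self, wag):
        _, m1, _ = self._refs(wag)
        row, cat = concatenate_markers({"g1": "A" * 100}, {"g1": m1}, ["g1"])
        assert row == "A" * 100
        assert cat.rows == m1.rows

    def test_missing_marker_gap_filled(self, wag):
        _, m1, m2 = self._refs(wag)
        row, _ = concatenate_markers(
            {"g1": "A" * 100, "g2": None}, {"g1": m1, "g2": m2}, ["g1", "g2"]
        )
        assert row[100:] == "-" * 120

    def test_mismatched_taxa_rejected(self, wag):
        _, m1, m2 = self._refs(wag)
        m2 = m2.drop(["D"])
        with pytest.raises(PreprocessError):
            concatenate_markers({"g1": None, "g2": None}, {"g1": m1, "g2": m2})

    def test_concatenated_loglik_is_sum_of_markers(self, wag):
        """With shared fixed branch lengths, site independence makes the
        concatenated log-likelihood the sum of per-marker ones."""
        t1, m1, m2 = self._refs(wag)
        _, cat = concatenate_markers({"g1": None, "g2": None}, {"g1": m1, "g2": m2})
        total = log_likelihood(t1, cat, wag)
        assert total == pytest.approx(
            log_likelihood(t1, m1, wag) + log_likelihood(t1, m2, wag), abs=1e-8
        )


class TestQueryMasking:
    def test_mask_blanks_removed_columns_only(self):
        mask = np.array([True, False, True, True])
        assert apply_trim_to_query("ACDE", mask) == "A-DE"
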