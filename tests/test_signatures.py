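import numpy as np
import pandas as pd
import pytest

from allclones.signatures import (
    CONTEXTS_96,
    PYRIMIDINE_TRINUCS_32,
    ContextMatrix,
    MotifFrequencies,
    context_label,
    extract_contexts,
    kmer_frequencies,
    load_reference_catalogue,
    match_signatures,
    motif_of_context,
    nmf_decompose,
    normalize_motifs,
    revcomp,
    synthetic_reference_catalogue,
)


def cosine(a, b):
    return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))


class TestContexts:
    def test_canonical_ordering_is_the_96_set(self):
        assert len(CONTEXTS_96) == len(set(CONTEXTS_96)) == 96
        assert CONTEXTS_96[0] == "A[C>A]A" and CONTEXTS_96[-1] == "T[T>G]T"

    def test_pyrimidine_reference_context(self):
        assert context_label("ACG", "C", "T") == "A[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        # G>A at CGT collapses to A[C>T]G on the opposite strand
        assert context_label("CGT", "G", "A") == "A[C>T]G"

    def test_mismatched_center_rejected(self):
        with pytest.raises(ValueError, match="center"):
            context_label("ACG", "T", "A")

    def test_extract_counts_and_recurrent_exclusion(self):
        fetch = {("1", 100): "ACG", ("1", 200): "CGT", ("1", 300): "TCA"}.__getitem__
        fetcher = lambda c, p: fetch((c, p))
        snvs = pd.DataFrame(
            [
                {"patient_id": "P1", "chrom": "1", "pos": 100, "ref": "C", "alt": "T"},
                {"patient_id": "P1", "chrom": "1", "pos": 200, "ref": "G", "alt": "A"},
                # identical SNV in two patients -> excluded entirely
                {"patient_id": "P1", "chrom": "1", "pos": 300, "ref": "C", "alt": "G"},
                {"patient_id": "P2", "chrom": "1", "pos": 300, "ref": "C", "alt": "G"},
            ]
        )
        groups = {"P1": "A", "P2": "A"}
        matrix = extract_contexts(snvs, fetcher, groups)
        assert matrix.total() == 2
        assert matrix.counts.loc["A", "A[C>T]G"] == 2

    def test_reference_mismatch_is_an_error(self):
        snvs = pd.DataFrame(
            [{"patient_id": "P1", "chrom": "1", "pos": 5, "ref": "C", "alt": "T"}]
        )
        with pytest.raises(ValueError, match="reference mismatch"):
            extract_contexts(snvs, lambda c, p: "ATA", {"P1": "A"})


class TestNormalizeMotifs:
    def _matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        return ContextMatrix(
            pd.DataFrame(
                rng.poisson(10, (3, 96)).astype(float),
                index=["a", "b", "c"], columns=CONTEXTS_96,
            )
        )

    def _freqs(self, label, seed):
        rng = np.random.default_rng(seed)
        return MotifFrequencies(
            label, pd.Series(rng.uniform(0.5, 2, 32), index=PYRIMIDINE_TRINUCS_32)
        )

    def test_identical_frequencies_are_identity(self):
        m = self._matrix()
        f = self._freqs("x", 1)
        out = normalize_motifs(m, f, f)
        np.testing.assert_allclose(out.counts, m.counts)

    def test_doubled_panel_motif_halves_its_contexts(self):
        m = self._matrix()
        genome = MotifFrequencies(
            "g", pd.Series(1.0, index=PYRIMIDINE_TRINUCS_32)
        )
        panel_freqs = pd.Series(1.0, index=PYRIMIDINE_TRINUCS_32)
        panel_freqs["ACG"] = 2.0
        panel = MotifFrequencies("p", panel_freqs)
        out = normalize_motifs(m, panel, genome)
        for ctx in CONTEXTS_96:
            ratio = out.counts.loc["a", ctx] / m.counts.loc["a", ctx]
            # frequencies are renormalized, so ratios match up to a constant
            if motif_of_context(ctx) == "ACG":
                assert ratio == pytest.approx(0.5 * (33 / 32), rel=1e-9)
            else:
                assert ratio == pytest.approx(1.0 * (33 / 32), rel=1e-9)

    def test_swapping_arguments_inverts_exactly(self):
        m = self._matrix()
        t, g = self._freqs("t", 2), self._freqs("g", 3)
        back = normalize_motifs(normalize_motifs(m, t, g), g, t)
        np.testing.assert_allclose(back.counts, m.counts, atol=1e-10)

    def test_totals_not_conserved_in_general(self):
        m = self._matrix()
        t, g = self._freqs("t", 2), self._freqs("g", 3)
        assert normalize_motifs(m, t, g).total() != pytest.approx(m.total())


class TestKmerFrequencies:
    def test_hand_enumerated_acgt(self, tmp_path):
        fa = tmp_path / "toy.fa"
        fa.write_text(">s\nACGT\n")
        out = kmer_frequencies(fa)
        # ACG + CGT; CGT is purine-centered and collapses to ACG
        assert out.freqs["ACG"] == pytest.approx(1.0)

    def test_all_ambiguous_sequence_rejected(self, tmp_path):
        fa = tmp_path / "n.fa"
        fa.write_text(">s\nNNNNNNNN\n")
        with pytest.raises(ValueError, match="no unambiguous"):
            kmer_frequencies(fa)

    def test_bed_covering_everything_matches_whole_sequence(self, tmp_path):
        fa = tmp_path / "toy.fa"
        fa.write_text(">s\nACGTTGCAACGGT\n")
        whole = kmer_frequencies(fa)
        bed = pd.DataFrame([{"chrom": "s", "start": 0, "end": 13}])
        sub = kmer_frequencies(fa, regions=bed)
        pd.testing.assert_series_equal(whole.freqs, sub.freqs)

    def test_empty_region_set_rejected(self, tmp_path):
        fa = tmp_path / "toy.fa"
        fa.write_text(">s\nACGT\n")
        with pytest.raises(ValueError, match="empty region"):
            kmer_frequencies(fa, regions=pd.DataFrame(columns=["chrom", "start", "end"]))


class TestNMF:
    def test_rank_one_matrix_reconstructed_exactly(self):
        base = synthetic_reference_catalogue().loc["Flat"].to_numpy()
        X = np.outer([1.0, 2.0, 3.0], base)
        cm = ContextMatrix(pd.DataFrame(X, index=list("abc"), columns=CONTEXTS_96))
        ss = nmf_decompose(cm, k=1, seed=0, n_restarts=5)
        assert ss.reconstruction_error < 1e-6
        assert np.allclose(ss.signatures.sum(axis=1), 1.0)

    def test_more_iterations_never_increase_error(self):
        rng = np.random.default_rng(3)
        cm = ContextMatrix(
            pd.DataFrame(rng.poisson(20, (5, 96)).astype(float),
                         index=list("abcde"), columns=CONTEXTS_96)
        )
        short = nmf_decompose(cm, k=2, seed=1, n_restarts=1, max_iter=20)
        long = nmf_decompose(cm, k=2, seed=1, n_restarts=1, max_iter=2000)
        assert long.reconstruction_error <= short.reconstruction_error + 1e-9

    def test_invalid_inputs_rejected(self):
        cm = ContextMatrix(
            pd.DataFrame(np.zeros((2, 96)), index=["a", "b"], columns=CONTEXTS_96)
        )
        with pytest.raises(ValueError, match="k"):
            nmf_decompose(cm, k=0)
        with pytest.raises(ValueError, match="zero"):
            nmf_decompose(cm, k=1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        cm = ContextMatrix(
            pd.DataFrame(rng.poisson(30, (4, 96)).astype(float),
                         index=list("abcd"), columns=CONTEXTS_96)
        )
        a = nmf_decompose(cm, k=2, seed=7, n_restarts=3)
        b = nmf_decompose(cm, k=2, seed=7, n_restarts=3)
        pd.testing.assert_frame_equal(a.signatures, b.signatures)


class TestMatching:
    def test_identical_signature_matches_with_cosine_one(self):
        cat = synthetic_reference_catalogue()
        found = cat.loc[["APOBEC"]].rename(index={"APOBEC": "S1"})
        m = match_signatures(found, cat)
        assert m.best.loc[0, "match"] == "APOBEC"
        assert m.best.loc[0, "cosine"] == pytest.approx(1.0)

    def test_orthogonal_vectors_have_zero_cosine(self):
        a = np.zeros(96); a[:48] = 1 / 48
        b = np.zeros(96); b[48:] = 1 / 48
        found = pd.DataFrame([a], index=["S1"], columns=CONTEXTS_96)
        ref = pd.DataFrame([b], index=["other"], columns=CONTEXTS_96)
        m = match_signatures(found, ref)
        assert m.best.loc[0, "cosine"] == pytest.approx(0.0)

    def test_apobec_like_mass_ranks_apobec_first(self):
        v = np.zeros(96)
        v[CONTEXTS_96.index("T[C>G]A")] = 0.5
        v[CONTEXTS_96.index("T[C>G]T")] = 0.5
        found = pd.DataFrame([v], index=["S1"], columns=CONTEXTS_96)
        m = match_signatures(found, synthetic_reference_catalogue())
        assert m.best.loc[0, "match"] == "APOBEC"

    def test_context_order_mismatch_rejected(self):
        cat = synthetic_reference_catalogue()
        shuffled = cat[cat.columns[::-1]]
        with pytest.raises(ValueError, match="context order"):
            match_signatures(cat.iloc[:1], shuffled)

    def test_packaged_catalogue_round_trips(self):
        loaded = load_reference_catalogue()
        built = synthetic_reference_catalogue()
        assert list(loaded.index) == list(built.index)
        np.testing.assert_allclose(loaded.to_numpy(), built.to_numpy(), atol=1e-7)

    def test_revcomp(self):
        assert revcomp("ACG") == "CGT"
        assert revcomp("TCA") == "TGA"
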