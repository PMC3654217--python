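"""Composition vectors, PCA contract, clustering recovery, screening, surveys."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from thermocomm._seq import random_dna, revcomp
from thermocomm.binning import (
    BinAssignment,
    canonical_kmers,
    cluster_composition,
    composition_vectors,
    pca_composition,
    screen_bins,
    summarize_bins,
    survey_single_copy,
)
from thermocomm.ordination import pca
from thermocomm.simulate import PopulationSpec, generate_population_genome, shred_contigs


def rec(seq, rid="c"):
    return SeqRecord(Seq(seq), id=rid)


def oracle_canonical_counts(seq: str, k: int) -> dict[str, int]:
    """Independent sliding-window canonical k-mer counter."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) - set("ACGT"):
            continue
        cw = min(w, revcomp(w))
        counts[cw] = counts.get(cw, 0) + 1
    return counts


class TestCompositionVectors:
    def test_homopolymer_all_mass_on_one_word(self):
        v = composition_vectors([rec("A" * 2000)], k=4, min_len=1000)
        assert v.freqs.loc["c", "AAAA"] == pytest.approx(1.0)
        assert v.freqs.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_strand_invariance(self):
        rng = np.random.default_rng(3)
        s = random_dna(rng, 3000)
        v = composition_vectors([rec(s, "f"), rec(revcomp(s), "r")], min_len=1000)
        np.testing.assert_allclose(v.freqs.loc["f"], v.freqs.loc["r"], atol=1e-12)

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(4)
        s = random_dna(rng, 10_000)
        v = composition_vectors([rec(s)], k=4, min_len=1000)
        oracle = oracle_canonical_counts(s, 4)
        total = sum(oracle.values())
        for w in v.freqs.columns:
            assert v.freqs.loc["c", w] == pytest.approx(oracle.get(w, 0) / total, abs=1e-12)

    def test_short_contigs_excluded(self):
        v = composition_vectors([rec("ACGT" * 300, "short"), rec("ACGT" * 2000, "long")],
                                min_len=5000)
        assert list(v.freqs.index) == ["long"]

    def test_canonical_dimension_at_k4(self):
        words, _ = canonical_kmers(4)
        assert len(words) == 136

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_vectors_normalized_and_strand_invariant(self, seed):
        rng = np.random.default_rng(seed)
        s = random_dna(rng, 1500)
        v = composition_vectors([rec(s, "f"), rec(revcomp(s), "r")], min_len=1000)
        assert v.freqs.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(v.freqs.loc["f"], v.freqs.loc["r"], atol=1e-12)


def eig_oracle(X: np.ndarray):
    """Independent PCA: eigendecomposition of the sample covariance."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][: min(X.shape)]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        pivot = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[pivot, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = Xc @ vecs
    ratio = np.clip(vals, 0, None) / np.trace(cov)
    return scores, ratio


class TestPca:
    def test_duplicated_observations_identical_scores(self):
        rng = np.random.default_rng(5)
        X = rng.random((5, 10))
        X[3] = X[0]
        out = pca(X)
        np.testing.assert_allclose(out.scores[0], out.scores[3], atol=1e-10)

    def test_single_axis_variation(self):
        X = np.zeros((6, 4))
        X[:, 2] = np.arange(6)
        out = pca(X)
        assert out.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_identical_input_zero_variance_not_error(self):
        out = pca(np.ones((4, 3)))
        assert np.all(out.explained_variance_ratio == 0)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.random((20, 136))
        out = pca(X)
        scores, ratio = eig_oracle(X)
        np.testing.assert_allclose(out.scores, scores[:, : out.scores.shape[1]], atol=1e-8)
        np.testing.assert_allclose(out.explained_variance_ratio,
                                   ratio[: len(out.explained_variance_ratio)], atol=1e-8)

    def test_variance_fraction_invariants(self):
        rng = np.random.default_rng(7)
        out = pca(rng.random((10, 6)))
        r = out.explained_variance_ratio
        assert np.all(r >= 0) and np.all(np.diff(r) <= 1e-12) and r.sum() <= 1 + 1e-9


def make_planted_contigs(gcs, seeds, seed=5, length=300_000):
    recs, labels = [], []
    for gc, sig in zip(gcs, seeds):
        p = PopulationSpec(f"p{sig}", length, gc, 2, sig)
        g = generate_population_genome(p, seed)
        c, _ = shred_contigs(g, (5000, 12000, 1.0), seed)
        recs += c
        labels += [p.name] * len(c)
    return recs, labels


class TestClustering:
    def test_two_populations_perfect_recovery(self):
        recs, labels = make_planted_contigs([0.38, 0.62], [1, 2])
        v = composition_vectors(recs)
        ba = cluster_composition(pca_composition(v), v.meta["gc"], seed=0)
        truth = dict(zip([r.id for r in recs], labels))
        ari = adjusted_rand_score([truth[c] for c in ba.assign.contig_id],
                                  ba.assign["bin"])
        assert ari == pytest.approx(1.0)

    def test_osp8_like_four_populations(self):
        recs, labels = make_planted_contigs([0.325, 0.478, 0.482, 0.575],
                                            [100, 101, 102, 103])
        v = composition_vectors(recs)
        ba = cluster_composition(pca_composition(v), v.meta["gc"], seed=0)
        truth = dict(zip([r.id for r in recs], labels))
        ari = adjusted_rand_score([truth[c] for c in ba.assign.contig_id],
                                  ba.assign["bin"])
        assert ari >= 0.90

    def test_single_bin_request(self):
        recs, _ = make_planted_contigs([0.4], [1], length=100_000)
        v = composition_vectors(recs)
        ba = cluster_composition(pca_composition(v), v.meta["gc"], n_bins=1)
        assert ba.assign["bin"].nunique() == 1

    def test_more_bins_than_contigs_raises(self):
        recs, _ = make_planted_contigs([0.4], [1], length=100_000)
        v = composition_vectors(recs)
        with pytest.raises(ValueError):
            cluster_composition(pca_composition(v), v.meta["gc"],
                                n_bins=len(recs) + 5)


def toy_assignment(gcs, lengths, bins, flags=None):
    ids = [f"c{i}" for i in range(len(gcs))]
    assign = pd.DataFrame({"contig_id": ids, "bin": bins,
                           "flag": flags or ["kept"] * len(ids)})
    meta = pd.DataFrame({"length": lengths, "gc": gcs}, index=ids)
    return BinAssignment(assign=assign), meta


class TestScreening:
    def test_gc_outlier_dropped(self):
        ba, meta = toy_assignment([0.53] * 10 + [0.60], [10_000] * 11, ["b"] * 11)
        out = screen_bins(ba, meta)
        flags = dict(zip(out.assign.contig_id, out.assign.flag))
        assert flags["c10"] == "dropped-gc"
        assert all(flags[f"c{i}"] == "kept" for i in range(10))

    def test_taxon_conflict_dropped(self):
        ba, meta = toy_assignment([0.5] * 4, [10_000] * 4, ["b"] * 4)
        taxa = pd.Series(["X", "X", "X", "Y"], index=[f"c{i}" for i in range(4)])
        out = screen_bins(ba, meta, taxon_labels=taxa)
        assert dict(zip(out.assign.contig_id, out.assign.flag))["c3"] == "dropped-taxon"

    def test_no_taxa_only_gc_rule(self):
        ba, meta = toy_assignment([0.5, 0.5, 0.5], [10_000] * 3, ["b"] * 3)
        out = screen_bins(ba, meta)
        assert (out.assign.flag == "kept").all()

    def test_tightening_threshold_monotone(self):
        rng = np.random.default_rng(8)
        gcs = 0.5 + 0.04 * rng.standard_normal(40)
        ba, meta = toy_assignment(gcs, [10_000] * 40, ["b"] * 40)
        kept_prev = None
        for thr in (0.10, 0.05, 0.02, 0.01):
            out = screen_bins(ba, meta, gc_threshold=thr)
            n_kept = int((out.assign.flag == "kept").sum())
            if kept_prev is not None:
                assert n_kept <= kept_prev
            kept_prev = n_kept

    def test_planted_contaminant_flagged(self):
        recs, labels = make_planted_contigs([0.40, 0.60], [1, 2], length=200_000)
        v = composition_vectors(recs)
        ba = cluster_composition(pca_composition(v), v.meta["gc"], n_bins=2, seed=0)
        # move one contig of the high-GC population into the low-GC bin
        truth = dict(zip([r.id for r in recs], labels))
        assign = ba.assign.copy()
        bins_by_pop = assign.assign(pop=assign.contig_id.map(truth)) \
            .groupby("pop")["bin"].agg(lambda s: s.mode()[0])
        victim = assign[assign.contig_id.map(truth) == "p2"].index[0]
        assign.loc[victim, "bin"] = bins_by_pop["p1"]
        out = screen_bins(BinAssignment(assign=assign), v.meta)
        assert out.assign.loc[victim, "flag"] == "dropped-gc"


class TestSummaries:
    def test_arithmetic_example(self):
        ba, meta = toy_assignment([0.50, 0.56], [10_000, 20_000], ["b", "b"])
        summ = summarize_bins(ba, meta)
        row = summ.iloc[0]
        assert row.n_scaffolds == 2
        assert row.total_mbp == pytest.approx(0.030)
        assert row.largest_kbp == pytest.approx(20.0)
        assert row.mean_gc_pct == pytest.approx(54.0)

    def test_single_contig_bin_largest_equals_total(self):
        ba, meta = toy_assignment([0.5], [12_000], ["b"])
        summ = summarize_bins(ba, meta)
        assert summ.iloc[0].largest_kbp * 1000 == pytest.approx(
            summ.iloc[0].total_mbp * 1e6)

    def test_bin_total_near_genome_length(self):
        recs, _ = make_planted_contigs([0.5], [9], length=300_000)
        v = composition_vectors(recs)
        ba = cluster_composition(pca_composition(v), v.meta["gc"], n_bins=1)
        summ = summarize_bins(ba, v.meta)
        assert abs(summ.iloc[0].total_mbp * 1e6 - 300_000) / 300_000 < 0.2


class TestSingleCopySurvey:
    def _annotations(self, contig_families):
        rows = []
        for cid, fams in contig_families.items():
            for i, f in enumerate(fams):
                rows.append(dict(gene_id=f"{cid}g{i}", contig_id=cid, site="s",
                                 family_id=f, category_id="c"))
        return pd.DataFrame(rows)

    def test_complete_uncontaminated_bin(self):
        markers = [f"m{i}" for i in range(20)]
        ba, _ = toy_assignment([0.5], [10_000], ["b"])
        ann = self._annotations({"c0": markers})
        survey = survey_single_copy(ba, ann, markers)
        assert survey.proxies.loc["b", "completeness"] == 1.0
        assert survey.proxies.loc["b", "contamination"] == 0.0

    def test_empty_marker_list(self):
        ba, _ = toy_assignment([0.5], [10_000], ["b"])
        survey = survey_single_copy(ba, self._annotations({"c0": ["m1"]}), [])
        assert survey.counts.empty

    def test_merged_bin_shows_contamination(self):
        markers = ["m1", "m2"]
        ba, _ = toy_assignment([0.4, 0.6], [10_000, 10_000], ["b", "b"])
        ann = self._annotations({"c0": markers, "c1": markers})
        survey = survey_single_copy(ba, ann, markers)
        assert survey.proxies.loc["b", "contamination"] > 0
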