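"""CRISPR detection, DR census/classification, spacer matching, viral grouping."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from thermocomm._seq import hamming, random_dna, revcomp
from thermocomm.crispr import (
    CrisprArray,
    call_viral,
    classify_dr,
    dr_census,
    extract_spacers,
    find_crispr_arrays,
    linkage_report,
    match_spacers,
    viral_group_clustering,
)


def rec(seq, rid="s"):
    return SeqRecord(Seq(seq), id=rid)


def build_array(rng, dr_len=30, n_units=4, spacer_len=36):
    dr = random_dna(rng, dr_len)
    spacers = [random_dna(rng, spacer_len) for _ in range(n_units - 1)]
    return dr, spacers, dr + "".join(s + dr for s in spacers)


class TestDetector:
    def test_planted_array_detected_with_exact_consensus(self):
        rng = np.random.default_rng(1)
        dr, spacers, arr = build_array(rng)
        flank = random_dna(rng, 2000)
        contig = rec(flank + arr + random_dna(rng, 2000))
        found = find_crispr_arrays(contig)
        assert len(found) == 1
        a = found[0]
        assert a.consensus == dr
        assert a.n_units == 4
        assert a.units[0] == (2000, 2030)
        assert a.spacer_seqs == spacers

    def test_two_unit_repeat_rejected(self):
        rng = np.random.default_rng(2)
        dr = random_dna(rng, 30)
        sp = random_dna(rng, 36)
        contig = rec(random_dna(rng, 1000) + dr + sp + dr + random_dna(rng, 1000))
        assert find_crispr_arrays(contig) == []

    def test_tandem_repeat_rejected_by_spacer_rule(self):
        rng = np.random.default_rng(3)
        unit = random_dna(rng, 40)
        contig = rec(random_dna(rng, 500) + unit * 5 + random_dna(rng, 500))
        assert find_crispr_arrays(contig) == []

    def test_no_false_arrays_in_random_sequence(self):
        rng = np.random.default_rng(4)
        contig = rec(random_dna(rng, 200_000))
        assert len(find_crispr_arrays(contig)) <= 1

    def test_reverse_complement_contig_still_detected(self):
        rng = np.random.default_rng(5)
        dr, _, arr = build_array(rng)
        seq = random_dna(rng, 1500) + arr + random_dna(rng, 1500)
        fwd = find_crispr_arrays(rec(seq))
        bwd = find_crispr_arrays(rec(revcomp(seq)))
        assert len(fwd) == len(bwd) == 1
        assert bwd[0].consensus == revcomp(dr)


class TestCensus:
    def _arrays(self, consensus, n_units, k):
        return [CrisprArray("c", "s", [(0, 1)] * n_units, [], consensus, [])
                for _ in range(k)]

    def test_nine_units_excluded_at_default_threshold(self):
        arrays = self._arrays("ACGTACGTACGTACGTACGTA", 9, 1)
        assert len(dr_census(arrays, min_instances=10)) == 0

    def test_ten_units_retained(self):
        arrays = self._arrays("ACGTACGTACGTACGTACGTA", 10, 1)
        census = dr_census(arrays, min_instances=10)
        assert len(census) == 1 and census.iloc[0].n_units == 10

    def test_min_instances_one_excludes_nothing(self):
        arrays = (self._arrays("A" * 21 + "C", 3, 1)
                  + self._arrays("C" * 21 + "G", 4, 2))
        census = dr_census(arrays, min_instances=1)
        assert census.n_units.sum() == 3 + 8

    def test_counts_pool_across_arrays_and_strands(self):
        dr = "ATGCATGCATGCATGCATGCA"
        arrays = (self._arrays(dr, 6, 1) + self._arrays(revcomp(dr), 5, 1))
        census = dr_census(arrays, min_instances=10)
        assert len(census) == 1 and census.iloc[0].n_units == 11

    def test_retained_families_monotone_in_threshold(self):
        arrays = (self._arrays("A" * 20 + "CG", 12, 1)
                  + self._arrays("C" * 20 + "AT", 8, 1)
                  + self._arrays("G" * 20 + "TA", 4, 1))
        prev = None
        for mi in (1, 5, 9, 13):
            n = len(dr_census(arrays, min_instances=mi))
            if prev is not None:
                assert n <= prev
            prev = n


class TestClassifyDr:
    REFS = [rec("ATGCATGCATGCATGCATGCATGCA", "r1"),
            rec("GGGGGCCCCCGGGGGCCCCCGGGGG", "r2")]

    def setup_method(self):
        self.REFS[0].description = "r1 taxon=Sulfolobus"
        self.REFS[1].description = "r2 taxon=Pyrobaculum"

    def _census(self, consensus):
        return pd.DataFrame({"consensus": [consensus], "n_units": [10], "n_arrays": [1]})

    def test_exact_match(self):
        out = classify_dr(self._census("ATGCATGCATGCATGCATGCATGCA"), self.REFS)
        assert out.iloc[0].taxon == "Sulfolobus" and out.iloc[0].distance == 0

    def test_divergent_unclassified(self):
        rng = np.random.default_rng(6)
        out = classify_dr(self._census(random_dna(rng, 25)), self.REFS)
        assert out.iloc[0].taxon == "unclassified"

    def test_reverse_complement_same_classification(self):
        fwd = classify_dr(self._census("ATGCATGCATGCATGCATGCATGCA"), self.REFS)
        bwd = classify_dr(self._census(revcomp("ATGCATGCATGCATGCATGCATGCA")), self.REFS)
        assert fwd.iloc[0].taxon == bwd.iloc[0].taxon == "Sulfolobus"


def brute_force_matches(spacer_id, spacer, scaffolds, max_mm):
    """Per-position Hamming oracle, both strands."""
    rows = []
    m = len(spacer)
    for sc in scaffolds:
        seq = str(sc.seq)
        for strand, query in (("+", spacer), ("-", revcomp(spacer))):
            for i in range(len(seq) - m + 1):
                window = seq[i : i + m]
                mm = sum(a != b or a not in "ACGT" for a, b in zip(window, query))
                if mm <= max_mm:
                    rows.append((spacer_id, sc.id, i, strand, mm))
    return sorted(rows)


def spacer_frame(pairs):
    return pd.DataFrame(
        [dict(spacer_id=sid, sequence=seq, source_contig="", source_start=-1,
              source_end=-1) for sid, seq in pairs]
    )


class TestMatcher:
    def test_planted_exact_spacer_found_at_position(self):
        rng = np.random.default_rng(7)
        spacer = random_dna(rng, 36)
        scaffold = rec(random_dna(rng, 3000) + spacer + random_dna(rng, 1000), "v")
        m = match_spacers(spacer_frame([("s0", spacer)]), [scaffold], 0)
        assert len(m) == 1
        assert (m.iloc[0].start, m.iloc[0].mismatches, m.iloc[0].strand) == (3000, 0, "+")

    def test_two_substitutions_found_at_3_not_1(self):
        rng = np.random.default_rng(8)
        spacer = random_dna(rng, 36)
        proto = list(spacer)
        proto[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[5]]
        proto[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[20]]
        scaffold = rec(random_dna(rng, 1000) + "".join(proto) + random_dna(rng, 1000), "v")
        sp = spacer_frame([("s0", spacer)])
        assert len(match_spacers(sp, [scaffold], 3)) == 1
        assert len(match_spacers(sp, [scaffold], 1)) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(25):
            m = int(rng.integers(20, 45))
            spacer = random_dna(rng, m)
            scaffold_seq = random_dna(rng, 500)
            # plant a perturbed copy half the time so matches exist
            if trial % 2 == 0:
                pos = int(rng.integers(0, 500 - m))
                scaffold_seq = (scaffold_seq[:pos] + spacer[: m // 2]
                                + scaffold_seq[pos + m // 2:])
            scaffold = rec(scaffold_seq, "v")
            max_mm = int(rng.integers(0, 4))
            sp = spacer_frame([("s0", spacer)])
            got = sorted(match_spacers(sp, [scaffold], max_mm).itertuples(index=False))
            got = [tuple(r) for r in got]
            assert got == brute_force_matches("s0", spacer, [scaffold], max_mm)

    def test_match_sets_monotone_in_mismatch_budget(self):
        rng = np.random.default_rng(10)
        spacer = random_dna(rng, 24)
        scaffold = rec(random_dna(rng, 4000), "v")
        sp = spacer_frame([("s0", spacer)])
        prev = set()
        for mm in range(4):
            cur = {tuple(r) for r in
                   match_spacers(sp, [scaffold], mm).itertuples(index=False)}
            assert {c[:4] for c in prev} <= {c[:4] for c in cur}
            prev = cur

    def test_source_array_masking(self):
        rng = np.random.default_rng(11)
        spacer = random_dna(rng, 30)
        contig_seq = random_dna(rng, 500) + spacer + random_dna(rng, 500)
        sp = pd.DataFrame([dict(spacer_id="s0", sequence=spacer,
                                source_contig="host", source_start=480,
                                source_end=560)])
        contig = rec(contig_seq, "host")
        assert len(match_spacers(sp, [contig], 0, mask_sources=True)) == 0
        assert len(match_spacers(sp, [contig], 0, mask_sources=False)) == 1

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError):
            match_spacers(spacer_frame([("s0", "ACGTACGTACGT")]), [rec("A" * 100)], 0)


class TestViralCallsAndReport:
    def hit(self, q, e):
        return dict(qseqid=q, sseqid="virusref", pident=90.0, length=100,
                    mismatch=1, gapopen=0, qstart=1, qend=100, sstart=1,
                    send=100, evalue=e, bitscore=200.0)

    def test_threshold_rule(self):
        hits = pd.DataFrame([self.hit("a", 1e-20), self.hit("b", 1e-3)])
        calls = call_viral(["a", "b", "c"], hit_table=hits)
        by = calls.set_index("contig_id")
        assert bool(by.loc["a", "is_viral"]) and not bool(by.loc["b", "is_viral"])
        assert by.loc["c", "note"] == "no-evidence"

    def test_report_counts_and_invariants(self, community_dir, truth, siteA_arrays):
        from Bio import SeqIO

        spacers = extract_spacers(siteA_arrays)
        viral = list(SeqIO.parse(str(community_dir / "viral.fasta"), "fasta"))
        m1 = match_spacers(spacers, viral, 1)
        m3 = match_spacers(spacers, viral, 3)
        calls = call_viral([v.id for v in viral],
                           truth_labels={v.id: True for v in viral})
        rep = linkage_report(m1, m3, calls, spacers)
        assert rep.spacers_viral_le1 <= rep.spacers_viral_le3 <= rep.total_spacers
        links = truth["spacer_links"]
        assert rep.spacers_viral_le1 == (links.planted_mismatches.isin([0, 1])).sum()
        assert rep.spacers_viral_le3 == (links.planted_mismatches >= 0).sum()

    def test_all_decoys_zero_links(self):
        rng = np.random.default_rng(12)
        spacers = spacer_frame([(f"s{i}", random_dna(rng, 30)) for i in range(5)])
        viral = [rec(random_dna(rng, 5000), "v")]
        m1 = match_spacers(spacers, viral, 1)
        m3 = match_spacers(spacers, viral, 3)
        calls = call_viral(["v"], truth_labels={"v": True})
        rep = linkage_report(m1, m3, calls, spacers)
        assert rep.spacers_viral_le3 == 0 and rep.total_spacers == 5

    def test_strand_symmetry_of_report(self):
        rng = np.random.default_rng(13)
        spacer = random_dna(rng, 32)
        vseq = random_dna(rng, 4000) + spacer + random_dna(rng, 1000)
        spacers = spacer_frame([("s0", spacer)])
        calls = call_viral(["v"], truth_labels={"v": True})
        reps = []
        for seq in (vseq, revcomp(vseq)):
            m1 = match_spacers(spacers, [rec(seq, "v")], 1)
            m3 = match_spacers(spacers, [rec(seq, "v")], 3)
            reps.append(linkage_report(m1, m3, calls, spacers))
        assert reps[0] == reps[1]


class TestViralGroups:
    def test_duplicate_scaffolds_grouped(self):
        rng = np.random.default_rng(14)
        s = random_dna(rng, 8000)
        groups = viral_group_clustering([rec(s, "a"), rec(s, "b"),
                                         rec(random_dna(rng, 8000), "c")])
        assert ["a", "b"] in groups and ["c"] in groups

    def test_five_percent_divergence_grouped_at_92_split_at_99(self):
        rng = np.random.default_rng(15)
        s = random_dna(rng, 8000)
        mutated = list(s)
        for i in rng.choice(8000, size=400, replace=False):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        pair = [rec(s, "a"), rec("".join(mutated), "b")]
        assert viral_group_clustering(pair, min_identity=0.92) == [["a", "b"]]
        assert viral_group_clustering(pair, min_identity=0.99) == [["a"], ["b"]]

    def test_unrelated_scaffolds_singletons(self):
        rng = np.random.default_rng(16)
        recs = [rec(random_dna(rng, 6000), f"v{i}") for i in range(4)]
        groups = viral_group_clustering(recs)
        assert all(len(g) == 1 for g in groups)
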