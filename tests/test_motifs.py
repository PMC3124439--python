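"""Scanner, dyad, promoter-retrieval and enrichment behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cremap.iupac import DyadSpec, InvalidPatternError, IUPACPattern, reverse_complement
from cremap.motifs import (
    cluster_enrichment,
    count_pattern,
    discover_motifs,
    retrieve_promoters,
    scan_dyad,
    scan_pattern,
)

from oracles import dyad_count_oracle, greedy_scan_oracle, revcomp

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestScanPattern:
    @pytest.mark.parametrize(
        "pattern,seq,expected",
        [
            ("SYGGRG", "CTGGAG", [0]),      # S~C, Y~T, R~A
            ("SYGGRG", "AAAAAA", []),
            ("GTGGAG", "GTGGAGGTGGAG", [0, 6]),
            ("AAA", "AAAAA", [0]),          # greedy consumption: 2 bases left
            ("AAA", "AAAAAA", [0, 3]),
            ("SYGGRG", "NCTGGAGN", [1]),    # N in sequence matches nothing
            ("ACGT", "", []),
        ],
    )
    def test_examples(self, pattern, seq, expected):
        assert scan_pattern(pattern, seq) == expected

    def test_invalid_character_rejected(self):
        with pytest.raises(InvalidPatternError):
            scan_pattern("SYGGQG", "ACGT")

    @given(seq=dna, pattern=st.sampled_from(["SYGGRG", "AAA", "RYW", "SAGGGRG", "GC"]))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_greedy_oracle(self, seq, pattern):
        assert scan_pattern(pattern, seq) == greedy_scan_oracle(pattern, seq)

    @given(seq=dna, pattern=st.sampled_from(["SYGGRG", "CYCCRS", "RY", "WSN"]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strand_duality(self, seq, pattern):
        assert count_pattern(pattern, seq) == count_pattern(
            reverse_complement(pattern), revcomp(seq)
        )

    @given(seq=dna)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_non_overlap_bound(self, seq):
        assert count_pattern("SYGGRG", seq) <= len(seq) // 6


class TestScanDyad:
    def test_gap_definition(self):
        # first site at 0 (len 6), second at 16: gap 10
        seq = "GTGGAG" + "T" * 10 + "GTGGAG"
        for max_gap in (20, 50):
            assert scan_dyad(DyadSpec(IUPACPattern("GTGGAG"), IUPACPattern("GTGGAG"), max_gap), seq) == 1
        # gap 30: only within the 50 bp bound
        seq30 = "GTGGAG" + "T" * 30 + "GTGGAG"
        d20 = DyadSpec(IUPACPattern("GTGGAG"), IUPACPattern("GTGGAG"), 20)
        d50 = DyadSpec(IUPACPattern("GTGGAG"), IUPACPattern("GTGGAG"), 50)
        assert scan_dyad(d20, seq30) == 0
        assert scan_dyad(d50, seq30) == 1

    def test_all_ordered_combinations_counted(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for gap in (0, 5, 20, 50):
                dyad = DyadSpec(IUPACPattern("SYGGRG"), IUPACPattern("SYGGRG"), gap)
                assert scan_dyad(dyad, seq) == dyad_count_oracle("SYGGRG", "SYGGRG", gap, seq)

    def test_monotone_in_gap(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        base = IUPACPattern("SYGGRG")
        counts = [scan_dyad(DyadSpec(base, base, g), seq) for g in (0, 10, 20, 50, 200)]
        assert counts == sorted(counts)

    def test_unbounded_gap_equals_pair_enumeration(self):
        seq = "GTGGAGTTGTGGAGTTTTGTGGAG"
        pos = scan_pattern("GTGGAG", seq)
        pairs = sum(1 for i in pos for j in pos if j >= i + 6)
        assert scan_dyad(DyadSpec(IUPACPattern("GTGGAG"), IUPACPattern("GTGGAG"), 10**6), seq) == pairs


class TestRetrievePromoters:
    def _genome(self):
        rng = np.random.default_rng(11)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=3000))}

    def test_plus_strand_window(self):
        genome = self._genome()
        genes = pd.DataFrame(
            [{"gene_id": "gA", "contig": "chr1", "start": 1001, "end": 1500, "strand": "+"}]
        )
        promoters = retrieve_promoters(genes, genome, length=1000)
        assert promoters["gA"] == genome["chr1"][0:1000]

    def test_minus_strand_is_revcomp_of_downstream_window(self):
        genome = self._genome()
        genes = pd.DataFrame(
            [{"gene_id": "gB", "contig": "chr1", "start": 500, "end": 1200, "strand": "-"}]
        )
        promoters = retrieve_promoters(genes, genome, length=1000)
        assert promoters["gB"] == revcomp(genome["chr1"][1200:2200])

    def test_truncated_at_contig_edge(self):
        genome = self._genome()
        genes = pd.DataFrame(
            [{"gene_id": "gC", "contig": "chr1", "start": 201, "end": 400, "strand": "+"}]
        )
        promoters = retrieve_promoters(genes, genome, length=1000)
        assert promoters["gC"] == genome["chr1"][0:200]
        assert len(promoters["gC"]) == 200

    def test_missing_contig_names_gene(self):
        genes = pd.DataFrame(
            [{"gene_id": "gD", "contig": "chrZ", "start": 1500, "end": 1800, "strand": "+"}]
        )
        with pytest.raises(KeyError, match="gD"):
            retrieve_promoters(genes, self._genome())


class TestClusterEnrichment:
    def test_identical_counts_zero_enrichment(self):
        counts = pd.Series(2.0, index=[f"g{i}" for i in range(100)])
        enr = cluster_enrichment(counts, [f"g{i}" for i in range(10)])
        assert enr.enrichment_pct == pytest.approx(0.0)
        assert enr.p == pytest.approx(1.0)

    def test_percent_formula(self):
        # genome mean 1.0, cluster mean 1.23 -> +23%
        genes = [f"g{i}" for i in range(100)]
        values = np.ones(100)
        cluster = genes[:20]
        values[:20] = 1.23
        values[20:] = (100 * 1.0 - 20 * 1.23) / 80  # keep genome mean at 1.0
        counts = pd.Series(values, index=genes)
        enr = cluster_enrichment(counts, cluster)
        assert enr.genome_mean == pytest.approx(1.0)
        assert enr.enrichment_pct == pytest.approx(23.0)

    def test_zero_cluster_mean_is_minus_100(self):
        counts = pd.Series([0, 0, 1, 2, 3, 1], index=list("abcdef"))
        enr = cluster_enrichment(counts, ["a", "b"])
        assert enr.enrichment_pct == pytest.approx(-100.0)

    def test_zero_genome_mean_is_error(self):
        counts = pd.Series(0.0, index=list("abcdef"))
        with pytest.raises(ValueError, match="genome mean"):
            cluster_enrichment(counts, ["a", "b"])

    def test_welch_null_calibration(self):
        """Random same-size gene draws from a homogeneous genome reject
        at ~ the nominal 5% level (quick version; the full 10^4-draw
        calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(3)
        counts = pd.Series(rng.poisson(2.0, size=800).astype(float),
                           index=[f"g{i}" for i in range(800)])
        rejections = 0
        n_draws = 400
        for _ in range(n_draws):
            cluster = rng.choice(counts.index, size=50, replace=False)
            if cluster_enrichment(counts, cluster).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_draws <= 0.08


class TestDiscovery:
    def test_planted_word_accepted(self):
        rng = np.random.default_rng(9)
        promoters = {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(60)
        }
        cluster = [f"g{i}" for i in range(12)]
        for g in cluster:
            s = promoters[g]
            promoters[g] = s[:100] + "GAGGGAGG" + s[108:]
        res = discover_motifs(cluster, promoters, word_lengths=(8,), rng=1)
        assert "GAGGGAGG" in set(res["word"])
        top = res.set_index("word").loc["GAGGGAGG"]
        assert top["score"] > top["threshold"]

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs([], {"g1": "ACGT" * 50})

    def test_cluster_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs(["g1", "g2"], {"g1": "ACGT" * 50})
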