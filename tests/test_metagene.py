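"""Coverage, expression filters and the tail-normalized metagene profile."""

import numpy as np
import pytest

from ribodrift import (
    FootprintAlignment,
    Transcript,
    TranscriptSet,
    coverage,
    coverage_map,
    expression_table,
    metagene_profile,
    peak_area,
    select_genes,
)
from ribodrift.metagene import MetageneProfile


def brute_force_coverage(tx, alignments, mode):
    counts = np.zeros(tx.length, dtype=int)
    for aln in alignments:
        if mode == "full":
            for i in range(aln.start, aln.end):
                counts[i] += 1
        elif mode == "end5":
            counts[aln.start] += 1
        else:
            counts[aln.end - 1] += 1
    return counts


class TestCoverage:
    def test_full_mode_covers_every_nucleotide(self, toy_tx):
        cov = coverage(toy_tx, [FootprintAlignment("tx1", 100, 128)], mode="full")
        assert cov.counts[100:128].tolist() == [1] * 28
        assert cov.counts.sum() == 28

    def test_end_modes_mark_single_nucleotide(self, toy_tx):
        aln = [FootprintAlignment("tx1", 100, 128)]
        cov5 = coverage(toy_tx, aln, mode="end5")
        cov3 = coverage(toy_tx, aln, mode="end3")
        assert cov5.counts[100] == 1 and cov5.counts.sum() == 1
        assert cov3.counts[127] == 1 and cov3.counts.sum() == 1

    def test_overlapping_footprints_stack(self, toy_tx):
        alns = [
            FootprintAlignment("tx1", 100, 128),
            FootprintAlignment("tx1", 110, 138),
        ]
        cov = coverage(toy_tx, alns, mode="full")
        assert cov.counts[110:128].tolist() == [2] * 18

    @pytest.mark.parametrize("mode", ["full", "end5", "end3"])
    def test_matches_brute_force_on_random_reads(self, toy_tx, mode):
        rng = np.random.default_rng(0)
        alns = [
            FootprintAlignment("tx1", int(s), int(s) + 28)
            for s in rng.integers(0, toy_tx.length - 28, size=200)
        ]
        cov = coverage(toy_tx, alns, mode=mode)
        assert np.array_equal(cov.counts, brute_force_coverage(toy_tx, alns, mode))

    def test_mass_conservation_full_mode(self, toy_set):
        rng = np.random.default_rng(1)
        alns = []
        for tid in toy_set:
            n = toy_set[tid].length
            for s in rng.integers(0, n - 31, size=100):
                alns.append(FootprintAlignment(tid, int(s), int(s + rng.integers(27, 32))))
        covs = coverage_map(toy_set, alns, mode="full")
        total = sum(c.counts.sum() for c in covs.values())
        assert total == sum(a.length for a in alns)

    def test_out_of_bounds_alignment_rejected(self, toy_tx):
        with pytest.raises(ValueError, match="out of bounds"):
            coverage(toy_tx, [FootprintAlignment("tx1", 1390, 1418)])


class TestExpression:
    def test_rpkm_formula(self):
        tx = Transcript("g", length=1000, cds_start=0, cds_end=999)
        other = Transcript("h", length=2000, cds_start=0, cds_end=1998)
        txs = TranscriptSet([tx, other])
        # 10 reads on g out of a 1e6-read library -> rpkm 10
        reads = [FootprintAlignment("g", 0, 28)] * 10
        reads += [FootprintAlignment("h", 0, 28)] * (1_000_000 - 10)
        table = {e.transcript_id: e for e in expression_table(txs, reads)}
        assert table["g"].rpkm == pytest.approx(10.0)
        assert table["g"].read_count == 10

    def test_rpkm_with_half_million_library(self):
        txs = TranscriptSet(
            [
                Transcript("g", length=2000, cds_start=0, cds_end=1998),
                Transcript("h", length=1000, cds_start=0, cds_end=999),
            ]
        )
        reads = [FootprintAlignment("g", 5, 33)] * 30
        reads += [FootprintAlignment("h", 0, 28)] * (500_000 - 30)
        table = {e.transcript_id: e for e in expression_table(txs, reads)}
        assert table["g"].rpkm == pytest.approx(30.0)  # 30 / (2 kb * 0.5 M)

    def test_zero_reads_zero_rpkm(self, toy_set):
        reads = [FootprintAlignment("tx1", 0, 28)]
        table = {e.transcript_id: e for e in expression_table(toy_set, reads)}
        assert table["txu"].rpkm == 0.0

    def test_empty_library_is_an_error(self, toy_set):
        with pytest.raises(ValueError, match="no footprint"):
            expression_table(toy_set, [])


class TestGeneFilter:
    def _make(self, length, exons):
        return Transcript(
            f"L{length}E{exons}",
            length=length,
            cds_start=0,
            cds_end=3 * (length // 3),
            exon_count=exons,
        )

    def test_boundaries_are_strict_and_exons_single(self):
        from ribodrift.metagene import GeneExpression

        txs = TranscriptSet(
            [
                self._make(1000, 1),  # at length boundary -> out
                self._make(1001, 1),  # in, if rpkm passes
                self._make(5000, 2),  # multi-exon -> out
                self._make(2000, 1),  # rpkm boundary -> out
            ]
        )
        expr = [
            GeneExpression("L1000E1", 100, 100.0),
            GeneExpression("L1001E1", 100, 30.5),
            GeneExpression("L5000E2", 100, 100.0),
            GeneExpression("L2000E1", 100, 30.0),
        ]
        assert select_genes(txs, expr) == ["L1001E1"]


def brute_force_metagene(txs, ids, coverages, up=50, down=1000, tail=300):
    rows = []
    for tid in ids:
        tx = txs[tid]
        if tx.cds_start < up or tx.cds_length < down:
            continue
        row = [coverages[tid].counts[tx.cds_start + p] for p in range(-up, down)]
        rows.append(row)
    mean = [sum(col) / len(rows) for col in zip(*rows)]
    tail_mean = sum(mean[-tail:]) / tail
    return mean, tail_mean


class TestMetageneProfile:
    @pytest.fixture
    def gene_cohort(self):
        rng = np.random.default_rng(7)
        txs = TranscriptSet(
            [
                Transcript(f"g{i}", length=1500, cds_start=80, cds_end=1430)
                for i in range(6)
            ]
        )
        alns = []
        for tid in txs:
            for s in rng.integers(0, 1500 - 28, size=300):
                alns.append(FootprintAlignment(tid, int(s), int(s) + 28))
        return txs, alns

    def test_uniform_coverage_normalizes_to_one(self):
        txs = TranscriptSet([Transcript("g", length=1500, cds_start=80, cds_end=1430)])
        from ribodrift.metagene import CoverageVector

        covs = {"g": CoverageVector("g", np.full(1500, 7))}
        profile = metagene_profile(txs, ["g"], covs)
        assert np.allclose(profile.normalized, 1.0)
        assert profile.n_genes == 1

    def test_two_uniform_genes_average(self):
        from ribodrift.metagene import CoverageVector

        txs = TranscriptSet(
            [
                Transcript("a", length=1500, cds_start=80, cds_end=1430),
                Transcript("b", length=1500, cds_start=80, cds_end=1430),
            ]
        )
        covs = {
            "a": CoverageVector("a", np.full(1500, 4)),
            "b": CoverageVector("b", np.full(1500, 10)),
        }
        profile = metagene_profile(txs, ["a", "b"], covs)
        assert np.allclose(profile.mean_coverage, 7.0)
        assert np.allclose(profile.normalized, 1.0)

    def test_matches_brute_force_double_loop(self, gene_cohort):
        txs, alns = gene_cohort
        covs = coverage_map(txs, alns)
        profile = metagene_profile(txs, list(txs), covs)
        mean, tail_mean = brute_force_metagene(txs, list(txs), covs)
        assert np.allclose(profile.mean_coverage, mean)
        assert profile.tail_mean == pytest.approx(tail_mean)
        assert np.allclose(profile.normalized, np.array(mean) / tail_mean)

    def test_tail_mean_of_normalized_is_unity(self, gene_cohort):
        txs, alns = gene_cohort
        profile = metagene_profile(txs, list(txs), coverage_map(txs, alns))
        assert profile.normalized[-300:].mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_of_normalized_profile(self, gene_cohort):
        txs, alns = gene_cohort
        covs = coverage_map(txs, alns)
        profile = metagene_profile(txs, list(txs), covs)
        from ribodrift.metagene import CoverageVector

        scaled = {
            tid: CoverageVector(tid, c.counts * 13) for tid, c in covs.items()
        }
        profile2 = metagene_profile(txs, list(txs), scaled)
        assert np.allclose(profile.normalized, profile2.normalized)

    def test_window_incompatible_genes_dropped(self, gene_cohort):
        txs_base, alns = gene_cohort
        short = Transcript("short", length=800, cds_start=80, cds_end=710)
        txs = TranscriptSet(list(txs_base.values()) + [short])
        alns = alns + [FootprintAlignment("short", 10, 38)]
        covs = coverage_map(txs, alns)
        profile = metagene_profile(txs, list(txs), covs)
        assert profile.n_genes == len(txs_base)

    def test_all_genes_window_incompatible_is_an_error(self):
        txs = TranscriptSet([Transcript("s", length=800, cds_start=80, cds_end=710)])
        covs = coverage_map(txs, [FootprintAlignment("s", 10, 38)])
        with pytest.raises(ValueError, match="window"):
            metagene_profile(txs, ["s"], covs)


class TestPeakArea:
    def _profile(self, normalized):
        positions = np.arange(-50, 1000)
        return MetageneProfile(
            positions=positions,
            mean_coverage=normalized.copy(),
            normalized=normalized,
            n_genes=1,
            tail_mean=1.0,
        )

    def test_flat_profile_has_zero_area(self):
        assert peak_area(self._profile(np.ones(1050))) == 0.0

    def test_rectangular_excess(self):
        norm = np.ones(1050)
        norm[50:150] = 1.5  # positions 0..99
        assert peak_area(self._profile(norm)) == pytest.approx(50.0)

    def test_dips_below_one_do_not_go_negative(self):
        norm = np.ones(1050) * 0.2
        assert peak_area(self._profile(norm)) == 0.0
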