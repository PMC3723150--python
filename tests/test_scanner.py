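import numpy as np
import pytest

from mirtarnet.models import GeneModel, MatureMiRNA
from mirtarnet.scanner import (STACK_ENERGIES, DuplexAlignment, ScannerParams,
                               align_duplex, duplex_energy, scan_gene)
from mirtarnet.simulate import perfect_duplex_energy, revcomp

from _oracles import brute_force_best_score

MIR22 = "UGCUUGGACUACAGGCUUAGCA"


class TestAlignDuplex:
    def test_perfect_22mer_scores_180(self):
        aln = align_duplex(MIR22, revcomp(MIR22))
        # 7 seed positions x 5 x 3 + 15 plain matches x 5
        assert aln.raw_score == pytest.approx(180.0)
        assert aln.gene_start == 1 and aln.gene_end == 22
        assert all(kind == "wc" for _, _, kind in aln.columns)

    def test_no_complementarity_scores_zero(self):
        aln = align_duplex("A" * 22, "A" * 30)
        assert aln.raw_score == 0.0
        assert aln.columns == []

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            align_duplex("ACGUN" + "A" * 17, "ACGT" * 8)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="window"):
            align_duplex(MIR22, "ACGT")

    def test_score_recomputes_from_columns(self):
        params = ScannerParams()
        aln = align_duplex(MIR22, revcomp(MIR22), params)
        smat = params.substitution_matrix()
        enc = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
        total = sum(
            (params.seed_scaling if i in params.seed_positions else 1.0)
            * smat[enc[MIR22[i - 1]], enc[aln.gene_window[j - 1]]]
            for i, j, kind in aln.columns)
        assert total == pytest.approx(aln.raw_score)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_small_duplexes(self, seed):
        rng = np.random.default_rng(1000 + seed)
        nq = int(rng.integers(6, 8))
        nt = int(rng.integers(max(2, nq - 5), 10))
        q = "".join(rng.choice(list("ACGU"), size=nq))
        t = "".join(rng.choice(list("ACGT"), size=nt))
        params = ScannerParams()
        assert align_duplex(q, t, params).raw_score == pytest.approx(
            brute_force_best_score(q, t, params))

    def test_brute_force_agrees_on_planted_complement(self):
        rng = np.random.default_rng(9)
        q = "".join(rng.choice(list("ACGU"), size=7))
        t = revcomp(q)
        params = ScannerParams()
        assert align_duplex(q, t, params).raw_score == pytest.approx(
            brute_force_best_score(q, t, params))


class TestDuplexEnergy:
    def test_single_pair_has_no_stack(self):
        aln = DuplexAlignment(mirna_seq="G", gene_window="C",
                              columns=[(1, 1, "wc")], raw_score=5.0,
                              gene_start=1, gene_end=1)
        assert duplex_energy(aln) == 0.0

    def test_empty_pairing_rejected(self):
        aln = DuplexAlignment("A", "A", [], 0.0, 0, 0)
        with pytest.raises(ValueError):
            duplex_energy(aln)

    def test_gc_rich_helix_clears_filter(self):
        mir = "GCGCGCGCGCGCGCGCGCGCGC"
        aln = align_duplex(mir, revcomp(mir))
        expected = sum(STACK_ENERGIES[mir[i:i + 2]] for i in range(21))
        assert aln.energy == pytest.approx(expected)
        assert aln.energy < -25.0

    def test_all_stack_terms_negative(self):
        assert all(v < 0 for v in STACK_ENERGIES.values())

    def test_monotone_in_helix_length(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=24))
        energies = [perfect_duplex_energy(seq[:k]) for k in range(2, 25)]
        assert all(b <= a for a, b in zip(energies, energies[1:]))

    def test_mismatch_and_gap_penalised(self):
        # interior mismatch costs two unpaired nucleotides
        aln = align_duplex("GGGGAGGGG", revcomp("GGGGUGGGG"))
        mismatch_cols = [c for c in aln.columns if c[2] == "mismatch"]
        assert len(mismatch_cols) == 1
        wc_stacks = sum(
            1 for (i1, j1, k1), (i2, j2, k2) in zip(aln.columns, aln.columns[1:])
            if k1 == "wc" and k2 == "wc")
        assert aln.energy == pytest.approx(
            wc_stacks * STACK_ENERGIES["GG"] + 2 * 0.5)


class TestScanGene:
    def _planted_gene(self, mir, pos, length=400, seed=3):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=length))
        site = revcomp(mir)
        seq = seq[:pos - 1] + site + seq[pos - 1 + len(site):]
        return GeneModel(gene_id="g1", sequence=seq, cds_start=100, cds_end=300)

    def test_planted_site_recovered_at_coordinates(self):
        mirna = MatureMiRNA("hsa-miR-900", MIR22)
        for pos in (1, 137, 379):
            gene = self._planted_gene(MIR22, pos)
            sites = scan_gene(gene, mirna)
            planted = [s for s in sites if s.start == pos]
            assert len(planted) == 1
            assert planted[0].end == pos + 21
            assert planted[0].score == pytest.approx(180.0)
            # string-search coordinate oracle
            assert gene.sequence.find(revcomp(MIR22)) == pos - 1

    def test_threshold_monotonicity(self):
        mirna = MatureMiRNA("hsa-miR-900", MIR22)
        gene = self._planted_gene(MIR22, 137)
        counts = [len(scan_gene(gene, mirna, ScannerParams(score_threshold=s)))
                  for s in (100.0, 150.0, 170.0, 181.0)]
        assert counts == sorted(counts, reverse=True)

    def test_filter_composition(self):
        mirna = MatureMiRNA("hsa-miR-900", MIR22)
        gene = self._planted_gene(MIR22, 137)
        strict = scan_gene(gene, mirna,
                           ScannerParams(score_threshold=150, energy_threshold=-25))
        loose = scan_gene(gene, mirna,
                          ScannerParams(score_threshold=100, energy_threshold=-10))
        strict_keys = {(s.start, s.end) for s in strict}
        loose_keys = {(s.start, s.end) for s in loose}
        assert strict_keys <= loose_keys

    def test_determinism(self):
        mirna = MatureMiRNA("hsa-miR-900", MIR22)
        gene = self._planted_gene(MIR22, 137)
        assert scan_gene(gene, mirna) == scan_gene(gene, mirna)

    def test_overlapping_candidates_merge_to_best(self):
        # a gene with two overlapping near-identical planted frames keeps one site
        mir = MIR22
        mirna = MatureMiRNA("hsa-miR-900", mir)
        gene = self._planted_gene(mir, 137)
        sites = scan_gene(gene, mirna, ScannerParams(score_threshold=140))
        starts = [s.start for s in sites]
        assert len(starts) == len(set(starts))
        for a, b in zip(sites, sites[1:]):
            assert a.end < b.start  # accepted sites never overlap


class TestScannerParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ScannerParams(gap_open_penalty=-1)
        with pytest.raises(ValueError):
            ScannerParams(seed_scaling=0.5)
        with pytest.raises(ValueError):
            ScannerParams(score_threshold=float("nan"))

    def test_seed_weighting_only_at_seed_positions(self):
        w = ScannerParams().weight_vector(22)
        assert list(np.nonzero(w == 3.0)[0] + 1) == [2, 3, 4, 5, 6, 7, 8]
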