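"""Metagene density, codon occupancy shifts and stratified fold changes."""

import numpy as np
import pandas as pd
import pytest

import valtrans as vt
from valtrans.genetic_code import SENSE_CODONS
from valtrans.ribo import RpfDataset


def uniform_dataset(genes, count=1, read_length=30):
    """One read of weight `count` at every valid 5' position."""
    tx_rows, read_rows = [], []
    for rec in genes:
        length = len(rec.sequence)
        tx_rows.append({"transcript_id": rec.transcript_id, "length": length,
                        "cds_start": 0, "cds_end": length})
        for p in range(length - read_length + 1):
            read_rows.append({"transcript_id": rec.transcript_id, "pos": p,
                              "read_length": read_length, "count": count})
    return RpfDataset(pd.DataFrame(tx_rows), pd.DataFrame(read_rows))


class TestMetagene:
    def test_uniform_coverage_is_flat_unity(self, small_genes):
        genes = small_genes[:5]
        tx, reads = [], []
        for rec in genes:
            length = len(rec.sequence)
            tx.append({"transcript_id": rec.transcript_id, "length": length,
                       "cds_start": 0, "cds_end": length})
            for p in range(length):
                reads.append({"transcript_id": rec.transcript_id, "pos": p,
                              "read_length": 1, "count": 3})
        ds = RpfDataset(pd.DataFrame(tx), pd.DataFrame(reads))
        prof = vt.metagene(ds, n_cds_bins=10, utr_window_nt=0)
        assert np.allclose(prof.cds, 1.0, atol=1e-9)

    def test_all_reads_at_cds_start(self):
        tx = pd.DataFrame([{"transcript_id": "t", "length": 300,
                            "cds_start": 0, "cds_end": 300}])
        reads = pd.DataFrame([{"transcript_id": "t", "pos": 0,
                               "read_length": 30, "count": 10}])
        prof = vt.metagene(RpfDataset(tx, reads), n_cds_bins=10, utr_window_nt=0)
        assert prof.cds[0] > 1
        assert np.all(prof.cds[1:] == 0)

    def test_invariant_to_per_transcript_depth(self, small_genes):
        genes = small_genes[:4]
        shallow = uniform_dataset(genes, count=1)
        deep = uniform_dataset(genes, count=10)
        p1 = vt.metagene(shallow, n_cds_bins=12, utr_window_nt=0)
        p2 = vt.metagene(deep, n_cds_bins=12, utr_window_nt=0)
        assert np.allclose(p1.cds, p2.cds, atol=1e-12)


class TestCodonOccupancy:
    def test_identical_datasets_have_zero_shift(self, small_genes):
        genes = small_genes[:10]
        ds = vt.generate_rpf_dataset(genes, vt.PauseSpec(seed=1))
        cds_map = {r.transcript_id: r.sequence for r in genes}
        occ = vt.codon_occupancy(ds, ds, cds_map)
        assert np.allclose(occ["log2_shift"], 0.0, atol=1e-12)

    def test_fractions_sum_to_one_per_offset(self, small_genes):
        genes = small_genes[:10]
        cds_map = {r.transcript_id: r.sequence for r in genes}
        a = vt.generate_rpf_dataset(genes, vt.PauseSpec(seed=2))
        b = vt.generate_rpf_dataset(genes, vt.PauseSpec(seed=3))
        occ = vt.codon_occupancy(a, b, cds_map)
        for o, grp in occ.groupby("offset"):
            assert grp["fraction_a"].sum() == pytest.approx(1.0, abs=1e-9)
            assert grp["fraction_b"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_recount_oracle(self, small_genes):
        """Fractions equal a brute-force O(reads x offsets) recount."""
        genes = small_genes[:8]
        cds_map = {r.transcript_id: r.sequence for r in genes}
        a = vt.generate_rpf_dataset(genes, vt.PauseSpec(seed=4))
        b = vt.generate_rpf_dataset(genes, vt.PauseSpec(seed=5))
        occ = vt.codon_occupancy(a, b, cds_map, offsets=(15,))

        def naive(ds):
            tally = {c: 0.0 for c in SENSE_CODONS}
            for row in ds.reads.itertuples():
                seq = cds_map[row.transcript_id]
                nt = row.pos + 15
                codon = seq[nt // 3 * 3: nt // 3 * 3 + 3]
                if codon in tally:
                    tally[codon] += row.count
            total = sum(tally.values())
            return {c: v / total for c, v in tally.items()}

        ref_a, ref_b = naive(a), naive(b)
        for row in occ.itertuples():
            assert row.fraction_a == pytest.approx(ref_a[row.codon], abs=1e-12)
            assert row.fraction_b == pytest.approx(ref_b[row.codon], abs=1e-12)

    def test_planted_pause_recovered(self, small_genes):
        cds_map = {r.transcript_id: r.sequence for r in small_genes}
        kd = vt.generate_rpf_dataset(
            small_genes, vt.PauseSpec(pause_codon="GTG", pause_offset=15,
                                      fold_enrichment=4.0, seed=6))
        ctrl = vt.generate_rpf_dataset(small_genes, vt.PauseSpec(seed=7))
        occ = vt.codon_occupancy(kd, ctrl, cds_map)
        a_site = occ[occ.offset == 15].set_index("codon")
        assert a_site["z_shift"].abs().idxmax() == "GTG"

    def test_offset_beyond_read_length_rejected(self, small_genes):
        genes = small_genes[:3]
        ds = vt.generate_rpf_dataset(genes, vt.PauseSpec(seed=8))
        cds_map = {r.transcript_id: r.sequence for r in genes}
        with pytest.raises(ValueError, match="offset"):
            vt.codon_occupancy(ds, ds, cds_map, offsets=(40,))


class TestStratifyFc:
    def test_stratum_sizes(self, small_genes, small_aa_background):
        eff = vt.EffectSpec(amino_acid="V", mean_shift=-0.8, n_significant=40, seed=9)
        tab = vt.generate_fc_table(small_genes, eff)
        res = vt.stratify_fc(tab, small_aa_background, "V")
        assert len(res.top_genes) == len(res.bottom_genes) == 10  # ceil(0.25*40)
        assert not set(res.top_genes) & set(res.bottom_genes)

    def test_planted_valine_shift_detected(self, small_genes, small_aa_background):
        eff = vt.EffectSpec(amino_acid="V", mean_shift=-0.8, noise_sd=0.3,
                            n_significant=40, seed=10)
        tab = vt.generate_fc_table(small_genes, eff)
        assert vt.stratify_fc(tab, small_aa_background, "V").p < 0.01

    def test_all_equal_fc_gives_p_one(self, small_aa_background):
        genes = sorted(small_aa_background.universe)
        tab = pd.DataFrame({"gene_id": genes, "log2fc": 0.5, "significant": True})
        res = vt.stratify_fc(tab, small_aa_background, "V")
        assert res.t_stat == 0.0 and res.p == 1.0

    def test_invariant_to_gene_order(self, small_genes, small_aa_background):
        eff = vt.EffectSpec(amino_acid="V", mean_shift=-0.5, n_significant=30, seed=11)
        tab = vt.generate_fc_table(small_genes, eff)
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = vt.stratify_fc(tab, small_aa_background, "V")
        r2 = vt.stratify_fc(shuffled, small_aa_background, "V")
        assert r1.top_genes == r2.top_genes
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_too_few_significant_genes_rejected(self, small_aa_background):
        genes = sorted(small_aa_background.universe)[:3]
        tab = pd.DataFrame({"gene_id": genes, "log2fc": [0.1, 0.2, 0.3],
                            "significant": True})
        with pytest.raises(ValueError, match="at least 4"):
            vt.stratify_fc(tab, small_aa_background, "V")


class TestCandidateFcHeatmap:
    def test_missing_gene_flagged_na(self):
        tabs = {
            "ribo": pd.DataFrame({"gene_id": ["A", "B"], "log2fc": [-1.0, -2.0],
                                  "significant": [True, False]}),
            "poly": pd.DataFrame({"gene_id": ["A"], "log2fc": [-0.5],
                                  "significant": [True]}),
        }
        fc, sig = vt.candidate_fc_heatmap(tabs, ["A", "B"])
        assert np.isnan(fc.at["B", "poly"]) and not sig.at["B", "poly"]
        assert fc.at["A", "ribo"] == -1.0

    def test_single_gene_single_table(self):
        tabs = {"t": pd.DataFrame({"gene_id": ["X"], "log2fc": [0.7], "significant": [True]})}
        fc, sig = vt.candidate_fc_heatmap(tabs, ["X"])
        assert fc.shape == (1, 1) and fc.at["X", "t"] == 0.7 and sig.at["X", "t"]
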