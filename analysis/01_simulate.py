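#!/usr/bin/env python
"""Generate the synthetic study inputs every later analysis step consumes.

Builds the 1,000-gene coding transcriptome with a 50-gene GTG-biased set,
ribosome/polysome differential tables with the valine translation defect,
footprint datasets with and without the A-site GTG pause, tRNA isodecoder
counts with the Val-CAC doubling, and writes the bulky raw files under
scratch/data/ (regenerable) plus a compact summary under results/.
"""

import sys
from pathlib import Path

import pandas as pd

import valtrans as vt
from valtrans import io as vio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    spec = vt.TranscriptomeSpec(
        n_genes=1000, seed=SEED,
        planted_sets=(vt.PlantedSet("gtg_biased", 0.05, "GTG", 4.0),))
    genes = vt.generate_transcriptome(spec)
    planted = vt.planted_gene_ids(spec)["gtg_biased"]
    vio.write_cds_fasta(genes, DATA / "transcriptome.fasta")
    (DATA / "planted_genes.txt").write_text("\n".join(planted) + "\n")

    ribo_fc = vt.generate_fc_table(genes, vt.EffectSpec(
        amino_acid="V", mean_shift=-0.5, noise_sd=0.3, n_significant=200,
        seed=SEED + 1))
    poly_fc = vt.generate_fc_table(genes, vt.EffectSpec(
        amino_acid="V", mean_shift=-0.5, noise_sd=0.3, n_significant=200,
        seed=SEED + 2))
    vio.write_table(ribo_fc, DATA / "ribo_fc.tsv")
    vio.write_table(poly_fc, DATA / "poly_fc.tsv")

    kd = vt.generate_rpf_dataset(genes, vt.PauseSpec(
        pause_codon="GTG", pause_offset=15, fold_enrichment=4.0,
        seed=SEED + 10), "kd")
    ctrl = vt.generate_rpf_dataset(genes, vt.PauseSpec(
        fold_enrichment=1.0, seed=SEED + 11), "ctrl")
    vio.write_table(kd.reads, DATA / "rpf_kd.tsv")
    vio.write_table(ctrl.reads, DATA / "rpf_ctrl.tsv")

    trna_counts, conditions = vt.generate_trna_counts(
        planted=[("V", "CAC", 2.0)], seed=SEED + 20)
    vio.write_table(trna_counts, DATA / "trna_counts.tsv")
    pd.DataFrame(conditions.items(), columns=["sample_id", "condition"]).to_csv(
        DATA / "trna_conditions.tsv", sep="\t", index=False)

    lengths = pd.Series([len(r.sequence) // 3 for r in genes])
    summary = pd.DataFrame([
        {"quantity": "n_genes", "value": len(genes)},
        {"quantity": "planted_gtg_genes", "value": len(planted)},
        {"quantity": "median_cds_codons", "value": lengths.median()},
        {"quantity": "ribo_fc_significant", "value": int(ribo_fc["significant"].sum())},
        {"quantity": "rpf_reads_per_condition", "value": kd.total_reads},
        {"quantity": "trna_isodecoders", "value": len(trna_counts)},
        {"quantity": "seed", "value": SEED},
    ])
    summary.to_csv(RESULTS / "simulation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nraw inputs -> {DATA}/, summary -> {RESULTS}/simulation_summary.tsv")


if __name__ == "__main__":
    main()
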