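#!/usr/bin/env python
"""Ribosome-footprint statistics: metagene, site occupancy, stratified FC.

Computes the metagene density profile of the control footprints, the
E/P/A-site differential codon occupancy between the pause-planted and
control datasets, and the valine/leucine/isoleucine content-stratified
fold-change comparison of the ribosome differential table.  Expected
picture: flat metagene near 1, GTG the top |z| codon at the A site only,
and a valine-specific stratified difference.
"""

from pathlib import Path

import pandas as pd

import valtrans as vt
from valtrans import io as vio
from valtrans.codon_content import build_background, content_matrix
from valtrans.ribo import RpfDataset

DATA = Path("scratch/data")
RESULTS = Path("results")


def load_dataset(reads_path, genes, condition):
    tx = pd.DataFrame([
        {"transcript_id": r.transcript_id, "length": len(r.sequence),
         "cds_start": 0, "cds_end": len(r.sequence)}
        for r in genes
    ])
    return RpfDataset(tx, vio.read_rpf_table(reads_path), condition)


def main() -> None:
    genes = vio.read_cds_fasta(DATA / "transcriptome.fasta")
    cds_map = {r.transcript_id: r.sequence for r in genes}
    kd = load_dataset(DATA / "rpf_kd.tsv", genes, "kd")
    ctrl = load_dataset(DATA / "rpf_ctrl.tsv", genes, "ctrl")

    prof = vt.metagene(ctrl, n_cds_bins=50, utr_window_nt=0)
    pd.DataFrame({"bin": range(50), "density": prof.cds}).to_csv(
        RESULTS / "metagene_cds.tsv", sep="\t", index=False)
    print(f"metagene: {prof.n_transcripts} transcripts, "
          f"CDS density mean {prof.cds.mean():.3f} (uniform coverage -> 1)")

    occ = vt.codon_occupancy(kd, ctrl, cds_map)
    vio.write_table(occ, RESULTS / "codon_occupancy.tsv")
    print("\n== top |z| codon per site ==")
    for o, grp in occ.groupby("offset"):
        top = grp.loc[grp["z_shift"].abs().idxmax()]
        print(f"offset {o:2d} ({top.site} site): {top.codon} z={top.z_shift:+.2f}")

    ribo_fc = vio.read_fc_table(DATA / "ribo_fc.tsv")
    aa_bg = build_background(
        content_matrix(vt.select_longest_transcript(genes), "aa"), "aa")
    rows = []
    for aa, name in (("V", "valine"), ("L", "leucine"), ("I", "isoleucine")):
        res = vt.stratify_fc(ribo_fc, aa_bg, aa)
        rows.append({"amino_acid": name, "n_top": len(res.top_genes),
                     "n_bottom": len(res.bottom_genes),
                     "t_stat": res.t_stat, "p": res.p})
    strat = pd.DataFrame(rows)
    strat.to_csv(RESULTS / "stratified_fc.tsv", sep="\t", index=False)
    print("\n== content-stratified fold-change comparison ==")
    print(strat.to_string(index=False))
    print(f"\ntables -> {RESULTS}/metagene_cds.tsv, codon_occupancy.tsv, stratified_fc.tsv")


if __name__ == "__main__":
    main()
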