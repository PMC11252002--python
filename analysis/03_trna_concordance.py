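#!/usr/bin/env python
"""tRNA differential expression and concordance with codon enrichment.

Aggregates the simulated isodecoder counts to isoacceptor and
alloisoacceptor level, tests RES-vs-SENS differences, and overlays the
isoacceptor calls with the codon-level enrichment table from step 02.
Expected picture: Val-CAC up (the planted doubling), and the GTG
enrichment concordant with it through exact codon-anticodon pairing.
"""

from pathlib import Path

import valtrans as vt
from valtrans import io as vio

DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    counts = vio.read_trna_counts(DATA / "trna_counts.tsv")
    cond = dict(vio.read_table(DATA / "trna_conditions.tsv",
                               required=("sample_id", "condition"))
                .set_index("sample_id")["condition"])

    diffs = {}
    for level in ("iso", "allo"):
        agg = vt.aggregate(counts, cond, level=level)
        diff = vt.differential(agg, cond)
        diffs[level] = diff
        vio.write_table(diff, RESULTS / f"trna_differential_{level}.tsv")
        called = diff[diff["direction"] != "none"]
        label = "isoacceptor" if level == "iso" else "alloisoacceptor"
        print(f"== {label}: {len(called)} differential key(s) ==")
        cols = (["amino_acid", "anticodon"] if level == "iso" else ["amino_acid"])
        print(called[cols + ["log2fc", "p", "direction"]].to_string(index=False))

    enrichment = vio.read_table(RESULTS / "enrichment_codon.tsv",
                                required=("feature", "direction", "significant"))
    conc = vt.concordance(enrichment, diffs["iso"], level="iso")
    vio.write_table(conc, RESULTS / "concordance_codon_isoacceptor.tsv")
    print(f"\n== concordance: {int(conc['concordant'].sum())} concordant feature(s) ==")
    print(conc[conc["concordant"]].to_string(index=False))
    print(f"\ntables -> {RESULTS}/trna_differential_*.tsv, concordance_codon_isoacceptor.tsv")


if __name__ == "__main__":
    main()
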