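"""Ribosome-profiling downstream statistics.

Three analyses sit here, each consuming ribosome-protected-fragment (RPF)
5'-end positions in transcript coordinates:

* a metagene profile of intra-gene normalized footprint density over the CDS
  (plus fixed-width UTR windows), to check for global or start/stop-local
  changes in ribosome density;
* differential per-codon occupancy between two conditions at fixed offsets
  from the read 5' end (9, 12 and 15 nt, conventionally the E, P and A
  sites of an ~30-nt footprint), the core of a Diricore-style analysis;
* codon-content-stratified comparison of fold changes: do transcripts in
  the top quartile of, say, valine content shift differently from the
  bottom quartile in ribosome or polysome sequencing?
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_content import CodonBackground, rank_bottom_fraction, rank_top_fraction
from .genetic_code import SENSE_CODONS, STOP_CODONS

logger = logging.getLogger(__name__)

#: nt from the RPF 5' end to the first nt of the E/P/A-site codons
DEFAULT_OFFSETS: tuple[int, ...] = (9, 12, 15)
SITE_LABELS: dict[int, str] = {9: "E", 12: "P", 15: "A"}

#: pseudo-fraction guarding log ratios of zero-count codons
EPSILON = 1e-6


@dataclass
class RpfDataset:
    """Footprint 5'-end positions for one condition.

    ``transcripts``: columns transcript_id, length, cds_start, cds_end
    (0-based, half-open, transcript coordinates).
    ``reads``: columns transcript_id, pos (5'-end), read_length, count.
    """

    transcripts: pd.DataFrame
    reads: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        tx = self.transcripts.set_index("transcript_id")
        joined = self.reads.join(tx, on="transcript_id")
        if (joined["pos"] < 0).any() or (joined["pos"] + joined["read_length"] > joined["length"]).any():
            raise ValueError("read positions outside transcript bounds")
        if (self.reads["count"] < 1).any():
            raise ValueError("read counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return int(self.reads["count"].sum())


@dataclass
class MetageneProfile:
    """Average intra-gene normalized RPF density around and across the CDS."""

    utr5: np.ndarray  # per-nt, positions -utr_window .. -1 relative to CDS start
    cds: np.ndarray  # n_cds_bins values
    utr3: np.ndarray  # per-nt, positions 0 .. utr_window-1 past the stop
    n_transcripts: int
    n_excluded: int = 0


def metagene(dataset: RpfDataset, n_cds_bins: int = 100, utr_window_nt: int = 50) -> MetageneProfile:
    """Metagene density profile of 5'-end RPF density.

    Each transcript's per-nucleotide density is divided by its own mean CDS
    density, the CDS is rescaled to ``n_cds_bins``, UTR windows are kept in
    nucleotides, and transcripts are averaged with equal weight, so the
    profile is invariant to per-transcript sequencing depth and a
    uniformly covered dataset gives a flat profile of 1.0.
    """
    utr5_sum = np.zeros(utr_window_nt)
    cds_sum = np.zeros(n_cds_bins)
    utr3_sum = np.zeros(utr_window_nt)
    n_used = 0
    n_excluded = 0
    reads_by_tx = dict(tuple(dataset.reads.groupby("transcript_id")))
    for row in dataset.transcripts.itertuples(index=False):
        tx_reads = reads_by_tx.get(row.transcript_id)
        if tx_reads is None:
            n_excluded += 1
            continue
        cds_len = row.cds_end - row.cds_start
        density = np.zeros(row.length)
        np.add.at(density, tx_reads["pos"].to_numpy(), tx_reads["count"].to_numpy(dtype=float))
        mean_cds = density[row.cds_start : row.cds_end].mean()
        if mean_cds == 0:
            n_excluded += 1
            continue
        norm = density / mean_cds
        # CDS: mean normalized density per bin
        pos_in_cds = np.arange(cds_len)
        bins = (pos_in_cds * n_cds_bins) // cds_len
        binned = np.bincount(bins, weights=norm[row.cds_start : row.cds_end], minlength=n_cds_bins)
        per_bin_n = np.bincount(bins, minlength=n_cds_bins)
        cds_sum += binned / np.maximum(per_bin_n, 1)
        # UTR windows, per-nt; transcript may not cover the full window
        for off in range(utr_window_nt):
            p5 = row.cds_start - utr_window_nt + off
            if 0 <= p5 < row.length:
                utr5_sum[off] += norm[p5]
            p3 = row.cds_end + off
            if 0 <= p3 < row.length:
                utr3_sum[off] += norm[p3]
        n_used += 1
    if n_used == 0:
        raise ValueError("no transcript with CDS reads; cannot build metagene profile")
    return MetageneProfile(
        utr5=utr5_sum / n_used,
        cds=cds_sum / n_used,
        utr3=utr3_sum / n_used,
        n_transcripts=n_used,
        n_excluded=n_excluded,
    )


def codon_occupancy(
    dataset_a: RpfDataset,
    dataset_b: RpfDataset,
    cds_map: dict[str, str],
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """Differential per-codon RPF occupancy at fixed 5'-end offsets.

    For each offset o, every read is assigned the codon containing
    nucleotide (5'end + o); out-of-frame positions fall into the codon
    spanning them.  Count-weighted codon fractions are computed per
    condition, and per-codon shifts are log2((f_A+eps)/(f_B+eps)),
    standardized across codons into z-scores per offset.

    Returns one row per (offset, codon) over the 61 sense codons, with
    columns offset, site, codon, fraction_a, fraction_b, log2_shift,
    z_shift.
    """
    min_len = int(min(dataset_a.reads["read_length"].min(), dataset_b.reads["read_length"].min()))
    for o in offsets:
        if o >= min_len:
            raise ValueError(f"offset {o} is beyond the shortest read length ({min_len} nt)")

    def fractions(ds: RpfDataset) -> dict[int, pd.Series]:
        tx_info = ds.transcripts.set_index("transcript_id")
        out: dict[int, pd.Series] = {}
        for o in offsets:
            counts = pd.Series(0.0, index=list(SENSE_CODONS) + list(STOP_CODONS))
            for tid, grp in ds.reads.groupby("transcript_id"):
                seq = cds_map[tid]
                cds_start = int(tx_info.at[tid, "cds_start"])
                cds_end = int(tx_info.at[tid, "cds_end"])
                nt = grp["pos"].to_numpy() + o
                ok = (nt >= cds_start) & (nt < cds_end)
                idx = (nt[ok] - cds_start) // 3
                w = grp["count"].to_numpy(dtype=float)[ok]
                for i, wt in zip(idx, w):
                    codon = seq[3 * i : 3 * i + 3]
                    counts[codon] += wt
            # fractions are over sense codons; footprints whose site codon is
            # a stop (reads overhanging the very end of the ORF) are dropped
            counts = counts[list(SENSE_CODONS)]
            total = counts.sum()
            if total == 0:
                raise ValueError(f"no in-CDS reads at offset {o} for condition {ds.condition!r}")
            out[o] = counts / total
        return out

    frac_a = fractions(dataset_a)
    frac_b = fractions(dataset_b)
    rows = []
    for o in offsets:
        fa = frac_a[o].reindex(SENSE_CODONS)
        fb = frac_b[o].reindex(SENSE_CODONS)
        shift = np.log2((fa + EPSILON) / (fb + EPSILON))
        z = (shift - shift.mean()) / shift.std(ddof=0)
        for codon in SENSE_CODONS:
            rows.append({
                "offset": o, "site": SITE_LABELS.get(o, str(o)), "codon": codon,
                "fraction_a": fa[codon], "fraction_b": fb[codon],
                "log2_shift": shift[codon], "z_shift": z[codon],
            })
    return pd.DataFrame(rows)


@dataclass
class StratifiedFcResult:
    """Fold changes of content-extreme strata and their comparison."""

    amino_acid: str
    top_genes: list[str]
    bottom_genes: list[str]
    top_fc: np.ndarray = field(repr=False)
    bottom_fc: np.ndarray = field(repr=False)
    t_stat: float = float("nan")
    p: float = float("nan")


def stratify_fc(
    diff: pd.DataFrame,
    background: CodonBackground,
    amino_acid: str,
    significant_only: bool = True,
    frac: float = 0.25,
) -> StratifiedFcResult:
    """Compare log2FC between content-extreme quartiles of a gene set.

    Restricts to significant genes (when ``significant_only``), ranks them
    by the amino acid's content in the supplied background, takes the top
    and bottom ceil(frac*n) strata, and runs a two-tailed pooled t-test
    between their log2 fold changes.  Quartiles are recomputed within the
    analysed (significant) set, not reused from the transcriptome-wide
    membership.
    """
    if amino_acid not in background.content.columns:
        raise ValueError(f"{amino_acid!r} not a feature of the background (level={background.level})")
    sub = diff[diff["significant"]] if significant_only else diff
    sub = sub[sub["gene_id"].isin(background.content.index)]
    if len(sub) < 4:
        raise ValueError(f"only {len(sub)} usable genes; need at least 4 to stratify")
    content = background.content.loc[sub["gene_id"], amino_acid]
    top = rank_top_fraction(content, frac)
    bottom = rank_bottom_fraction(content, frac)
    # a gene cannot sit in both strata; drop the overlap from both (ties)
    overlap = top & bottom
    top, bottom = top - overlap, bottom - overlap
    fc = sub.set_index("gene_id")["log2fc"]
    top_genes, bottom_genes = sorted(top), sorted(bottom)
    top_fc = fc.loc[top_genes].to_numpy(dtype=float)
    bottom_fc = fc.loc[bottom_genes].to_numpy(dtype=float)
    if np.ptp(np.concatenate([top_fc, bottom_fc])) == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(top_fc, bottom_fc, equal_var=True)
    return StratifiedFcResult(
        amino_acid=amino_acid,
        top_genes=top_genes, bottom_genes=bottom_genes,
        top_fc=top_fc, bottom_fc=bottom_fc,
        t_stat=float(t_stat), p=float(p),
    )


def candidate_fc_heatmap(
    diff_tables: dict[str, pd.DataFrame],
    genes: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2FC matrix (genes x tables) plus a matching significance-flag matrix.

    Genes absent from a table get NaN fold change and a False flag.
    """
    present = set()
    for tab in diff_tables.values():
        present |= set(tab["gene_id"])
    missing = [g for g in genes if g not in present]
    if missing:
        raise ValueError(f"gene(s) absent from every table: {missing}")
    fc = pd.DataFrame(index=genes, columns=list(diff_tables), dtype=float)
    sig = pd.DataFrame(False, index=genes, columns=list(diff_tables))
    for name, tab in diff_tables.items():
        t = tab.set_index("gene_id")
        for g in genes:
            if g in t.index:
                fc.at[g, name] = t.at[g, "log2fc"]
                sig.at[g, name] = bool(t.at[g, "significant"])
    return fc, sig
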