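"""Synthetic inputs with planted effects for every pipeline stage.

The generators emulate the statistical structure the downstream analyses
assume — a transcriptome with codon-usage heterogeneity, differential
tables with an amino-acid-stratified translation defect, footprint datasets
with a codon-specific ribosome pause, tRNA isodecoder count tables with a
planted isoacceptor shift, and count matrices with signature-high samples —
so the whole pipeline is testable without any sequencing download.

Every generator is a pure function of its spec, including the seed; the
global seed is split into per-gene (or per-transcript / per-isodecoder)
substreams by index, so output is reproducible independent of iteration
order.  Codons are sampled i.i.d. per position from a weight vector over
the 61 sense codons; a planted bias multiplies the target codon's sampling
weight, which keeps every sequence a valid single-stop ORF and makes the
bias magnitude directly interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codon_content import (
    CdsRecord,
    content_matrix,
    rank_bottom_fraction,
    rank_top_fraction,
)
from .genetic_code import AMINO_ACIDS, SENSE_CODONS, STOP_CODONS, codon_to_anticodon
from .ribo import RpfDataset

logger = logging.getLogger(__name__)

# substream tags keeping independent generators off each other's streams
_TAG_ASSIGN = 1_000_003
_TAG_LENGTH = 1_000_033
_TAG_FC = 2_000_003
_TAG_RPF = 3_000_017
_TAG_TRNA = 4_000_037
_TAG_EXPR = 5_000_011


def _rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, path)])


@dataclass(frozen=True)
class PlantedSet:
    """A named gene subset whose sampling weight for one codon is biased."""

    name: str
    gene_fraction: float
    codon: str
    bias_multiplier: float

    def __post_init__(self) -> None:
        if not 0 < self.gene_fraction < 1:
            raise ValueError("gene_fraction must be in (0, 1)")
        if self.bias_multiplier <= 0:
            raise ValueError("bias_multiplier must be > 0")
        if self.codon not in SENSE_CODONS:
            raise ValueError(f"{self.codon!r} is not a sense codon")


@dataclass(frozen=True)
class TranscriptomeSpec:
    """Parameters of the synthetic coding transcriptome.

    Defaults model a desk-scale stand-in for a human transcriptome
    background: 1,000 genes of 100-600 codons with uniform base codon
    weights (``base_codon_weights=None``).
    """

    n_genes: int = 1000
    cds_length_range: tuple[int, int] = (100, 600)  # codons, inclusive
    base_codon_weights: dict[str, float] | None = None
    planted_sets: tuple[PlantedSet, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        lo, hi = self.cds_length_range
        if lo < 3 or hi < lo:
            raise ValueError("invalid cds_length_range")
        if self.base_codon_weights is not None:
            w = np.array([self.base_codon_weights.get(c, 0.0) for c in SENSE_CODONS])
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("base_codon_weights must be non-negative with positive sum")


def planted_gene_ids(spec: TranscriptomeSpec) -> dict[str, list[str]]:
    """Deterministic planted-set membership (set name -> gene ids)."""
    all_ids = [_gene_id(i) for i in range(spec.n_genes)]
    out = {}
    for k, ps in enumerate(spec.planted_sets):
        rng = _rng(spec.seed, _TAG_ASSIGN, k)
        n = int(round(ps.gene_fraction * spec.n_genes))
        out[ps.name] = sorted(rng.choice(all_ids, size=n, replace=False))
    return out


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def generate_transcriptome(spec: TranscriptomeSpec) -> list[CdsRecord]:
    """Simulate one CDS per gene.

    Every sequence starts with ATG, ends with a single stop codon, and has
    internal codons drawn i.i.d. from the (possibly planted-biased) weight
    vector; its length in codons is uniform over ``cds_length_range``.
    """
    base = np.array(
        [1.0] * len(SENSE_CODONS)
        if spec.base_codon_weights is None
        else [spec.base_codon_weights.get(c, 0.0) for c in SENSE_CODONS]
    )
    if base.sum() <= 0:
        raise ValueError("zero-weight codon alphabet")
    membership = planted_gene_ids(spec)
    codon_idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    lo, hi = spec.cds_length_range
    records = []
    for i in range(spec.n_genes):
        gid = _gene_id(i)
        rng = _rng(spec.seed, _TAG_LENGTH, i)
        n_codons = int(rng.integers(lo, hi + 1))
        w = base.copy()
        for ps in spec.planted_sets:
            if gid in membership[ps.name]:
                w[codon_idx[ps.codon]] *= ps.bias_multiplier
        p = w / w.sum()
        internal = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=p)
        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
        seq = "ATG" + "".join(SENSE_CODONS[j] for j in internal) + stop
        records.append(CdsRecord(gene_id=gid, transcript_id=f"{gid}.1", sequence=seq))
    return records


@lru_cache(maxsize=8)
def _aa_content(genes: tuple[CdsRecord, ...]) -> pd.DataFrame:
    """Amino-acid content matrix, cached across repeated-seed simulations."""
    return content_matrix(list(genes), level="aa")


@dataclass(frozen=True)
class EffectSpec:
    """A planted log2 fold-change shift on one amino-acid content stratum."""

    amino_acid: str = "V"
    stratum: str = "top"  # which content quartile carries the shift
    mean_shift: float = -0.5
    noise_sd: float = 0.3
    n_significant: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amino_acid not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid {self.amino_acid!r}")
        if self.stratum not in ("top", "bottom"):
            raise ValueError("stratum must be 'top' or 'bottom'")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def generate_fc_table(genes: list[CdsRecord], effect: EffectSpec) -> pd.DataFrame:
    """Differential table with a content-stratified planted shift.

    Genes in the target content quartile draw log2FC from
    Normal(mean_shift, noise_sd); all others from Normal(0, noise_sd).
    Two-sided normal p-values accompany the fold changes and the
    ``n_significant`` largest |log2FC| are flagged significant.
    """
    if effect.n_significant > len(genes):
        raise ValueError("n_significant exceeds the number of genes")
    aa_content = _aa_content(tuple(genes))[effect.amino_acid]
    pick = rank_top_fraction if effect.stratum == "top" else rank_bottom_fraction
    stratum = pick(aa_content)
    rows = []
    for i, rec in enumerate(genes):
        rng = _rng(effect.seed, _TAG_FC, i)
        mu = effect.mean_shift if rec.gene_id in stratum else 0.0
        fc = float(rng.normal(mu, effect.noise_sd))
        rows.append({"gene_id": rec.gene_id, "log2fc": fc})
    tab = pd.DataFrame(rows)
    z = tab["log2fc"].abs() / effect.noise_sd
    tab["p"] = 2 * stats.norm.sf(z)
    tab["p_adj"] = multipletests(tab["p"], method="fdr_bh")[1]
    cutoff = tab["log2fc"].abs().nlargest(effect.n_significant)
    tab["significant"] = tab.index.isin(cutoff.index)
    return tab


@dataclass(frozen=True)
class PauseSpec:
    """A codon-specific ribosome pause planted at one 5'-end offset."""

    pause_codon: str = "GTG"
    pause_offset: int = 15
    fold_enrichment: float = 1.0
    read_length: int = 30
    reads_per_transcript: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_enrichment < 1:
            raise ValueError("fold_enrichment must be >= 1")
        if self.pause_offset + 3 > self.read_length:
            raise ValueError("pause_offset + 3 must fit within read_length")
        if self.pause_codon not in SENSE_CODONS:
            raise ValueError(f"{self.pause_codon!r} is not a sense codon")


def generate_rpf_dataset(genes: list[CdsRecord], pause: PauseSpec, condition: str = "") -> RpfDataset:
    """Place footprint 5' ends over each CDS with an optional planted pause.

    Positions are uniform over the valid range, then reweighted so reads
    whose codon at ``pause_offset`` equals ``pause_codon`` are
    ``fold_enrichment`` times as likely.  Transcripts shorter than one read
    are skipped with a warning.
    """
    tx_rows, read_rows = [], []
    for i, rec in enumerate(genes):
        length = len(rec.sequence)
        if length < pause.read_length:
            logger.warning("%s skipped: %d nt < read length %d", rec.transcript_id, length, pause.read_length)
            continue
        tx_rows.append({
            "transcript_id": rec.transcript_id, "length": length,
            "cds_start": 0, "cds_end": length,
        })
        n_pos = length - pause.read_length + 1
        positions = np.arange(n_pos)
        site = positions + pause.pause_offset
        codon_idx = site // 3
        codons = np.array([rec.sequence[3 * j : 3 * j + 3] for j in codon_idx])
        w = np.where(codons == pause.pause_codon, pause.fold_enrichment, 1.0)
        rng = _rng(pause.seed, _TAG_RPF, i)
        draws = rng.choice(n_pos, size=pause.reads_per_transcript, p=w / w.sum())
        pos, counts = np.unique(draws, return_counts=True)
        for p, c in zip(pos, counts):
            read_rows.append({
                "transcript_id": rec.transcript_id, "pos": int(p),
                "read_length": pause.read_length, "count": int(c),
            })
    if not tx_rows:
        raise ValueError("every transcript was shorter than the read length")
    return RpfDataset(
        transcripts=pd.DataFrame(tx_rows),
        reads=pd.DataFrame(read_rows),
        condition=condition,
    )


def generate_trna_counts(
    planted: list[tuple[str, str, float]] = (),
    n_isodecoders_per_anticodon: int = 2,
    replicates: int = 3,
    base_mean: float = 1000.0,
    noise_sigma: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Isodecoder count table for two conditions (SENS vs RES).

    One anticodon per sense codon (exact reverse complement), each with
    ``n_isodecoders_per_anticodon`` isodecoder genes.  Baseline means are
    lognormal around ``base_mean``; counts carry multiplicative lognormal
    noise (sigma in log space).  Each ``planted`` entry
    (amino_acid, anticodon, fold) scales that anticodon's isodecoder means
    by ``fold`` in the RES condition.

    Returns (table, condition map); the table has isodecoder_id,
    amino_acid, anticodon plus one integer column per sample.
    """
    if replicates < 2:
        raise ValueError("differential testing requires >= 2 replicates per condition")
    for _, _, fold in planted:
        if fold <= 0:
            raise ValueError("planted folds must be > 0")
    planted_map = {(aa, ac): fold for aa, ac, fold in planted}
    from .genetic_code import CODON_TO_AA

    samples = [f"SENS_{r+1}" for r in range(replicates)] + [f"RES_{r+1}" for r in range(replicates)]
    conditions = {s: ("SENS" if s.startswith("SENS") else "RES") for s in samples}
    rows = []
    idx = 0
    for codon in SENSE_CODONS:
        aa = CODON_TO_AA[codon]
        anticodon = codon_to_anticodon(codon)
        fold = planted_map.get((aa, anticodon), 1.0)
        for k in range(n_isodecoders_per_anticodon):
            rng = _rng(seed, _TAG_TRNA, idx)
            mean = base_mean * rng.lognormal(0.0, 0.5)
            row = {
                "isodecoder_id": f"tRNA-{aa}-{anticodon}-{k+1}",
                "amino_acid": aa,
                "anticodon": anticodon,
            }
            for s in samples:
                mu = mean * (fold if conditions[s] == "RES" else 1.0)
                row[s] = int(round(mu * rng.lognormal(0.0, noise_sigma)))
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows), conditions


def generate_expression_matrix(
    n_genes: int,
    n_samples: int,
    signature: list[str],
    n_high_samples: int,
    shift: float,
    seed: int = 0,
    base_mean: float = 500.0,
    dispersion: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene-by-sample negative-binomial count matrix with signature-high samples.

    Gene base means are lognormal around ``base_mean``; counts are NB with
    the given dispersion.  In the ``n_high_samples`` designated "high"
    samples, signature genes' expected counts are multiplied by 2**shift.
    Signature gene ids must belong to the generated universe
    (G00000..G<n-1>).

    Returns (matrix indexed genes x samples, list of high sample ids).
    """
    gene_ids = [_gene_id(i) for i in range(n_genes)]
    unknown = set(signature) - set(gene_ids)
    if unknown:
        raise ValueError(f"signature gene(s) outside universe: {sorted(unknown)[:3]}")
    if n_high_samples > n_samples:
        raise ValueError("n_high_samples exceeds n_samples")
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    rng_assign = _rng(seed, _TAG_EXPR, 0)
    high = sorted(rng_assign.choice(sample_ids, size=n_high_samples, replace=False))
    sig_set = set(signature)
    nb_n = 1.0 / dispersion
    mat = np.zeros((n_genes, n_samples), dtype=int)
    for i, gid in enumerate(gene_ids):
        rng = _rng(seed, _TAG_EXPR, 1, i)
        mean = base_mean * rng.lognormal(0.0, 1.0)
        mult = 2.0 ** shift if gid in sig_set else 1.0
        for j, sid in enumerate(sample_ids):
            mu = mean * (mult if sid in high else 1.0)
            mat[i, j] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
    return pd.DataFrame(mat, index=gene_ids, columns=sample_ids), high
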