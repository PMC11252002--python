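"""Per-gene codon / amino-acid content and gene-set enrichment testing.

The analysis asks whether a gene set (for example, the transcripts encoding
proteins upregulated in therapy-resistant cells) is enriched for particular
codons or amino acids relative to the transcriptome.  A transcript counts as
"high" for a feature when its content lies in the top quartile of that
feature's transcriptome-wide distribution; enrichment of a gene set is then a
2x2 Pearson chi-squared test of quartile membership inside versus outside the
set.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetic_code import AMINO_ACIDS, CODON_TO_AA, SENSE_CODONS, STOP_CODONS

logger = logging.getLogger(__name__)

#: fraction of the transcriptome defining quartile membership
MEMBER_FRACTION = 0.25

#: records with more than this fraction of ambiguous codons are dropped
MAX_SKIPPED_FRACTION = 0.05


class CdsValidationError(ValueError):
    """A sequence does not validate as a CDS."""


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence with lazily computed codon and amino-acid counts.

    ``aa_counts`` excludes stop codons (they encode no amino acid), so at
    amino-acid level the denominator is the number of sense codons.
    """

    gene_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise CdsValidationError(
                f"CDS length of {self.gene_id}|{self.transcript_id} "
                f"({len(self.sequence)} nt) is not divisible by 3"
            )

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def codon_counts(self) -> dict[str, int]:
        return count_codons(self.sequence, record_name=f"{self.gene_id}|{self.transcript_id}")

    @property
    def aa_counts(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for codon, n in self.codon_counts.items():
            aa = CODON_TO_AA.get(codon)
            if aa is not None:
                out[aa] += n
        return dict(out)

    @property
    def skipped_codons(self) -> int:
        """Number of frame-0 triplets containing non-ACGT characters."""
        seq = self.sequence
        return sum(
            1
            for i in range(0, len(seq), 3)
            if any(b not in "ACGT" for b in seq[i : i + 3])
        )


def count_codons(sequence: str, record_name: str = "<anonymous>") -> dict[str, int]:
    """Count non-overlapping frame-0 triplets of a CDS.

    Triplets containing characters outside ACGT (typically N) are skipped
    and the skip is logged; the returned counts therefore may total less
    than ``len(sequence)//3``.
    """
    if len(sequence) % 3 != 0:
        raise CdsValidationError(
            f"sequence length of {record_name} ({len(sequence)} nt) is not divisible by 3"
        )
    counts: Counter[str] = Counter()
    skipped = 0
    for i in range(0, len(sequence), 3):
        codon = sequence[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            skipped += 1
            continue
        counts[codon] += 1
    if skipped:
        logger.warning("%s: skipped %d ambiguous codon(s)", record_name, skipped)
    return dict(counts)


def select_longest_transcript(records: list[CdsRecord]) -> list[CdsRecord]:
    """Keep one transcript per gene: the longest, ties broken by transcript id.

    Mirrors the convention of representing each gene by its longest
    annotated CDS when computing codon frequencies.
    """
    by_gene: dict[str, CdsRecord] = {}
    for rec in records:
        cur = by_gene.get(rec.gene_id)
        if cur is None:
            by_gene[rec.gene_id] = rec
        else:
            key_new = (-len(rec.sequence), rec.transcript_id)
            key_cur = (-len(cur.sequence), cur.transcript_id)
            if key_new < key_cur:
                by_gene[rec.gene_id] = rec
    return [by_gene[g] for g in sorted(by_gene)]


def content_profile(record: CdsRecord, level: str = "codon") -> dict[str, float]:
    """Feature fractions of one CDS.

    The denominator counts sense codons only: the start codon is included,
    stop codons are excluded, so codon- and amino-acid-level fractions each
    sum to one over their alphabet.
    """
    if level not in ("codon", "aa"):
        raise ValueError(f"level must be 'codon' or 'aa', got {level!r}")
    codon_counts = record.codon_counts
    denom = sum(n for c, n in codon_counts.items() if c not in STOP_CODONS)
    if denom == 0:
        raise CdsValidationError(
            f"{record.gene_id}|{record.transcript_id}: no sense codons, cannot profile"
        )
    if level == "codon":
        return {c: codon_counts.get(c, 0) / denom for c in SENSE_CODONS}
    aa_counts = record.aa_counts
    return {a: aa_counts.get(a, 0) / denom for a in AMINO_ACIDS}


def content_matrix(records: list[CdsRecord], level: str = "codon") -> pd.DataFrame:
    """Gene-by-feature content fractions for a transcriptome.

    Records in which more than 5% of codons were skipped as ambiguous are
    dropped (and logged); rows are indexed by gene_id.
    """
    rows = {}
    dropped = 0
    for rec in records:
        if rec.n_codons > 0 and rec.skipped_codons / rec.n_codons > MAX_SKIPPED_FRACTION:
            logger.warning(
                "%s|%s dropped: %d/%d codons ambiguous",
                rec.gene_id, rec.transcript_id, rec.skipped_codons, rec.n_codons,
            )
            dropped += 1
            continue
        rows[rec.gene_id] = content_profile(rec, level)
    if not rows:
        raise CdsValidationError("no usable records after ambiguity filtering")
    if dropped:
        logger.warning("dropped %d record(s) with >%.0f%% ambiguous codons",
                       dropped, 100 * MAX_SKIPPED_FRACTION)
    features = list(SENSE_CODONS if level == "codon" else AMINO_ACIDS)
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=features).sort_index()


@dataclass
class CodonBackground:
    """Transcriptome-wide content distributions and top-quartile membership.

    ``members[f]`` holds the ceil(0.25*N) gene ids with the highest content
    of feature ``f`` (ties broken by gene id, ascending), where N is the
    universe size.
    """

    level: str
    content: pd.DataFrame  # genes x features
    members: dict[str, frozenset[str]] = field(repr=False)
    n_members: int

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.content.index)

    @property
    def features(self) -> list[str]:
        return list(self.content.columns)


def rank_top_fraction(values: pd.Series, frac: float = MEMBER_FRACTION) -> frozenset[str]:
    """Ids of the ceil(frac*N) highest values; ties broken by id ascending."""
    n = len(values)
    k = math.ceil(frac * n)
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return frozenset(order[:k])


def rank_bottom_fraction(values: pd.Series, frac: float = MEMBER_FRACTION) -> frozenset[str]:
    """Ids of the ceil(frac*N) lowest values; ties broken by id ascending."""
    n = len(values)
    k = math.ceil(frac * n)
    order = sorted(values.index, key=lambda g: (values[g], g))
    return frozenset(order[:k])


def build_background(content: pd.DataFrame, level: str = "codon") -> CodonBackground:
    """Build top-quartile membership sets per feature from a content matrix."""
    n = len(content)
    if n < 4:
        raise ValueError(f"background requires at least 4 genes, got {n}")
    members = {f: rank_top_fraction(content[f]) for f in content.columns}
    return CodonBackground(
        level=level,
        content=content,
        members=members,
        n_members=math.ceil(MEMBER_FRACTION * n),
    )


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Pearson chi-squared (1 df, no continuity correction) on [[a,b],[c,d]].

    Returns (chi2, p, low_expected).  Degenerate margins give (0, 1).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), bool((expected < 1).any())


def enrichment_test(
    gene_set: set[str],
    background: CodonBackground,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test a gene set for feature enrichment against the background.

    For each feature, the 2x2 contingency crosses set membership (in-set vs
    out-of-set; the query set is excluded from the outside margin) with
    top-quartile membership, and is tested with a Pearson chi-squared (1 df,
    no Yates correction).  Direction is the sign of the membership-fraction
    difference; rows with any expected cell below 1 carry ``low_expected``.
    Raw p-values drive the calls; BH-adjusted values are an extra column.
    """
    universe = background.universe
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    unknown = gene_set - universe
    if unknown:
        raise ValueError(f"{len(unknown)} gene(s) not in background universe, e.g. {sorted(unknown)[:3]}")
    outside = universe - gene_set
    n_set, n_bg = len(gene_set), len(outside)

    rows = []
    for feature in background.features:
        mem = background.members[feature]
        k_set = len(gene_set & mem)
        k_bg = len(mem) - k_set
        chi2, p, low_exp = _chi2_2x2(k_set, n_set - k_set, k_bg, n_bg - k_bg)
        frac_set = k_set / n_set
        frac_bg = k_bg / n_bg if n_bg else float("nan")
        significant = p < alpha
        if not significant or frac_set == frac_bg:
            direction = "none"
        elif frac_set > frac_bg:
            direction = "enriched"
        else:
            direction = "impoverished"
        rows.append({
            "feature": feature, "k_set": k_set, "n_set": n_set,
            "k_bg": k_bg, "n_bg": n_bg, "chi2": chi2, "p": p,
            "direction": direction, "significant": significant,
            "low_expected": low_exp,
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
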