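"""Translational-signature derivation, scoring and screen arithmetic.

A translational signature is a gene set whose members are downregulated at
the protein level while their mRNA is essentially unchanged (protein
log2FC below a negative cut, |mRNA log2FC| inside a window) and that
carry high content of a target amino acid (top-quartile membership in the
transcriptome background).  The module also provides the chi-squared
superposition test of the signature against ribosome/polysome calls, the
expression-matrix preprocessing (count filter, log-CPM), a single-sample
GSEA scorer for patient stratification, extreme-group selection, and the
relative-nuclear-fragmentation score used to read out drug
re-sensitization in cell-death assays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_content import _chi2_2x2

logger = logging.getLogger(__name__)

#: protein-level log2FC magnitude cut defining translation-driven change
PROTEIN_CUT = 0.32
#: mRNA log2FC window within which expression is "poorly impacted"
RNA_CUT = 1.0
#: default ssGSEA rank-weight exponent
SSGSEA_EXPONENT = 0.25
#: default extreme-group fraction
EXTREME_FRACTION = 0.15


def classify_translation_groups(
    pairs: pd.DataFrame,
    protein_cut: float = PROTEIN_CUT,
    rna_cut: float = RNA_CUT,
) -> pd.DataFrame:
    """Assign each gene one translation group from its (protein, mRNA) log2FCs.

    translation_down: |rna| < rna_cut and protein < -protein_cut;
    translation_up: |rna| < rna_cut and protein > +protein_cut;
    concordant: protein and mRNA both beyond their cuts with the same sign;
    everything else unclassified.  Genes missing either value are dropped
    and logged.
    """
    required = {"gene_id", "protein_log2fc", "rna_log2fc"}
    missing_cols = required - set(pairs.columns)
    if missing_cols:
        raise ValueError(f"missing column(s): {sorted(missing_cols)}")
    ok = pairs[["protein_log2fc", "rna_log2fc"]].notna().all(axis=1)
    if (~ok).any():
        logger.warning("dropped %d gene(s) with missing fold changes", int((~ok).sum()))
    out = pairs[ok].copy()
    prot = out["protein_log2fc"]
    rna = out["rna_log2fc"]
    flat_rna = rna.abs() < rna_cut
    group = pd.Series("unclassified", index=out.index)
    group[flat_rna & (prot < -protein_cut)] = "translation_down"
    group[flat_rna & (prot > protein_cut)] = "translation_up"
    group[~flat_rna & (prot.abs() > protein_cut) & (np.sign(prot) == np.sign(rna))] = "concordant"
    out["group"] = group
    return out


@dataclass
class TranslationSignature:
    """A derived signature gene set with its provenance."""

    genes: frozenset[str]
    protein_cut: float = PROTEIN_CUT
    rna_cut: float = RNA_CUT
    content_source: str = "top-quartile amino-acid membership"

    def __len__(self) -> int:
        return len(self.genes)


def derive_signature(
    classified: pd.DataFrame,
    content_members: frozenset[str] | set[str],
) -> TranslationSignature:
    """Signature = translation_down genes that are content-quartile members.

    ``content_members`` is the top-quartile membership set for the target
    amino acid from the transcriptome background.  An empty intersection is
    a valid (warned) outcome.
    """
    down = set(classified.loc[classified["group"] == "translation_down", "gene_id"])
    sig = frozenset(down & set(content_members))
    if not sig:
        logger.warning("signature is empty (translation_down n=%d, members n=%d)",
                       len(down), len(content_members))
    return TranslationSignature(genes=sig)


def superposition_test(
    signature: TranslationSignature | frozenset[str] | set[str],
    translation_calls: pd.DataFrame,
    direction: str = "down",
    alpha: float = 0.05,
) -> dict:
    """Chi-squared superposition of the signature with translation calls.

    2x2 of signature membership x translationally-regulated call (gene
    significant with log2fc in ``direction``), Pearson chi-squared with
    1 df and no continuity correction.  Returns the statistic, p-value,
    the contingency table and a degenerate-margin flag.
    """
    genes = signature.genes if isinstance(signature, TranslationSignature) else frozenset(signature)
    sign = -1 if direction == "down" else 1
    called = set(
        translation_calls.loc[
            translation_calls["significant"] & (np.sign(translation_calls["log2fc"]) == sign),
            "gene_id",
        ]
    )
    universe = set(translation_calls["gene_id"])
    in_sig = genes & universe
    a = len(in_sig & called)
    b = len(in_sig - called)
    c = len(called - in_sig)
    d = len(universe - in_sig - called)
    chi2, p, low_exp = _chi2_2x2(a, b, c, d)
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    return {
        "chi2": chi2, "p": p, "table": ((a, b), (c, d)),
        "degenerate": degenerate, "low_expected": low_exp,
        "significant": p < alpha,
    }


def filter_low_counts(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    min_count: int = 10,
    max_frac: float = 0.30,
) -> pd.DataFrame:
    """Drop genes weakly detected in both sample groups.

    A gene is removed iff the fraction of samples with count < ``min_count``
    exceeds ``max_frac`` in group 1 AND in group 2.
    """
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    g1 = [s for s in matrix.columns if groups.get(s) == names[0]]
    g2 = [s for s in matrix.columns if groups.get(s) == names[1]]
    if not g1 or not g2:
        raise ValueError("both groups must contain at least one sample")
    frac1 = (matrix[g1] < min_count).mean(axis=1)
    frac2 = (matrix[g2] < min_count).mean(axis=1)
    keep = ~((frac1 > max_frac) & (frac2 > max_frac))
    return matrix[keep]


def log_cpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """voom-style log2 counts per million: log2((c + 0.5)/(lib + 1) * 1e6)."""
    lib = matrix.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return np.log2((matrix + 0.5) / (lib + 1.0) * 1e6)


def _ssgsea_one(values: pd.Series, in_sig: np.ndarray, exponent: float) -> float:
    """Barbie-style rank-weighted ECDF-difference score for one sample."""
    if values.nunique() == 1:
        logger.warning("constant expression vector; ssGSEA score set to 0")
        return 0.0
    ranks = values.rank(method="average", ascending=True).to_numpy()
    # walk the list in descending expression; ids break ties deterministically
    order = np.lexsort((values.index.to_numpy(), -values.to_numpy()))
    in_s = in_sig[order]
    w = np.where(in_s, np.abs(ranks[order]) ** exponent, 0.0)
    total_in = w.sum()
    n_out = (~in_s).sum()
    if total_in == 0 or n_out == 0:
        return 0.0
    ecdf_in = np.cumsum(w) / total_in
    ecdf_out = np.cumsum(~in_s) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea_score(
    expression: pd.DataFrame,
    signature: frozenset[str] | set[str] | list[str],
    exponent: float = SSGSEA_EXPONENT,
    normalize: bool = True,
) -> pd.Series:
    """Single-sample GSEA scores of a gene set across samples.

    Per sample, genes are ranked by expression (average ranks for ties) and
    the score is the running sum of the difference between the
    rank-weighted in-signature ECDF (weights rank**exponent) and the
    unweighted out-of-signature ECDF.  With ``normalize``, scores are
    divided by their range across samples, bounding them in [-1, 1].
    Scores depend only on within-sample ranks, so they are invariant to
    any strictly monotone transform of one sample's values.
    """
    sig = set(signature)
    in_sig = expression.index.isin(sig).astype(bool)
    if in_sig.sum() == 0:
        raise ValueError("signature has no overlap with the expression matrix")
    scores = pd.Series(
        {s: _ssgsea_one(expression[s], in_sig, exponent) for s in expression.columns},
        name="ssgsea_score",
    )
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return scores


def group_extremes(scores: pd.Series, frac: float = EXTREME_FRACTION) -> pd.Series:
    """Label the top/bottom ``frac`` of samples high/low, the rest middle.

    Group size k = round-half-up(frac * N); ties are broken by sample id so
    labels are deterministic.  2k may equal N (empty middle) but not
    exceed it.
    """
    n = len(scores)
    k = math.floor(frac * n + 0.5)
    if 2 * k > n:
        raise ValueError(f"extreme groups of {k} would overlap in {n} samples")
    order = sorted(scores.index, key=lambda s: (-scores[s], s))
    labels = pd.Series("middle", index=scores.index, name="group")
    labels[order[:k]] = "high"
    if k:
        labels[order[-k:]] = "low"
    return labels


def relative_fragmentation(induced_pct: float, spontaneous_pct: float) -> float:
    """Relative nuclear fragmentation of a drug-treated cell-death assay.

    score = 1 + 100 * (induced - spontaneous) / (100 - spontaneous).
    Equal induced and spontaneous fragmentation gives exactly 1; values
    below 1 indicate less death upon treatment than spontaneously.
    """
    for v in (induced_pct, spontaneous_pct):
        if not 0 <= v < 100:
            raise ValueError("percentages must lie in [0, 100)")
    return 1.0 + 100.0 * (induced_pct - spontaneous_pct) / (100.0 - spontaneous_pct)
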