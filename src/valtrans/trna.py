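"""tRNA isodecoder aggregation, differential testing and concordance.

tRNA-seq quantifies individual tRNA genes (isodecoders).  Analysis works at
two aggregated levels: the isoacceptor (all isodecoders sharing an
anticodon, e.g. tRNA-Val-CAC) and the alloisoacceptor (all tRNAs charging
the same amino acid regardless of anticodon).  Aggregates are per-sample
sums of isodecoder counts; differences between conditions are tested with
a two-tailed unpaired t-test; and the concordance overlay asks whether
features called enriched at the codon/amino-acid level move in the same
direction as their cognate tRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import codon_to_anticodon

logger = logging.getLogger(__name__)

META_COLS = ("isodecoder_id", "amino_acid", "anticodon")

#: pseudo-count added to group means before the log2 ratio
FC_PSEUDOCOUNT = 0.5


def _validate_counts(counts: pd.DataFrame, conditions: dict[str, str]) -> list[str]:
    for col in META_COLS:
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    samples = [c for c in counts.columns if c not in META_COLS]
    missing = [s for s in samples if s not in conditions]
    if missing:
        raise ValueError(f"samples without condition label: {missing}")
    if (counts[samples] < 0).any().any():
        raise ValueError("negative counts")
    bad = counts.groupby("anticodon")["amino_acid"].nunique()
    bad = bad[bad > 1]
    if len(bad):
        raise ValueError(f"anticodon(s) mapped to multiple amino acids: {list(bad.index)}")
    return samples


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed unpaired Student t-test (pooled variance) of b vs a.

    Degenerate zero-variance inputs: equal means give (0, 1); unequal
    means give (inf-signed t, 0) — the caller flags these rows.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(b.mean() - a.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return float(t), float(p)


def aggregate(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    level: str = "allo",
    significant_only: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sum isodecoder counts to isoacceptor or alloisoacceptor level.

    ``level='iso'`` keys on (amino_acid, anticodon); ``level='allo'`` keys
    on amino_acid alone.  With ``significant_only`` (isoacceptor option),
    only isodecoders individually passing a two-tailed unpaired t-test at
    ``alpha`` contribute to the sums; keys left with no significant
    isodecoder are emitted with zero counts and ``all_filtered=True``.
    """
    if level not in ("iso", "allo"):
        raise ValueError("level must be 'iso' or 'allo'")
    samples = _validate_counts(counts, conditions)
    work = counts.copy()
    if significant_only:
        sens = [s for s in samples if conditions[s] == "SENS"]
        res = [s for s in samples if conditions[s] == "RES"]
        if len(sens) < 2 or len(res) < 2:
            raise ValueError("significant_only filtering requires >= 2 replicates per condition")
        keep = []
        for _, row in work.iterrows():
            _, p = pooled_t_test(row[sens].to_numpy(float), row[res].to_numpy(float))
            keep.append(p < alpha)
        contributing = work[pd.Series(keep, index=work.index)]
    else:
        contributing = work

    keys = ["amino_acid", "anticodon"] if level == "iso" else ["amino_acid"]
    sums = contributing.groupby(keys)[samples].sum()
    # keys whose isodecoders were all filtered still appear, zero-filled
    all_keys = work.groupby(keys)[samples].sum().index
    sums = sums.reindex(all_keys, fill_value=0)
    out = sums.reset_index()
    out["level"] = "isoacceptor" if level == "iso" else "alloisoacceptor"
    out["all_filtered"] = (out[samples].sum(axis=1) == 0) & (
        work.groupby(keys)[samples].sum().reset_index(drop=True).sum(axis=1) > 0
    )
    return out


def differential(
    aggregated: pd.DataFrame,
    conditions: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-key two-tailed unpaired t-test (RES vs SENS) with log2 fold change.

    log2fc = log2((mean_RES + 0.5) / (mean_SENS + 0.5)); the pseudo-count
    guards zero-count aggregates.  ``direction`` is up/down at ``alpha``,
    otherwise none.
    """
    samples = [c for c in aggregated.columns if c in conditions]
    sens = [s for s in samples if conditions[s] == "SENS"]
    res = [s for s in samples if conditions[s] == "RES"]
    if len(sens) < 2 or len(res) < 2:
        raise ValueError("need >= 2 replicates per condition")
    out = aggregated.copy()
    t_list, p_list, fc_list, flagged = [], [], [], []
    for _, row in aggregated.iterrows():
        a = row[sens].to_numpy(float)
        b = row[res].to_numpy(float)
        t, p = pooled_t_test(a, b)
        fc = float(np.log2((b.mean() + FC_PSEUDOCOUNT) / (a.mean() + FC_PSEUDOCOUNT)))
        flagged.append(not np.isfinite(t))
        t_list.append(t)
        p_list.append(p)
        fc_list.append(fc)
    out["log2fc"] = fc_list
    out["t_stat"] = t_list
    out["p"] = p_list
    out["degenerate"] = flagged
    out["direction"] = "none"
    sig = out["p"] < alpha
    out.loc[sig & (out["log2fc"] > 0), "direction"] = "up"
    out.loc[sig & (out["log2fc"] < 0), "direction"] = "down"
    return out


@dataclass(frozen=True)
class ConcordanceRow:
    feature: str
    enrichment_direction: str
    trna_direction: str
    concordant: bool


def concordance(
    enrichment: pd.DataFrame,
    trna: pd.DataFrame,
    level: str = "allo",
) -> pd.DataFrame:
    """Overlay codon/amino-acid enrichment calls with tRNA differential calls.

    At amino-acid ('allo') level, features map to alloisoacceptors by
    identity; at codon ('iso') level, a codon maps to the isoacceptor whose
    anticodon is its exact reverse complement (no wobble).  One row per
    feature significant in either input; a feature with no cognate tRNA row
    gets trna_direction 'absent'.  Concordant means both calls significant
    and in the same sense (enriched~up, impoverished~down).
    """
    if level == "iso":
        trna_dir = {row.anticodon: row.direction for row in trna.itertuples(index=False)}
        to_key = codon_to_anticodon
    else:
        trna_dir = {row.amino_acid: row.direction for row in trna.itertuples(index=False)}
        to_key = lambda f: f  # noqa: E731

    same_sense = {("enriched", "up"), ("impoverished", "down")}
    rows = []
    for erow in enrichment.itertuples(index=False):
        t_dir = trna_dir.get(to_key(erow.feature), "absent")
        if erow.direction == "none" and t_dir in ("none", "absent"):
            continue
        rows.append(ConcordanceRow(
            feature=erow.feature,
            enrichment_direction=erow.direction,
            trna_direction=t_dir,
            concordant=(erow.direction, t_dir) in same_sense,
        ))
    return pd.DataFrame([r.__dict__ for r in rows], columns=["feature", "enrichment_direction", "trna_direction", "concordant"])
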