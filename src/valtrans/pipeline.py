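"""End-to-end orchestration: simulate -> enrich -> tRNA -> ribo -> signature.

``run_pipeline`` executes the stages in dependency order from a single
``RunConfig`` (loadable from YAML), writes every intermediate table under
the output directory, and returns a ``RunReport`` capturing parameter
snapshots, SHA-256 hashes of the stage outputs and summary counts, so a
rerun with the same config and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import codon_content as cc
from . import io as vio
from . import ribo, signature as sig, synthetic, trna

logger = logging.getLogger(__name__)

STAGES = ("simulate", "enrichment", "trna", "ribo", "signature")


@dataclass
class RunConfig:
    """All pipeline tunables with their analysis defaults."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    # synthetic transcriptome
    n_genes: int = 1000
    cds_length_range: tuple[int, int] = (100, 600)
    planted_codon: str = "GTG"
    planted_fraction: float = 0.05
    planted_bias: float = 4.0

    # planted translation effect
    effect_amino_acid: str = "V"
    effect_shift: float = -0.5
    effect_noise_sd: float = 0.3
    n_significant: int = 200

    # ribosome footprints
    pause_codon: str = "GTG"
    pause_offset: int = 15
    pause_fold: float = 4.0
    read_length: int = 30
    reads_per_transcript: int = 100
    offsets: tuple[int, ...] = ribo.DEFAULT_OFFSETS
    n_cds_bins: int = 50
    utr_window_nt: int = 30

    # tRNA
    trna_planted_fold: float = 2.0
    trna_replicates: int = 3

    # enrichment / signature
    alpha: float = 0.05
    protein_cut: float = sig.PROTEIN_CUT
    rna_cut: float = sig.RNA_CUT
    ssgsea_exponent: float = sig.SSGSEA_EXPONENT
    extreme_fraction: float = sig.EXTREME_FRACTION
    n_expression_samples: int = 60
    n_high_samples: int = 9
    expression_shift: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("cds_length_range", "offsets", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Per-stage parameter snapshots, output hashes and summaries."""

    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages, "warnings": self.warnings},
            indent=2, default=str,
        ) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    artifacts: dict[str, object] = {}

    deps = {
        "simulate": (),
        "enrichment": ("simulate",),
        "trna": ("simulate", "enrichment"),
        "ribo": ("simulate", "enrichment"),
        "signature": ("simulate", "enrichment"),
    }
    runners = {
        "simulate": _stage_simulate,
        "enrichment": _stage_enrichment,
        "trna": _stage_trna,
        "ribo": _stage_ribo,
        "signature": _stage_signature,
    }
    summaries = {
        "simulate": lambda a: {
            "n_genes": config.n_genes,
            "total_rpf_reads": {c: a[f"rpf_{c}"].total_reads for c in ("ctrl", "kd")}},
        "enrichment": lambda a: {
            "n_significant_codons": int(a["codon_enrichment"]["significant"].sum()),
            "planted_codon_p": float(
                a["codon_enrichment"].set_index("feature").at[config.planted_codon, "p"])},
        "trna": lambda a: {"n_concordant": int(a["concordance"]["concordant"].sum())},
        "ribo": lambda a: {"stratified_p": {aa: a[f"strat_{aa}"].p for aa in ("V", "L", "I")}},
        "signature": lambda a: {
            "signature_size": len(a["signature"]),
            "superposition_p": a["superposition"]["p"],
            "group_sizes": a["group_sizes"]},
    }
    completed: set[str] = set()
    for stage in STAGES:
        if stage not in config.stages:
            continue
        unmet = [d for d in deps[stage] if d not in completed]
        if unmet:
            report.stages[stage] = {"status": "skipped", "unmet_dependencies": unmet}
            report.warnings.append(f"{stage}: skipped (needs {unmet})")
            continue
        try:
            files = runners[stage](config, out, artifacts)
        except Exception as exc:  # recorded, dependents skipped
            report.stages[stage] = {"status": "failed", "error": repr(exc)}
            report.warnings.append(f"{stage}: failed ({exc})")
            logger.exception("stage %s failed", stage)
            continue
        report.stages[stage] = {
            "status": "ok",
            "outputs": {f.name: _sha256(f) for f in files},
            **summaries[stage](artifacts),
        }
        completed.add(stage)
    report.save(out / "report.json")
    return report


def _stage_simulate(config: RunConfig, out: Path, art: dict) -> list[Path]:
    tx_spec = synthetic.TranscriptomeSpec(
        n_genes=config.n_genes,
        cds_length_range=config.cds_length_range,
        planted_sets=(synthetic.PlantedSet(
            "planted", config.planted_fraction, config.planted_codon, config.planted_bias),),
        seed=config.seed,
    )
    genes = synthetic.generate_transcriptome(tx_spec)
    art["genes"] = genes
    art["planted_ids"] = synthetic.planted_gene_ids(tx_spec)["planted"]
    files = []
    fasta = out / "transcriptome.fasta"
    vio.write_cds_fasta(genes, fasta)
    files.append(fasta)
    (out / "planted_genes.txt").write_text("\n".join(art["planted_ids"]) + "\n")
    files.append(out / "planted_genes.txt")

    effect = synthetic.EffectSpec(
        amino_acid=config.effect_amino_acid, mean_shift=config.effect_shift,
        noise_sd=config.effect_noise_sd, n_significant=config.n_significant,
        seed=config.seed + 1,
    )
    for name, seed_off in (("ribo_fc", 1), ("poly_fc", 2)):
        tab = synthetic.generate_fc_table(
            genes, dataclasses.replace(effect, seed=config.seed + seed_off))
        art[name] = tab
        p = out / f"{name}.tsv"
        vio.write_table(tab, p)
        files.append(p)

    for cond, fold, seed_off in (("ctrl", 1.0, 10), ("kd", config.pause_fold, 11)):
        ds = synthetic.generate_rpf_dataset(
            genes,
            synthetic.PauseSpec(
                pause_codon=config.pause_codon, pause_offset=config.pause_offset,
                fold_enrichment=fold, read_length=config.read_length,
                reads_per_transcript=config.reads_per_transcript,
                seed=config.seed + seed_off),
            condition=cond,
        )
        art[f"rpf_{cond}"] = ds
        p = out / f"rpf_{cond}.tsv"
        vio.write_table(ds.reads, p)
        files.append(p)

    counts, conditions = synthetic.generate_trna_counts(
        planted=[("V", "CAC", config.trna_planted_fold)],
        replicates=config.trna_replicates, seed=config.seed + 20,
    )
    art["trna_counts"], art["trna_conditions"] = counts, conditions
    p = out / "trna_counts.tsv"
    vio.write_table(counts, p)
    files.append(p)
    return files


def _stage_enrichment(config: RunConfig, out: Path, art: dict) -> list[Path]:
    genes = art["genes"]
    picked = cc.select_longest_transcript(genes)
    art["codon_background"] = cc.build_background(cc.content_matrix(picked, "codon"), "codon")
    art["aa_background"] = cc.build_background(cc.content_matrix(picked, "aa"), "aa")
    files = []
    for level, bg in (("codon", art["codon_background"]), ("aa", art["aa_background"])):
        tab = cc.enrichment_test(set(art["planted_ids"]), bg, alpha=config.alpha)
        art[f"{level}_enrichment"] = tab
        p = out / f"enrichment_{level}.tsv"
        vio.write_table(tab, p)
        files.append(p)
    return files


def _stage_trna(config: RunConfig, out: Path, art: dict) -> list[Path]:
    counts, conditions = art["trna_counts"], art["trna_conditions"]
    files = []
    for level in ("iso", "allo"):
        agg = trna.aggregate(counts, conditions, level=level)
        diff = trna.differential(agg, conditions, alpha=config.alpha)
        art[f"trna_{level}"] = diff
        p = out / f"trna_{level}_differential.tsv"
        vio.write_table(diff, p)
        files.append(p)
    conc = trna.concordance(art["codon_enrichment"], art["trna_iso"], level="iso")
    art["concordance"] = conc
    p = out / "concordance_codon_isoacceptor.tsv"
    vio.write_table(conc, p)
    files.append(p)
    return files


def _stage_ribo(config: RunConfig, out: Path, art: dict) -> list[Path]:
    genes = art["genes"]
    cds_map = {r.transcript_id: r.sequence for r in genes}
    files = []
    prof = ribo.metagene(art["rpf_ctrl"], n_cds_bins=config.n_cds_bins,
                         utr_window_nt=config.utr_window_nt)
    art["metagene"] = prof
    mg = pd.DataFrame({"bin": range(config.n_cds_bins), "density": prof.cds})
    p = out / "metagene_cds.tsv"
    vio.write_table(mg, p)
    files.append(p)

    occ = ribo.codon_occupancy(art["rpf_kd"], art["rpf_ctrl"], cds_map, offsets=config.offsets)
    art["occupancy"] = occ
    p = out / "codon_occupancy.tsv"
    vio.write_table(occ, p)
    files.append(p)

    for aa in ("V", "L", "I"):
        res = ribo.stratify_fc(art["ribo_fc"].assign(gene_id=art["ribo_fc"]["gene_id"]),
                               art["aa_background"], aa)
        art[f"strat_{aa}"] = res
    strat = pd.DataFrame([
        {"amino_acid": aa, "t_stat": art[f"strat_{aa}"].t_stat, "p": art[f"strat_{aa}"].p}
        for aa in ("V", "L", "I")
    ])
    p = out / "stratified_fc.tsv"
    vio.write_table(strat, p)
    files.append(p)
    return files


def _stage_signature(config: RunConfig, out: Path, art: dict) -> list[Path]:
    genes = art["genes"]
    # protein FCs follow the ribosome-level effect; mRNA FCs are null
    prot = synthetic.generate_fc_table(genes, synthetic.EffectSpec(
        amino_acid=config.effect_amino_acid, mean_shift=config.effect_shift,
        noise_sd=config.effect_noise_sd, n_significant=config.n_significant,
        seed=config.seed + 30))
    rna = synthetic.generate_fc_table(genes, synthetic.EffectSpec(
        amino_acid=config.effect_amino_acid, mean_shift=0.0,
        noise_sd=config.effect_noise_sd, n_significant=config.n_significant,
        seed=config.seed + 31))
    pairs = pd.DataFrame({
        "gene_id": prot["gene_id"],
        "protein_log2fc": prot["log2fc"],
        "rna_log2fc": rna["log2fc"].to_numpy(),
    })
    classified = sig.classify_translation_groups(pairs, config.protein_cut, config.rna_cut)
    members = art["aa_background"].members[config.effect_amino_acid]
    signature = sig.derive_signature(classified, members)
    art["signature"] = signature
    files = []
    p = out / "signature_genes.txt"
    p.write_text("\n".join(sorted(signature.genes)) + "\n")
    files.append(p)

    art["superposition"] = sig.superposition_test(signature, art["ribo_fc"], direction="down")
    p = out / "superposition.json"
    p.write_text(json.dumps(art["superposition"], default=str, indent=2) + "\n")
    files.append(p)

    expr, high = synthetic.generate_expression_matrix(
        n_genes=config.n_genes, n_samples=config.n_expression_samples,
        signature=sorted(signature.genes) or [g.gene_id for g in genes[:10]],
        n_high_samples=config.n_high_samples, shift=config.expression_shift,
        seed=config.seed + 40)
    groups = {s: ("high" if s in high else "other") for s in expr.columns}
    filtered = sig.filter_low_counts(expr, groups)
    logcpm = sig.log_cpm(filtered)
    scores = sig.ssgsea_score(logcpm, signature.genes or frozenset(g.gene_id for g in genes[:10]),
                              exponent=config.ssgsea_exponent)
    labels = sig.group_extremes(scores, frac=config.extreme_fraction)
    art["group_sizes"] = labels.value_counts().to_dict()
    score_tab = pd.DataFrame({"sample_id": scores.index, "ssgsea_score": scores.values,
                              "group": labels.values, "planted_high": [s in high for s in scores.index]})
    p = out / "sample_scores.tsv"
    vio.write_table(score_tab, p)
    files.append(p)
    return files
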