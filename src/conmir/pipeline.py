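"""End-to-end pipeline orchestration from a single run configuration.

Stages run in a fixed order — prep, classify, search, extract, fold, targets,
conservation, reports — each writing plain-text artifacts into the output
tree, and a run manifest records the configuration (verbatim and hashed) with
per-stage record counts.  A rerun with the same configuration and inputs is
byte-identical; missing inputs fail fast naming the stage and path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, conservation, folding, homology, precursor, reports
from . import smallrna_prep as prep
from . import targets as tp
from .sequtils import read_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    reads: str
    mature: str
    genome: str
    transcripts: str
    out_dir: str
    go_annotations: Optional[str] = None
    stress_genes: Optional[str] = None
    evidence_table: Optional[str] = None  # defaults to the packaged table
    class_references: dict[str, str] = field(default_factory=dict)  # label -> FASTA

    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    quality_cutoff: int = 20
    min_len: int = 16
    max_len: int = 30
    min_identity: float = 0.90
    max_evalue: float = 1e-4
    min_coverage: float = 0.90
    flank: int = 80
    max_expectation: float = 3.0
    hspsize: int = 18
    top_n: int = 50
    min_paired_fraction: float = 0.60
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def validate(self) -> None:
        if not 0 < self.min_identity <= 1 or not 0 < self.min_coverage <= 1:
            raise ValueError("identity/coverage thresholds must be in (0, 1]")
        if self.max_evalue <= 0 or self.max_expectation < 0:
            raise ValueError("max_evalue must be positive, max_expectation >= 0")
        if self.min_len > self.max_len or self.flank < 0:
            raise ValueError("invalid length window or flank")


def _require(path: Optional[str], stage: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"stage {stage}: required input not configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"stage {stage}: missing input {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- stage 1: prep (trim + collapse) --------------------------------
    reads_path = _require(config.reads, "prep")
    trimmed = list(
        prep.trim_reads(
            prep.read_fastq(reads_path),
            adapter=config.adapter,
            quality_cutoff=config.quality_cutoff,
            min_len=config.min_len,
            max_len=config.max_len,
        )
    )
    uniques = prep.collapse(r.sequence for r in trimmed)
    prep.write_collapsed_fasta(out / "collapsed.fa", uniques)
    counts["prep"] = len(uniques)
    _warn_if_empty("prep", uniques)

    # --- stage 2: classify ----------------------------------------------
    refs_by_class = []
    for label, path in config.class_references.items():
        p = _require(path, "classify")
        refs_by_class.append((label, [seq for _, seq in read_fasta(p)]))
    profile = prep.classify_known_rna(uniques, refs_by_class)
    profile.write_tsv(out / "class_profile.tsv")
    counts["classify"] = profile.total

    # --- stage 3: homology search ---------------------------------------
    mature_path = _require(config.mature, "search")
    refs = homology.parse_mirbase_fasta(mature_path)
    hits = homology.search(
        uniques,
        refs,
        min_identity=config.min_identity,
        max_evalue=config.max_evalue,
        min_coverage=config.min_coverage,
    )
    homology.write_hits_tsv(out / "hits.tsv", hits)
    summary = homology.summarize_families(hits)
    summary.table.to_csv(out / "family_summary.tsv", sep="\t", index=False)
    counts["search"] = len(hits)
    _warn_if_empty("search", hits)

    # --- stage 4: precursor extraction ----------------------------------
    genome_path = _require(config.genome, "extract")
    scaffolds = {header.split()[0]: seq for header, seq in read_fasta(genome_path)}
    hit_matures = sorted({(h.ref.ref_id, h.read.sequence) for h in hits})
    candidates = []
    for ref_id, mature_seq in hit_matures:
        for locus in precursor.find_exact_matches(mature_seq, scaffolds):
            candidates.append(
                precursor.extract_precursor(ref_id, locus, scaffolds, flank=config.flank)
            )
    precursor.write_candidates(out / "precursors.fa", out / "precursors.tsv", candidates)
    counts["extract"] = len(candidates)
    _warn_if_empty("extract", candidates)

    # --- stage 5: folding + stem-loop verdicts --------------------------
    ct_dir = out / "ct"
    ct_dir.mkdir(exist_ok=True)
    verdicts = []
    with open(out / "structures.txt", "w") as db:
        for i, cand in enumerate(candidates):
            if cand.is_short:
                continue
            name = f"cand{i + 1:04d}_{cand.mature_id}"
            structure = folding.fold_mfe(cand.sequence)
            verdict = folding.classify_stem_loop(
                structure,
                cand.mature_offset,
                cand.mature_length,
                min_paired_fraction=config.min_paired_fraction,
            )
            (ct_dir / f"{name}.ct").write_text(folding.write_ct(structure, name))
            db.write(f">{name}\n{structure.sequence}\n{structure.dot_bracket}\n")
            verdicts.append((name, structure, verdict))
    folding.write_verdicts_tsv(out / "stem_loops.tsv", verdicts)
    counts["fold"] = sum(1 for _, _, v in verdicts if v.is_stem_loop)

    # --- stage 6: target prediction -------------------------------------
    transcripts_path = _require(config.transcripts, "targets")
    transcripts = {h.split()[0]: s for h, s in read_fasta(transcripts_path)}
    all_hits: list[tp.TargetHit] = []
    mirna_map: dict[str, str] = {}
    for h in hits:
        mirna_id = h.ref.ref_id
        if mirna_id in mirna_map:
            continue
        mirna_map[mirna_id] = h.read.sequence
    for mirna_id in sorted(mirna_map):
        all_hits.extend(
            tp.scan_transcripts(
                mirna_id,
                mirna_map[mirna_id],
                transcripts,
                max_expectation=config.max_expectation,
                hspsize=config.hspsize,
                top_n=config.top_n,
            )
        )
    tp.write_targets_tsv(out / "targets.tsv", all_hits)
    frac, n_cleav, n_trans = tp.summarize_cleavage_fraction(all_hits)
    counts["targets"] = len(all_hits)
    _warn_if_empty("targets", all_hits)

    # --- stage 7: conservation ------------------------------------------
    if config.evidence_table:
        evidence = conservation.read_evidence_table(_require(config.evidence_table, "conservation"))
    else:
        evidence = conservation.load_evidence_table()
    cons_summary = conservation.summary_counts(evidence)
    histograms = {
        cond: conservation.conservation_histogram(evidence, cond)
        for cond in evidence.conditions
    }
    family_of = {rid: homology._MIRBASE_ID.match(rid).group(2) for rid in mirna_map}
    if config.stress_genes:
        stress_list = [
            line.strip()
            for line in _require(config.stress_genes, "conservation").read_text().splitlines()
            if line.strip()
        ]
    else:
        stress_list = []
    records = conservation.stress_gene_overlap(all_hits, stress_list, family_of=family_of)
    with open(out / "stress_targets.tsv", "w") as fh:
        fh.write("family\tmirna_name\tdrought\tsalt\ttarget_gene_id\n")
        for r in records:
            fh.write(
                f"{r.family}\t{r.mirna_name}\t{int(r.drought)}\t{int(r.salt)}\t{r.target_gene_id}\n"
            )
    (out / "conservation.json").write_text(
        json.dumps(
            {"summary": cons_summary, "histograms": histograms, "cleavage_fraction": frac,
             "n_cleavage": n_cleav, "n_translation": n_trans},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    counts["conservation"] = len(records)

    # --- stage 8: reports -----------------------------------------------
    mirna_seqs = sorted({h.read.sequence for h in hits})
    if mirna_seqs:
        comp = reports.composition_report(mirna_seqs)
        comp.write(out / "lengths.tsv", out / "position_bias.tsv")
        counts["reports"] = comp.n_sequences
    else:
        counts["reports"] = 0
    if config.go_annotations:
        go_df = pd.read_csv(_require(config.go_annotations, "reports"), sep="\t")
        target_genes = sorted({h.transcript_id for h in all_hits})
        cluster = reports.go_cluster(go_df, target_genes)
        cluster.write_tsv(out / "go_clusters.tsv")

    manifest = {
        "package": "conmir",
        "version": __version__,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "stages": list(counts),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _warn_if_empty(stage: str, items) -> None:
    if not items:
        logger.warning("stage %s produced zero records; downstream stages still run", stage)
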