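"""Seeded synthetic inputs with ground truth for the whole pipeline.

No sequencing data are bundled with the package; instead this module
generates, from a single seed, every input the pipeline consumes — a mature
miRNA reference shared across toy species, genome scaffolds with planted
hairpin precursors (mature + loop + near-reverse-complement star), adaptered
small-RNA reads at heterogeneous negative-binomial depth with substitution
errors and decoy reads from non-miRNA RNA classes, a transcriptome with
planted complementary target sites of specified mismatch structure, a GO
annotation table and a stress-gene list — together with truth tables that
record what was planted where.  Identical seeds reproduce identical bytes.

Default parameters are the study conditions exercised by the test suite:
12 miRNA families across 3 species (30 of the 36 variants planted), perfect
star arms with an 8-nt loop, negative-binomial read depth (mean 50,
dispersion 5), 0.5% substitution error, 30% decoy reads behind the TruSeq
small-RNA 3' adapter, and 20 cleavage-type to 5 translation-type target
sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .homology import MatureRef
from .sequtils import revcomp, write_fasta
from .targets import classify_inhibition, score_duplex

#: TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: canonical plant miRNA family numbers used for realistic identifiers
_FAMILY_NUMBERS = [
    156, 159, 160, 164, 166, 167, 168, 169, 171, 172,
    319, 393, 395, 396, 398, 399, 408, 444, 528, 529,
    535, 845, 894, 1125, 5048, 5049,
]

_DNA = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, u_bias_first: bool = False) -> str:
    seq = rng.choice(_DNA, size=length)
    if u_bias_first and rng.random() < 0.5:
        seq[0] = "T"  # mature miRNAs favour a 5' U
    return "".join(seq)


def _substitute(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


# ---------------------------------------------------------------------------
# Reference


def generate_reference(
    n_families: int = 12, n_species: int = 3, seed: int = 0
) -> tuple[list[MatureRef], pd.DataFrame]:
    """Random 20-22-nt matures, one variant per family per species.

    Variants within a family differ from the family canonical by at most two
    substitutions, exercising the >90% identity filter.  Identifiers are
    miRBase-style: ``spa-miR156a-5p``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3EF]))
    fam_numbers = list(_FAMILY_NUMBERS)
    while len(fam_numbers) < n_families:
        fam_numbers.append(9000 + len(fam_numbers))
    refs: list[MatureRef] = []
    rows = []
    for fi in range(n_families):
        number = fam_numbers[fi]
        length = int(rng.integers(20, 23))
        canonical = _random_seq(rng, length, u_bias_first=True)
        for si in range(n_species):
            species = "sp" + chr(ord("a") + si)
            n_sub = int(rng.integers(0, 3)) if si else 0
            positions = sorted(rng.choice(length, size=n_sub, replace=False)) if n_sub else []
            variant = _substitute(rng, canonical, positions)
            ref_id = f"{species}-miR{number}a-5p"
            refs.append(
                MatureRef(
                    ref_id=ref_id,
                    species_code=species,
                    family=f"miR{number}",
                    sequence=variant,
                )
            )
            rows.append(
                {
                    "ref_id": ref_id,
                    "family": f"miR{number}",
                    "species": species,
                    "sequence": variant,
                    "canonical": canonical,
                    "n_substitutions": len(positions),
                }
            )
    return refs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome with planted precursors


def plant_precursors(
    matures: Sequence[MatureRef],
    n_scaffolds: int = 4,
    scaffold_length: int = 6000,
    loop_len: int = 8,
    star_mismatches: int = 0,
    n_edge: int = 2,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random scaffolds with one hairpin (mature + loop + star) per mature.

    Strands alternate.  The first ``n_edge`` hairpins are planted 30 nt from
    a scaffold start so flank extraction is forced to truncate.  Raises when
    the scaffolds cannot hold their share of hairpins with 80-nt margins.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E0]))
    scaffolds = {
        f"scaffold{si + 1}": list(_random_seq(rng, scaffold_length))
        for si in range(n_scaffolds)
    }
    names = list(scaffolds)
    per_scaffold: dict[str, list[int]] = {name: [] for name in names}
    for mi in range(len(matures)):
        per_scaffold[names[mi % n_scaffolds]].append(mi)

    rows = []
    edge_budget = n_edge
    for name, indices in per_scaffold.items():
        if not indices:
            continue
        max_h = max(
            2 * len(matures[mi].sequence) + loop_len for mi in indices
        )
        block = scaffold_length // len(indices)
        if block < max_h + 200:
            raise ValueError(
                f"{name}: {len(indices)} hairpins of up to {max_h} nt do not fit "
                f"{scaffold_length} nt with 80-nt margins"
            )
        for slot, mi in enumerate(indices):
            ref = matures[mi]
            L = len(ref.sequence)
            star = revcomp(ref.sequence)
            if star_mismatches:
                positions = sorted(
                    rng.choice(L, size=min(star_mismatches, L), replace=False)
                )
                star = _substitute(rng, star, positions)
            loop = _random_seq(rng, loop_len)
            hairpin = ref.sequence + loop + star
            strand = "+" if mi % 2 == 0 else "-"
            if edge_budget > 0 and slot == 0:
                pos = 30
                edge_budget -= 1
            else:
                lo_bound = max(slot * block + 90, 90)
                hi_bound = (slot + 1) * block - len(hairpin) - 90
                pos = int(rng.integers(lo_bound, hi_bound))
            insert = hairpin if strand == "+" else revcomp(hairpin)
            scaffolds[name][pos : pos + len(hairpin)] = list(insert)
            if strand == "+":
                mstart = pos
            else:
                mstart = pos + L + loop_len
            rows.append(
                {
                    "mature_id": ref.ref_id,
                    "family": ref.family,
                    "sequence": ref.sequence,
                    "scaffold": name,
                    "hairpin_start": pos,
                    "mature_start": mstart,
                    "mature_end": mstart + L,
                    "strand": strand,
                    "loop_len": loop_len,
                    "star_mismatches": star_mismatches,
                    "expect_stem_loop": star_mismatches == 0,
                }
            )
    genome = {name: "".join(chars) for name, chars in scaffolds.items()}
    return genome, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reads


def toy_class_references(seed: int = 0) -> list[tuple[str, list[str]]]:
    """Synthetic stand-ins for known-RNA class references (decoy sources).

    Purely random sequences labelled with the class names used in small-RNA
    profiling; they carry no biological sequence content.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1A55]))
    spec = [
        ("rRNA", 2, 300),
        ("tRNA", 4, 75),
        ("snoRNA", 2, 120),
        ("snRNA", 2, 150),
        ("ncRNA", 2, 200),
        ("CDS/mRNA", 3, 400),
    ]
    return [
        (label, [_random_seq(rng, length) for _ in range(n)])
        for label, n, length in spec
    ]


def simulate_reads(
    planted: Sequence[MatureRef],
    depth_mean: float = 50.0,
    dispersion: float = 5.0,
    adapter: str = DEFAULT_ADAPTER,
    error_rate: float = 0.005,
    decoy_fraction: float = 0.3,
    read_len: int = 50,
    class_refs: Optional[Sequence[tuple[str, list[str]]]] = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Adaptered reads for the planted matures plus decoys, with truth rows.

    Per mature the read count is negative-binomial (mean ``depth_mean``,
    dispersion ``dispersion``); each read is the mature (with occasional 1-nt
    3' jitter) followed by the adapter and random fill to ``read_len``,
    with i.i.d. substitution errors and constant Q35 qualities.  Decoys are
    random sequences or fragments of the toy class references, at an expected
    ``decoy_fraction`` of all reads.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be within [0, 0.05]")
    if not 0.0 <= decoy_fraction < 1.0:
        raise ValueError("decoy_fraction must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2EAD5]))
    if class_refs is None:
        class_refs = toy_class_references(seed)

    inserts: list[tuple[str, str, str]] = []  # (origin, mature_id, insert)
    # NB(mean, dispersion): p = r/(r+mean)
    r = dispersion
    p = r / (r + depth_mean)
    for ref in planted:
        count = max(1, int(rng.negative_binomial(r, p)))
        for _ in range(count):
            insert = ref.sequence
            jitter = rng.random()
            if jitter < 0.15:
                insert = insert[:-1]
            elif jitter > 0.85:
                insert = insert + str(rng.choice(_DNA))
            inserts.append(("mature", ref.ref_id, insert))
    n_mirna = len(inserts)
    if decoy_fraction > 0:
        n_decoy = int(rng.binomial(round(n_mirna / (1 - decoy_fraction)), decoy_fraction))
    else:
        n_decoy = 0
    for _ in range(n_decoy):
        length = int(rng.integers(18, 31))
        if rng.random() < 0.5:
            inserts.append(("random", "", _random_seq(rng, length)))
        else:
            label, seqs = class_refs[int(rng.integers(len(class_refs)))]
            src = seqs[int(rng.integers(len(seqs)))]
            start = int(rng.integers(0, len(src) - length + 1))
            inserts.append((label, "", src[start : start + length]))

    order = rng.permutation(len(inserts))
    records: list[tuple[str, str, str]] = []
    rows = []
    for serial, idx in enumerate(order):
        origin, mature_id, insert = inserts[idx]
        raw = (insert + adapter + _random_seq(rng, read_len))[:read_len]
        errors = np.flatnonzero(rng.random(len(raw)) < error_rate)
        if len(errors):
            raw = _substitute(rng, raw, errors)
        read_id = f"r{serial:06d}"
        records.append((read_id, raw, "D" * len(raw)))  # 'D' = Q35
        rows.append({"read_id": read_id, "origin": origin, "mature_id": mature_id})
    return records, pd.DataFrame(rows)


def write_fastq(path, records: Sequence[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Transcriptome with planted target sites


@dataclass(frozen=True)
class SiteSpec:
    """A planted target site: miRNA plus per-position pairing states.

    ``states`` maps 1-based miRNA positions to 'GU' or 'mismatch'; all other
    positions pair Watson-Crick.
    """

    mirna_id: str
    mirna_seq: str
    states: dict[int, str] = field(default_factory=dict, hash=False)

    def build_site(self, rng: np.random.Generator) -> str:
        """A transcript-sense site realising exactly the specified states."""
        m = self.mirna_seq
        L = len(m)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        site = [comp[m[k - 1]] for k in range(L, 0, -1)]  # site index L-k
        for k, state in self.states.items():
            base = m[k - 1]
            if state == "GU":
                if base == "G":
                    site[L - k] = "T"
                elif base == "T":
                    site[L - k] = "G"
                else:
                    raise ValueError(f"position {k}: base {base} cannot form G:U")
            elif state == "mismatch":
                partners = {comp[base]}
                partners |= {"T"} if base == "G" else {"G"} if base == "T" else set()
                choices = sorted(set("ACGT") - partners)
                site[L - k] = str(rng.choice(choices))
            else:
                raise ValueError(f"unknown state {state!r}")
        return "".join(site)


def default_site_specs(
    mirnas: Sequence[tuple[str, str]],
    n_cleavage: int = 20,
    n_translation: int = 5,
    seed: int = 0,
) -> list[SiteSpec]:
    """Planted-site specifications at the default cleavage:translation ratio.

    Cleavage-type sites are perfect, carry one G:U wobble (where the miRNA
    base permits one) or one peripheral mismatch; translation-type sites
    carry a central mismatch at position 10.  Every spec's expectation stays
    at or below the scan ceiling of 3.0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51755]))
    specs: list[SiteSpec] = []
    for i in range(n_cleavage):
        mirna_id, seq = mirnas[i % len(mirnas)]
        kind = i % 3
        if kind == 0:
            states: dict[int, str] = {}
        elif kind == 1:
            wobbly = [k for k in range(2, len(seq)) if seq[k - 1] in "GT" and not 9 <= k <= 11]
            states = {int(rng.choice(wobbly)): "GU"} if wobbly else {}
        else:
            k = int(rng.choice([14, 15, 16, len(seq)]))
            states = {k: "mismatch"}
        specs.append(SiteSpec(mirna_id=mirna_id, mirna_seq=seq, states=states))
    for i in range(n_translation):
        mirna_id, seq = mirnas[(n_cleavage + i) % len(mirnas)]
        specs.append(SiteSpec(mirna_id=mirna_id, mirna_seq=seq, states={10: "mismatch"}))
    return specs


def generate_transcriptome(
    site_specs: Sequence[SiteSpec],
    n_extra_transcripts: int = 10,
    transcript_length: int = 600,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """One transcript per planted site plus site-free negatives, with truth.

    The truth table stores each site's position, its expectation recomputed
    from the realised site sequence, and the expected inhibition call.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x72A]))
    transcripts: dict[str, str] = {}
    rows = []
    for i, spec in enumerate(site_specs):
        name = f"gene{i + 1:04d}.1"
        site = spec.build_site(rng)
        L = len(site)
        pos = int(rng.integers(50, transcript_length - L - 50))
        seq = _random_seq(rng, transcript_length)
        seq = seq[:pos] + site + seq[pos + L :]
        transcripts[name] = seq
        d = score_duplex(spec.mirna_seq, site, site_start=pos)
        rows.append(
            {
                "transcript_id": name,
                "mirna_id": spec.mirna_id,
                "site_start": pos,
                "site_end": pos + L,
                "expectation": d.expectation,
                "inhibition": classify_inhibition(d),
            }
        )
    for j in range(n_extra_transcripts):
        name = f"gene{len(site_specs) + j + 1:04d}.1"
        transcripts[name] = _random_seq(rng, transcript_length)
    return transcripts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GO annotation and stress genes

#: toy slim vocabulary; ids follow the GO numbering convention
_GO_TERMS = {
    "biological process": [
        ("GO:0006950", "response to stress"),
        ("GO:0009414", "response to water deprivation"),
        ("GO:0009651", "response to salt stress"),
        ("GO:0006355", "regulation of transcription"),
        ("GO:0009737", "response to abscisic acid"),
        ("GO:0006468", "protein phosphorylation"),
    ],
    "molecular function": [
        ("GO:0003700", "DNA-binding transcription factor activity"),
        ("GO:0004672", "protein kinase activity"),
        ("GO:0003824", "catalytic activity"),
        ("GO:0005515", "protein binding"),
    ],
    "cellular component": [
        ("GO:0005634", "nucleus"),
        ("GO:0005737", "cytoplasm"),
        ("GO:0009507", "chloroplast"),
        ("GO:0005886", "plasma membrane"),
    ],
}

#: the three namespaces with their default sampling weights
DEFAULT_NAMESPACE_WEIGHTS = {
    "biological process": 0.39,
    "cellular component": 0.35,
    "molecular function": 0.26,
}


def generate_go(
    genes: Sequence[str],
    namespace_weights: Optional[dict[str, float]] = None,
    n_annotations: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random (gene, go_id, namespace, term) annotations at stated proportions."""
    weights = dict(namespace_weights or DEFAULT_NAMESPACE_WEIGHTS)
    total = sum(weights.values())
    namespaces = sorted(weights)
    probs = np.array([weights[ns] / total for ns in namespaces])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x60]))
    if n_annotations is None:
        n_annotations = 8 * len(genes)
    rows = []
    for _ in range(n_annotations):
        gene = genes[int(rng.integers(len(genes)))]
        ns = namespaces[int(rng.choice(len(namespaces), p=probs))]
        go_id, term = _GO_TERMS[ns][int(rng.integers(len(_GO_TERMS[ns])))]
        rows.append({"gene": gene, "go_id": go_id, "namespace": ns, "term": term})
    return pd.DataFrame(rows)


def pick_stress_genes(
    target_truth: pd.DataFrame, fraction: float = 0.4, seed: int = 0
) -> list[str]:
    """A deterministic stress-gene list drawn from the planted target genes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57E55]))
    genes = sorted(target_truth["transcript_id"].unique())
    n = max(1, int(round(fraction * len(genes))))
    chosen = sorted(rng.choice(genes, size=n, replace=False))
    return [str(g) for g in chosen]


# ---------------------------------------------------------------------------
# One-call generation of a full input set


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the documented conditions."""

    n_families: int = 12
    n_species: int = 3
    n_planted: int = 30
    n_scaffolds: int = 4
    scaffold_length: int = 6000
    loop_len: int = 8
    star_mismatches: int = 0
    depth_mean: float = 50.0
    dispersion: float = 5.0
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.005
    decoy_fraction: float = 0.3
    n_cleavage_sites: int = 20
    n_translation_sites: int = 5
    n_extra_transcripts: int = 10
    transcript_length: int = 600


def simulate_all(outdir, seed: int, config: Optional[SimConfig] = None) -> dict[str, Path]:
    """Write every pipeline input plus ``truth/*.tsv`` into ``outdir``.

    Child generators get independent streams spawned from ``seed`` so that
    any one output is reproducible from the same (seed, config).
    """
    cfg = config or SimConfig()
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(6)]

    refs, ref_truth = generate_reference(cfg.n_families, cfg.n_species, seeds[0])
    planted = refs[: cfg.n_planted]
    genome, genome_truth = plant_precursors(
        planted,
        n_scaffolds=cfg.n_scaffolds,
        scaffold_length=cfg.scaffold_length,
        loop_len=cfg.loop_len,
        star_mismatches=cfg.star_mismatches,
        seed=seeds[1],
    )
    class_refs = toy_class_references(seeds[2])
    reads, read_truth = simulate_reads(
        planted,
        depth_mean=cfg.depth_mean,
        dispersion=cfg.dispersion,
        adapter=cfg.adapter,
        error_rate=cfg.error_rate,
        decoy_fraction=cfg.decoy_fraction,
        class_refs=class_refs,
        seed=seeds[3],
    )
    mirnas = [(r.ref_id, r.sequence) for r in planted]
    specs = default_site_specs(
        mirnas, cfg.n_cleavage_sites, cfg.n_translation_sites, seed=seeds[4]
    )
    transcripts, target_truth = generate_transcriptome(
        specs, cfg.n_extra_transcripts, cfg.transcript_length, seed=seeds[4]
    )
    go = generate_go(sorted(transcripts), seed=seeds[5])
    stress_genes = pick_stress_genes(target_truth, seed=seeds[5])

    paths = {
        "mature": outdir / "mature.fa",
        "genome": outdir / "genome.fa",
        "reads": outdir / "reads.fastq",
        "transcripts": outdir / "transcripts.fa",
        "go": outdir / "go_annotations.tsv",
        "stress_genes": outdir / "stress_genes.txt",
    }
    write_fasta(paths["mature"], [(r.ref_id, r.sequence) for r in refs])
    write_fasta(paths["genome"], genome.items())
    write_fastq(paths["reads"], reads)
    write_fasta(paths["transcripts"], transcripts.items())
    go.to_csv(paths["go"], sep="\t", index=False)
    paths["stress_genes"].write_text("\n".join(stress_genes) + "\n")
    for label, seqs in class_refs:
        safe = label.replace("/", "_")
        p = outdir / f"class_{safe}.fa"
        write_fasta(p, [(f"{safe}{i + 1}", s) for i, s in enumerate(seqs)])
        paths[f"class_{safe}"] = p

    ref_truth.to_csv(outdir / "truth" / "reference.tsv", sep="\t", index=False)
    genome_truth.to_csv(outdir / "truth" / "precursors.tsv", sep="\t", index=False)
    read_truth.to_csv(outdir / "truth" / "reads.tsv", sep="\t", index=False)
    target_truth.to_csv(outdir / "truth" / "targets.tsv", sep="\t", index=False)
    return paths
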