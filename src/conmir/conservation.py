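"""Stress-conservation analysis of miRNA families across plant species.

The evidence table is a family x (species, condition) boolean matrix of
literature support for salt- and drought-responsiveness.  A family counts as
stress-related for a condition when at least one species carries evidence for
it.  The module also intersects predicted target genes with a stress-gene
list, annotating each record with the family's salt/drought status.

Two transcribed literature tables ship with the package as TSV data files and
can be loaded with :func:`load_evidence_table` / :func:`load_stress_targets`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .targets import TargetHit

_TRUTHY = {"1", "√", "true", "yes"}
_CELL_MAP = {"1": 1, "0": 0, "": 0, "√": 1, "x": 0}


@dataclass
class EvidenceTable:
    """Boolean family x (species, condition) evidence matrix."""

    data: pd.DataFrame  # index: family; columns: MultiIndex (species, condition)

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return sorted({c for _, c in self.data.columns})

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for sp, _ in self.data.columns:
            if sp not in seen:
                seen.append(sp)
        return seen

    def _condition_block(self, condition: str) -> pd.DataFrame:
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}; table has {self.conditions}")
        return self.data.loc[:, [c for c in self.data.columns if c[1] == condition]]


@dataclass(frozen=True)
class StressTargetRecord:
    family: str
    mirna_name: str
    drought: bool
    salt: bool
    target_gene_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (self.drought or self.salt):
            raise ValueError(f"{self.mirna_name}: neither drought nor salt evidence")


def read_evidence_table(path) -> EvidenceTable:
    """Read a TSV evidence table; header columns are ``species|condition``.

    Cells may be 1/0, blank, or a checkmark transcribed as 1.  Duplicate
    family rows raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.empty or df.shape[1] < 2:
        raise ValueError("evidence table is empty or has no condition columns")
    fam_col = df.columns[0]
    if df[fam_col].duplicated().any():
        dups = df.loc[df[fam_col].duplicated(), fam_col].tolist()
        raise ValueError(f"duplicate family rows: {dups}")
    cols = []
    for c in df.columns[1:]:
        if "|" not in c:
            raise ValueError(f"column {c!r} is not of the form species|condition")
        sp, cond = c.split("|", 1)
        cols.append((sp, cond))
    values = df.iloc[:, 1:].map(lambda v: _CELL_MAP.get(str(v).strip(), None))
    if values.isna().any().any():
        bad = sorted(set(df.iloc[:, 1:].values.ravel()) - set(_CELL_MAP))
        raise ValueError(f"unrecognised evidence cells: {bad}")
    values.columns = pd.MultiIndex.from_tuples(cols, names=["species", "condition"])
    values.index = pd.Index(df[fam_col], name="family")
    return EvidenceTable(data=values.astype(bool))


def write_evidence_table(table: EvidenceTable, path) -> None:
    out = table.data.astype(int)
    out.columns = [f"{sp}|{cond}" for sp, cond in out.columns]
    out.to_csv(path, sep="\t")


def load_evidence_table() -> EvidenceTable:
    """The packaged species x condition stress-evidence table (30 families)."""
    ref = resources.files("conmir.data").joinpath("table1_evidence.tsv")
    with resources.as_file(ref) as p:
        return read_evidence_table(p)


def condition_families(table: EvidenceTable, condition: str) -> list[str]:
    """Families with evidence in >= 1 species for ``condition``, sorted."""
    block = table._condition_block(condition)
    return sorted(block.index[block.any(axis=1)])


def condition_intersection(table: EvidenceTable, cond_a: str, cond_b: str) -> list[str]:
    return sorted(
        set(condition_families(table, cond_a)) & set(condition_families(table, cond_b))
    )


def conservation_histogram(table: EvidenceTable, condition: str) -> dict[int, int]:
    """Map (number of supporting species -> family count), zeros excluded."""
    block = table._condition_block(condition)
    support = block.sum(axis=1)
    support = support[support > 0]
    return {int(k): int(v) for k, v in support.value_counts().sort_index().items()}


def normalize_gene_id(gene_id: str) -> str:
    """Case-insensitive match with transcript/version suffix (".1") stripped."""
    return re.sub(r"\.\d+$", "", gene_id.strip()).upper()


def stress_gene_overlap(
    hits: Iterable[TargetHit],
    stress_genes: Iterable[str],
    evidence: Optional[EvidenceTable] = None,
    family_of: Optional[Mapping[str, str]] = None,
) -> list[StressTargetRecord]:
    """Target hits whose gene is in the stress list, as stress-target records.

    ``family_of`` maps mirna_id -> family (defaults to the mirna_id itself);
    salt/drought status comes from ``evidence`` when given, else both are
    marked True (unknown provenance is treated as stress-relevant by virtue
    of the list membership).
    """
    stress = {normalize_gene_id(g) for g in stress_genes}
    records: list[StressTargetRecord] = []
    for h in hits:
        if normalize_gene_id(h.transcript_id) not in stress:
            continue
        family = family_of.get(h.mirna_id, h.mirna_id) if family_of else h.mirna_id
        if evidence is not None and family in evidence.families:
            salt = family in condition_families(evidence, "salt")
            drought = family in condition_families(evidence, "drought")
            if not (salt or drought):
                continue
        else:
            salt = drought = True
        records.append(
            StressTargetRecord(
                family=family,
                mirna_name=h.mirna_id,
                drought=drought,
                salt=salt,
                target_gene_id=h.transcript_id,
            )
        )
    return records


def read_stress_targets(path) -> list[StressTargetRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        StressTargetRecord(
            family=r["family"],
            mirna_name=r["mirna_name"],
            drought=str(r["drought"]).strip() in _TRUTHY,
            salt=str(r["salt"]).strip() in _TRUTHY,
            target_gene_id=r["target_gene_id"],
            product=r.get("product", ""),
        )
        for _, r in df.iterrows()
    ]


def load_stress_targets() -> list[StressTargetRecord]:
    """The packaged stress-related target-prediction summary (30 records)."""
    ref = resources.files("conmir.data").joinpath("table2_stress_targets.tsv")
    with resources.as_file(ref) as p:
        return read_stress_targets(p)


def summary_counts(table: EvidenceTable) -> dict[str, int]:
    """(salt, drought, both) family counts as a small JSON-ready dict."""
    salt = condition_families(table, "salt")
    drought = condition_families(table, "drought")
    return {
        "salt": len(salt),
        "drought": len(drought),
        "both": len(set(salt) & set(drought)),
    }
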