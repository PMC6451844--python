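"""Descriptive profiling of identified miRNAs and GO clustering of targets.

``composition_report`` computes the read-length distribution, a position x
base count matrix and a per-length first-base matrix for a set of miRNA
sequences (U and T are one symbol, reported as U — the convention for mature
miRNAs).  ``go_cluster`` counts gene-term matches for a gene set per GO root
namespace and tabulates the ten most populous terms per namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .conservation import normalize_gene_id
from .sequtils import normalize

logger = logging.getLogger(__name__)

GO_NAMESPACES = ("biological process", "molecular function", "cellular component")
BASES = ("A", "C", "G", "U")


@dataclass
class CompositionReport:
    length_fractions: dict[int, float]
    position_base: pd.DataFrame = field(repr=False)  # index 1..max_len, columns BASES
    first_base_by_length: pd.DataFrame = field(repr=False)  # index length, columns BASES
    n_sequences: int = 0

    def write(self, lengths_path, position_path) -> None:
        with open(lengths_path, "w") as fh:
            fh.write("length\tfraction\n")
            for length in sorted(self.length_fractions):
                fh.write(f"{length}\t{self.length_fractions[length]:.6f}\n")
        self.position_base.to_csv(position_path, sep="\t", index_label="position")


def composition_report(sequences: Sequence[str]) -> CompositionReport:
    if not sequences:
        raise ValueError("no sequences to profile")
    seqs = [normalize(s).replace("T", "U") for s in sequences]
    n = len(seqs)
    lengths = pd.Series([len(s) for s in seqs])
    length_fractions = {
        int(k): float(v) for k, v in (lengths.value_counts().sort_index() / n).items()
    }
    max_len = int(lengths.max())
    pos = pd.DataFrame(0, index=range(1, max_len + 1), columns=list(BASES))
    first = pd.DataFrame(0, index=sorted(set(lengths)), columns=list(BASES))
    for s in seqs:
        for i, b in enumerate(s, start=1):
            if b in BASES:
                pos.loc[i, b] += 1
        if s[0] in BASES:
            first.loc[len(s), s[0]] += 1
    return CompositionReport(
        length_fractions=length_fractions,
        position_base=pos,
        first_base_by_length=first,
        n_sequences=n,
    )


@dataclass
class GoCluster:
    """Per-namespace GO term counts over a gene set (unit: gene-term match)."""

    term_counts: dict[str, pd.Series] = field(repr=False)  # namespace -> term -> count
    totals: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    empty: bool = False

    def top_terms(self, namespace: str, n: int = 10) -> pd.Series:
        """The ``n`` most populous terms of a namespace (ties by term name)."""
        counts = self.term_counts[namespace]
        ordered = counts.sort_index().sort_values(ascending=False, kind="stable")
        return ordered.head(n)

    def write_tsv(self, path, top_n: int = 10) -> None:
        with open(path, "w") as fh:
            fh.write("namespace\tterm\tgenes\tnamespace_total\tnamespace_fraction\n")
            for ns in GO_NAMESPACES:
                for term, count in self.top_terms(ns, top_n).items():
                    fh.write(
                        f"{ns}\t{term}\t{count}\t{self.totals[ns]}\t"
                        f"{self.fractions[ns]:.4f}\n"
                    )


def go_cluster(annotations: pd.DataFrame, genes: Iterable[str]) -> GoCluster:
    """Cluster GO annotations of ``genes`` by root namespace.

    ``annotations`` needs columns (gene, go_id, namespace, term).  Each
    distinct gene-term pair counts once.  Records with a namespace outside
    the three GO roots are skipped with a warning.  A gene set disjoint from
    the annotation yields zero counts and zero fractions, flagged ``empty``.
    """
    required = {"gene", "go_id", "namespace", "term"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    gene_set = {normalize_gene_id(g) for g in genes}
    df = annotations.copy()
    df["namespace"] = df["namespace"].str.strip().str.lower()
    unknown = ~df["namespace"].isin(GO_NAMESPACES)
    if unknown.any():
        logger.warning(
            "go_cluster: skipping %d records with unknown namespaces %s",
            int(unknown.sum()),
            sorted(df.loc[unknown, "namespace"].unique()),
        )
        df = df[~unknown]
    df = df[df["gene"].map(normalize_gene_id).isin(gene_set)]
    df = df.drop_duplicates(subset=["gene", "term", "namespace"])

    term_counts: dict[str, pd.Series] = {}
    totals: dict[str, int] = {}
    for ns in GO_NAMESPACES:
        sub = df[df["namespace"] == ns]
        term_counts[ns] = sub.groupby("term").size() if not sub.empty else pd.Series(dtype=int)
        totals[ns] = int(len(sub))
    grand = sum(totals.values())
    fractions = {ns: (totals[ns] / grand if grand else 0.0) for ns in GO_NAMESPACES}
    return GoCluster(
        term_counts=term_counts, totals=totals, fractions=fractions, empty=grand == 0
    )
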