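"""Relative allele and gene usage with duplicated-gene collapsing.

Duplicated IGHV genes can carry identical reference alleles, so an
annotator must emit multi-label calls such as
``"IGHV3-23*01, IGHV3-23D*01"``.  Those reads are genuinely usable — the
ambiguity reflects duplicated reference, not alignment failure — so before
usage analysis a small set of collapse rules rewrites each such *label
set* to a single merged label (``IGHV3-23*01D``, read "either copy").
Remaining multi-label calls are removed by the analysis-read filter.

Relative usage of an allele within an individual is the fraction of their
retained reads annotated with exactly that label; gene usage sums allele
fractions over alleles of the same gene, with merged labels mapped to
their own pseudo-gene (e.g. ``IGHV3-23(D)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .germline import parse_label

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CollapseRule:
    labels: frozenset[str]
    collapsed: str
    pseudo_gene: str


DEFAULT_COLLAPSE_RULES: tuple[CollapseRule, ...] = (
    CollapseRule(frozenset({"IGHV3-23*01", "IGHV3-23D*01"}), "IGHV3-23*01D", "IGHV3-23(D)"),
    CollapseRule(frozenset({"IGHV1-69*01", "IGHV1-69D*01"}), "IGHV1-69*01D", "IGHV1-69(D)"),
    CollapseRule(frozenset({"IGHV2-70*04", "IGHV2-70D*04"}), "IGHV2-70*04D", "IGHV2-70(D)"),
    CollapseRule(frozenset({"IGHV3-30-5*01", "IGHV3-30*18"}), "IGHV3-30X*doub", "IGHV3-30X"),
    CollapseRule(frozenset({"IGHV3-30-5*01", "IGHV3-30*18", "IGHV3-30*01"}), "IGHV3-30X*trip", "IGHV3-30X"),
)


@dataclass(frozen=True)
class CollapseMap:
    """Exact label-set → merged-label rules (order-insensitive matching)."""

    rules: tuple[CollapseRule, ...] = DEFAULT_COLLAPSE_RULES

    def __post_init__(self) -> None:
        collapsed = [r.collapsed for r in self.rules]
        if len(set(collapsed)) != len(collapsed):
            raise ValueError("collapsed labels must be unique")

    def collapse(self, v_call: str) -> str:
        labels = frozenset(t.strip() for t in v_call.split(","))
        for rule in self.rules:
            if labels == rule.labels:
                return rule.collapsed
        return v_call

    def pseudo_gene(self, label: str) -> str | None:
        for rule in self.rules:
            if rule.collapsed == label:
                return rule.pseudo_gene
        return None

    @classmethod
    def for_database(cls, db) -> "CollapseMap":
        """Rules for every duplicated-gene pair with identical V-REGIONs in ``db``.

        Includes the default (human-locus) rules, then adds a rule for each
        set of alleles in ``db`` sharing an identical ungapped V-REGION:
        the merged label is the lexicographically first label with a ``D``
        suffix, the pseudo-gene is ``gene(D)``.
        """
        by_seq: dict[str, list] = {}
        for allele in db:
            by_seq.setdefault(allele.v_region_ungapped, []).append(allele)
        rules = list(DEFAULT_COLLAPSE_RULES)
        known = {r.labels for r in rules}
        for alleles in by_seq.values():
            if len(alleles) < 2:
                continue
            labels = frozenset(a.label for a in alleles)
            if labels in known:
                continue
            first = sorted(alleles, key=lambda a: a.label)[0]
            rules.append(CollapseRule(labels, first.label + "D", first.gene + "(D)"))
        return cls(tuple(rules))


def collapse_vcalls(table: pd.DataFrame, cmap: CollapseMap | None = None) -> pd.DataFrame:
    """Rewrite multi-label ``v_call`` strings matching a collapse rule.

    Matching is on the label *set*, so annotator ordering is irrelevant;
    non-matching multi-label calls are left untouched (to be removed later
    by the analysis-read filter).
    """
    cmap = cmap or CollapseMap()
    out = table.copy()
    out["v_call"] = out["v_call"].map(cmap.collapse)
    return out


def allele_usage(table: pd.DataFrame, expected_samples: list[str] | None = None
                 ) -> pd.DataFrame:
    """Per-sample relative allele usage (rows = samples, columns = alleles).

    Expects a table already collapsed and filtered to single-call analysis
    reads; each row of the result sums to 1.  Samples listed in
    ``expected_samples`` but absent from the table are omitted with a
    logged warning.
    """
    counts = table.groupby(["sample_id", "v_call"]).size().unstack(fill_value=0)
    usage = counts.div(counts.sum(axis=1), axis=0)
    if expected_samples is not None:
        for s in expected_samples:
            if s not in usage.index:
                logger.warning("sample %s has no retained reads; omitted from usage", s)
    usage.columns.name = "allele"
    return usage


def gene_of_label(label: str, cmap: CollapseMap | None = None) -> str:
    """Gene (or pseudo-gene, for merged labels) of an allele label."""
    cmap = cmap or CollapseMap()
    pseudo = cmap.pseudo_gene(label)
    if pseudo is not None:
        return pseudo
    gene, _ = parse_label(label)
    return gene


def gene_usage(allele_fractions: pd.DataFrame, cmap: CollapseMap | None = None
               ) -> pd.DataFrame:
    """Sum allele fractions into per-gene fractions (exact coarsening).

    Every gene detected in at least one sample appears as a column; merged
    duplicated-gene labels contribute to their own pseudo-gene.
    """
    cmap = cmap or CollapseMap()
    genes = {label: gene_of_label(label, cmap) for label in allele_fractions.columns}
    out = allele_fractions.T.groupby(allele_fractions.columns.map(genes)).sum().T
    out.columns.name = "gene"
    return out


def usage_long(usage: pd.DataFrame, value_name: str = "fraction") -> pd.DataFrame:
    """Long-format (sample, label, fraction) table for plotting."""
    col = usage.columns.name or "label"
    long = usage.reset_index().melt(id_vars="sample_id", var_name=col, value_name=value_name)
    return long[long[value_name] > 0].reset_index(drop=True)
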