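"""Upstream-based disambiguation of near-identical V alleles.

Duplicated IGHV genes (e.g. IGHV3-64 and IGHV3-64D) can have reference
alleles that differ at only a couple of V-REGION positions, so a novel
allele lying between them cannot be assigned to a gene from the V-REGION
alone.  Their upstream sequences, however, typically differ across the
whole 5'UTR/leader, so comparing a candidate's upstream consensus against
each competing gene's upstream records resolves the assignment: the gene
whose records are closest (right-anchored, over the common support, N
positions skipped) wins, provided it wins by at least ``min_margin``
mismatches; otherwise the call is "ambiguous" — never a coin flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .germline import GermlineAllele, diff_positions
from .upstream import UpstreamConsensusRecord

AMBIGUOUS = "ambiguous"


class NoOverlapError(ValueError):
    """Candidate and record upstream sequences share no comparable window."""


@dataclass(frozen=True)
class DisambiguationCall:
    """Outcome of assigning a candidate to one of several competing genes."""

    candidate: str
    distances: dict[str, int]  # gene -> best mismatch count over its records
    assigned: str  # gene name, or "ambiguous"
    margin: int | None  # runner-up distance − best distance (None if single gene)
    relabeled: str | None = None  # new label after reassignment, if computed


def _upstream_distance(candidate: str, record: str) -> int | None:
    window = min(len(candidate), len(record))
    if window == 0:
        return None
    comparable = sum(
        1 for k in range(1, window + 1)
        if candidate[-k] not in "N." and record[-k] not in "N."
    )
    if comparable == 0:
        return None
    return len(diff_positions(candidate, record, anchor="right"))


def assign_by_upstream(candidate_upstream: str,
                       gene_records: dict[str, list[UpstreamConsensusRecord | str]],
                       min_margin: int = 1,
                       candidate_label: str = "candidate") -> DisambiguationCall:
    """Assign a candidate to the competing gene with the closest upstream.

    ``gene_records`` maps each competing gene to its upstream consensus
    records (records or raw sequences).  The distance to a gene is the
    minimum mismatch count over its records, compared right-anchored over
    the common support with N positions skipped.  The unique minimizer is
    assigned if the runner-up is at least ``min_margin`` mismatches worse;
    ties (including identical upstream records for both genes) yield
    ``"ambiguous"``.  The result does not depend on gene order.
    """
    if not gene_records:
        raise ValueError("no competing genes supplied")
    distances: dict[str, int] = {}
    for gene in sorted(gene_records):
        records = gene_records[gene]
        if not records:
            raise ValueError(f"gene {gene} has no upstream records")
        best: int | None = None
        for rec in records:
            seq = rec.sequence if isinstance(rec, UpstreamConsensusRecord) else rec
            d = _upstream_distance(candidate_upstream, seq)
            if d is not None and (best is None or d < best):
                best = d
        if best is None:
            raise NoOverlapError(
                f"no comparable window between candidate and records of {gene}")
        distances[gene] = best
    ranked = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ranked) == 1:
        return DisambiguationCall(candidate_label, distances, ranked[0][0], None)
    margin = ranked[1][1] - ranked[0][1]
    assigned = ranked[0][0] if margin >= min_margin else AMBIGUOUS
    return DisambiguationCall(candidate_label, distances, assigned, margin)


def relabel_to_gene(candidate_v_region: str, gene_alleles: list[GermlineAllele]) -> str:
    """Rename a candidate against the newly assigned gene's closest allele.

    Finds the closest allele of the assigned gene by mismatch count over
    the (gapped) V-REGION and names the candidate by its substitution(s)
    relative to it — the same sequence can legitimately carry one label
    per plausible parent gene (e.g. a candidate annotated against one
    paralog gets an equivalent name against the other).
    """
    if not gene_alleles:
        raise ValueError("no alleles supplied for the assigned gene")
    best_allele = None
    best_diffs: list[tuple[int, str, str]] | None = None
    for allele in sorted(gene_alleles, key=lambda a: a.label):
        diffs = diff_positions(allele.v_region, candidate_v_region, anchor="left")
        if best_diffs is None or len(diffs) < len(best_diffs):
            best_allele, best_diffs = allele, diffs
    assert best_allele is not None and best_diffs is not None
    if not best_diffs:
        return best_allele.label
    tokens = [f"{ref}{pos}{obs}" for pos, ref, obs in best_diffs]
    return f"{best_allele.label}_{'_'.join(tokens)}"


def calls_to_frame(calls: list[DisambiguationCall]) -> pd.DataFrame:
    """TSV-ready report: candidate, per-gene distances, assignment, margin."""
    rows = []
    for c in calls:
        row = {"candidate": c.candidate, "assigned": c.assigned, "margin": c.margin,
               "relabeled": c.relabeled or ""}
        for gene, d in sorted(c.distances.items()):
            row[f"dist_{gene}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
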