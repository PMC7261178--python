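"""Inference of consensus upstream sequences (5'UTR + L-PART1 + L-PART2).

The upstream region of each rearranged transcript is everything 5' of the
V-REGION.  Because library preparation truncates the 5'UTR variably, the
reads for one allele form a ragged right-anchored stack: position −1 is
the last L-PART2 base, immediately 5' of the V-REGION start.  The pipeline
turns that stack into a cohort database of upstream variants per allele:

1.  extract upstream fragments from analysis-grade reads, keeping the
    original V allele annotation;
2.  per gene, N-pad the 5' ends to equal length and trim everything 5' of
    the first position (scanning from the anchor) where ≥95% of reads are
    N, then drop the artificial Ns;
3.  per allele, keep only "frequent" lengths (frequency strictly above
    0.1): shorter reads are discarded, longer ones trimmed at the 5' end;
4.  per allele and individual, single-linkage cluster at 99.9% identity
    (effectively exact matching, Ns ignored) and build a 60%-majority
    consensus per cluster; clusters with fewer than 10 reads or frequency
    below 0.1 of the individual's reads for that allele are removed;
5.  consensuses still containing an ambiguous N where members disagree are
    split at the 5'-most such position and rebuilt, re-applying the
    cluster filters;
6.  per allele, all individuals' consensuses are trimmed to the shortest,
    deduplicated per individual, and identical sequences across
    individuals are collapsed into one record per distinct upstream
    variant, with the number of carrier individuals attached.

All coordinates in the output are negative, relative to the V-REGION
start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .germline import AlleleDatabase
from .qc import _N, _stack

logger = logging.getLogger(__name__)


class DegenerateLengthsError(ValueError):
    """No upstream length reaches the frequency threshold for an allele."""


@dataclass(frozen=True)
class UpstreamCluster:
    """One cluster of identical upstream reads for an allele in a sample."""

    allele: str
    sample_id: str
    members: tuple[int, ...]  # indices into the sample's read list
    consensus: str
    freq: float  # members / reads of this allele in this sample


@dataclass(frozen=True)
class UpstreamConsensusRecord:
    """One distinct upstream variant of an allele in the cohort database."""

    allele: str
    variant_index: int
    sequence: str
    n_individuals: int
    carriers: frozenset[str]

    @property
    def name(self) -> str:
        # suffix only when an allele has >1 variant; resolved at assembly
        return f"{self.allele}_{self.variant_index}"

    @property
    def start_coordinate(self) -> int:
        """Coordinate of the first (5'-most) base, counting −1 = last base."""
        return -len(self.sequence)


# ---------------------------------------------------------------------------
# Stage operations

def extract_upstream(table: pd.DataFrame, db: AlleleDatabase | None = None) -> pd.DataFrame:
    """Split off everything 5' of the V-REGION, keeping the V annotation.

    Returns a frame with columns ``allele``, ``sample_id``, ``bases``;
    reads with an empty upstream are dropped.  Expects analysis-grade
    reads (single ``v_call``, ≤3 mutations).
    """
    bases = [
        seq[: int(start) - 1]
        for seq, start in zip(table["sequence"], table["v_sequence_start"])
    ]
    out = pd.DataFrame({
        "allele": table["v_call"].to_numpy(),
        "sample_id": table["sample_id"].to_numpy(),
        "bases": bases,
    })
    return out[out["bases"].str.len() > 0].reset_index(drop=True)


def pad_and_trim_95n(seqs: list[str], n_frac: float = 0.95) -> list[str]:
    """Trim ragged 5' ends where ≥``n_frac`` of right-anchored reads are N.

    Reads are conceptually right-anchored and N-padded to the longest;
    scanning from the anchor (position −1) toward 5', the first position
    whose N fraction reaches ``n_frac`` — together with everything 5' of
    it — is removed, and the artificial padding is dropped.  If no
    position reaches the threshold the reads are returned unchanged.
    """
    if not seqs:
        return []
    arr = _right_stack(seqs)
    n_fracs = (arr == _N).mean(axis=0)  # column 0 = 5'-most, last column = −1
    width = arr.shape[1]
    keep = width
    for k in range(1, width + 1):  # k = distance from anchor (position −k)
        if n_fracs[width - k] >= n_frac:
            keep = k - 1
            break
    return [s[len(s) - keep:] if len(s) > keep else s for s in seqs]


def _right_stack(seqs: list[str]) -> np.ndarray:
    """Byte matrix of right-anchored sequences, left-padded with N."""
    width = max(len(s) for s in seqs)
    buf = "".join(s.rjust(width, "N") for s in seqs).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(seqs), width)


def length_frequency_filter(seqs: list[str], min_len_freq: float = 0.1
                            ) -> list[str]:
    """Remove extreme-length reads for one allele.

    Lengths with frequency strictly above ``min_len_freq`` are "frequent";
    reads shorter than the shortest frequent length are dropped, reads
    longer than the longest frequent length are 5'-trimmed to it.  Raises
    :class:`DegenerateLengthsError` when no length is frequent.
    """
    if not seqs:
        return []
    lengths = pd.Series([len(s) for s in seqs])
    freqs = lengths.value_counts(normalize=True)
    frequent = freqs[freqs > min_len_freq].index
    if len(frequent) == 0:
        raise DegenerateLengthsError("no upstream length reaches the frequency threshold")
    lo, hi = int(frequent.min()), int(frequent.max())
    out = []
    for s in seqs:
        if len(s) < lo:
            continue
        out.append(s[len(s) - hi:] if len(s) > hi else s)
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Identity over the right-anchored overlap; N positions are skipped.

    Returns matches / compared positions, or 0.0 when nothing is
    comparable.
    """
    window = min(len(a), len(b))
    matches = compared = 0
    for k in range(1, window + 1):
        ca, cb = a[-k], b[-k]
        if ca == "N" or cb == "N":
            continue
        compared += 1
        if ca == cb:
            matches += 1
    return matches / compared if compared else 0.0


def cluster_reads(seqs: list[str], ident: float = 0.999) -> list[list[int]]:
    """Single-linkage clusters of reads at pairwise identity ≥ ``ident``.

    At the default 0.999 and typical upstream lengths (<1000 nt) a single
    mismatch breaks a link, so this reduces to exact-match grouping over
    the overlap, ignoring Ns.  Returns clusters as lists of read indices,
    largest first.
    """
    if not seqs:
        return []
    # All-N reads have no comparable positions (identity 0 to everything,
    # themselves included): each is its own singleton cluster.
    singletons = [i for i, s in enumerate(seqs) if not set(s) & set("ACGT")]
    # collapse exact duplicates first; linkage is transitive over them
    uniq: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        if i not in singletons:
            uniq.setdefault(s, []).append(i)
    if not uniq:
        return sorted(([i] for i in singletons), key=lambda c: (-len(c), c))
    keys = list(uniq)
    parent = list(range(len(keys)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if pairwise_identity(keys[i], keys[j]) >= ident:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(find(i), []).extend(uniq[key])
    clusters = [sorted(members) for members in groups.values()]
    clusters.extend([i] for i in singletons)
    return sorted(clusters, key=lambda c: (-len(c), c))


def build_consensus(seqs: list[str], freq: float = 0.6) -> str:
    """Per-position majority consensus of right-anchored reads.

    At each position the modal base is called if its frequency among
    non-N bases is at least ``freq``; otherwise the position is N.
    Positions covered by no read (left padding) are N.  The consensus
    length equals the longest member.
    """
    if not seqs:
        return ""
    arr = _right_stack(seqs)
    out = []
    for col in arr.T:
        counts = {b: int((col == ord(b)).sum()) for b in "ACGT"}
        total = sum(counts.values())
        if total == 0:
            out.append("N")
            continue
        base = max(counts, key=lambda b: (counts[b], b))
        out.append(base if counts[base] / total >= freq else "N")
    return "".join(out)


def filter_clusters(clusters: list[UpstreamCluster], min_members: int = 10,
                    min_freq: float = 0.1) -> list[UpstreamCluster]:
    """Keep clusters with ≥ ``min_members`` reads and frequency ≥ ``min_freq``.

    Both bounds are inclusive: exactly 10 members at exactly 0.1 survives.
    """
    return [c for c in clusters
            if len(c.members) >= min_members and c.freq >= min_freq]


def _splittable_position(seqs: list[str], consensus: str) -> int | None:
    """5'-most consensus-N position where members actually disagree.

    Returns an index into the right-anchored frame (0 = 5'-most), or None.
    Positions that are N only through padding (no two distinct called
    bases) are not splittable.
    """
    arr = _right_stack(seqs)
    width = arr.shape[1]
    offset = width - len(consensus)
    for p, c in enumerate(consensus):
        if c != "N":
            continue
        col = arr[:, offset + p]
        called = {b for b in "ACGT" if (col == ord(b)).any()}
        if len(called) >= 2:
            return offset + p
    return None


def split_ambiguous(seqs: list[str], freq: float = 0.6
                    ) -> list[tuple[list[int], str]]:
    """Split one cluster at its 5'-most genuinely ambiguous position.

    Members are partitioned by their base at the 5'-most position where
    the consensus is N but members carry at least two distinct bases
    (reads with N there form their own part); a consensus is rebuilt per
    part.  If there is no such position the cluster is returned as a
    single part with its consensus.  One level of splitting only — the
    pipeline re-applies the cluster filters and recurses.
    """
    cons = build_consensus(seqs, freq=freq)
    pos = _splittable_position(seqs, cons)
    if pos is None:
        return [(list(range(len(seqs))), cons)]
    arr = _right_stack(seqs)
    parts: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        parts.setdefault(int(arr[i, pos]), []).append(i)
    out = []
    for key in sorted(parts):
        members = parts[key]
        out.append((members, build_consensus([seqs[i] for i in members], freq=freq)))
    return out


def _resolve_clusters(allele: str, sample_id: str, seqs: list[str], total: int,
                      ident: float, cons_freq: float, min_members: int,
                      min_freq: float) -> list[UpstreamCluster]:
    """Cluster one allele+sample group, with recursive ambiguity splitting."""
    initial = [
        UpstreamCluster(allele, sample_id, tuple(members),
                        build_consensus([seqs[i] for i in members], freq=cons_freq),
                        len(members) / total)
        for members in cluster_reads(seqs, ident=ident)
    ]
    queue = filter_clusters(initial, min_members, min_freq)
    done: list[UpstreamCluster] = []
    while queue:
        clu = queue.pop()
        member_seqs = [seqs[i] for i in clu.members]
        parts = split_ambiguous(member_seqs, freq=cons_freq)
        if len(parts) == 1:
            done.append(replace(clu, consensus=parts[0][1]))
            continue
        children = [
            UpstreamCluster(allele, sample_id,
                            tuple(clu.members[i] for i in members),
                            cons, len(members) / total)
            for members, cons in parts
        ]
        queue.extend(filter_clusters(children, min_members, min_freq))
    return sorted(done, key=lambda c: (-len(c.members), c.consensus))


def assemble_cohort_db(per_sample: pd.DataFrame) -> list[UpstreamConsensusRecord]:
    """Collapse per-individual consensuses into the cohort upstream database.

    ``per_sample`` must have columns ``allele``, ``sample_id``,
    ``sequence``.  Per allele, all consensuses are 5'-trimmed to the
    shortest, deduplicated within each individual, and identical sequences
    across individuals become one record; variant indices are assigned in
    descending carrier count, ties broken lexicographically.  The result
    is invariant to sample processing order.
    """
    records: list[UpstreamConsensusRecord] = []
    for allele, grp in per_sample.groupby("allele"):
        shortest = int(grp["sequence"].str.len().min())
        trimmed = grp["sequence"].str[-shortest:]
        pairs = set(zip(grp["sample_id"], trimmed))  # re-collapse per individual
        carriers: dict[str, set[str]] = {}
        for sample, seq in pairs:
            carriers.setdefault(seq, set()).add(sample)
        ordered = sorted(carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        for i, (seq, samples) in enumerate(ordered, start=1):
            records.append(UpstreamConsensusRecord(
                allele=str(allele), variant_index=i, sequence=seq,
                n_individuals=len(samples), carriers=frozenset(samples)))
    return sorted(records, key=lambda r: (r.allele, r.variant_index))


# ---------------------------------------------------------------------------
# Pipeline driver

def infer_upstream_db(table: pd.DataFrame, db: AlleleDatabase | None = None,
                      n_trim_frac: float = 0.95, min_len_freq: float = 0.1,
                      ident: float = 0.999, cons_freq: float = 0.6,
                      min_members: int = 10, min_cluster_freq: float = 0.1,
                      ) -> tuple[list[UpstreamConsensusRecord], pd.DataFrame]:
    """Run the full upstream inference on an analysis-grade read table.

    Returns the cohort database records and the per-sample consensus table
    (columns ``allele``, ``sample_id``, ``sequence``, ``members``,
    ``freq``).  Alleles whose upstream lengths are all infrequent are
    skipped with a warning.
    """
    ups = extract_upstream(table, db)
    if ups.empty:
        return [], pd.DataFrame(columns=["allele", "sample_id", "sequence", "members", "freq"])

    # stage 2: per-gene 95%-N trimming (pooled across the gene's alleles)
    genes = ups["allele"].str.split("*").str[0]
    trimmed = pd.Series(index=ups.index, dtype=object)
    for _, idx in genes.groupby(genes).groups.items():
        seqs = ups.loc[idx, "bases"].tolist()
        trimmed.loc[idx] = pad_and_trim_95n(seqs, n_frac=n_trim_frac)
    ups["bases"] = trimmed
    ups = ups[ups["bases"].str.len() > 0]

    consensus_rows: list[dict] = []
    for allele, allele_grp in ups.groupby("allele"):
        try:
            filtered = length_frequency_filter(allele_grp["bases"].tolist(),
                                               min_len_freq=min_len_freq)
        except DegenerateLengthsError:
            logger.warning("allele %s: no frequent upstream length; skipped", allele)
            continue
        filtered_frame = pd.DataFrame({
            "sample_id": _reselect_samples(allele_grp, filtered, min_len_freq),
            "bases": filtered,
        })
        for sample, sample_grp in filtered_frame.groupby("sample_id"):
            seqs = sample_grp["bases"].tolist()
            for clu in _resolve_clusters(str(allele), str(sample), seqs, len(seqs),
                                         ident, cons_freq, min_members,
                                         min_cluster_freq):
                consensus_rows.append({
                    "allele": clu.allele,
                    "sample_id": clu.sample_id,
                    "sequence": clu.consensus,
                    "members": len(clu.members),
                    "freq": clu.freq,
                })
    per_sample = pd.DataFrame(consensus_rows,
                              columns=["allele", "sample_id", "sequence", "members", "freq"])
    if per_sample.empty:
        return [], per_sample
    records = assemble_cohort_db(per_sample)
    return records, per_sample


def _reselect_samples(allele_grp: pd.DataFrame, filtered: list[str],
                      min_len_freq: float) -> list[str]:
    """Sample ids aligned with length_frequency_filter's output order."""
    lengths = allele_grp["bases"].str.len()
    freqs = lengths.value_counts(normalize=True)
    frequent = freqs[freqs > min_len_freq].index
    lo = int(frequent.min())
    return [s for s, n in zip(allele_grp["sample_id"], lengths) if n >= lo]


# ---------------------------------------------------------------------------
# Output writers

def _variant_names(records: list[UpstreamConsensusRecord]) -> dict[UpstreamConsensusRecord, str]:
    per_allele: dict[str, int] = {}
    for r in records:
        per_allele[r.allele] = max(per_allele.get(r.allele, 0), r.variant_index)
    return {r: (r.name if per_allele[r.allele] > 1 else r.allele) for r in records}


def upstream_db_to_frame(records: list[UpstreamConsensusRecord]) -> pd.DataFrame:
    names = _variant_names(records)
    return pd.DataFrame([{
        "allele": r.allele,
        "variant_index": r.variant_index,
        "name": names[r],
        "n_individuals": r.n_individuals,
        "sequence": r.sequence,
        "start_coordinate": r.start_coordinate,
    } for r in records])


def write_upstream_db_tsv(records: list[UpstreamConsensusRecord], path: str | Path) -> None:
    upstream_db_to_frame(records).to_csv(path, sep="\t", index=False)


def write_upstream_db_fasta(records: list[UpstreamConsensusRecord], path: str | Path) -> None:
    names = _variant_names(records)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{names[r]}\n{r.sequence}\n")


def write_upstream_db_xlsx(records: list[UpstreamConsensusRecord], path: str | Path) -> None:
    """Optional XLSX mirror of the upstream-variant table (needs openpyxl)."""
    upstream_db_to_frame(records).to_excel(path, index=False)


def upstream_db_long(records: list[UpstreamConsensusRecord]) -> pd.DataFrame:
    """Long-format (position, allele_variant, base) table for tile plots."""
    names = _variant_names(records)
    rows = [
        {"position": -len(r.sequence) + i, "allele_variant": names[r], "base": b}
        for r in records
        for i, b in enumerate(r.sequence)
    ]
    return pd.DataFrame(rows, columns=["position", "allele_variant", "base"])
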