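"""Sample- and read-level quality filters applied before all analyses.

Two kinds of filtering happen up front: whole samples with low sequencing
depth are excluded (strictly fewer than 2000 reads by default), and
individual reads are restricted to near-germline, unambiguously annotated
sequences — V-REGION longer than 200 nt, at most three mismatches to the
assigned germline allele counted over gapped coordinates up to position 312
(the region inference tools actually cover), and, where required, a single
allele label in ``v_call``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .germline import GAP, AlleleDatabase

_N = ord("N")


def filter_samples_by_depth(table: pd.DataFrame, min_depth: int = 2000
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop whole samples with read count strictly below ``min_depth``.

    Returns the retained table and an exclusion report with columns
    ``sample_id``, ``depth``, ``reason``.  A sample at exactly ``min_depth``
    is retained.
    """
    counts = table.groupby("sample_id").size()
    excluded = counts[counts < min_depth]
    report = pd.DataFrame({
        "sample_id": excluded.index,
        "depth": excluded.to_numpy(),
        "reason": "low_depth",
    }).reset_index(drop=True)
    kept = table[~table["sample_id"].isin(excluded.index)].copy()
    return kept, report


def first_v_call(v_call: str) -> str:
    return v_call.split(",")[0].strip()


def _resolve_label(label: str, db: AlleleDatabase, cmap=None) -> str:
    """Resolve a (possibly collapsed) label to a database allele label.

    Merged duplicated-gene labels (e.g. ``IGHV3-23*01D``) are mapped to any
    constituent allele — constituents share an identical V-REGION.
    """
    if label in db or cmap is None:
        return label
    for rule in cmap.rules:
        if rule.collapsed == label:
            return sorted(rule.labels)[0]
    return label


def v_region_length(table: pd.DataFrame) -> pd.Series:
    return table["sequence"].str.len() - table["v_sequence_start"] + 1


def _stack(seqs: list[str]) -> np.ndarray:
    """Byte matrix of sequences, right-padded with N (treated as no data)."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    width = max(len(s) for s in seqs)
    buf = "".join(s.ljust(width, "N") for s in seqs).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(seqs), max(width, 1) if width else 0)


def _comparable_positions(v_gapped: str, max_position: int) -> tuple[np.ndarray, np.ndarray]:
    """Read-string indices and germline bytes for gapped coords 1..max_position.

    Gap positions consume a coordinate but nothing in the read; germline N
    positions are skipped.
    """
    read_idx: list[int] = []
    germ: list[int] = []
    j = 0
    for c in v_gapped[:max_position]:
        if c == GAP:
            continue
        if c != "N":
            read_idx.append(j)
            germ.append(ord(c))
        j += 1
    return np.asarray(read_idx, dtype=int), np.asarray(germ, dtype=np.uint8)


def count_v_mutations(read: pd.Series | dict, db: AlleleDatabase,
                      max_position: int = 312) -> int:
    """Mismatches between one read's V-REGION and its assigned germline.

    The germline is the first ``v_call`` label; comparison runs over gapped
    germline coordinates 1..``max_position``, skipping N and gap positions,
    and stops at the read's end.
    """
    label = _resolve_label(first_v_call(read["v_call"]), db)
    germ = db[label].v_region
    read_v = read["sequence"][int(read["v_sequence_start"]) - 1:]
    n = 0
    j = 0
    for c in germ[:max_position]:
        if c == GAP:
            continue
        if j >= len(read_v):
            break
        r = read_v[j]
        j += 1
        if c == "N" or r == "N":
            continue
        if r != c:
            n += 1
    return n


def count_v_mutations_table(table: pd.DataFrame, db: AlleleDatabase,
                            max_position: int = 312, cmap=None) -> np.ndarray:
    """Vectorized mutation counts, one per row, in table order."""
    out = np.zeros(len(table), dtype=int)
    if not len(table):
        return out
    labels = table["v_call"].map(lambda v: _resolve_label(first_v_call(v), db, cmap))
    seqs = table["sequence"].to_numpy()
    starts = table["v_sequence_start"].to_numpy(dtype=int)
    pos = np.arange(len(table))
    for label, grp_pos in pd.Series(pos).groupby(labels.to_numpy()).groups.items():
        grp = np.asarray(grp_pos, dtype=int)
        germ = db[str(label)].v_region
        ridx, gbytes = _comparable_positions(germ, max_position)
        arr = _stack([seqs[k][starts[k] - 1:] for k in grp])
        mask = ridx < arr.shape[1]
        if arr.shape[1] == 0 or not mask.any():
            continue
        sub = arr[:, ridx[mask]]
        mism = (sub != gbytes[mask]) & (sub != _N)
        out[grp] = mism.sum(axis=1)
    return out


def select_analysis_reads(table: pd.DataFrame, db: AlleleDatabase,
                          max_mut: int = 3, min_vlen: int = 200,
                          require_single_call: bool = True, cmap=None) -> pd.DataFrame:
    """Keep reads suitable for usage and upstream analyses.

    Retains reads whose V-REGION length is strictly greater than
    ``min_vlen``, with at most ``max_mut`` mutations to the assigned
    germline, and — when ``require_single_call`` — exactly one label in
    ``v_call`` (apply any duplicated-gene collapsing beforehand).  The
    result is always a subset of the input and the operation is idempotent.
    """
    keep = v_region_length(table) > min_vlen
    if require_single_call:
        keep &= ~table["v_call"].str.contains(",")
    subset = table[keep]
    muts = count_v_mutations_table(subset, db, cmap=cmap)
    return subset[muts <= max_mut].copy()
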