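"""False-positive filtering of candidate novel germline alleles.

Recurrent identical "mutations" in near-unmutated naïve reads are the
signature of an undocumented germline allele — but PCR and sequencing
artifacts leave the same signature.  The filter implemented here scores
each candidate by its *mismatch frequency*: within each carrier
individual, the fraction of reads assigned to the closest germline allele
(in the original, pre-realignment annotation) that carry a non-reference
base at the candidate position.  A genuine heterozygous germline variant
sits near 0.5 (or higher, if homozygous); amplification artifacts sit much
lower.  Candidates below the threshold (default 0.35) in *all* carriers
are called false positives.  Two further rules catch artifacts the
frequency statistic cannot: candidates confined to a secondary sequencing
batch with 100% mutation frequency in every carrier, and a configurable
blacklist of recurrent artifact substitution patterns (default A152G,
T154G, A85C — A→C being the dominant Illumina MiSeq substitution error).

A naive positional candidate detector is included as plumbing so the
filter can be exercised end-to-end on simulated cohorts; it stands in for
external inference tools, not for their algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .germline import GAP, AlleleDatabase, name_novel
from .qc import _N, _stack, count_v_mutations_table, first_v_call

VERDICT_RETAINED = "retained"
VERDICT_LOW_FREQUENCY = "fp_low_frequency"
VERDICT_BATCH_ARTIFACT = "fp_batch_artifact"
VERDICT_BLACKLIST = "fp_blacklist"

DEFAULT_BLACKLIST = ("A152G", "T154G", "A85C")


class NoInformativeReadsError(ValueError):
    """A carrier has no reads covering the candidate position.

    Distinct from a mismatch frequency of 0.0, which means reads cover the
    position and all match the germline.
    """


@dataclass(frozen=True)
class NovelCandidate:
    """A putative novel allele: one substitution on a known reference."""

    closest_allele: str
    position: int  # 1-based gapped V-REGION coordinate
    from_base: str
    to_base: str
    carriers: frozenset[str] = frozenset()
    source_tool: str = "naive"
    verdict: str | None = None
    per_carrier_freq: dict[str, float] = field(default_factory=dict, compare=False)

    @property
    def substitution(self) -> str:
        return f"{self.from_base}{self.position}{self.to_base}"

    def label(self, db: AlleleDatabase) -> str:
        return name_novel(db[self.closest_allele], self.position, self.from_base, self.to_base)


def _position_read_index(v_gapped: str, position: int) -> int:
    """Map a gapped V-REGION coordinate to an index into the ungapped read."""
    if not 1 <= position <= len(v_gapped):
        raise ValueError(f"position {position} outside V-REGION (length {len(v_gapped)})")
    if v_gapped[position - 1] == GAP:
        raise ValueError(f"position {position} is a gap in the reference")
    return sum(1 for c in v_gapped[:position] if c != GAP) - 1


def _assigned_mask(v_calls: pd.Series, label: str) -> pd.Series:
    return v_calls.map(lambda s: label in [t.strip() for t in s.split(",")])


def mismatch_frequency(candidate: NovelCandidate, sample_reads: pd.DataFrame,
                       db: AlleleDatabase) -> float:
    """Fraction of one sample's assigned reads carrying the candidate base change.

    Denominator: reads of this sample whose (pre-realignment) ``v_call``
    includes the candidate's closest allele and that cover the candidate
    position with a called base.  Numerator: those whose base there differs
    from the germline ``from_base``.  Reads not covering the position, or
    with N there, are excluded from both.  Raises
    :class:`NoInformativeReadsError` on an empty denominator.
    """
    germ = db[candidate.closest_allele].v_region
    ref = germ[candidate.position - 1]
    if ref != candidate.from_base:
        raise ValueError(
            f"candidate from_base {candidate.from_base!r} disagrees with "
            f"{candidate.closest_allele} position {candidate.position} ({ref!r})")
    idx = _position_read_index(germ, candidate.position)
    assigned = sample_reads[_assigned_mask(sample_reads["v_call"], candidate.closest_allele)]
    num = den = 0
    for seq, start in zip(assigned["sequence"], assigned["v_sequence_start"]):
        v = seq[int(start) - 1:]
        if idx >= len(v) or v[idx] == "N":
            continue
        den += 1
        if v[idx] != candidate.from_base:
            num += 1
    if den == 0:
        raise NoInformativeReadsError(
            f"no reads informative for {candidate.closest_allele} position {candidate.position}")
    return num / den


def classify_candidates(candidates: list[NovelCandidate], table: pd.DataFrame,
                        db: AlleleDatabase, threshold: float = 0.35,
                        main_batch: str = "B1",
                        blacklist: tuple[str, ...] = DEFAULT_BLACKLIST,
                        apply_blacklist: bool = True,
                        ) -> tuple[list[NovelCandidate], pd.DataFrame]:
    """Assign a verdict to every candidate and build a per-candidate report.

    Rules, in decreasing precedence:

    * ``fp_blacklist`` — the substitution pattern (from, position, to) is
      blacklisted and pattern exclusion is enabled;
    * ``fp_batch_artifact`` — every carrier lies outside ``main_batch`` and
      every carrier's mismatch frequency equals 1.0;
    * ``fp_low_frequency`` — mismatch frequency below ``threshold`` in
      *all* carriers (a single carrier at or above it rescues the
      candidate);
    * otherwise ``retained``.
    """
    by_sample = {s: grp for s, grp in table.groupby("sample_id")}
    sample_batch = table.groupby("sample_id")["batch_id"].first()
    out: list[NovelCandidate] = []
    report_rows: list[dict] = []
    for cand in candidates:
        if not cand.carriers:
            raise ValueError(f"candidate {cand.substitution} has no carriers")
        missing = [s for s in cand.carriers if s not in by_sample]
        if missing:
            raise ValueError(f"candidate carriers absent from table: {missing}")
        freqs = {s: mismatch_frequency(cand, by_sample[s], db)
                 for s in sorted(cand.carriers)}
        if apply_blacklist and cand.substitution in blacklist:
            verdict = VERDICT_BLACKLIST
        elif (all(sample_batch[s] != main_batch for s in freqs)
              and all(f >= 1.0 - 1e-12 for f in freqs.values())):
            verdict = VERDICT_BATCH_ARTIFACT
        elif all(f < threshold for f in freqs.values()):
            verdict = VERDICT_LOW_FREQUENCY
        else:
            verdict = VERDICT_RETAINED
        out.append(replace(cand, verdict=verdict, per_carrier_freq=freqs))
        report_rows.append({
            "candidate": cand.label(db),
            "closest_allele": cand.closest_allele,
            "position": cand.position,
            "from_base": cand.from_base,
            "to_base": cand.to_base,
            "source_tool": cand.source_tool,
            "verdict": verdict,
            "carrier_frequencies": ";".join(f"{s}={f:.4f}" for s, f in freqs.items()),
        })
    return out, pd.DataFrame(report_rows)


def detect_candidates_naive(table: pd.DataFrame, db: AlleleDatabase,
                            min_reads: int = 50, min_freq: float = 0.2,
                            max_position: int = 312,
                            prefilter_max_mut: int = 1) -> list[NovelCandidate]:
    """Positional novel-allele candidate detector (plumbing, not inference).

    Reads are restricted to at most ``prefilter_max_mut`` mutations to
    their assigned germline.  Then, per sample and per allele with at least
    ``min_reads`` assigned reads, every V-REGION position (gapped
    coordinates up to ``max_position``) whose modal non-germline base
    reaches ``min_freq`` of the covering reads yields a candidate;
    identical candidates found in several samples are merged, carriers
    being the union.
    """
    muts = count_v_mutations_table(table, db, max_position=max_position)
    table = table[muts <= prefilter_max_mut]
    found: dict[tuple[str, int, str, str], set[str]] = {}
    labels = table["v_call"].map(first_v_call)
    for (sample, label), grp in table.groupby([table["sample_id"], labels]):
        if len(grp) < min_reads:
            continue
        germ = db[str(label)].v_region
        arr = _stack([s[int(v) - 1:] for s, v in zip(grp["sequence"], grp["v_sequence_start"])])
        if arr.shape[1] == 0:
            continue
        j = 0
        for gi, c in enumerate(germ[:max_position]):
            if c == GAP:
                continue
            ridx = j
            j += 1
            if c == "N" or ridx >= arr.shape[1]:
                continue
            col = arr[:, ridx]
            covered = col != _N
            n_cov = int(covered.sum())
            if n_cov == 0:
                continue
            best_base, best_count = None, 0
            for b in "ACGT":
                if b == c:
                    continue
                count = int((col == ord(b)).sum())
                if count > best_count:
                    best_base, best_count = b, count
            if best_base is not None and best_count / n_cov >= min_freq:
                key = (str(label), gi + 1, c, best_base)
                found.setdefault(key, set()).add(str(sample))
    out = [
        NovelCandidate(closest_allele=k[0], position=k[1], from_base=k[2],
                       to_base=k[3], carriers=frozenset(v))
        for k, v in found.items()
    ]
    return sorted(out, key=lambda c: (c.closest_allele, c.position, c.to_base))


# ---------------------------------------------------------------------------
# Candidate TSV I/O

_CAND_COLUMNS = ["closest_allele", "position", "from_base", "to_base", "carriers", "source_tool"]


def write_candidates(candidates: list[NovelCandidate], path) -> None:
    rows = [{
        "closest_allele": c.closest_allele,
        "position": c.position,
        "from_base": c.from_base,
        "to_base": c.to_base,
        "carriers": ";".join(sorted(c.carriers)),
        "source_tool": c.source_tool,
    } for c in candidates]
    pd.DataFrame(rows, columns=_CAND_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidates(path) -> list[NovelCandidate]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CAND_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise ValueError(f"candidates TSV missing columns: {missing}")
    return [
        NovelCandidate(
            closest_allele=row["closest_allele"],
            position=int(row["position"]),
            from_base=row["from_base"],
            to_base=row["to_base"],
            carriers=frozenset(s for s in row["carriers"].split(";") if s),
            source_tool=row.get("source_tool", "external") or "external",
        )
        for _, row in frame.iterrows()
    ]
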