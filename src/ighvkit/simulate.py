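"""Synthetic AIRR-seq cohorts with known germline truth.

The generator emulates a naïve B-cell heavy-chain repertoire experiment at
the level this package analyses it: each individual carries a diploid IGHV
genotype drawn from a small germline database (optionally with planted
heterozygous novel alleles and allele-specific upstream haplotypes); each
read is an upstream fragment (5'-truncated 5'UTR plus the full leader)
followed by the V-REGION with 0–3 germline-style point mutations, passed
through a uniform sequencing-error model with an optional A→C-biased mode
mimicking the dominant Illumina MiSeq substitution artifact.  The annotation
column ``v_call`` is filled the way an annotator would fill it: the closest
reference allele(s) by Hamming distance, so reads from a planted novel
allele are assigned to its closest reference allele and reads from
duplicated genes with identical references receive multi-label calls.

Everything is driven by a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .germline import (
    AlleleDatabase,
    GermlineAllele,
    closest_alleles,
)

AIRR_REQUIRED_COLUMNS = ["sequence", "v_call", "v_sequence_start", "sample_id", "batch_id"]
_OTHER_BASES = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


class MissingColumnError(ValueError):
    """A rearrangement table lacks one or more mandatory AIRR columns."""


@dataclass(frozen=True)
class NovelAlleleSpec:
    """A novel allele to plant: one substitution on a reference allele.

    ``position`` is 1-based over the (gapped) reference V-REGION.  Carrier
    individuals (drawn at ``population_frequency``) are heterozygous: one
    haplotype keeps the closest reference allele, the other carries the
    novel one.
    """

    closest: str
    position: int
    to_base: str
    population_frequency: float = 0.5


@dataclass(frozen=True)
class DepthLaw:
    """Per-sample read-count law: fixed, or log-normal (rounded, ≥1)."""

    kind: str = "fixed"  # "fixed" | "lognormal"
    depth: int = 2000
    meanlog: float = 8.0
    sdlog: float = 0.35

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.depth, dtype=int)
        if self.kind == "lognormal":
            return np.maximum(1, np.rint(rng.lognormal(self.meanlog, self.sdlog, n)).astype(int))
        raise ValueError(f"unknown depth law {self.kind!r}")


@dataclass
class SimConfig:
    """Full description of one synthetic cohort.

    Notes on defaults: allelic expression within a heterozygous gene is
    50:50 (``expression_imbalance`` is the probability of the first copy);
    the 5'UTR capture length follows a discrete triangular law rising to the
    full UTR length, so most reads capture the whole UTR but a tail is
    short; per-read V-REGION mutation counts follow ``mutation_probs`` over
    0..k mutations.
    """

    germline_db: AlleleDatabase
    n_individuals: int = 20
    depth: DepthLaw = field(default_factory=DepthLaw)
    # gene -> {allele label -> frequency}; the per-gene remainder to 1 is the
    # probability that a haplotype carries a deletion of the gene.  The keys
    # of this mapping define which genes are simulated.
    genotype_model: dict[str, dict[str, float]] | None = None
    novel_alleles: tuple[NovelAlleleSpec, ...] = ()
    # allele label -> [(full upstream haplotype, frequency)]; one haplotype
    # is drawn per individual per allele.  Unlisted alleles use their
    # database upstream.  Novel-allele labels fall back to their closest
    # reference allele's entry.
    upstream_variants: dict[str, list[tuple[str, float]]] | None = None
    # 5'UTR capture law: with probability 1 - truncation_short_prob the number
    # of captured UTR bases follows a discrete triangular law rising over the
    # last `truncation_window` lengths up to the full UTR (library prep leaves
    # only slight length variation); otherwise the read is extremely short,
    # uniform over the remaining lengths — the tail the length-frequency
    # filter exists to remove.
    truncation_window: int = 8
    truncation_short_prob: float = 0.05
    mutation_probs: tuple[float, ...] = (0.6, 0.25, 0.1, 0.05)
    error_rate: float = 0.0
    ac_bias: float = 1.0  # weight of C among error targets at A sites (1 = uniform)
    expression_imbalance: float = 0.5
    batch_assignment: dict[str, str] | None = None
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    truth_db: AlleleDatabase  # reference plus planted novel alleles
    genotypes: dict[str, dict[str, tuple[str, ...]]]  # sample -> gene -> copies
    upstream_haplotypes: dict[str, dict[str, str]]  # sample -> allele -> upstream
    per_read: pd.DataFrame

    def genotype_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "gene": g, "alleles": ",".join(copies)}
            for s, genes in self.genotypes.items()
            for g, copies in genes.items()
        ]
        return pd.DataFrame(rows, columns=["sample_id", "gene", "alleles"])

    def haplotype_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "allele": a, "upstream": u}
            for s, haps in self.upstream_haplotypes.items()
            for a, u in haps.items()
        ]
        return pd.DataFrame(rows, columns=["sample_id", "allele", "upstream"])


# ---------------------------------------------------------------------------
# Cohort simulation

def default_genotype_model(db: AlleleDatabase, deletion_prob: float | dict[str, float] = 0.0,
                           genes: list[str] | None = None) -> dict[str, dict[str, float]]:
    """Uniform allele frequencies per gene, with optional deletion mass."""
    model: dict[str, dict[str, float]] = {}
    for gene, alleles in db.by_gene().items():
        if genes is not None and gene not in genes:
            continue
        p_del = deletion_prob.get(gene, 0.0) if isinstance(deletion_prob, dict) else deletion_prob
        share = (1.0 - p_del) / len(alleles)
        model[gene] = {a.label: share for a in alleles}
    return model


def _validate_config(config: SimConfig) -> None:
    if len(config.germline_db) == 0:
        raise ValueError("germline database is empty")
    for spec in config.novel_alleles:
        if spec.closest not in config.germline_db:
            raise ValueError(f"novel allele spec references absent allele {spec.closest!r}")
        if not 0.0 <= spec.population_frequency <= 1.0:
            raise ValueError(f"population frequency out of [0,1]: {spec.population_frequency}")
    total = sum(config.mutation_probs)
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"mutation_probs must sum to 1, got {total}")
    model = config.genotype_model
    if model is not None:
        for gene, freqs in model.items():
            s = sum(freqs.values())
            if s > 1.0 + 1e-9 or any(f < 0 for f in freqs.values()):
                raise ValueError(f"allele frequencies for {gene} invalid (sum {s})")


def _capture_law(utr_len: int, window: int, short_prob: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of captured 5'UTR bases: (lengths, probabilities).

    Triangular weights rising over the last ``window`` lengths up to the
    full UTR carry mass ``1 - short_prob``; the remaining shorter lengths
    share ``short_prob`` uniformly (the extremely-short tail).
    """
    if utr_len == 0:
        return np.array([0]), np.array([1.0])
    lo = max(0, utr_len - window)
    win_lengths = np.arange(lo, utr_len + 1)
    win_w = np.arange(1, len(win_lengths) + 1, dtype=float)
    win_w /= win_w.sum()
    if lo == 0 or short_prob <= 0.0:
        return win_lengths, win_w
    short_lengths = np.arange(0, lo)
    short_w = np.full(lo, short_prob / lo)
    lengths = np.concatenate([short_lengths, win_lengths])
    probs = np.concatenate([short_w, win_w * (1.0 - short_prob)])
    return lengths, probs / probs.sum()


def _leader_len(allele: GermlineAllele) -> int:
    return len(allele.l_part1 or "") + len(allele.l_part2 or "")


def _apply_errors(seq: list[str], positions: np.ndarray, rng: np.random.Generator,
                  ac_bias: float) -> None:
    for p in positions:
        base = seq[p]
        others = _OTHER_BASES.get(base)
        if others is None:  # N stays N
            continue
        if ac_bias != 1.0 and base == "A":
            # targets C, G, T with weights rho, 1, 1
            r = rng.random() * (ac_bias + 2.0)
            seq[p] = "C" if r < ac_bias else ("G" if r < ac_bias + 1.0 else "T")
        else:
            seq[p] = others[rng.integers(3)]


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a cohort; returns the AIRR rearrangement table and its truth."""
    _validate_config(config)
    rng = np.random.default_rng(config.seed)
    db = config.germline_db

    # Truth database: reference alleles plus planted novel alleles.
    truth_db = AlleleDatabase(list(db), version_tag=db.version_tag + "+novel")
    novel_labels: dict[NovelAlleleSpec, str] = {}
    for spec in config.novel_alleles:
        novel = db[spec.closest].with_substitution(spec.position, spec.to_base)
        novel_labels[spec] = novel.label
        if novel.label not in truth_db:
            truth_db.add(novel)

    model = config.genotype_model or default_genotype_model(db)
    for gene, freqs in model.items():
        for label in freqs:
            if label not in db:
                raise ValueError(f"genotype model references absent allele {label!r}")

    # Annotator behaviour: each truth allele maps deterministically to its
    # closest reference allele(s); ties are joined with ", ".
    annotation: dict[str, str] = {}
    for allele in truth_db:
        _, labels = closest_alleles(allele.v_region_ungapped, db)
        annotation[allele.label] = ", ".join(labels)

    samples = [f"S{i + 1:03d}" for i in range(config.n_individuals)]
    batches = config.batch_assignment or {}
    depths = config.depth.draw(rng, config.n_individuals)

    upstream_variants = config.upstream_variants or {}

    def variant_list(label: str) -> list[tuple[str, float]]:
        if label in upstream_variants:
            return upstream_variants[label]
        if label in novel_labels.values():
            spec = next(s for s, l in novel_labels.items() if l == label)
            if spec.closest in upstream_variants:
                return upstream_variants[spec.closest]
        up = truth_db[label].upstream
        return [(up, 1.0)] if up is not None else [("", 1.0)]

    genotypes: dict[str, dict[str, tuple[str, ...]]] = {}
    haplotypes: dict[str, dict[str, str]] = {}
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    n_mut_max = len(config.mutation_probs)
    mut_probs = np.asarray(config.mutation_probs, dtype=float)

    for s, depth in zip(samples, depths):
        # --- diploid genotype ---------------------------------------------
        genotype: dict[str, tuple[str, ...]] = {}
        for gene, freqs in model.items():
            labels = list(freqs)
            p = np.array([freqs[l] for l in labels] + [max(0.0, 1.0 - sum(freqs.values()))])
            p = p / p.sum()
            copies = tuple(
                labels[k]
                for k in rng.choice(len(labels) + 1, size=2, p=p)
                if k < len(labels)
            )
            if copies:
                genotype[gene] = copies
        for spec in config.novel_alleles:
            if rng.random() < spec.population_frequency:
                gene = db[spec.closest].gene
                genotype[gene] = (spec.closest, novel_labels[spec])
        genotypes[s] = genotype

        # --- upstream haplotype per allele --------------------------------
        haps: dict[str, str] = {}
        for copies in genotype.values():
            for label in copies:
                if label in haps:
                    continue
                variants = variant_list(label)
                seqs = [v[0] for v in variants]
                w = np.array([v[1] for v in variants], dtype=float)
                haps[label] = seqs[rng.choice(len(seqs), p=w / w.sum())]
        haplotypes[s] = haps

        # --- read-level allele picks --------------------------------------
        genes_present = sorted(genotype)
        allele_list: list[str] = []
        probs: list[float] = []
        for gene in genes_present:
            copies = genotype[gene]
            gene_w = 1.0 / len(genes_present)
            if len(copies) == 2 and copies[0] != copies[1]:
                probs += [gene_w * config.expression_imbalance,
                          gene_w * (1.0 - config.expression_imbalance)]
                allele_list += [copies[0], copies[1]]
            else:
                probs.append(gene_w)
                allele_list.append(copies[0])
        probs_arr = np.asarray(probs)
        picks = rng.choice(len(allele_list), size=depth, p=probs_arr / probs_arr.sum())
        mut_counts = rng.choice(n_mut_max, size=depth, p=mut_probs)

        # capture-length law per allele (depends on its haplotype's UTR length)
        capture_cache: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        for label in sorted(set(allele_list)):
            allele = truth_db[label]
            hap = haps[label]
            llen = min(_leader_len(allele), len(hap))
            utr_len = len(hap) - llen
            lengths, probs = _capture_law(utr_len, config.truncation_window,
                                          config.truncation_short_prob)
            capture_cache[label] = (lengths, probs, llen)

        batch = batches.get(s, "B1")
        for i, k in enumerate(picks):
            label = allele_list[k]
            allele = truth_db[label]
            hap = haps[label]
            lengths, probs, llen = capture_cache[label]
            cap_u = int(lengths[rng.choice(len(lengths), p=probs)])
            upstream_read = hap[len(hap) - (cap_u + llen):] if (cap_u + llen) else ""

            v = list(allele.v_region_ungapped)
            m = int(mut_counts[i])
            mut_positions: np.ndarray = np.empty(0, dtype=int)
            if m:
                mut_positions = rng.choice(len(v), size=m, replace=False)
                for p in mut_positions:
                    v[p] = _OTHER_BASES[v[p]][rng.integers(3)]

            read = list(upstream_read) + v
            err_positions: np.ndarray = np.empty(0, dtype=int)
            if config.error_rate > 0.0:
                err_positions = np.flatnonzero(rng.random(len(read)) < config.error_rate)
                _apply_errors(read, err_positions, rng, config.ac_bias)

            sequence_id = f"{s}_{i}"
            rows.append((sequence_id, "".join(read), annotation[label],
                         len(upstream_read) + 1, s, batch))
            truth_rows.append((sequence_id, s, label,
                               ";".join(str(p + 1) for p in sorted(mut_positions)),
                               ";".join(str(p + 1) for p in err_positions),
                               cap_u))

    table = pd.DataFrame(rows, columns=["sequence_id"] + AIRR_REQUIRED_COLUMNS)
    per_read = pd.DataFrame(
        truth_rows,
        columns=["sequence_id", "sample_id", "true_allele", "v_mut_positions",
                 "error_positions", "captured_utr5_len"],
    )
    return table, SimTruth(truth_db=truth_db, genotypes=genotypes,
                           upstream_haplotypes=haplotypes, per_read=per_read)


# ---------------------------------------------------------------------------
# AIRR rearrangement TSV I/O

def write_airr(table: pd.DataFrame, path: str | Path) -> None:
    """Write a rearrangement table as AIRR-style TSV (tab-separated, header)."""
    missing = [c for c in AIRR_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise MissingColumnError(f"rearrangement table missing mandatory columns: {missing}")
    table.to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    """Read an AIRR rearrangement TSV, validating mandatory columns."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing mandatory columns: {missing}")
    table["v_sequence_start"] = table["v_sequence_start"].astype(int)
    return table


# ---------------------------------------------------------------------------
# Bundled synthetic germline reference

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(4, size=n))


def _substitute(seq: str, rng: np.random.Generator, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p - 1] = _OTHER_BASES[out[p - 1]][rng.integers(3)]
    return "".join(out)


def default_reference(seed: int = 7) -> AlleleDatabase:
    """A small synthetic germline V database for simulations and examples.

    Synthetic stand-in for a real germline reference: eight genes with
    realistic structure — 315 nt ungapped V-REGIONs, 45 nt L-PART1 and 10 nt
    L-PART2, family-specific 5'UTR lengths — including two deliberately
    awkward cases found in the human IGHV locus:

    * ``IGHV3-23`` / ``IGHV3-23D``: duplicated genes with *identical*
      V-REGION references (annotators emit multi-label calls), but distinct
      5'UTRs;
    * ``IGHV3-64`` / ``IGHV3-64D``: paralogs whose reference alleles differ
      at only two V-REGION positions, with fully distinct upstream
      sequences — the disambiguation test case.
    """
    rng = np.random.default_rng(seed)
    db = AlleleDatabase(version_tag=f"synthetic-v1-seed{seed}")

    def make(gene: str, utr_len: int, v_region: str | None = None,
             upstream: tuple[str, str, str] | None = None) -> GermlineAllele:
        v = v_region if v_region is not None else _random_seq(rng, 315)
        if upstream is None:
            upstream = (_random_seq(rng, utr_len), _random_seq(rng, 45), _random_seq(rng, 10))
        return GermlineAllele(gene=gene, allele_id="*01", v_region=v,
                              utr5=upstream[0], l_part1=upstream[1], l_part2=upstream[2])

    # IGHV1-8: two alleles differing at three positions
    v1_8 = make("IGHV1-8", utr_len=50)
    db.add(v1_8)
    db.add(dataclasses.replace(v1_8, allele_id="*02",
                               v_region=_substitute(v1_8.v_region, rng, [45, 190, 280])))

    # IGHV2-5: short 5'UTR family
    db.add(make("IGHV2-5", utr_len=20))

    # IGHV3-23 / IGHV3-23D: identical V-REGIONs, distinct 5'UTRs
    v3_23 = make("IGHV3-23", utr_len=64)
    db.add(v3_23)
    d_utr = _substitute(v3_23.utr5, rng, [5, 12, 30])
    db.add(dataclasses.replace(v3_23, gene="IGHV3-23D", utr5=d_utr))

    # IGHV3-64 / IGHV3-64D: V-REGIONs two apart, upstream fully distinct
    v3_64 = make("IGHV3-64", utr_len=64)
    v3_64 = dataclasses.replace(v3_64, allele_id="*05")
    db.add(v3_64)
    v3_64d = dataclasses.replace(
        v3_64, gene="IGHV3-64D", allele_id="*06",
        v_region=_substitute(v3_64.v_region, rng, [210, 265]),
        utr5=_random_seq(rng, 64), l_part1=_random_seq(rng, 45), l_part2=_random_seq(rng, 10))
    db.add(v3_64d)

    db.add(make("IGHV4-59", utr_len=40))
    sub51 = make("IGHV5-51", utr_len=55)
    db.add(sub51)
    db.add(dataclasses.replace(sub51, allele_id="*03",
                               v_region=_substitute(sub51.v_region, rng, [45])))
    return db


def novel_allele_benchmark(seed: int = 0, n_individuals: int = 20, depth: int = 2000,
                           error_rate: float = 0.005, ac_bias: float = 3.0) -> SimConfig:
    """Cohort for measuring novel-allele filter sensitivity and specificity.

    Twenty individuals at depth 2000 with a biased sequencing-error model
    (rate 0.005, threefold A→C excess) and two planted heterozygous novel
    alleles at population frequency 0.5 on different genes.  Carriers are
    heterozygous with balanced (50:50) allelic expression.
    """
    db = default_reference()
    specs = []
    for label, pos in (("IGHV1-8*01", 150), ("IGHV4-59*01", 80)):
        ref = db[label].v_region[pos - 1]
        to = "C" if ref != "C" else "G"
        specs.append(NovelAlleleSpec(label, pos, to, population_frequency=0.5))
    return SimConfig(germline_db=db, n_individuals=n_individuals,
                     depth=DepthLaw(kind="fixed", depth=depth),
                     novel_alleles=tuple(specs),
                     error_rate=error_rate, ac_bias=ac_bias, seed=seed)


def upstream_benchmark(seed: int = 0, n_individuals: int = 6, depth: int = 800) -> SimConfig:
    """Zero-noise cohort for upstream-database recovery checks.

    No mutations and no sequencing error; two alleles carry a second
    upstream haplotype (one mid-5'UTR substitution) at population
    frequency 0.5, so the cohort database should contain one record per
    true haplotype with exact carrier counts.
    """
    db = default_reference()
    variants: dict[str, list[tuple[str, float]]] = {}
    for label, pos in (("IGHV4-59*01", 20), ("IGHV1-8*01", 25)):
        base = db[label].upstream
        alt = base[:pos] + ("A" if base[pos] != "A" else "C") + base[pos + 1:]
        variants[label] = [(base, 0.5), (alt, 0.5)]
    return SimConfig(germline_db=db, n_individuals=n_individuals,
                     depth=DepthLaw(kind="fixed", depth=depth),
                     mutation_probs=(1.0,), error_rate=0.0,
                     upstream_variants=variants, seed=seed)


def duplicated_gene_scenario(seed: int = 0, identical_upstream: bool = False,
                             n_individuals: int = 4, depth: int = 500):
    """Cohort exercising upstream-based disambiguation of a duplicated gene pair.

    The bundled reference contains IGHV3-64*05 and IGHV3-64D*06, whose
    V-REGIONs differ at exactly two positions while their upstream
    sequences are fully distinct.  Every individual carries a novel allele
    heterozygously on IGHV3-64: the *05 sequence with the first of the two
    discriminating positions switched to the D-gene base, so the novel
    V-REGION is one mismatch from *each* paralog and annotators emit the
    tied call ``"IGHV3-64*05, IGHV3-64D*06"``.  Its true upstream is the
    D gene's (or, with ``identical_upstream``, the two genes share an
    upstream, making the assignment genuinely undecidable).

    Returns ``(config, info)`` where ``info`` holds the tied-call collapse
    rule, the candidate pseudo-label, the novel V-REGION and the true gene.
    """
    from .germline import diff_positions
    from .usage import DEFAULT_COLLAPSE_RULES, CollapseMap, CollapseRule

    db = default_reference()
    a, d = db["IGHV3-64*05"], db["IGHV3-64D*06"]
    if identical_upstream:
        d = dataclasses.replace(d, utr5=a.utr5, l_part1=a.l_part1, l_part2=a.l_part2)
        db = AlleleDatabase([d if al.label == "IGHV3-64D*06" else al for al in db],
                            version_tag=db.version_tag + "-shared-upstream")
    pos, _, d_base = diff_positions(a.v_region, d.v_region, anchor="left")[0]
    spec = NovelAlleleSpec(closest=a.label, position=pos, to_base=d_base,
                           population_frequency=1.0)
    novel_label = name = a.label + f"_{a.v_region[pos - 1]}{pos}{d_base}"
    config = SimConfig(
        germline_db=db, n_individuals=n_individuals,
        depth=DepthLaw(kind="fixed", depth=depth),
        mutation_probs=(1.0,), error_rate=0.0,
        novel_alleles=(spec,),
        upstream_variants={novel_label: [(d.upstream, 1.0)]},
        seed=seed)
    candidate_call = "IGHV3-64X*cand"
    cmap = CollapseMap(tuple(DEFAULT_COLLAPSE_RULES) + (
        CollapseRule(frozenset({a.label, d.label}), candidate_call, "IGHV3-64X"),))
    info = {
        "novel_label": name,
        "novel_v_region": db[a.label].with_substitution(pos, d_base).v_region,
        "candidate_call": candidate_call,
        "collapse_map": cmap,
        "true_gene": d.gene,
        "competing_genes": (a.gene, d.gene),
    }
    return config, info
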