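"""Independent brute-force reference implementations of the upstream rules.

Deliberately naive: explicit padded matrices, all-pairs linkage via BFS,
character-by-character counting.  Used to cross-check the pipeline
operations on random instances.
"""

from collections import Counter


def pad_right_anchor(seqs):
    width = max(len(s) for s in seqs)
    return [("N" * (width - len(s))) + s for s in seqs]


def bf_pad_and_trim_95n(seqs, n_frac=0.95):
    if not seqs:
        return []
    padded = pad_right_anchor(seqs)
    width = len(padded[0])
    keep = width
    # walk from the anchor (rightmost column) leftward
    for dist in range(1, width + 1):
        col = [p[width - dist] for p in padded]
        if sum(c == "N" for c in col) / len(col) >= n_frac:
            keep = dist - 1
            break
    return [s[-keep:] if (keep and len(s) > keep) else ("" if keep == 0 else s)
            for s in seqs]


def bf_length_filter(seqs, min_len_freq=0.1):
    counts = Counter(len(s) for s in seqs)
    total = len(seqs)
    frequent = [n for n, c in counts.items() if c / total > min_len_freq]
    if not frequent:
        return None  # degenerate
    lo, hi = min(frequent), max(frequent)
    out = []
    for s in seqs:
        if len(s) < lo:
            continue
        out.append(s[-hi:] if len(s) > hi else s)
    return out


def bf_identity(a, b):
    window = min(len(a), len(b))
    matches = compared = 0
    for k in range(1, window + 1):
        if a[-k] == "N" or b[-k] == "N":
            continue
        compared += 1
        matches += a[-k] == b[-k]
    return matches / compared if compared else 0.0


def bf_cluster(seqs, ident=0.999):
    """All-pairs single linkage by BFS over the identity graph."""
    n = len(seqs)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if bf_identity(seqs[i], seqs[j]) >= ident:
                adj[i].append(j)
                adj[j].append(i)
    seen = set()
    clusters = []
    for i in range(n):
        if i in seen:
            continue
        queue, comp = [i], []
        seen.add(i)
        while queue:
            k = queue.pop()
            comp.append(k)
            for m in adj[k]:
                if m not in seen:
                    seen.add(m)
                    queue.append(m)
        clusters.append(sorted(comp))
    return sorted(clusters, key=lambda c: (-len(c), c))


def bf_consensus(seqs, freq=0.6):
    padded = pad_right_anchor(seqs)
    width = len(padded[0])
    out = []
    for p in range(width):
        counts = Counter(row[p] for row in padded if row[p] in "ACGT")
        if not counts:
            out.append("N")
            continue
        total = sum(counts.values())
        base, count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        out.append(base if count / total >= freq else "N")
    return "".join(out)


def bf_split(seqs, freq=0.6):
    """One-level split at the 5'-most genuinely ambiguous position."""
    cons = bf_consensus(seqs, freq)
    padded = pad_right_anchor(seqs)
    width = len(padded[0])
    for p in range(width):
        if cons[p] != "N":
            continue
        called = {row[p] for row in padded if row[p] in "ACGT"}
        if len(called) >= 2:
            parts = {}
            for i, row in enumerate(padded):
                parts.setdefault(row[p], []).append(i)
            return [
                (members, bf_consensus([seqs[i] for i in members], freq))
                for _, members in sorted(parts.items())
            ]
    return [(list(range(len(seqs))), cons)]


def random_reads(rng, n_max=40, len_max=30, n_prob=0.05, ragged=True):
    """Random right-anchored read set, possibly ragged, with occasional Ns."""
    n = int(rng.integers(2, n_max + 1))
    base_len = int(rng.integers(3, len_max + 1))
    out = []
    for _ in range(n):
        length = int(rng.integers(1, base_len + 1)) if ragged else base_len
        chars = [
            "N" if rng.random() < n_prob else "ACGT"[rng.integers(4)]
            for _ in range(length)
        ]
        out.append("".join(chars))
    return out
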