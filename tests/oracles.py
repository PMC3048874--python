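"""Independent brute-force oracles used to cross-check the implementation.

Everything here works by direct enumeration (per-base sets, all-pairs
loops, explicit ECDF evaluation) and deliberately shares no code with the
package's vectorized paths.
"""

import numpy as np


def interval_bases(start, end):
    """Half-open interval as an explicit set of base positions."""
    return set(range(start, end))


def overlap_by_bases(a, b):
    """Interval overlap decided by per-base set intersection."""
    if a.chrom != b.chrom:
        return False
    return bool(interval_bases(a.start, a.end) & interval_bases(b.start, b.end))


def extend_by_hand(pos5p, strand, length, chrom_size):
    """Directional extension computed from first principles, clipped."""
    if strand == "+":
        bases = range(pos5p, pos5p + length)
    else:
        bases = range(pos5p - length + 1, pos5p + 1)
    return [b for b in bases if 0 <= b < chrom_size]


def coverage_by_counting(tags, genome, ext, window):
    """Per-base depth by explicit counting, then explicit window averaging."""
    out = {}
    for chrom in genome.chrom_names:
        size = genome.size(chrom)
        depth = [0] * size
        for tag in tags:
            if tag.chrom != chrom:
                continue
            for b in extend_by_hand(tag.pos5p, tag.strand, ext, size):
                depth[b] += 1
        means = []
        for w in range(0, size, window):
            chunk = depth[w : min(w + window, size)]
            means.append(sum(chunk) / len(chunk))
        out[chrom] = np.array(means)
    return out


def rpp_by_pairs(peaks, tags, genome, ext):
    """Reads-per-peak by enumerating every tag x peak pair."""
    counts = []
    for p in peaks:
        size = genome.size(p.interval.chrom)
        n = 0
        for tag in tags:
            if tag.chrom != p.interval.chrom:
                continue
            bases = extend_by_hand(tag.pos5p, tag.strand, ext, size)
            if bases and bases[0] < p.interval.end and bases[-1] >= p.interval.start:
                n += 1
        counts.append(n)
    return np.array(counts)


def ks_d_by_ecdf(x, y):
    """Supremum ECDF distance evaluated at every observed point."""
    x, y = np.sort(x), np.sort(y)
    points = np.concatenate([x, y])
    d = 0.0
    for t in points:
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        d = max(d, abs(fx - fy))
    return d


def pearson_by_formula(x, y):
    """Textbook Pearson r from raw sums."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx * sx) * np.sqrt(n * (y * y).sum() - sy * sy)
    return num / den


def scan_by_enumeration(weights, spacers, threshold, sequence):
    """Best bipartite-site hit by looping over (pos, strand, spacer).

    ``weights`` is the 4 x 10 log-odds matrix (rows A, C, G, T); N scores
    the column minimum.  Returns (position, strand, spacer, score) on the
    forward sequence, or None.  Tie order: score desc, position asc, '+'
    first, smaller spacer.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    width = weights.shape[1]

    def half_score(s):
        total = 0.0
        for j, b in enumerate(s):
            if b in idx:
                total += weights[idx[b], j]
            else:
                total += weights[:, j].min()
        return total

    candidates = []
    seq = sequence.upper()
    for strand in ("+", "-"):
        s = seq if strand == "+" else "".join(comp[b] for b in reversed(seq))
        for spacer in spacers:
            site_len = 2 * width + spacer
            for pos in range(len(s) - site_len + 1):
                window = s[pos : pos + site_len]
                score = half_score(window[:width]) + half_score(
                    window[width + spacer :]
                )
                if score >= threshold:
                    fwd = pos if strand == "+" else len(s) - pos - site_len
                    candidates.append((score, fwd, strand, spacer))
    if not candidates:
        return None
    candidates.sort(
        key=lambda c: (-c[0], c[1], 0 if c[2] == "+" else 1, c[3])
    )
    score, pos, strand, spacer = candidates[0]
    return pos, strand, spacer, score


def binomial_tail_by_summation(k, n, p):
    """Exact P(X >= k) for X ~ Binomial(n, p) by direct summation."""
    from math import comb

    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
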