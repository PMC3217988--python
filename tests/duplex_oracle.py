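"""Independent brute-force reference for duplex alignment scoring.

Enumerates every placement (every transcript offset; ungapped plus every
single-gap variant) and scores it directly from the published penalty
constants, with no shared code with the package's search.  Used as the
ground-truth oracle in equivalence tests.
"""

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
WOBBLE = {("G", "T"), ("T", "G")}
SEED = (2, 7)
WINDOW = 20


def _pen(m, t, pos):
    """Penalty of pairing miRNA base m (1-based pos) with target base t."""
    if t == COMP[m]:
        return 0.0
    if (m, t) in WOBBLE:
        return 0.5
    extra = 0.5 if SEED[0] <= pos <= SEED[1] else 0.0
    return 1.0 + extra


def _windowed(pos_pen, bonds):
    """Min over consecutive 20-position windows; bonds sit between positions."""
    L = len(pos_pen)
    if L <= WINDOW:
        return sum(pos_pen) + sum(bonds)
    best = None
    for w in range(0, L - WINDOW + 1):
        s = sum(pos_pen[w:w + WINDOW]) + sum(bonds[w:w + WINDOW - 1])
        if best is None or s < best:
            best = s
    return best


def placements(mirna, transcript, max_indels):
    """Yield (score, start, end) for every placement."""
    L = len(mirna)
    n = len(transcript)
    for s in range(0, n - L + 1):
        rev = transcript[s:s + L][::-1]
        pos_pen = [_pen(mirna[i], rev[i], i + 1) for i in range(L)]
        yield _windowed(pos_pen, [0.0] * (L - 1)), s, s + L
    if max_indels < 1:
        return
    # target deletion opposite miRNA position d (miRNA base bulged)
    for s in range(0, n - (L - 1) + 1):
        rev = transcript[s:s + L - 1][::-1]
        for d in range(1, L + 1):
            pos_pen, j = [], 0
            for i in range(L):
                if i + 1 == d:
                    pos_pen.append(2.0)
                else:
                    pos_pen.append(_pen(mirna[i], rev[j], i + 1))
                    j += 1
            yield _windowed(pos_pen, [0.0] * (L - 1)), s, s + L - 1
    # extra target base between miRNA positions g and g+1
    for s in range(0, n - (L + 1) + 1):
        rev = transcript[s:s + L + 1][::-1]
        for g in range(1, L):
            pos_pen = []
            for i in range(L):
                t = rev[i] if i < g else rev[i + 1]
                pos_pen.append(_pen(mirna[i], t, i + 1))
            bonds = [0.0] * (L - 1)
            bonds[g - 1] = 2.0
            yield _windowed(pos_pen, bonds), s, s + L + 1


def best_sites(mirna, transcript, max_indels=1):
    """Greedy best-first non-overlapping placements, ties leftmost.

    Returns a set of (start, end, score) triples.
    """
    cand = sorted(placements(mirna, transcript, max_indels),
                  key=lambda c: (c[0], c[1], c[2]))
    occupied = [False] * len(transcript)
    out = set()
    for score, s, e in cand:
        if not any(occupied[s:e]):
            for i in range(s, e):
                occupied[i] = True
            out.add((s, e, round(score, 6)))
    return out
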