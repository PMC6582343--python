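"""Exhaustive affine-gap global-alignment oracle for short sequences.

Independent of the package's aligner: a dynamic program over
(i, j, last-move) states that records, for every achievable score, the
set of (matches, columns) outcomes, then reports the maximum percent
identity among maximum-score alignments. Scoring convention: match +1,
mismatch -1, first gapped column of a run -2, each further gapped
column -1; end gaps penalized.
"""

MATCH, MISMATCH, OPEN, EXTEND = 1, -1, -2, -1


def oracle_identity(a: str, b: str) -> float:
    # state -> {score: set of (matches, columns)}
    order = [(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1)]
    order.sort(key=lambda ij: ij[0] + ij[1])
    table = {}
    table[(0, 0, None)] = {0: {(0, 0)}}

    def add(state, score, pair):
        bucket = table.setdefault(state, {})
        bucket.setdefault(score, set()).add(pair)

    for i, j in order:
        for last in (None, "M", "X", "Y"):
            state = (i, j, last)
            if state not in table:
                continue
            for score, pairs in list(table[state].items()):
                for m, cols in pairs:
                    if i < len(a) and j < len(b):
                        hit = a[i] == b[j]
                        add((i + 1, j + 1, "M"),
                            score + (MATCH if hit else MISMATCH),
                            (m + (1 if hit else 0), cols + 1))
                    if i < len(a):
                        cost = EXTEND if last == "X" else OPEN
                        add((i + 1, j, "X"), score + cost, (m, cols + 1))
                    if j < len(b):
                        cost = EXTEND if last == "Y" else OPEN
                        add((i, j + 1, "Y"), score + cost, (m, cols + 1))

    finals = {}
    for last in ("M", "X", "Y", None):
        state = (len(a), len(b), last)
        for score, pairs in table.get(state, {}).items():
            finals.setdefault(score, set()).update(pairs)
    best_score = max(finals)
    return max(100.0 * m / cols for m, cols in finals[best_score] if cols)
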