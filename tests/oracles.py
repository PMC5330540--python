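"""Independent reference implementations used as test oracles.

These deliberately avoid the package's DP code paths: the CYK oracle
enumerates parse trees recursively; the folding oracle enumerates all
nested pairings; the alignment oracle is a plain affine-gap DP table.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def enum_best_parse(model, seq: str) -> float:
    """Maximum parse score by exhaustive parse-tree enumeration."""
    codes = [NT_INDEX[c] for c in seq.upper().replace("U", "T")]
    states = model.states

    def parses(v, i, j):
        s = states[v]
        if s.kind == "E":
            if i == j:
                yield 0.0
            return
        if s.kind == "B":
            for k in range(i, j + 1):
                for a in parses(s.children[0], i, k):
                    for b in parses(s.children[1], k, j):
                        yield a + b
            return
        e = 0.0
        if s.kind == "MP":
            if j - i < 2:
                return
            e = float(s.emit[codes[i], codes[j - 1]])
        elif s.kind in ("ML", "IL"):
            if j - i < 1:
                return
            e = float(s.emit[codes[i]])
        elif s.kind in ("MR", "IR"):
            if j - i < 1:
                return
            e = float(s.emit[codes[j - 1]])
        for k, c in enumerate(s.children):
            for sub in parses(c, i + s.dl, j - s.dr):
                yield e + float(s.t[k]) + sub

    return max(parses(model.root_state, 0, len(codes)), default=float("-inf"))


_PAIR_OK = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def enum_max_pairs(seq: str, min_hairpin: int = 3) -> int:
    """Maximum number of nested pairs by exhaustive enumeration."""
    s = seq.upper().replace("U", "T")

    def best(i, j):
        if j - i < 2:
            return 0
        # i unpaired
        m = best(i + 1, j)
        for k in range(i + min_hairpin + 1, j):
            if (s[i], s[k]) in _PAIR_OK:
                m = max(m, 1 + best(i + 1, k) + best(k + 1, j))
        return m

    return best(0, len(s))


def sw_affine_score(query: str, subject: str, open_gap: float = -11.0,
                    extend_gap: float = -1.0) -> float:
    """Smith-Waterman local score with affine gaps (BLOSUM62), plain DP."""
    blosum = substitution_matrices.load("BLOSUM62")
    q, s = query.upper(), subject.upper()
    n, m = len(q), len(s)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]   # match state
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in subject
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in query
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = blosum[q[i - 1]][s[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], X[i - 1][j - 1],
                                   Y[i - 1][j - 1]) + sub)
            X[i][j] = max(M[i - 1][j] + open_gap, X[i - 1][j] + extend_gap)
            Y[i][j] = max(M[i][j - 1] + open_gap, Y[i][j - 1] + extend_gap)
            best = max(best, M[i][j])
    return best
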