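"""Independent affine-gap global-alignment oracles for the test suite.

Kept deliberately separate from the package: a hand-written Gotoh
three-state dynamic program with free end gaps, plus an exhaustive
alignment enumerator for tiny sequences that validates the DP itself.
Both score a gap of length L as open + (L-1)*extend, with gap runs
touching either sequence end costing nothing.
"""

from itertools import product

NEG = float("-inf")


def gotoh_score(a, b, sub, gap_open=10.0, gap_extend=0.5):
    """Optimal global alignment score with affine gaps, free end gaps.

    ``sub(x, y)`` returns the substitution score.  Three-state DP:
    M ends in a substitution column, X in a gap in ``b`` (a-residue over
    '-'), Y in a gap in ``a``.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading gap in b is free
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # leading gap in a is free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )
    # trailing end gaps are free: best over the last row and last column
    best = max(M[n][m], X[n][m], Y[n][m])
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def enumerate_alignments(a, b):
    """Yield every global alignment of a and b as paired gapped strings."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def score_alignment(ga, gb, sub, gap_open=10.0, gap_extend=0.5):
    """Score one gapped alignment; end-touching gap runs are free."""
    length = len(ga)
    total = 0.0
    for seq in (ga, gb):
        i = 0
        while i < length:
            if seq[i] != "-":
                i += 1
                continue
            j = i
            while j < length and seq[j] == "-":
                j += 1
            if i != 0 and j != length:  # internal gap run
                total -= gap_open + (j - i - 1) * gap_extend
            i = j
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            total += sub(x, y)
    return total


def brute_force_score(a, b, sub, gap_open=10.0, gap_extend=0.5):
    """Optimal score by exhaustive enumeration; only for tiny sequences."""
    return max(
        score_alignment(ga, gb, sub, gap_open, gap_extend)
        for ga, gb in enumerate_alignments(a, b)
    )


def all_sequences(alphabet, max_len):
    """Every sequence over ``alphabet`` with length 1..max_len."""
    for length in range(1, max_len + 1):
        for letters in product(alphabet, repeat=length):
            yield "".join(letters)
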