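"""Independent oracles used by the test suite.

These deliberately use different algorithms from the package: a
Waterman–Smith–Beyer general-gap-penalty DP and a literal enumeration of
all alignments (feasible only for tiny sequences), both scoring a maximal
run of gap columns as gap_open + gap_extension * (run_length - 1).
"""

from __future__ import annotations


def gap_cost(length: int, gap_open: int, gap_ext: int) -> int:
    return gap_open + gap_ext * (length - 1)


def wsb_best_score(
    q: str,
    r: str,
    match: int = 1,
    mismatch: int = 0,
    gap_open: int = -2,
    gap_ext: int = 0,
) -> int:
    """General gap-penalty DP over all gap lengths at every cell."""
    n, m = len(q), len(r)
    NEG = -(10**9)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0
    for j in range(1, m + 1):
        H[0][j] = gap_cost(j, gap_open, gap_ext)
    for i in range(1, n + 1):
        H[i][0] = gap_cost(i, gap_open, gap_ext)
        for j in range(1, m + 1):
            s = match if (q[i - 1] == r[j - 1] and q[i - 1] != "N") else mismatch
            best = H[i - 1][j - 1] + s
            for k in range(1, j + 1):
                best = max(best, H[i][j - k] + gap_cost(k, gap_open, gap_ext))
            for k in range(1, i + 1):
                best = max(best, H[i - k][j] + gap_cost(k, gap_open, gap_ext))
            H[i][j] = best
    return H[n][m]


def enumerate_best_score(
    q: str,
    r: str,
    match: int = 1,
    mismatch: int = 0,
    gap_open: int = -2,
    gap_ext: int = 0,
) -> int:
    """Exhaustive enumeration of every global alignment (tiny inputs only)."""
    best = [-(10**9)]

    def step(i: int, j: int, last: str, score: int) -> None:
        if i == len(q) and j == len(r):
            best[0] = max(best[0], score)
            return
        if i < len(q) and j < len(r):
            s = match if (q[i] == r[j] and q[i] != "N") else mismatch
            step(i + 1, j + 1, "M", score + s)
        if j < len(r):  # deletion column (consumes reference)
            step(i, j + 1, "D", score + (gap_ext if last == "D" else gap_open))
        if i < len(q):  # insertion column (consumes query)
            step(i + 1, j, "I", score + (gap_ext if last == "I" else gap_open))

    step(0, 0, "", 0)
    return best[0]


def brute_force_offtarget_windows(protospacer: str, subject: str, pam: str = "NGG"):
    """All (strand, 0-based start in scanned strand, mismatches) PAM-adjacent windows."""
    from ampedit.amplicon import revcomp

    L = len(protospacer)
    out = []
    for strand in "+-":
        seq = subject if strand == "+" else revcomp(subject)
        for i in range(len(seq) - L - 2):
            window = seq[i : i + L]
            site_pam = seq[i + L : i + L + 3]
            if not all(p == "N" or s == p for s, p in zip(site_pam, pam)):
                continue
            mm = sum(1 for a, b in zip(window, protospacer) if a != b or a == "N")
            out.append((strand, i, mm))
    return out
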