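"""Independent reference implementations used only by the test suite.

These are deliberately naive (quadratic dynamic programming, exhaustive
enumeration) and share no code path with the package internals they check.
"""

from __future__ import annotations


def semiglobal_oracle(pattern: str, text: str) -> tuple[int, int, int]:
    """Brute-force infix alignment: (distance, start, end).

    Full O(m*n) dynamic programme aligning the entire pattern against any
    substring of the text with unit-cost edits; among co-optimal intervals
    the smallest start and then the smallest end is returned. N in the text
    matches nothing (cost 1), including N in the pattern.
    """
    m, n = len(pattern), len(text)
    assert 1 <= m
    # D[j]: distance for pattern[:i] vs best suffix of text[:j]
    # S[j]: minimal start among optimal alignments reaching that cell
    D = list(range(0, n + 1))
    D = [0] * (n + 1)
    S = list(range(n + 1))
    for i in range(1, m + 1):
        prev_D, prev_S = D, S
        D = [i] + [0] * n
        S = [0] + [0] * n
        for j in range(1, n + 1):
            match = pattern[i - 1] == text[j - 1] and text[j - 1] != "N"
            candidates = [
                (prev_D[j - 1] + (0 if match else 1), prev_S[j - 1]),  # diag
                (prev_D[j] + 1, prev_S[j]),                            # up
                (D[j - 1] + 1, S[j - 1]),                              # left
            ]
            best_cost = min(c for c, _ in candidates)
            D[j] = best_cost
            S[j] = min(s for c, s in candidates if c == best_cost)
    d = min(D[1:]) if n else D[0]
    best = min((S[j], j) for j in range(1, n + 1) if D[j] == d)
    return d, best[0], best[1]


def exhaustive_cutoff_oracle(samples, beta, s_grid, loc_grid):
    """Exhaustive enumeration of the full cutoff grid for one AP end.

    Returns (similarity_cutoff, location_cutoff, L, precision, recall,
    f_beta) maximizing F_beta with ties preferring larger s_cut, smaller
    loc_cut, larger L — counting a true sample as retained when it passes
    both cutoffs and a random sample as a false positive when it passes the
    similarity cutoff.
    """
    eps = 1e-9
    best_key = None
    best_row = None
    for L in sorted({s.ap_sub_length for s in samples}):
        sub = [s for s in samples if s.ap_sub_length == L]
        for s_cut in s_grid:
            for loc_cut in loc_grid:
                tp = fp = fn = 0
                for s in sub:
                    sim_pass = s.similarity >= s_cut - eps
                    if s.label == "true":
                        if sim_pass and s.end_distance <= loc_cut:
                            tp += 1
                        else:
                            fn += 1
                    elif sim_pass:
                        fp += 1
                precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
                recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
                denom = beta * beta * precision + recall
                f = (0.0 if denom == 0
                     else (1 + beta * beta) * precision * recall / denom)
                key = (f, s_cut, -loc_cut, L)
                if best_key is None or key > best_key:
                    best_key = key
                    best_row = (s_cut, loc_cut, L, precision, recall, f)
    return best_row
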