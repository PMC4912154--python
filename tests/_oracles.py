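"""Independent reference implementations used only as test oracles.

These are deliberately naive (full dynamic programming, exhaustive
enumeration) and share no code with the package paths they check.
"""

from __future__ import annotations


def gotoh_local_score(
    a: str,
    b: str,
    substitution,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal local alignment score, full Gotoh dynamic programming.

    ``substitution(x, y)`` returns the pair score; a gap of length k costs
    ``gap_open + gap_extend * k``.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    first_gap = gap_open + gap_extend
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        e_cur = [neg] * (m + 1)
        f = neg  # gap in b along this row
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(h_prev[j] - first_gap, e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - first_gap, f - gap_extend)
            h = max(0.0, h_prev[j - 1] + substitution(ai, b[j - 1]), e, f)
            h_cur[j] = h
            e_cur[j] = e
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    return best


def brute_force_best_window(
    rows: list[str], window: int, max_gap_fraction: float = 0.0
) -> tuple[int, float] | None:
    """Exhaustively score every window of alignment columns.

    Per-column conservation is mean pairwise identity among non-gap
    residues (double loop over pairs); windows containing any column whose
    gap fraction exceeds the cap are ineligible. Returns (start, mean score)
    of the best window, leftmost on ties (scores closer than 1e-9 count as
    tied), or None when no window is eligible.
    """
    n_cols = len(rows[0])
    n_rows = len(rows)
    col_score = []
    col_ok = []
    for c in range(n_cols):
        col = [r[c] for r in rows]
        residues = [x for x in col if x != "-"]
        gap_frac = (n_rows - len(residues)) / n_rows
        col_ok.append(gap_frac <= max_gap_fraction)
        same = total = 0
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                total += 1
                if residues[i] == residues[j]:
                    same += 1
        col_score.append(same / total if total else 0.0)
    best = None
    for s in range(n_cols - window + 1):
        if not all(col_ok[s : s + window]):
            continue
        mean = sum(col_score[s : s + window]) / window
        if best is None or mean > best[1] + 1e-9:
            best = (s, mean)
    return best
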