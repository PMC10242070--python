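"""Independent brute-force oracles used by the unit and acceptance tests.

Each function here deliberately avoids the code paths of the package
implementation it checks: membership tests instead of regexes, explicit
loops instead of vectorized cumsums, the step-up rule written out instead
of a library call.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def parse_pattern_sets(pattern: str) -> list[set[str]]:
    out, i = [], 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            j = pattern.index(")", i)
            out.append(set(pattern[i + 1 : j].split("/")))
            i = j + 1
        elif ch in "nN":
            out.append(set("ACGT"))
            i += 1
        else:
            out.append({ch})
            i += 1
    return out


def window_matches(window: str, sets: list[set[str]]) -> bool:
    return len(window) == len(sets) and all(b in s for b, s in zip(window, sets))


def brute_scan(sequence: str, motif_patterns: dict[str, str]):
    """All (motif_id, position, strand) hits by testing every window of the
    sequence against the pattern and, for the minus strand, testing the
    reverse complement of the window read backwards."""
    hits = []
    seq = sequence.upper()
    for motif_id, pattern in motif_patterns.items():
        sets = parse_pattern_sets(pattern)
        L = len(sets)
        for pos in range(len(seq) - L + 1):
            window = seq[pos : pos + L]
            if any(b not in "ACGT" for b in window):
                continue
            if window_matches(window, sets):
                hits.append((motif_id, pos, "+"))
            if window_matches(brute_revcomp(window), sets):
                hits.append((motif_id, pos, "-"))
    return sorted(hits, key=lambda h: (h[1], h[2] != "+", h[0]))


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up written out literally:
    fdr_(i) = min_{j >= i} p_(j) * m / j, capped at 1, back-mapped."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def brute_enrichment_score(metrics: np.ndarray, member_mask: np.ndarray, p: float = 1.0):
    """Running-sum ES accumulated step by step in a plain loop."""
    n = len(metrics)
    n_s = int(member_mask.sum())
    n_r = float(np.sum(np.abs(metrics[member_mask]) ** p))
    running = 0.0
    profile = []
    for i in range(n):
        if member_mask[i]:
            running += abs(metrics[i]) ** p / n_r
        else:
            running -= 1.0 / (n - n_s)
        profile.append(running)
    best_abs = max(abs(v) for v in profile)
    for v in profile:  # earliest position within float tolerance of the max
        if abs(v) >= best_abs - 1e-12:
            return v
    return 0.0


def brute_hypergeom_upper(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X hypergeometric(M, K, n) by direct combinatorics."""
    from math import comb

    total = comb(M, n)
    return sum(comb(K, x) * comb(M - K, n - x) for x in range(k, min(K, n) + 1)) / total
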