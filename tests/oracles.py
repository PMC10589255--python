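"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected value by a different route from the
implementation it checks (exhaustive scans, closed forms, enumeration).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from paraquant._seq import revcomp, seq_to_array

SENTINEL = 0  # padding byte that equals no DNA character


def brute_force_match(read: str, core: str, extended: str,
                      core_offset: int, max_mismatch: int = 1) -> bool:
    """Try every alignment of the read against the extended motif on both
    strands: the core region must be fully inside the read and match
    exactly, and mismatches over the read/extended overlap must not exceed
    the budget."""
    ext = seq_to_array(extended)
    core_arr = seq_to_array(core)
    core_len = len(core)
    for strand in (read.upper(), revcomp(read.upper())):
        s = seq_to_array(strand)
        pad = np.full(len(ext), SENTINEL, dtype=np.uint8)
        padded = np.concatenate([pad, s, pad])
        windows = np.lib.stride_tricks.sliding_window_view(padded, len(ext))
        core_ok = (windows[:, core_offset:core_offset + core_len]
                   == core_arr).all(axis=1)
        if not core_ok.any():
            continue
        mism = ((windows != ext) & (windows != SENTINEL)).sum(axis=1)
        # core positions matched exactly wherever core_ok, so their zero
        # contribution is already reflected in mism
        if (core_ok & (mism <= max_mismatch)).any():
            return True
    return False


def column_diagnostic_sites(seqs: list[str]) -> list[list[int]]:
    """Exhaustive column-by-column scan: position j is diagnostic for
    sequence i iff seqs[i][j] differs from every other sequence's base and
    the column has no N or gap."""
    k = len(seqs)
    L = len(seqs[0])
    out: list[list[int]] = [[] for _ in range(k)]
    for j in range(L):
        col = [s[j] for s in seqs]
        if "N" in col or "-" in col:
            continue
        for i in range(k):
            if all(col[i] != col[o] for o in range(k) if o != i):
                out[i].append(j)
    return out


def sliding_hamming_oracle(query: str, subject: str) -> int:
    """Per-character sliding-window minimum Hamming distance."""
    best = len(query) + 1
    for start in range(len(subject) - len(query) + 1):
        d = sum(a != b for a, b in zip(query, subject[start:start + len(query)]))
        best = min(best, d)
    return best


def anova_oneway_ss(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA from explicit sums of squares."""
    from scipy.stats import f as fdist
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = fdist.sf(F, df_b, df_w)
    return float(F), float(p)


def exhaustive_partition_p(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact one-sided partition p-values by enumerating every size-m
    subset of the pooled values as a candidate paralog slot."""
    k, m = values.shape
    pool = values.ravel()
    obs = values.mean(axis=1)
    means = np.array([pool[list(c)].mean()
                      for c in combinations(range(k * m), m)])
    p_high = np.array([(means >= o).mean() for o in obs])
    p_low = np.array([(means <= o).mean() for o in obs])
    return p_high, p_low


def rank_sum_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments
    (small samples, no ties)."""
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    obs = ranks[:nx].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in combinations(range(len(pooled)), nx)])
    mu = sums.mean()
    p = (np.abs(sums - mu) >= abs(obs - mu) - 1e-12).mean()
    return float(p)


def coverage_pass_probability(transcript_len: int, ext_start: int,
                              read_len: int, min_ins: int, max_ins: int,
                              error_rate: float, core_len: int = 20,
                              flank: int = 55) -> float:
    """Probability that one sequenced read from the transcript passes the
    two-stage screen for its own motif: uniform insert length, uniform
    fragment start, i.i.d. per-base substitution errors.

    A read covering transcript interval [a, a+L) passes iff the core
    region [c0, c0+core_len) is inside the interval, the core is
    error-free, and at most one error falls in the non-core overlap with
    the extended window [e0, e0+core_len+2*flank).
    """
    L = read_len
    e0 = ext_start
    c0 = ext_start + flank
    q = 1.0 - error_rate
    ext_len = core_len + 2 * flank
    total = 0.0
    n_ins = max_ins - min_ins + 1
    for ins in range(min_ins, max_ins + 1):
        n_starts = transcript_len - ins + 1
        acc = 0.0
        for a in range(c0 + core_len - L, c0 + 1):
            overlap = min(a + L, e0 + ext_len) - max(a, e0)
            o = overlap - core_len
            p_pass = (q ** core_len) * (q ** o + o * q ** (o - 1) * (1 - q))
            acc += p_pass
        total += acc / n_starts
    return total / n_ins
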