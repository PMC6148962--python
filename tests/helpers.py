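"""Independent oracles and small builders shared across the test suite.

Each oracle recomputes an operation from its definition by a different
route than the implementation (position-by-position scans, exhaustive
enumeration, direct formulas) so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np

from saavpipe.core_io import ProteinSeq


def brute_force_digest(seq: str, max_missed: int, min_len: int,
                       proline_rule: bool = True):
    """Enumerate tryptic peptides by scanning every (i, j) substring.

    A substring is a valid peptide iff both ends are cleavage boundaries
    (terminus, or after K/R not followed by P) and it retains at most
    ``max_missed`` internal boundaries.  Returns sorted
    (start, end, sequence, missed) tuples with 1-based inclusive spans.
    """
    n = len(seq)

    def is_boundary(pos: int) -> bool:
        if pos == 0 or pos == n:
            return True
        if seq[pos - 1] not in "KR":
            return False
        return not (proline_rule and seq[pos] == "P")

    out = []
    for i in range(n):
        if not is_boundary(i):
            continue
        for j in range(i + 1, n + 1):
            if not is_boundary(j):
                continue
            internal = sum(1 for k in range(i + 1, j) if is_boundary(k))
            if internal <= max_missed and j - i >= min_len:
                out.append((i + 1, j, seq[i:j], internal))
    return sorted(out)


def embed_peptide(peptide: str, start: int, accession: str = "TEST",
                  tail: str = "AAAAAAAAAR") -> ProteinSeq:
    """Build a protein whose tryptic digest contains ``peptide`` exactly
    at 1-based span [start, start+len-1].

    The prefix is a single fragment ending in K; the peptide itself must
    end in K/R (or pass ``tail=""`` to place it at the C-terminus).
    """
    if start > 1:
        prefix = "A" * (start - 2) + "K"
    else:
        prefix = ""
    if tail and peptide[-1] not in "KR":
        raise ValueError("peptide must end in K/R to precede a tail")
    return ProteinSeq(accession=accession, sequence=prefix + peptide + tail)


def random_protein(rng: np.random.Generator, length: int,
                   accession: str = "RND") -> ProteinSeq:
    """Random sequence over the canonical alphabet, K/R enriched so that
    short proteins still contain several cleavage sites."""
    from saavpipe.core_io import CANONICAL_AA
    letters = list(CANONICAL_AA)
    probs = np.array([0.06 if aa in "KRP" else (1 - 3 * 0.06) / 17
                      for aa in letters])
    seq = "".join(rng.choice(letters, size=length, p=probs))
    return ProteinSeq(accession=accession, sequence=seq)


def logrank_direct(times_a, events_a, times_b, events_b):
    """Mantel-Haenszel log-rank chi-square from the direct formula:
    sum over distinct event times of (O_A - E_A) with hypergeometric
    variance."""
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    events_a = np.asarray(events_a, int)
    events_b = np.asarray(events_b, int)
    all_event_times = np.unique(np.concatenate(
        [times_a[events_a == 1], times_b[events_b == 1]]))
    o_minus_e, var = 0.0, 0.0
    for t in all_event_times:
        n_a = np.sum(times_a >= t)
        n_b = np.sum(times_b >= t)
        n = n_a + n_b
        d = np.sum((times_a == t) & (events_a == 1)) + \
            np.sum((times_b == t) & (events_b == 1))
        d_a = np.sum((times_a == t) & (events_a == 1))
        if n == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e ** 2 / var)


def km_direct(times, events):
    """Product-limit estimate by the textbook formula.

    Returns dict mapping each distinct event time to S(t).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / n_at_risk
        out[float(t)] = s
    return out
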