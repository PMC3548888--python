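"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions, not from the package's
algorithms: occurrence counting by naive sliding-window comparison,
minimum unique lengths by tabulating every (position, length) window, and
paired-end uniqueness by exhaustive enumeration of all mate pairings.
"""

from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_ACGT = set("ACGT")


def rc(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def naive_occurrences(seqs: dict, query: str, strand_mode: str = "both"):
    """All (name, pos, strand) exact matches by direct window comparison."""
    query = query.upper()
    out = []
    if set(query) - _ACGT:
        return out
    rcq = rc(query)
    L = len(query)
    for name, seq in seqs.items():
        seq = seq.upper()
        for p in range(len(seq) - L + 1):
            window = seq[p : p + L]
            if window == query:
                out.append((name, p, "+"))
            if strand_mode == "both" and window == rcq:
                out.append((name, p, "-"))
    return sorted(out)


def brute_force_mul(seqs: dict, seq_name: str, kmin: int, kmax: int,
                    strand_mode: str = "both"):
    """MUL per position straight from the definition.

    For every length L from kmin up, tabulate all length-L windows of all
    sequences and record, for each still-unresolved position, the first L
    at which its window occurs exactly once (both-strand counts add the
    reverse-complement window's tally, so palindromes count twice).
    """
    seqs = {k: v.upper() for k, v in seqs.items()}
    target = seqs[seq_name]
    n = len(target)
    values = [0] * n
    unresolved = set(range(n))
    for L in range(kmin, kmax + 1):
        if not unresolved:
            break
        counts = Counter()
        for seq in seqs.values():
            for p in range(len(seq) - L + 1):
                counts[seq[p : p + L]] += 1
        for p in sorted(unresolved):
            if p + L > n:
                unresolved.discard(p)
                continue
            window = target[p : p + L]
            if set(window) - _ACGT:
                unresolved.discard(p)  # ambiguous base: never matchable
                continue
            total = counts[window]
            if strand_mode == "both":
                total += counts[rc(window)]
            if total == 1:
                values[p] = L
                unresolved.discard(p)
    return values


def brute_force_bisulfite_mul(genome: dict, strand: str, kmin: int, kmax: int,
                              crosscheck: str = "both"):
    """Bisulfite MUL from the definition, all (p, L) pairs."""
    def conv(seq, st):
        seq = seq.upper()
        return seq.replace("C", "T") if st == "fw" else seq.replace("G", "A")

    other = "rv" if strand == "fw" else "fw"
    own = {k: conv(v, strand) for k, v in genome.items()}
    oth = {k: conv(v, other) for k, v in genome.items()}
    out = {}
    for name, seq in own.items():
        n = len(seq)
        values = [0] * n
        for p in range(n):
            for L in range(kmin, min(kmax, n - p) + 1):
                read = seq[p : p + L]
                if len(naive_occurrences(own, read, "forward_only")) != 1:
                    continue
                mode = "both" if crosscheck == "both" else "forward_only"
                if naive_occurrences(oth, read, mode):
                    continue
                values[p] = L
                break
        out[name] = values
    return out


def exhaustive_pair_spans(seqs: dict, mate1: str, mate2: str, read_length: int,
                          insert_min: float, insert_max: float):
    """All deduplicated candidate fragment spans for a mate pair.

    Enumerates every placement of each mate on every sequence and strand
    and keeps forward-reverse pairings whose implied span lies within the
    insert bounds and exceeds the read length (no complete overlap).
    """
    spans = set()
    occ1 = naive_occurrences(seqs, mate1, "both")
    occ2 = naive_occurrences(seqs, mate2, "both")
    for n1, p1, s1 in occ1:
        for n2, p2, s2 in occ2:
            if n1 != n2 or s1 == s2:
                continue
            pp, pm = (p1, p2) if s1 == "+" else (p2, p1)
            if pp > pm:
                continue
            span = pm + read_length - pp
            if span <= read_length:
                continue
            if insert_min <= span <= insert_max:
                spans.add((n1, pp, pm + read_length))
    return spans


def pair_unique_oracle(seqs, mate1, mate2, read_length, insert_min, insert_max):
    """Gene-level uniqueness of a mate pair from the exhaustive span set."""
    spans = exhaustive_pair_spans(seqs, mate1, mate2, read_length,
                                  insert_min, insert_max)
    if not spans:
        return False
    starts = {(n, s) for n, s, _ in spans}
    ends = {(n, e) for n, _, e in spans}
    return len(starts) == 1 or len(ends) == 1
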