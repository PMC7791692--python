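"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's scanning/intersection code paths:
the repeat oracle tests every (start, motif-length) pair exhaustively, the
interval oracle compares all pairs, and the genotype oracle evaluates the
filter predicates directly on genotype triples.
"""

from __future__ import annotations


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n)
    )


def brute_force_repeats(
    seq: str, name: str, min_repeats: dict[int, int]
) -> list[tuple[str, int, int, str, int]]:
    """All maximal perfect tandem repeats, by exhaustive start enumeration.

    Returns sorted (scaffold, start, end, motif, count) tuples with 1-based
    inclusive coordinates, complete units only.
    """
    n = len(seq)
    out = []
    for unit, min_count in min_repeats.items():
        for i in range(n - unit + 1):
            window = seq[i : i + unit]
            if "N" in window or not _primitive(window):
                continue
            if i > 0 and seq[i - 1] == seq[i - 1 + unit]:
                continue  # extendable leftward: not the run start
            j = i + unit
            while j < n and seq[j] == seq[j - unit]:
                j += 1
            count = (j - i) // unit
            if count >= min_count:
                out.append((name, i + 1, i + count * unit, window, count))
    return sorted(out)


def brute_force_overlaps(
    queries: list[tuple[str, int, int]],
    targets: list[tuple[str, int, int]],
) -> dict[int, int]:
    """All-pairs interval intersection (1-based inclusive).

    Maps query index -> index of the overlapping target with the largest
    overlap (ties to the leftmost target); queries with no overlap are absent.
    """
    best: dict[int, int] = {}
    for qi, (qs, qa, qb) in enumerate(queries):
        top = None
        for ti, (ts, ta, tb) in enumerate(targets):
            if qs != ts or qa > tb or ta > qb:
                continue
            ov = min(qb, tb) - max(qa, ta) + 1
            key = (ov, -ta)
            if top is None or key > top[0]:
                top = (key, ti)
        if top is not None:
            best[qi] = top[1]
    return best


def shared_predicate(gts: tuple) -> bool:
    """True when the site would be dropped as identically shared non-reference."""
    norm = [tuple(sorted(g)) for g in gts]
    return len(set(norm)) == 1 and norm[0] != (0, 0)


def treatment_differs_predicate(gts: tuple) -> bool:
    """True when at least one treated genotype differs from the control."""
    ctrl, low, high = (tuple(sorted(g)) for g in gts)
    return low != ctrl or high != ctrl
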