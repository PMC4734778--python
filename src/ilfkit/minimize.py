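"""Exact two-level minimization: Quine-McCluskey primes + minimum cover.

Terms are represented as ``(value, mask)`` pairs: ``mask`` bit k set means
input k is constrained, in which case ``value`` bit k gives its polarity.

The covering step is exact branch-and-bound over the prime implicants with
a lexicographic objective: fewest terms first, then fewest total literals.
Among covers tied on both counts the term list with the smallest canonical
sort order is returned, so results are deterministic.
"""

from __future__ import annotations

import itertools
from typing import Iterable

from .truthtable import Cover, Implicant, TruthTable


def quine_mccluskey_primes(on_set: frozenset[int] | set[int], n: int) -> list[tuple[int, int]]:
    """All prime implicants of a completely specified function.

    Classic tabulation: repeatedly merge pairs of cubes differing in one
    constrained bit; cubes never merged are prime.
    """
    if not on_set:
        return []
    full = (1 << n) - 1
    current = {(m, full) for m in on_set}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        # group by (mask, popcount(value & mask)) so only neighbours compare
        groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for value, mask in current:
            groups.setdefault((mask, bin(value).count("1")), []).append((value, mask))
        for (mask, ones), cubes in groups.items():
            partner_key = (mask, ones + 1)
            for a in cubes:
                for b in groups.get(partner_key, ()):
                    diff = a[0] ^ b[0]
                    if bin(diff).count("1") == 1:
                        used.add(a)
                        used.add(b)
                        merged.add((a[0] & ~diff, mask & ~diff))
        primes |= current - used
        current = merged
    return sorted(primes, key=lambda vm: (vm[1], vm[0]))


def _cover_search(
    primes: list[tuple[int, int]],
    cover_sets: list[frozenset[int]],
    literal_costs: list[int],
    minterms: frozenset[int],
) -> list[int]:
    """Exact minimum-cost cover (terms, then literals) by branch and bound."""
    order = sorted(
        range(len(primes)),
        key=lambda i: (-len(cover_sets[i]), literal_costs[i], primes[i][1], primes[i][0]),
    )

    # greedy incumbent for the initial bound
    remaining = set(minterms)
    greedy: list[int] = []
    while remaining:
        best_i = max(
            order,
            key=lambda i: (len(cover_sets[i] & remaining), -literal_costs[i]),
        )
        greedy.append(best_i)
        remaining -= cover_sets[best_i]
    best = [
        len(greedy),
        sum(literal_costs[i] for i in greedy),
        sorted(greedy),
    ]

    covers_of: dict[int, list[int]] = {m: [] for m in minterms}
    for i in order:
        for m in cover_sets[i]:
            covers_of[m].append(i)
    max_cover = max((len(cs) for cs in cover_sets), default=1)

    def search(chosen: list[int], lit_cost: int, remaining: frozenset[int]):
        if not remaining:
            cand = [len(chosen), lit_cost, sorted(chosen)]
            if cand[:2] < best[:2] or (cand[:2] == best[:2] and cand[2] < best[2]):
                best[:] = cand
            return
        # admissible lower bound on the final term count
        lower = len(chosen) + -(-len(remaining) // max_cover)
        if lower > best[0]:
            return
        if lower == best[0] and lit_cost >= best[1]:
            return  # equal-term extension cannot reduce the literal count
        # branch on the hardest minterm: fewest candidate primes
        m = min(remaining, key=lambda x: (len(covers_of[x]), x))
        for i in covers_of[m]:
            search(chosen + [i], lit_cost + literal_costs[i], remaining - cover_sets[i])

    search([], 0, minterms)
    return best[2]


def minimum_cover(
    primes: list[tuple[int, int]], on_set: frozenset[int] | set[int], n: int
) -> list[tuple[int, int]]:
    """Select a minimum-term (then minimum-literal) subset of primes."""
    minterms = frozenset(on_set)
    if not minterms:
        return []
    cover_sets = []
    literal_costs = []
    for value, mask in primes:
        free = [k for k in range(n) if not mask >> k & 1]
        ms = set()
        for bits in itertools.product((0, 1), repeat=len(free)):
            m = value
            for k, b in zip(free, bits):
                m |= b << k
            ms.add(m)
        cover_sets.append(frozenset(ms & minterms))
        literal_costs.append(bin(mask).count("1"))

    # essential primes: sole coverer of some minterm
    chosen: set[int] = set()
    remaining = set(minterms)
    changed = True
    while changed:
        changed = False
        for m in list(remaining):
            cands = [i for i in range(len(primes)) if m in cover_sets[i]]
            if len(cands) == 1:
                i = cands[0]
                if i not in chosen:
                    chosen.add(i)
                    remaining -= cover_sets[i]
                    changed = True
                    break

    if remaining:
        sub_idx = [i for i in range(len(primes)) if i not in chosen and cover_sets[i] & remaining]
        sub_primes = [primes[i] for i in sub_idx]
        sub_sets = [cover_sets[i] & frozenset(remaining) for i in sub_idx]
        sub_costs = [literal_costs[i] for i in sub_idx]
        picked = _cover_search(sub_primes, sub_sets, sub_costs, frozenset(remaining))
        chosen |= {sub_idx[i] for i in picked}

    return sorted((primes[i] for i in chosen), key=lambda vm: (vm[1], vm[0]))


def minimize_sop(tt: TruthTable, output: str | None = None) -> Cover:
    """Minimum sum-of-products cover of one output of a truth table.

    Exact (Quine-McCluskey prime generation plus branch-and-bound covering);
    limited to N <= 12 inputs.  Constant 0 yields the empty cover; constant 1
    a single tautology term.
    """
    n = tt.n_inputs
    if n > 12:
        raise ValueError("exact minimization limited to N <= 12 inputs")
    on = tt.on_set(output)
    primes = quine_mccluskey_primes(on, n)
    selected = minimum_cover(primes, on, n)
    terms = tuple(
        sorted(
            (Implicant.from_value_mask(v, m, n) for v, m in selected),
            key=Implicant.sort_key,
        )
    )
    return Cover(terms, n)
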