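"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations — per-family loops, explicit
pathway enumeration — kept separate from the library implementations they
check.
"""

from __future__ import annotations

import math
from itertools import permutations


def brute_force_enc(counts: dict[str, int], code) -> float:
    """Wright's ENC by a direct per-family loop (naive re-derivation)."""
    f_by_size: dict[int, list[float]] = {}
    n_aa_by_size: dict[int, int] = {}
    for aa, family in code.families.items():
        k = len(family)
        n_aa_by_size[k] = n_aa_by_size.get(k, 0) + 1
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in family)
        if n < 2:
            continue
        f = (n * sum((counts.get(c, 0) / n) ** 2 for c in family) - 1) / (n - 1)
        if f > 0:
            f_by_size.setdefault(k, []).append(f)
    total = 0.0
    for k, n_aa in n_aa_by_size.items():
        if k == 1:
            total += n_aa
        else:
            fs = f_by_size.get(k)
            f_bar = sum(fs) / len(fs) if fs else 1.0 / k
            total += n_aa / f_bar
    return min(total, sum(len(f) for f in code.families.values()))


def _bf_codon_syn_sites(codon: str, code) -> float:
    s = 0.0
    for pos in range(3):
        syn, valid = 0, 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in code.stop_codons:
                continue
            valid += 1
            syn += code.codon_to_aa[alt] == code.codon_to_aa[codon]
        if valid:
            s += syn / valid
    return s


def _bf_codon_diffs(c1: str, c2: str, code) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in permutations(positions):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in code.stop_codons:
                ok = False
                break
            if code.codon_to_aa[cur] == code.codon_to_aa[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        for order in permutations(positions):
            cur, sd, nd = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                a1 = "*" if cur in code.stop_codons else code.codon_to_aa[cur]
                a2 = "*" if nxt in code.stop_codons else code.codon_to_aa[nxt]
                sd += a1 == a2
                nd += a1 != a2
                cur = nxt
            results.append((sd, nd))
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def brute_force_ng86(codons1, codons2, code) -> tuple[float, float]:
    """(dN, dS) by explicit enumeration; mirrors the NG86 definition."""
    s = n = sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        s_pair = (_bf_codon_syn_sites(c1, code) + _bf_codon_syn_sites(c2, code)) / 2
        s += s_pair
        n += 3 - s_pair
        d_s, d_n = _bf_codon_diffs(c1, c2, code)
        sd += d_s
        nd += d_n
    pn, ps = nd / n, sd / s
    return (-0.75 * math.log(1 - 4 * pn / 3), -0.75 * math.log(1 - 4 * ps / 3))


def random_sense_codon_pairs(rng, code, n_codons: int, p_mut: float = 0.2):
    """A random sense-codon sequence and a mutated partner (no stops)."""
    sense = list(code.sense_codons)
    seq1 = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    seq2 = []
    for c in seq1:
        new = c
        for pos in range(3):
            if rng.random() < p_mut:
                b = "ACGT"[rng.integers(0, 4)]
                new = new[:pos] + b + new[pos + 1:]
        seq2.append(new if new not in code.stop_codons else c)
    return tuple(seq1), tuple(seq2)
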