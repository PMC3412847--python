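"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by direct enumeration, staying
independent of the library code paths it checks.
"""

from __future__ import annotations

CODON_TABLE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            CODON_TABLE[_a + _b + _c] = _AA[16 * _i + 4 * _j + _k]


def translate_walk(cds: str) -> str:
    """Codon-by-codon translation via a literal table walk."""
    assert len(cds) % 3 == 0
    out = []
    for i in range(0, len(cds), 3):
        out.append(CODON_TABLE[cds[i:i + 3].upper()])
    prot = "".join(out)
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_WOB = {("G", "T"), ("T", "G")}


def _pairs(a, b):
    return (a, b) in _PAIRS


def brute_presence_vectors(genes: dict[str, list[tuple[int, int]]]) -> list[frozenset]:
    """Presence vectors by direct enumeration: genes maps species -> list of
    (residue-or-column, phase) sites; every distinct key collects the species
    holding it."""
    table: dict[tuple[int, int], set] = {}
    for sp, sites in genes.items():
        for key in sites:
            table.setdefault(key, set()).add(sp)
    return sorted((frozenset(v) for v in table.values()),
                  key=lambda s: (len(s), sorted(s)))


def oracle_cd_pairs(seq: str, targets: list[tuple[str, str]],
                    min_span=40, max_span=180, min_stem=4, stem_window=10,
                    min_guide=9, max_guide=20, max_wobble=1, gap_max=2,
                    boxc_mismatch=1, min_intron=60) -> set[tuple[int, int]]:
    """Every (box C start, box D start) pair that admits a terminal stem and
    (when targets are given) a guide duplex — full enumeration of box pairs,
    stem arms and ungapped duplex registers."""
    s = seq.upper()
    if len(s) < min_intron:
        return set()

    def is_c(k):
        if len(k) != 7:
            return False
        mm = 0 if k[0] in "AG" else 1
        mm += sum(1 for o, e in zip(k[1:], "TGATGA") if o != e)
        return mm <= boxc_mismatch

    out = set()
    for c0 in range(len(s) - 6):
        if not is_c(s[c0:c0 + 7]):
            continue
        for d0 in range(c0 + 7, len(s) - 3):
            if s[d0:d0 + 4] != "CTGA":
                continue
            span = d0 + 4 - c0
            if not (min_span <= span <= max_span):
                continue
            # stem: any >=min_stem consecutive-pair run in the windows
            stem_found = False
            for i0 in range(max(0, c0 - stem_window), c0):
                for j1 in range(d0 + 4, min(len(s), d0 + 4 + stem_window) + 1):
                    k = 0
                    while (i0 + k < c0 and j1 - 1 - k >= d0 + 4
                           and _pairs(s[i0 + k], s[j1 - 1 - k])):
                        k += 1
                    if k >= min_stem:
                        stem_found = True
            if not stem_found:
                continue
            if not targets:
                out.add((c0, d0))
                continue
            # guide ending 0..gap_max nt upstream of box D or any internal D'
            boxes = [d0] + [i for i in range(c0 + 7, d0 - 3)
                            if s[i:i + 4] == "CTGA"]
            found = False
            for bx in boxes:
                for gap in range(gap_max + 1):
                    g_end = bx - gap
                    for L in range(min_guide, max_guide + 1):
                        g0 = g_end - L
                        if g0 < c0 + 7:
                            continue
                        guide = s[g0:g_end]
                        for tid, tseq in targets:
                            for t0 in range(len(tseq) - L + 1):
                                w = tseq[t0:t0 + L]
                                wob = 0
                                ok = True
                                for k in range(L):
                                    a, b = guide[k], w[L - 1 - k]
                                    if not _pairs(a, b):
                                        ok = False
                                        break
                                    if (a, b) in _WOB:
                                        wob += 1
                                if ok and wob <= max_wobble:
                                    found = True
                                    break
                            if found:
                                break
                        if found:
                            break
                    if found:
                        break
                if found:
                    break
            if found:
                out.add((c0, d0))
    return out


def nussinov_recursive(seq: str, min_loop: int = 3) -> int:
    """Independent memoized recursion for maximum nested base pairs."""
    s = seq.upper()
    memo: dict[tuple[int, int], int] = {}

    def best(i, j):
        if j - i <= min_loop:
            return 0
        if (i, j) in memo:
            return memo[(i, j)]
        b = best(i, j - 1)
        for k in range(i, j - min_loop):
            if _pairs(s[k], s[j]):
                left = best(i, k - 1) if k > i else 0
                b = max(b, left + 1 + best(k + 1, j - 1))
        memo[(i, j)] = b
        return b

    return best(0, len(s) - 1) if s else 0


def oracle_haca_pairs(seq: str, targets: list[tuple[str, str]],
                      min_pairs=8, min_loop=3, max_span=100, min_span=19,
                      pocket_min=4, pocket_max=10, dist_min=14, dist_max=16,
                      max_wobble=1, min_intron=120) -> set[tuple[int, int]]:
    """Every (H box start, ACA start) geometry admitting two folded hairpins
    and (when targets are given) a pseudouridylation pocket."""
    s = seq.upper()
    if len(s) < min_intron:
        return set()
    out = set()
    for a in range(len(s) - 5):
        if s[a:a + 3] != "ACA" or a + 6 > len(s):
            continue
        for h in range(max(0, a - max_span - 6), a - 6):
            k = s[h:h + 6]
            if not (len(k) == 6 and k[0] == "A" and k[2] == "A" and k[5] == "A"):
                continue
            hp2 = (h + 6, a)
            if not (min_span <= hp2[1] - hp2[0] <= max_span):
                continue
            if nussinov_recursive(s[hp2[0]:hp2[1]], min_loop) < min_pairs:
                continue
            hp1 = None
            for span in range(min_span, min(max_span, h) + 1):
                if nussinov_recursive(s[h - span:h], min_loop) >= min_pairs:
                    hp1 = (h - span, h)
                    break
            if hp1 is None:
                continue
            if not targets:
                out.add((h, a))
                continue
            found = False
            for region, box in ((hp1, h), (hp2, a)):
                if found:
                    break
                r0, r1 = region
                for dist in range(dist_min, dist_max + 1):
                    q1 = box - dist
                    if q1 <= r0 or q1 > r1 or found:
                        continue
                    for l3 in range(pocket_min, pocket_max + 1):
                        q0 = q1 - l3
                        if q0 < r0 or found:
                            continue
                        for tid, tseq in targets:
                            for t0 in range(len(tseq) - l3 - 2 + 1):
                                wob = 0
                                ok = True
                                for k2 in range(l3):
                                    pr = (s[q0 + k2], tseq[t0 + l3 - 1 - k2])
                                    if pr not in _PAIRS:
                                        ok = False
                                        break
                                    if pr in _WOB:
                                        wob += 1
                                if not ok or t0 + l3 >= len(tseq) or tseq[t0 + l3] != "T":
                                    continue
                                for l5 in range(pocket_min, pocket_max + 1):
                                    w2_lo = t0 + l3 + 2
                                    if w2_lo + l5 > len(tseq):
                                        continue
                                    for p1 in range(r0 + l5, q0 - min_loop + 1):
                                        p0 = p1 - l5
                                        wob2 = wob
                                        ok2 = True
                                        for k2 in range(l5):
                                            pr = (s[p0 + k2],
                                                  tseq[w2_lo + l5 - 1 - k2])
                                            if pr not in _PAIRS:
                                                ok2 = False
                                                break
                                            if pr in _WOB:
                                                wob2 += 1
                                        if ok2 and wob2 <= max_wobble:
                                            found = True
                                            break
                                    if found:
                                        break
                                if found:
                                    break
                            if found:
                                break
            if found:
                out.add((h, a))
    return out
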