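"""C/D box and H/ACA box snoRNA screening in intron sequences.

C/D box snoRNAs carry box C (RUGAUGA) near the 5' end and box D (CUGA)
near the 3' end, closed by a short terminal stem; an antisense guide
element immediately upstream of box D (or internal box D') base-pairs a
target rRNA, and the target nucleotide paired to the guide position five
nucleotides upstream of the box D start is the predicted 2'-O-methylation
site (the "D+5"/"N+5" rule).  H/ACA snoRNAs fold into two hairpins joined
by a single-stranded hinge carrying the H box (ANANNA), with the ACA box
ending exactly three nucleotides before the 3' end; each hairpin may hold
a bipartite pseudouridylation pocket whose two guide segments pair the
target around an unpaired "UN", the U being the predicted pseudouridine.

Structure checks use base-pair maximization (a tabulated Nussinov DP with
a minimum hairpin loop), not thermodynamic folding.  All thresholds are
explicit parameters; defaults follow canonical C/D and H/ACA descriptions.
Sequences are handled as DNA (T for U).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .alignment import pairwise_align, percent_identity
from .gene_models import revcomp

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

# 0..3 = ACGT, 4 = anything else (never pairs)
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_PAIR_OK = np.zeros((5, 5), dtype=bool)
_WOB_OK = np.zeros((5, 5), dtype=bool)
for _a, _bb in _WC | _WOBBLE:
    _PAIR_OK["ACGT".index(_a), "ACGT".index(_bb)] = True
for _a, _bb in _WOBBLE:
    _WOB_OK["ACGT".index(_a), "ACGT".index(_bb)] = True


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    p = (a.upper(), b.upper())
    return p in _WC or (allow_gu and p in _WOBBLE)


def is_wobble(a: str, b: str) -> bool:
    return (a.upper(), b.upper()) in _WOBBLE


def _duplex_positions(fixed: np.ndarray, scan: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """All start positions p in ``scan`` where scan[p:p+L] forms a full
    antiparallel duplex with ``fixed`` (scan[p+k] pairs fixed[L-1-k]).
    Returns (valid boolean array, wobble counts), length len(scan)-L+1."""
    L, N = len(fixed), len(scan)
    if N < L or L == 0:
        return np.zeros(0, dtype=bool), np.zeros(0, dtype=np.int32)
    n_out = N - L + 1
    valid = np.ones(n_out, dtype=bool)
    wob = np.zeros(n_out, dtype=np.int32)
    for k in range(L):
        partner = fixed[L - 1 - k]
        window = scan[k:k + n_out]
        valid &= _PAIR_OK[window, partner]
        wob += _WOB_OK[window, partner]
    return valid, wob


def matches_box_c(kmer: str, max_mismatch: int = 1) -> bool:
    """Box C consensus RUGAUGA (R = A/G), with a mismatch budget."""
    if len(kmer) != 7:
        return False
    kmer = kmer.upper()
    mm = 0 if kmer[0] in "AG" else 1
    for obs, exp in zip(kmer[1:], "TGATGA"):
        if obs != exp:
            mm += 1
    return mm <= max_mismatch


def matches_box_h(kmer: str) -> bool:
    """H box consensus ANANNA."""
    k = kmer.upper()
    return len(k) == 6 and k[0] == "A" and k[2] == "A" and k[5] == "A"


def nussinov_table(seq: str, min_loop: int = 3) -> np.ndarray:
    """dp[i, j] = maximum nested base pairs (WC + G·U) in seq[i..j]
    inclusive, with hairpin loops of at least ``min_loop`` — the classic
    base-pair maximization recursion, tabulated."""
    s = _encode(seq.upper())
    n = len(s)
    dp = np.zeros((n, n), dtype=np.int16)
    if n == 0:
        return dp
    P = _PAIR_OK[s[:, None], s[None, :]]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            ks = np.nonzero(P[i:j - min_loop, j])[0] + i
            if len(ks):
                left = np.where(ks > i, dp[i, np.maximum(ks - 1, 0)], 0)
                right = dp[ks + 1, j - 1]
                best = max(best, int((left + 1 + right).max()))
            dp[i, j] = best
    return dp


def max_base_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum nested base pairs over the whole sequence."""
    n = len(seq)
    if n == 0:
        return 0
    return int(nussinov_table(seq, min_loop)[0, n - 1])


# --- C/D box detection ----------------------------------------------------

@dataclass(frozen=True)
class CDParams:
    min_intron: int = 60
    boxc_mismatch: int = 1
    min_span: int = 40        # box C start to box D end
    max_span: int = 180
    min_stem: int = 4
    stem_window: int = 10     # stem arms within this many nt of box C / box D
    min_guide: int = 9
    max_guide: int = 20
    max_guide_wobble: int = 1
    guide_gap_max: int = 2    # guide ends 0..2 nt upstream of box D/D'


@dataclass
class GuideDuplex:
    guide_start: int          # intron coordinates, half-open
    guide_end: int
    target_id: str
    target_start: int         # target coordinates, half-open
    target_end: int
    wobbles: int
    box: str                  # "D" or "Dprime"
    methyl_site: int | None   # 1-based position on target, D+5 rule


@dataclass
class CDCandidate:
    intron_key: str
    start: int                # candidate span in intron, half-open
    end: int
    boxc_start: int
    boxc_seq: str
    boxd_start: int
    boxd_seq: str
    boxdprime_start: int | None
    stem_pairs: list[tuple[int, int]]
    guide: GuideDuplex | None
    orphan: bool
    score: float


def _find_terminal_stem(
    seq: str, c_start: int, d_end: int, p: CDParams
) -> list[tuple[int, int]] | None:
    """Longest run of >=min_stem consecutive pairs closing the candidate,
    with the 5' arm within stem_window nt upstream of box C and the 3' arm
    within stem_window nt downstream of box D."""
    lo5 = max(0, c_start - p.stem_window)
    hi3 = min(len(seq), d_end + p.stem_window)
    best: list[tuple[int, int]] | None = None
    for i0 in range(lo5, c_start):
        for j1 in range(hi3, d_end, -1):
            run: list[tuple[int, int]] = []
            k = 0
            while (
                i0 + k < c_start
                and j1 - 1 - k >= d_end
                and can_pair(seq[i0 + k], seq[j1 - 1 - k])
            ):
                run.append((i0 + k, j1 - 1 - k))
                k += 1
            if len(run) >= p.min_stem and (best is None or len(run) > len(best)):
                best = run
    return best


def _best_guide(
    seq: str,
    box_start: int,
    box_name: str,
    targets: list[tuple[str, np.ndarray]],
    region_lo: int,
    p: CDParams,
) -> GuideDuplex | None:
    """Best antisense element ending 0..guide_gap_max nt upstream of a box:
    contiguous duplex of >=min_guide pairs, at most max_guide_wobble G·U,
    rest Watson-Crick.  Best = highest net score (length − wobbles), then
    fewest wobbles; ties resolve to the first target/leftmost window."""
    best: GuideDuplex | None = None
    best_key = None
    for gap in range(p.guide_gap_max + 1):
        g_end = box_start - gap
        for L in range(p.max_guide, p.min_guide - 1, -1):
            g_start = g_end - L
            if g_start < region_lo:
                continue
            guide = _encode(seq[g_start:g_end])
            for tid, tenc in targets:
                valid, wob = _duplex_positions(guide, tenc)
                ok = np.nonzero(valid & (wob <= p.max_guide_wobble))[0]
                if len(ok) == 0:
                    continue
                # best window for this guide: fewest wobbles, then leftmost
                t0 = int(ok[np.argmin(wob[ok])])
                w = int(wob[t0])
                key = (L - w, -w)
                if best_key is None or key > best_key:
                    gi = box_start - 5
                    site = None
                    if g_start <= gi < g_end:
                        site = t0 + (L - 1 - (gi - g_start)) + 1  # 1-based
                    best = GuideDuplex(g_start, g_end, tid, t0, t0 + L, w,
                                       box_name, site)
                    best_key = key
    return best


def find_cd_candidates(
    seq: str,
    intron_key: str = "",
    targets: list[tuple[str, str]] | None = None,
    params: CDParams | None = None,
) -> list[CDCandidate]:
    """Screen one intron for C/D box snoRNA candidates.

    With an empty target list, candidates that satisfy the box and stem
    constraints are emitted with empty guide fields and flagged orphan
    (a snoRNA whose target RNA is unknown).  With targets, a guide duplex
    is required.  Candidates are ranked by score = stem length + duplex
    length − wobbles.
    """
    p = params or CDParams()
    targets = targets or []
    s = seq.upper()
    if len(s) < p.min_intron:
        return []
    tencs = [(tid, _encode(t.upper().replace("U", "T"))) for tid, t in targets]
    out: list[CDCandidate] = []
    c_positions = [i for i in range(len(s) - 6)
                   if matches_box_c(s[i:i + 7], p.boxc_mismatch)]
    d_positions = [i for i in range(len(s) - 3) if s[i:i + 4] == "CTGA"]
    for c0 in c_positions:
        c_end = c0 + 7
        for d0 in d_positions:
            d_end = d0 + 4
            span = d_end - c0
            if d0 < c_end or not (p.min_span <= span <= p.max_span):
                continue
            stem = _find_terminal_stem(s, c0, d_end, p)
            if stem is None:
                continue
            dprimes = [i for i in d_positions if c_end <= i and i + 4 <= d0]
            guide = None
            guide_box_pos: int | None = None
            if tencs:
                guide = _best_guide(s, d0, "D", tencs, c_end, p)
                if guide is not None:
                    guide_box_pos = d0
                for dp in dprimes:
                    g2 = _best_guide(s, dp, "Dprime", tencs, c_end, p)
                    if g2 and (
                        guide is None
                        or (g2.guide_end - g2.guide_start - g2.wobbles, -g2.wobbles)
                        > (guide.guide_end - guide.guide_start - guide.wobbles,
                           -guide.wobbles)
                    ):
                        guide, guide_box_pos = g2, dp
                if guide is None:
                    continue
            duplex_len = (guide.guide_end - guide.guide_start) if guide else 0
            wob = guide.wobbles if guide else 0
            out.append(
                CDCandidate(
                    intron_key=intron_key,
                    start=stem[0][0],
                    end=stem[0][1] + 1,
                    boxc_start=c0,
                    boxc_seq=s[c0:c0 + 7],
                    boxd_start=d0,
                    boxd_seq=s[d0:d0 + 4],
                    boxdprime_start=(
                        guide_box_pos
                        if guide is not None and guide.box == "Dprime"
                        else None
                    ),
                    stem_pairs=stem,
                    guide=guide,
                    orphan=not tencs,
                    score=len(stem) + duplex_len - wob,
                )
            )
    out.sort(key=lambda c: (-c.score, c.boxc_start, c.boxd_start))
    return out


# --- H/ACA detection ------------------------------------------------------

@dataclass(frozen=True)
class HACAParams:
    min_intron: int = 120
    min_hairpin_pairs: int = 8
    min_loop: int = 3
    max_hairpin_span: int = 100
    min_hairpin_span: int = 19   # 2*8 pairs + loop 3
    pocket_min: int = 4
    pocket_max: int = 10
    pocket_dist_min: int = 14    # 3' pocket arm end to downstream box start
    pocket_dist_max: int = 16
    max_pocket_wobble: int = 1


@dataclass
class PocketGuide:
    arm5_start: int
    arm5_end: int
    arm3_start: int
    arm3_end: int
    target_id: str
    target_start: int       # half-open window: arm3-match + UN + arm5-match
    target_end: int
    psi_site: int           # 1-based U position on target
    wobbles: int
    hairpin: int            # 1 (5' hairpin, H box) or 2 (3' hairpin, ACA box)


@dataclass
class HACACandidate:
    intron_key: str
    start: int
    end: int
    hairpin1: tuple[int, int]
    hairpin2: tuple[int, int]
    boxh_start: int
    boxh_seq: str
    aca_start: int
    pockets: list[PocketGuide]
    orphan: bool
    score: float


def _pocket_search(
    seq: str,
    region: tuple[int, int],
    box_start: int,
    hairpin_no: int,
    targets: list[tuple[str, np.ndarray]],
    p: HACAParams,
) -> PocketGuide | None:
    """Bipartite pocket inside one hairpin: a 3' arm ending
    pocket_dist_min..max nt upstream of the downstream box and a 5' arm
    further 5', both 4-10 nt, pairing the target antiparallel around an
    unpaired 'UN' (target layout: pairs-arm3 + U + N + pairs-arm5)."""
    r0, r1 = region
    best: PocketGuide | None = None
    best_key = None
    senc = _encode(seq)
    for dist in range(p.pocket_dist_min, p.pocket_dist_max + 1):
        q1 = box_start - dist
        if q1 <= r0 or q1 > r1:
            continue
        for l3 in range(p.pocket_max, p.pocket_min - 1, -1):
            q0 = q1 - l3
            if q0 < r0:
                continue
            arm3 = senc[q0:q1]
            for tid, tenc in targets:
                valid3, wob3 = _duplex_positions(arm3, tenc)
                if len(valid3) == 0:
                    continue
                # 'T' right after the arm3 match (False when out of range)
                is_u = np.zeros(len(valid3), dtype=bool)
                n_u = max(len(tenc) - l3, 0)
                is_u[:n_u] = tenc[l3:l3 + n_u] == 3
                starts = np.nonzero(valid3 & is_u
                                    & (wob3 <= p.max_pocket_wobble))[0]
                for t0 in starts.tolist():
                    for l5 in range(p.pocket_max, p.pocket_min - 1, -1):
                        w2_lo = t0 + l3 + 2
                        if w2_lo + l5 > len(tenc):
                            continue
                        w2 = tenc[w2_lo:w2_lo + l5]
                        # arm5 must sit in [r0, q0 - min_loop) of the intron
                        reg_hi = q0 - p.min_loop
                        if reg_hi - r0 < l5:
                            continue
                        region_enc = senc[r0:reg_hi]
                        valid5, wob5 = _duplex_positions(w2, region_enc)
                        okp = np.nonzero(
                            valid5 & (wob5 + wob3[t0] <= p.max_pocket_wobble)
                        )[0]
                        if len(okp) == 0:
                            continue
                        p0 = r0 + int(okp[np.argmin(wob5[okp])])
                        wtot = int(wob3[t0] + wob5[p0 - r0])
                        key = (l3 + l5 - wtot, -wtot)
                        if best_key is None or key > best_key:
                            best = PocketGuide(
                                p0, p0 + l5, q0, q1, tid,
                                t0, t0 + l3 + 2 + l5, t0 + l3 + 1,
                                wtot, hairpin_no,
                            )
                            best_key = key
    return best


def find_haca_candidates(
    seq: str,
    intron_key: str = "",
    targets: list[tuple[str, str]] | None = None,
    params: HACAParams | None = None,
) -> list[HACACandidate]:
    """Screen one intron for H/ACA box snoRNA candidates.

    Geometry: [5' hairpin] [H box ANANNA in the hinge] [3' hairpin]
    [ACA] [3 nt tail].  Each hairpin must reach min_hairpin_pairs by
    base-pair maximization.  Pocket guides are required when targets are
    given; otherwise candidates are flagged orphan.
    """
    p = params or HACAParams()
    targets = targets or []
    s = seq.upper()
    if len(s) < p.min_intron:
        return []
    tencs = [(tid, _encode(t.upper().replace("U", "T"))) for tid, t in targets]
    out: list[HACACandidate] = []
    hp1_tables: dict[int, np.ndarray] = {}
    for a in range(len(s) - 5):
        if s[a:a + 3] != "ACA" or a + 6 > len(s):
            continue
        end = a + 6  # ACA ends exactly 3 nt before the candidate 3' end
        for h in range(max(0, a - p.max_hairpin_span - 6), a - 6):
            if not matches_box_h(s[h:h + 6]):
                continue
            hp2 = (h + 6, a)
            if not (p.min_hairpin_span <= hp2[1] - hp2[0] <= p.max_hairpin_span):
                continue
            if max_base_pairs(s[hp2[0]:hp2[1]], p.min_loop) < p.min_hairpin_pairs:
                continue
            # 5' hairpin: smallest upstream region folding well enough;
            # one DP table per H position serves every span (suffixes)
            if h not in hp1_tables:
                w0 = max(0, h - p.max_hairpin_span)
                hp1_tables[h] = nussinov_table(s[w0:h], p.min_loop)
            table = hp1_tables[h]
            w0 = max(0, h - p.max_hairpin_span)
            hp1 = None
            for span in range(p.min_hairpin_span, min(p.max_hairpin_span, h) + 1):
                s0 = h - span
                if table[s0 - w0, h - w0 - 1] >= p.min_hairpin_pairs:
                    hp1 = (s0, h)
                    break
            if hp1 is None:
                continue
            pockets = []
            if tencs:
                pk1 = _pocket_search(s, hp1, h, 1, tencs, p)
                pk2 = _pocket_search(s, hp2, a, 2, tencs, p)
                pockets = [pk for pk in (pk1, pk2) if pk]
                if not pockets:
                    continue
            out.append(
                HACACandidate(
                    intron_key=intron_key,
                    start=hp1[0],
                    end=end,
                    hairpin1=hp1,
                    hairpin2=hp2,
                    boxh_start=h,
                    boxh_seq=s[h:h + 6],
                    aca_start=a,
                    pockets=pockets,
                    orphan=not tencs,
                    score=sum(
                        (pk.arm5_end - pk.arm5_start) + (pk.arm3_end - pk.arm3_start)
                        - pk.wobbles
                        for pk in pockets
                    )
                    + p.min_hairpin_pairs * 2,
                )
            )
    out.sort(key=lambda c: (-c.score, c.start))
    return out


# --- duplications, library matching, target conservation ------------------

@dataclass
class DuplicationPair:
    gene_id: str
    ordinals: tuple[int, int]
    candidate_ids: tuple[str, str]
    identity: float
    aligned_length: int


def detect_neighboring_duplications(
    candidate_seqs: dict[tuple[int, str], str],
    gene_id: str = "",
    identity_threshold: float = 70.0,
) -> list[DuplicationPair]:
    """Cis-duplications: candidates in ADJACENT introns of one gene whose
    global-alignment identity reaches the threshold.

    ``candidate_seqs`` maps (intron ordinal, candidate id) -> sequence.
    """
    out: list[DuplicationPair] = []
    by_ord: dict[int, list[tuple[str, str]]] = {}
    for (ordn, cid), cseq in sorted(candidate_seqs.items()):
        by_ord.setdefault(ordn, []).append((cid, cseq))
    for ordn in sorted(by_ord):
        if ordn + 1 not in by_ord:
            continue
        for cid_a, seq_a in by_ord[ordn]:
            for cid_b, seq_b in by_ord[ordn + 1]:
                ra, rb = pairwise_align(seq_a, seq_b, kind="dna")
                ident = percent_identity(ra, rb)
                if ident >= identity_threshold:
                    out.append(
                        DuplicationPair(
                            gene_id=gene_id,
                            ordinals=(ordn, ordn + 1),
                            candidate_ids=(cid_a, cid_b),
                            identity=ident,
                            aligned_length=len(ra),
                        )
                    )
    return out


def _local_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 2.0
    al.mismatch_score = -1.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -2.0
    return al


@dataclass
class LibraryHit:
    library_id: str
    identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    strand: str


def match_known(
    candidate_seq: str,
    library: dict[str, str],
    min_identity: float = 60.0,
    min_length: int = 30,
    search_both_strands: bool = True,
) -> LibraryHit | None:
    """Best local-alignment hit of a candidate against a known-snoRNA
    library; None when nothing reaches the floors (candidate is novel)."""
    if not library:
        raise ValueError("empty snoRNA library")
    al = _local_aligner()
    best: LibraryHit | None = None
    q = candidate_seq.upper()
    for lid, lseq in sorted(library.items()):
        for strand, subject in (("+", lseq.upper()),) + (
            (("-", revcomp(lseq.upper())),) if search_both_strands else ()
        ):
            alns = al.align(q, subject)
            if len(alns) == 0:
                continue
            aln = alns[0]
            qa, sa = aln[0], aln[1]
            same = sum(1 for x, y in zip(qa, sa) if x == y and x != "-")
            cols = sum(1 for x, y in zip(qa, sa) if not (x == "-" and y == "-"))
            if cols < min_length:
                continue
            ident = 100.0 * same / cols
            if ident < min_identity:
                continue
            qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
            sspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
            hit = LibraryHit(lid, ident, qspan, sspan, strand)
            if best is None or hit.identity > best.identity:
                best = hit
    return best


def target_site_conservation(
    reference_target: str,
    footprint: tuple[int, int],
    query_target: str,
    context: int = 15,
    conserved_threshold: float = 90.0,
) -> tuple[str, float | None]:
    """Is a guide-duplex footprint conserved in another species' rRNA?

    The footprint ± context nt of the reference is locally aligned to the
    query; identity over the footprint columns decides "conserved" vs
    "poorly_conserved"; a footprint that cannot be located (missing or
    incomplete query region) returns ("not_determined", None).
    """
    f0, f1 = footprint
    c0 = max(0, f0 - context)
    c1 = min(len(reference_target), f1 + context)
    ref = reference_target[c0:c1].upper()
    al = _local_aligner()
    alns = al.align(ref, query_target.upper())
    if len(alns) == 0:
        return ("not_determined", None)
    aln = alns[0]
    ra, qa = aln[0], aln[1]
    ref_off = int(aln.aligned[0][0][0])  # ref position of first aligned col
    pos = ref_off
    same = cols = covered = 0
    for x, y in zip(ra, qa):
        if x != "-":
            ref_pos = c0 + pos
            if f0 <= ref_pos < f1:
                cols += 1
                if y != "-":
                    covered += 1
                    if x == y:
                        same += 1
            pos += 1
    if cols < (f1 - f0) or covered == 0:
        return ("not_determined", None)
    ident = 100.0 * same / cols
    return ("conserved" if ident >= conserved_threshold else "poorly_conserved", ident)


# --- candidate re-validation (independent constraint checker) -------------

def revalidate_cd(seq: str, cand: CDCandidate, p: CDParams | None = None,
                  targets: list[tuple[str, str]] | None = None) -> list[str]:
    """Re-check every constraint of a reported C/D candidate directly from
    the sequence; returns a list of violations (empty = valid)."""
    p = p or CDParams()
    s = seq.upper()
    bad = []
    if not matches_box_c(s[cand.boxc_start:cand.boxc_start + 7], p.boxc_mismatch):
        bad.append("box C does not match RUGAUGA within budget")
    if s[cand.boxd_start:cand.boxd_start + 4] != "CTGA":
        bad.append("box D is not CUGA")
    if not (cand.boxc_start < cand.boxd_start):
        bad.append("box C not upstream of box D")
    span = cand.boxd_start + 4 - cand.boxc_start
    if not (p.min_span <= span <= p.max_span):
        bad.append(f"box span {span} outside [{p.min_span},{p.max_span}]")
    if len(cand.stem_pairs) < p.min_stem:
        bad.append("terminal stem too short")
    for i, j in cand.stem_pairs:
        if not can_pair(s[i], s[j]):
            bad.append(f"stem positions {i},{j} cannot pair")
    g = cand.guide
    if g is not None:
        L = g.guide_end - g.guide_start
        if L < p.min_guide:
            bad.append("guide too short")
        box_start = cand.boxd_start if g.box == "D" else cand.boxdprime_start
        if box_start is None or not (0 <= box_start - g.guide_end <= p.guide_gap_max):
            bad.append("guide does not abut its box")
        if targets:
            tseq = dict(targets).get(g.target_id, "")
            wob = 0
            for k in range(L):
                a = s[g.guide_start + k]
                b = tseq[g.target_end - 1 - k]
                if not can_pair(a, b):
                    bad.append(f"guide position {k} unpaired")
                    break
                if is_wobble(a, b):
                    wob += 1
            if wob > p.max_guide_wobble:
                bad.append("too many G·U wobbles in guide duplex")
    elif not cand.orphan:
        bad.append("non-orphan candidate without guide")
    return bad


def revalidate_haca(seq: str, cand: HACACandidate,
                    p: HACAParams | None = None,
                    targets: list[tuple[str, str]] | None = None) -> list[str]:
    """Independent constraint check for a reported H/ACA candidate."""
    p = p or HACAParams()
    s = seq.upper()
    bad = []
    if s[cand.aca_start:cand.aca_start + 3] != "ACA":
        bad.append("ACA box missing")
    if cand.end - (cand.aca_start + 3) != 3:
        bad.append("ACA box does not end 3 nt before candidate 3' end")
    if not matches_box_h(s[cand.boxh_start:cand.boxh_start + 6]):
        bad.append("H box does not match ANANNA")
    h1, h2 = cand.hairpin1, cand.hairpin2
    if not (h1[1] <= cand.boxh_start and cand.boxh_start + 6 <= h2[0]):
        bad.append("H box not in the hinge between hairpins")
    for lo, hi in (h1, h2):
        if max_base_pairs(s[lo:hi], p.min_loop) < p.min_hairpin_pairs:
            bad.append(f"hairpin [{lo},{hi}) below {p.min_hairpin_pairs} pairs")
    if targets:
        tmap = dict(targets)
        for pk in cand.pockets:
            w = tmap[pk.target_id][pk.target_start:pk.target_end]
            l3 = pk.arm3_end - pk.arm3_start
            if w[l3] != "T":
                bad.append("pocket target position is not U")
            for k in range(l3):
                if not can_pair(s[pk.arm3_start + k], w[l3 - 1 - k]):
                    bad.append("pocket 3' arm unpaired")
                    break
            l5 = pk.arm5_end - pk.arm5_start
            for k in range(l5):
                if not can_pair(s[pk.arm5_start + k], w[l3 + 2 + (l5 - 1 - k)]):
                    bad.append("pocket 5' arm unpaired")
                    break
        if not cand.pockets:
            bad.append("no pocket against provided targets")
    return bad
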