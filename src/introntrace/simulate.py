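"""Synthetic ortholog families with known intron gain/loss and planted snoRNAs.

The generator emulates the structure of ribosomal-protein gene families:
conserved coding exons over a species tree, introns at ancestral
(codon, phase) positions subject to lineage-specific loss and gain,
intron sequences far more divergent than exons (intron GC ~31%, exon GC
~44%, echoing the measured sponge values), and a minority of introns
hosting C/D or H/ACA snoRNAs whose guides are cut from synthetic rRNA
targets — some cis-duplicated into the neighboring intron.

Every fixture ships with machine-readable truth (ancestral sites, per-
branch events, realized per-species sites, planted snoRNAs) and is a pure
function of its seed: one master seed is split with numpy SeedSequence
spawning so each family draws from an independent, reproducible stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from io import StringIO
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .gene_models import GeneModel, revcomp

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP = [a + b + c for a in _BASES for b in _BASES for c in _BASES
            if a + b + c not in _STOPS]


@dataclass
class SimConfig:
    """Study conditions for the simulator; defaults follow the measured
    sponge ribosomal-protein gene statistics (4.01 introns/gene, median
    intron 68 nt, phases 50/30/20, intron GC 31.2%, CDS GC 44.2%)."""

    tree_newick: str = "((SPA:0.2,SPB:0.2):0.1,SPC:0.3);"
    n_families: int = 20
    introns_per_gene: float = 4.0          # Poisson mean, ancestral CDS introns
    intron_length_median: float = 68.0     # log-normal median
    intron_length_sigma: float = 0.7
    min_intron_length: int = 37
    phase_probs: tuple[float, float, float] = (0.50, 0.30, 0.20)
    utr5_intron_prob: float = 0.08
    loss_prob: float = 0.1                 # per branch, per site
    gain_rate: float = 0.1                 # Poisson mean per branch
    exon_sub_rate: float = 0.15            # per site per unit branch length
    intron_sub_rate: float = 0.8
    intron_indel_rate: float = 0.01        # per site per unit branch length
    indel_mean_length: float = 4.0
    intron_gc: float = 0.312
    exon_gc: float = 0.442
    cds_codons_min: int = 90
    cds_codons_max: int = 240
    utr_len_min: int = 20
    utr_len_max: int = 60
    snorna_cd_prob: float = 0.0            # per ancestral CDS intron
    snorna_haca_prob: float = 0.0
    duplication_prob: float = 0.0          # cis-copy into a neighboring intron
    minus_strand_prob: float = 0.3
    seed: int = 0


# --- sequence generators --------------------------------------------------

def _codon_weights(gc_target: float) -> np.ndarray:
    """Exponentially tilted weights over non-stop codons whose expected GC
    matches the target (solved by bisection; deterministic)."""
    gc_counts = np.array([sum(c in "GC" for c in cod) for cod in _NONSTOP], float)

    def expected(w):
        p = np.exp(w * gc_counts)
        p /= p.sum()
        return float((p * gc_counts).sum()) / 3.0

    lo, hi = -5.0, 5.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected(mid) < gc_target:
            lo = mid
        else:
            hi = mid
    p = np.exp(lo * gc_counts)
    return p / p.sum()


def random_cds(n_codons: int, gc_target: float, rng: np.random.Generator) -> str:
    """ATG + (n_codons-2) weighted non-stop codons + one stop codon."""
    w = _codon_weights(gc_target)
    idx = rng.choice(len(_NONSTOP), size=n_codons - 2, p=w)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(_NONSTOP[i] for i in idx) + stop


def random_noncoding(length: int, gc_target: float, rng: np.random.Generator) -> str:
    """First-order chain with stationary composition at the GC target
    (rows = 0.75*pi + 0.25*identity keep pi stationary while adding local
    correlation, as in low-complexity genomic background)."""
    pi = np.array([
        (1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2
    ])
    rows = 0.75 * pi[None, :] + 0.25 * np.eye(4)
    out = [int(rng.choice(4, p=pi))]
    for _ in range(length - 1):
        out.append(int(rng.choice(4, p=rows[out[-1]])))
    return "".join(_BASES[i] for i in out)


def random_intron(length: int, gc_target: float, rng: np.random.Generator) -> str:
    # the fixed GT/AG splice ends are 50% GC; tilt the body so the whole
    # intron hits the target composition
    body_len = max(length - 4, 1)
    body_gc = min(max((gc_target * length - 2.0) / body_len, 0.05), 0.95)
    body = random_noncoding(body_len, body_gc, rng)
    return "GT" + body + "AG"


def _intron_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    L = int(round(float(rng.lognormal(np.log(cfg.intron_length_median),
                                      cfg.intron_length_sigma))))
    return max(L, cfg.min_intron_length)


# --- planted snoRNAs ------------------------------------------------------

@dataclass
class PlantedSnoRNA:
    sno_id: str
    kind: str                  # "CD" | "HACA"
    site_id: str               # host ancestral intron site
    sequence: str
    target_id: str
    predicted_site: int        # 1-based on target (methyl G / psi U)
    duplicated_to: str | None = None   # neighboring site id


def _complex_window(w: str) -> bool:
    """Reject low-complexity guide targets (homopolymer-ish windows make
    the guide register ambiguous and the planted site unidentifiable)."""
    return len(set(w)) >= 3 and max(w.count(b) for b in _BASES) <= len(w) // 2


def build_cd_snorna(rng: np.random.Generator, targets: dict[str, str],
                    sno_id: str) -> PlantedSnoRNA:
    """arm5 + box C + filler + 12-nt guide + box D + revcomp(arm5).

    The guide is the reverse complement of a target window, so the duplex
    is perfect Watson–Crick and the D+5 rule predicts target position
    window_start + 5 (1-based)."""
    tid = sorted(targets)[rng.integers(len(targets))]
    tseq = targets[tid]
    while True:
        t0 = int(rng.integers(0, len(tseq) - 12))
        if _complex_window(tseq[t0:t0 + 12]):
            break
    guide = revcomp(tseq[t0:t0 + 12])
    arm = "".join(_BASES[i] for i in rng.integers(0, 4, size=6))
    filler = random_noncoding(30, 0.4, rng)
    seq = arm + "ATGATGA" + filler + guide + "CTGA" + revcomp(arm)
    return PlantedSnoRNA(sno_id, "CD", "", seq, tid, t0 + 5)


def build_haca_snorna(rng: np.random.Generator, targets: dict[str, str],
                      sno_id: str) -> PlantedSnoRNA:
    """Two designed hairpins around an H box; the 3' hairpin holds a
    bipartite pocket cut from a target window tA+UN+tB with the unpaired U
    as the predicted pseudouridine."""
    tid = sorted(targets)[rng.integers(len(targets))]
    tseq = targets[tid]
    # need a complex window w of length 14 with w[6] == 'T'
    while True:
        t0 = int(rng.integers(0, len(tseq) - 14))
        w = tseq[t0:t0 + 14]
        if w[6] == "T" and _complex_window(w):
            break
    g3 = revcomp(w[0:6])    # pairs target 5' part
    g5 = revcomp(w[8:14])   # pairs target 3' part
    def rand(n):
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))
    armA = rand(10)
    loop1 = rand(5)
    hairpin1 = armA + loop1 + revcomp(armA)
    lower5 = rand(5)
    upper5 = rand(5)
    apex = rand(4)
    hairpin2 = lower5 + g5 + upper5 + apex + revcomp(upper5) + g3 + revcomp(lower5)
    spacer = rand(10)
    seq = hairpin1 + "ATAGCA" + hairpin2 + spacer + "ACA" + rand(3)
    return PlantedSnoRNA(sno_id, "HACA", "", seq, tid, t0 + 7)


# --- evolving state -------------------------------------------------------

@dataclass
class _Site:
    site_id: str
    region: str            # "cds" | "utr5"
    r: int                 # codon index (cds) or utr offset
    phase: int             # 0/1/2 for cds, -1 for utr5
    segments: list[list[str]]   # [kind, seq]; kind in fix/free/sno

    def sequence(self) -> str:
        return "".join(s for _, s in self.segments)

    def offset_key(self, utr5_len: int) -> int:
        if self.region == "utr5":
            return self.r
        return utr5_len + 3 * self.r + self.phase

    def clone(self) -> "_Site":
        return _Site(self.site_id, self.region, self.r, self.phase,
                     [[k, s] for k, s in self.segments])


def _make_segments(pre: str, sno: str | None, post: str) -> list[list[str]]:
    segs: list[list[str]] = [["fix", "GT"], ["free", pre]]
    if sno is not None:
        segs.append(["sno", sno])
    segs += [["free", post], ["fix", "AG"]]
    return segs


def _mutate_noncoding(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    if not seq or p_sub <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < p_sub)[0]
    for i in hits:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _indel(seq: str, rate: float, mean_len: float, gc: float,
           rng: np.random.Generator) -> str:
    if not seq or rate <= 0:
        return seq
    n = rng.poisson(rate * len(seq))
    for _ in range(n):
        L = max(1, int(rng.geometric(1.0 / mean_len)))
        pos = int(rng.integers(0, len(seq) + 1))
        if rng.random() < 0.5 and len(seq) > L + 4:
            seq = seq[:pos] + seq[pos + L:]
        else:
            seq = seq[:pos] + random_noncoding(L, gc, rng) + seq[pos:]
    return seq


def _mutate_cds(cds: str, p_sub: float, rng: np.random.Generator) -> str:
    """Per-site substitutions that never create a stop codon; the ATG start
    and the terminal stop are immutable."""
    if p_sub <= 0:
        return cds
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for ci in range(1, len(codons) - 1):
        cod = list(codons[ci])
        changed = False
        for k in range(3):
            if rng.random() < p_sub:
                cod[k] = _BASES[rng.integers(4)]
                changed = True
        if changed:
            trial = "".join(cod)
            codons[ci] = trial if trial not in _STOPS else codons[ci]
    return "".join(codons)


# --- the simulator --------------------------------------------------------

@dataclass
class SimBundle:
    config: SimConfig
    species: list[str]
    gene_models: dict[str, list[GeneModel]]   # species -> genes
    families: list[tuple[str, str, str]]      # family, species, gene id
    targets: dict[str, str]                   # synthetic rRNA
    planted: list[PlantedSnoRNA]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sp in self.species:
            fa, gff = write_species_files(self.gene_models[sp], self.truth, sp)
            (outdir / f"{sp}.fasta").write_text(fa)
            (outdir / f"{sp}.gff3").write_text(gff)
            paths[f"{sp}.fasta"] = outdir / f"{sp}.fasta"
            paths[f"{sp}.gff3"] = outdir / f"{sp}.gff3"
        fam = "family_id\tspecies_id\tgene_id\n" + "".join(
            f"{f}\t{s}\t{g}\n" for f, s, g in self.families
        )
        (outdir / "families.tsv").write_text(fam)
        rr = "".join(f">{tid}\n{seq}\n" for tid, seq in sorted(self.targets.items()))
        (outdir / "rrna.fasta").write_text(rr)
        lib = "".join(f">{p.sno_id}\n{p.sequence}\n" for p in self.planted)
        (outdir / "known_snornas.fasta").write_text(lib)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))
        for name in ("families.tsv", "rrna.fasta", "known_snornas.fasta", "truth.json"):
            paths[name] = outdir / name
        return paths


def write_species_files(genes: list[GeneModel], truth: dict, species: str
                        ) -> tuple[str, str]:
    """One contig per gene; minus-strand genes are emitted reverse-
    complemented with minus-strand features, exercising loader
    normalization."""
    fa, gff = StringIO(), StringIO()
    gff.write("##gff-version 3\n")
    for g in genes:
        contig = f"ctg_{g.gene_id}"
        seq = g.sequence if g.strand_original == "+" else revcomp(g.sequence)
        fa.write(f">{contig}\n")
        for i in range(0, len(seq), 70):
            fa.write(seq[i:i + 70] + "\n")
        L = len(seq)
        st = g.strand_original

        def coords(s, e):  # sense-span half-open -> contig 1-based inclusive
            if st == "+":
                return s + 1, e
            return L - e + 1, L - s

        gs, ge = coords(0, len(g.sequence))
        gff.write(f"{contig}\t.\tgene\t{gs}\t{ge}\t.\t{st}\t.\tID={g.gene_id}\n")
        gff.write(
            f"{contig}\t.\tmRNA\t{gs}\t{ge}\t.\t{st}\t.\t"
            f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
        )
        # CDS gene-span intervals from transcript cds bounds
        tpos = 0
        for k, (s, e) in enumerate(g.exons):
            es, ee = coords(s, e)
            gff.write(
                f"{contig}\t.\texon\t{es}\t{ee}\t.\t{st}\t.\t"
                f"ID={g.gene_id}.e{k+1};Parent={g.gene_id}.t1\n"
            )
        for k, (s, e) in enumerate(g.exons):
            ex_t0, ex_t1 = tpos, tpos + (e - s)
            lo = max(g.cds_start, ex_t0)
            hi = min(g.cds_end, ex_t1)
            if lo < hi:
                cs = s + (lo - ex_t0)
                ce = s + (hi - ex_t0)
                es, ee = coords(cs, ce)
                gff.write(
                    f"{contig}\t.\tCDS\t{es}\t{ee}\t.\t{st}\t0\t"
                    f"ID={g.gene_id}.c{k+1};Parent={g.gene_id}.t1\n"
                )
            tpos = ex_t1
    return fa.getvalue(), gff.getvalue()


def _assemble_gene(gene_id: str, species: str, utr5: str, cds: str, utr3: str,
                   sites: list[_Site], strand: str) -> GeneModel:
    transcript = utr5 + cds + utr3
    ordered = sorted(sites, key=lambda s: s.offset_key(len(utr5)))
    exons = []
    gene_seq = []
    prev_t = 0
    gpos = 0
    for s in ordered:
        t = s.offset_key(len(utr5))
        gene_seq.append(transcript[prev_t:t])
        exons.append((gpos, gpos + (t - prev_t)))
        gpos += t - prev_t
        iseq = s.sequence()
        gene_seq.append(iseq)
        gpos += len(iseq)
        prev_t = t
    gene_seq.append(transcript[prev_t:])
    exons.append((gpos, gpos + len(transcript) - prev_t))
    model = GeneModel(
        gene_id=gene_id,
        species_id=species,
        sequence="".join(gene_seq),
        exons=exons,
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds),
        strand_original=strand,
    )
    model.validate()
    return model


def simulate(cfg: SimConfig) -> SimBundle:
    """Run the full generator; deterministic for a fixed config/seed."""
    tree = TreeNode.read(StringIO(cfg.tree_newick))
    tips = sorted(t.name for t in tree.tips())
    if len(tips) != len(set(tips)) or not tips:
        raise ValueError("species tree must have uniquely named tips")
    n_internal = 0
    for node in tree.postorder():
        if not node.is_tip() and node.name is None:
            n_internal += 1
            node.name = f"N{n_internal}"

    master = np.random.SeedSequence(cfg.seed)
    rng_global, rng_rrna, *fam_seeds = [
        np.random.default_rng(s) for s in master.spawn(cfg.n_families + 2)
    ]
    targets = {
        "rRNA18S": random_noncoding(1800, 0.50, rng_rrna),
        "rRNA28S": random_noncoding(3500, 0.50, rng_rrna),
    }

    gene_models: dict[str, list[GeneModel]] = {sp: [] for sp in tips}
    families: list[tuple[str, str, str]] = []
    planted_all: list[PlantedSnoRNA] = []
    truth: dict = {
        "species": tips,
        "tree": cfg.tree_newick,
        "config": asdict(cfg),
        "families": {},
    }

    for fi in range(cfg.n_families):
        rng = fam_seeds[fi]
        fam_id = f"RPG{fi+1:03d}"
        n_codons = int(rng.integers(cfg.cds_codons_min, cfg.cds_codons_max + 1))
        cds = random_cds(n_codons, cfg.exon_gc, rng)
        utr5 = random_noncoding(int(rng.integers(cfg.utr_len_min, cfg.utr_len_max + 1)),
                                cfg.intron_gc, rng)
        utr3 = random_noncoding(int(rng.integers(cfg.utr_len_min, cfg.utr_len_max + 1)),
                                cfg.intron_gc, rng)
        # ancestral CDS intron sites at distinct (codon, phase)
        n_sites = int(rng.poisson(cfg.introns_per_gene))
        anc_sites: list[_Site] = []
        used: set[tuple[int, int]] = set()
        sid = 0
        attempts = 0
        while len(anc_sites) < n_sites and attempts < 50 * (n_sites + 1):
            attempts += 1
            r = int(rng.integers(1, n_codons - 1))
            p = int(rng.choice(3, p=list(cfg.phase_probs)))
            if (r, p) in used or (r, p) == (0, 0):
                continue
            used.add((r, p))
            sid += 1
            L = _intron_length(cfg, rng)
            body = random_intron(L, cfg.intron_gc, rng)
            anc_sites.append(_Site(
                f"{fam_id}.S{sid}", "cds", r, p,
                _make_segments(body[2:-2], None, ""),
            ))
        if rng.random() < cfg.utr5_intron_prob and len(utr5) > 4:
            sid += 1
            L = _intron_length(cfg, rng)
            body = random_intron(L, cfg.intron_gc, rng)
            anc_sites.append(_Site(
                f"{fam_id}.S{sid}", "utr5", int(rng.integers(1, len(utr5))), -1,
                _make_segments(body[2:-2], None, ""),
            ))
        anc_sites.sort(key=lambda s: s.offset_key(len(utr5)))

        # plant snoRNAs into ancestral CDS introns
        fam_planted: list[PlantedSnoRNA] = []
        cds_sites = [s for s in anc_sites if s.region == "cds"]
        for si, site in enumerate(cds_sites):
            if any(k == "sno" for k, _ in site.segments):
                continue  # already hosts a cis-duplicated copy
            roll = rng.random()
            sno: PlantedSnoRNA | None = None
            if roll < cfg.snorna_cd_prob:
                sno = build_cd_snorna(rng, targets, f"{site.site_id}.CD")
            elif roll < cfg.snorna_cd_prob + cfg.snorna_haca_prob:
                sno = build_haca_snorna(rng, targets, f"{site.site_id}.HACA")
            if sno is None:
                continue
            sno.site_id = site.site_id
            free = site.segments[1][1]
            if sno.kind == "HACA" and len(free) < 60:
                # keep the host intron comfortably above detection length
                free = free + random_noncoding(60 - len(free), cfg.intron_gc, rng)
            pad = max(len(free) // 2, 12)
            site.segments = _make_segments(free[:pad], sno.sequence, free[pad:])
            neighbors = [
                cds_sites[j] for j in (si - 1, si + 1) if 0 <= j < len(cds_sites)
            ]
            if neighbors and rng.random() < cfg.duplication_prob:
                nb = neighbors[int(rng.integers(len(neighbors)))]
                if not any(k == "sno" for k, _ in nb.segments):
                    nfree = nb.segments[1][1]
                    npad = max(len(nfree) // 2, 12)
                    nb.segments = _make_segments(
                        nfree[:npad], sno.sequence, nfree[npad:]
                    )
                    sno.duplicated_to = nb.site_id
            fam_planted.append(sno)
        planted_all.extend(fam_planted)

        # evolve along the tree
        events: dict[str, dict] = {}
        tip_state: dict[str, tuple[str, str, str, list[_Site]]] = {}
        gain_counter = [0]

        def evolve(node, state):
            cds_s, u5, u3, sites = state
            for child in node.children:
                bl = float(child.length or 0.0)
                branch = child.name
                ev = {"losses": [], "gains": []}
                new_sites: list[_Site] = []
                for s in sites:
                    if rng.random() < cfg.loss_prob:
                        ev["losses"].append(s.site_id)
                        continue
                    ns = s.clone()
                    p_sub = min(cfg.intron_sub_rate * bl, 0.75)
                    for seg in ns.segments:
                        if seg[0] == "free":
                            seg[1] = _mutate_noncoding(seg[1], p_sub, rng)
                            if not any(k == "sno" for k, _ in ns.segments):
                                seg[1] = _indel(
                                    seg[1], cfg.intron_indel_rate * bl,
                                    cfg.indel_mean_length, cfg.intron_gc, rng,
                                )
                    new_sites.append(ns)
                n_gain = int(rng.poisson(cfg.gain_rate))
                occupied = {(s.r, s.phase) for s in new_sites if s.region == "cds"}
                for _ in range(n_gain):
                    r = int(rng.integers(1, n_codons - 1))
                    p = int(rng.choice(3, p=list(cfg.phase_probs)))
                    if (r, p) in occupied:
                        continue
                    occupied.add((r, p))
                    gain_counter[0] += 1
                    L = _intron_length(cfg, rng)
                    body = random_intron(L, cfg.intron_gc, rng)
                    gs = _Site(
                        f"{fam_id}.G{gain_counter[0]}", "cds", r, p,
                        _make_segments(body[2:-2], None, ""),
                    )
                    new_sites.append(gs)
                    ev["gains"].append(
                        {"site_id": gs.site_id, "r": r, "phase": p}
                    )
                p_exon = min(cfg.exon_sub_rate * bl, 0.5)
                new_cds = _mutate_cds(cds_s, p_exon, rng)
                new_u5 = _mutate_noncoding(u5, min(cfg.intron_sub_rate * bl, 0.75), rng)
                new_u3 = _mutate_noncoding(u3, min(cfg.intron_sub_rate * bl, 0.75), rng)
                events[branch] = ev
                if child.is_tip():
                    tip_state[child.name] = (new_cds, new_u5, new_u3, new_sites)
                else:
                    evolve(child, (new_cds, new_u5, new_u3, new_sites))

        evolve(tree, (cds, utr5, utr3, anc_sites))

        fam_truth: dict = {
            "ancestral_sites": [
                {"site_id": s.site_id, "region": s.region, "r": s.r,
                 "phase": s.phase, "length": len(s.sequence())}
                for s in anc_sites
            ],
            "events": events,
            "tips": {},
            "snornas": [asdict(p) for p in fam_planted],
        }
        for sp in tips:
            cds_s, u5, u3, sites = tip_state[sp]
            gene_id = f"{fam_id}_{sp}"
            strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
            model = _assemble_gene(gene_id, sp, u5, cds_s, u3, sites, strand)
            gene_models[sp].append(model)
            families.append((fam_id, sp, gene_id))
            ordered = sorted(sites, key=lambda s: s.offset_key(len(u5)))
            fam_truth["tips"][sp] = {
                "gene_id": gene_id,
                "sites": [
                    {"site_id": s.site_id, "region": s.region,
                     "r": s.r, "phase": s.phase, "ordinal": i + 1}
                    for i, s in enumerate(ordered)
                ],
            }
        truth["families"][fam_id] = fam_truth

    return SimBundle(
        config=cfg,
        species=tips,
        gene_models=gene_models,
        families=families,
        targets=targets,
        planted=planted_all,
        truth=truth,
    )


def replay_tip_sites(truth: dict, family_id: str) -> dict[str, set]:
    """Reapply recorded per-branch loss/gain events to the ancestral site
    set and return each tip's expected site-id set (the replay check)."""
    fam = truth["families"][family_id]
    anc = {s["site_id"] for s in fam["ancestral_sites"]}
    tree = TreeNode.read(StringIO(truth["tree"]))
    n = 0
    for node in tree.postorder():
        if not node.is_tip() and node.name is None:
            n += 1
            node.name = f"N{n}"
    out: dict[str, set] = {}

    def walk(node, present: set):
        for child in node.children:
            ev = fam["events"].get(child.name, {"losses": [], "gains": []})
            nxt = (present - set(ev["losses"])) | {g["site_id"] for g in ev["gains"]}
            if child.is_tip():
                out[child.name] = nxt
            else:
                walk(child, nxt)

    walk(tree, anc)
    return out


# --- dinucleotide-preserving shuffle --------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle: an Eulerian-path resampling of the
    dinucleotide multigraph, preserving exact dinucleotide counts and the
    first/last residue."""
    if len(seq) < 3:
        return seq
    s = seq.upper()
    verts = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    start, end = s[0], s[-1]
    # choose a "last edge" per non-end vertex forming an arborescence to end
    for _ in range(10000):
        last = {}
        ok = True
        for v in verts:
            if v == end or not edges[v]:
                continue
            last[v] = edges[v][int(rng.integers(len(edges[v])))]
        for v in last:
            seen = {v}
            cur = v
            while cur != end:
                cur = last.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - bounded retry
        return seq
    out_edges = {}
    for v in verts:
        pool = list(edges[v])
        if v in last:
            pool.remove(last[v])
        order = list(rng.permutation(len(pool))) if pool else []
        lst = [pool[i] for i in order]
        if v in last:
            lst.append(last[v])
        out_edges[v] = lst
    walk = [start]
    ptr = {v: 0 for v in verts}
    cur = start
    for _ in range(len(s) - 1):
        nxt = out_edges[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def shuffle_introns(bundle: SimBundle, seed: int) -> SimBundle:
    """Negative control: every intron sequence dinucleotide-shuffled, gene
    structure untouched.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD1)))
    new_models: dict[str, list[GeneModel]] = {}
    for sp in bundle.species:
        new_models[sp] = []
        for g in bundle.gene_models[sp]:
            parts = []
            prev = 0
            seq = g.sequence
            pieces = []
            for i in range(len(g.exons) - 1):
                ex_e = g.exons[i][1]
                nxt_s = g.exons[i + 1][0]
                pieces.append((ex_e, nxt_s))
            for (a, b) in pieces:
                parts.append(seq[prev:a])
                parts.append(dinucleotide_shuffle(seq[a:b], rng))
                prev = b
            parts.append(seq[prev:])
            ng = GeneModel(
                gene_id=g.gene_id, species_id=g.species_id,
                sequence="".join(parts), exons=list(g.exons),
                cds_start=g.cds_start, cds_end=g.cds_end,
                strand_original=g.strand_original,
            )
            ng.validate()
            new_models[sp].append(ng)
    return SimBundle(
        config=bundle.config, species=bundle.species, gene_models=new_models,
        families=bundle.families, targets=bundle.targets,
        planted=bundle.planted, truth=bundle.truth,
    )


# --- Suberites-like intron triples (synthetic Text S1 stand-in) -----------

def make_suberites_like_set(
    seed: int,
    n_introns: int = 42,
    species: tuple[str, str, str] = ("SD", "SF", "SP"),
    sub_probs: tuple[float, float, float] = (0.20, 0.20, 0.36),
    indel_rate: float = 0.004,
    outlier_key: str = "4L5",
    outlier_species: str = "SF",
    outlier_insertion: int = 400,
) -> tuple[str, dict]:
    """SYNTHETIC stand-in for a three-species orthologous intron collection
    in the FASTA-like supplementary layout (126 records at the default 42
    triples): each triple descends from one ancestral intron on a star
    tree with per-species substitution probabilities, and one intron
    carries a large lineage-specific insertion (the divergence outlier).

    Returns (fasta_text, truth) where truth records ancestral sequences,
    per-species mutation fractions and the planted outlier.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x51)))
    genes = ["L5", "L28", "S18", "P0", "S15A", "L14", "L13A", "S12", "S19",
             "L7A", "S27", "S21", "L3", "S9"]
    keys = []
    gi = 0
    ordn = 1
    while len(keys) < n_introns:
        key = f"{ordn}{genes[gi % len(genes)]}"
        if key not in keys:
            keys.append(key)
        gi += 1
        if gi % len(genes) == 0:
            ordn += 1
    if outlier_key not in keys:
        keys[0] = outlier_key
    keys.sort()
    records = []
    truth = {"ancestors": {}, "sub_probs": dict(zip(species, sub_probs)),
             "outlier": {"key": outlier_key, "species": outlier_species,
                         "insertion": outlier_insertion}}
    for key in keys:
        L = max(int(rng.lognormal(np.log(110.0), 0.45)), 50)
        anc = random_intron(L, 0.35, rng)
        truth["ancestors"][key] = anc
        for sp, p in zip(species, sub_probs):
            seq = _mutate_noncoding(anc, p, rng)
            seq = _indel(seq, indel_rate, 3.0, 0.35, rng)
            if key == outlier_key and sp == outlier_species:
                pos = len(seq) // 2
                seq = seq[:pos] + random_noncoding(outlier_insertion, 0.35, rng) + seq[pos:]
            records.append((sp, key, seq))
    out = StringIO()
    for sp, key, seq in records:
        out.write(f">{sp} {key}\n")
        for i in range(0, len(seq), 60):
            out.write(seq[i:i + 60] + "\n")
    return out.getvalue(), truth
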