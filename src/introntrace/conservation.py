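"""Cross-species intron position/phase conservation.

Orthologous proteins are aligned; each species' CDS intron positions are
projected into alignment coordinates as (column, phase) sites; sites are
classified shared or unique, yielding per-species unique-intron ratios,
asymmetric pairwise sharing percentages and exact-subset combinatorial
grouping of species by shared sites.

Site equivalence is an EXACT (column, phase) match: two introns are the
same site only if they interrupt the same alignment column with the same
phase.  Near-miss sites (±1 codon, same phase) are surfaced in a
diagnostics table but never merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from Bio.Seq import Seq

from .alignment import AlignParams, progressive_align
from .gene_models import GeneModel, IntronRecord, extract_introns


class TranslationError(ValueError):
    pass


def translate_cds(gene: GeneModel) -> str:
    """Translate the spliced CDS with the standard code.

    A terminal stop codon is stripped; an internal stop is an error (the
    family member is then flagged and excluded by the caller).
    """
    cds = gene.cds_sequence
    if len(cds) % 3 != 0:
        raise TranslationError(f"{gene.gene_id}: CDS length not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise TranslationError(f"{gene.gene_id}: internal stop codon")
    return prot


@dataclass
class OrthologFamily:
    """One ortholog group: per-species gene models and translated proteins."""

    family_id: str
    members: dict[str, GeneModel]
    proteins: dict[str, str] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)  # species -> reason

    @classmethod
    def from_members(cls, family_id: str, members: dict[str, GeneModel]) -> "OrthologFamily":
        fam = cls(family_id=family_id, members={})
        for sp, gene in sorted(members.items()):
            if gene.incomplete:
                fam.excluded[sp] = f"{gene.gene_id}: incomplete CDS"
                continue
            try:
                fam.proteins[sp] = translate_cds(gene)
            except TranslationError as exc:
                fam.excluded[sp] = str(exc)
                continue
            fam.members[sp] = gene
        return fam


@dataclass
class ProteinMSA:
    family_id: str
    rows: dict[str, str]

    def validate_against(self, proteins: dict[str, str]) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.family_id}: ragged MSA")
        for sp, row in self.rows.items():
            if row.replace("-", "") != proteins[sp]:
                raise ValueError(f"{self.family_id}/{sp}: MSA row does not degap to protein")


def align_family(family: OrthologFamily, params: AlignParams | None = None) -> ProteinMSA:
    """Progressive protein alignment of the family (see :mod:`.alignment`).

    An externally produced alignment may be substituted by constructing a
    :class:`ProteinMSA` directly from aligned FASTA rows.
    """
    if len(family.proteins) < 2:
        raise ValueError(f"{family.family_id}: need >=2 alignable members")
    rows = progressive_align(family.proteins, kind="protein", params=params)
    msa = ProteinMSA(family.family_id, rows)
    msa.validate_against(family.proteins)
    return msa


def _column_of_residue(msa_row: str) -> list[int]:
    """Alignment column of each residue index."""
    cols = []
    for c, ch in enumerate(msa_row):
        if ch != "-":
            cols.append(c)
    return cols


def project_intron_sites(gene: GeneModel, msa_row: str) -> list[tuple[int, int]]:
    """Project CDS introns of ``gene`` into alignment coordinates.

    For an intron with coding-nucleotide offset ``t`` (from the CDS start),
    residue index r = t // 3 and phase p = t % 3; the site's column is the
    alignment column of residue r.  Phase-1/2 introns interrupt codon r;
    a phase-0 intron lies on the boundary before codon r.  UTR introns are
    excluded.  Returned in 5'->3' intron order.
    """
    cols = _column_of_residue(msa_row)
    nres = len(cols)
    sites: list[tuple[int, int]] = []
    transcript_pos = 0
    for i in range(len(gene.exons) - 1):
        s, e = gene.exons[i]
        transcript_pos += e - s
        t = transcript_pos
        if t <= gene.cds_start or t >= gene.cds_end:
            continue
        off = t - gene.cds_start
        r, p = off // 3, off % 3
        if r > nres or (r == nres and p != 0):
            raise ValueError(
                f"{gene.gene_id}: intron offset {off} beyond protein length {nres}"
            )
        # phase-0 intron exactly at the stop-codon boundary sits after the
        # last residue; anchor it to a virtual column one past the last
        col = cols[r] if r < nres else cols[-1] + 1
        sites.append((col, p))
    return sites


@dataclass
class IntronSite:
    """A distinct (column, phase) intron site with per-species presence."""

    column: int
    phase: int
    presence: dict[str, int]  # species -> intron ordinal (1-based)

    @property
    def species(self) -> frozenset:
        return frozenset(self.presence)


@dataclass
class IntronSiteTable:
    family_id: str
    species: list[str]          # species informative for this family
    sites: list[IntronSite]


def build_site_table(
    family: OrthologFamily,
    msa: ProteinMSA,
    introns: dict[str, list[IntronRecord]] | None = None,
) -> IntronSiteTable:
    """Key projected introns by exact (column, phase) and collect presence.

    Sites are sorted by column then phase.  Two introns of one gene mapping
    to one key would mean the gene model is invalid and raises.
    """
    table: dict[tuple[int, int], IntronSite] = {}
    for sp, gene in sorted(family.members.items()):
        row = msa.rows[sp]
        projected = project_intron_sites(gene, row)
        # ordinals of CDS introns only, in order
        recs = introns[sp] if introns else extract_introns(gene)
        cds_ords = [r.ordinal for r in recs if r.phase in "012"]
        if len(cds_ords) != len(projected):
            raise ValueError(
                f"{family.family_id}/{sp}: projection/extraction mismatch"
            )
        for (col, p), ordn in zip(projected, cds_ords):
            site = table.setdefault((col, p), IntronSite(col, p, {}))
            if sp in site.presence:
                raise ValueError(
                    f"{family.family_id}/{sp}: two introns at one (column, phase)"
                )
            site.presence[sp] = ordn
    sites = [table[k] for k in sorted(table)]
    return IntronSiteTable(family.family_id, sorted(family.members), sites)


def near_miss_sites(table: IntronSiteTable) -> list[tuple[IntronSite, IntronSite]]:
    """Diagnostics: pairs of distinct same-phase sites within one column of
    each other (candidate alignment slippage; reported, never merged)."""
    out = []
    for a, b in combinations(table.sites, 2):
        if a.phase == b.phase and abs(a.column - b.column) == 1:
            out.append((a, b))
    return out


@dataclass
class SharingReport:
    species: list[str]
    n_introns: dict[str, int]            # CDS introns per species (informative families)
    unique_ratio: dict[str, float]       # percent
    pairwise: pd.DataFrame               # share(A,B): % of A's introns present in B
    subset_counts: dict[frozenset, int]  # exact presence-set -> site count
    n_sites: int

    def subset_table(self) -> pd.DataFrame:
        rows = []
        for subset, count in sorted(
            self.subset_counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        ):
            row = {sp: int(sp in subset) for sp in self.species}
            row["n_shared_introns"] = count
            rows.append(row)
        return pd.DataFrame(rows)


def sharing_report(tables: list[IntronSiteTable]) -> SharingReport:
    """Aggregate site tables over families into the sharing report.

    A species absent from a family is uninformative there and excluded
    from that family's denominators.  Percentages carry one decimal of
    meaningful precision in the formatted outputs.
    """
    if not tables:
        raise ValueError("no site tables")
    universe = sorted({sp for t in tables for sp in t.species})
    n_introns = {sp: 0 for sp in universe}
    n_unique = {sp: 0 for sp in universe}
    shared_num = {(a, b): 0 for a in universe for b in universe}
    shared_den = {(a, b): 0 for a in universe for b in universe}
    subset_counts: dict[frozenset, int] = {}
    n_sites = 0
    for t in tables:
        fam_species = set(t.species)
        for site in t.sites:
            n_sites += 1
            pres = site.species
            subset_counts[pres] = subset_counts.get(pres, 0) + 1
            for sp in pres:
                n_introns[sp] += 1
                if len(pres) == 1:
                    n_unique[sp] += 1
            for a in pres:
                for b in fam_species:
                    if b == a:
                        continue
                    shared_den[(a, b)] += 1
                    if b in pres:
                        shared_num[(a, b)] += 1
    unique_ratio = {
        sp: (100.0 * n_unique[sp] / n_introns[sp]) if n_introns[sp] else 0.0
        for sp in universe
    }
    mat = pd.DataFrame(index=universe, columns=universe, dtype=float)
    for a in universe:
        for b in universe:
            if a == b:
                mat.loc[a, b] = 100.0 if n_introns[a] else 0.0
            else:
                den = shared_den[(a, b)]
                mat.loc[a, b] = 100.0 * shared_num[(a, b)] / den if den else float("nan")
    return SharingReport(
        species=universe,
        n_introns=n_introns,
        unique_ratio=unique_ratio,
        pairwise=mat,
        subset_counts=subset_counts,
        n_sites=n_sites,
    )


def site_table_to_tsv(tables: list[IntronSiteTable]) -> pd.DataFrame:
    """Long-form site table: family, column, phase, one presence flag per species."""
    universe = sorted({sp for t in tables for sp in t.species})
    rows = []
    for t in tables:
        for site in t.sites:
            row = {"family_id": t.family_id, "column": site.column, "phase": site.phase}
            for sp in universe:
                if sp not in t.species:
                    row[sp] = "."          # uninformative for this family
                else:
                    row[sp] = int(sp in site.presence)
            rows.append(row)
    return pd.DataFrame(rows)
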