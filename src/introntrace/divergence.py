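"""Orthologous-intron divergence from a multi-species consensus.

Each orthologous intron set (one sequence per species) is aligned with
the DNA progressive aligner; a plurality consensus is drawn per column;
percent change of each species' row from the consensus is the fraction of
considered columns at which the row differs (base-vs-gap counts as a
difference; gap-gap columns are dropped from numerator and denominator).
Conservation is 100 − percent change.

Concatenated per-species values are computed two ways, because aligning
"concatenated sequences" can mean either concatenating the per-intron
alignments or aligning the concatenated raw sequences: both modes are
reported and neither is privileged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .alignment import AlignParams, progressive_align

DNA_PARAMS = AlignParams(gap_open=10.0, gap_extend=0.5, match=2.0, mismatch=-1.0, kmer=4)

# tie order: gap < A < C < G < T, the LAST (largest) of a tied set wins,
# so a base always beats a gap on ties
_TIE_ORDER = {"-": 0, "A": 1, "C": 2, "G": 3, "T": 4}


@dataclass
class IntronAlignmentSet:
    """One orthologous intron, aligned across species."""

    intron_key: str
    rows: dict[str, str]

    def validate(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.intron_key}: ragged alignment")
        if len(self.rows) < 2:
            raise ValueError(f"{self.intron_key}: need >=2 rows")


def align_intron_set(
    seqs: dict[str, str],
    intron_key: str = "",
    params: AlignParams | None = None,
) -> IntronAlignmentSet:
    """Align one orthologous intron set (DNA scoring; deterministic)."""
    if len(seqs) < 2:
        raise ValueError(f"{intron_key}: need >=2 sequences")
    for sp, s in seqs.items():
        if not s:
            raise ValueError(f"{intron_key}/{sp}: empty sequence")
    rows = progressive_align(seqs, kind="dna", params=params or DNA_PARAMS)
    aln = IntronAlignmentSet(intron_key, rows)
    aln.validate()
    return aln


def consensus_sequence(aln: IntronAlignmentSet) -> str:
    """Per-column plurality symbol over {A,C,G,T,-}; ties resolved to the
    largest symbol in the fixed order gap < A < C < G < T."""
    aln.validate()
    rows = list(aln.rows.values())
    L = len(rows[0])
    out = []
    for j in range(L):
        counts: dict[str, int] = {}
        for r in rows:
            c = r[j].upper()
            if c == "N":
                continue  # ambiguous bases carry no consensus weight
            counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("-")
            continue
        best = max(counts.values())
        winner = max(
            (sym for sym, n in counts.items() if n == best),
            key=lambda s: _TIE_ORDER.get(s, 0),
        )
        out.append(winner)
    return "".join(out)


def percent_change(row: str, consensus: str) -> float:
    """Percent of considered columns where ``row`` differs from the
    consensus.  Gap-gap columns are excluded entirely; base-vs-gap in
    either direction is a difference.  Raises if no column is considered.
    """
    if len(row) != len(consensus):
        raise ValueError("row/consensus length mismatch")
    diff = total = 0
    for r, c in zip(row.upper(), consensus.upper()):
        if r == "-" and c == "-":
            continue
        total += 1
        if r != c:
            diff += 1
    if total == 0:
        raise ValueError("percent_change undefined: no considered columns")
    return 100.0 * diff / total


@dataclass
class ConsensusReport:
    """Per-intron and per-species divergence from consensus."""

    per_intron: pd.DataFrame        # rows: intron_key; columns: species; percent change
    species_mean: dict[str, float]  # average over introns
    concat_aligned: dict[str, float]   # concatenate per-intron alignments
    concat_raw: dict[str, float] | None  # align concatenated raw sequences
    skipped: list[str] = field(default_factory=list)

    def conservation(self, mode: str = "concat_aligned") -> dict[str, float]:
        vals = getattr(self, mode)
        return {sp: 100.0 - v for sp, v in vals.items()}


def concatenated_report(
    intron_seqs: dict[str, dict[str, str]],
    params: AlignParams | None = None,
    compute_concat_raw: bool = True,
) -> ConsensusReport:
    """Full divergence analysis over many orthologous introns.

    ``intron_seqs`` maps intron key -> (species -> raw sequence).  Introns
    missing a species present elsewhere are excluded from concatenation
    (with a note in ``skipped``) but still reported per-intron.
    Concatenation follows lexicographic intron-key order.
    """
    if not intron_seqs:
        raise ValueError("no introns")
    keys = sorted(intron_seqs)
    species_all = sorted({sp for d in intron_seqs.values() for sp in d})
    per_intron_rows = {}
    aligned_blocks: dict[str, list[str]] = {sp: [] for sp in species_all}
    skipped = []
    for key in keys:
        seqs = intron_seqs[key]
        aln = align_intron_set(seqs, intron_key=key, params=params)
        cons = consensus_sequence(aln)
        per_intron_rows[key] = {
            sp: percent_change(row, cons) for sp, row in aln.rows.items()
        }
        if set(seqs) == set(species_all):
            for sp in species_all:
                aligned_blocks[sp].append(aln.rows[sp])
        else:
            missing = sorted(set(species_all) - set(seqs))
            skipped.append(f"{key}: missing {','.join(missing)}; excluded from concatenation")
    per_intron = pd.DataFrame.from_dict(per_intron_rows, orient="index")
    per_intron = per_intron.reindex(index=keys, columns=species_all)
    species_mean = {sp: float(per_intron[sp].mean()) for sp in species_all}

    concat_aligned: dict[str, float] = {}
    if all(aligned_blocks[sp] for sp in species_all):
        cat = IntronAlignmentSet(
            "CONCAT", {sp: "".join(aligned_blocks[sp]) for sp in species_all}
        )
        cons = consensus_sequence(cat)
        concat_aligned = {sp: percent_change(row, cons) for sp, row in cat.rows.items()}

    concat_raw = None
    if compute_concat_raw:
        raw = {
            sp: "".join(
                intron_seqs[k][sp]
                for k in keys
                if set(intron_seqs[k]) == set(species_all)
            )
            for sp in species_all
        }
        if all(raw.values()):
            aln = align_intron_set(raw, intron_key="CONCAT_RAW", params=params)
            cons = consensus_sequence(aln)
            concat_raw = {sp: percent_change(row, cons) for sp, row in aln.rows.items()}

    return ConsensusReport(
        per_intron=per_intron,
        species_mean=species_mean,
        concat_aligned=concat_aligned,
        concat_raw=concat_raw,
        skipped=skipped,
    )


# --- Text S1-style reader -------------------------------------------------

_KEY_RE = re.compile(r"^(\d+)([A-Za-z]+\d+[A-Za-z]*)$")


@dataclass
class IntronSeqRecord:
    species: str
    intron_key: str       # e.g. "4L28" = 4th intron of RPL28
    sequence: str
    ordinal: int | None = None
    gene: str | None = None


def parse_intron_fasta(
    text: str,
    species_tokens: tuple[str, ...] = ("SD", "SF", "SP", "AQ"),
) -> list[IntronSeqRecord]:
    """Tolerant FASTA-like reader for per-species intron collections.

    Headers are whitespace/underscore-separated tokens; the species is the
    first token matching ``species_tokens`` (case-insensitive) and the
    intron key is the first remaining token.  Keys of the form
    ``<ordinal><gene>`` (e.g. ``4L28``, fourth intron of RPL28) are
    decomposed; unrecognized keys pass through verbatim.  Sequence lines
    are concatenated with whitespace stripped; U is read as T.
    """
    records: list[IntronSeqRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        tokens = [t for t in re.split(r"[\s_|,;]+", header) if t]
        species = ""
        rest = []
        upper_tokens = {t.upper() for t in species_tokens}
        for t in tokens:
            if not species and t.upper() in upper_tokens:
                species = t.upper()
            else:
                rest.append(t)
        key = rest[0] if rest else header.strip()
        m = _KEY_RE.match(key)
        records.append(
            IntronSeqRecord(
                species=species or (tokens[0] if tokens else ""),
                intron_key=key,
                sequence=seq,
                ordinal=int(m.group(1)) if m else None,
                gene=m.group(2) if m else None,
            )
        )

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            chunks = []
        elif header is not None:
            chunks.append(re.sub(r"[^A-Za-z]", "", line))
    flush()
    return [r for r in records if r.sequence]


def group_by_intron(records: list[IntronSeqRecord]) -> dict[str, dict[str, str]]:
    """Group parsed records into intron key -> species -> sequence."""
    out: dict[str, dict[str, str]] = {}
    for r in records:
        out.setdefault(r.intron_key, {})[r.species] = r.sequence
    return out
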