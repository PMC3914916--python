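"""Amplicon processing and MOTU clustering for *nifH* clone libraries.

Implements the sequence stage of the dead-wood diazotroph pipeline:

* degenerate (IUPAC) PolF/PolR primer trimming,
* greedy 97 %-identity clustering into molecular OTUs (MOTUs),
* three-frame translation with stop-codon screening and frame selection
  against a reference NifH profile,
* per-column majority consensus proteins with a check for the two
  Fe4S4-coordinating cysteines,
* rank-abundance and tree-species exclusivity summaries.

Identity follows the CD-HIT convention: matches in the optimal global
alignment divided by the length of the shorter sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = [
    "AmpliconRecord",
    "PrimerPair",
    "TrimResult",
    "Motu",
    "ProteinConsensus",
    "DEFAULT_PRIMERS",
    "NIFH_REFERENCE_PROFILE",
    "CONSERVED_CYSTEINE_POSITIONS",
    "trim_primers",
    "pairwise_identity",
    "cluster_greedy",
    "select_reading_frame",
    "consensus_protein",
    "motu_summaries",
]

# IUPAC nucleotide ambiguity codes -> the set of bases each matches.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# Synthetic NifH-like reference profile (106 residues), NOT a database
# sequence: a constructed stand-in for the PolF-PolR protein window used to
# pick reading frames and to anchor the conserved-cysteine coordinates.  The
# two Fe4S4 cluster cysteines sit at alignment positions 54 and 93 (1-based).
NIFH_REFERENCE_PROFILE = (
    "MRLFAMIRDAKDGAKHQSDFTTHDDFKILVQQQLERSYSTRLERAISGAGAAR"
    "CKEPTIFLVKSKRAHEKLKEEKKAKDPKSALLVGDALLNCANPLAIINLEPYT"
)

#: 1-based positions of the iron-sulfur coordinating cysteines in the
#: reference alignment coordinates.
CONSERVED_CYSTEINE_POSITIONS: tuple[int, int] = (54, 93)


@dataclass
class AmpliconRecord:
    """One amplicon nucleotide sequence with its provenance metadata."""

    id: str
    sequence: str
    log_id: str
    species: str | None = None
    truth_motu: str | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """Degenerate forward/reverse amplification primers (IUPAC strings)."""

    forward: str = "TGCGAYCCSAARGCBGACTC"
    reverse: str = "ATSGCCATCATYTCRCCGGA"

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{name} primer is empty")
            bad = set(seq) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC codes: {sorted(bad)}")


DEFAULT_PRIMERS = PrimerPair()


def iupac_regex(primer: str) -> re.Pattern[str]:
    """Compile a primer into a regex with each ambiguity code expanded."""
    return re.compile("".join(f"[{IUPAC_CODES[c]}]" for c in primer))


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes."""
    return str(Seq(seq).reverse_complement())


def _mismatches(window: str, primer: str) -> int:
    return sum(base not in IUPAC_CODES[code] for base, code in zip(window, primer))


@dataclass
class TrimResult:
    """Outcome of primer trimming: the (possibly) trimmed record plus flags."""

    record: AmpliconRecord
    trimmed: bool
    reason: str | None = None


def trim_primers(
    record: AmpliconRecord,
    primers: PrimerPair = DEFAULT_PRIMERS,
    max_mismatches: int = 0,
) -> TrimResult:
    """Strip the forward primer at 5' and the reverse primer site at 3'.

    The 3' end of the read carries the reverse complement of the reverse
    primer.  Both sites must match over their full length with at most
    ``max_mismatches`` mismatches (IUPAC-aware); otherwise the record is
    returned unchanged and flagged.
    """
    seq = record.sequence
    if not seq:
        raise ValueError("empty sequence")
    nf, nr = len(primers.forward), len(primers.reverse)
    if len(seq) < nf + nr:
        return TrimResult(record, False, "shorter than combined primers")
    fwd_ok = _mismatches(seq[:nf], primers.forward) <= max_mismatches
    rev_site = reverse_complement(primers.reverse)
    rev_ok = _mismatches(seq[-nr:], rev_site) <= max_mismatches
    if not (fwd_ok and rev_ok):
        missing = [n for n, ok in (("forward", fwd_ok), ("reverse", rev_ok)) if not ok]
        return TrimResult(record, False, f"unmatched {'+'.join(missing)} primer site")
    trimmed = AmpliconRecord(
        id=record.id,
        sequence=seq[nf : len(seq) - nr],
        log_id=record.log_id,
        species=record.species,
        truth_motu=record.truth_motu,
    )
    return TrimResult(trimmed, True)


# Aligner maximizing the number of matched bases in a global alignment
# (match 1, mismatch/gap 0), i.e. the longest common subsequence.
_NT_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=0,
    extend_gap_score=0,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity with the shorter sequence as denominator."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    matches = _NT_ALIGNER.score(a, b)
    return matches / min(len(a), len(b))


@dataclass
class Motu:
    """A molecular OTU: member reads clustered at the identity threshold."""

    id: str
    representative: AmpliconRecord
    members: list[AmpliconRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def singleton(self) -> bool:
        return self.size == 1

    def abundance_by_log(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.members:
            counts[rec.log_id] = counts.get(rec.log_id, 0) + 1
        return counts

    def counts_by_species(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.members:
            if rec.species is not None:
                counts[rec.species] = counts.get(rec.species, 0) + 1
        return counts


def cluster_greedy(
    records: list[AmpliconRecord],
    threshold: float = 0.97,
    id_prefix: str = "MOTU",
) -> list[Motu]:
    """Greedy incremental clustering at the given identity threshold.

    Records are processed longest-first (ties keep input order).  Each record
    joins the first existing cluster whose representative it matches at
    ``threshold`` identity or better, else founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: -len(r.sequence))
    motus: list[Motu] = []
    for rec in ordered:
        for motu in motus:
            if pairwise_identity(rec.sequence, motu.representative.sequence) >= threshold:
                motu.members.append(rec)
                break
        else:
            motus.append(
                Motu(id=f"{id_prefix}{len(motus) + 1}", representative=rec, members=[rec])
            )
    return motus


def translate_frame(sequence: str, frame: int) -> str:
    """Translate one forward-strand frame, truncating to whole codons."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    sub = sequence[frame:]
    sub = sub[: 3 * (len(sub) // 3)]
    return str(Seq(sub).translate())


def _has_internal_stop(protein: str) -> bool:
    # A stop in the terminal codon is tolerated; anything earlier is not.
    return "*" in protein[:-1]


_AA_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=0,
    extend_gap_score=0,
)


def select_reading_frame(
    sequence: str,
    reference: str = NIFH_REFERENCE_PROFILE,
) -> int | None:
    """Pick the forward reading frame without a premature stop codon.

    Among stop-free frames the translation most similar to ``reference``
    (global-alignment matched residues) wins; ties go to the lowest frame
    index.  Returns ``None`` when every frame has an internal stop.
    """
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    best_frame: int | None = None
    best_score = -1.0
    for frame in (0, 1, 2):
        protein = translate_frame(sequence, frame)
        if not protein or _has_internal_stop(protein):
            continue
        score = _AA_ALIGNER.score(protein.rstrip("*"), reference)
        if score > best_score:
            best_frame, best_score = frame, score
    return best_frame


@dataclass
class ProteinConsensus:
    """Majority-rule consensus protein of a MOTU in its selected frame."""

    motu_id: str
    frame: int
    sequence: str
    conserved_cysteines: bool


def consensus_protein(
    motu: Motu,
    frame: int,
    cysteine_positions: tuple[int, int] = CONSERVED_CYSTEINE_POSITIONS,
) -> ProteinConsensus:
    """Per-column majority consensus of all member translations.

    Members must translate to equal-length proteins (the substitution-only
    model guarantees this; indels are unsupported).  Column ties are broken
    in favour of the cluster representative's residue.  The conserved-
    cysteine flag is true iff both configured (1-based) positions hold 'C'.
    """
    proteins = [translate_frame(rec.sequence, frame) for rec in motu.members]
    lengths = {len(p) for p in proteins}
    if len(lengths) != 1:
        raise ValueError(
            f"MOTU {motu.id}: member translations have unequal lengths {sorted(lengths)}; "
            "indels are not supported"
        )
    rep_protein = translate_frame(motu.representative.sequence, frame)
    if motu.singleton:
        consensus = proteins[0]
    else:
        cols = []
        for i, rep_res in enumerate(rep_protein):
            counts: dict[str, int] = {}
            for p in proteins:
                counts[p[i]] = counts.get(p[i], 0) + 1
            top = max(counts.values())
            winners = {res for res, c in counts.items() if c == top}
            cols.append(rep_res if rep_res in winners else sorted(winners)[0])
        consensus = "".join(cols)
    if _has_internal_stop(consensus):
        raise ValueError(f"MOTU {motu.id}: consensus contains an internal stop codon")
    flag = all(
        pos <= len(consensus) and consensus[pos - 1] == "C" for pos in cysteine_positions
    )
    return ProteinConsensus(motu.id, frame, consensus, flag)


def motu_summaries(motus: list[Motu]) -> dict:
    """Rank-abundance table, singleton fraction and species exclusivity.

    Returns a dict with keys ``rank_abundance`` (list of dicts sorted by
    size desc, ties by id), ``singleton_fraction`` and ``exclusivity``
    (counts of MOTUs found in only one tree species vs shared).
    """
    if not motus:
        raise ValueError("motu_summaries requires at least one MOTU")
    ranked = sorted(motus, key=lambda m: (-m.size, m.id))
    table = [
        {"rank": i + 1, "motu": m.id, "size": m.size, "singleton": m.singleton}
        for i, m in enumerate(ranked)
    ]
    n_singletons = sum(m.singleton for m in motus)
    species_seen = sorted({s for m in motus for s in m.counts_by_species()})
    exclusivity: dict[str, int] = {f"{s}_only": 0 for s in species_seen}
    exclusivity["shared"] = 0
    for m in motus:
        present = [s for s, c in m.counts_by_species().items() if c > 0]
        if len(present) == 1:
            exclusivity[f"{present[0]}_only"] += 1
        elif len(present) > 1:
            exclusivity["shared"] += 1
    return {
        "rank_abundance": table,
        "singleton_fraction": n_singletons / len(motus),
        "n_motus": len(motus),
        "n_singletons": n_singletons,
        "exclusivity": exclusivity,
    }
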