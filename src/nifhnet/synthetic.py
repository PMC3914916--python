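"""Synthetic study generator: dead-wood logs, occurrences and amplicons.

Emulates the field design the pipeline targets: 45 logs of two tree species
(*Fagus sylvatica*, *Picea abies*) under three forest-management types, a
sporocarp (fungal fruiting body) occurrence table, a nifH MOTU clone-count
table with 3-14 MOTUs per log, and a clone-library FASTA of ~360 bp nifH
amplicons.  Ground-truth fungus-MOTU associations of configurable sign and
strength can be planted and are reported in a truth record so downstream
null-model and network stages can be validated against a known answer.

Occurrence model
----------------
Cell probabilities follow a logit-additive (odds-multiplicative) model,
``logit p[log, taxon] = alpha_taxon + pref_taxon * species_effect * s_log
+ c_log``, where ``c_log`` is solved so expected per-log richness hits a
species-specific target.  With ``species_effect = 0`` the occurrence odds
factor into a row term times a column term, so conditioning on the margins
yields the uniform fixed-fixed distribution and the null-model stage is
exactly calibrated.  Planted pairs share marginal parameters and are coupled
through a mixture copula on a common uniform: strength 0 is independence,
strength 1 is comonotone (positive) or countermonotone (negative).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .motu import (
    DEFAULT_PRIMERS,
    IUPAC_CODES,
    NIFH_REFERENCE_PROFILE,
    AmpliconRecord,
    PrimerPair,
    reverse_complement,
)

__all__ = [
    "StudyDesign",
    "PlantedAssociation",
    "generate_logs",
    "generate_occurrences",
    "generate_amplicons",
]

SPECIES_LABELS = ("Fagus", "Picea")
MANAGEMENT_LABELS = ("age-class", "selection", "unmanaged")

# Remaining-mass bands (percent) per decay stratum, most to least intact.
_MASS_BANDS = ((75.0, 95.0), (55.0, 75.0), (35.0, 55.0), (15.0, 35.0))


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: how many logs, which species and managements."""

    n_logs: int = 45
    species_labels: tuple[str, ...] = SPECIES_LABELS
    management_labels: tuple[str, ...] = MANAGEMENT_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_logs < 4:
            raise ValueError(f"n_logs must be >= 4, got {self.n_logs}")
        if not self.species_labels or not self.management_labels:
            raise ValueError("species and management label sets must be non-empty")


@dataclass(frozen=True)
class PlantedAssociation:
    """Ground-truth pairwise association planted into the occurrence tables.

    At least one member must be a nifH MOTU.  ``strength`` interpolates from
    independence (0) to a deterministic coupling (1): positive couplings
    raise the joint occurrence probability, negative ones lower it.
    """

    taxon_a: str
    taxon_b: str
    sign: str = "positive"
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise ValueError(f"sign must be 'positive' or 'negative', got {self.sign!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"strength must lie in [0, 1], got {self.strength}")
        if self.taxon_a == self.taxon_b:
            raise ValueError("planted pair must involve two distinct taxa")


def generate_logs(
    design: StudyDesign,
    water_peak_mass: float = 55.0,
    water_peak: float = 54.9,
    covariate_coupling: float = 1.0,
) -> pd.DataFrame:
    """Generate the per-log covariate table.

    Remaining mass is drawn uniformly within one of four decay strata
    (cycled over logs); nitrogen per density unit increases in expectation
    as remaining mass falls, scaled by ``covariate_coupling`` (0 decouples
    them); water content is a unimodal function of remaining mass peaking
    at ``water_peak`` percent near ``water_peak_mass`` percent remaining
    mass.  Deterministic for a given design seed.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_logs
    species = [design.species_labels[i % len(design.species_labels)] for i in range(n)]
    management = [
        design.management_labels[(i // len(design.species_labels)) % len(design.management_labels)]
        for i in range(n)
    ]
    strata = [i % len(_MASS_BANDS) for i in range(n)]
    lo = np.array([_MASS_BANDS[s][0] for s in strata])
    hi = np.array([_MASS_BANDS[s][1] for s in strata])
    mass = rng.uniform(lo, hi)

    decay_progress = (100.0 - mass) / 100.0
    n_dens = 8e-4 * (1.0 + 2.5 * covariate_coupling * decay_progress)
    n_dens = n_dens * rng.lognormal(mean=0.0, sigma=0.15, size=n)
    c_dens = 0.25 * (1.0 - 0.10 * covariate_coupling * decay_progress)
    c_dens = c_dens * rng.lognormal(mean=0.0, sigma=0.08, size=n)
    water = water_peak * np.exp(-(((mass - water_peak_mass) / 30.0) ** 2))
    water = np.clip(water + rng.normal(0.0, 2.0, size=n), 1.0, None)

    return pd.DataFrame(
        {
            "log_id": [f"L{i + 1:02d}" for i in range(n)],
            "species": species,
            "management": management,
            "remaining_mass": mass,
            "water_content": water,
            "n_per_density": n_dens,
            "c_per_density": c_dens,
        }
    ).set_index("log_id")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _solve_offset(base_logit: np.ndarray, target: float) -> float:
    """Find c with sum(sigmoid(base_logit + c)) = target by bisection."""
    target = min(max(target, 1e-6), len(base_logit) - 1e-6)
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sigmoid(base_logit + mid).sum() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_occurrences(
    logs: pd.DataFrame,
    n_fungi: int = 30,
    n_motus: int = 40,
    planted: tuple[PlantedAssociation, ...] | list[PlantedAssociation] = (),
    seed: int | None = 0,
    species_effect: float = 1.0,
    nifh_richness_range: tuple[int, int] = (3, 14),
    fungal_richness_range: tuple[int, int] = (2, 20),
    nifh_target_richness: dict[str, float] | None = None,
    fungal_target_richness: dict[str, float] | None = None,
    abundance_mean: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (sporocarp table, nifH MOTU clone-count table, truth record).

    Rows are logs, columns taxa (fungi ``Fxxx`` are 0/1 presence, MOTUs
    ``Mxxx`` carry clone counts).  Per-log nifH richness is kept within
    ``nifh_richness_range`` (and fungal richness within its range) by a
    deterministic adjustment of the most/least probable non-planted taxa,
    which triggers only in the rare tails of the richness distribution.
    """
    if n_fungi <= 0 or n_motus <= 0:
        raise ValueError("taxon counts must be positive")
    rng = np.random.default_rng(seed)
    fungi = [f"F{i + 1:03d}" for i in range(n_fungi)]
    motus = [f"M{i + 1:03d}" for i in range(n_motus)]
    taxa = fungi + motus
    taxon_idx = {t: i for i, t in enumerate(taxa)}
    motu_set = set(motus)

    for pa in planted:
        for t in (pa.taxon_a, pa.taxon_b):
            if t not in taxon_idx:
                raise ValueError(f"planted association references unknown taxon {t!r}")
        if pa.taxon_a not in motu_set and pa.taxon_b not in motu_set:
            raise ValueError(
                f"planted pair ({pa.taxon_a}, {pa.taxon_b}) must involve at least one nifH MOTU"
            )
    planted_taxa = {t for pa in planted for t in (pa.taxon_a, pa.taxon_b)}

    alpha = rng.normal(0.0, 0.8, size=len(taxa))
    pref = rng.uniform(-1.0, 1.0, size=len(taxa))
    for pa in planted:  # shared marginals so strength-1 coupling is exact;
        # planted taxa get a floored baseline so the ground truth is prevalent
        # enough to pass downstream occupancy filters
        ia, ib = taxon_idx[pa.taxon_a], taxon_idx[pa.taxon_b]
        alpha[ia] = max(alpha[ia], 0.0)
        alpha[ib] = alpha[ia]
        pref[ib] = pref[ia]

    nifh_target_richness = nifh_target_richness or {"Fagus": 9.5, "Picea": 7.5}
    fungal_target_richness = fungal_target_richness or {"Fagus": 9.1, "Picea": 6.0}
    f_sl = slice(0, n_fungi)
    m_sl = slice(n_fungi, len(taxa))

    log_ids = list(logs.index)
    probs = np.empty((len(log_ids), len(taxa)))
    for li, log_id in enumerate(log_ids):
        sp = logs.loc[log_id, "species"]
        s = 1.0 if sp == "Fagus" else -1.0
        base = alpha + species_effect * pref * s
        for sl, targets in ((f_sl, fungal_target_richness), (m_sl, nifh_target_richness)):
            target = targets.get(sp, float(np.mean(list(targets.values()))))
            c = _solve_offset(base[sl], target)
            probs[li, sl] = _sigmoid(base[sl] + c)
    probs = np.clip(probs, 1e-9, 1 - 1e-9)

    u = rng.uniform(size=probs.shape)
    couple = {
        (taxon_idx[pa.taxon_a], taxon_idx[pa.taxon_b]): pa for pa in planted
    }
    for (ia, ib), pa in couple.items():
        coupled = rng.uniform(size=len(log_ids)) < pa.strength
        if pa.sign == "positive":
            u[coupled, ib] = u[coupled, ia]
        else:
            u[coupled, ib] = 1.0 - u[coupled, ia]
    present = (u < probs).astype(np.int8)

    # Enforce richness ranges without touching planted taxa.
    free = np.array([t not in planted_taxa for t in taxa])
    for sl, (lo, hi) in ((f_sl, fungal_richness_range), (m_sl, nifh_richness_range)):
        block_free = free[sl]
        for li in range(len(log_ids)):
            row = present[li, sl]
            rich = int(row.sum())
            p_row = probs[li, sl]
            if rich < lo:
                absent = np.flatnonzero((row == 0) & block_free)
                add = absent[np.argsort(-p_row[absent])][: lo - rich]
                row[add] = 1
            elif rich > hi:
                here = np.flatnonzero((row == 1) & block_free)
                drop = here[np.argsort(p_row[here])][: rich - hi]
                row[drop] = 0

    fungal_df = pd.DataFrame(present[:, f_sl], index=log_ids, columns=fungi)
    motu_presence = present[:, m_sl]
    counts = motu_presence * (1 + rng.poisson(abundance_mean, size=motu_presence.shape))
    motu_df = pd.DataFrame(counts, index=log_ids, columns=motus)

    truth = {
        "seed": seed,
        "planted": [
            {
                "taxon_a": pa.taxon_a,
                "taxon_b": pa.taxon_b,
                "sign": pa.sign,
                "strength": pa.strength,
            }
            for pa in planted
        ],
        "species_effect": species_effect,
        "n_fungi": n_fungi,
        "n_motus": n_motus,
    }
    return fungal_df, motu_df, truth


# --------------------------------------------------------------------------
# Amplicon generation

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()

_STOPS = set(standard_dna_table.stop_codons)
_AA_POOL = sorted(set(_CODONS_BY_AA) - {"C"})  # cysteines stay put
_CYS_KEEP = {53, 92}  # 0-based positions of the conserved cysteines

#: Length of the full amplicon (primer + insert + primer), bp.
AMPLICON_LENGTH = 360


def _random_primer_instance(primer: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))] for c in primer)


def _encode_protein(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein
    )


def _pick_alt_base(inner: list[str], pos: int, rng: np.random.Generator) -> str:
    """A substitute base at ``pos`` that does not create an in-frame stop."""
    codon_start = 3 * (pos // 3)
    current = inner[pos]
    alts = [b for b in "ACGT" if b != current]
    rng.shuffle(alts)
    for b in alts:
        codon = inner[codon_start:codon_start + 3]
        codon[pos - codon_start] = b
        if "".join(codon) not in _STOPS:
            return b
    raise AssertionError("unreachable: at most two of three substitutions form stops")


def generate_amplicons(
    motu_table: pd.DataFrame,
    divergence_within: float = 0.02,
    seed: int | None = 0,
    log_species: dict[str, str] | None = None,
    aa_divergence: float = 0.10,
    primers: PrimerPair = DEFAULT_PRIMERS,
) -> list[AmpliconRecord]:
    """Emit one read per clone in ``motu_table`` as ~360 bp nifH amplicons.

    Each MOTU gets a seed insert: the reference NifH window with a private
    set of amino-acid substitutions (``aa_divergence`` of positions, the two
    conserved cysteines excepted) reverse-translated with random synonymous
    codons.  Within-MOTU variation is confined to a MOTU-specific pool of
    polymorphic sites of size ``divergence_within * insert_length`` with one
    fixed alternative base each, so no read is further than
    ``divergence_within`` from the seed and no two reads of one MOTU differ
    by more than that fraction.  Substitutions never introduce an in-frame
    stop, keeping frame 0 open.  Reads are flanked by random IUPAC instances
    of the forward primer and the reverse complement of the reverse primer.
    """
    if divergence_within < 0:
        raise ValueError("divergence_within must be non-negative")
    if divergence_within >= 0.03:
        warnings.warn(
            f"within-MOTU divergence {divergence_within} is not below the 0.03 "
            "complement of the default 0.97 clustering threshold; MOTUs may merge or split",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    insert_len = AMPLICON_LENGTH - len(primers.forward) - len(primers.reverse)
    n_codons = insert_len // 3
    protein_window = NIFH_REFERENCE_PROFILE[:n_codons]

    motu_seeds: dict[str, list[str]] = {}
    motu_pools: dict[str, list[tuple[int, str]]] = {}
    pool_size = math.floor(divergence_within * insert_len)
    coding_len = 3 * n_codons
    for motu in motu_table.columns:
        protein = list(protein_window)
        mutable = [i for i in range(len(protein)) if i not in _CYS_KEEP]
        n_aa_mut = math.floor(aa_divergence * len(protein))
        for pos in rng.choice(mutable, size=n_aa_mut, replace=False):
            choices = [a for a in _AA_POOL if a != protein[pos]]
            protein[pos] = choices[rng.integers(len(choices))]
        inner = list(_encode_protein("".join(protein), rng))
        inner += [("ACGT")[rng.integers(4)] for _ in range(insert_len - coding_len)]
        # polymorphic sites avoid the conserved cysteine codons
        poolable = np.array(
            [p for p in range(coding_len) if p // 3 not in _CYS_KEEP]
        )
        pool_pos = rng.choice(poolable, size=pool_size, replace=False) if pool_size else []
        pool = [(int(p), _pick_alt_base(inner, int(p), rng)) for p in pool_pos]
        motu_seeds[motu] = inner
        motu_pools[motu] = pool

    records: list[AmpliconRecord] = []
    for log_id in motu_table.index:
        species = (log_species or {}).get(log_id)
        for motu in motu_table.columns:
            count = int(motu_table.loc[log_id, motu])
            for j in range(count):
                inner = list(motu_seeds[motu])
                pool = motu_pools[motu]
                if pool:
                    n_mut = int(rng.integers(0, len(pool) + 1))
                    for k in rng.choice(len(pool), size=n_mut, replace=False):
                        pos, alt = pool[int(k)]
                        inner[pos] = alt
                seq = (
                    _random_primer_instance(primers.forward, rng)
                    + "".join(inner)
                    + reverse_complement(_random_primer_instance(primers.reverse, rng))
                )
                records.append(
                    AmpliconRecord(
                        id=f"{log_id}_{motu}_{j + 1}",
                        sequence=seq,
                        log_id=log_id,
                        species=species,
                        truth_motu=motu,
                    )
                )
    return records
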