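"""Functional distances for missense substitutions from profile-HMM emissions.

The deleteriousness of an amino-acid substitution is quantified as the
magnitude of the log-odds between the match-state emission probabilities of
the reference and alternate residues in a protein-domain profile HMM: a
substitution between two residues that the domain family tolerates equally
scores zero, while replacing a strongly conserved residue with one rarely
observed at that position scores highly.  Per-site distances between two
genomes are then scaled by zygosity: genotypes that agree contribute
nothing, a single-allele difference contributes the site distance once, and
opposite homozygotes contribute four times the site distance.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: The 20 standard amino acids in fixed alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Emission probabilities are floored at this value and renormalised on
#: ingest so every log-odds is finite (pseudocount convention).
EMISSION_FLOOR: float = 1e-6


class InputError(ValueError):
    """Raised when an input violates a documented precondition."""


class Zygosity(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def code(self) -> int:
        """Integer dosage code: 0, 1, 2; missing maps to -1."""
        return _ZYG_CODE[self]


_ZYG_CODE = {
    Zygosity.HOM_REF: 0,
    Zygosity.HET: 1,
    Zygosity.HOM_ALT: 2,
    Zygosity.MISSING: -1,
}

#: Multiplier applied to a site's functional distance for each ordered pair
#: of dosage codes (0=hom_ref, 1=het, 2=hom_alt).  Equal genotypes
#: contribute nothing; opposite homozygotes are scaled fourfold; every other
#: differing pair carries the baseline factor 1.
ZYGOSITY_FACTOR: np.ndarray = np.array(
    [[0.0, 1.0, 4.0],
     [1.0, 0.0, 1.0],
     [4.0, 1.0, 0.0]]
)


@dataclass(frozen=True)
class ProfileHMM:
    """Match-state emission table of one profile HMM.

    Parameters
    ----------
    id
        Model identifier (e.g. a SUPERFAMILY or Pfam accession).
    emissions
        Array of shape ``(n_match_states, 20)``; row ``s-1`` holds the
        emission probability vector of 1-based match state ``s`` over
        :data:`AMINO_ACIDS`.  Rows must be strictly positive and sum to 1.
    """

    id: str
    emissions: np.ndarray

    def __post_init__(self) -> None:
        emis = np.asarray(self.emissions, dtype=float)
        if emis.ndim != 2 or emis.shape[1] != len(AMINO_ACIDS):
            raise InputError(
                f"emissions must be (n_states, 20), got {emis.shape}"
            )
        if not np.all(emis > 0):
            raise InputError(f"HMM {self.id}: emissions must be strictly positive")
        if not np.allclose(emis.sum(axis=1), 1.0, atol=1e-9):
            raise InputError(f"HMM {self.id}: emission rows must sum to 1")
        object.__setattr__(self, "emissions", emis)

    @property
    def n_match_states(self) -> int:
        return self.emissions.shape[0]

    @classmethod
    def from_raw(cls, id: str, emissions: np.ndarray) -> "ProfileHMM":
        """Build from a possibly unnormalised/zero-containing table.

        Values are floored at :data:`EMISSION_FLOOR` and each row is
        renormalised, so downstream log-odds are always finite.
        """
        emis = np.asarray(emissions, dtype=float)
        emis = np.maximum(emis, EMISSION_FLOOR)
        emis = emis / emis.sum(axis=1, keepdims=True)
        return cls(id=id, emissions=emis)


@dataclass(frozen=True)
class DomainHit:
    """One HMM hit on a protein, with the residue-to-match-state alignment.

    ``residue_to_state`` maps 1-based protein residue indices to 1-based HMM
    match states; residues aligned to insertion columns are simply absent
    from the mapping.  ``score`` is the hit score used to resolve overlaps.
    """

    protein_id: str
    hmm_id: str
    protein_start: int
    protein_end: int
    residue_to_state: Mapping[int, int]
    score: float = 0.0

    def __post_init__(self) -> None:
        for res, state in self.residue_to_state.items():
            if not (self.protein_start <= res <= self.protein_end):
                raise InputError(
                    f"hit {self.protein_id}/{self.hmm_id}: residue {res} outside "
                    f"[{self.protein_start}, {self.protein_end}]"
                )
            if state < 1:
                raise InputError(f"match state must be >= 1, got {state}")


@dataclass(frozen=True)
class MissenseVariant:
    """A missense variant pre-mapped to a protein residue.

    Genomic coordinates are bookkeeping only (1-based); the functional model
    works entirely on ``(protein_id, residue_index, ref_aa, alt_aa)``.
    ``maf`` is the minor allele frequency in ``[0, 0.5]``.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    protein_id: str
    residue_index: int
    ref_aa: str
    alt_aa: str
    maf: float

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise InputError(f"{self.variant_id}: ref_aa == alt_aa")
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AA_INDEX:
                raise InputError(f"{self.variant_id}: unknown amino acid {aa!r}")
        if not (0.0 <= self.maf <= 0.5):
            raise InputError(f"{self.variant_id}: maf {self.maf} outside [0, 0.5]")


def score_substitution(
    hmm: ProfileHMM, state: int, ref_aa: str, alt_aa: str
) -> float:
    """Functional distance |ln P(ref)/P(alt)| at a 1-based match state.

    Symmetric in the two amino acids; zero iff the state emits both with
    equal probability.
    """
    if ref_aa not in AA_INDEX or alt_aa not in AA_INDEX:
        raise InputError(f"unknown amino-acid code: {ref_aa!r} or {alt_aa!r}")
    if not (1 <= state <= hmm.n_match_states):
        raise InputError(
            f"state {state} out of range [1, {hmm.n_match_states}] for HMM {hmm.id}"
        )
    p_ref = hmm.emissions[state - 1, AA_INDEX[ref_aa]]
    p_alt = hmm.emissions[state - 1, AA_INDEX[alt_aa]]
    return abs(math.log(p_ref / p_alt))


def map_variant_to_state(
    variant: MissenseVariant, hits: Iterable[DomainHit]
) -> Optional[tuple[str, int]]:
    """Locate the HMM match state covering a variant's protein residue.

    Returns ``(hmm_id, state)`` or ``None`` when the residue falls outside
    every hit or aligns to an insertion column.  When several hits cover the
    residue the highest-scoring hit wins, ties broken by lexicographic
    ``hmm_id`` for determinism.
    """
    covering: list[DomainHit] = []
    for hit in hits:
        if hit.protein_id != variant.protein_id:
            continue
        if variant.residue_index in hit.residue_to_state:
            covering.append(hit)
    if not covering:
        return None
    best = min(covering, key=lambda h: (-h.score, h.hmm_id))
    return best.hmm_id, best.residue_to_state[variant.residue_index]


def site_distance(a: Zygosity, b: Zygosity, d: float) -> float:
    """Per-site genetic distance between two genotypes.

    Zero when the genotypes agree; ``4*d`` for opposite homozygotes; ``d``
    for every other differing pair.  A missing genotype is treated as
    homozygous reference (conservative: missingness never inflates
    distance).
    """
    if d < 0:
        raise InputError(f"functional distance must be >= 0, got {d}")
    ca = max(a.code, 0)  # missing -> hom_ref
    cb = max(b.code, 0)
    return float(ZYGOSITY_FACTOR[ca, cb] * d)


# ---------------------------------------------------------------------------
# External formats
# ---------------------------------------------------------------------------

def read_emissions_tsv(path: str | Path) -> dict[str, ProfileHMM]:
    """Read HMM match-emission tables from TSV.

    Columns: ``hmm_id``, ``state_index`` (1-based), then 20 probability
    columns in fixed alphabetical amino-acid order.  States of one model may
    appear in any order but must form a contiguous 1..n block.  Emissions
    are pseudocounted on ingest.
    """
    rows: dict[str, dict[int, np.ndarray]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 + len(AMINO_ACIDS):
                raise InputError(f"{path}:{line_no}: expected 22 columns, got {len(parts)}")
            hmm_id, state = parts[0], int(parts[1])
            rows.setdefault(hmm_id, {})[state] = np.array(parts[2:], dtype=float)
    hmms: dict[str, ProfileHMM] = {}
    for hmm_id, states in rows.items():
        n = max(states)
        if sorted(states) != list(range(1, n + 1)):
            raise InputError(f"HMM {hmm_id}: states are not contiguous 1..{n}")
        table = np.vstack([states[s] for s in range(1, n + 1)])
        hmms[hmm_id] = ProfileHMM.from_raw(hmm_id, table)
    return hmms


def write_emissions_tsv(hmms: Mapping[str, ProfileHMM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#hmm_id\tstate\t" + "\t".join(AMINO_ACIDS) + "\n")
        for hmm_id in sorted(hmms):
            for s, row in enumerate(hmms[hmm_id].emissions, 1):
                probs = "\t".join(f"{p:.10g}" for p in row)
                fh.write(f"{hmm_id}\t{s}\t{probs}\n")


def read_hmmer3(path: str | Path) -> dict[str, ProfileHMM]:
    """Convert HMMER3 ``.hmm`` text models to emission tables.

    Only the match-emission lines are used; HMMER stores them as negative
    natural-log probabilities, so ``p = exp(-x)`` (``'*'`` means p = 0,
    pseudocounted on ingest).  The HMMER alphabet header is honoured and
    columns are reordered to :data:`AMINO_ACIDS` if needed.
    """
    hmms: dict[str, ProfileHMM] = {}
    name: Optional[str] = None
    alphabet: list[str] = []
    states: list[np.ndarray] = []
    in_model = False
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "NAME":
                name = tok[1]
            elif tok[0] == "HMM" and len(tok) == 21:
                alphabet = tok[1:]
                in_model = True
                states = []
            elif tok[0] == "//":
                if name is None or not states:
                    raise InputError(f"{path}: malformed HMMER3 record")
                order = [alphabet.index(aa) for aa in AMINO_ACIDS]
                table = np.vstack(states)[:, order]
                hmms[name] = ProfileHMM.from_raw(name, table)
                name, in_model, states = None, False, []
            elif in_model and re.fullmatch(r"\d+", tok[0]):
                vals = [0.0 if v == "*" else math.exp(-float(v)) for v in tok[1:21]]
                states.append(np.array(vals))
    return hmms


def _expand_columns(start: int, columns: str) -> dict[int, int]:
    """Expand a CIGAR-like column string into a residue->state mapping.

    ``M`` columns consume one protein residue and one match state, ``I``
    (insertion relative to the model) consume a residue only, ``D``
    (deletion) consume a match state only.
    """
    mapping: dict[int, int] = {}
    res, state = start, 1
    for count, op in re.findall(r"(\d+)([MID])", columns):
        n = int(count)
        if op == "M":
            for _ in range(n):
                mapping[res] = state
                res += 1
                state += 1
        elif op == "I":
            res += n
        else:
            state += n
    return mapping


def read_domain_hits_tsv(path: str | Path) -> list[DomainHit]:
    """Read domain hits from TSV.

    Columns: ``protein_id``, ``hmm_id``, ``protein_start``, ``protein_end``
    (1-based inclusive), a CIGAR-like column string (e.g. ``10M2I5M``), and
    an optional hit score.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (5, 6):
                raise InputError(f"{path}:{line_no}: expected 5-6 columns")
            protein_id, hmm_id = parts[0], parts[1]
            start, end = int(parts[2]), int(parts[3])
            mapping = _expand_columns(start, parts[4])
            score = float(parts[5]) if len(parts) == 6 else 0.0
            hits.append(
                DomainHit(protein_id, hmm_id, start, end, mapping, score)
            )
    return hits


def write_domain_hits_tsv(hits: Sequence[DomainHit], path: str | Path) -> None:
    """Write hits back to the TSV dialect of :func:`read_domain_hits_tsv`.

    The column string is reconstructed from the residue->state mapping.
    """
    with open(path, "w") as fh:
        fh.write("#protein_id\thmm_id\tstart\tend\tcolumns\tscore\n")
        for h in hits:
            ops: list[str] = []
            state = 1
            res = h.protein_start
            while res <= h.protein_end:
                if res in h.residue_to_state:
                    target = h.residue_to_state[res]
                    if target > state:  # deletion columns before this match
                        ops.append(f"{target - state}D")
                        state = target
                    n = 0
                    while (
                        res in h.residue_to_state
                        and h.residue_to_state[res] == state
                    ):
                        n += 1
                        res += 1
                        state += 1
                    ops.append(f"{n}M")
                else:
                    n = 0
                    while res <= h.protein_end and res not in h.residue_to_state:
                        n += 1
                        res += 1
                    ops.append(f"{n}I")
            fh.write(
                f"{h.protein_id}\t{h.hmm_id}\t{h.protein_start}\t{h.protein_end}"
                f"\t{''.join(ops)}\t{h.score:g}\n"
            )
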