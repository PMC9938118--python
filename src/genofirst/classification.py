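"""Genetic explanation of above-threshold outlier calls.

Every call is dissected by ablation: the individual's genotype at a chosen
subset of profile sites is reset to homozygous reference and the whole
per-term pipeline re-run (the rest of the cohort is untouched, so the
background geometry is preserved).  A variant is *required* when ablating
it alone drops the transformed score below the call threshold, and merely
*contributing* when ablation strictly decreases the score without killing
the call.  The role pattern assigns one of four outlier types:

    1-a  a single required variant and nothing else contributing
    1-b  a single required variant plus contributing variant(s)
    2-a  no single (or several) required variants, but one variant's solo
         score drop dominates the sum of all the others'
    2-b  multiple variants jointly required, none dominant

Each variant also gets a frequency class from its minor allele frequency
and the carrier's zygosity: rare (MAF < 0.5% het, < 1% hom), low-frequency
(MAF < 1% het, < 5% hom), else common.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .functional_model import InputError, Zygosity
from .outlier_engine import OutlierScoreSet, ScoreParams, score_term
from .term_profiles import TermProfile

#: Ablation must lower the score by more than this to count as a decrease.
CONTRIBUTION_TOL = 1e-9


class Role(str, Enum):
    REQUIRED = "required"
    CONTRIBUTING = "contributing"
    NONE = "none"


class FrequencyClass(str, Enum):
    RARE = "rare"
    LOW_FREQUENCY = "low_frequency"
    COMMON = "common"


@dataclass(frozen=True)
class VariantRole:
    variant_id: str
    role: Role
    ablated_score: float
    drop: float


@dataclass(frozen=True)
class OutlierCall:
    """One above-threshold (individual, term) prediction, explained."""

    individual_id: str
    term_id: str
    transformed_score: float
    outlier_type: str  # 1-a | 1-b | 2-a | 2-b
    roles: tuple[VariantRole, ...]
    combinatorial_contribution: float
    frequency_classes: tuple[FrequencyClass, ...]


def frequency_class(maf: float, zygosity: Zygosity) -> FrequencyClass:
    """MAF class of a carried variant, conditioned on zygosity."""
    if not (0.0 <= maf <= 0.5):
        raise InputError(f"maf {maf} outside [0, 0.5]")
    het = zygosity == Zygosity.HET
    if (het and maf < 0.005) or (not het and maf < 0.01):
        return FrequencyClass.RARE
    if (het and maf < 0.01) or (not het and maf < 0.05):
        return FrequencyClass.LOW_FREQUENCY
    return FrequencyClass.COMMON


def ablate_and_rescore(
    individual_index: int,
    profile: TermProfile,
    genotypes: np.ndarray,
    individuals: Sequence[str],
    excluded: Iterable[int],
    params: ScoreParams = ScoreParams(),
    seed: int = 0,
) -> float:
    """Transformed score after resetting sites in ``excluded`` to hom_ref.

    ``excluded`` holds site indices into ``profile.sites``.  Only the named
    individual's genotypes change; everyone else keeps theirs, so the
    ablation probes this individual's variants against an unchanged cohort.
    """
    excluded = list(excluded)
    if any(not (0 <= s < profile.n_sites) for s in excluded):
        raise InputError("excluded site index out of range")
    g = np.array(genotypes, copy=True)
    g[individual_index, excluded] = 0
    scores = score_term(profile, g, individuals, params, seed=seed)
    return float(scores.transformed[individual_index])


def classify_variant_roles(
    individual_index: int,
    profile: TermProfile,
    genotypes: np.ndarray,
    individuals: Sequence[str],
    original_score: float,
    params: ScoreParams = ScoreParams(),
    seed: int = 0,
) -> tuple[VariantRole, ...]:
    """Single-ablation role of every non-reference site the individual carries.

    Sites where the individual is hom_ref (or missing) trivially have no
    effect and are labelled ``none`` without re-scoring.
    """
    if original_score < params.threshold:
        raise InputError("roles are defined only for above-threshold calls")
    roles: list[VariantRole] = []
    carried = np.asarray(genotypes)[individual_index]
    for s, site in enumerate(profile.sites):
        if carried[s] <= 0:
            roles.append(VariantRole(site.variant.variant_id, Role.NONE, original_score, 0.0))
            continue
        ablated = ablate_and_rescore(
            individual_index, profile, genotypes, individuals, [s], params, seed
        )
        drop = original_score - ablated
        if ablated < params.threshold:
            role = Role.REQUIRED
        elif drop > CONTRIBUTION_TOL:
            role = Role.CONTRIBUTING
        else:
            role = Role.NONE
        roles.append(VariantRole(site.variant.variant_id, role, ablated, drop))
    return tuple(roles)


def classify_outlier_type(roles: Sequence[VariantRole]) -> str:
    """Map a role pattern to outlier type 1-a / 1-b / 2-a / 2-b."""
    required = [r for r in roles if r.role == Role.REQUIRED]
    contributing = [r for r in roles if r.role == Role.CONTRIBUTING]
    if not required and not contributing:
        raise InputError("inconsistent call: no variant has any effect")
    if len(required) == 1:
        return "1-b" if contributing else "1-a"
    # zero or several required variants: multi-variant outlier
    effective = required + contributing
    drops = sorted((r.drop for r in effective), reverse=True)
    if len(drops) >= 2 and drops[0] > sum(drops[1:]):
        return "2-a"
    if len(drops) == 1:
        # several-required cannot happen with one effective variant; the
        # zero-required single-effect case is dominance by definition
        return "2-a"
    return "2-b"


def combinatorial_contribution(scores: OutlierScoreSet, individual_index: int) -> float:
    """Excess of the clustered raw score over the unclustered mean-distance
    score for one individual; zero when the term shows no structure."""
    return float(scores.combinatorial[individual_index])


def explain_call(
    individual_index: int,
    profile: TermProfile,
    genotypes: np.ndarray,
    individuals: Sequence[str],
    scores: OutlierScoreSet,
    params: ScoreParams = ScoreParams(),
    seed: int = 0,
) -> OutlierCall:
    """Full explanation of one above-threshold call."""
    original = float(scores.transformed[individual_index])
    roles = classify_variant_roles(
        individual_index, profile, genotypes, individuals, original, params, seed
    )
    carried = np.asarray(genotypes)[individual_index]
    freq = tuple(
        frequency_class(
            site.variant.maf,
            Zygosity.HOM_ALT if carried[s] == 2 else
            Zygosity.HET if carried[s] == 1 else Zygosity.HOM_REF,
        )
        for s, site in enumerate(profile.sites)
    )
    return OutlierCall(
        individual_id=individuals[individual_index],
        term_id=profile.term_id,
        transformed_score=original,
        outlier_type=classify_outlier_type(roles),
        roles=roles,
        combinatorial_contribution=combinatorial_contribution(scores, individual_index),
        frequency_classes=freq,
    )


def find_calls(
    scores: OutlierScoreSet, threshold: Optional[float] = None,
    params: ScoreParams = ScoreParams(),
) -> list[int]:
    """Indices of individuals at or above the call threshold."""
    thr = params.threshold if threshold is None else threshold
    return np.flatnonzero(scores.transformed >= thr).tolist()
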