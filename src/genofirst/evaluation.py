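"""Confirmation of genetics-first predictions against phenotype answers.

Predictions are confirmed blind: each participant answers yes/no questions
about their own top-scoring ontology terms mixed with the top terms of a
randomly drawn *decoy* genome from the background, so the decoy yes-rate
measures how often people self-identify a random phenotype.  Questions
whose yes-rate is too high identify common phenotypes rather than
outliers and are removed by QC.  Significance is assessed by permutation:
re-allocating the outlier scores over the answer records and asking how
often random allocations do as well as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .functional_model import InputError

ANSWER_COLUMNS = ["individual_id", "term_id", "answer", "is_decoy", "score"]


def validate_answers(answers: pd.DataFrame) -> pd.DataFrame:
    """Check the answer-table schema: one record per (individual, term)."""
    missing = set(ANSWER_COLUMNS) - set(answers.columns)
    if missing:
        raise InputError(f"answer table missing columns: {sorted(missing)}")
    if answers.duplicated(["individual_id", "term_id"]).any():
        raise InputError("answer table has duplicate (individual, term) records")
    return answers


def read_answers_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["answer"] = df["answer"].astype(bool)
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return validate_answers(df)


def write_answers_csv(answers: pd.DataFrame, path) -> None:
    validate_answers(answers)[ANSWER_COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    z_score: float

    @classmethod
    def from_null(cls, observed: float, permuted: np.ndarray) -> "PermutationResult":
        permuted = np.asarray(permuted, dtype=float)
        b = int(np.sum(permuted >= observed))
        p = (1 + b) / (1 + len(permuted))  # add-one: p never exactly zero
        sd = permuted.std()
        z = float((observed - permuted.mean()) / sd) if sd > 0 else float("nan")
        return cls(observed=float(observed), permuted=permuted, p_value=p, z_score=z)


@dataclass(frozen=True)
class PhenotypeRanking:
    """Per-term permutation p-values with the expected-by-chance curve."""

    term_ids: tuple[str, ...]  # sorted by ascending p-value
    p_values: np.ndarray
    expected_mean: np.ndarray  # terms expected by chance at each rank's p
    expected_sd: np.ndarray
    excess: np.ndarray  # observed rank minus expected_mean


# ---------------------------------------------------------------------------
# Questionnaire construction and QC
# ---------------------------------------------------------------------------

def _top_terms(scores: Mapping[str, float], n: int) -> list[str]:
    """Terms ranked by descending score; ties broken by term id."""
    ranked = sorted(scores, key=lambda t: (-scores[t], t))
    return ranked[:n] if n <= len(ranked) else ranked


def build_questionnaire(
    participant_scores: Mapping[str, float],
    background_pool: Mapping[str, Mapping[str, float]],
    n_top: int = 25,
    seed: int = 0,
) -> tuple[str, list[tuple[str, bool]]]:
    """Personalised questionnaire: participant top terms mixed with a decoy's.

    A decoy genome is drawn uniformly from the background pool; its
    ``n_top`` top-scoring terms are shuffled together with the
    participant's.  A term appearing in both top lists is asked once,
    attributed to the participant, and the decoy side takes its
    next-ranked term instead.

    Returns ``(decoy_id, [(term_id, is_decoy), ...])`` in question order.
    """
    rng = np.random.default_rng(seed)
    if not background_pool:
        raise InputError("background pool is empty")
    decoy_id = sorted(background_pool)[rng.integers(len(background_pool))]

    part_top = _top_terms(participant_scores, n_top)
    if len(part_top) < n_top:
        raise InputError(
            f"participant has {len(part_top)} scoreable terms; need {n_top}"
        )
    decoy_ranked = _top_terms(background_pool[decoy_id], len(background_pool[decoy_id]))
    decoy_top = [t for t in decoy_ranked if t not in set(part_top)][:n_top]
    if len(decoy_top) < n_top:
        raise InputError(
            f"decoy {decoy_id} has only {len(decoy_top)} usable terms; need {n_top}"
        )
    questions = [(t, False) for t in part_top] + [(t, True) for t in decoy_top]
    order = rng.permutation(len(questions))
    return decoy_id, [questions[i] for i in order]


def qc_questions(
    answers: pd.DataFrame, max_rate: float = 0.05, min_answers: int = 20
) -> set[str]:
    """Terms whose yes-rate is non-zero and strictly below ``max_rate``,
    with at least ``min_answers`` answers recorded.

    A question answered yes too often identifies a common phenotype rather
    than an outlier, so the boundary is exclusive: exactly ``max_rate``
    fails.
    """
    validate_answers(answers)
    grouped = answers.groupby("term_id")["answer"].agg(["sum", "count"])
    rate = grouped["sum"] / grouped["count"]
    keep = (grouped["sum"] > 0) & (rate < max_rate) & (grouped["count"] >= min_answers)
    return set(grouped.index[keep])


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _random_subset_indices(
    rng: np.random.Generator, n: int, k: int, n_perm: int
) -> np.ndarray:
    """(n_perm, k) indices of independent uniform k-subsets of range(n).

    Indices are sorted within each row so that a subset equal to the
    observed one reproduces the observed statistic bit-for-bit.
    """
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    idx.sort(axis=1)
    return idx


def global_score_permutation(
    answers: pd.DataFrame, n_perm: int = 2000, seed: int = 0
) -> PermutationResult:
    """Are observed scores higher, on average, for confirmed phenotypes?

    Statistic: mean outlier score over yes-answered questions.  Null:
    scores re-allocated uniformly over all answer records.
    """
    validate_answers(answers)
    scores = answers["score"].to_numpy(dtype=float)
    yes = answers["answer"].to_numpy(dtype=bool)
    k = int(yes.sum())
    if k == 0:
        raise InputError("no positive answers: statistic undefined")
    observed = scores[yes].mean()
    rng = np.random.default_rng(seed)
    idx = _random_subset_indices(rng, len(scores), k, n_perm)
    permuted = scores[idx].mean(axis=1)
    return PermutationResult.from_null(observed, permuted)


def threshold_rate_test(
    answers: pd.DataFrame,
    threshold: float = 0.022,
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[float, float, PermutationResult]:
    """Yes-rate among above-threshold questions versus decoys.

    Returns ``(rate, decoy_rate, permutation_result)`` where ``rate`` is
    the fraction of yes answers among questions scoring at or above the
    threshold and ``decoy_rate`` the fraction of yes among decoy questions.
    The null re-allocates scores over records (answers fixed), so each
    permuted rate is the yes-rate of a random same-size subset.
    """
    validate_answers(answers)
    scores = answers["score"].to_numpy(dtype=float)
    yes = answers["answer"].to_numpy(dtype=bool)
    decoy = answers["is_decoy"].to_numpy(dtype=bool)
    above = scores >= threshold
    n_above = int(above.sum())
    if n_above == 0:
        raise InputError("no questions score at or above the threshold")
    rate = float(yes[above].mean())
    decoy_rate = float(yes[decoy].mean()) if decoy.any() else float("nan")
    rng = np.random.default_rng(seed)
    idx = _random_subset_indices(rng, len(scores), n_above, n_perm)
    permuted = yes[idx].mean(axis=1)
    return rate, decoy_rate, PermutationResult.from_null(rate, permuted)


def per_phenotype_permutation(
    answers: pd.DataFrame,
    n_perm: int = 2000,
    seed: int = 0,
    n_curve: int = 200,
) -> PhenotypeRanking:
    """Rank phenotypes by how well their scores predict their answers.

    Per term, the statistic is the sum of scores over yes-answers and the
    p-value comes from permuting scores within the term (a term with no
    positives gets p = 1 by convention).  To quantify how many top terms
    exceed chance, scores are re-permuted ``n_curve`` times; each time all
    term p-values are recomputed against the same within-term permutation
    distributions, giving, at each observed rank x with p-value p_(x), the
    mean and standard deviation of the number of terms reaching p <= p_(x)
    by chance.  The excess curve is x minus that mean.
    """
    validate_answers(answers)
    terms = sorted(answers["term_id"].unique())
    if len(terms) < 2:
        raise InputError("need at least 2 terms")
    rng = np.random.default_rng(seed)

    p_obs: dict[str, float] = {}
    null_ps: list[np.ndarray] = []  # per term: n_curve null p-values
    for term in terms:
        sub = answers[answers["term_id"] == term]
        s = sub["score"].to_numpy(dtype=float)
        y = sub["answer"].to_numpy(dtype=bool)
        k = int(y.sum())
        if k == 0:
            p_obs[term] = 1.0
            null_ps.append(np.ones(n_curve))
            continue
        observed = s[y].sum()
        idx = _random_subset_indices(rng, len(s), k, n_perm)
        permuted = np.sort(s[idx].sum(axis=1))
        # right-tail count via sorted search: #{permuted >= x}
        def tail(x: np.ndarray) -> np.ndarray:
            return n_perm - np.searchsorted(permuted, x, side="left")
        p_obs[term] = float((1 + tail(np.array([observed]))[0]) / (1 + n_perm))
        draw_idx = _random_subset_indices(rng, len(s), k, n_curve)
        draws = s[draw_idx].sum(axis=1)
        null_ps.append((1 + tail(draws)) / (1 + n_perm))

    order = sorted(terms, key=lambda t: (p_obs[t], t))
    p_sorted = np.array([p_obs[t] for t in order])
    null_matrix = np.vstack([null_ps[terms.index(t)] for t in order])  # (T, n_curve)

    # expected number of chance terms at each observed rank's p-value
    counts = (null_matrix[None, :, :] <= p_sorted[:, None, None]).sum(axis=1)
    expected_mean = counts.mean(axis=1).astype(float)
    expected_sd = counts.std(axis=1).astype(float)
    ranks = np.arange(1, len(order) + 1, dtype=float)
    return PhenotypeRanking(
        term_ids=tuple(order),
        p_values=p_sorted,
        expected_mean=expected_mean,
        expected_sd=expected_sd,
        excess=ranks - expected_mean,
    )


# ---------------------------------------------------------------------------
# Annotation-based confirmation
# ---------------------------------------------------------------------------

def confirm_against_annotations(
    calls: Sequence,
    annotations: Mapping[str, Sequence[str]],
    matcher: Callable[[str, str], bool],
) -> list:
    """Keep the calls whose predicted term closely matches an annotation.

    ``matcher(a, b)`` decides closeness (e.g. a partial of
    :func:`genofirst.term_profiles.close_match`).  Individuals without any
    annotation are never confirmed — the necessary assumption for a fair,
    automatic evaluation.
    """
    confirmed = []
    for call in calls:
        annotated = annotations.get(call.individual_id, ())
        if any(matcher(call.term_id, a) for a in annotated):
            confirmed.append(call)
    return confirmed
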