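"""End-to-end orchestration: profiles -> distances -> scores -> calls ->
classification -> evaluation.

The pipeline consumes a :class:`~genofirst.simulate.World` (built by the
generator or assembled from files by :mod:`genofirst.io`), scores every
ontology term independently, explains the subjects' above-threshold calls
by ablation, builds decoy-mixed questionnaires, simulates or ingests
answers, and runs the permutation confirmation.  Everything is
deterministic given the run seed; no stage mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import OutlierCall, explain_call, find_calls
from .evaluation import (
    PermutationResult,
    PhenotypeRanking,
    build_questionnaire,
    global_score_permutation,
    per_phenotype_permutation,
    qc_questions,
    threshold_rate_test,
)
from .io import RunConfig
from .outlier_engine import OutlierScoreSet, ScoreParams, score_term
from .simulate import World, generate_answers

logger = logging.getLogger("genofirst")


@dataclass
class PipelineResult:
    config: RunConfig
    scores: dict[str, OutlierScoreSet]  # by term
    calls: list[OutlierCall]
    answers: Optional[pd.DataFrame] = None
    qc_terms: Optional[set[str]] = None
    global_test: Optional[PermutationResult] = None
    threshold_test: Optional[tuple[float, float, PermutationResult]] = None
    ranking: Optional[PhenotypeRanking] = None

    def scores_frame(self) -> pd.DataFrame:
        rows = []
        for term, s in self.scores.items():
            sizes = {}
            if s.labels is not None:
                vals, counts = np.unique(s.labels, return_counts=True)
                sizes = dict(zip(vals.tolist(), counts.tolist()))
            for i, ind in enumerate(s.individuals):
                rows.append(
                    {
                        "term_id": term,
                        "individual_id": ind,
                        "raw": s.raw[i],
                        "local": s.local[i],
                        "global": s.global_[i],
                        "combinatorial": s.combinatorial[i],
                        "rank": s.rank[i],
                        "transformed": s.transformed[i],
                        "has_structure": s.has_structure,
                        "k": s.k if s.k is not None else 0,
                        "cluster_size": (
                            sizes.get(int(s.labels[i]), 0)
                            if s.labels is not None else 0
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "individual_id": c.individual_id,
                    "term_id": c.term_id,
                    "score": c.transformed_score,
                    "type": c.outlier_type,
                    "combinatorial_contribution": c.combinatorial_contribution,
                    "required_variants": ";".join(
                        r.variant_id for r in c.roles if r.role.value == "required"
                    ),
                    "contributing_variants": ";".join(
                        r.variant_id for r in c.roles if r.role.value == "contributing"
                    ),
                }
            )
        return pd.DataFrame(rows)

    def calls_detail(self, world) -> list[dict]:
        """Per-call records with per-variant role, frequency class,
        zygosity and genomic coordinates, for the JSON output."""
        records = []
        for c in self.calls:
            profile = world.build_profile(c.term_id)
            genotypes = world.profile_genotypes(profile)
            row = world.individuals.index(c.individual_id)
            variants = []
            for s, (site, role, fc) in enumerate(
                zip(profile.sites, c.roles, c.frequency_classes)
            ):
                code = int(genotypes[row, s])
                zygosity = {0: "hom_ref", 1: "het", 2: "hom_alt"}.get(code, "missing")
                variants.append(
                    {
                        "variant_id": site.variant.variant_id,
                        "chrom": site.variant.chrom,
                        "pos": site.variant.pos,
                        "ref": site.variant.ref,
                        "alt": site.variant.alt,
                        "maf": site.variant.maf,
                        "zygosity": zygosity,
                        "role": role.role.value,
                        "frequency_class": fc.value,
                        "ablated_score": role.ablated_score,
                    }
                )
            records.append(
                {
                    "individual_id": c.individual_id,
                    "term_id": c.term_id,
                    "score": c.transformed_score,
                    "type": c.outlier_type,
                    "combinatorial_contribution": c.combinatorial_contribution,
                    "variants": variants,
                }
            )
        return records


def score_world(
    world: World,
    config: RunConfig = RunConfig(),
) -> dict[str, OutlierScoreSet]:
    """Score every (filtered) term of a world independently."""
    terms = sorted(world.domain_term_map.terms())
    if config.term_filter is not None:
        allowed = set(config.term_filter)
        terms = [t for t in terms if t in allowed]
    scores: dict[str, OutlierScoreSet] = {}
    for idx, term in enumerate(terms):
        profile = world.build_profile(term)
        if profile.is_empty:
            logger.info("term %s: empty profile, skipped", term)
            continue
        s = score_term(
            profile,
            world.profile_genotypes(profile),
            world.individuals,
            config.params,
            seed=config.seed + idx,
        )
        sizes = s.labels is not None and np.bincount(s.labels).tolist() or []
        logger.info(
            "term %s: %d sites, structure=%s k=%s clusters=%s calls=%d",
            term, profile.n_sites, s.has_structure, s.k, sizes,
            int(np.sum(s.transformed >= config.params.threshold)),
        )
        scores[term] = s
    return scores


def run_pipeline(
    world: World,
    config: RunConfig = RunConfig(),
    answers: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run the full framework on a world.

    Subjects (or everyone, in self-background mode) are screened for
    above-threshold calls, each call is explained by ablation, and
    predictions are confirmed against answers — simulated from the world's
    truth and answer model when none are supplied.
    """
    scores = score_world(world, config)
    if not scores:
        logger.info("no terms to process")
        return PipelineResult(config=config, scores={}, calls=[])

    if config.background_mode == "self":
        call_ids = list(world.individuals)
    else:
        call_ids = list(world.subject_ids)
    call_rows = [world.individuals.index(i) for i in call_ids]

    calls: list[OutlierCall] = []
    for idx, (term, s) in enumerate(sorted(scores.items())):
        profile = world.build_profile(term)
        genotypes = world.profile_genotypes(profile)
        for row in find_calls(s, params=config.params):
            if row not in call_rows:
                continue
            calls.append(
                explain_call(
                    row, profile, genotypes, world.individuals, s,
                    config.params, seed=config.seed + idx,
                )
            )
    logger.info("%d above-threshold calls across %d terms", len(calls), len(scores))

    # --- questionnaires and confirmation
    subject_scores = {
        ind: {
            term: float(s.transformed[world.individuals.index(ind)])
            for term, s in scores.items()
        }
        for ind in call_ids
    }
    pool = {
        ind: {
            term: float(s.transformed[world.individuals.index(ind)])
            for term, s in scores.items()
        }
        for ind in world.background_ids
    }
    questions = []
    for q_idx, ind in enumerate(sorted(subject_scores)):
        if len(scores) < 2 * config.n_top or not pool:
            break
        decoy_id, qs = build_questionnaire(
            subject_scores[ind], pool, config.n_top, seed=config.seed + 7000 + q_idx
        )
        for term, is_decoy in qs:
            source = pool[decoy_id] if is_decoy else subject_scores[ind]
            questions.append(
                {
                    "individual_id": ind,
                    "term_id": term,
                    "is_decoy": is_decoy,
                    "score": source[term],
                }
            )
    result = PipelineResult(config=config, scores=scores, calls=calls)
    if questions:
        qframe = pd.DataFrame(questions)
        if answers is None:
            answers = generate_answers(world, qframe, seed=config.seed + 9001)
        result.answers = answers
        result.qc_terms = qc_questions(answers)
        if answers["answer"].any():
            result.global_test = global_score_permutation(
                answers, config.n_perm, seed=config.seed + 11
            )
            if (answers["score"] >= config.params.threshold).any():
                result.threshold_test = threshold_rate_test(
                    answers, config.params.threshold, config.n_perm,
                    seed=config.seed + 12,
                )
            if answers["term_id"].nunique() >= 2:
                result.ranking = per_phenotype_permutation(
                    answers, config.n_perm, seed=config.seed + 13
                )
    if config.out_dir is not None:
        _write_outputs(result, world, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, world: World, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    result.scores_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
    result.calls_frame().to_csv(out / "calls.tsv", sep="\t", index=False)
    with open(out / "calls.json", "w") as fh:
        json.dump(result.calls_detail(world), fh, indent=1)
    if result.ranking is not None:
        pd.DataFrame(
            {
                "term_id": result.ranking.term_ids,
                "p_value": result.ranking.p_values,
                "expected_by_chance": result.ranking.expected_mean,
                "expected_sd": result.ranking.expected_sd,
                "excess": result.ranking.excess,
            }
        ).to_csv(out / "phenotype_ranking.tsv", sep="\t", index=False)
    if result.answers is not None:
        from .evaluation import write_answers_csv

        write_answers_csv(result.answers, out / "answers.csv")
    summary: dict = {"n_terms": len(result.scores), "n_calls": len(result.calls)}
    if result.global_test is not None:
        summary["global_test"] = {
            "observed_mean_yes_score": result.global_test.observed,
            "p_value": result.global_test.p_value,
            "z_score": result.global_test.z_score,
        }
    if result.threshold_test is not None:
        rate, decoy_rate, perm = result.threshold_test
        summary["threshold_test"] = {
            "rate_above_threshold": rate,
            "decoy_rate": decoy_rate,
            "p_value": perm.p_value,
        }
    if result.ranking is not None:
        summary["per_phenotype"] = {
            "n_terms": len(result.ranking.term_ids),
            "top_term": result.ranking.term_ids[0],
            "top_p": float(result.ranking.p_values[0]),
            "max_excess": float(result.ranking.excess.max()),
        }
    with open(out / "evaluation.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    logger.info("outputs written to %s", out)
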