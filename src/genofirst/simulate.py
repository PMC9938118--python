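"""Synthetic cohorts with the statistical structure the method assumes.

The generator emulates the study design the scorer expects: a large,
diverse background cohort (standing in for reference-panel genomes) plus a
small batch of subjects, domain profile HMMs with peaked (Dirichlet-drawn)
emissions so that some substitutions are strongly disfavoured, a toy
ontology DAG with dcGO-style domain links, and a variant catalogue whose
minor allele frequencies follow a rare / low-frequency / common mixture.
Genotypes are drawn independently per site under Hardy-Weinberg
equilibrium; linkage is absent except where a planted effect explicitly
induces co-occurrence.

Three kinds of ground-truth effects can be planted, each recorded in a
truth file sufficient to score recall without re-inspecting genotypes:

single_rare
    one subject is given a homozygous genotype at a freshly minted site
    with MAF 0.1% and a maximal functional distance — the classic
    one-variant outlier.
multi_variant
    one subject carries heterozygous genotypes at three moderately rare,
    moderate-distance sites; no single one suffices.
combinatorial
    a genotype-defined subgroup of the background (co-occurring common
    variants, deliberately off Hardy-Weinberg) forms a cluster, and the
    planted subject carries, on top of the subgroup genotype, an allele
    that is common marginally but absent within the subgroup — rarity
    conditional on the cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .functional_model import (
    AMINO_ACIDS,
    DomainHit,
    InputError,
    MissenseVariant,
    ProfileHMM,
    score_substitution,
)
from .term_profiles import DomainTermMap, Ontology, TermProfile, build_term_profile


class GenerationError(InputError):
    """A requested plant cannot be realised under the configuration."""


@dataclass(frozen=True)
class PlantSpec:
    """One requested ground-truth effect.

    ``kind`` is ``single_rare``, ``multi_variant`` or ``combinatorial``;
    subject and term are auto-assigned when omitted.
    """

    kind: str
    subject: Optional[str] = None
    term: Optional[str] = None


@dataclass(frozen=True)
class TruthRecord:
    subject: str
    term: str
    variant_ids: tuple[str, ...]
    kind: str
    combinatorial: bool


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic world.

    Defaults are desk-scale: a 500-genome background with 20 subjects over
    200 ontology terms and 50 domains runs end to end in minutes.  The
    decoy answer rate of 0.8% mirrors the measured rate at which people
    self-identify a random phenotype; planted predictions are answered yes
    at 90%, an optimistic but noisy self-report.
    """

    seed: int = 0
    n_background: int = 500
    n_subjects: int = 20
    n_terms: int = 200
    n_domains: int = 50
    domain_length: int = 25
    variants_per_domain: int = 6
    dirichlet_concentration: float = 0.3
    maf_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)  # rare/low/common
    combinatorial_fraction: float = 0.08  # subgroup share of the cohort
    plants: tuple[PlantSpec, ...] = ()
    answer_base_rate: float = 0.008
    answer_planted_rate: float = 0.9

    def __post_init__(self) -> None:
        for name in ("n_background", "n_subjects", "n_terms", "n_domains",
                     "domain_length", "variants_per_domain"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        for rate in (self.answer_base_rate, self.answer_planted_rate):
            if not (0.0 <= rate <= 1.0):
                raise InputError("answer rates must lie in [0, 1]")


@dataclass
class World:
    """Everything the pipeline consumes, plus the planted ground truth."""

    config: SimulationConfig
    hmms: dict[str, ProfileHMM]
    hits: list[DomainHit]
    domain_term_map: DomainTermMap
    ontology: Ontology
    variants: list[MissenseVariant]  # catalogue, column order of `genotypes`
    individuals: list[str]  # background first, then subjects
    background_ids: list[str]
    subject_ids: list[str]
    genotypes: np.ndarray  # (n_individuals, n_catalogue_sites) int8 dosages
    truth: list[TruthRecord]

    @property
    def site_index(self) -> dict[str, int]:
        return {v.variant_id: j for j, v in enumerate(self.variants)}

    def profile_genotypes(self, profile: TermProfile) -> np.ndarray:
        """Genotype submatrix aligned to a term profile's site order."""
        idx = [self.site_index[vid] for vid in profile.variant_ids]
        return self.genotypes[:, idx]

    def build_profile(self, term_id: str) -> TermProfile:
        return build_term_profile(
            term_id, self.domain_term_map, self.hits, self.variants, self.hmms
        )


def _sample_hwe(rng: np.random.Generator, maf: float, n: int) -> np.ndarray:
    p = maf
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def _draw_maf(rng: np.random.Generator, weights: Sequence[float]) -> float:
    w = np.asarray(weights, dtype=float)
    cls = rng.choice(3, p=w / w.sum())
    lo, hi = [(0.0005, 0.005), (0.005, 0.05), (0.05, 0.5)][cls]
    return float(rng.uniform(lo, hi))


def _aa_pair(
    hmm: ProfileHMM,
    state: int,
    kind: str,
    rng: np.random.Generator,
    target: float = 3.0,
) -> tuple[str, str]:
    """Pick (ref, alt) amino acids at a state.

    ``max`` maximises the functional distance, ``mid`` targets a given
    log-odds (default about 3 nats), ``min`` picks the most tolerated
    substitution, ``typical`` draws the alternate uniformly.
    """
    emis = hmm.emissions[state - 1]
    ref_idx = int(np.argmax(emis))
    ref = AMINO_ACIDS[ref_idx]
    log_odds = np.log(emis[ref_idx] / emis)
    log_odds[ref_idx] = np.inf
    if kind == "max":
        alt = AMINO_ACIDS[int(np.argmin(emis))]
    elif kind == "mid":
        alt = AMINO_ACIDS[int(np.argmin(np.abs(log_odds - target)))]
    elif kind == "min":
        alt = AMINO_ACIDS[int(np.argmin(log_odds))]
    else:
        choices = [aa for aa in AMINO_ACIDS if aa != ref]
        alt = choices[rng.integers(len(choices))]
    return ref, alt


class _Catalogue:
    """Mutable variant catalogue + genotype columns during generation."""

    def __init__(self) -> None:
        self.variants: list[MissenseVariant] = []
        self.columns: list[np.ndarray] = []
        self._pos = 0

    def add(
        self,
        domain: int,
        tag: str,
        protein_id: str,
        residue: int,
        ref_aa: str,
        alt_aa: str,
        maf: float,
        genotype_column: np.ndarray,
    ) -> MissenseVariant:
        self._pos += 100
        v = MissenseVariant(
            variant_id=f"v{domain:03d}_{tag}",
            chrom="1",
            pos=self._pos,
            ref="A",
            alt="G",
            protein_id=protein_id,
            residue_index=residue,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            maf=maf,
        )
        self.variants.append(v)
        self.columns.append(genotype_column.astype(np.int8))
        return v


def generate_world(config: SimulationConfig) -> World:
    """Deterministically build a synthetic world from a configuration."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_background + config.n_subjects
    background_ids = [f"bg{i:04d}" for i in range(config.n_background)]
    subject_ids = [f"subj{i:03d}" for i in range(config.n_subjects)]
    individuals = background_ids + subject_ids

    # --- domains: one protein per HMM, full-length match alignment
    hmms: dict[str, ProfileHMM] = {}
    hits: list[DomainHit] = []
    for d in range(config.n_domains):
        hmm_id = f"HMM{d:03d}"
        emis = rng.dirichlet(
            np.full(len(AMINO_ACIDS), config.dirichlet_concentration),
            size=config.domain_length,
        )
        hmms[hmm_id] = ProfileHMM.from_raw(hmm_id, emis)
        hits.append(
            DomainHit(
                protein_id=f"P{d:03d}",
                hmm_id=hmm_id,
                protein_start=1,
                protein_end=config.domain_length,
                residue_to_state={r: r for r in range(1, config.domain_length + 1)},
                score=100.0,
            )
        )

    # --- ontology: random tree rooted at T0000 (occasional second parent)
    graph = nx.DiGraph()
    graph.add_node("T0000", name="root")
    term_ids = [f"T{i:04d}" for i in range(1, config.n_terms)]
    for i, term in enumerate(term_ids):
        graph.add_node(term, name=f"synthetic term {term}")
        pool = ["T0000"] + term_ids[:i]
        parent = pool[rng.integers(len(pool))]
        graph.add_edge(term, parent)
        if len(pool) > 1 and rng.random() < 0.1:
            second = pool[rng.integers(len(pool))]
            if second != parent and second != term:
                graph.add_edge(term, second)
    ontology = Ontology(graph)

    # --- dcGO-style map: each non-root term linked to 1-3 domains
    pairs: set[tuple[str, str]] = set()
    domain_ids = sorted(hmms)
    for term in term_ids:
        n_links = 1 + rng.integers(3)
        for d in rng.choice(len(domain_ids), size=n_links, replace=False):
            pairs.add((domain_ids[d], term))
    domain_term_map = DomainTermMap.from_records(sorted(pairs))

    # --- background variant catalogue under Hardy-Weinberg
    cat = _Catalogue()
    used_residues: dict[int, set[int]] = {d: set() for d in range(config.n_domains)}
    for d in range(config.n_domains):
        hmm_id = domain_ids[d]
        n_var = min(config.variants_per_domain, config.domain_length)
        residues = rng.choice(config.domain_length, size=n_var, replace=False) + 1
        for j, res in enumerate(sorted(residues)):
            used_residues[d].add(int(res))
            maf = _draw_maf(rng, config.maf_weights)
            # purifying selection: the more frequent the allele, the more
            # tolerated the substitution
            kind = "typical" if maf < 0.005 else ("mid" if maf < 0.05 else "min")
            ref, alt = _aa_pair(hmms[hmm_id], int(res), kind, rng, target=2.0)
            cat.add(
                d, f"n{j}", f"P{d:03d}", int(res), ref, alt, maf,
                _sample_hwe(rng, maf, n_total),
            )

    # --- plants
    truth: list[TruthRecord] = []
    free_subjects = list(subject_ids)
    # terms with exactly one linked domain keep planted effects interpretable
    single_domain_terms = sorted(
        t for t in term_ids if len(domain_term_map.domains_for(t)) == 1
    )
    free_terms = list(single_domain_terms)

    def claim(spec: PlantSpec) -> tuple[str, str, int]:
        subject = spec.subject or (free_subjects.pop(0) if free_subjects else None)
        if subject is None or subject not in subject_ids:
            raise GenerationError(f"no subject available for plant {spec.kind}")
        if spec.term is not None:
            term = spec.term
        elif free_terms:
            term = free_terms.pop(0)
        else:
            raise GenerationError("no single-domain term available for planting")
        if subject in free_subjects:
            free_subjects.remove(subject)
        if term in free_terms:
            free_terms.remove(term)
        domain = sorted(domain_term_map.domains_for(term))[0]
        return subject, term, domain_ids.index(domain)

    def fresh_residue(d: int, best: bool = False) -> int:
        free = [r for r in range(1, config.domain_length + 1)
                if r not in used_residues[d]]
        if not free:
            raise GenerationError(f"domain {d} has no free residue for a plant")
        if best:
            # most discriminating match state: widest emission log-range
            emis = hmms[domain_ids[d]].emissions
            span = np.log(emis.max(axis=1) / emis.min(axis=1))
            res = max(free, key=lambda r: span[r - 1])
        else:
            res = free[rng.integers(len(free))]
        used_residues[d].add(res)
        return res

    for spec in config.plants:
        subject, term, d = claim(spec)
        hmm = hmms[domain_ids[d]]
        subj_row = individuals.index(subject)
        if spec.kind == "single_rare":
            res = fresh_residue(d, best=True)
            ref, alt = _aa_pair(hmm, res, "max", rng)
            maf = 0.001
            col = _sample_hwe(rng, maf, n_total)
            col[subj_row] = 2
            v = cat.add(d, "sr", f"P{d:03d}", res, ref, alt, maf, col)
            truth.append(TruthRecord(subject, term, (v.variant_id,), spec.kind, False))
        elif spec.kind == "multi_variant":
            vids = []
            for j in range(3):
                res = fresh_residue(d)
                ref, alt = _aa_pair(hmm, res, "max", rng)
                maf = 0.004
                col = _sample_hwe(rng, maf, n_total)
                col[subj_row] = 1
                v = cat.add(d, f"mv{j}", f"P{d:03d}", res, ref, alt, maf, col)
                vids.append(v.variant_id)
            truth.append(TruthRecord(subject, term, tuple(vids), spec.kind, False))
        elif spec.kind == "combinatorial":
            n_sub = int(round(config.combinatorial_fraction * n_total))
            if n_sub < 5:
                raise GenerationError(
                    f"combinatorial subgroup of {n_sub} genomes is too small"
                )
            members = rng.choice(config.n_background, size=n_sub, replace=False)
            vids = []
            # the conditional-rarity site: carried homozygous by most of the
            # cohort outside the subgroup, absent within it — so the planted
            # subject's homozygous alternate is common marginally yet rare
            # relative to its own cluster
            res_cc = fresh_residue(d, best=True)
            ref_cc, alt_cc = _aa_pair(hmm, res_cc, "max", rng)
            d_cc = score_substitution(hmm, res_cc, ref_cc, alt_cc)
            # two co-occurring cluster-defining alleles (deliberately off
            # Hardy-Weinberg: they define the subgroup); their joint
            # separation is sized just above the conditional-rarity
            # distance so the planted subject still clusters with its
            # subgroup while its within-cluster rarity dominates the score
            for j in range(2):
                res = fresh_residue(d)
                ref, alt = _aa_pair(hmm, res, "mid", rng, target=d_cc / 2.0 * 1.35)
                col = np.zeros(n_total, dtype=np.int8)
                col[members] = 2
                col[subj_row] = 2
                maf = min(0.5, (n_sub + 1) / n_total)
                v = cat.add(d, f"cd{j}", f"P{d:03d}", res, ref, alt, maf, col)
                vids.append(v.variant_id)
            col = 2 * (rng.random(n_total) < 0.9).astype(np.int8)
            col[members] = 0
            col[subj_row] = 2
            freq = float(col.mean() / 2)
            maf = float(min(freq, 1.0 - freq))  # marginal: common
            v = cat.add(d, "cc", f"P{d:03d}", res_cc, ref_cc, alt_cc, maf, col)
            vids.append(v.variant_id)
            truth.append(TruthRecord(subject, term, tuple(vids), spec.kind, True))
        else:
            raise GenerationError(f"unknown plant kind {spec.kind!r}")

    genotypes = (
        np.column_stack(cat.columns) if cat.columns
        else np.zeros((n_total, 0), dtype=np.int8)
    )
    return World(
        config=config,
        hmms=hmms,
        hits=hits,
        domain_term_map=domain_term_map,
        ontology=ontology,
        variants=cat.variants,
        individuals=individuals,
        background_ids=background_ids,
        subject_ids=subject_ids,
        genotypes=genotypes,
        truth=truth,
    )


def generate_answers(
    world: World,
    questions: pd.DataFrame,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate yes/no answers for a question table.

    ``questions`` needs columns ``individual_id``, ``term_id``,
    ``is_decoy`` and ``score``.  Planted (subject, term) truth pairs are
    answered yes at the planted rate; everything else (decoys included) at
    the base rate.
    """
    config = config or world.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    planted = {(t.subject, t.term) for t in world.truth}
    rates = np.where(
        [
            (row.individual_id, row.term_id) in planted and not row.is_decoy
            for row in questions.itertuples()
        ],
        config.answer_planted_rate,
        config.answer_base_rate,
    )
    answers = questions.copy()
    answers["answer"] = rng.random(len(questions)) < rates
    return answers[["individual_id", "term_id", "answer", "is_decoy", "score"]]


def write_truth_json(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(t) for t in truth], fh, indent=1)


def read_truth_json(path: str | Path) -> list[TruthRecord]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        TruthRecord(
            subject=t["subject"],
            term=t["term"],
            variant_ids=tuple(t["variant_ids"]),
            kind=t["kind"],
            combinatorial=t["combinatorial"],
        )
        for t in raw
    ]
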