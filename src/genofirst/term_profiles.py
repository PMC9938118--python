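"""Per-ontology-term variant profiles and ontology-graph closeness.

Each ontology term (e.g. an HPO phenotype) is linked to protein domains by
a domain-centric annotation table (dcGO-style).  A term's *profile* is the
set of missense variant sites that fall inside a domain linked to the term,
each weighted by its HMM-derived functional distance.  Terms are processed
independently; the domain-term map is consumed flat, with no propagation of
links along the ontology graph at profile-build time.

For confirmation against clinical annotations the module also provides a
graph-aware closeness test: two terms match closely when one is an ancestor
of the other and their information contents — derived from cumulative
annotation counts traversing the graph — differ by at most a configurable
band.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .functional_model import (
    DomainHit,
    InputError,
    MissenseVariant,
    ProfileHMM,
    map_variant_to_state,
    score_substitution,
)


class Ontology:
    """A DAG of terms with ``is_a`` parent links.

    Internally a :class:`networkx.DiGraph` with edges child -> parent, the
    orientation obonet uses.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise InputError("ontology graph contains a cycle")
        self.graph = graph

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", term_id)

    def parents(self, term_id: str) -> set[str]:
        return set(self.graph.successors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable via parent links (excluding the term)."""
        return nx.descendants(self.graph, term_id)

    def descendants(self, term_id: str) -> set[str]:
        return nx.ancestors(self.graph, term_id)

    @classmethod
    def from_obo(cls, path: str | Path) -> "Ontology":
        import obonet

        graph = obonet.read_obo(path)
        # keep only is_a edges; obonet stores other relations with a key
        keep = nx.DiGraph()
        keep.add_nodes_from(graph.nodes(data=True))
        for u, v, key in graph.edges(keys=True):
            if key == "is_a":
                keep.add_edge(u, v)
        return cls(keep)

    def to_obo(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\n\n")
            for term in sorted(self.graph.nodes):
                fh.write("[Term]\n")
                fh.write(f"id: {term}\n")
                fh.write(f"name: {self.name(term)}\n")
                for parent in sorted(self.parents(term)):
                    fh.write(f"is_a: {parent}\n")
                fh.write("\n")


@dataclass(frozen=True)
class DomainTermMap:
    """Flat (hmm_id, term_id) association table."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "DomainTermMap":
        seen: set[tuple[str, str]] = set()
        for rec in records:
            pair = (str(rec[0]), str(rec[1]))
            if pair in seen:
                raise InputError(f"duplicate domain-term pair {pair}")
            seen.add(pair)
        return cls(frozenset(seen))

    def domains_for(self, term_id: str) -> set[str]:
        return {hmm for hmm, term in self.pairs if term == term_id}

    def terms(self) -> set[str]:
        return {term for _, term in self.pairs}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DomainTermMap":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                hmm_id, term_id = line.split("\t")[:2]
                records.append((hmm_id, term_id))
        return cls.from_records(records)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#hmm_id\tterm_id\n")
            for hmm_id, term_id in sorted(self.pairs):
                fh.write(f"{hmm_id}\t{term_id}\n")


@dataclass(frozen=True)
class ProfileSite:
    """One variant site of a term profile with its functional distance."""

    variant: MissenseVariant
    hmm_id: str
    state: int
    distance: float


@dataclass(frozen=True)
class TermProfile:
    """The variant list of one ontology term.

    ``empty`` profiles (term unmapped, or no variant falls in a linked
    domain) are flagged rather than treated as errors: an empty profile
    simply yields no genetic signal for the term.
    """

    term_id: str
    sites: tuple[ProfileSite, ...]

    @property
    def is_empty(self) -> bool:
        return len(self.sites) == 0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(s.variant.variant_id for s in self.sites)

    @property
    def distances(self) -> tuple[float, ...]:
        return tuple(s.distance for s in self.sites)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "term_id": self.term_id,
            "sites": [
                {
                    "variant_id": s.variant.variant_id,
                    "chrom": s.variant.chrom,
                    "pos": s.variant.pos,
                    "ref": s.variant.ref,
                    "alt": s.variant.alt,
                    "protein_id": s.variant.protein_id,
                    "residue_index": s.variant.residue_index,
                    "ref_aa": s.variant.ref_aa,
                    "alt_aa": s.variant.alt_aa,
                    "maf": s.variant.maf,
                    "hmm_id": s.hmm_id,
                    "state": s.state,
                    "distance": s.distance,
                }
                for s in self.sites
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TermProfile":
        with open(path) as fh:
            payload = json.load(fh)
        sites = tuple(
            ProfileSite(
                variant=MissenseVariant(
                    variant_id=s["variant_id"],
                    chrom=s["chrom"],
                    pos=s["pos"],
                    ref=s["ref"],
                    alt=s["alt"],
                    protein_id=s["protein_id"],
                    residue_index=s["residue_index"],
                    ref_aa=s["ref_aa"],
                    alt_aa=s["alt_aa"],
                    maf=s["maf"],
                ),
                hmm_id=s["hmm_id"],
                state=s["state"],
                distance=s["distance"],
            )
            for s in payload["sites"]
        )
        return cls(term_id=payload["term_id"], sites=sites)


def build_term_profile(
    term_id: str,
    domain_term_map: DomainTermMap,
    hits: Sequence[DomainHit],
    variants: Sequence[MissenseVariant],
    hmms: Mapping[str, ProfileHMM],
) -> TermProfile:
    """Collect the variants that map into a domain linked to ``term_id``.

    Each variant is located on a match state via its protein's domain hits;
    it enters the profile iff the winning hit's HMM is linked to the term.
    Sites are sorted by ``variant_id`` so construction is order-independent
    with respect to input record order.
    """
    linked = domain_term_map.domains_for(term_id)
    if not linked:
        return TermProfile(term_id=term_id, sites=())
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        hits_by_protein.setdefault(hit.protein_id, []).append(hit)

    sites: list[ProfileSite] = []
    seen: set[str] = set()
    for variant in variants:
        mapped = map_variant_to_state(
            variant, hits_by_protein.get(variant.protein_id, ())
        )
        if mapped is None:
            continue
        hmm_id, state = mapped
        if hmm_id not in linked:
            continue
        if variant.variant_id in seen:
            raise InputError(f"duplicate variant_id {variant.variant_id}")
        seen.add(variant.variant_id)
        hmm = hmms.get(hmm_id)
        if hmm is None:
            raise InputError(f"HMM {hmm_id} referenced by hits but not provided")
        d = score_substitution(hmm, state, variant.ref_aa, variant.alt_aa)
        sites.append(ProfileSite(variant, hmm_id, state, d))
    sites.sort(key=lambda s: s.variant.variant_id)
    return TermProfile(term_id=term_id, sites=tuple(sites))


# ---------------------------------------------------------------------------
# Annotation counts and graph closeness
# ---------------------------------------------------------------------------

def cumulative_annotation_counts(
    annotations: Mapping[str, Iterable[str]], ontology: Ontology
) -> dict[str, int]:
    """Cumulative individual counts per term.

    ``annotations`` maps individual -> annotated term ids.  A term's count
    is the number of individuals annotated at that term *or any of its
    descendants* (annotations propagate up the graph), which guarantees
    ``count(parent) >= count(child)`` on every edge.
    """
    carriers: dict[str, set[str]] = {t: set() for t in ontology.terms}
    for individual, terms in annotations.items():
        for term in terms:
            if term not in ontology:
                continue
            carriers[term].add(individual)
            for anc in ontology.ancestors(term):
                carriers[anc].add(individual)
    return {t: len(who) for t, who in carriers.items()}


def information_content(
    term_id: str, counts: Mapping[str, int], total: int
) -> float:
    """Graph information content ``-ln(count(term) / total)``.

    Monotone non-increasing from child to parent because cumulative counts
    are monotone non-decreasing.  A zero count leaves the term unusable for
    matching and raises.
    """
    count = counts.get(term_id, 0)
    if count < 1:
        raise InputError(f"term {term_id} has zero annotation count; IC undefined")
    if not (1 <= count <= total):
        raise InputError(f"count {count} outside [1, total={total}]")
    return -math.log(count / total)


def close_match(
    a: str,
    b: str,
    ontology: Ontology,
    counts: Mapping[str, int],
    total: int,
    delta_ic: float = 1.0,
) -> bool:
    """Is term ``a`` a close match of term ``b``?

    True iff the terms are identical, or one is an ancestor of the other
    and their information contents differ by at most ``delta_ic`` nats.
    Symmetric by construction.
    """
    if a not in ontology or b not in ontology:
        raise InputError(f"unknown term: {a if a not in ontology else b}")
    if a == b:
        return True
    if b not in ontology.ancestors(a) and a not in ontology.ancestors(b):
        return False
    ic_a = information_content(a, counts, total)
    ic_b = information_content(b, counts, total)
    return abs(ic_a - ic_b) <= delta_ic


def read_annotation_counts_tsv(path: str | Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term_id, count = line.split("\t")[:2]
            counts[term_id] = int(count)
    return counts


def write_annotation_counts_tsv(counts: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#term_id\tcount\n")
        for term_id in sorted(counts):
            fh.write(f"{term_id}\t{counts[term_id]}\n")
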