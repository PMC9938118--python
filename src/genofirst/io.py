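"""Readers and writers for the external formats, plus run configuration.

Genotypes arrive either as multi-sample VCF (biallelic SNVs, ``GT`` field)
or as direct-to-consumer array exports (tab-separated
``rsid chrom pos genotype`` with letter-pair genotypes).  Both are
normalised to dosage codes against the variant catalogue; sites absent
from the catalogue are dropped with a logged count.  Coordinates are
1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .functional_model import InputError, MissenseVariant
from .outlier_engine import ScoreParams

logger = logging.getLogger("genofirst")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    variants: Sequence[MissenseVariant],
    genotypes: np.ndarray,
    individuals: Sequence[str],
    path: str | Path,
) -> None:
    """Write a minimal multi-sample VCF with GT fields.

    ``genotypes`` is (n_individuals, n_variants) dosage codes; -1 becomes
    ``./.``.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    order = np.argsort([v.pos for v in variants], kind="stable")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for j in order:
            v = variants[j]
            gts = "\t".join(gt_strings[int(g)] for g in genotypes[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | Path, catalogue: Sequence[MissenseVariant]
) -> tuple[list[str], np.ndarray, int]:
    """Read genotypes from a VCF, aligned to the catalogue column order.

    Only biallelic SNV records are used; multi-allelic records are skipped
    with a warning.  Catalogue sites absent from the file stay missing
    (-1).  Returns ``(individuals, genotypes, n_dropped)`` where
    ``n_dropped`` counts records not present in the catalogue.
    """
    from cyvcf2 import VCF

    index = {(v.chrom, v.pos, v.ref, v.alt): j for j, v in enumerate(catalogue)}
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    genotypes = np.full((len(individuals), len(catalogue)), -1, dtype=np.int8)
    dropped = 0
    skipped_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            dropped += 1
            continue
        key = (rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        j = index.get(key)
        if j is None:
            dropped += 1
            continue
        # gt_types: 0 hom_ref, 1 het, 2 unknown, 3 hom_alt
        codes = np.array(rec.gt_types)
        col = np.select(
            [codes == 0, codes == 1, codes == 3], [0, 1, 2], default=-1
        ).astype(np.int8)
        genotypes[:, j] = col
    if skipped_multi:
        logger.warning("%s: skipped %d multi-allelic records", path, skipped_multi)
    if dropped:
        logger.info("%s: dropped %d records absent from the catalogue", path, dropped)
    return individuals, genotypes, dropped


# ---------------------------------------------------------------------------
# DTC array exports
# ---------------------------------------------------------------------------

def read_dtc_tsv(
    path: str | Path, catalogue: Sequence[MissenseVariant]
) -> tuple[np.ndarray, int]:
    """Read one individual's DTC-style genotype file.

    Dialect: tab-separated ``rsid chrom pos genotype`` with letter-pair
    genotypes (``AG``, ``GG``, ``--`` for no-calls); header lines start
    with ``#``.  Sites are matched to the catalogue by (chrom, pos) and
    the letters interpreted against the catalogue ref/alt alleles.
    Returns ``(dosage vector, n_dropped)``.
    """
    by_pos = {(v.chrom, v.pos): (j, v) for j, v in enumerate(catalogue)}
    genotype = np.full(len(catalogue), -1, dtype=np.int8)
    dropped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InputError(f"{path}:{line_no}: expected 4 columns")
            _, chrom, pos, call = parts
            entry = by_pos.get((chrom, int(pos)))
            if entry is None:
                dropped += 1
                continue
            j, v = entry
            if call in ("--", "", "00"):
                continue  # stays missing
            if len(call) != 2 or any(c not in (v.ref, v.alt) for c in call):
                logger.warning("%s:%d: genotype %r does not match %s/%s",
                               path, line_no, call, v.ref, v.alt)
                continue
            genotype[j] = sum(1 for c in call if c == v.alt)
    if dropped:
        logger.info("%s: dropped %d sites absent from the catalogue", path, dropped)
    return genotype, dropped


def read_genotypes(
    path: str | Path,
    format: str,
    catalogue: Sequence[MissenseVariant],
    individual_id: Optional[str] = None,
) -> tuple[list[str], np.ndarray]:
    """Dispatch to the VCF or DTC reader; returns (individuals, matrix)."""
    if format == "vcf":
        individuals, genotypes, _ = read_vcf(path, catalogue)
        return individuals, genotypes
    if format == "dtc_tsv":
        vec, _ = read_dtc_tsv(path, catalogue)
        name = individual_id or Path(path).stem
        return [name], vec[None, :]
    raise InputError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# World round-trip
# ---------------------------------------------------------------------------

def write_world(world, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a synthetic world to the formats the readers consume."""
    from .functional_model import write_domain_hits_tsv, write_emissions_tsv
    from .simulate import write_truth_json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hmms": out / "hmm_emissions.tsv",
        "hits": out / "domain_hits.tsv",
        "map": out / "domain_term_map.tsv",
        "ontology": out / "ontology.obo",
        "vcf": out / "cohort.vcf",
        "catalogue": out / "variant_catalogue.tsv",
        "truth": out / "truth.json",
    }
    write_emissions_tsv(world.hmms, paths["hmms"])
    write_domain_hits_tsv(world.hits, paths["hits"])
    world.domain_term_map.write_tsv(paths["map"])
    world.ontology.to_obo(paths["ontology"])
    write_vcf(world.variants, world.genotypes, world.individuals, paths["vcf"])
    write_variant_catalogue_tsv(world.variants, paths["catalogue"])
    write_truth_json(world.truth, paths["truth"])
    return paths


def write_variant_catalogue_tsv(
    variants: Sequence[MissenseVariant], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#variant_id\tchrom\tpos\tref\talt\tprotein_id\tresidue_index"
            "\tref_aa\talt_aa\tmaf\n"
        )
        for v in variants:
            fh.write(
                f"{v.variant_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
                f"\t{v.protein_id}\t{v.residue_index}\t{v.ref_aa}\t{v.alt_aa}"
                f"\t{v.maf:.17g}\n"
            )


def read_variant_catalogue_tsv(path: str | Path) -> list[MissenseVariant]:
    variants = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            (vid, chrom, pos, ref, alt, protein, res, ref_aa, alt_aa, maf
             ) = line.split("\t")
            variants.append(
                MissenseVariant(vid, chrom, int(pos), ref, alt, protein,
                                int(res), ref_aa, alt_aa, float(maf))
            )
    return variants


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``background_mode`` selects whether subjects are scored against an
    external background cohort or the cohort itself serves as background
    (every individual is then a subject).  ``term_filter`` restricts the
    run to a subset of ontology terms (e.g. one branch of the ontology).
    """

    background_mode: str = "external"
    params: ScoreParams = field(default_factory=ScoreParams)
    n_perm: int = 2000
    n_top: int = 25
    seed: int = 0
    delta_ic: float = 1.0
    term_filter: Optional[tuple[str, ...]] = None
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.background_mode not in ("external", "self"):
            raise InputError("background_mode must be 'external' or 'self'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = ScoreParams(**raw.pop("params", {}))
        if "term_filter" in raw and raw["term_filter"] is not None:
            raw["term_filter"] = tuple(raw["term_filter"])
        return cls(params=params, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)
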