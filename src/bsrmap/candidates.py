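"""Candidate-gene screening inside a mapping interval.

Intersects the called interval with a gene annotation, summarizes per-sample
expression (counts, FPKM, log2 fold changes between restorer and sterile
accessions), finds genes differentially expressed in the same direction in
both the parent comparison (restorer line vs CMS line) and the pool
comparison (restorer pool vs sterile pool), applies a presence/absence rule
(near-zero FPKM in every sterile sample, clearly expressed in every restorer
sample — the signature expected of a dominant restorer allele absent from
the sterile genome), and ranks the surviving candidates. Also provides the
ORF-length -> protein-length check and the marker-phenotype concordance used
to validate a mapping region.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .mapping import Interval

STERILE_SAMPLES = ("8A", "SP")
RESTORER_SAMPLES = ("R1", "RP")


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "+"

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class CandidateReport:
    genes_in_interval: list[str]
    detected_by_sample: dict[str, set[str]]
    detected_common: set[str]
    common_up: set[str]
    common_down: set[str]
    presence_absence: set[str]
    ranked: list[str]
    expression: pd.DataFrame = field(repr=False, default=None)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "genes_in_interval": self.genes_in_interval,
                    "n_detected_by_sample": {
                        s: len(g) for s, g in self.detected_by_sample.items()
                    },
                    "n_detected_common": len(self.detected_common),
                    "common_up": sorted(self.common_up),
                    "common_down": sorted(self.common_down),
                    "presence_absence": sorted(self.presence_absence),
                    "ranked": self.ranked,
                },
                fh,
                indent=2,
            )


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = [
        GeneModel(
            gene_id=f.id,
            chrom=f.seqid,
            start_bp=f.start,
            end_bp=f.end,
            strand=f.strand or "+",
        )
        for f in db.features_of_type("gene")
    ]
    return sorted(genes, key=lambda g: (g.chrom, g.start_bp))


def genes_in_interval(genes: Iterable[GeneModel], interval: Interval) -> list[GeneModel]:
    """Genes whose span overlaps the interval by at least one base."""
    return [
        g
        for g in genes
        if g.chrom == interval.chrom
        and g.start_bp <= interval.end_bp
        and g.end_bp >= interval.start_bp
    ]


def fpkm(counts: float, gene_length_bp: float, total_mapped_reads: float) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if gene_length_bp <= 0 or total_mapped_reads <= 0:
        raise ValueError("gene length and library size must be positive")
    return counts * 1e9 / (gene_length_bp * total_mapped_reads)


def log2_fold_change(
    fpkm_num: float, fpkm_den: float, pseudocount: float = 0.0
) -> float | None:
    """log2((num + pseudocount) / (den + pseudocount)); None when undefined.

    With a zero denominator and no pseudocount the fold change is undefined
    (reported downstream as a flag, never as +/-infinity).
    """
    num = fpkm_num + pseudocount
    den = fpkm_den + pseudocount
    if den == 0 or num == 0:
        return None
    return math.log2(num / den)


def classify_deg(log2fc: float | None, min_abs_log2fc: float = 1.0) -> str | None:
    """Classify a fold change as "up", "down" or None (not differential).

    An undefined fold change with a nonzero numerator counts as "up" (the
    gene is expressed only in the numerator sample); undefined with a zero
    numerator is not classifiable.
    """
    if log2fc is None:
        return None
    if log2fc >= min_abs_log2fc:
        return "up"
    if log2fc <= -min_abs_log2fc:
        return "down"
    return None


def expression_summary(
    expr: pd.DataFrame,
    samples: Sequence[str] = ("8A", "R1", "SP", "RP"),
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Augment an expression table with FPKM and log2 fold-change columns.

    ``expr`` needs ``gene_id``, ``length_bp`` and one ``counts_<sample>``
    column per sample. Library size is the per-sample total count over all
    genes in the table. Adds ``fpkm_<sample>``, ``log2fc_parents`` (restorer
    line over sterile line), ``log2fc_pools`` (restorer pool over sterile
    pool) and the matching ``*_undefined`` flags.
    """
    out = expr.copy()
    lib = {s: max(float(out[f"counts_{s}"].sum()), 1.0) for s in samples}
    for s in samples:
        out[f"fpkm_{s}"] = [
            fpkm(c, l, lib[s]) for c, l in zip(out[f"counts_{s}"], out["length_bp"])
        ]
    sterile_parent, restorer_parent, sterile_pool, restorer_pool = samples
    for label, num, den in (
        ("parents", restorer_parent, sterile_parent),
        ("pools", restorer_pool, sterile_pool),
    ):
        fcs = [
            log2_fold_change(a, b, pseudocount)
            for a, b in zip(out[f"fpkm_{num}"], out[f"fpkm_{den}"])
        ]
        out[f"log2fc_{label}"] = [float("nan") if v is None else v for v in fcs]
        out[f"log2fc_{label}_undefined"] = [v is None for v in fcs]
    return out


def deg_sets(
    summary: pd.DataFrame, comparison: str, min_abs_log2fc: float = 1.0
) -> tuple[set[str], set[str]]:
    """Up- and downregulated gene sets for one comparison ("parents"/"pools").

    Genes expressed only in the restorer sample of the pair (undefined fold
    change, nonzero numerator) are counted as upregulated.
    """
    num_sample = {"parents": "R1", "pools": "RP"}[comparison]
    up, down = set(), set()
    for row in summary.itertuples():
        if getattr(row, f"log2fc_{comparison}_undefined"):
            if getattr(row, f"fpkm_{num_sample}") > 0:
                up.add(row.gene_id)
            continue
        fc = getattr(row, f"log2fc_{comparison}")
        cls = classify_deg(fc, min_abs_log2fc)
        if cls == "up":
            up.add(row.gene_id)
        elif cls == "down":
            down.add(row.gene_id)
    return up, down


def overlap_candidates(
    deg_parents_up: set[str],
    deg_parents_down: set[str],
    deg_pools_up: set[str],
    deg_pools_down: set[str],
) -> tuple[set[str], set[str]]:
    """Genes differential in the same direction in both comparisons."""
    return deg_parents_up & deg_pools_up, deg_parents_down & deg_pools_down


def presence_absence_screen(
    summary: pd.DataFrame,
    sterile_samples: Sequence[str] = STERILE_SAMPLES,
    restorer_samples: Sequence[str] = RESTORER_SAMPLES,
    absent_fpkm_max: float = 0.5,
    present_fpkm_min: float = 5.0,
) -> set[str]:
    """Genes absent (FPKM <= ``absent_fpkm_max``) in every sterile sample and
    expressed (FPKM >= ``present_fpkm_min``) in every restorer sample."""
    selected = set()
    for row in summary.itertuples():
        absent = all(
            getattr(row, f"fpkm_{s}") <= absent_fpkm_max for s in sterile_samples
        )
        present = all(
            getattr(row, f"fpkm_{s}") >= present_fpkm_min for s in restorer_samples
        )
        if absent and present:
            selected.add(row.gene_id)
    return selected


def rank_candidates(report: CandidateReport) -> list[str]:
    """Order candidate genes by strength of evidence.

    Tier 1: in both the common-upregulated set and the presence/absence set;
    tier 2: common-upregulated only; tier 3: presence/absence only. Ties
    break by pools log2 fold change descending (an undefined fold change with
    restorer-pool expression ranks above any finite value), then gene id.
    """
    summary = report.expression
    fc_by_gene: dict[str, float] = {}
    for row in summary.itertuples():
        if row.log2fc_pools_undefined:
            fc_by_gene[row.gene_id] = math.inf if row.fpkm_RP > 0 else -math.inf
        else:
            fc_by_gene[row.gene_id] = row.log2fc_pools

    def tier(g: str) -> int:
        in_up = g in report.common_up
        in_pa = g in report.presence_absence
        if in_up and in_pa:
            return 1
        if in_up:
            return 2
        return 3

    candidates = sorted(
        report.common_up | report.presence_absence,
        key=lambda g: (tier(g), -fc_by_gene.get(g, -math.inf), g),
    )
    return candidates


def screen_candidates(
    genes: Sequence[GeneModel],
    interval: Interval,
    expr: pd.DataFrame,
    samples: Sequence[str] = ("8A", "R1", "SP", "RP"),
    min_abs_log2fc: float = 1.0,
    absent_fpkm_max: float = 0.5,
    present_fpkm_min: float = 5.0,
    pseudocount: float = 0.0,
) -> CandidateReport:
    """Full screen: interval genes -> expression summary -> DEG overlap +
    presence/absence -> ranked candidates.

    FPKM library sizes are computed over the whole expression table before
    restricting to the interval; "detected" means counts > 0.
    """
    summary_all = expression_summary(expr, samples, pseudocount)
    in_interval = genes_in_interval(genes, interval)
    ids = [g.gene_id for g in in_interval]
    summary = summary_all[summary_all["gene_id"].isin(ids)].reset_index(drop=True)

    detected = {
        s: set(summary.loc[summary[f"counts_{s}"] > 0, "gene_id"]) for s in samples
    }
    detected_common = set.intersection(*detected.values()) if detected else set()

    p_up, p_down = deg_sets(summary, "parents", min_abs_log2fc)
    q_up, q_down = deg_sets(summary, "pools", min_abs_log2fc)
    common_up, common_down = overlap_candidates(p_up, p_down, q_up, q_down)
    pa = presence_absence_screen(
        summary, STERILE_SAMPLES, RESTORER_SAMPLES, absent_fpkm_max, present_fpkm_min
    )

    report = CandidateReport(
        genes_in_interval=ids,
        detected_by_sample=detected,
        detected_common=detected_common,
        common_up=common_up,
        common_down=common_down,
        presence_absence=pa,
        ranked=[],
        expression=summary,
    )
    report.ranked = rank_candidates(report)
    return report


def orf_protein_length(orf_length_nt: int) -> int:
    """Residues encoded by an ORF, excluding the terminal stop codon."""
    if orf_length_nt < 6 or orf_length_nt % 3:
        raise ValueError(
            f"ORF length {orf_length_nt} is not a whole number of codons >= 2"
        )
    return orf_length_nt // 3 - 1


def marker_phenotype_concordance(
    genotypes: Sequence[int | bool], phenotypes: Sequence[bool]
) -> float:
    """Fraction of individuals whose marker genotype predicts their phenotype.

    Under the dominant model a carrier of the restorer-linked marker allele
    (genotype truthy, e.g. 1 or 2 copies) is predicted fertile; phenotypes
    are True for fertile.
    """
    if len(genotypes) != len(phenotypes):
        raise ValueError("genotype and phenotype vectors differ in length")
    if len(genotypes) == 0:
        raise ValueError("empty input")
    hits = sum(bool(g) == bool(p) for g, p in zip(genotypes, phenotypes))
    return hits / len(genotypes)
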