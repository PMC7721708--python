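"""SNP filtering cascade for four-sample bulked-segregant designs.

The input is a multi-sample VCF holding the two parents of a cross (a
cytoplasmic-male-sterile seed parent and a fertility-restorer parent) and two
extreme-phenotype F2 pools (sterile pool, restorer pool), each with per-allele
read depths. The cascade removes clustered SNPs, low-quality and
poorly-supported sites, multi-allelic ("degenerate") sites and sites whose
pool genotypes are inconsistent with the corresponding parent or identical
between the two pools, leaving the polymorphic sites used for the
Euclidean-distance association scan.
"""

from __future__ import annotations

import json
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: genotype-class labels derived from pooled read depths
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

#: default alt-allele-fraction cutoffs for depth-based genotype classes
DEFAULT_HOM_REF_MAX_FRAC = 0.1
DEFAULT_HOM_ALT_MIN_FRAC = 0.9


class RoleError(KeyError):
    """A sample named in :class:`SampleRoles` is absent from the VCF."""


class OrderingError(ValueError):
    """Records handed to a positional filter are not sorted by (chrom, pos)."""


@dataclass(frozen=True)
class SampleRoles:
    """Maps the four experimental roles onto VCF sample ids."""

    sterile_parent: str = "8A"
    restorer_parent: str = "R1"
    sterile_pool: str = "SP"
    restorer_pool: str = "RP"

    def all(self) -> tuple[str, str, str, str]:
        return (
            self.sterile_parent,
            self.restorer_parent,
            self.sterile_pool,
            self.restorer_pool,
        )

    def __post_init__(self) -> None:
        if len(set(self.all())) != 4:
            raise RoleError("the four sample roles must be distinct ids")


@dataclass
class SnpRecord:
    """One biallelic-or-multiallelic SNP site with per-sample base depths.

    ``depth_by_base[sample]`` maps each of A/C/G/T to a read count; these
    depths are the A_RP, C_RP, ... terms of the ED statistic once converted
    to frequencies.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    depth_by_base: dict[str, dict[str, int]]

    def total_depth(self, sample: str) -> int:
        return sum(self.depth_by_base[sample].values())

    def site_depth(self) -> int:
        """Combined read depth over all samples, used to standardize QUAL."""
        return sum(self.total_depth(s) for s in self.depth_by_base)

    def alt_depth(self, sample: str) -> int:
        d = self.depth_by_base[sample]
        return sum(v for b, v in d.items() if b != self.ref)


def classify_genotype(
    record: SnpRecord,
    sample: str,
    hom_ref_max_frac: float = DEFAULT_HOM_REF_MAX_FRAC,
    hom_alt_min_frac: float = DEFAULT_HOM_ALT_MIN_FRAC,
) -> str:
    """Classify a sample's genotype at a site from its read depths.

    With alt-allele fraction ``f`` (non-reference reads over total reads):
    ``f <= hom_ref_max_frac`` is homozygous-reference, ``f >=
    hom_alt_min_frac`` homozygous-alternate, anything between heterozygous;
    zero depth is missing. The cutoffs are permissive enough to call pools
    (expected allele mixtures) het without demanding an exact 50/50 split.
    """
    total = record.total_depth(sample)
    if total == 0:
        return MISSING
    f = record.alt_depth(sample) / total
    if f <= hom_ref_max_frac:
        return HOM_REF
    if f >= hom_alt_min_frac:
        return HOM_ALT
    return HET


def read_variants(vcf_path: str, roles: SampleRoles) -> list[SnpRecord]:
    """Read a four-sample VCF into :class:`SnpRecord` objects.

    Per-sample base depths are populated from the allele-depth (AD) FORMAT
    field, mapped onto the REF/ALT bases. Multi-allelic sites are retained at
    this stage (removed later by :func:`filter_degenerate`); sites with indel
    or symbolic alleles are dropped and counted in a log message.
    """
    vcf = VCF(vcf_path)
    sample_index: dict[str, int] = {}
    for role_sample in roles.all():
        try:
            sample_index[role_sample] = vcf.samples.index(role_sample)
        except ValueError:
            raise RoleError(
                f"sample {role_sample!r} not present in {vcf_path} "
                f"(samples: {vcf.samples})"
            ) from None

    records: list[SnpRecord] = []
    n_excluded = 0
    for v in vcf:
        alleles = [v.REF, *v.ALT]
        if any(len(a) != 1 or a not in BASES for a in alleles):
            n_excluded += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"site {v.CHROM}:{v.POS} lacks the AD FORMAT field")
        depth_by_base: dict[str, dict[str, int]] = {}
        for sample, idx in sample_index.items():
            depths = {b: 0 for b in BASES}
            for allele, d in zip(alleles, ad[idx]):
                depths[allele] += max(int(d), 0)  # missing AD encoded negative
            depth_by_base[sample] = depths
        records.append(
            SnpRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                depth_by_base=depth_by_base,
            )
        )
    if n_excluded:
        logger.info("excluded %d non-SNP (indel/symbolic) sites", n_excluded)
    return records


def _check_sorted(records: Sequence[SnpRecord]) -> None:
    for a, b in zip(records, records[1:]):
        if a.chrom == b.chrom and a.pos > b.pos:
            raise OrderingError(
                f"records not sorted by (chrom, pos) at {b.chrom}:{b.pos}"
            )


def filter_cluster(
    records: Sequence[SnpRecord], max_snps: int = 3, window_bp: int = 35
) -> list[SnpRecord]:
    """Remove SNP clusters: more than ``max_snps`` SNPs within ``window_bp``.

    A window of ``window_bp`` bases starting at position p covers
    [p, p + window_bp - 1]. Every SNP that lies in any same-chromosome window
    containing more than ``max_snps`` SNPs is removed — all members of an
    offending cluster go, not just the excess ones. Exactly ``max_snps`` SNPs
    in a window are permitted.
    """
    _check_sorted(records)
    removed: set[int] = set()
    # any offending window can be shifted left until its left edge is a SNP,
    # so anchoring windows at SNP positions is exhaustive
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_chrom.setdefault(r.chrom, []).append(i)
    for idxs in by_chrom.values():
        positions = [records[i].pos for i in idxs]
        for a in range(len(idxs)):
            b = a
            while b + 1 < len(idxs) and positions[b + 1] - positions[a] <= window_bp - 1:
                b += 1
            if b - a + 1 > max_snps:
                removed.update(idxs[a : b + 1])
    return [r for i, r in enumerate(records) if i not in removed]


def filter_quality(
    records: Sequence[SnpRecord], min_standardized_qual: float = 2.0
) -> list[SnpRecord]:
    """Keep sites whose QUAL standardized by combined depth exceeds the cutoff.

    The standardized quality is QUAL divided by the total read depth across
    all samples (the quality-by-depth convention); the comparison is strict.
    Zero-depth sites cannot be standardized and are removed.
    """
    kept = []
    for r in records:
        depth = r.site_depth()
        if depth > 0 and r.qual / depth > min_standardized_qual:
            kept.append(r)
    return kept


def filter_min_support(
    records: Sequence[SnpRecord], min_reads: int = 3
) -> list[SnpRecord]:
    """Remove sites where any sample is supported by fewer than ``min_reads``."""
    return [
        r
        for r in records
        if all(r.total_depth(s) >= min_reads for s in r.depth_by_base)
    ]


def filter_degenerate(records: Sequence[SnpRecord]) -> list[SnpRecord]:
    """Keep only biallelic SNPs (exactly one alternate base)."""
    return [r for r in records if len(r.alts) == 1]


def filter_parent_pool_consistency(
    records: Sequence[SnpRecord],
    roles: SampleRoles,
    hom_ref_max_frac: float = DEFAULT_HOM_REF_MAX_FRAC,
    hom_alt_min_frac: float = DEFAULT_HOM_ALT_MIN_FRAC,
) -> list[SnpRecord]:
    """Apply the parent/pool genotype consistency filters.

    (a) Discrepant sites — a pool called homozygous for the allele its own
    parent lacks (restorer pool vs restorer parent; sterile pool vs sterile
    parent) — are removed. A het pool never conflicts with a homozygous
    parent, because an F2 bulk is an expected allele mixture.
    (b) Consistent-type sites where the two pools are homozygous for the
    same allele (no polymorphism between the pools) are removed. Sites
    heterozygous in both pools are kept: their allele frequencies can still
    differ, and they form the background of the association scan. Sites with
    a missing genotype in any sample are removed and counted in a log
    message.
    """
    kept = []
    n_missing = 0
    for r in records:
        cls = {
            s: classify_genotype(r, s, hom_ref_max_frac, hom_alt_min_frac)
            for s in roles.all()
        }
        if MISSING in cls.values():
            n_missing += 1
            continue
        if _hom_conflict(cls[roles.restorer_pool], cls[roles.restorer_parent]):
            continue
        if _hom_conflict(cls[roles.sterile_pool], cls[roles.sterile_parent]):
            continue
        rp_cls, sp_cls = cls[roles.restorer_pool], cls[roles.sterile_pool]
        if rp_cls == sp_cls and rp_cls in (HOM_REF, HOM_ALT):
            continue
        kept.append(r)
    if n_missing:
        logger.info("removed %d sites with a missing genotype", n_missing)
    return kept


def _hom_conflict(pool_class: str, parent_class: str) -> bool:
    homs = (HOM_REF, HOM_ALT)
    return (
        pool_class in homs and parent_class in homs and pool_class != parent_class
    )


#: cascade stages in execution order
CASCADE_STAGES = ("input", "cluster", "quality", "degenerate", "min_support", "consistency")


def run_filter_cascade(
    records: Sequence[SnpRecord],
    roles: SampleRoles,
    max_cluster_snps: int = 3,
    cluster_window_bp: int = 35,
    min_standardized_qual: float = 2.0,
    min_reads: int = 3,
) -> "OrderedDict[str, list[SnpRecord]]":
    """Run the full filtering cascade, returning the record set at each stage."""
    stages: "OrderedDict[str, list[SnpRecord]]" = OrderedDict()
    stages["input"] = list(records)
    stages["cluster"] = filter_cluster(stages["input"], max_cluster_snps, cluster_window_bp)
    stages["quality"] = filter_quality(stages["cluster"], min_standardized_qual)
    stages["degenerate"] = filter_degenerate(stages["quality"])
    stages["min_support"] = filter_min_support(stages["degenerate"], min_reads)
    stages["consistency"] = filter_parent_pool_consistency(stages["min_support"], roles)
    return stages


@dataclass
class FilterReport:
    """Per-sample hom/het/total tallies per cascade stage plus the
    per-chromosome distribution of the retained SNPs."""

    stage_tallies: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    chrom_counts: dict[str, int] = field(default_factory=dict)
    chrom_percentages: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "stage_tallies": self.stage_tallies,
                    "chrom_counts": self.chrom_counts,
                    "chrom_percentages": self.chrom_percentages,
                },
                fh,
                indent=2,
            )


def tally_report(
    records_by_stage: Mapping[str, Iterable[SnpRecord]], roles: SampleRoles
) -> FilterReport:
    """Tabulate hom/het/total SNP counts per sample and stage, and the
    chromosome distribution of the final stage's sites.

    Totals count called genotypes only (hom + het = total); sites where a
    sample's genotype is missing do not contribute to that sample's tally.
    """
    report = FilterReport()
    final_stage: list[SnpRecord] = []
    for stage, records in records_by_stage.items():
        records = list(records)
        final_stage = records
        tallies: dict[str, dict[str, int]] = {}
        for sample in roles.all():
            hom = het = 0
            for r in records:
                c = classify_genotype(r, sample)
                if c in (HOM_REF, HOM_ALT):
                    hom += 1
                elif c == HET:
                    het += 1
            tallies[sample] = {"hom": hom, "het": het, "total": hom + het}
        report.stage_tallies[stage] = tallies
    for r in final_stage:
        report.chrom_counts[r.chrom] = report.chrom_counts.get(r.chrom, 0) + 1
    n = sum(report.chrom_counts.values())
    if n:
        report.chrom_percentages = {
            c: 100.0 * k / n for c, k in report.chrom_counts.items()
        }
    return report


def write_sites_tsv(records: Sequence[SnpRecord], roles: SampleRoles, path: str) -> None:
    """Write filtered sites as a TSV consumed by the association stage."""
    samples = roles.all()
    with open(path, "w") as fh:
        cols = ["chrom", "pos", "ref", "alt", "qual"]
        for s in samples:
            cols += [f"{s}_{b}" for b in BASES]
            cols.append(f"{s}_class")
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.chrom, str(r.pos), r.ref, ",".join(r.alts), f"{r.qual:g}"]
            for s in samples:
                row += [str(r.depth_by_base[s][b]) for b in BASES]
                row.append(classify_genotype(r, s))
            fh.write("\t".join(row) + "\n")


def read_sites_tsv(path: str, roles: SampleRoles) -> list[SnpRecord]:
    """Read a sites TSV written by :func:`write_sites_tsv`."""
    records: list[SnpRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            depth_by_base = {
                s: {b: int(f[col[f"{s}_{b}"]]) for b in BASES} for s in roles.all()
            }
            records.append(
                SnpRecord(
                    chrom=f[col["chrom"]],
                    pos=int(f[col["pos"]]),
                    ref=f[col["ref"]],
                    alts=tuple(f[col["alt"]].split(",")),
                    qual=float(f[col["qual"]]),
                    depth_by_base=depth_by_base,
                )
            )
    return records
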