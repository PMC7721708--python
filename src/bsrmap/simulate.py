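"""Synthetic F2 bulk-segregant data with known truth.

Emulates the cross behind a restorer-of-fertility mapping experiment: a
cytoplasmic-male-sterile (CMS) seed parent crossed to a restorer line, F1
selfed, and two extreme-phenotype F2 pools sequenced. All F2 carry sterile
cytoplasm (the mother is the CMS line), so the phenotype is governed by a
single dominant nuclear restorer locus Rf: Rf/- individuals are fertile,
rf/rf sterile. The sterile bulk is therefore pure rf/rf while the restorer
bulk is a 1:2 mix of Rf/Rf and Rf/rf, giving an expected alternate-allele
frequency of 2/3 at the causal site in the restorer pool and 0 in the
sterile pool.

Crossovers per chromosome per meiosis are Poisson with uniform positions (no
interference), so the recombination fraction at physical distance d on a
chromosome of length L is Haldane's r = (1 - exp(-2*lambda))/2 with lambda =
recomb_rate * d / L. Conditioning chromosomes on the bulk phenotype gives the
expected alternate frequencies recorded in :class:`SimTruth`:

    sterile pool:  E[f_alt] = r
    restorer pool: E[f_alt] = 2/3 * (1 - r) + 1/3 * r = 2/3 - r/3

Read depths are negative-binomial per sample per site; each read's allele is
drawn from the bulk's genotype-weighted allele frequency. Parents are pure
opposite homozygotes at every marker, so every simulated site is fully
informative; non-informative markers for filter tests are injected by the
test suite, not here. Expression is simulated at the count level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import BASES, SampleRoles, SnpRecord

SAMPLES = ("8A", "R1", "SP", "RP")  # sterile parent, restorer parent, pools


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study design of the simulated mapping experiment.

    Defaults are the conditions used throughout the test suite: three
    chromosomes of 20 Mb with 2000 SNPs each, the causal locus mid-way along
    the second chromosome, 200 F2 individuals, 20 per bulk, 50x mean depth.
    """

    n_chromosomes: int = 3
    chrom_length_bp: int = 20_000_000
    n_snps_per_chrom: int = 2000
    causal_chrom: str = "Chr02"
    causal_pos_bp: int = 10_000_000
    n_f2: int = 200
    bulk_size: int = 20
    mean_depth: float = 50.0
    depth_dispersion: float = 5.0  # negative-binomial size; larger = less overdispersed
    recomb_rate: float = 2.0  # expected crossovers per chromosome per meiosis
    error_rate: float = 0.0  # per-read miscall probability
    n_genes: int = 300
    expr_mean: float = 500.0
    expr_dispersion: float = 10.0
    causal_gene_fold: float = 10.0
    causal_sterile_frac: float = 0.0  # causal-gene mean in sterile samples, as a fraction of expr_mean
    null_bulks: bool = False  # draw both bulks from all F2, ignoring phenotype
    seed: int = 0

    def chromosomes(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_snps_per_chrom": self.n_snps_per_chrom,
            "n_f2": self.n_f2,
            "bulk_size": self.bulk_size,
            "mean_depth": self.mean_depth,
            "depth_dispersion": self.depth_dispersion,
            "expr_mean": self.expr_mean,
            "expr_dispersion": self.expr_dispersion,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.recomb_rate < 0 or not 0 <= self.error_rate < 1:
            raise ConfigError("recomb_rate must be >= 0 and error_rate in [0, 1)")
        if self.causal_chrom not in self.chromosomes():
            raise ConfigError(f"causal_chrom {self.causal_chrom!r} not among {self.chromosomes()}")
        if not 1 <= self.causal_pos_bp <= self.chrom_length_bp:
            raise ConfigError("causal_pos_bp must lie on the chromosome")
        if self.n_genes < 0 or self.causal_gene_fold < 0 or self.causal_sterile_frac < 0:
            raise ConfigError("n_genes, causal_gene_fold and causal_sterile_frac must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    causal_chrom: str
    causal_pos_bp: int
    #: per-site expected alternate-allele frequencies, aligned with the records
    expected_rp_freq: np.ndarray = field(repr=False, default=None)
    expected_sp_freq: np.ndarray = field(repr=False, default=None)
    site_chrom: list[str] = field(repr=False, default=None)
    site_pos: np.ndarray = field(repr=False, default=None)
    #: True = fertile (Rf carrier) for each F2 individual
    phenotypes: np.ndarray = field(repr=False, default=None)
    causal_gene: str | None = None


def _recomb_fraction(distance_bp: np.ndarray, config: SimConfig) -> np.ndarray:
    lam = config.recomb_rate * distance_bp / config.chrom_length_bp
    return 0.5 * (1.0 - np.exp(-2.0 * lam))


def _gametes(rng: np.random.Generator, positions: np.ndarray, n: int, config: SimConfig) -> np.ndarray:
    """Simulate n gametes from a fully heterozygous F1 on one chromosome.

    Returns an (n, n_sites) 0/1 array: 1 = allele from the restorer parent.
    """
    out = np.empty((n, positions.size), dtype=np.int8)
    n_co = rng.poisson(config.recomb_rate, size=n)
    phases = rng.integers(0, 2, size=n)
    for i in range(n):
        if n_co[i] == 0:
            out[i] = phases[i]
            continue
        breaks = np.sort(rng.uniform(0, config.chrom_length_bp, size=n_co[i]))
        out[i] = (phases[i] + np.searchsorted(breaks, positions)) % 2
    return out


def _sample_depths(
    rng: np.random.Generator, alt_freq: np.ndarray, ref_idx: np.ndarray,
    alt_idx: np.ndarray, config: SimConfig,
) -> np.ndarray:
    """Draw per-site A/C/G/T read counts for one sample.

    Total depth is negative-binomial (mean ``mean_depth``, size
    ``depth_dispersion``); each read is alt with probability ``alt_freq`` and
    miscalled to a uniform other base with probability ``error_rate``.
    """
    n = alt_freq.size
    size = config.depth_dispersion
    p = size / (size + config.mean_depth)
    total = rng.negative_binomial(size, p, size=n)
    alt = rng.binomial(total, alt_freq)
    ref = total - alt
    counts = np.zeros((n, 4), dtype=np.int64)
    if config.error_rate > 0:
        for truth_idx, n_true in ((ref_idx, ref), (alt_idx, alt)):
            errors = rng.binomial(n_true, config.error_rate)
            correct = n_true - errors
            np.add.at(counts, (np.arange(n), truth_idx), correct)
            # distribute miscalls uniformly over the three other bases
            for k in range(n):
                if errors[k]:
                    others = [b for b in range(4) if b != truth_idx[k]]
                    counts[k, others] += rng.multinomial(errors[k], [1 / 3] * 3)
    else:
        np.add.at(counts, (np.arange(n), ref_idx), ref)
        np.add.at(counts, (np.arange(n), alt_idx), alt)
    return counts


def simulate_f2_bulks(config: SimConfig) -> tuple[list[SnpRecord], SimTruth]:
    """Simulate the four-sample variant table of an F2 bulk-segregant design.

    Returns one :class:`SnpRecord` per simulated SNP (parents fixed opposite
    homozygotes, pool depths sampled from the bulks' true allele frequencies)
    and the :class:`SimTruth` with expected pool frequencies per site.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base_idx = {b: i for i, b in enumerate(BASES)}

    # SNP positions per chromosome; the causal position is itself a marker
    positions: dict[str, np.ndarray] = {}
    for chrom in config.chromosomes():
        pos = rng.choice(config.chrom_length_bp, size=config.n_snps_per_chrom, replace=False) + 1
        if chrom == config.causal_chrom:
            pos = np.concatenate([pos, [config.causal_pos_bp]])
        positions[chrom] = np.unique(pos)

    # F2 genotypes: two gametes per individual per chromosome
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in config.chromosomes():
        h1 = _gametes(rng, positions[chrom], config.n_f2, config)
        h2 = _gametes(rng, positions[chrom], config.n_f2, config)
        haplotypes[chrom] = (h1, h2)

    causal_site = int(np.searchsorted(positions[config.causal_chrom], config.causal_pos_bp))
    h1c, h2c = haplotypes[config.causal_chrom]
    rf_copies = h1c[:, causal_site] + h2c[:, causal_site]
    fertile = rf_copies >= 1  # dominant restorer

    if config.null_bulks:
        chosen = rng.choice(config.n_f2, size=2 * config.bulk_size, replace=False)
        sterile_bulk = chosen[: config.bulk_size]
        restorer_bulk = chosen[config.bulk_size :]
    else:
        sterile_pool_candidates = np.flatnonzero(~fertile)
        restorer_pool_candidates = np.flatnonzero(fertile)
        for name, cand in (
            ("sterile", sterile_pool_candidates),
            ("restorer", restorer_pool_candidates),
        ):
            if cand.size < config.bulk_size:
                raise ConfigError(
                    f"only {cand.size} {name} F2 individuals for a bulk of {config.bulk_size}; "
                    "increase n_f2"
                )
        sterile_bulk = rng.choice(sterile_pool_candidates, size=config.bulk_size, replace=False)
        restorer_bulk = rng.choice(restorer_pool_candidates, size=config.bulk_size, replace=False)

    records: list[SnpRecord] = []
    site_chrom: list[str] = []
    site_pos: list[int] = []
    exp_rp: list[np.ndarray] = []
    exp_sp: list[np.ndarray] = []
    for chrom in config.chromosomes():
        pos = positions[chrom]
        n = pos.size
        h1, h2 = haplotypes[chrom]
        sp_freq = (h1[sterile_bulk].sum(0) + h2[sterile_bulk].sum(0)) / (2 * config.bulk_size)
        rp_freq = (h1[restorer_bulk].sum(0) + h2[restorer_bulk].sum(0)) / (2 * config.bulk_size)

        if config.null_bulks or chrom != config.causal_chrom:
            r = np.full(n, 0.5)
        else:
            r = _recomb_fraction(np.abs(pos - config.causal_pos_bp), config)
        if config.null_bulks:
            e_sp = np.full(n, 0.5)
            e_rp = np.full(n, 0.5)
        else:
            e_sp = r
            e_rp = 2.0 / 3.0 - r / 3.0

        # ref carried by the sterile parent, alt by the restorer parent
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        sample_freqs = {
            "8A": np.zeros(n),
            "R1": np.ones(n),
            "SP": sp_freq,
            "RP": rp_freq,
        }
        depths = {
            s: _sample_depths(rng, f, ref_idx, alt_idx, config)
            for s, f in sample_freqs.items()
        }
        site_depth = sum(d.sum(1) for d in depths.values())
        qual = np.round(site_depth * rng.uniform(2.2, 8.0, size=n), 2)

        for k in range(n):
            depth_by_base = {
                s: {b: int(depths[s][k, base_idx[b]]) for b in BASES} for s in SAMPLES
            }
            records.append(
                SnpRecord(
                    chrom=chrom,
                    pos=int(pos[k]),
                    ref=BASES[ref_idx[k]],
                    alts=(BASES[alt_idx[k]],),
                    qual=float(qual[k]),
                    depth_by_base=depth_by_base,
                )
            )
        site_chrom += [chrom] * n
        site_pos.append(pos)
        exp_sp.append(e_sp)
        exp_rp.append(e_rp)

    truth = SimTruth(
        causal_chrom=config.causal_chrom,
        causal_pos_bp=config.causal_pos_bp,
        expected_rp_freq=np.concatenate(exp_rp),
        expected_sp_freq=np.concatenate(exp_sp),
        site_chrom=site_chrom,
        site_pos=np.concatenate(site_pos),
        phenotypes=fertile,
    )
    return records, truth


def make_gene_models(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place ``n_genes`` uniformly over the chromosomes.

    One gene is guaranteed to span the causal position; its id becomes the
    causal gene. Lengths are uniform in 0.5-5 kb.
    """
    chroms = config.chromosomes()
    rows = []
    lengths = rng.integers(500, 5001, size=config.n_genes) if config.n_genes else []
    for g in range(config.n_genes):
        chrom = chroms[g % len(chroms)]
        start = int(rng.integers(1, max(config.chrom_length_bp - int(lengths[g]), 2)))
        rows.append(
            {
                "gene_id": f"G{g + 1:04d}",
                "chrom": chrom,
                "start_bp": start,
                "end_bp": start + int(lengths[g]) - 1,
                "strand": "+" if rng.integers(0, 2) else "-",
            }
        )
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp", "strand"])
    if config.n_genes:
        # relocate the gene nearest the causal site to span it exactly
        on_chrom = genes.index[genes["chrom"] == config.causal_chrom]
        mid = (genes.loc[on_chrom, "start_bp"] + genes.loc[on_chrom, "end_bp"]) / 2
        causal_idx = (mid - config.causal_pos_bp).abs().idxmin()
        length = int(genes.at[causal_idx, "end_bp"] - genes.at[causal_idx, "start_bp"])
        start = max(1, config.causal_pos_bp - length // 2)
        genes.at[causal_idx, "start_bp"] = start
        genes.at[causal_idx, "end_bp"] = start + length
        genes = genes.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)
    return genes


def simulate_expression(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Simulate per-gene, per-sample expression counts.

    Background genes draw counts from a negative binomial with mean
    ``expr_mean``; the gene spanning the causal locus has its mean multiplied
    by ``causal_gene_fold`` in the restorer samples (R1, RP) and set to
    ``causal_sterile_frac * expr_mean`` (default 0) in the sterile samples
    (8A, SP). Updates ``truth.causal_gene`` in place.

    Returns a table with gene coordinates, length, and one count column per
    sample (``counts_8A`` ... ``counts_RP``).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = make_gene_models(config, rng)
    n = len(genes)
    if n == 0:
        for s in SAMPLES:
            genes[f"counts_{s}"] = pd.Series(dtype=int)
        genes["length_bp"] = pd.Series(dtype=int)
        return genes
    genes["length_bp"] = genes["end_bp"] - genes["start_bp"] + 1

    causal_mask = np.zeros(n, dtype=bool)
    overlaps = (
        (genes["chrom"] == truth.causal_chrom)
        & (genes["start_bp"] <= truth.causal_pos_bp)
        & (genes["end_bp"] >= truth.causal_pos_bp)
    )
    if overlaps.any():
        causal_idx = int(genes.index[overlaps][0])
        causal_mask[causal_idx] = True
        truth.causal_gene = genes.at[causal_idx, "gene_id"]

    size = config.expr_dispersion
    for s in SAMPLES:
        mean = np.full(n, config.expr_mean)
        if s in ("R1", "RP"):
            mean[causal_mask] = config.expr_mean * config.causal_gene_fold
        else:
            mean[causal_mask] = config.expr_mean * config.causal_sterile_frac
        counts = np.zeros(n, dtype=np.int64)
        nz = mean > 0
        counts[nz] = rng.negative_binomial(size, size / (size + mean[nz]))
        genes[f"counts_{s}"] = counts
    return genes


def write_simulated_inputs(
    records: list[SnpRecord],
    truth: SimTruth,
    expression: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the simulated experiment to disk.

    Emits a four-sample VCF v4.2 with AD depths, a GFF3 gene annotation, a
    TSV expression table and two truth tables (per-site expected frequencies
    and a key/value summary with exactly one causal-gene row). Output is
    byte-deterministic given the records.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "variants.vcf",
        "gff": out / "genes.gff3",
        "expression": out / "expression.tsv",
        "truth": out / "truth.tsv",
        "truth_sites": out / "truth_sites.tsv",
    }

    chrom_order = list(dict.fromkeys(r.chrom for r in records))
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsrmap-simulate\n")
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLES) + "\n")
        for r in records:
            cols = [
                r.chrom, str(r.pos), ".", r.ref, ",".join(r.alts),
                f"{r.qual:g}", "PASS", ".", "GT:AD",
            ]
            alleles = (r.ref, *r.alts)
            for s in SAMPLES:
                ad = [r.depth_by_base[s].get(a, 0) for a in alleles]
                total = sum(ad)
                alt = sum(ad[1:])
                if total == 0:
                    gt = "./."
                elif alt / total <= DEFAULTS_HOM_FRAC[0]:
                    gt = "0/0"
                elif alt / total >= DEFAULTS_HOM_FRAC[1]:
                    gt = "1/1"
                else:
                    gt = "0/1"
                cols.append(f"{gt}:" + ",".join(map(str, ad)))
            fh.write("\t".join(cols) + "\n")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for row in expression.itertuples():
            fh.write(
                f"{row.chrom}\tbsrmap\tgene\t{row.start_bp}\t{row.end_bp}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )

    expression.to_csv(paths["expression"], sep="\t", index=False)

    pd.DataFrame(
        {
            "chrom": truth.site_chrom,
            "pos": truth.site_pos,
            "expected_rp_alt_freq": truth.expected_rp_freq,
            "expected_sp_alt_freq": truth.expected_sp_freq,
        }
    ).to_csv(paths["truth_sites"], sep="\t", index=False)

    with open(paths["truth"], "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"causal_chrom\t{truth.causal_chrom}\n")
        fh.write(f"causal_pos_bp\t{truth.causal_pos_bp}\n")
        fh.write(f"causal_gene\t{truth.causal_gene}\n")
        fh.write(f"n_f2\t{truth.phenotypes.size}\n")
        fh.write(f"n_fertile\t{int(truth.phenotypes.sum())}\n")
    return paths


# hom-call alt-fraction cutoffs used when emitting VCF GT fields; mirrors
# filtering.classify_genotype defaults
DEFAULTS_HOM_FRAC = (0.1, 0.9)
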