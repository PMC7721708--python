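"""Tests of the SNP filtering cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsrmap import (
    SampleRoles,
    classify_genotype,
    filter_cluster,
    filter_degenerate,
    filter_min_support,
    filter_parent_pool_consistency,
    filter_quality,
    read_sites_tsv,
    read_variants,
    run_filter_cascade,
    tally_report,
    write_sites_tsv,
)
from bsrmap.filtering import HET, HOM_ALT, HOM_REF, MISSING, OrderingError, RoleError

from conftest import make_record


# ---------------------------------------------------------------- genotypes
@pytest.mark.parametrize(
    "depths, expected",
    [
        ({"A": 10, "G": 0}, HOM_REF),
        ({"A": 0, "G": 12}, HOM_ALT),
        ({"A": 6, "G": 6}, HET),
        ({"A": 0, "G": 0}, MISSING),
        ({"A": 9, "G": 1}, HOM_REF),  # f = 0.1 inclusive
        ({"A": 1, "G": 9}, HOM_ALT),  # f = 0.9 inclusive
    ],
)
def test_classify_genotype_from_depths(depths, expected):
    rec = make_record(depths={"SP": depths})
    assert classify_genotype(rec, "SP") == expected


# ------------------------------------------------------------------ reading
VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=Chr01>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t8A\tR1\tSP\tRP
"""


def write_vcf(path, body):
    path.write_text(VCF_HEADER + body)
    return str(path)


def test_read_variants_maps_allele_depths_onto_bases(tmp_path, roles):
    path = write_vcf(
        tmp_path / "t.vcf",
        "Chr01\t50\t.\tA\tG\t99\tPASS\t.\tGT:AD\t"
        "0/0:5,7\t1/1:0,9\t0/1:4,4\t0/1:3,6\n",
    )
    (rec,) = read_variants(path, roles)
    assert rec.depth_by_base["8A"] == {"A": 5, "C": 0, "G": 7, "T": 0}
    assert rec.depth_by_base["R1"] == {"A": 0, "C": 0, "G": 9, "T": 0}
    assert rec.qual == 99.0


def test_read_variants_drops_indels_and_keeps_multiallelic(tmp_path, roles):
    body = (
        "Chr01\t10\t.\tA\tG\t99\tPASS\t.\tGT:AD\t0/0:5,0\t1/1:0,5\t0/1:3,3\t0/1:3,3\n"
        "Chr01\t20\t.\tAT\tA\t99\tPASS\t.\tGT:AD\t0/0:5,0\t1/1:0,5\t0/1:3,3\t0/1:3,3\n"
        "Chr01\t30\t.\tA\tG,T\t99\tPASS\t.\tGT:AD\t0/0:5,0,0\t1/1:0,5,1\t0/1:3,3,0\t0/1:3,3,0\n"
    )
    records = read_variants(write_vcf(tmp_path / "t.vcf", body), roles)
    assert [r.pos for r in records] == [10, 30]
    assert records[1].alts == ("G", "T")
    assert records[1].depth_by_base["R1"] == {"A": 0, "C": 0, "G": 5, "T": 1}


def test_read_variants_unknown_sample_is_role_error(tmp_path):
    path = write_vcf(
        tmp_path / "t.vcf",
        "Chr01\t10\t.\tA\tG\t99\tPASS\t.\tGT:AD\t0/0:5,0\t1/1:0,5\t0/1:3,3\t0/1:3,3\n",
    )
    with pytest.raises(RoleError):
        read_variants(path, SampleRoles(sterile_parent="nope"))


# ----------------------------------------------------------- cluster filter
def positions_to_records(positions, chrom="Chr01"):
    return [make_record(chrom=chrom, pos=p) for p in sorted(positions)]


@pytest.mark.parametrize(
    "positions, survivors",
    [
        ([100, 110, 120, 130], []),  # 4 SNPs spanning 31 bp: whole cluster out
        ([100, 110, 120], [100, 110, 120]),  # exactly 3 in-window permitted
        ([100, 120, 140, 160], [100, 120, 140, 160]),  # no 35 bp window holds >3
        ([100, 110, 120, 130, 500], [500]),  # distant site survives the cluster
    ],
)
def test_cluster_filter_stated_rules(positions, survivors):
    out = filter_cluster(positions_to_records(positions))
    assert [r.pos for r in out] == survivors


def brute_force_cluster(positions, max_snps=3, window_bp=35):
    """Independent oracle: scan every possible window start position."""
    positions = sorted(positions)
    removed = set()
    if not positions:
        return []
    for start in range(positions[0] - window_bp, positions[-1] + 1):
        inside = [p for p in positions if start <= p <= start + window_bp - 1]
        if len(inside) > max_snps:
            removed.update(inside)
    return [p for p in positions if p not in removed]


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.integers(min_value=1, max_value=600), min_size=0, max_size=40, unique=True)
)
def test_cluster_filter_matches_exhaustive_window_scan(positions):
    out = filter_cluster(positions_to_records(positions))
    assert [r.pos for r in out] == brute_force_cluster(positions)


def test_cluster_filter_rejects_unsorted_input():
    records = [make_record(pos=200), make_record(pos=100)]
    with pytest.raises(OrderingError):
        filter_cluster(records)


# ------------------------------------------------- quality and read support
def test_quality_filter_standardizes_by_combined_depth():
    # 4 samples x 5 reads = depth 20
    d = {s: {"A": 5} for s in ("8A", "R1", "SP", "RP")}
    kept = make_record(qual=100.0, depths=d)  # 5.0 > 2.0
    removed = make_record(qual=30.0, depths=d)  # 1.5
    boundary = make_record(qual=40.0, depths=d)  # exactly 2.0: strict
    out = filter_quality([kept, removed, boundary])
    assert out == [kept]


def test_min_support_requires_every_sample():
    good = make_record(depths={s: {"A": 3} for s in ("8A", "R1", "SP", "RP")})
    weak_pool = make_record(
        depths={"8A": {"A": 9}, "R1": {"A": 9}, "SP": {"A": 2}, "RP": {"A": 9}}
    )
    assert filter_min_support([good, weak_pool]) == [good]
    assert filter_min_support([good, weak_pool], min_reads=0) == [good, weak_pool]


def test_degenerate_filter_keeps_only_biallelic():
    bi = make_record(alts=("G",))
    multi = make_record(pos=200, alts=("G", "T"))
    assert filter_degenerate([bi, multi]) == [bi]
    assert filter_degenerate([bi]) == [bi]


# ------------------------------------------------------- consistency filter
def consistency_case(p8a, pr1, psp, prp):
    """Record with the requested per-sample alt fractions at an A->G site."""
    def d(f):
        return {"A": round(20 * (1 - f)), "G": round(20 * f)}

    return make_record(depths={"8A": d(p8a), "R1": d(pr1), "SP": d(psp), "RP": d(prp)})


def test_consistency_keeps_informative_segregating_site(roles):
    rec = consistency_case(0.0, 1.0, 0.0, 0.5)  # SP hom_ref, RP het
    assert filter_parent_pool_consistency([rec], roles) == [rec]


def test_consistency_removes_pool_discrepant_with_parent(roles):
    rec = consistency_case(0.0, 1.0, 0.0, 0.0)  # RP hom_ref vs R1 hom_alt
    assert filter_parent_pool_consistency([rec], roles) == []


def test_consistency_removes_pools_fixed_for_same_allele(roles):
    rec = consistency_case(0.0, 1.0, 1.0, 1.0)  # both pools hom_alt
    assert filter_parent_pool_consistency([rec], roles) == []


def test_consistency_keeps_het_het_background(roles):
    """Sites heterozygous in both pools stay: their allele frequencies are
    the background of the association scan (they dominate the retained set
    in a real F2 design)."""
    rec = consistency_case(0.0, 1.0, 0.5, 0.5)
    assert filter_parent_pool_consistency([rec], roles) == [rec]


def test_consistency_drops_sites_with_missing_genotype(roles):
    rec = make_record(
        depths={"8A": {"A": 10}, "R1": {"G": 10}, "SP": {}, "RP": {"A": 5, "G": 5}}
    )
    assert filter_parent_pool_consistency([rec], roles) == []


# ------------------------------------------------------- cascade and report
def test_cascade_is_monotone_and_order_stable(default_sim, roles):
    _, records, _ = default_sim
    stages = run_filter_cascade(records, roles)
    previous = None
    for stage, recs in stages.items():
        keys = [(r.chrom, r.pos) for r in recs]
        assert keys == sorted(keys), f"stage {stage} broke ordering"
        if previous is not None:
            ids = {id(r) for r in previous}
            assert all(id(r) in ids for r in recs), f"stage {stage} not a subset"
            assert len(recs) <= len(previous)
        previous = recs


def test_tally_report_conserves_hom_plus_het(default_sim, roles):
    _, records, _ = default_sim
    stages = run_filter_cascade(records, roles)
    report = tally_report(stages, roles)
    for stage, tallies in report.stage_tallies.items():
        for sample, t in tallies.items():
            assert t["hom"] + t["het"] == t["total"], (stage, sample)
    assert sum(report.chrom_counts.values()) == len(stages["consistency"])
    assert sum(report.chrom_percentages.values()) == pytest.approx(100.0, abs=0.1)


def test_tally_report_empty_input_is_all_zero(roles):
    report = tally_report({"input": []}, roles)
    assert all(
        t == {"hom": 0, "het": 0, "total": 0}
        for t in report.stage_tallies["input"].values()
    )
    assert report.chrom_counts == {}


def test_sites_tsv_round_trip(tmp_path, roles):
    records = [
        make_record(pos=10, depths={"SP": {"A": 4, "G": 8}}),
        make_record(pos=50, ref="C", alts=("T",), depths={"RP": {"C": 3, "T": 9}}),
    ]
    path = tmp_path / "sites.tsv"
    write_sites_tsv(records, roles, str(path))
    back = read_sites_tsv(str(path), roles)
    assert back == records
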