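import numpy as np
import pandas as pd
import pytest

from imprintkit.counting import (
    GeneModel,
    SnpVariant,
    aggregate_gene_counts,
    assign_snps_to_genes,
    combine_crosses,
    count_snp_alleles,
    filter_min_counts,
    load_gene_models,
    load_snps,
    mask_reference,
)

CHROM_LEN = 100
# 1-based SNP positions with ref/alt; pos 95 is intergenic
SNPS = [
    SnpVariant("chr1", 21, "A", "G"),
    SnpVariant("chr1", 41, "C", "T"),
    SnpVariant("chr1", 61, "G", "A"),
    SnpVariant("chr1", 95, "A", "C"),
]

GENES = [
    GeneModel("geneA", "chr1", "+", [(10, 30), (25, 50)]),  # overlapping exons
    GeneModel("geneB", "chr1", "+", [(55, 90)]),
]


def reference_seq() -> str:
    seq = ["T"] * CHROM_LEN
    for v in SNPS:
        seq[v.pos - 1] = v.ref
    return "".join(seq)


def write_fasta(path, name="chr1", seq=None, width=60):
    seq = seq or reference_seq()
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def sam_line(name, pos, seq, qual=None, flag=0, mapq=60, chrom="chr1", tags=()):
    qual = qual or "I" * len(seq)  # phred 40
    fields = [
        name, str(flag), chrom, str(pos), str(mapq), f"{len(seq)}M",
        "*", "0", "0", seq, qual,
    ]
    fields += list(tags)
    return "\t".join(fields)


def write_sam(path, lines):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:chr1\tLN:{CHROM_LEN}\n")
        for line in lines:
            fh.write(line + "\n")


def read_seq(start_1based, length, overrides=None):
    """Reference-matching read sequence with optional {1-based pos: base}."""
    ref = reference_seq()
    seq = list(ref[start_1based - 1 : start_1based - 1 + length])
    for pos, base in (overrides or {}).items():
        seq[pos - start_1based] = base
    return "".join(seq)


# -- reference masking ---------------------------------------------------


def test_mask_with_no_variants_is_identity(tmp_path):
    fa = tmp_path / "ref.fa"
    out = tmp_path / "masked.fa"
    write_fasta(fa)
    mask_reference(fa, [], out)
    assert out.read_text() == fa.read_text()


def test_mask_single_position_zero_based_offset(tmp_path):
    fa = tmp_path / "ref.fa"
    out = tmp_path / "masked.fa"
    write_fasta(fa, seq="ACGTACGTAC")
    mask_reference(fa, [SnpVariant("chr1", 5, "A", "G")], out)
    masked = out.read_text().splitlines()[1]
    assert masked == "ACGTNCGTAC"  # exactly one N, at offset 4
    assert masked.count("N") == 1


def test_mask_adds_one_n_per_variant(tmp_path):
    fa = tmp_path / "ref.fa"
    out = tmp_path / "masked.fa"
    write_fasta(fa)
    variants = [v for v in SNPS]
    mask_reference(fa, variants, out)
    ref = reference_seq()
    masked = "".join(out.read_text().splitlines()[1:])
    assert masked.count("N") == ref.count("N") + len(variants)
    # all other bases byte-identical
    for i, (a, b) in enumerate(zip(ref, masked)):
        if i + 1 not in {v.pos for v in variants}:
            assert a == b


def test_mask_out_of_bounds_names_variant(tmp_path):
    fa = tmp_path / "ref.fa"
    write_fasta(fa, seq="ACGTACGTAC")
    with pytest.raises(ValueError, match="chr1:500"):
        mask_reference(fa, [SnpVariant("chr1", 500, "A", "G")], tmp_path / "o.fa")


# -- SNP allele counting -------------------------------------------------


def test_one_count_at_leftmost_snp(tmp_path):
    """A read spanning two SNPs with high-quality bases contributes a
    single observation, at the leftmost SNP."""
    sam = tmp_path / "a.sam"
    write_sam(sam, [sam_line("r1", 15, read_seq(15, 30))])  # covers SNPs 21 & 41
    res = count_snp_alleles(sam, SNPS)
    assert res.counts.loc[("chr1", 21), "ref_count"] == 1
    assert res.counts.loc[("chr1", 41)].sum() == 0
    assert res.n_reads_counted == 1


def test_low_quality_base_not_counted(tmp_path):
    sam = tmp_path / "a.sam"
    qual = ["I"] * 20
    qual[21 - 12] = chr(19 + 33)  # phred 19 at the only covered SNP
    write_sam(sam, [sam_line("r1", 12, read_seq(12, 20), qual="".join(qual))])
    res = count_snp_alleles(sam, SNPS, min_base_quality=20)
    assert res.n_reads_counted == 0
    assert res.counts.loc[("chr1", 21), "skipped_lowqual"] == 1


def test_low_quality_at_first_snp_counts_next(tmp_path):
    """The leftmost *usable* base wins: a low-quality base at the first
    SNP lets the read count at the next covered SNP."""
    sam = tmp_path / "a.sam"
    qual = ["I"] * 30
    qual[21 - 15] = chr(10 + 33)
    write_sam(sam, [sam_line("r1", 15, read_seq(15, 30, {41: "T"}), qual="".join(qual))])
    res = count_snp_alleles(sam, SNPS)
    assert res.counts.loc[("chr1", 41), "alt_count"] == 1
    assert res.counts.loc[("chr1", 21)].drop("skipped_lowqual").sum() == 0


def test_non_unique_reads_skipped(tmp_path):
    sam = tmp_path / "a.sam"
    write_sam(
        sam,
        [
            sam_line("multi", 15, read_seq(15, 20), tags=("NH:i:3",)),
            sam_line("lowmapq", 15, read_seq(15, 20), mapq=5),
            sam_line("good", 15, read_seq(15, 20), tags=("NH:i:1",)),
        ],
    )
    res = count_snp_alleles(sam, SNPS, unique_only=True)
    assert res.counts.loc[("chr1", 21), "ref_count"] == 1


def test_mismatching_base_tallied_separately(tmp_path):
    sam = tmp_path / "a.sam"
    write_sam(sam, [sam_line("r1", 12, read_seq(12, 20, {21: "C"}))])  # neither allele
    res = count_snp_alleles(sam, SNPS)
    assert res.n_reads_counted == 0
    assert res.counts.loc[("chr1", 21), "other_base"] == 1


def test_mate_pair_same_snp_counted_once(tmp_path):
    sam = tmp_path / "a.sam"
    write_sam(
        sam,
        [
            sam_line("frag", 50, read_seq(50, 20), flag=99),  # covers SNP 61
            sam_line("frag", 55, read_seq(55, 20), flag=147),  # covers SNP 61 too
            sam_line("other", 50, read_seq(50, 20), flag=99),
        ],
    )
    res = count_snp_alleles(sam, SNPS)
    assert res.counts.loc[("chr1", 61), "ref_count"] == 2  # frag once + other


def test_contig_mismatch_reports_offenders(tmp_path):
    sam = tmp_path / "a.sam"
    write_sam(sam, [sam_line("r1", 15, read_seq(15, 20))])
    bad = [SnpVariant("chr9", 5, "A", "G")]
    with pytest.raises(ValueError, match="chr9"):
        count_snp_alleles(sam, bad)


def test_counts_match_brute_force_oracle(tmp_path):
    """30 generated reads with randomized alleles/qualities: the counter
    agrees with an independent per-read tally."""
    rng = np.random.default_rng(17)
    snp_pos = [21, 41, 61]
    reads = []
    for i in range(30):
        start = int(rng.integers(5, 75))
        length = 25
        overrides, quals = {}, ["I"] * length
        for v in SNPS:
            if start <= v.pos < start + length:
                overrides[v.pos] = str(rng.choice([v.ref, v.alt, "N"]))
                if rng.random() < 0.3:
                    quals[v.pos - start] = chr(int(rng.integers(5, 19)) + 33)
        reads.append(
            ("r%d" % i, start, read_seq(start, length, overrides), "".join(quals))
        )
    sam = tmp_path / "a.sam"
    write_sam(sam, [sam_line(n, s, q, qual) for n, s, q, qual in reads])
    res = count_snp_alleles(sam, SNPS)

    # independent oracle: leftmost covered SNP with usable, allele-matching base
    expect = {v.pos: [0, 0] for v in SNPS}
    by_pos = {v.pos: v for v in SNPS}
    for _, start, seq, qual in reads:
        for pos in sorted(by_pos):
            if not (start <= pos < start + len(seq)):
                continue
            base = seq[pos - start]
            q = ord(qual[pos - start]) - 33
            if q < 20:
                continue
            v = by_pos[pos]
            if base == v.ref:
                expect[pos][0] += 1
                break
            if base == v.alt:
                expect[pos][1] += 1
                break
    for pos, (ref_n, alt_n) in expect.items():
        assert res.counts.loc[("chr1", pos), "ref_count"] == ref_n, pos
        assert res.counts.loc[("chr1", pos), "alt_count"] == alt_n, pos


# -- VCF / GFF loading ---------------------------------------------------


def test_load_snps_skips_non_biallelic(tmp_path):
    vcf = tmp_path / "v.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID=chr1,length={CHROM_LEN}>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t21\t.\tA\tG\t50\tPASS\t.\n"
        "chr1\t30\t.\tAT\tA\t50\tPASS\t.\n"  # indel
        "chr1\t41\t.\tC\tT,G\t50\tPASS\t.\n"  # multiallelic
        "chr1\t61\t.\tG\tA\t50\tPASS\t.\n"
    )
    variants, skipped = load_snps(vcf)
    assert [(v.pos, v.ref, v.alt) for v in variants] == [(21, "A", "G"), (61, "G", "A")]
    assert skipped["indel"] == 1 and skipped["multiallelic"] == 1


def test_load_gene_models_merges_exons(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\t.\tgene\t11\t50\t.\t+\t.\tID=geneA\n"
        "chr1\t.\texon\t11\t30\t.\t+\t.\tID=geneA.e1;Parent=geneA\n"
        "chr1\t.\texon\t26\t50\t.\t+\t.\tID=geneA.e2;Parent=geneA\n"
        "chr1\t.\tgene\t56\t90\t.\t+\t.\tID=geneB\n"
        "chr1\t.\texon\t56\t90\t.\t+\t.\tID=geneB.e1;Parent=geneB\n"
    )
    genes = load_gene_models(gff)
    by_id = {g.gene_id: g for g in genes}
    assert by_id["geneA"].exons == [(10, 50)]  # merged, 0-based half-open
    assert by_id["geneB"].exons == [(55, 90)]


# -- gene aggregation ----------------------------------------------------


def snp_count_frame(rows):
    frame = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref_count", "alt_count"]
    )
    return frame.set_index(["chrom", "pos"])


def test_gene_counts_are_snp_sums():
    counts = snp_count_frame(
        [("chr1", 21, 10, 5), ("chr1", 41, 4, 1), ("chr1", 61, 7, 2)]
    )
    assignment = assign_snps_to_genes(SNPS, GENES)
    table, dropped = aggregate_gene_counts(
        counts, GENES, assignment, ref_parent="maternal"
    )
    assert table.frame.loc["geneA", "maternal_1"] == 14
    assert table.frame.loc["geneA", "paternal_1"] == 6
    assert table.frame.loc["geneB", "maternal_1"] == 7
    assert len(dropped) == 0


def test_reciprocal_cross_swaps_labels():
    counts = snp_count_frame([("chr1", 21, 10, 5), ("chr1", 41, 4, 1)])
    assignment = assign_snps_to_genes(SNPS, GENES)
    fwd, _ = aggregate_gene_counts(counts, GENES, assignment, ref_parent="maternal")
    rev, _ = aggregate_gene_counts(counts, GENES, assignment, ref_parent="paternal")
    assert (
        fwd.frame.loc["geneA", "maternal_1"] == rev.frame.loc["geneA", "paternal_1"]
    )
    assert (
        fwd.frame.loc["geneA", "paternal_1"] == rev.frame.loc["geneA", "maternal_1"]
    )


def test_intergenic_snp_dropped_with_tally():
    counts = snp_count_frame([("chr1", 21, 3, 1), ("chr1", 95, 6, 2)])
    assignment = assign_snps_to_genes(SNPS, GENES)
    assert assignment.dropped["intergenic"] == 1
    table, dropped = aggregate_gene_counts(counts, GENES, assignment)
    assert len(dropped) == 1
    assert dropped.iloc[0]["pos"] == 95
    total = table.frame.to_numpy().sum()
    assert total == 4  # the intergenic SNP's 8 reads appear in no gene


def test_snp_in_two_genes_assigned_to_neither():
    overlapping = GENES + [GeneModel("geneC", "chr1", "-", [(15, 25)])]
    assignment = assign_snps_to_genes(SNPS, overlapping)
    assert ("chr1", 21) not in assignment.gene_of
    assert assignment.dropped["multi_gene"] == 1


def test_combine_crosses_and_filter():
    c1 = snp_count_frame([("chr1", 21, 8, 1)])
    c2 = snp_count_frame([("chr1", 21, 2, 7)])
    assignment = assign_snps_to_genes(SNPS, GENES)
    t1, _ = aggregate_gene_counts(c1, GENES, assignment, ref_parent="maternal", cross="AxB")
    t2, _ = aggregate_gene_counts(c2, GENES, assignment, ref_parent="paternal", cross="BxA")
    combined = combine_crosses({"AxB": t1, "BxA": t2})
    assert combined.crosses == ["AxB", "BxA"]
    assert combined.frame.loc["geneA", "maternal_BxA"] == 7
    kept = filter_min_counts(combined, 10)
    assert list(kept.gene_ids) == ["geneA"]  # geneB has zero counts
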