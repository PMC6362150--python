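"""Allelic read counting from alignments and parental SNPs.

Workflow: mask known SNP positions in the reference with 'N' (so the
aligner cannot favour the reference allele), align reads externally,
then count reads per SNP allele and aggregate to per-gene maternal and
paternal counts for one cross.

Counting rules:

* only uniquely mapped reads (NH tag == 1 where present, else MAPQ >= 20);
* a base must have phred quality >= ``min_base_quality`` (default 20) to
  be used;
* no more than one SNP is counted per read — the leftmost covered SNP
  with a usable base wins — preventing pseudo-replication from reads
  spanning several SNPs;
* mates of a read pair covering the same SNP contribute one observation;
* bases matching neither allele are tallied separately, never counted.

Coordinates are 1-based on disk (VCF, GFF3) and 0-based half-open
internally; every public container states which convention it uses.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .counts import AllelicCounts

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SnpVariant:
    """A biallelic SNP; ``pos`` is 1-based (as in VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"{self.chrom}:{self.pos}: alleles must be A/C/G/T")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")


@dataclass
class GeneModel:
    """Gene with merged exon intervals, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        merged: list[tuple[int, int]] = []
        for s, e in sorted(self.exons):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.exons = merged


def load_snps(vcf_path) -> tuple[list[SnpVariant], dict[str, int]]:
    """Biallelic SNPs from a VCF; indels and multiallelic records are
    skipped with a logged tally (returned as the second element)."""
    from cyvcf2 import VCF

    skipped = {"indel": 0, "multiallelic": 0, "non_acgt": 0}
    variants: list[SnpVariant] = []
    for rec in VCF(str(vcf_path)):
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1:
            skipped["indel"] += 1
            continue
        if ref not in _BASES or alt not in _BASES:
            skipped["non_acgt"] += 1
            continue
        variants.append(SnpVariant(rec.CHROM, rec.POS, ref, alt))
    n_skipped = sum(skipped.values())
    if n_skipped:
        logger.info("skipped %d non-SNP records: %s", n_skipped, skipped)
    return variants, skipped


def mask_reference(fasta_path, variants: list[SnpVariant], out_path, line_width: int = 60) -> None:
    """Write a copy of the genome with 'N' at every SNP position.

    All non-variant bases are byte-identical to the input.  A variant
    outside its chromosome raises an error naming it.
    """
    fasta = Fasta(str(fasta_path))
    seqs = {name: bytearray(str(fasta[name]), "ascii") for name in fasta.keys()}
    for v in variants:
        if v.chrom not in seqs:
            raise ValueError(f"variant {v.chrom}:{v.pos}: unknown chromosome")
        if not 1 <= v.pos <= len(seqs[v.chrom]):
            raise ValueError(
                f"variant {v.chrom}:{v.pos} outside chromosome "
                f"(length {len(seqs[v.chrom])})"
            )
        seqs[v.chrom][v.pos - 1] = ord("N")
    with open(out_path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width].decode("ascii") + "\n")


@dataclass
class SnpCountResult:
    """Per-SNP allele tallies; index of ``counts`` is (chrom, pos 1-based)
    with columns ref_count, alt_count, skipped_lowqual, other_base."""

    counts: pd.DataFrame
    n_reads_seen: int
    n_reads_counted: int


def count_snp_alleles(
    alignments,
    variants: list[SnpVariant],
    min_base_quality: int = 20,
    unique_only: bool = True,
    min_mapq: int = 20,
    dedup: bool = False,
) -> SnpCountResult:
    """Count reads supporting each SNP allele.

    ``alignments`` is a SAM/BAM path; reads are streamed in file order,
    so coordinate sorting is not required for counting itself.  Each
    read contributes at most one observation, at its leftmost covered
    SNP with a usable (phred >= ``min_base_quality``, ref- or
    alt-matching) base.  Mates covering the same SNP are counted once.
    ``dedup=True`` additionally skips reads flagged as PCR/optical
    duplicates (off by default).
    """
    by_chrom: dict[str, dict[int, SnpVariant]] = defaultdict(dict)
    for v in variants:
        by_chrom[v.chrom][v.pos - 1] = v  # 0-based lookup

    mode = "rb" if str(alignments).endswith(".bam") else "r"
    af = pysam.AlignmentFile(str(alignments), mode)
    missing = sorted(set(by_chrom) - set(af.references))
    if missing:
        raise ValueError(
            "variant chromosomes absent from the alignment header: "
            + ", ".join(missing)
        )

    tallies: dict[tuple[str, int], np.ndarray] = {
        (v.chrom, v.pos): np.zeros(4, dtype=np.int64) for v in variants
    }  # columns: ref, alt, lowqual, other
    mate_counted: dict[str, tuple[str, int]] = {}
    n_seen = n_counted = 0
    for read in af.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if dedup and read.is_duplicate:
            continue
        if unique_only:
            if read.has_tag("NH"):
                if read.get_tag("NH") != 1:
                    continue
            elif read.mapping_quality < min_mapq:
                continue
        chrom = read.reference_name
        snps = by_chrom.get(chrom)
        if not snps:
            continue
        n_seen += 1
        seq = read.query_sequence
        quals = read.query_qualities
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            v = snps.get(rpos)
            if v is None:
                continue
            key = (chrom, rpos + 1)
            if quals is not None and quals[qpos] < min_base_quality:
                tallies[key][2] += 1
                continue
            base = seq[qpos].upper()
            if base == v.ref:
                col = 0
            elif base == v.alt:
                col = 1
            else:
                tallies[key][3] += 1
                continue
            if read.is_paired:
                if mate_counted.get(read.query_name) == key:
                    break  # the mate already observed this SNP
                mate_counted[read.query_name] = key
            tallies[key][col] += 1
            n_counted += 1
            break  # one SNP per read
    frame = pd.DataFrame(
        [
            {
                "chrom": c,
                "pos": p,
                "ref_count": t[0],
                "alt_count": t[1],
                "skipped_lowqual": t[2],
                "other_base": t[3],
            }
            for (c, p), t in sorted(tallies.items())
        ]
    )
    if len(frame):
        frame = frame.set_index(["chrom", "pos"])
    return SnpCountResult(counts=frame, n_reads_seen=n_seen, n_reads_counted=n_counted)


def load_gene_models(gff_path) -> list[GeneModel]:
    """Gene models with merged exons from a GFF3 file (1-based on disk,
    converted to 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end) for e in db.children(g, featuretype="exon")
        ]
        if not exons:
            exons = [(g.start - 1, g.end)]
        genes.append(GeneModel(g.id, g.seqid, g.strand, exons))
    return genes


@dataclass
class SnpAssignment:
    """SNP -> gene mapping; SNPs in no gene or in more than one gene are
    left unassigned with a reason tally."""

    gene_of: dict[tuple[str, int], str]
    dropped: dict[str, int] = field(default_factory=dict)


def assign_snps_to_genes(
    variants: list[SnpVariant], genes: list[GeneModel]
) -> SnpAssignment:
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        for s, e in g.exons:
            trees[g.chrom][s:e] = g.gene_id
    gene_of: dict[tuple[str, int], str] = {}
    dropped = {"intergenic": 0, "multi_gene": 0}
    for v in variants:
        hits = {iv.data for iv in trees[v.chrom][v.pos - 1]}
        if len(hits) == 1:
            gene_of[(v.chrom, v.pos)] = hits.pop()
        elif not hits:
            dropped["intergenic"] += 1
        else:
            dropped["multi_gene"] += 1
    if any(dropped.values()):
        logger.info("unassigned SNPs: %s", dropped)
    return SnpAssignment(gene_of=gene_of, dropped=dropped)


def aggregate_gene_counts(
    snp_counts: pd.DataFrame,
    genes: list[GeneModel],
    assignment: SnpAssignment,
    ref_parent: str = "maternal",
    cross: str = "1",
) -> tuple[AllelicCounts, pd.DataFrame]:
    """Sum per-SNP allele counts to per-gene maternal/paternal counts.

    ``ref_parent`` states which parent of this cross carries the
    reference allele (for reciprocal crosses of the same two accessions
    the two directions simply swap it).  Returns the one-cross count
    table over all supplied genes (zeros where no SNP was counted) and a
    frame of dropped, unassigned SNP counts.
    """
    if ref_parent not in ("maternal", "paternal"):
        raise ValueError("ref_parent must be 'maternal' or 'paternal'")
    maternal = {g.gene_id: 0 for g in genes}
    paternal = {g.gene_id: 0 for g in genes}
    dropped_rows = []
    for (chrom, pos), row in snp_counts.iterrows():
        gene = assignment.gene_of.get((chrom, pos))
        if gene is None:
            dropped_rows.append(
                {"chrom": chrom, "pos": pos, "ref_count": row["ref_count"], "alt_count": row["alt_count"]}
            )
            continue
        if ref_parent == "maternal":
            maternal[gene] += int(row["ref_count"])
            paternal[gene] += int(row["alt_count"])
        else:
            maternal[gene] += int(row["alt_count"])
            paternal[gene] += int(row["ref_count"])
    gene_ids = [g.gene_id for g in genes]
    table = AllelicCounts.from_arrays(
        gene_ids,
        np.array([[maternal[g]] for g in gene_ids]),
        np.array([[paternal[g]] for g in gene_ids]),
        crosses=[cross],
    )
    dropped = pd.DataFrame(dropped_rows, columns=["chrom", "pos", "ref_count", "alt_count"])
    if len(dropped):
        logger.info("dropped %d unassigned SNPs with counts", len(dropped))
    return table, dropped


def combine_crosses(tables: dict[str, AllelicCounts]) -> AllelicCounts:
    """Join one-cross tables (same gene universe) into a multi-cross table."""
    frames = []
    for label, t in tables.items():
        if t.n_crosses != 1:
            raise ValueError("combine_crosses expects one-cross tables")
        old = t.crosses[0]
        frames.append(
            t.frame.rename(
                columns={
                    f"maternal_{old}": f"maternal_{label}",
                    f"paternal_{old}": f"paternal_{label}",
                }
            )
        )
    base = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(base):
            raise ValueError("gene universes differ between crosses")
    return AllelicCounts(pd.concat(frames, axis=1))


def filter_min_counts(table: AllelicCounts, min_total: int = 10) -> AllelicCounts:
    """Discard genes with fewer than ``min_total`` allelic reads summed
    over parents and crosses (a gene with exactly ``min_total`` stays)."""
    return table.filter_min_total(min_total)
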