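"""Readers and writers for the standard formats the pipeline touches.

VCF v4.2 via pysam (diploid GT as unphased pairs, haploid as a single
allele), GFF3 gene/exon models via gffutils, FASTA via Biopython, coded-allele
matrices as TSV, plus the packaged reference gene table.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .errors import FixtureCorruptionError, VcfParseError
from .models import GeneModel, GenotypePanel, site_key

logger = logging.getLogger(__name__)

_FIXTURE_SHA256 = "6359c22b7ef6265c88033c4fd8df868bd39820fc49480758790fff21ca1b2075"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    panel: GenotypePanel,
    path: str,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write the panel as uncompressed VCF v4.2.

    Diploid genotypes are written as unphased allele pairs, haploid ones as a
    single allele. Gene and region annotations, when present, go to the
    ``GENE`` and ``REGION`` INFO fields so a round trip preserves them.
    """
    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(panel.sites["chromosome"]))
    for chrom in chroms:
        length = None
        if contig_lengths and chrom in contig_lengths:
            length = contig_lengths[chrom]
        else:
            length = int(panel.sites.loc[panel.sites["chromosome"] == chrom, "position"].max()) + 1000
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("GENE", 1, "String", "Gene identifier of the site")
    header.info.add("REGION", 1, "String", "Gene region of the site (exon/intron/flank)")
    for acc in panel.accessions:
        header.add_sample(acc)
    with pysam.VariantFile(path, "w", header=header) as out:
        for sid, row in panel.sites.iterrows():
            rec = out.new_record(
                contig=row.chromosome,
                start=int(row.position) - 1,
                alleles=(row.ref, row.alt),
                id=str(sid),
            )
            if pd.notna(row.gene_id):
                rec.info["GENE"] = str(row.gene_id)
            if pd.notna(row.region):
                rec.info["REGION"] = str(row.region)
            allele_index = {row.ref: 0, row.alt: 1}
            for acc in panel.accessions:
                gt = panel.genotypes.at[sid, acc]
                ploidy = panel.ploidy[acc]
                if gt is None:
                    rec.samples[acc]["GT"] = (None,) * ploidy
                else:
                    rec.samples[acc]["GT"] = tuple(allele_index[a] for a in gt)
            out.write(rec)


def read_vcf(path: str) -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel`.

    Multiallelic and non-SNP records are skipped (count logged). Haploid GT
    entries are preserved as single-allele genotypes; ``./.`` becomes missing.
    """
    panel, _ = read_vcf_counted(path)
    return panel


def read_vcf_counted(path: str) -> Tuple[GenotypePanel, int]:
    """As :func:`read_vcf` but also return the number of skipped records."""
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc
    accessions = list(vf.header.samples)
    has_gene = "GENE" in vf.header.info
    has_region = "REGION" in vf.header.info
    rows = []
    columns: Dict[str, list] = {a: [] for a in accessions}
    ploidy: Dict[str, int] = {}
    skipped = 0
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
            ):
                skipped += 1
                continue
            alleles = (rec.ref, alts[0])
            sid = site_key(rec.chrom, rec.pos)
            rows.append(
                {
                    "site_id": sid,
                    "chromosome": rec.chrom,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": alts[0],
                    "gene_id": rec.info.get("GENE", None) if has_gene else None,
                    "region": rec.info.get("REGION", None) if has_region else None,
                }
            )
            for acc in accessions:
                try:
                    gt = rec.samples[acc]["GT"]
                except KeyError as exc:
                    raise VcfParseError(
                        f"record {rec.chrom}:{rec.pos}: no GT for sample {acc}"
                    ) from exc
                if gt is None or all(a is None for a in gt):
                    columns[acc].append(None)
                    if gt and len(gt) in (1, 2):
                        ploidy.setdefault(acc, len(gt))
                else:
                    if any(a is None for a in gt):
                        columns[acc].append(None)  # half-calls treated as missing
                    else:
                        columns[acc].append(tuple(sorted(alleles[i] for i in gt)))
                    ploidy.setdefault(acc, len(gt))
    if skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    sites = pd.DataFrame(rows).set_index("site_id") if rows else pd.DataFrame(
        columns=["chromosome", "position", "ref", "alt", "gene_id", "region"]
    )
    sites.index.name = None
    genotypes = pd.DataFrame(
        {a: pd.Series(columns[a], index=sites.index, dtype=object) for a in accessions},
        index=sites.index,
    )
    for acc in accessions:
        ploidy.setdefault(acc, 2)
    return GenotypePanel(sites, genotypes, ploidy), skipped


def write_phased_vcf(
    panel: GenotypePanel,
    haplotypes: Mapping[Tuple[str, str], Sequence],
    path: str,
) -> None:
    """Write a VCF restricted to phased accessions with ``|``-separated GT.

    ``haplotypes`` maps (accession, gene_id) to the accession's two
    :class:`~citrusdiag.models.Haplotype` objects; sites without phase
    information are written as missing.
    """
    accessions = sorted({acc for (acc, _g) in haplotypes})
    phased: Dict[str, Dict[str, tuple]] = {a: {} for a in accessions}
    for (acc, gid), pair in haplotypes.items():
        sids = panel.gene_sites(gid)
        h1, h2 = pair[0].alleles, pair[1].alleles
        for sid, a1, a2 in zip(sids, h1, h2):
            if a1 is not None and a2 is not None:
                phased[acc][sid] = (a1, a2)
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(panel.sites["chromosome"]):
        length = int(panel.sites.loc[panel.sites["chromosome"] == chrom, "position"].max()) + 1000
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for acc in accessions:
        header.add_sample(acc)
    with pysam.VariantFile(path, "w", header=header) as out:
        for sid, row in panel.sites.iterrows():
            rec = out.new_record(
                contig=row.chromosome,
                start=int(row.position) - 1,
                alleles=(row.ref, row.alt),
                id=str(sid),
            )
            idx = {row.ref: 0, row.alt: 1}
            for acc in accessions:
                pair = phased[acc].get(sid)
                if pair is None:
                    rec.samples[acc]["GT"] = (None, None)
                else:
                    rec.samples[acc]["GT"] = (idx[pair[0]], idx[pair[1]])
                    rec.samples[acc].phased = True
            out.write(rec)


# ---------------------------------------------------------------------------
# GFF3 / FASTA
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene/exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tcitrusdiag\tgene\t{g.start}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\tcitrusdiag\texon\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str) -> List[GeneModel]:
    """Load gene models (gene + exon features) from a GFF3 file."""
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(
            (ex.start, ex.end)
            for ex in db.children(feat, featuretype="exon", order_by="start")
        )
        genes.append(GeneModel(feat.id, feat.seqid, feat.start, feat.end, exons))
    return genes


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# coded matrices
# ---------------------------------------------------------------------------

def write_coded_matrix(coded: pd.DataFrame, path: str) -> None:
    """TSV with accession rows, marker columns, values 0 / 0.5 / 1 / NA."""
    coded.to_csv(path, sep="\t", na_rep="NA", index_label="accession")


def read_coded_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="accession", na_values=["NA"])
    df.index.name = None
    bad = set(df.stack().unique()) - {0.0, 0.5, 1.0}
    if bad:
        raise VcfParseError(f"coded matrix contains invalid values: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# region annotation
# ---------------------------------------------------------------------------

def annotate_region(panel: GenotypePanel, genes: Sequence[GeneModel]) -> GenotypePanel:
    """Label each site exon/intron within its gene, flank outside all genes.

    Boundaries are inclusive on both ends; the operation is idempotent and
    returns a new panel.
    """
    gene_trees: Dict[str, IntervalTree] = {}
    exon_trees: Dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.chromosome, IntervalTree())[g.start : g.end + 1] = g.gene_id
        et = exon_trees.setdefault(g.chromosome, IntervalTree())
        for (s, e) in g.exons:
            et[s : e + 1] = g.gene_id
    out = panel.copy()
    gene_col, region_col = [], []
    for _, row in out.sites.iterrows():
        hits = gene_trees.get(row.chromosome, IntervalTree())[row.position]
        if not hits:
            gene_col.append(pd.NA)
            region_col.append("flank")
            continue
        gid = sorted(iv.data for iv in hits)[0]
        in_exon = any(
            iv.data == gid
            for iv in exon_trees.get(row.chromosome, IntervalTree())[row.position]
        )
        gene_col.append(gid)
        region_col.append("exon" if in_exon else "intron")
    out.sites["gene_id"] = gene_col
    out.sites["region"] = region_col
    return out


# ---------------------------------------------------------------------------
# packaged gene table
# ---------------------------------------------------------------------------

def load_gene_fixture() -> pd.DataFrame:
    """Load the packaged 38-gene reference table (fruit-quality pathway genes
    with per-gene SNP class counts), indexed by gene code.

    Raises :class:`FixtureCorruptionError` if the packaged file does not match
    its recorded checksum.
    """
    ref = resources.files("citrusdiag.data").joinpath("table1_genes.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureCorruptionError(
            f"gene table checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    return df.set_index("code")
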