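"""Core containers: gene models, genotype panels, and population/pedigree configuration.

Conventions used throughout the package:

* coordinates are 1-based and inclusive on both ends (VCF/GFF3 convention);
* every variant site is a biallelic SNP with single-base ref and alt alleles;
* a genotype is an unordered pair of alleles for a diploid accession, a
  single-allele tuple for a haploid one, and ``None`` when missing;
* the coded representation of a genotype at an oriented marker is
  0 (homozygous *C. reticulata* allele), 1 (homozygous *C. maxima* allele)
  or 0.5 (interspecific heterozygote).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .errors import ConfigurationError

VALID_BASES = frozenset("ACGT")

#: genotype: ('A','G') diploid unordered, ('A',) haploid, None missing
Genotype = Optional[Tuple[str, ...]]


def site_key(chromosome: str, position: int) -> str:
    """Canonical site identifier, ``chrom:pos``."""
    return f"{chromosome}:{position}"


def normalize_genotype(alleles: Optional[Iterable[str]]) -> Genotype:
    """Canonicalize a genotype: sort diploid pairs, pass haploids/missing through."""
    if alleles is None:
        return None
    t = tuple(alleles)
    if len(t) == 2:
        return tuple(sorted(t))
    if len(t) == 1:
        return t
    raise ValueError(f"genotype must have 1 or 2 alleles, got {t!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene's span and exon structure on a chromosome (1-based, inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        prev_end = None
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end ({s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s}, {e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def in_exon(self, position: int) -> bool:
        return any(s <= position <= e for (s, e) in self.exons)


class GenotypePanel:
    """Accessions x variant sites with diploid, haploid or missing genotypes.

    Parameters
    ----------
    sites
        DataFrame indexed by site id (``chrom:pos``) with columns
        ``chromosome, position, ref, alt, gene_id, region``; ``gene_id`` may be
        NA for unannotated sites and ``region`` is one of
        ``exon / intron / flank`` or NA.
    genotypes
        Object-dtype DataFrame, index = site ids, columns = accession ids,
        entries as produced by :func:`normalize_genotype`.
    ploidy
        Accession id -> 1 or 2.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        genotypes: pd.DataFrame,
        ploidy: Mapping[str, int],
    ):
        required = {"chromosome", "position", "ref", "alt"}
        missing_cols = required - set(sites.columns)
        if missing_cols:
            raise ValueError(f"sites missing columns: {sorted(missing_cols)}")
        sites = sites.copy()
        for col in ("gene_id", "region"):
            if col not in sites.columns:
                sites[col] = pd.NA
        for sid, row in sites.iterrows():
            if row.ref not in VALID_BASES or row.alt not in VALID_BASES:
                raise ValueError(f"{sid}: ref/alt must be single bases")
            if row.ref == row.alt:
                raise ValueError(f"{sid}: ref == alt")
        # positions strictly increasing within each chromosome, in index order
        for chrom, grp in sites.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if len(pos) > 1 and not (pos[1:] > pos[:-1]).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if not genotypes.index.equals(sites.index):
            raise ValueError("genotypes index must equal sites index")
        unknown = set(genotypes.columns) - set(ploidy)
        if unknown:
            raise ValueError(f"accessions without ploidy: {sorted(unknown)}")
        self.sites = sites
        self.genotypes = genotypes
        self.ploidy = dict(ploidy)

    # -- introspection -------------------------------------------------------
    @property
    def site_ids(self) -> list:
        return list(self.sites.index)

    @property
    def accessions(self) -> list:
        return list(self.genotypes.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.genotypes.columns)

    def genotype(self, site_id: str, accession: str) -> Genotype:
        return self.genotypes.at[site_id, accession]

    def set_genotype(self, site_id: str, accession: str, gt: Genotype) -> None:
        self.genotypes.at[site_id, accession] = normalize_genotype(gt)

    def gene_sites(self, gene_id: str) -> list:
        """Site ids of a gene, in position order."""
        mask = self.sites["gene_id"] == gene_id
        return list(self.sites.index[mask])

    def gene_genotypes(self, accession: str, gene_id: str) -> list:
        """Genotypes of one accession over a gene's sites, position order."""
        return [self.genotypes.at[s, accession] for s in self.gene_sites(gene_id)]

    def add_accession(
        self, name: str, ploidy: int, genotypes: Mapping[str, Genotype]
    ) -> None:
        if name in self.genotypes.columns:
            raise ValueError(f"accession {name!r} already present")
        col = [normalize_genotype(genotypes.get(s)) for s in self.sites.index]
        self.genotypes[name] = pd.Series(col, index=self.sites.index, dtype=object)
        self.ploidy[name] = ploidy

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            self.sites.copy(), self.genotypes.copy(), dict(self.ploidy)
        )


@dataclass
class Haplotype:
    """One chromosome copy of a gene: an allele vector over the gene's sites.

    ``alleles`` is ordered like :meth:`GenotypePanel.gene_sites`; ``None``
    marks an unknown allele. ``source_parent`` is set once the haplotype has
    been attributed to a transmitting parent.
    """

    accession: str
    gene_id: str
    alleles: Tuple[Optional[str], ...]
    hap_index: int = 0
    source_parent: Optional[str] = None


@dataclass
class PanelConfig:
    """Taxon membership, pedigree and haploid-derivative structure of a panel."""

    taxon: Dict[str, str] = field(default_factory=dict)
    pure: Set[str] = field(default_factory=set)
    pedigree: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    haploid_of: Dict[str, str] = field(default_factory=dict)
    outgroup: Set[str] = field(default_factory=set)
    subgroup: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for acc in self.pure:
            if self.taxon.get(acc) not in ("reticulata", "maxima"):
                raise ConfigurationError(
                    f"pure representative {acc!r} must be reticulata or maxima"
                )
        for hap, dip in self.haploid_of.items():
            if dip not in self.taxon:
                raise ConfigurationError(
                    f"haploid {hap!r} derives from unknown accession {dip!r}"
                )
        # pedigree acyclicity (offspring -> parents edges)
        state: Dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for parent in self.pedigree.get(node, ()):
                if state.get(parent) == 1:
                    raise ConfigurationError(f"pedigree cycle through {parent!r}")
                if state.get(parent) != 2:
                    visit(parent)
            state[node] = 2

        for off in self.pedigree:
            if state.get(off) != 2:
                visit(off)

    def accessions_of_taxon(self, label: str) -> list:
        return sorted(a for a, t in self.taxon.items() if t == label)

    def pure_of_taxon(self, label: str) -> list:
        return sorted(a for a in self.pure if self.taxon.get(a) == label)

    def outgroup_accessions(self) -> list:
        return sorted(self.outgroup)

    # -- JSON round trip -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "taxon": self.taxon,
                "pure": sorted(self.pure),
                "pedigree": {k: list(v) for k, v in self.pedigree.items()},
                "haploid_of": self.haploid_of,
                "outgroup": sorted(self.outgroup),
                "subgroup": self.subgroup,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PanelConfig":
        d = json.loads(text)
        cfg = cls(
            taxon=dict(d.get("taxon", {})),
            pure=set(d.get("pure", [])),
            pedigree={k: tuple(v) for k, v in d.get("pedigree", {}).items()},
            haploid_of=dict(d.get("haploid_of", {})),
            outgroup=set(d.get("outgroup", [])),
            subgroup=dict(d.get("subgroup", {})),
        )
        cfg.validate()
        return cfg
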