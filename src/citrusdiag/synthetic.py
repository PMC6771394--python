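"""Synthetic citrus-like genotype panels with known truth.

Emulates the structure of a two-ancestor discovery panel: two ancestral taxa
("R" for *C. reticulata*-like, "M" for *C. maxima*-like) with fixed
inter-taxon differences and intra-taxon polymorphism organised as two
sub-haplotype groups per taxon, pure representative accessions, outgroups
fixed for ancestral alleles, admixed accessions built by gamete sampling
(F1, backcrosses, recorded trios), and uniform random missingness.

Each simulated site carries a truth class:

``RM``
    fixed difference between the taxa (the diagnostic-marker class),
``RR`` / ``MM``
    polymorphic only within R (M), split cleanly between the taxon's two
    sub-haplotype groups,
``ancestral-shared``
    polymorphic within both taxa (an old polymorphism predating their split),
``monomorphic``
    fixed for the same allele in both taxa but divergent from the outgroups.

Genes have no within-gene recombination: a gamete transmits one of the
parent's two gene haplotypes intact, chosen independently per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .models import GeneModel, GenotypePanel, PanelConfig, site_key

BASES = np.array(list("ACGT"))

_RECIPES = ("F1", "BC-to-R", "BC-to-M", "trio-offspring")


@dataclass(frozen=True)
class HybridSpec:
    """One admixed accession to simulate: a name, a recipe and, for recorded
    trios, the two named parents."""

    name: str
    recipe: str
    parents: Optional[Tuple[str, str]] = None

    def __post_init__(self):
        if self.recipe not in _RECIPES:
            raise ConfigurationError(f"unknown recipe {self.recipe!r}")
        if self.recipe == "trio-offspring" and self.parents is None:
            raise ConfigurationError(
                f"{self.name!r}: trio-offspring requires named parents"
            )


def _default_hybrids() -> Tuple[HybridSpec, ...]:
    return (
        HybridSpec("f1_1", "F1"),
        HybridSpec("bc1r_1", "BC-to-R"),
        HybridSpec("trio_child", "trio-offspring", ("pure_R_1", "pure_M_1")),
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel.

    Defaults mirror the real discovery panel this generator stands in for:
    38 fruit-quality genes of 27-243 SNPs each, with roughly 31% of sites
    fixed between the taxa and 17.5% intraspecific (split between the taxa),
    and ~1% missing genotypes.
    """

    n_genes: int = 38
    gene_length_range: Tuple[int, int] = (1432, 8650)
    exons_per_gene_range: Tuple[int, int] = (1, 14)
    snps_per_gene_range: Tuple[int, int] = (27, 243)
    p_fixed_interspecific: float = 0.31
    p_intra_R: float = 0.087
    p_intra_M: float = 0.088
    n_pure_R: int = 4
    n_pure_M: int = 2
    n_outgroup: int = 5
    hybrid_specs: Tuple[HybridSpec, ...] = field(default_factory=_default_hybrids)
    missing_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        psum = self.p_fixed_interspecific + self.p_intra_R + self.p_intra_M
        if psum > 1 + 1e-12:
            raise ConfigurationError("site-class probabilities sum above 1")
        if min(self.p_fixed_interspecific, self.p_intra_R, self.p_intra_M) < 0:
            raise ConfigurationError("site-class probabilities must be >= 0")
        if min(self.n_genes, self.n_pure_R, self.n_pure_M, self.n_outgroup) < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.gene_length_range[0] < 200:
            raise ConfigurationError(
                "minimum gene length must be >= 200 bp so 50 bp flanks fit"
            )
        for lo, hi in (
            self.gene_length_range,
            self.exons_per_gene_range,
            self.snps_per_gene_range,
        ):
            if lo > hi or lo < 1:
                raise ConfigurationError("ranges must satisfy 1 <= lo <= hi")
        if self.snps_per_gene_range[1] > self.gene_length_range[0] - 100:
            raise ConfigurationError(
                "snps_per_gene max exceeds interior positions of shortest gene"
            )
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass
class TruthTables:
    """Ground truth of a simulated panel.

    site_class
        per site id, one of RM / RR / MM / ancestral-shared / monomorphic;
    ancestral_allele
        per site id, the allele carried homozygously by the outgroups;
    haplotypes / origins
        per (accession, gene_id): the two true allele vectors over the gene's
        sites (position order) and their taxon-of-origin labels
        ("R", "M" or "ancestral").
    """

    site_class: pd.Series
    ancestral_allele: pd.Series
    haplotypes: Dict[Tuple[str, str], Tuple[Tuple[str, ...], Tuple[str, ...]]]
    origins: Dict[Tuple[str, str], Tuple[str, str]]

    def haplotype_frame(self) -> pd.DataFrame:
        rows = []
        for (acc, gene), pair in sorted(self.haplotypes.items()):
            o = self.origins[(acc, gene)]
            for i, hap in enumerate(pair):
                rows.append(
                    {
                        "accession": acc,
                        "gene_id": gene,
                        "hap_index": i,
                        "origin": o[i],
                        "alleles": ",".join(hap),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_CLASSES = ("RM", "RR", "MM", "ancestral-shared", "monomorphic")


def _class_probabilities(cfg: SimulationConfig) -> np.ndarray:
    rem = 1.0 - cfg.p_fixed_interspecific - cfg.p_intra_R - cfg.p_intra_M
    rem = max(rem, 0.0)
    return np.array(
        [cfg.p_fixed_interspecific, cfg.p_intra_R, cfg.p_intra_M, rem / 2, rem / 2]
    )


def _simulate_genes(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay genes along chromosomes chr1..chr9 with 10 kb gaps."""
    chroms = [f"chr{i}" for i in range(1, 10)]
    next_free = {c: 10_001 for c in chroms}
    genes: List[GeneModel] = []
    for g in range(cfg.n_genes):
        chrom = chroms[g % len(chroms)]
        length = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
        start = next_free[chrom]
        end = start + length - 1
        next_free[chrom] = end + 10_000
        n_ex = int(rng.integers(cfg.exons_per_gene_range[0], cfg.exons_per_gene_range[1] + 1))
        n_seg = 2 * n_ex - 1
        # alternating exon/intron segments, each at least 20 bp
        if n_seg * 20 > length:
            n_ex = max(1, length // 40)
            n_seg = 2 * n_ex - 1
        extra = rng.multinomial(length - n_seg * 20, np.full(n_seg, 1 / n_seg))
        seg_lengths = 20 + extra
        exons = []
        pos = start
        for i, sl in enumerate(seg_lengths):
            if i % 2 == 0:
                exons.append((pos, pos + int(sl) - 1))
            pos += int(sl)
        genes.append(GeneModel(f"gene{g + 1:03d}", chrom, start, end, tuple(exons)))
    return genes


def _simulate_sites(cfg, rng, genes):
    """Per-gene SNP positions, classes, alleles and founder haplotype tables."""
    probs = _class_probabilities(cfg)
    records = []  # one dict per site
    for gene in genes:
        n_snps = int(
            rng.integers(cfg.snps_per_gene_range[0], cfg.snps_per_gene_range[1] + 1)
        )
        lo, hi = gene.start + 50, gene.end - 50
        positions = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_snps, replace=False))
        classes = rng.choice(len(_CLASSES), size=n_snps, p=probs)
        for pos, ci in zip(positions, classes):
            ref, alt = rng.choice(BASES, size=2, replace=False)
            cls = _CLASSES[ci]
            both = [str(ref), str(alt)]
            pick = lambda: both[int(rng.integers(2))]  # noqa: E731
            if cls == "RM":
                allele_R = pick()
                allele_M = both[1] if allele_R == both[0] else both[0]
                founders = {"R1": allele_R, "R2": allele_R, "M1": allele_M, "M2": allele_M}
                ancestral = pick()
            elif cls == "RR":
                m = pick()
                order = rng.permutation(2)
                founders = {"R1": both[order[0]], "R2": both[order[1]], "M1": m, "M2": m}
                ancestral = m
            elif cls == "MM":
                r = pick()
                order = rng.permutation(2)
                founders = {"R1": r, "R2": r, "M1": both[order[0]], "M2": both[order[1]]}
                ancestral = r
            elif cls == "ancestral-shared":
                ro = rng.permutation(2)
                mo = rng.permutation(2)
                founders = {
                    "R1": both[ro[0]],
                    "R2": both[ro[1]],
                    "M1": both[mo[0]],
                    "M2": both[mo[1]],
                }
                ancestral = pick()
            else:  # monomorphic within R+M, divergent outgroup
                shared = pick()
                founders = {k: shared for k in ("R1", "R2", "M1", "M2")}
                ancestral = both[1] if shared == both[0] else both[0]
            records.append(
                {
                    "site_id": site_key(gene.chromosome, int(pos)),
                    "chromosome": gene.chromosome,
                    "position": int(pos),
                    "ref": str(ref),
                    "alt": str(alt),
                    "gene_id": gene.gene_id,
                    "region": "exon" if gene.in_exon(int(pos)) else "intron",
                    "site_class": cls,
                    "ancestral": ancestral,
                    "founders": founders,
                }
            )
    return records


def simulate_panel(
    config: SimulationConfig,
) -> Tuple[GenotypePanel, List[GeneModel], PanelConfig, TruthTables]:
    """Simulate a full panel with genotypes, gene models, config and truth.

    Deterministic for a fixed ``config.seed``. Missingness is applied last,
    independently per site x accession, to the emitted diploid genotypes only
    (truth haplotypes are never masked).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _simulate_genes(config, rng)
    site_records = _simulate_sites(config, rng, genes)

    # founder haplotype vectors per gene x subgroup label
    gene_site_ids: Dict[str, List[str]] = {g.gene_id: [] for g in genes}
    for rec in site_records:
        gene_site_ids[rec["gene_id"]].append(rec["site_id"])
    founder_vec: Dict[Tuple[str, str], Tuple[str, ...]] = {}
    anc_vec: Dict[str, Tuple[str, ...]] = {}
    by_gene: Dict[str, List[dict]] = {g.gene_id: [] for g in genes}
    for rec in site_records:
        by_gene[rec["gene_id"]].append(rec)
    for gid, recs in by_gene.items():
        for label in ("R1", "R2", "M1", "M2"):
            founder_vec[(gid, label)] = tuple(r["founders"][label] for r in recs)
        anc_vec[gid] = tuple(r["ancestral"] for r in recs)

    # accessions
    panel_cfg = PanelConfig()
    haplotypes: Dict[Tuple[str, str], Tuple[Tuple[str, ...], Tuple[str, ...]]] = {}
    origins: Dict[Tuple[str, str], Tuple[str, str]] = {}
    acc_order: List[str] = []

    def add_accession(name, taxon, per_gene, *, pure=False, outgroup=False, subgroup=None):
        acc_order.append(name)
        panel_cfg.taxon[name] = taxon
        if pure:
            panel_cfg.pure.add(name)
        if outgroup:
            panel_cfg.outgroup.add(name)
        if subgroup is not None:
            panel_cfg.subgroup[name] = subgroup
        for gid, (h1, o1, h2, o2) in per_gene.items():
            haplotypes[(name, gid)] = (h1, h2)
            origins[(name, gid)] = (o1, o2)

    gids = [g.gene_id for g in genes]

    for i in range(config.n_pure_R):
        sub = f"R{i % 2 + 1}"
        per_gene = {
            gid: (founder_vec[(gid, sub)], "R", founder_vec[(gid, sub)], "R")
            for gid in gids
        }
        add_accession(f"pure_R_{i + 1}", "reticulata", per_gene, pure=True, subgroup=sub)
    for i in range(config.n_pure_M):
        sub = f"M{i % 2 + 1}"
        per_gene = {
            gid: (founder_vec[(gid, sub)], "M", founder_vec[(gid, sub)], "M")
            for gid in gids
        }
        add_accession(f"pure_M_{i + 1}", "maxima", per_gene, pure=True, subgroup=sub)
    for i in range(config.n_outgroup):
        per_gene = {
            gid: (anc_vec[gid], "ancestral", anc_vec[gid], "ancestral") for gid in gids
        }
        add_accession(f"outgroup_{i + 1}", "outgroup", per_gene, outgroup=True)

    def random_pool_gamete(taxon_letter):
        sub = f"{taxon_letter}{int(rng.integers(2)) + 1}"
        return sub

    for spec in config.hybrid_specs:
        if spec.name in panel_cfg.taxon:
            raise ConfigurationError(f"duplicate accession name {spec.name!r}")
        per_gene = {}
        if spec.recipe == "F1":
            rs, ms = random_pool_gamete("R"), random_pool_gamete("M")
            for gid in gids:
                per_gene[gid] = (
                    founder_vec[(gid, rs)], "R", founder_vec[(gid, ms)], "M",
                )
        elif spec.recipe in ("BC-to-R", "BC-to-M"):
            # virtual F1 parent crossed back to a pure-pool gamete
            rs0, ms0 = random_pool_gamete("R"), random_pool_gamete("M")
            rec_letter = "R" if spec.recipe == "BC-to-R" else "M"
            rec_sub = random_pool_gamete(rec_letter)
            for gid in gids:
                if rng.integers(2) == 0:
                    trans, t_origin = founder_vec[(gid, rs0)], "R"
                else:
                    trans, t_origin = founder_vec[(gid, ms0)], "M"
                per_gene[gid] = (
                    trans, t_origin, founder_vec[(gid, rec_sub)], rec_letter,
                )
        else:  # trio-offspring
            pa, pb = spec.parents
            for p in (pa, pb):
                if p not in panel_cfg.taxon:
                    raise ConfigurationError(
                        f"{spec.name!r}: parent {p!r} not declared before offspring"
                    )
            panel_cfg.pedigree[spec.name] = (pa, pb)
            for gid in gids:
                ia = int(rng.integers(2))
                ib = int(rng.integers(2))
                ha = haplotypes[(pa, gid)][ia]
                hb = haplotypes[(pb, gid)][ib]
                oa = origins[(pa, gid)][ia]
                ob = origins[(pb, gid)][ib]
                per_gene[gid] = (ha, oa, hb, ob)
        add_accession(spec.name, "hybrid", per_gene)

    # assemble site table and genotype matrix
    sites = pd.DataFrame(
        [
            {k: rec[k] for k in ("chromosome", "position", "ref", "alt", "gene_id", "region")}
            for rec in site_records
        ],
        index=[rec["site_id"] for rec in site_records],
    )
    order = sites.sort_values(["chromosome", "position"]).index
    sites = sites.loc[order]

    gt = {}
    for acc in acc_order:
        col = {}
        for gid in gids:
            sids = gene_site_ids[gid]
            h1, h2 = haplotypes[(acc, gid)]
            for sid, a1, a2 in zip(sids, h1, h2):
                col[sid] = tuple(sorted((a1, a2)))
        gt[acc] = [col[s] for s in order]
    genotypes = pd.DataFrame(gt, index=order, dtype=object)

    # missingness last, uniform and independent
    if config.missing_rate > 0:
        mask = rng.random((len(order), len(acc_order))) < config.missing_rate
        for j, acc in enumerate(acc_order):
            for i in np.nonzero(mask[:, j])[0]:
                genotypes.iat[int(i), j] = None

    panel = GenotypePanel(sites, genotypes, {a: 2 for a in acc_order})
    truth = TruthTables(
        site_class=pd.Series(
            {rec["site_id"]: rec["site_class"] for rec in site_records},
            name="site_class",
        ).loc[order],
        ancestral_allele=pd.Series(
            {rec["site_id"]: rec["ancestral"] for rec in site_records},
            name="ancestral_allele",
        ).loc[order],
        haplotypes=haplotypes,
        origins=origins,
    )
    panel_cfg.validate()
    return panel, genes, panel_cfg, truth


def derive_haploid(
    panel: GenotypePanel,
    config: PanelConfig,
    accession: str,
    truth: TruthTables,
    which: int = 0,
    name: Optional[str] = None,
) -> str:
    """Add a haploid derivative of ``accession`` carrying truth haplotype ``which``.

    Mirrors a doubled-haploid reference line: the emitted record carries the
    chosen truth haplotype exactly at every site of every gene (no
    missingness) and is registered in ``config.haploid_of``.
    """
    if accession not in panel.genotypes.columns:
        raise KeyError(f"unknown accession {accession!r}")
    if name is None:
        name = f"{accession}_haploid"
    col: Dict[str, tuple] = {}
    for (acc, gid), pair in truth.haplotypes.items():
        if acc != accession:
            continue
        for sid, allele in zip(panel.gene_sites(gid), pair[which]):
            col[sid] = (allele,)
    if not col:
        raise KeyError(f"accession {accession!r} absent from truth tables")
    panel.add_accession(name, 1, col)
    config.taxon[name] = config.taxon.get(accession, "hybrid")
    config.haploid_of[name] = accession
    return name


def backbone_sequences(
    panel: GenotypePanel, genes: Sequence[GeneModel], seed: int = 0
) -> Dict[str, str]:
    """I.i.d. uniform nucleotide backbone per chromosome with panel ref alleles
    substituted at SNP positions; supports flank extraction."""
    rng = np.random.default_rng(seed)
    lengths: Dict[str, int] = {}
    for g in genes:
        lengths[g.chromosome] = max(lengths.get(g.chromosome, 0), g.end + 100)
    for chrom, grp in panel.sites.groupby("chromosome", sort=False):
        lengths[chrom] = max(lengths.get(chrom, 0), int(grp["position"].max()) + 100)
    seqs = {}
    for chrom in sorted(lengths):
        arr = rng.choice(BASES, size=lengths[chrom])
        grp = panel.sites[panel.sites["chromosome"] == chrom]
        for _, row in grp.iterrows():
            arr[row.position - 1] = row.ref
        seqs[chrom] = "".join(arr)
    return seqs
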