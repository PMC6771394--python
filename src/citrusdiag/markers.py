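"""Per-site diversity statistics, GST classification and assay-candidate filters.

The central statistic is Nei's coefficient of gene differentiation between
the two ancestral populations Ti (*C. reticulata*-like) and Tj
(*C. maxima*-like),

    GST = (He_tot - (He_Ti + He_Tj) / 2) / He_tot,

where He = 1 - sum(p_i^2) is the expected heterozygosity (gene diversity) of
a population and He_tot is computed from the pooled allele frequencies. With
the default equal-weight pooling the pooled frequency vector is the plain
mean of the two population vectors, which makes GST = 1 exactly when the two
populations are fixed for different alleles - the condition used to retain a
site as a species-diagnostic marker. Count-weighted pooling (weights
proportional to observation counts) is available as an option.

Population allele observations are drawn from phased haplotypes plus pure
diploid representatives (two observations each); missing genotypes are
dropped from the denominators.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import GeneModel, GenotypePanel, PanelConfig

#: sites closer than this to GST = 1 are treated as fixed differences
GST_ONE_TOL = 1e-9


def allele_frequencies(observations: Iterable[str]) -> Dict[str, float]:
    """Allele frequency vector from raw observations; empty dict when none."""
    counts = Counter(observations)
    n = sum(counts.values())
    if n == 0:
        return {}
    return {a: c / n for a, c in counts.items()}


def expected_heterozygosity(frequencies) -> float:
    """Gene diversity He = 1 - sum(p_i^2)."""
    if isinstance(frequencies, Mapping):
        values = list(frequencies.values())
    else:
        values = list(frequencies)
    return 1.0 - sum(p * p for p in values)


@dataclass(frozen=True)
class GstValue:
    """Allele frequencies, diversities and GST for one site."""

    freq_ti: Dict[str, float]
    freq_tj: Dict[str, float]
    n_ti: int
    n_tj: int
    he_ti: float
    he_tj: float
    he_tot: float
    gst: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.gst)


def gst_from_frequencies(
    freq_ti: Mapping[str, float],
    freq_tj: Mapping[str, float],
    n_ti: int = 0,
    n_tj: int = 0,
    pooling: str = "equal",
) -> GstValue:
    """GST from two population frequency vectors.

    ``pooling="equal"`` averages the two vectors with equal weight;
    ``pooling="count"`` weights them by their observation counts. GST is NaN
    when either population is empty or the pooled site is monomorphic.
    """
    if not freq_ti or not freq_tj:
        return GstValue(dict(freq_ti), dict(freq_tj), n_ti, n_tj,
                        math.nan, math.nan, math.nan, math.nan)
    alleles = sorted(set(freq_ti) | set(freq_tj))
    pi = np.array([freq_ti.get(a, 0.0) for a in alleles])
    pj = np.array([freq_tj.get(a, 0.0) for a in alleles])
    if pooling == "equal":
        pooled = (pi + pj) / 2
    elif pooling == "count":
        if n_ti <= 0 or n_tj <= 0:
            raise ValueError("count pooling requires positive observation counts")
        pooled = (n_ti * pi + n_tj * pj) / (n_ti + n_tj)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    he_ti = expected_heterozygosity(pi)
    he_tj = expected_heterozygosity(pj)
    he_tot = expected_heterozygosity(pooled)
    if he_tot <= 0:
        g = math.nan
    else:
        g = (he_tot - (he_ti + he_tj) / 2) / he_tot
    return GstValue(dict(freq_ti), dict(freq_tj), n_ti, n_tj, he_ti, he_tj, he_tot, g)


def gst(
    obs_ti: Sequence[str], obs_tj: Sequence[str], pooling: str = "equal"
) -> GstValue:
    """GST from raw allele observations of the two populations."""
    return gst_from_frequencies(
        allele_frequencies(obs_ti),
        allele_frequencies(obs_tj),
        len(list(obs_ti)),
        len(list(obs_tj)),
        pooling,
    )


# ---------------------------------------------------------------------------
# population observations and site classification
# ---------------------------------------------------------------------------

def population_observations(
    panel: GenotypePanel,
    members: Sequence[str],
    site_id: str,
    extra: Optional[Sequence[str]] = None,
) -> List[str]:
    """Allele observations at a site from pure diploid/haploid members plus
    optional extra haplotype observations; missing genotypes excluded."""
    obs: List[str] = []
    for acc in members:
        gt = panel.genotypes.at[site_id, acc]
        if gt is None:
            continue
        obs.extend(gt)
    if extra:
        obs.extend(extra)
    return obs


def _subgroups_fixed(
    panel: GenotypePanel,
    config: PanelConfig,
    members: Sequence[str],
    site_id: str,
    tol: float,
    pooling: str,
) -> bool:
    """True when the taxon's two labelled subgroups are fixed for different
    alleles at the site; also true when no usable subgroup labels exist
    (classification then rests on within-taxon polymorphism alone)."""
    labels = {config.subgroup.get(a) for a in members}
    if None in labels or len(labels) != 2:
        return True
    la, lb = sorted(labels)
    obs_a = population_observations(
        panel, [a for a in members if config.subgroup[a] == la], site_id
    )
    obs_b = population_observations(
        panel, [a for a in members if config.subgroup[a] == lb], site_id
    )
    val = gst(obs_a, obs_b, pooling)
    return val.defined and abs(val.gst - 1) < tol


def classify_sites(
    panel: GenotypePanel,
    config: PanelConfig,
    haplotype_obs: Optional[Mapping[str, Mapping[str, Sequence[str]]]] = None,
    pooling: str = "equal",
    tol: float = GST_ONE_TOL,
) -> pd.DataFrame:
    """Classify every panel site as RM / RR / MM / other / monomorphic.

    A site is RM when inter-taxon GST equals 1 (fixed difference); RR (MM)
    when it is polymorphic only within the reticulata (maxima) pure
    representatives and, where subgroup labels are configured, the subgroups
    are fixed for different alleles; sites with no observations in one
    population are reported as ``undefined``.

    ``haplotype_obs`` optionally maps taxon label ("reticulata"/"maxima") to
    ``{site_id: [alleles]}`` so phased haplotypes can contribute single
    observations alongside the pure diploids.
    """
    pure_r = config.pure_of_taxon("reticulata")
    pure_m = config.pure_of_taxon("maxima")
    hap_r = (haplotype_obs or {}).get("reticulata", {})
    hap_m = (haplotype_obs or {}).get("maxima", {})
    rows = []
    for sid in panel.site_ids:
        obs_r = population_observations(panel, pure_r, sid, hap_r.get(sid))
        obs_m = population_observations(panel, pure_m, sid, hap_m.get(sid))
        val = gst(obs_r, obs_m, pooling)
        if not obs_r or not obs_m:
            cls = "undefined"
        elif val.he_tot <= 0:
            cls = "monomorphic"
        elif abs(val.gst - 1) < tol:
            cls = "RM"
        else:
            poly_r = val.he_ti > 0
            poly_m = val.he_tj > 0
            if poly_r and not poly_m:
                cls = (
                    "RR"
                    if _subgroups_fixed(panel, config, pure_r, sid, tol, pooling)
                    else "other"
                )
            elif poly_m and not poly_r:
                cls = (
                    "MM"
                    if _subgroups_fixed(panel, config, pure_m, sid, tol, pooling)
                    else "other"
                )
            else:
                cls = "other"
        site = panel.sites.loc[sid]
        rows.append(
            {
                "site_id": sid,
                "gene_id": site.gene_id,
                "region": site.region,
                "n_obs_R": val.n_ti,
                "n_obs_M": val.n_tj,
                "p_alt_R": val.freq_ti.get(site.alt, 0.0) if obs_r else math.nan,
                "p_alt_M": val.freq_tj.get(site.alt, 0.0) if obs_m else math.nan,
                "he_R": val.he_ti,
                "he_M": val.he_tj,
                "he_tot": val.he_tot,
                "gst": val.gst,
                "site_class": cls,
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


def gene_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-gene SNP counts in the reference-table layout.

    Columns: total SNPs, interspecific (RM) count and percentage,
    intraspecific (RR+MM) count and percentage, and the intraspecific type
    string (``RR``, ``MM``, ``RR (n) MM (m)`` or ``-``).
    """
    rows = []
    for gid, grp in classified.groupby("gene_id", sort=True):
        total = len(grp)
        inter = int((grp["site_class"] == "RM").sum())
        n_rr = int((grp["site_class"] == "RR").sum())
        n_mm = int((grp["site_class"] == "MM").sum())
        intra = n_rr + n_mm
        if n_rr and n_mm:
            kind = f"RR ({n_rr}) MM ({n_mm})"
        elif n_rr:
            kind = "RR"
        elif n_mm:
            kind = "MM"
        else:
            kind = "-"
        rows.append(
            {
                "gene_id": gid,
                "total_snps": total,
                "interspecific": inter,
                "interspecific_pct": round(inter / total * 100, 1) if total else math.nan,
                "intraspecific": intra,
                "intraspecific_pct": round(intra / total * 100, 1) if total else math.nan,
                "intraspecific_type": kind,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# assay candidates
# ---------------------------------------------------------------------------

@dataclass
class AssayCandidate:
    """A classified SNP with the context an allele-specific PCR assay needs."""

    site_id: str
    gene_id: str
    site_class: str
    region: str
    n_flanking_snps_25: int
    n_flanking_snps_50: int
    flank_up: str
    flank_down: str
    truncated: bool

    @property
    def rank_key(self) -> tuple:
        # fewer SNPs within 25 b, exon preferred, fewer within the 50 b flanks
        return (
            self.n_flanking_snps_25,
            0 if self.region == "exon" else 1,
            self.n_flanking_snps_50,
            self.site_id,
        )


@dataclass
class Shortfall:
    gene_id: str
    wanted_class: str
    requested: int
    available: int


def count_flanking_snps(
    positions: np.ndarray, position: int, window: int
) -> int:
    """Other panel SNPs within ``window`` bases (inclusive) on either side."""
    lo = np.searchsorted(positions, position - window, side="left")
    hi = np.searchsorted(positions, position + window, side="right")
    # the site itself is not its own neighbour
    return int(hi - lo) - int((positions[lo:hi] == position).sum())


def build_candidates(
    classified: pd.DataFrame,
    panel: GenotypePanel,
    sequences: Mapping[str, str],
    flank: int = 50,
    near_window: int = 24,
) -> List[AssayCandidate]:
    """Annotate every classified site with flanking-SNP counts and sequences.

    ``near_window`` implements the "no additional SNP closer than 25 bases"
    criterion as distance <= 24 bp; it is a soft ranking criterion, not a
    hard filter.
    """
    by_chrom = {
        chrom: np.sort(grp["position"].to_numpy())
        for chrom, grp in panel.sites.groupby("chromosome", sort=False)
    }
    out = []
    for sid, row in classified.iterrows():
        site = panel.sites.loc[sid]
        pos = int(site.position)
        positions = by_chrom[site.chromosome]
        seq = sequences[site.chromosome]
        up_start = max(0, pos - 1 - flank)
        flank_up = seq[up_start : pos - 1]
        flank_down = seq[pos : pos + flank]
        out.append(
            AssayCandidate(
                site_id=sid,
                gene_id=row.gene_id if pd.notna(row.gene_id) else "",
                site_class=row.site_class,
                region=str(row.region),
                n_flanking_snps_25=count_flanking_snps(positions, pos, near_window),
                n_flanking_snps_50=count_flanking_snps(positions, pos, flank),
                flank_up=flank_up,
                flank_down=flank_down,
                truncated=len(flank_up) < flank or len(flank_down) < flank,
            )
        )
    return out


def select_assay_candidates(
    classified: pd.DataFrame,
    panel: GenotypePanel,
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
    n_inter: int = 2,
    n_intra: int = 1,
) -> Tuple[List[AssayCandidate], List[Shortfall]]:
    """Pick per-gene assay candidates: the best ``n_inter`` interspecific (RM)
    and ``n_intra`` intraspecific (RR/MM) sites by rank, with shortfalls
    reported for genes lacking qualifying sites."""
    candidates = build_candidates(classified, panel, sequences)
    by_gene: Dict[str, List[AssayCandidate]] = {}
    for c in candidates:
        by_gene.setdefault(c.gene_id, []).append(c)
    selected: List[AssayCandidate] = []
    shortfalls: List[Shortfall] = []
    for gene in genes:
        pool = by_gene.get(gene.gene_id, [])
        inter = sorted((c for c in pool if c.site_class == "RM"), key=lambda c: c.rank_key)
        intra = sorted(
            (c for c in pool if c.site_class in ("RR", "MM")), key=lambda c: c.rank_key
        )
        selected.extend(inter[:n_inter])
        selected.extend(intra[:n_intra])
        if len(inter) < n_inter:
            shortfalls.append(Shortfall(gene.gene_id, "RM", n_inter, len(inter)))
        if len(intra) < n_intra:
            shortfalls.append(Shortfall(gene.gene_id, "RR/MM", n_intra, len(intra)))
    return selected, shortfalls


def candidates_frame(candidates: Sequence[AssayCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": c.site_id,
                "gene_id": c.gene_id,
                "site_class": c.site_class,
                "region": c.region,
                "n_flanking_snps_25": c.n_flanking_snps_25,
                "n_flanking_snps_50": c.n_flanking_snps_50,
                "flank_up": c.flank_up,
                "flank_down": c.flank_down,
                "truncated": c.truncated,
            }
            for c in candidates
        ]
    )
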