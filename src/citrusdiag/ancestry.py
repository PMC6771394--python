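"""Marker orientation, ancestral alleles, per-gene origin calls and summaries.

Once a site is classified as a fixed inter-taxon difference it becomes an
oriented marker: one allele is the *C. reticulata* (R) allele, the other the
*C. maxima* (M) allele, and genotypes are coded 0 / 0.5 / 1 for homozygous-R,
heterozygous and homozygous-M. Per-gene ancestry calls take the unanimous
state across a gene's markers (any disagreement is an unidentified origin),
and summary statistics - introgression rate, observed heterozygosity, marker
redundancy, PCA coordinates - are computed from the coded matrix or the call
table.

For accessions with one parent from a third taxon fixed at the markers
(citron-like), the fixed parental allele can be subtracted from the genotype
to recover the allele inherited from the other parent and call states such
as ``R/medica``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InternalConsistencyError, PedigreeConflictError
from .models import Genotype, GenotypePanel, PanelConfig

DOSAGE = {"R/R": 0, "R/M": 1, "M/M": 2}


@dataclass(frozen=True)
class OrientedMarker:
    """A diagnostic site with taxon-oriented alleles and coding map."""

    site_id: str
    gene_id: str
    allele_R: str
    allele_M: str
    ancestral_allele: Optional[str] = None

    @property
    def coding(self) -> Dict[frozenset, float]:
        return {
            frozenset((self.allele_R,)): 0.0,
            frozenset((self.allele_R, self.allele_M)): 0.5,
            frozenset((self.allele_M,)): 1.0,
        }


@dataclass
class OriginCall:
    """Ancestry state of one accession at one gene with supporting counts."""

    accession: str
    gene_id: str
    state: str  # R/R, M/M, R/M, R/medica, M/medica, undetermined
    n_markers: int
    n_agreeing: int


# ---------------------------------------------------------------------------
# orientation and coding
# ---------------------------------------------------------------------------

def _fixed_allele(panel: GenotypePanel, members: Sequence[str], site_id: str):
    seen = set()
    for acc in members:
        gt = panel.genotypes.at[site_id, acc]
        if gt is None:
            continue
        seen.update(gt)
    if len(seen) == 1:
        return seen.pop()
    return None


def orient_markers(
    panel: GenotypePanel,
    config: PanelConfig,
    classified: pd.DataFrame,
) -> List[OrientedMarker]:
    """Orient every RM-classified site by its fixed alleles in the pure pools."""
    pure_r = config.pure_of_taxon("reticulata")
    pure_m = config.pure_of_taxon("maxima")
    markers = []
    for sid in classified.index[classified["site_class"] == "RM"]:
        a_r = _fixed_allele(panel, pure_r, sid)
        a_m = _fixed_allele(panel, pure_m, sid)
        if a_r is None or a_m is None or a_r == a_m:
            raise InternalConsistencyError(
                f"site {sid} classed RM but pure pools not fixed for "
                f"different alleles (R={a_r}, M={a_m})"
            )
        markers.append(
            OrientedMarker(sid, str(classified.at[sid, "gene_id"]), a_r, a_m)
        )
    return markers


def infer_ancestral_allele(
    panel: GenotypePanel,
    site_id: str,
    outgroup_accessions: Sequence[str],
    threshold: float = 1.0,
) -> Optional[str]:
    """The allele carried homozygously by at least ``threshold`` of the
    non-missing outgroups; ``None`` when no allele reaches it."""
    hom_counts: Dict[str, int] = {}
    n = 0
    for acc in outgroup_accessions:
        gt = panel.genotypes.at[site_id, acc]
        if gt is None:
            continue
        n += 1
        alleles = set(gt)
        if len(alleles) == 1:
            a = alleles.pop()
            hom_counts[a] = hom_counts.get(a, 0) + 1
    if n == 0:
        return None
    for allele, c in sorted(hom_counts.items()):
        if c / n >= threshold:
            return allele
    return None


def attach_ancestral_alleles(
    panel: GenotypePanel,
    config: PanelConfig,
    markers: Sequence[OrientedMarker],
    threshold: float = 1.0,
) -> List[OrientedMarker]:
    outgroups = config.outgroup_accessions()
    return [
        OrientedMarker(
            m.site_id,
            m.gene_id,
            m.allele_R,
            m.allele_M,
            infer_ancestral_allele(panel, m.site_id, outgroups, threshold),
        )
        for m in markers
    ]


def code_genotype(gt: Genotype, marker: OrientedMarker) -> float:
    """Code one genotype at an oriented marker; NaN for missing or alleles
    outside the marker's pair (logged by callers as undetermined)."""
    if gt is None:
        return math.nan
    return marker.coding.get(frozenset(gt), math.nan)


def code_genotypes(
    panel: GenotypePanel, markers: Sequence[OrientedMarker]
) -> pd.DataFrame:
    """Coded matrix: accession rows x marker columns with 0 / 0.5 / 1 / NaN."""
    data = {}
    for m in markers:
        col = panel.genotypes.loc[m.site_id]
        data[m.site_id] = [code_genotype(col[acc], m) for acc in panel.accessions]
    return pd.DataFrame(data, index=panel.accessions)


# ---------------------------------------------------------------------------
# origin calls
# ---------------------------------------------------------------------------

def call_locus_origin(gt: Genotype, marker: OrientedMarker) -> str:
    """Single-marker ancestry state: R/R, M/M, R/M, missing or undetermined."""
    if gt is None:
        return "missing"
    alleles = set(gt)
    if not alleles <= {marker.allele_R, marker.allele_M}:
        return "undetermined"
    if alleles == {marker.allele_R}:
        return "R/R"
    if alleles == {marker.allele_M}:
        return "M/M"
    return "R/M"


def call_gene_origin(
    panel: GenotypePanel,
    accession: str,
    markers: Sequence[OrientedMarker],
    majority: bool = False,
) -> OriginCall:
    """Consensus ancestry of one accession at one gene.

    Default rule is strict unanimity over the non-missing marker states; any
    disagreement (or no usable marker) yields ``undetermined``. With
    ``majority=True`` the modal state wins and ties are undetermined.
    """
    if not markers:
        raise ValueError("call_gene_origin requires at least one marker")
    gene_id = markers[0].gene_id
    states = []
    for m in markers:
        s = call_locus_origin(panel.genotypes.at[m.site_id, accession], m)
        if s not in ("missing", "undetermined"):
            states.append(s)
    n = len(states)
    if n == 0:
        return OriginCall(accession, gene_id, "undetermined", 0, 0)
    counts = pd.Series(states).value_counts()
    top = counts.iloc[0]
    if majority:
        tied = (counts == top).sum() > 1
        state = "undetermined" if tied else counts.index[0]
    else:
        state = counts.index[0] if len(counts) == 1 else "undetermined"
    return OriginCall(accession, gene_id, state, n, int(top))


def call_panel_origins(
    panel: GenotypePanel,
    markers: Sequence[OrientedMarker],
    accessions: Optional[Sequence[str]] = None,
    majority: bool = False,
) -> Tuple[pd.DataFrame, float]:
    """Call every accession x gene cell; also return the panel-wide marker
    agreement rate over cells with at least two usable markers."""
    if accessions is None:
        accessions = panel.accessions
    by_gene: Dict[str, List[OrientedMarker]] = {}
    for m in markers:
        by_gene.setdefault(m.gene_id, []).append(m)
    calls = {}
    agree = total = 0
    for gid in sorted(by_gene):
        col = {}
        for acc in accessions:
            c = call_gene_origin(panel, acc, by_gene[gid], majority)
            col[acc] = c.state
            if c.n_markers >= 2:
                total += 1
                if c.n_agreeing == c.n_markers and c.state != "undetermined":
                    agree += 1
        calls[gid] = col
    frame = pd.DataFrame(calls, index=list(accessions))
    rate = agree / total if total else math.nan
    return frame, rate


def subtract_fixed_parent(gt: Genotype, fixed_allele: str) -> str:
    """Allele inherited from the non-fixed parent, given the other parent is
    fixed for ``fixed_allele``.

    Heterozygous {c, x} -> x; homozygous {c, c} -> c; a genotype lacking the
    fixed allele contradicts the documented pedigree and raises
    :class:`PedigreeConflictError`.
    """
    if gt is None:
        raise ValueError("cannot subtract from a missing genotype")
    alleles = list(gt) if len(gt) == 2 else [gt[0], gt[0]]
    if fixed_allele not in alleles:
        raise PedigreeConflictError(
            f"genotype {gt} lacks the fixed parental allele {fixed_allele}"
        )
    alleles.remove(fixed_allele)
    return alleles[0]


def fixed_parent_alleles(
    panel: GenotypePanel,
    config: PanelConfig,
    parent_taxon: str,
    markers: Sequence[OrientedMarker],
) -> Dict[str, Optional[str]]:
    """Per marker, the allele the parent taxon is fixed for (None when the
    taxon is polymorphic there; such markers are skipped downstream)."""
    members = config.accessions_of_taxon(parent_taxon)
    return {m.site_id: _fixed_allele(panel, members, m.site_id) for m in markers}


def call_gene_origin_with_fixed_parent(
    panel: GenotypePanel,
    accession: str,
    markers: Sequence[OrientedMarker],
    fixed_alleles: Mapping[str, Optional[str]],
    parent_label: str = "medica",
) -> OriginCall:
    """Consensus origin of the non-fixed-parent allele for an accession with a
    documented fixed-taxon parent (e.g. ``R/medica``).

    Markers where the parent taxon is not fixed are skipped; pedigree
    conflicts at individual markers make the gene undetermined.
    """
    if not markers:
        raise ValueError("requires at least one marker")
    gene_id = markers[0].gene_id
    sides = []
    conflict = False
    for m in markers:
        c = fixed_alleles.get(m.site_id)
        if c is None:
            continue
        gt = panel.genotypes.at[m.site_id, accession]
        if gt is None:
            continue
        try:
            inherited = subtract_fixed_parent(gt, c)
        except PedigreeConflictError:
            conflict = True
            continue
        if inherited == m.allele_R:
            sides.append("R")
        elif inherited == m.allele_M:
            sides.append("M")
    n = len(sides)
    if n == 0 or conflict:
        return OriginCall(accession, gene_id, "undetermined", n, 0)
    counts = pd.Series(sides).value_counts()
    if len(counts) == 1:
        return OriginCall(
            accession, gene_id, f"{counts.index[0]}/{parent_label}", n, int(counts.iloc[0])
        )
    return OriginCall(accession, gene_id, "undetermined", n, int(counts.iloc[0]))


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def introgression_rate(calls: pd.DataFrame) -> float:
    """Fraction of M alleles over the determined cells of a call table.

    ``calls`` holds states (R/R, R/M, M/M, anything else excluded); the rate
    is the total M dosage divided by two alleles per determined cell.
    """
    dosage = 0
    cells = 0
    for state in calls.to_numpy().ravel():
        if state in DOSAGE:
            dosage += DOSAGE[state]
            cells += 1
    if cells == 0:
        return math.nan
    return dosage / (2 * cells)


def observed_heterozygosity(coded: Sequence[float]) -> float:
    """Fraction of heterozygous (0.5) entries among non-missing coded values."""
    arr = np.asarray(list(coded), dtype=float)
    ok = ~np.isnan(arr)
    if not ok.any():
        return math.nan
    return float((arr[ok] == 0.5).mean())


def heterozygosity_table(coded: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {acc: observed_heterozygosity(coded.loc[acc]) for acc in coded.index},
        name="observed_heterozygosity",
    )


def detect_redundant_markers(
    coded: pd.DataFrame, missing_wildcard: bool = False
) -> List[List[str]]:
    """Groups of markers (columns) with identical coded patterns.

    By default missing entries must match exactly; with
    ``missing_wildcard=True`` a missing entry is compatible with anything and
    markers are grouped greedily by compatibility with the group's
    representative column.
    """
    cols = list(coded.columns)
    if not missing_wildcard:
        buckets: Dict[tuple, List[str]] = {}
        for c in cols:
            key = tuple(
                None if (isinstance(v, float) and math.isnan(v)) else v
                for v in coded[c]
            )
            buckets.setdefault(key, []).append(c)
        return [grp for grp in buckets.values() if len(grp) >= 2]
    groups: List[List[str]] = []
    reps: List[np.ndarray] = []
    for c in cols:
        v = coded[c].to_numpy(dtype=float)
        placed = False
        for rep, grp in zip(reps, groups):
            both = ~np.isnan(v) & ~np.isnan(rep)
            if (v[both] == rep[both]).all():
                grp.append(c)
                placed = True
                break
        if not placed:
            groups.append([c])
            reps.append(v)
    return [g for g in groups if len(g) >= 2]


def pca_coordinates(
    coded: pd.DataFrame, n_components: Optional[int] = None
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of the coded matrix (accessions x markers).

    Missing entries are mean-imputed per marker; coordinates come from the
    eigendecomposition of the covariance of the centred values. Returns the
    sample coordinates and the explained-variance fractions.
    """
    from sklearn.decomposition import PCA

    if coded.shape[0] < 2 or coded.shape[1] < 2:
        raise ValueError("PCA needs at least 2 accessions and 2 markers")
    x = coded.to_numpy(dtype=float)
    col_means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(col_means, idx[1])
    if np.allclose(x, x[0]):
        warnings.warn("coded matrix has zero variance; coordinates are all zero")
        k = n_components or min(coded.shape[0] - 1, coded.shape[1])
        coords = pd.DataFrame(
            np.zeros((coded.shape[0], k)),
            index=coded.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return coords, np.zeros(k)
    k = n_components or min(coded.shape[0] - 1, coded.shape[1], 10)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    coords = pd.DataFrame(
        scores, index=coded.index, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    return coords, pca.explained_variance_ratio_


def simple_matching_distance(coded: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - simple-matching similarity between accessions, computed
    over markers non-missing in both; used for the reporting heatmap."""
    accs = list(coded.index)
    x = coded.to_numpy(dtype=float)
    n = len(accs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if both.sum() == 0:
                dist = 1.0
            else:
                dist = float((x[i, both] != x[j, both]).mean())
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=accs, columns=accs)


def origin_heatmap(coded: pd.DataFrame, path: str) -> None:
    """Clustered heatmap of the coded matrix (reporting only).

    Rows (accessions) are ordered by hierarchical clustering on the
    simple-matching distance; cell colours follow the 0 / 0.5 / 1 coding.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    dist = simple_matching_distance(coded)
    order = list(coded.index)
    if len(order) > 2:
        z = linkage(squareform(dist.to_numpy(), checks=False), method="average")
        order = [coded.index[i] for i in leaves_list(z)]
    mat = coded.loc[order].to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(4, coded.shape[1] * 0.12), max(3, len(order) * 0.25))
    )
    im = ax.imshow(mat, aspect="auto", cmap="coolwarm", vmin=0, vmax=1)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=6)
    ax.set_xticks([])
    ax.set_xlabel("markers")
    fig.colorbar(im, ax=ax, label="coded genotype (0=R/R, 0.5=R/M, 1=M/M)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
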