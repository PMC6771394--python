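"""Marker orientation, origin calls, introgression and diversity summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from citrusdiag.ancestry import (
    OrientedMarker,
    attach_ancestral_alleles,
    call_gene_origin,
    call_gene_origin_with_fixed_parent,
    call_locus_origin,
    call_panel_origins,
    code_genotypes,
    detect_redundant_markers,
    fixed_parent_alleles,
    heterozygosity_table,
    infer_ancestral_allele,
    introgression_rate,
    observed_heterozygosity,
    orient_markers,
    pca_coordinates,
    subtract_fixed_parent,
)
from citrusdiag.errors import InternalConsistencyError, PedigreeConflictError
from citrusdiag.markers import classify_sites
from citrusdiag.models import GenotypePanel, PanelConfig


@pytest.fixture(scope="module")
def oriented_setup(clean_sim):
    panel, genes, config, truth = clean_sim
    classified = classify_sites(panel, config)
    markers = orient_markers(panel, config, classified)
    markers = attach_ancestral_alleles(panel, config, markers)
    return panel, genes, config, truth, classified, markers


# ---------------------------------------------------------------------------
# orientation and coding
# ---------------------------------------------------------------------------

def test_orientation_matches_truth_founders(oriented_setup):
    panel, genes, config, truth, classified, markers = oriented_setup
    pure_r = config.pure_of_taxon("reticulata")[0]
    pure_m = config.pure_of_taxon("maxima")[0]
    for m in markers:
        i = panel.gene_sites(m.gene_id).index(m.site_id)
        assert m.allele_R == truth.haplotypes[(pure_r, m.gene_id)][0][i]
        assert m.allele_M == truth.haplotypes[(pure_m, m.gene_id)][0][i]
        assert m.allele_R != m.allele_M


def test_orientation_rejects_non_fixed_pools(clean_sim):
    panel, genes, config, truth = clean_sim
    classified = classify_sites(panel, config)
    tampered = panel.copy()
    rm_site = classified.index[classified["site_class"] == "RM"][0]
    pure_r = config.pure_of_taxon("reticulata")[0]
    a_m = next(
        m for m in orient_markers(panel, config, classified) if m.site_id == rm_site
    ).allele_M
    tampered.set_genotype(rm_site, pure_r, (a_m, a_m))
    with pytest.raises(InternalConsistencyError):
        orient_markers(tampered, config, classified)


def test_coded_matrix_matches_truth_dosage(oriented_setup):
    panel, genes, config, truth, classified, markers = oriented_setup
    coded = code_genotypes(panel, markers)
    for m in markers:
        i = panel.gene_sites(m.gene_id).index(m.site_id)
        for acc in panel.accessions:
            if panel.ploidy[acc] != 2:
                continue
            h1, h2 = truth.haplotypes[(acc, m.gene_id)]
            expected = (h1[i] == m.allele_M) / 2 + (h2[i] == m.allele_M) / 2
            assert coded.at[acc, m.site_id] == pytest.approx(expected)


def test_ancestral_allele_inference(oriented_setup):
    panel, genes, config, truth, classified, markers = oriented_setup
    for m in markers:
        assert m.ancestral_allele == truth.ancestral_allele[m.site_id]


def test_ancestral_allele_split_outgroups_is_unknown():
    sites = pd.DataFrame(
        {"chromosome": "chr1", "position": [10], "ref": ["A"], "alt": ["G"]},
        index=["chr1:10"],
    )
    gts = pd.DataFrame(
        {"o1": [("A", "A")], "o2": [("G", "G")]}, index=sites.index, dtype=object
    )
    panel = GenotypePanel(sites, gts, {"o1": 2, "o2": 2})
    assert infer_ancestral_allele(panel, "chr1:10", ["o1", "o2"]) is None
    assert infer_ancestral_allele(panel, "chr1:10", ["o1"]) == "A"
    # relaxed threshold accepts the majority allele
    assert infer_ancestral_allele(panel, "chr1:10", ["o1", "o2"], threshold=0.5) == "A"


# ---------------------------------------------------------------------------
# locus and gene origin calls
# ---------------------------------------------------------------------------

MARKER = OrientedMarker("chr1:10", "g", "A", "G")


@pytest.mark.parametrize(
    "gt,state",
    [
        (("A", "A"), "R/R"),
        (("G", "G"), "M/M"),
        (("A", "G"), "R/M"),
        (None, "missing"),
        (("A", "T"), "undetermined"),
    ],
)
def test_locus_origin_states(gt, state):
    assert call_locus_origin(gt, MARKER) == state


def _mini_panel(gts_by_site):
    sids = list(gts_by_site)
    sites = pd.DataFrame(
        {
            "chromosome": "chr1",
            "position": [int(s.split(":")[1]) for s in sids],
            "ref": "A",
            "alt": "G",
            "gene_id": "g",
        },
        index=sids,
    )
    gts = pd.DataFrame({"acc": [gts_by_site[s] for s in sids]}, index=sids, dtype=object)
    return GenotypePanel(sites, gts, {"acc": 2})


def test_gene_origin_unanimity_and_discrepancy():
    m1 = OrientedMarker("chr1:10", "g", "A", "G")
    m2 = OrientedMarker("chr1:20", "g", "A", "G")
    panel = _mini_panel({"chr1:10": ("A", "G"), "chr1:20": ("A", "G")})
    call = call_gene_origin(panel, "acc", [m1, m2])
    assert (call.state, call.n_markers, call.n_agreeing) == ("R/M", 2, 2)
    panel = _mini_panel({"chr1:10": ("A", "A"), "chr1:20": ("G", "G")})
    assert call_gene_origin(panel, "acc", [m1, m2]).state == "undetermined"
    panel = _mini_panel({"chr1:10": None, "chr1:20": None})
    assert call_gene_origin(panel, "acc", [m1, m2]).state == "undetermined"
    # permutation invariance
    panel = _mini_panel({"chr1:10": ("A", "G"), "chr1:20": ("A", "G")})
    assert (
        call_gene_origin(panel, "acc", [m2, m1]).state
        == call_gene_origin(panel, "acc", [m1, m2]).state
    )


def test_f1_genes_all_interspecific_heterozygous(oriented_setup):
    panel, genes, config, truth, classified, markers = oriented_setup
    calls, _ = call_panel_origins(panel, markers)
    f1_states = calls.loc["f1_1"].dropna()
    assert (f1_states == "R/M").all()
    coded = code_genotypes(panel, markers)
    assert observed_heterozygosity(coded.loc["f1_1"]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# citron-style fixed-parent subtraction
# ---------------------------------------------------------------------------

def test_subtract_fixed_parent_rules():
    assert subtract_fixed_parent(("A", "G"), "A") == "G"
    assert subtract_fixed_parent(("A", "A"), "A") == "A"
    with pytest.raises(PedigreeConflictError):
        subtract_fixed_parent(("G", "G"), "A")


def test_medica_cross_recovered_as_r_medica(oriented_setup):
    """A reticulata x citron-like accession: every informative gene calls
    R/medica, mirroring a direct mandarin x citron origin."""
    panel, genes, config, truth, classified, markers = oriented_setup
    panel = panel.copy()
    config = PanelConfig(
        taxon=dict(config.taxon),
        pure=set(config.pure),
        pedigree=dict(config.pedigree),
        haploid_of=dict(config.haploid_of),
        outgroup=set(config.outgroup),
        subgroup=dict(config.subgroup),
    )
    gts = {}
    for g in genes:
        r_hap = truth.haplotypes[("pure_R_1", g.gene_id)][0]
        for sid, r_allele in zip(panel.gene_sites(g.gene_id), r_hap):
            anc = truth.ancestral_allele[sid]
            gts[sid] = tuple(sorted((r_allele, anc)))
    panel.add_accession("volkamer_like", 2, gts)
    config.taxon["volkamer_like"] = "hybrid"
    fixed = fixed_parent_alleles(panel, config, "outgroup", markers)
    assert all(v is not None for v in fixed.values())  # outgroups fully fixed
    by_gene = {}
    for m in markers:
        by_gene.setdefault(m.gene_id, []).append(m)
    for gid, ms in by_gene.items():
        call = call_gene_origin_with_fixed_parent(panel, "volkamer_like", ms, fixed)
        if call.n_markers:
            assert call.state == "R/medica", gid


# ---------------------------------------------------------------------------
# introgression rate
# ---------------------------------------------------------------------------

def test_introgression_all_homozygous_r_is_zero():
    calls = pd.DataFrame({"g1": ["R/R"] * 5, "g2": ["R/R"] * 5})
    assert introgression_rate(calls) == 0.0


def test_introgression_printed_counts_worked_example():
    """Two genes over 22 accessions: 8 het + 1 hom-M and 13 het + 1 hom-M
    give an M-allele rate of 25/88 = 28.4%."""
    gene_a = ["R/M"] * 8 + ["M/M"] + ["R/R"] * 13
    gene_b = ["R/M"] * 13 + ["M/M"] + ["R/R"] * 8
    calls = pd.DataFrame({"GDR_3": gene_a, "PAO_8": gene_b})
    rate = introgression_rate(calls)
    assert rate == pytest.approx(25 / 88)
    assert round(rate * 100, 1) == 28.4


def test_introgression_matches_counting_oracle():
    rng = np.random.default_rng(0)
    states = np.array(["R/R", "R/M", "M/M", "undetermined"])
    for _ in range(20):
        calls = pd.DataFrame(
            rng.choice(states, size=(8, 5), p=[0.4, 0.3, 0.2, 0.1])
        )
        dosage = {"R/R": 0, "R/M": 1, "M/M": 2}
        num = sum(dosage[s] for s in calls.to_numpy().ravel() if s in dosage)
        den = 2 * sum(1 for s in calls.to_numpy().ravel() if s in dosage)
        expected = num / den if den else math.nan
        got = introgression_rate(calls)
        if den:
            assert got == pytest.approx(expected)
            assert 0 <= got <= 1


def test_introgression_equals_mean_coded_dosage(oriented_setup):
    """Marker-level call table: the rate is exactly the mean coded value."""
    panel, genes, config, truth, classified, markers = oriented_setup
    from citrusdiag.ancestry import OrientedMarker, call_locus_origin

    dips = [a for a in panel.accessions if panel.ploidy[a] == 2]
    coded = code_genotypes(panel, markers).loc[dips]
    per_marker_calls = pd.DataFrame(
        {
            m.site_id: [
                call_locus_origin(panel.genotypes.at[m.site_id, acc], m)
                for acc in dips
            ]
            for m in markers
        },
        index=dips,
    )
    assert introgression_rate(per_marker_calls) == pytest.approx(
        float(np.nanmean(coded.to_numpy()))
    )


def test_bc1_introgression_near_quarter(bc_sim):
    """Planted BC1-to-R accessions show ~25% M-allele dosage."""
    panel, genes, config, truth = bc_sim
    classified = classify_sites(panel, config)
    markers = orient_markers(panel, config, classified)
    assert len(markers) >= 200
    calls, _ = call_panel_origins(
        panel, markers, accessions=[f"bc{i + 1}" for i in range(12)]
    )
    rate = introgression_rate(calls)
    n_cells = int(calls.isin(["R/R", "R/M", "M/M"]).to_numpy().sum())
    se = 0.5 * math.sqrt(0.25 / n_cells)
    assert abs(rate - 0.25) <= 3 * se


# ---------------------------------------------------------------------------
# heterozygosity, redundancy, PCA
# ---------------------------------------------------------------------------

def test_observed_heterozygosity_examples():
    assert observed_heterozygosity([0.5, 0.5]) == pytest.approx(1.0)
    assert observed_heterozygosity([0, 1, 0.5, math.nan]) == pytest.approx(1 / 3)
    assert math.isnan(observed_heterozygosity([math.nan]))


def test_heterozygosity_contrast_pure_vs_f1(oriented_setup):
    panel, genes, config, truth, classified, markers = oriented_setup
    het = heterozygosity_table(code_genotypes(panel, markers))
    assert het["f1_1"] == pytest.approx(1.0)
    assert het["pure_R_1"] == pytest.approx(0.0)
    assert het["pure_M_1"] == pytest.approx(0.0)


def test_redundancy_detection_matches_pairwise_oracle():
    rng = np.random.default_rng(1)
    base = rng.choice([0.0, 0.5, 1.0], size=(10, 6))
    coded = pd.DataFrame(base, columns=[f"m{i}" for i in range(6)])
    coded["m6"] = coded["m2"]  # planted duplicate
    coded["m7"] = coded["m4"]
    groups = detect_redundant_markers(coded)
    # brute-force pairwise comparison
    cols = list(coded.columns)
    expected_pairs = {
        (a, b)
        for i, a in enumerate(cols)
        for b in cols[i + 1 :]
        if list(coded[a]) == list(coded[b])
    }
    got_pairs = {
        (a, b) for grp in groups for i, a in enumerate(grp) for b in grp[i + 1 :]
    }
    assert got_pairs == expected_pairs
    assert {"m2", "m6"} <= {m for grp in groups for m in grp}


def test_redundancy_all_distinct_gives_no_groups():
    coded = pd.DataFrame([[0.0, 0.5], [1.0, 0.5], [0.0, 0.0]], columns=["a", "b"])
    assert detect_redundant_markers(coded) == []


def test_pca_identical_accessions_share_coordinates():
    coded = pd.DataFrame(
        [[0, 0, 1], [0, 0, 1], [1, 1, 0]], index=["a", "b", "c"], dtype=float
    )
    coords, _ = pca_coordinates(coded)
    assert np.allclose(coords.loc["a"], coords.loc["b"])


def test_pca_hand_two_by_two():
    coded = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["a", "b"])
    coords, explained = pca_coordinates(coded)
    # centred rows are (+-0.5, +-0.5); the single axis carries everything
    assert explained[0] == pytest.approx(1.0)
    assert abs(coords.iloc[0, 0]) == pytest.approx(math.sqrt(0.5))
    assert coords.iloc[0, 0] == pytest.approx(-coords.iloc[1, 0])


def test_pca_f1_midway_between_pure_clusters(oriented_setup):
    panel, genes, config, truth, classified, markers = oriented_setup
    coded = code_genotypes(panel, markers)
    dips = [a for a in panel.accessions if panel.ploidy[a] == 2]
    coords, explained = pca_coordinates(coded.loc[dips])
    pure_r = coords.loc[config.pure_of_taxon("reticulata"), "PC1"].mean()
    pure_m = coords.loc[config.pure_of_taxon("maxima"), "PC1"].mean()
    f1 = coords.at["f1_1", "PC1"]
    midpoint = (pure_r + pure_m) / 2
    spread = abs(pure_r - pure_m)
    assert spread > 0
    assert abs(f1 - midpoint) <= 0.25 * spread
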