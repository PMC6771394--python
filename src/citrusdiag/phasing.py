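"""Pedigree-guided haplotype phasing, gene by gene.

The entry points mirror how haplotypes can be traced through a citrus-style
pedigree without any statistical phasing:

1. a haploid derivative of a diploid accession directly exposes one
   haplotype; the second follows by complementation against the diploid
   genotype (:func:`deduce_second_haplotype`);
2. each haplotype is attributed to one of the accession's two parents by
   counting incongruences - sites where a candidate parent is homozygous for
   the allele the haplotype does not carry
   (:func:`assign_haplotypes_to_parents`);
3. the complement rule applied to each parent yields the parent's second
   haplotype (:func:`infer_parent_second_haplotype`);
4. a fully haplotyped parent lets both haplotypes of any of its descendants
   be recovered (:func:`propagate_to_descendant`).

Phasing is strictly per gene: no linkage between genes is assumed, and a
gamete is taken to transmit one parental gene haplotype intact.

Haplotype allele vectors are sequences ordered like
``GenotypePanel.gene_sites(gene_id)``; ``None`` marks an unknown allele.
Genotypes are unordered allele tuples or ``None`` when missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import AmbiguousParentageError, PhaseConflictError
from .models import GenotypePanel, Haplotype, PanelConfig

AlleleVec = Sequence[Optional[str]]
GenoVec = Sequence[Optional[tuple]]


@dataclass
class IncongruenceReport:
    """Sites at which a candidate parent contradicts a haplotype."""

    haplotype: str
    candidate_parent: str
    n_tested: int
    n_incongruent: int

    @property
    def fraction(self) -> float:
        return self.n_incongruent / self.n_tested if self.n_tested else math.nan


def _complement(genotypes: GenoVec, h1: AlleleVec, on_conflict: str = "raise"):
    """Core complement rule shared by the second-haplotype deductions."""
    h2: List[Optional[str]] = []
    conflicts: List[int] = []
    for i, (gt, a1) in enumerate(zip(genotypes, h1)):
        if gt is None:
            h2.append(None)
            continue
        if len(gt) == 1:
            gt = (gt[0], gt[0])
        if gt[0] == gt[1]:
            if a1 is not None and a1 != gt[0]:
                if on_conflict == "raise":
                    raise PhaseConflictError(
                        f"site {i}: diploid homozygous {gt[0]}/{gt[0]} but "
                        f"haplotype carries {a1}",
                        site=i,
                    )
                conflicts.append(i)
                h2.append(None)
                continue
            h2.append(gt[0])
        else:
            if a1 is None:
                h2.append(None)
            elif a1 == gt[0]:
                h2.append(gt[1])
            elif a1 == gt[1]:
                h2.append(gt[0])
            else:
                if on_conflict == "raise":
                    raise PhaseConflictError(
                        f"site {i}: haplotype allele {a1} absent from "
                        f"heterozygous genotype {gt}",
                        site=i,
                    )
                conflicts.append(i)
                h2.append(None)
    return h2, conflicts


def deduce_second_haplotype(
    diploid_genotypes: GenoVec, h1: AlleleVec, on_conflict: str = "raise"
) -> List[Optional[str]]:
    """Deduce the second haplotype of a diploid given one known haplotype.

    At heterozygous sites the second haplotype carries the allele of the pair
    not equal to ``h1``; at homozygous sites it carries that allele; at
    missing sites it is unknown. A homozygous genotype contradicting ``h1``
    raises :class:`PhaseConflictError` (``on_conflict="mask"`` instead marks
    the site unknown).
    """
    h2, _ = _complement(diploid_genotypes, h1, on_conflict)
    return h2


def infer_parent_second_haplotype(
    parent_genotypes: GenoVec, transmitted: AlleleVec, on_conflict: str = "raise"
) -> List[Optional[str]]:
    """Complement a parent's genotype against the haplotype it transmitted."""
    h2, _ = _complement(parent_genotypes, transmitted, on_conflict)
    return h2


def score_parent_incongruence(
    hap_alleles: AlleleVec,
    parent_genotypes: GenoVec,
    haplotype_id: str = "hap",
    parent_id: str = "parent",
) -> IncongruenceReport:
    """Count sites where the parent is homozygous for the complementary allele.

    Missing entries (either side) are skipped and excluded from ``n_tested``.
    """
    tested = incongruent = 0
    for a, gt in zip(hap_alleles, parent_genotypes):
        if a is None or gt is None:
            continue
        tested += 1
        alleles = gt if len(gt) == 2 else (gt[0], gt[0])
        if alleles[0] == alleles[1] and alleles[0] != a:
            incongruent += 1
    return IncongruenceReport(haplotype_id, parent_id, tested, incongruent)


def assign_haplotypes_to_parents(
    h1: Haplotype,
    h2: Haplotype,
    parent_a_genotypes: GenoVec,
    parent_b_genotypes: GenoVec,
    parent_a: str = "parentA",
    parent_b: str = "parentB",
    tolerance: float = 0.0,
) -> Tuple[Dict[str, str], List[IncongruenceReport]]:
    """Attribute each haplotype to the parent it is compatible with.

    A haplotype is compatible with a parent when its incongruence fraction is
    at or below ``tolerance`` (and at least one site was testable). The
    assignment must be a bijection; when both orientations are valid the input
    order is kept (H1 -> parent A), a deterministic, arbitrary tie-break.
    ``source_parent`` is set on both haplotypes.
    """
    reports = [
        score_parent_incongruence(h1.alleles, parent_a_genotypes, "H1", parent_a),
        score_parent_incongruence(h1.alleles, parent_b_genotypes, "H1", parent_b),
        score_parent_incongruence(h2.alleles, parent_a_genotypes, "H2", parent_a),
        score_parent_incongruence(h2.alleles, parent_b_genotypes, "H2", parent_b),
    ]
    r1a, r1b, r2a, r2b = reports

    def ok(rep: IncongruenceReport) -> bool:
        return rep.n_tested > 0 and rep.fraction <= tolerance

    straight = ok(r1a) and ok(r2b)
    crossed = ok(r1b) and ok(r2a)
    if straight:
        mapping = {"H1": parent_a, "H2": parent_b}
    elif crossed:
        mapping = {"H1": parent_b, "H2": parent_a}
    else:
        raise AmbiguousParentageError(
            f"gene {h1.gene_id}: no consistent bijection of haplotypes onto "
            f"parents ({parent_a}, {parent_b})"
        )
    h1.source_parent = mapping["H1"]
    h2.source_parent = mapping["H2"]
    return mapping, reports


def propagate_to_descendant(
    descendant_genotypes: GenoVec,
    parent_h1: AlleleVec,
    parent_h2: AlleleVec,
    tolerance: float = 0.0,
) -> Tuple[List[Optional[str]], List[Optional[str]]]:
    """Recover both haplotypes of a descendant of a fully haplotyped parent.

    The transmitted haplotype is the parental one compatible with the
    descendant's genotypes (an allele conflicts when the descendant's
    genotype, treated as an allele set, does not contain it); the other
    haplotype follows by complementation. Raises
    :class:`AmbiguousParentageError` when neither or both parental haplotypes
    are compatible.
    """

    def violations(hap: AlleleVec) -> Tuple[int, int]:
        tested = bad = 0
        for a, gt in zip(hap, descendant_genotypes):
            if a is None or gt is None:
                continue
            tested += 1
            if a not in gt:
                bad += 1
        return tested, bad

    scores = []
    for hap in (parent_h1, parent_h2):
        tested, bad = violations(hap)
        frac = bad / tested if tested else math.inf
        scores.append((tested > 0 and frac <= tolerance))
    if scores[0] == scores[1]:
        raise AmbiguousParentageError(
            "neither parental haplotype uniquely compatible with descendant"
            if not scores[0]
            else "both parental haplotypes compatible with descendant"
        )
    transmitted = list(parent_h1 if scores[0] else parent_h2)
    other = deduce_second_haplotype(descendant_genotypes, transmitted)
    return transmitted, other


# ---------------------------------------------------------------------------
# panel-level driver
# ---------------------------------------------------------------------------

@dataclass
class PhasingResult:
    """Phased haplotypes plus genes/sites flagged during phasing."""

    haplotypes: Dict[Tuple[str, str], Tuple[Haplotype, Haplotype]]
    flagged: List[Tuple[str, str, str]]  # (accession, gene_id, reason)

    def table(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        for (acc, gid), pair in sorted(self.haplotypes.items()):
            for hap in pair:
                rows.append(
                    {
                        "accession": acc,
                        "gene_id": gid,
                        "hap_index": hap.hap_index,
                        "source_parent": hap.source_parent or "",
                        "alleles": ",".join(a if a is not None else "." for a in hap.alleles),
                    }
                )
        return pd.DataFrame(rows)


def phase_panel(
    panel: GenotypePanel,
    gene_ids: Sequence[str],
    config: PanelConfig,
    tolerance: float = 0.0,
) -> PhasingResult:
    """Phase every accession reachable from the haploid derivatives.

    For each haploid derivative the diploid source is phased directly; if the
    diploid has recorded parents, haplotypes are attributed to them and the
    parents' second haplotypes inferred; phased parents are then propagated
    to further pedigree descendants until nothing changes. Site-level phase
    conflicts are masked (allele set unknown) and flagged; genes with
    ambiguous parentage are flagged and left unphased for that step.
    """
    result = PhasingResult({}, [])

    def store(acc, gid, a1, a2, sp1=None, sp2=None):
        result.haplotypes[(acc, gid)] = (
            Haplotype(acc, gid, tuple(a1), 0, sp1),
            Haplotype(acc, gid, tuple(a2), 1, sp2),
        )

    # step 1: haploid derivatives expose one haplotype of their source diploid
    for haploid, diploid in sorted(config.haploid_of.items()):
        for gid in gene_ids:
            sids = panel.gene_sites(gid)
            h1 = [
                (panel.genotypes.at[s, haploid] or (None,))[0] for s in sids
            ]
            dip = [panel.genotypes.at[s, diploid] for s in sids]
            h2, conflicts = _complement(dip, h1, on_conflict="mask")
            for c in conflicts:
                result.flagged.append((diploid, gid, f"phase conflict at {sids[c]}"))
            store(diploid, gid, h1, h2)

    # step 2: attribute trio-offspring haplotypes to parents, phase parents
    for off, (pa, pb) in sorted(config.pedigree.items()):
        for gid in gene_ids:
            if (off, gid) not in result.haplotypes:
                continue
            hp = result.haplotypes[(off, gid)]
            ga = panel.gene_genotypes(pa, gid)
            gb = panel.gene_genotypes(pb, gid)
            try:
                mapping, _reports = assign_haplotypes_to_parents(
                    hp[0], hp[1], ga, gb, pa, pb, tolerance
                )
            except AmbiguousParentageError as exc:
                result.flagged.append((off, gid, str(exc)))
                continue
            for hap, parent_gts, parent in (
                (hp[0], ga if mapping["H1"] == pa else gb, mapping["H1"]),
                (hp[1], ga if mapping["H2"] == pa else gb, mapping["H2"]),
            ):
                if (parent, gid) in result.haplotypes:
                    continue
                second, conflicts = _complement(
                    parent_gts, hap.alleles, on_conflict="mask"
                )
                sids = panel.gene_sites(gid)
                for c in conflicts:
                    result.flagged.append((parent, gid, f"phase conflict at {sids[c]}"))
                store(parent, gid, list(hap.alleles), second)

    # step 3: propagate through the pedigree while progress is made
    attempted: set = set()
    progress = True
    while progress:
        progress = False
        for off, parents in sorted(config.pedigree.items()):
            for gid in gene_ids:
                if (off, gid) in result.haplotypes or (off, gid) in attempted:
                    continue
                known = [p for p in parents if (p, gid) in result.haplotypes]
                if not known:
                    continue
                attempted.add((off, gid))
                parent = known[0]
                ph = result.haplotypes[(parent, gid)]
                try:
                    transmitted, other = propagate_to_descendant(
                        panel.gene_genotypes(off, gid),
                        ph[0].alleles,
                        ph[1].alleles,
                        tolerance,
                    )
                except (AmbiguousParentageError, PhaseConflictError) as exc:
                    result.flagged.append((off, gid, str(exc)))
                    continue
                store(off, gid, transmitted, other, sp1=parent)
                progress = True
    return result
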