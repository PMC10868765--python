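"""Pathway/subunit alteration calling and confound-filtered group building.

Two distinct predicates coexist and are never mixed silently:

* :func:`call_any_alteration` — the co-occurrence screen's symmetric rule:
  a gene counts as altered on any deep deletion (Gistic -2), focal
  amplification (+2) or nonsynonymous variant.  Used for complex-level
  frequency tables and the two-proportion test.
* :func:`call_nrf2_active` — the polarity-aware rule used to label tumors
  for signature derivation: KEAP1/CUL3 are NRF2-suppressors, so only their
  loss events count (deep deletion or nonsynonymous variant); NFE2L2 is the
  oncogene, so only amplification or missense stabilizing variants count.
  Nonsense/frameshift in NFE2L2 are deliberately NOT activating evidence.

Shallow Gistic events (-1/+1) never count as evidence under either rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort_io import CohortBundle

logger = logging.getLogger("nrf2screen")

#: Protein-altering variant classes counted as nonsynonymous by default.
DEFAULT_NONSYNONYMOUS = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
)

#: SWI/SNF subunits studied (BAF: ARID1A/B; PBAF: ARID2, PBRM1).
DEFAULT_SWISNF_PANEL = ("ARID1A", "ARID1B", "ARID2", "PBRM1")

#: KEAP1-NRF2-CUL3 pathway members.
NRF2_PANEL = ("KEAP1", "NFE2L2", "CUL3")

#: Sentinel gene-of-interest selecting the NRF2-pathway positive control.
NRF2_PATHWAY = "NRF2_PATHWAY"


@dataclass
class SampleAlterationStatus:
    """Per-sample boolean alteration status with supporting evidence."""

    name: str
    altered: dict[str, bool]
    evidence: dict[str, list[str]]

    def __post_init__(self) -> None:
        for s, flag in self.altered.items():
            assert flag == bool(self.evidence.get(s)), (
                f"status/evidence mismatch for {s}"
            )

    def altered_samples(self) -> set[str]:
        return {s for s, flag in self.altered.items() if flag}


@dataclass
class GroupAssignment:
    """Mutant / control / excluded partition for one gene of interest."""

    gene_of_interest: str
    mutant_samples: list[str]
    control_samples: list[str]
    excluded_samples: dict[str, str]  # sample -> reason
    undersized: bool = False

    def to_dict(self) -> dict:
        return {
            "gene_of_interest": self.gene_of_interest,
            "mutant_samples": self.mutant_samples,
            "control_samples": self.control_samples,
            "excluded_samples": self.excluded_samples,
            "undersized": self.undersized,
        }


def _variant_hits(
    bundle: CohortBundle, gene: str, classes: tuple[str, ...]
) -> pd.DataFrame:
    rec = bundle.variants.records
    return rec[(rec["gene"] == gene) & rec["variant_class"].isin(classes)]


def _cnv_hits(bundle: CohortBundle, gene: str, score: int) -> list[str]:
    cnv = bundle.cnv.scores
    if gene not in cnv.index:
        return []
    row = cnv.loc[gene]
    return list(row.index[row == score])


def call_any_alteration(
    bundle: CohortBundle,
    genes: tuple[str, ...] | list[str],
    variant_classes: tuple[str, ...] = DEFAULT_NONSYNONYMOUS,
    name: str = "any_alteration",
) -> SampleAlterationStatus:
    """Symmetric rule: altered iff Gistic -2 or +2, or a nonsynonymous variant,
    in any listed gene.  Absence of evidence means not altered."""
    absent = [
        g for g in genes
        if g not in bundle.cnv.scores.index
        and not (bundle.variants.records["gene"] == g).any()
    ]
    if absent:
        logger.warning("call_any_alteration: no evidence source for %s", absent)
    evidence: dict[str, list[str]] = {s: [] for s in bundle.shared_samples}
    for gene in genes:
        for score, label in ((-2, "deep_deletion"), (2, "amplification")):
            for s in _cnv_hits(bundle, gene, score):
                if s in evidence:
                    evidence[s].append(f"{gene}:{label}")
        hits = _variant_hits(bundle, gene, tuple(variant_classes))
        for _, row in hits.iterrows():
            s = row["sample"]
            if s in evidence:
                evidence[s].append(f"{gene}:{row['variant_class']}")
    altered = {s: bool(ev) for s, ev in evidence.items()}
    return SampleAlterationStatus(name=name, altered=altered, evidence=evidence)


def call_nrf2_active(
    bundle: CohortBundle,
    variant_classes: tuple[str, ...] = DEFAULT_NONSYNONYMOUS,
) -> SampleAlterationStatus:
    """Polarity-aware NRF2-activity rule.

    Active iff KEAP1 or CUL3 deep deletion (Gistic -2) or nonsynonymous
    variant, or NFE2L2 amplification (Gistic +2) or missense variant.
    """
    evidence: dict[str, list[str]] = {s: [] for s in bundle.shared_samples}
    for gene in ("KEAP1", "CUL3"):
        for s in _cnv_hits(bundle, gene, -2):
            if s in evidence:
                evidence[s].append(f"{gene}:deep_deletion")
        hits = _variant_hits(bundle, gene, tuple(variant_classes))
        for _, row in hits.iterrows():
            s = row["sample"]
            if s in evidence:
                evidence[s].append(f"{gene}:{row['variant_class']}")
    for s in _cnv_hits(bundle, "NFE2L2", 2):
        if s in evidence:
            evidence[s].append("NFE2L2:amplification")
    hits = _variant_hits(bundle, "NFE2L2", ("Missense_Mutation",))
    for _, row in hits.iterrows():
        s = row["sample"]
        if s in evidence:
            evidence[s].append("NFE2L2:Missense_Mutation")
    altered = {s: bool(ev) for s, ev in evidence.items()}
    return SampleAlterationStatus(
        name="nrf2_active", altered=altered, evidence=evidence
    )


def build_groups(
    bundle: CohortBundle,
    gene_of_interest: str,
    swisnf_panel: tuple[str, ...] = DEFAULT_SWISNF_PANEL,
    nrf2_panel: tuple[str, ...] = NRF2_PANEL,
    min_group_size: int = 5,
    variant_classes: tuple[str, ...] = DEFAULT_NONSYNONYMOUS,
) -> GroupAssignment:
    """Confound-filtered mutant vs wild-type groups for one subunit.

    mutant  = altered in the gene of interest, clean elsewhere (no other
              SWI/SNF-panel alteration, not NRF2-pathway altered);
    control = altered in nothing (neither panel);
    excluded = everything else, each with a recorded reason.

    The gene of interest may also be the :data:`NRF2_PATHWAY` sentinel, in
    which case the mutant group is the NRF2-active tumors (polarity-aware
    rule) without SWI/SNF-panel alterations — the positive-control contrast.
    """
    pathway_mode = gene_of_interest == NRF2_PATHWAY
    if not pathway_mode:
        if gene_of_interest not in swisnf_panel:
            raise ValueError(
                f"{gene_of_interest!r} not in the SWI/SNF panel {swisnf_panel}"
            )
        has_cnv = gene_of_interest in bundle.cnv.scores.index
        has_var = (bundle.variants.records["gene"] == gene_of_interest).any()
        if not has_cnv and not has_var:
            raise ValueError(
                f"{gene_of_interest!r} absent from all evidence sources"
            )
    if set(swisnf_panel) & set(nrf2_panel):
        raise ValueError("SWI/SNF and NRF2 panels must be disjoint")

    per_gene = {
        g: call_any_alteration(bundle, [g], variant_classes, name=g).altered_samples()
        for g in swisnf_panel
    }
    nrf2 = call_nrf2_active(bundle, variant_classes).altered_samples()

    mutant, control, excluded = [], [], {}
    for s in bundle.shared_samples:
        swisnf_hits = {g for g, hit in per_gene.items() if s in hit}
        if pathway_mode:
            goi_hit = s in nrf2
            confounders = swisnf_hits
        else:
            goi_hit = s in per_gene[gene_of_interest]
            confounders = swisnf_hits - {gene_of_interest}
            if s in nrf2:
                confounders = confounders | {"NRF2_pathway"}
        if goi_hit and not confounders:
            mutant.append(s)
        elif goi_hit and confounders:
            excluded[s] = f"confounded: {','.join(sorted(confounders))}"
        elif swisnf_hits or (not pathway_mode and s in nrf2):
            hits = sorted(swisnf_hits | ({"NRF2_pathway"} if s in nrf2 else set()))
            excluded[s] = f"altered_elsewhere: {','.join(hits)}"
        else:
            control.append(s)

    undersized = len(mutant) < min_group_size
    if undersized:
        logger.warning(
            "build_groups(%s): mutant group size %d < %d (flagged)",
            gene_of_interest, len(mutant), min_group_size,
        )
    return GroupAssignment(
        gene_of_interest=gene_of_interest,
        mutant_samples=mutant,
        control_samples=control,
        excluded_samples=excluded,
        undersized=undersized,
    )


def alteration_frequencies(
    bundles: list[CohortBundle],
    swisnf_panel: tuple[str, ...] = DEFAULT_SWISNF_PANEL,
    nrf2_panel: tuple[str, ...] = NRF2_PANEL,
    variant_classes: tuple[str, ...] = DEFAULT_NONSYNONYMOUS,
) -> pd.DataFrame:
    """Per-cohort alteration frequencies for the co-occurrence screen.

    Both pathway-level fractions use the symmetric any-alteration rule, which
    is how the frequency panel is defined; per-gene columns are included for
    the subunit heatmap.
    """
    if not bundles:
        raise ValueError("need at least one cohort")
    rows = []
    for bundle in bundles:
        n = len(bundle.shared_samples)
        row: dict[str, object] = {"cohort": bundle.cohort_name, "n_samples": n}
        if swisnf_panel:
            swisnf = call_any_alteration(
                bundle, list(swisnf_panel), variant_classes
            ).altered_samples()
        else:
            swisnf = set()
        if nrf2_panel:
            nrf2 = call_any_alteration(
                bundle, list(nrf2_panel), variant_classes
            ).altered_samples()
        else:
            nrf2 = set()
        row["frac_nrf2_altered"] = len(nrf2) / n if n else 0.0
        row["frac_swisnf_altered"] = len(swisnf) / n if n else 0.0
        row["frac_coincident"] = len(nrf2 & swisnf) / n if n else 0.0
        row["n_swisnf_altered"] = len(swisnf)
        for g in swisnf_panel:
            hits = call_any_alteration(bundle, [g], variant_classes)
            row[f"frac_{g}"] = len(hits.altered_samples()) / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
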