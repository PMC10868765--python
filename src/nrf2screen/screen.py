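"""Full screen orchestration: cohorts x genes-of-interest -> GSEA tables.

For every (cohort, gene of interest) pair the screen builds confound-filtered
mutant vs control groups, preprocesses expression (low-expression filter +
TMM + log-CPM, or median-centering for proteomic cohorts), ranks genes by
signal-to-noise between the groups (mutant minus control, so positive NES
means the signature is up in mutants) and runs permutation GSEA over every
configured collection.  The NRF2-pathway positive-control contrast is always
included.  Under-sized groups produce flagged rows, never crashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alterations import (
    DEFAULT_NONSYNONYMOUS,
    DEFAULT_SWISNF_PANEL,
    NRF2_PANEL,
    NRF2_PATHWAY,
    build_groups,
)
from .cohort_io import CohortBundle, GeneSetCollection
from .expression import filter_low_expression, log_cpm, median_center, tmm_factors
from .gsea import gsea_batch, rank_by_signal_to_noise, results_to_frame

logger = logging.getLogger("nrf2screen")


@dataclass
class ScreenConfig:
    """Everything that determines a screen run (recorded in the manifest)."""

    genes_of_interest: tuple[str, ...] = DEFAULT_SWISNF_PANEL
    include_positive_control: bool = True
    swisnf_panel: tuple[str, ...] = DEFAULT_SWISNF_PANEL
    nrf2_panel: tuple[str, ...] = NRF2_PANEL
    variant_classes: tuple[str, ...] = DEFAULT_NONSYNONYMOUS
    min_group_size: int = 5
    cpm_threshold: float = 1.0
    min_fraction: float = 0.2
    n_perm: int = 10_000
    weight_p: float = 1.0
    gsea_min_size: int = 5
    seed: int = 0
    sample_inclusion: tuple[str, ...] | None = None  # optional allow-list

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ScreenResult:
    """Long results table plus the run manifest."""

    table: pd.DataFrame
    manifest: dict


def _restrict(bundle: CohortBundle, allow: tuple[str, ...]) -> CohortBundle:
    keep = [s for s in bundle.shared_samples if s in set(allow)]
    if not keep:
        raise ValueError(f"{bundle.cohort_name}: inclusion list excludes all samples")
    return CohortBundle(
        cohort_name=bundle.cohort_name,
        count_matrix=bundle.count_matrix.subset_samples(keep),
        variants=bundle.variants.subset_samples(keep),
        cnv=bundle.cnv.subset_samples(keep),
        shared_samples=keep,
    )


def run_screen(
    bundles: list[CohortBundle],
    collections: dict[str, GeneSetCollection],
    config: ScreenConfig | None = None,
    proteomic: dict[str, pd.DataFrame] | None = None,
) -> ScreenResult:
    """Run the screen over all cohorts and genes of interest.

    ``collections`` maps collection name (e.g. "nrf2_signatures",
    "hallmark") to its gene sets.  ``proteomic`` optionally maps a cohort
    name to an abundance matrix; those cohorts skip count preprocessing and
    are median-centered instead.
    """
    config = config or ScreenConfig()
    if not bundles:
        raise ValueError("no cohorts")
    if not collections:
        raise ValueError("no gene-set collections")
    goi = list(config.genes_of_interest)
    if config.include_positive_control and NRF2_PATHWAY not in goi:
        goi.append(NRF2_PATHWAY)

    rows = []
    timings = {}
    failures = {}
    for bundle in bundles:
        t0 = time.perf_counter()
        try:
            if config.sample_inclusion is not None:
                bundle = _restrict(bundle, config.sample_inclusion)
            mode = "proteomic" if (proteomic and bundle.cohort_name in proteomic) else "rnaseq"
            if mode == "proteomic":
                norm = median_center(
                    proteomic[bundle.cohort_name][bundle.shared_samples]
                )
            else:
                counts = filter_low_expression(
                    bundle.count_matrix, config.cpm_threshold, config.min_fraction
                )
                norm = log_cpm(counts, tmm_factors(counts))
        except ValueError as exc:
            failures[bundle.cohort_name] = str(exc)
            logger.error("cohort %s failed preprocessing: %s",
                         bundle.cohort_name, exc)
            continue

        for gene in goi:
            flag = ""
            try:
                groups = build_groups(
                    bundle, gene,
                    swisnf_panel=config.swisnf_panel,
                    nrf2_panel=config.nrf2_panel,
                    min_group_size=config.min_group_size,
                    variant_classes=config.variant_classes,
                )
            except ValueError as exc:
                rows.append(_flagged_row(bundle.cohort_name, gene, mode,
                                         f"group_error: {exc}", collections))
                continue
            if groups.undersized or len(groups.control_samples) < config.min_group_size:
                rows.extend(_flagged_rows(
                    bundle.cohort_name, gene, mode,
                    f"undersized (mutant={len(groups.mutant_samples)}, "
                    f"control={len(groups.control_samples)})",
                    collections, groups,
                ))
                continue
            ranked = rank_by_signal_to_noise(
                norm.values, groups.mutant_samples, groups.control_samples
            )
            for coll_name, coll in collections.items():
                results = gsea_batch(
                    ranked, coll,
                    n_perm=config.n_perm, seed=config.seed,
                    weight_p=config.weight_p, min_size=config.gsea_min_size,
                )
                df = results_to_frame(results)
                df.insert(0, "cohort", bundle.cohort_name)
                df.insert(1, "gene_of_interest", gene)
                df.insert(2, "collection", coll_name)
                df["mode"] = mode
                df["n_mutant"] = len(groups.mutant_samples)
                df["n_control"] = len(groups.control_samples)
                rows.append(df)
        timings[bundle.cohort_name] = time.perf_counter() - t0

    if not timings:
        raise ValueError(f"no cohort completed the screen: {failures}")
    table = pd.concat(rows, ignore_index=True)
    dup = table.duplicated(["cohort", "gene_of_interest", "collection", "set_name"])
    assert not dup.any(), "duplicate (cohort, gene, signature) rows"
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohorts": [b.cohort_name for b in bundles],
        "collections": {k: list(v.names()) for k, v in collections.items()},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "failures": failures,
    }
    return ScreenResult(table=table, manifest=manifest)


def _flagged_rows(cohort, gene, mode, reason, collections, groups):
    out = []
    for coll_name, coll in collections.items():
        df = pd.DataFrame(
            {
                "cohort": cohort,
                "gene_of_interest": gene,
                "collection": coll_name,
                "set_name": coll.names(),
                "size": np.nan, "es": np.nan, "nes": np.nan,
                "p": np.nan, "padj": np.nan,
                "flag": reason,
                "mode": mode,
                "n_mutant": len(groups.mutant_samples),
                "n_control": len(groups.control_samples),
            }
        )
        out.append(df)
    return out


def _flagged_row(cohort, gene, mode, reason, collections):
    return pd.DataFrame(
        [{
            "cohort": cohort, "gene_of_interest": gene,
            "collection": name, "set_name": "*",
            "size": np.nan, "es": np.nan, "nes": np.nan,
            "p": np.nan, "padj": np.nan, "flag": reason,
            "mode": "", "n_mutant": 0, "n_control": 0,
        } for name in collections]
    )


def heatmap_table(
    result: ScreenResult,
    collection_filter: str | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide NES matrix (gene-of-interest x signature) plus a cell mask.

    Mask values: "sig" (adjusted p < alpha), "ns" (tested, not significant),
    "masked" (flagged row — distinguishable from non-significant).
    """
    df = result.table
    if collection_filter is not None:
        df = df[df["collection"] == collection_filter]
    if df.empty:
        raise ValueError("no rows after collection filter")
    nes = df.pivot_table(index="gene_of_interest", columns="set_name",
                         values="nes", aggfunc="first")
    mask = pd.DataFrame("", index=nes.index, columns=nes.columns)
    for _, row in df.iterrows():
        if row["flag"]:
            mask.loc[row["gene_of_interest"], row["set_name"]] = "masked"
        elif np.isfinite(row["padj"]) and row["padj"] < alpha:
            mask.loc[row["gene_of_interest"], row["set_name"]] = "sig"
        else:
            mask.loc[row["gene_of_interest"], row["set_name"]] = "ns"
    return nes, mask


def validate_cross_dataset(
    result_a: ScreenResult, result_b: ScreenResult
) -> pd.DataFrame:
    """Per (gene, signature) NES sign concordance between two screens.

    The returned table carries a ``concordance`` attribute: the fraction of
    shared, unflagged pairs whose NES signs agree.
    """
    cols = ["gene_of_interest", "set_name", "nes", "padj", "flag"]
    a = result_a.table[cols].rename(columns={"nes": "nes_a", "padj": "padj_a",
                                             "flag": "flag_a"})
    b = result_b.table[cols].rename(columns={"nes": "nes_b", "padj": "padj_b",
                                             "flag": "flag_b"})
    merged = a.merge(b, on=["gene_of_interest", "set_name"])
    if merged.empty:
        raise ValueError("no shared (gene, signature) pairs")
    ok = (
        (merged["flag_a"] == "") & (merged["flag_b"] == "")
        & np.isfinite(merged["nes_a"]) & np.isfinite(merged["nes_b"])
    )
    merged["sign_agree"] = np.where(
        ok, np.sign(merged["nes_a"]) == np.sign(merged["nes_b"]), np.nan
    )
    valid = merged.loc[ok, "sign_agree"]
    merged.attrs["concordance"] = float(valid.mean()) if len(valid) else np.nan
    return merged
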