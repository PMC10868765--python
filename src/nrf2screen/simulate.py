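"""Synthetic tumor cohorts with planted NRF2 activity and SWI/SNF events.

Each cohort emulates the statistical structure the downstream analysis
assumes, with full ground truth:

* RNA read counts follow a negative-binomial model with a common dispersion:
  mean_gs = libsize_s * 2^(baseline_g + active_s * effect_g + subunit
  effects), so a designated fraction of samples ("NRF2 active") over-express
  a planted set of NRF2 target genes.
* Every NRF2-active sample carries one pathway-consistent genomic event
  (KEAP1 or CUL3 nonsynonymous variant, CUL3 deep deletion, or NFE2L2
  missense / amplification), so the alteration-calling predicates recover
  the planted labels exactly when no confounders are simulated.
* Each SWI/SNF subunit has a mutation rate, a 2x2 odds ratio of
  co-occurrence with the NRF2-active state, and a direct effect (polarity
  x magnitude, in log2 units) on the planted signature genes — enough to
  plant the directional patterns the screen reads out without asserting any
  mechanism.

Background genes are named SYNG000001...; pathway and subunit events use
the real gene symbols (KEAP1, NFE2L2, CUL3, ARID1A, ARID1B, ARID2, PBRM1)
so the alteration rules run unmodified.  Every sample additionally receives
one silent passenger variant so that all three evidence sources list every
sample (sample harmonization is then lossless).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort_io import (
    CnvMatrix,
    CohortBundle,
    CountMatrix,
    GeneSetCollection,
    VariantTable,
    write_gmt,
)

logger = logging.getLogger("nrf2screen")

PATHWAY_GENES = ("KEAP1", "NFE2L2", "CUL3")
SUBUNIT_GENES = ("ARID1A", "ARID1B", "ARID2", "PBRM1")

_NONSYN_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del")


@dataclass
class SubunitConfig:
    """Planted behaviour of one SWI/SNF subunit."""

    mutation_rate: float = 0.1
    #: odds ratio of co-occurrence between subunit mutation and NRF2 activity
    odds_ratio: float = 1.0
    #: direct effect on planted signature genes: +1 up, 0 none, -1 down
    effect_polarity: int = 0
    #: log2 magnitude of that effect in mutant samples
    effect_magnitude: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0,1]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if self.effect_polarity not in (-1, 0, 1):
            raise ValueError("effect_polarity must be -1, 0 or +1")


def default_subunit_configs() -> dict[str, SubunitConfig]:
    """Default: subunits mutate at realistic rates but are neutral — no
    co-occurrence with NRF2 activity and no expression effect.  Directional
    structure is planted explicitly via :func:`hnsc_like_subunit_configs`."""
    return {
        "ARID1A": SubunitConfig(0.15),
        "ARID1B": SubunitConfig(0.15),
        "ARID2": SubunitConfig(0.10),
        "PBRM1": SubunitConfig(0.10),
    }


def hnsc_like_subunit_configs() -> dict[str, SubunitConfig]:
    """The head-neck-like planted pattern: ARID1A mutation co-occurs with
    NRF2 activity and up-regulates the planted targets; ARID1B mutation
    down-regulates them; the PBAF subunits stay neutral."""
    return {
        "ARID1A": SubunitConfig(0.15, odds_ratio=6.0, effect_polarity=1,
                                effect_magnitude=1.0),
        "ARID1B": SubunitConfig(0.15, odds_ratio=1.0, effect_polarity=-1,
                                effect_magnitude=1.0),
        "ARID2": SubunitConfig(0.10),
        "PBRM1": SubunitConfig(0.10),
    }


@dataclass
class SimulationSpec:
    """Generating parameters of one synthetic cohort.

    Defaults are the reference study conditions used throughout the test
    suite: a mid-size tumor cohort (120 samples, 2,000 genes) with 30%
    NRF2-active samples, 100 planted target genes at mean log2 fold change
    2, negative-binomial dispersion 0.2 and log-normal library sizes around
    5 million reads.
    """

    n_genes: int = 2000
    n_samples: int = 120
    frac_nrf2_active: float = 0.3
    n_signature_genes: int = 100
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.5
    nb_dispersion: float = 0.2
    libsize_log2_mean: float = float(np.log2(5e6))
    libsize_log2_sd: float = 0.25
    baseline_log2_mean: float = -11.0
    baseline_log2_sd: float = 1.5
    subunit_configs: dict[str, SubunitConfig] = field(
        default_factory=default_subunit_configs
    )
    confounder_rate: float = 0.0
    seed: int = 0
    cohort_name: str = "SYNTH"

    def __post_init__(self) -> None:
        if not 0 <= self.frac_nrf2_active < 1:
            raise ValueError("frac_nrf2_active must be in [0,1)")
        if not 0 <= self.confounder_rate <= 1:
            raise ValueError("confounder_rate must be in [0,1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("effect_log2fc_sd", "libsize_log2_sd", "baseline_log2_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_signature_genes >= self.n_genes:
            raise ValueError("n_signature_genes must be < n_genes")


@dataclass
class PlantedTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    active_samples: set[str]
    signature_genes: dict[str, float]  # gene -> planted log2 effect
    subunit_mutants: dict[str, set[str]]
    events: list[tuple[str, str, str]]  # (sample, gene, event kind)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "active_samples": sorted(self.active_samples),
                    "signature_genes": self.signature_genes,
                    "subunit_mutants": {
                        k: sorted(v) for k, v in self.subunit_mutants.items()
                    },
                    "events": self.events,
                },
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            active_samples=set(d["active_samples"]),
            signature_genes={k: float(v) for k, v in d["signature_genes"].items()},
            subunit_mutants={k: set(v) for k, v in d["subunit_mutants"].items()},
            events=[tuple(e) for e in d["events"]],
        )


def _cooccurrence_rates(
    rate: float, frac_active: float, odds_ratio: float
) -> tuple[float, float]:
    """Solve for P(mutant|active), P(mutant|inactive) given the marginal
    mutation rate and the target 2x2 odds ratio."""
    if rate == 0:
        return 0.0, 0.0
    if odds_ratio == 1.0:
        return rate, rate
    fa, fi = frac_active, 1 - frac_active

    def constraint(pi: float) -> float:
        odds_i = pi / (1 - pi)
        pa = odds_ratio * odds_i / (1 + odds_ratio * odds_i)
        return fa * pa + fi * pi - rate

    hi = min(1.0 - 1e-12, rate / fi) if fi > 0 else 1.0 - 1e-12
    pi = brentq(constraint, 1e-12, hi)
    odds_i = pi / (1 - pi)
    pa = odds_ratio * odds_i / (1 + odds_ratio * odds_i)
    return pa, pi


def _signature_gene_ids(spec: SimulationSpec) -> list[str]:
    return [f"SYNG{i + 1:06d}" for i in range(spec.n_signature_genes)]


def simulate_cohort(
    spec: SimulationSpec,
    signature_gene_ids: list[str] | None = None,
) -> tuple[CohortBundle, PlantedTruth]:
    """Draw one cohort (counts + variants + CNV) and its ground truth.

    ``signature_gene_ids`` overrides which genes carry the planted effect
    (used by :func:`simulate_multi_cohort` to control sharing); by default
    the first ``n_signature_genes`` genes are used.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"SYNG{i + 1:06d}" for i in range(spec.n_genes)]
    samples = [f"SYNSAMP{i + 1:04d}" for i in range(spec.n_samples)]
    sig_genes = signature_gene_ids or _signature_gene_ids(spec)
    unknown = set(sig_genes) - set(genes)
    if unknown:
        raise ValueError(f"signature genes outside the universe: {sorted(unknown)[:3]}")

    n_active = round(spec.frac_nrf2_active * spec.n_samples)
    active_idx = rng.choice(spec.n_samples, size=n_active, replace=False)
    active = np.zeros(spec.n_samples, dtype=bool)
    active[active_idx] = True

    # --- genomic events ---------------------------------------------------
    events: list[tuple[str, str, str]] = []
    cnv = pd.DataFrame(
        0,
        index=list(PATHWAY_GENES) + list(SUBUNIT_GENES),
        columns=samples,
        dtype=np.int64,
    )
    var_rows: list[tuple[str, str, str]] = []

    activating_menu = (
        ("KEAP1", "variant"),
        ("CUL3", "variant"),
        ("CUL3", "deep_deletion"),
        ("NFE2L2", "missense"),
        ("NFE2L2", "amplification"),
    )
    for j in np.flatnonzero(active):
        s = samples[j]
        gene, kind = activating_menu[rng.integers(len(activating_menu))]
        if kind == "variant":
            cls = _NONSYN_CLASSES[rng.integers(len(_NONSYN_CLASSES))]
            var_rows.append((gene, s, cls))
            events.append((s, gene, cls))
        elif kind == "missense":
            var_rows.append((gene, s, "Missense_Mutation"))
            events.append((s, gene, "Missense_Mutation"))
        elif kind == "deep_deletion":
            cnv.loc[gene, s] = -2
            events.append((s, gene, "deep_deletion"))
        else:
            cnv.loc[gene, s] = 2
            events.append((s, gene, "amplification"))

    subunit_mutants: dict[str, set[str]] = {}
    mutant_mask: dict[str, np.ndarray] = {}
    for gene, cfg in spec.subunit_configs.items():
        pa, pi = _cooccurrence_rates(
            cfg.mutation_rate, spec.frac_nrf2_active, cfg.odds_ratio
        )
        p = np.where(active, pa, pi)
        mask = rng.random(spec.n_samples) < p
        mutant_mask[gene] = mask
        subunit_mutants[gene] = {samples[j] for j in np.flatnonzero(mask)}
        for j in np.flatnonzero(mask):
            cls = _NONSYN_CLASSES[rng.integers(len(_NONSYN_CLASSES))]
            var_rows.append((gene, samples[j], cls))
            events.append((samples[j], gene, cls))

    if spec.confounder_rate > 0:
        pool = list(PATHWAY_GENES) + list(spec.subunit_configs)
        for j in np.flatnonzero(rng.random(spec.n_samples) < spec.confounder_rate):
            gene = pool[rng.integers(len(pool))]
            var_rows.append((gene, samples[j], "Missense_Mutation"))
            events.append((samples[j], gene, "confounder:Missense_Mutation"))

    # one silent passenger per sample keeps every sample visible in the MAF
    for j, s in enumerate(samples):
        g = genes[rng.integers(spec.n_genes)]
        var_rows.append((g, s, "Silent"))

    # --- expression -------------------------------------------------------
    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd,
                          size=spec.n_genes)
    libsize = 2.0 ** rng.normal(spec.libsize_log2_mean, spec.libsize_log2_sd,
                                size=spec.n_samples)
    effects = rng.normal(spec.effect_log2fc_mean, spec.effect_log2fc_sd,
                         size=len(sig_genes))
    sig_idx = np.array([genes.index(g) for g in sig_genes])

    log2_mu = np.tile(baseline[:, None], (1, spec.n_samples))
    log2_mu[np.ix_(sig_idx, np.flatnonzero(active))] += effects[:, None]
    for gene, cfg in spec.subunit_configs.items():
        if cfg.effect_polarity and cfg.effect_magnitude:
            cols = np.flatnonzero(mutant_mask[gene])
            if len(cols):
                log2_mu[np.ix_(sig_idx, cols)] += (
                    cfg.effect_polarity * cfg.effect_magnitude
                )
    mu = libsize[None, :] * 2.0 ** log2_mu
    r = 1.0 / spec.nb_dispersion  # NB size parameter: var = mu + phi mu^2
    counts = rng.negative_binomial(r, r / (r + mu))

    count_df = pd.DataFrame(counts, index=genes, columns=samples)
    var_df = pd.DataFrame(var_rows, columns=["gene", "sample", "variant_class"])
    bundle = CohortBundle(
        cohort_name=spec.cohort_name,
        count_matrix=CountMatrix(count_df),
        variants=VariantTable(var_df),
        cnv=CnvMatrix(cnv),
        shared_samples=samples,
    )
    truth = PlantedTruth(
        active_samples={samples[j] for j in np.flatnonzero(active)},
        signature_genes={g: float(e) for g, e in zip(sig_genes, effects)},
        subunit_mutants=subunit_mutants,
        events=events,
    )
    return bundle, truth


def simulate_multi_cohort(
    spec: SimulationSpec,
    n_cohorts: int = 3,
    shared_core: int | None = None,
) -> list[tuple[CohortBundle, PlantedTruth]]:
    """Cohorts sharing exactly ``shared_core`` planted signature genes.

    The remaining planted genes are cohort-private (pairwise disjoint).
    Per-cohort seeds derive deterministically from the master seed.
    """
    if n_cohorts < 2:
        raise ValueError("n_cohorts must be >= 2")
    if shared_core is None:
        shared_core = spec.n_signature_genes
    if shared_core > spec.n_signature_genes:
        raise ValueError("shared_core must be <= n_signature_genes")
    n_private = spec.n_signature_genes - shared_core
    needed = shared_core + n_private * n_cohorts
    if needed > spec.n_genes:
        raise ValueError("not enough genes for disjoint private signature sets")
    genes = [f"SYNG{i + 1:06d}" for i in range(spec.n_genes)]
    core = genes[:shared_core]
    out = []
    for c in range(n_cohorts):
        start = shared_core + c * n_private
        private = genes[start:start + n_private]
        sub_seed = int(
            np.random.SeedSequence([spec.seed, c]).generate_state(1)[0] % (2**31)
        )
        cohort_spec = SimulationSpec(
            **{
                **asdict_shallow(spec),
                "seed": sub_seed,
                "cohort_name": f"{spec.cohort_name}{c + 1}",
            }
        )
        out.append(simulate_cohort(cohort_spec, signature_gene_ids=core + private))
    return out


def asdict_shallow(spec: SimulationSpec) -> dict:
    d = {k: getattr(spec, k) for k in spec.__dataclass_fields__}
    d["subunit_configs"] = dict(spec.subunit_configs)
    return d


def make_nrf2_signature_collection(
    truth: PlantedTruth,
    n_sets: int = 5,
    set_size: int = 40,
    seed: int = 0,
) -> GeneSetCollection:
    """Five synthetic NRF2-activity gene sets drawn from the planted targets.

    Stands in for the five published NRF2 signatures the screen is run
    against: each set is an independent subsample of the planted target
    genes, so the sets overlap without being identical.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(truth.signature_genes)
    size = min(set_size, len(pool))
    sets = {}
    for i in range(n_sets):
        members = sorted(rng.choice(pool, size=size, replace=False))
        sets[f"NRF2_SYN_SIG_{i + 1}"] = (
            "synthetic NRF2 target subsample", list(members)
        )
    return GeneSetCollection(sets, provenance="synthetic")


# ---------------------------------------------------------------------------
# Disk round-trip in the exact dialects cohort_io reads
# ---------------------------------------------------------------------------

def write_cohort(
    bundle: CohortBundle, truth: PlantedTruth | None, outdir
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.count_matrix.counts.to_csv(outdir / "counts.tsv", sep="\t",
                                      index_label="gene")
    bundle.cnv.scores.to_csv(outdir / "gistic.tsv", sep="\t",
                             index_label="Gene Symbol")
    maf = bundle.variants.records.rename(
        columns={
            "gene": "Hugo_Symbol",
            "sample": "Tumor_Sample_Barcode",
            "variant_class": "Variant_Classification",
        }
    )
    maf.to_csv(outdir / "variants.maf.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_json(outdir / "truth.json")


def write_signature_collection(collection: GeneSetCollection, path) -> None:
    write_gmt(collection, path)
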