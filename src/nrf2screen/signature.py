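"""Derivation of a centroid-classifier NRF2 activity signature.

The procedure plants preliminary NRF2-active / inactive labels from
mutational status, performs a moderated-t differential expression between
the preliminary groups, takes the top 100 genes by p-value (either
direction) as a classifier panel, trains a nearest-centroid classifier on
z-standardized log-CPM over that panel, removes low-confidence samples
(misclassified, or too far from their assigned centroid along the
inter-centroid axis), refits the differential expression on the retained
samples, and finally intersects the per-cohort results: genes significantly
up in the active class in every cohort, ranked by the worst (largest) of
the per-cohort adjusted p-values, top 100 kept.

The confidence radius tau is expressed as a fraction of the inter-centroid
distance and measured along the projection onto the centroid axis, so both
a tight (0.0025) and a permissive (0.25) reading of "0.25%" are usable; the
default is 0.25 because the tight radius empties any realistically noisy
cohort.  Both values are plain config entries, nothing is chosen silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alterations import call_nrf2_active, DEFAULT_NONSYNONYMOUS
from .cohort_io import CohortBundle, GeneSetCollection
from .expression import (
    DEResult,
    NormalizedMatrix,
    filter_low_expression,
    log_cpm,
    moderated_t_de,
    tmm_factors,
)

logger = logging.getLogger("nrf2screen")

ACTIVE, INACTIVE = "active", "inactive"


@dataclass
class CentroidModel:
    """Nearest-centroid two-class model on z-standardized expression."""

    gene_panel: list[str]
    centroid_active: np.ndarray
    centroid_inactive: np.ndarray
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    confidence_tau: float = 0.25

    def __post_init__(self) -> None:
        if not self.gene_panel:
            raise ValueError("empty gene panel")
        if (self.standardize_sd <= 0).any():
            raise ValueError("non-positive standardization sd")
        if self.inter_centroid_distance == 0:
            raise ValueError("degenerate model: identical centroids")

    @property
    def inter_centroid_distance(self) -> float:
        return float(
            np.linalg.norm(self.centroid_active - self.centroid_inactive)
        )

    def standardize(self, vec: np.ndarray) -> np.ndarray:
        return (vec - self.standardize_mean) / self.standardize_sd

    def to_dict(self) -> dict:
        return {
            "gene_panel": self.gene_panel,
            "centroid_active": self.centroid_active.tolist(),
            "centroid_inactive": self.centroid_inactive.tolist(),
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "confidence_tau": self.confidence_tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidModel":
        return cls(
            gene_panel=list(d["gene_panel"]),
            centroid_active=np.asarray(d["centroid_active"], dtype=float),
            centroid_inactive=np.asarray(d["centroid_inactive"], dtype=float),
            standardize_mean=np.asarray(d["standardize_mean"], dtype=float),
            standardize_sd=np.asarray(d["standardize_sd"], dtype=float),
            confidence_tau=float(d["confidence_tau"]),
        )


def train_centroid(
    norm: NormalizedMatrix,
    labels: pd.Series,
    panel: list[str],
    confidence_tau: float = 0.25,
) -> CentroidModel:
    """Fit per-gene z-standardization and the two class centroids.

    ``labels`` maps sample id to "active"/"inactive"; both classes must be
    nonempty.  Panel genes with zero variance across the training samples
    are dropped with a warning.
    """
    labels = labels.loc[[s for s in labels.index if s in norm.values.columns]]
    classes = set(labels)
    if not {ACTIVE, INACTIVE} <= classes or len(classes) != 2:
        raise ValueError("labels must contain exactly 'active' and 'inactive'")
    missing = [g for g in panel if g not in norm.values.index]
    if missing:
        raise ValueError(f"panel genes absent from matrix: {missing[:5]}")
    sub = norm.values.loc[panel, labels.index]
    sd = sub.to_numpy().std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(panel, keep) if not k]
        logger.warning("train_centroid: dropped zero-variance genes %s", dropped[:5])
        panel = [g for g, k in zip(panel, keep) if k]
        if not panel:
            raise ValueError("no panel genes left after zero-variance drop")
        sub = sub.loc[panel]
        sd = sd[keep]
    mean = sub.to_numpy().mean(axis=1)
    z = (sub.to_numpy() - mean[:, None]) / sd[:, None]
    act = labels.index[labels == ACTIVE]
    inact = labels.index[labels == INACTIVE]
    mask_act = labels.to_numpy() == ACTIVE
    return CentroidModel(
        gene_panel=list(panel),
        centroid_active=z[:, mask_act].mean(axis=1),
        centroid_inactive=z[:, ~mask_act].mean(axis=1),
        standardize_mean=mean,
        standardize_sd=sd,
        confidence_tau=confidence_tau,
    )


def classify(model: CentroidModel, sample_vector: pd.Series) -> tuple[str, float]:
    """Assign a sample to the nearer centroid (Euclidean, panel space).

    Returns (class, margin) with margin = (d_other - d_assigned) / D, where
    D is the inter-centroid distance; margin >= 0, and an exact tie is
    broken to "inactive".
    """
    missing = [g for g in model.gene_panel if g not in sample_vector.index]
    if missing:
        raise ValueError(f"sample missing panel genes: {missing[:5]}")
    z = model.standardize(sample_vector.loc[model.gene_panel].to_numpy(dtype=float))
    d_act = np.linalg.norm(z - model.centroid_active)
    d_inact = np.linalg.norm(z - model.centroid_inactive)
    D = model.inter_centroid_distance
    if d_act < d_inact:
        return ACTIVE, float((d_inact - d_act) / D)
    return INACTIVE, float((d_act - d_inact) / D)


def _axis_positions(model: CentroidModel, z: np.ndarray) -> np.ndarray:
    """Signed position of standardized samples along the centroid axis.

    0 at the inactive centroid, D at the active centroid (units of z-space
    distance); columns of ``z`` are samples.
    """
    axis = model.centroid_active - model.centroid_inactive
    u = axis / np.linalg.norm(axis)
    return (z - model.centroid_inactive[:, None]).T @ u


def select_high_confidence(
    model: CentroidModel,
    norm: NormalizedMatrix,
    labels: pd.Series,
    tau: float | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Retain samples that are confidently, correctly classified.

    A sample survives iff the classifier agrees with its preliminary
    mutation-defined label AND its distance to the assigned centroid,
    measured along the inter-centroid axis, is at most tau * D.  Returns
    (retained samples, removal reasons).
    """
    tau = model.confidence_tau if tau is None else tau
    labels = labels.loc[[s for s in labels.index if s in norm.values.columns]]
    mat = norm.values.loc[model.gene_panel, labels.index].to_numpy(dtype=float)
    z = (mat - model.standardize_mean[:, None]) / model.standardize_sd[:, None]
    pos = _axis_positions(model, z)
    D = model.inter_centroid_distance
    pos_act = float(_axis_positions(model, model.centroid_active[:, None])[0])
    pos_inact = 0.0
    retained: list[str] = []
    removed: dict[str, str] = {}
    for j, s in enumerate(labels.index):
        d_act = np.linalg.norm(z[:, j] - model.centroid_active)
        d_inact = np.linalg.norm(z[:, j] - model.centroid_inactive)
        assigned = ACTIVE if d_act < d_inact else INACTIVE
        if assigned != labels.loc[s]:
            removed[s] = "misclassified"
            continue
        target = pos_act if assigned == ACTIVE else pos_inact
        if abs(pos[j] - target) > tau * D:
            removed[s] = "far_from_centroid"
            continue
        retained.append(s)
    kept = set(retained)
    for cls in (ACTIVE, INACTIVE):
        if not any(labels.loc[s] == cls for s in kept):
            raise ValueError(
                f"all {cls!r} samples removed; increase tau (currently {tau})"
            )
    return retained, removed


@dataclass
class CohortSignatureResult:
    """Per-cohort output of the derivation pipeline."""

    cohort_name: str
    preliminary_labels: pd.Series
    initial_de: DEResult
    panel: list[str]
    model: CentroidModel
    retained_samples: list[str]
    removed_samples: dict[str, str]
    final_de: DEResult
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class DerivationConfig:
    panel_size: int = 100
    tau: float = 0.25
    n_iter: int = 1
    min_group_size: int = 5
    cpm_threshold: float = 1.0
    min_fraction: float = 0.2
    variant_classes: tuple[str, ...] = DEFAULT_NONSYNONYMOUS
    alpha: float = 0.05
    signature_size: int = 100


def _preprocess(bundle: CohortBundle, config: DerivationConfig) -> NormalizedMatrix:
    counts = filter_low_expression(
        bundle.count_matrix, config.cpm_threshold, config.min_fraction
    )
    factors = tmm_factors(counts)
    return log_cpm(counts, factors)


def _top_panel(de: DEResult, k: int) -> list[str]:
    tab = de.table.sort_values(["p", "gene"], kind="mergesort")
    return list(tab["gene"].head(k))


def derive_cohort_signature(
    bundle: CohortBundle,
    config: DerivationConfig | None = None,
    norm: NormalizedMatrix | None = None,
) -> CohortSignatureResult:
    """Run the full single-cohort derivation pipeline.

    preliminary mutational labels -> DE -> top-k panel -> centroid model ->
    high-confidence filtering -> refit DE on retained samples.  The number
    of filtering rounds is ``config.n_iter`` (default one round, i.e. one
    filter + one refit).
    """
    config = config or DerivationConfig()
    status = call_nrf2_active(bundle, config.variant_classes)
    labels = pd.Series(
        {
            s: (ACTIVE if s in status.altered_samples() else INACTIVE)
            for s in bundle.shared_samples
        }
    )
    n_active = int((labels == ACTIVE).sum())
    if n_active < config.min_group_size:
        logger.warning(
            "%s: only %d NRF2-active samples (<%d); cohort skipped",
            bundle.cohort_name, n_active, config.min_group_size,
        )
        empty = DEResult(table=pd.DataFrame(), d0=np.nan, s0_2=np.nan)
        return CohortSignatureResult(
            cohort_name=bundle.cohort_name,
            preliminary_labels=labels,
            initial_de=empty, panel=[], model=None,  # type: ignore[arg-type]
            retained_samples=[], removed_samples={}, final_de=empty,
            skipped=True, skip_reason=f"active class size {n_active}",
        )
    if norm is None:
        norm = _preprocess(bundle, config)

    active = list(labels.index[labels == ACTIVE])
    inactive = list(labels.index[labels == INACTIVE])
    initial_de = moderated_t_de(norm, active, inactive)
    de, retained, removed, model, panel = initial_de, list(labels.index), {}, None, []
    for _ in range(config.n_iter):
        panel = _top_panel(de, config.panel_size)
        model = train_centroid(norm, labels.loc[retained], panel, config.tau)
        retained, removed = select_high_confidence(model, norm, labels.loc[retained])
        act = [s for s in retained if labels.loc[s] == ACTIVE]
        inact = [s for s in retained if labels.loc[s] == INACTIVE]
        de = moderated_t_de(norm, act, inact)
    final_panel = _top_panel(de, config.panel_size)
    final_model = train_centroid(norm, labels.loc[retained], final_panel, config.tau)
    return CohortSignatureResult(
        cohort_name=bundle.cohort_name,
        preliminary_labels=labels,
        initial_de=initial_de,
        panel=final_panel,
        model=final_model,
        retained_samples=retained,
        removed_samples=removed,
        final_de=de,
    )


def intersect_cohorts(
    results: list[CohortSignatureResult],
    alpha: float = 0.05,
    k: int = 100,
    signature_name: str = "HNLU",
) -> GeneSetCollection:
    """Cross-cohort signature: genes up in the active class everywhere.

    Candidates have BH-adjusted p < alpha and positive (active-up) fold
    change in every cohort; they are ranked ascending by the highest of the
    per-cohort adjusted p-values (so the worst cohort decides the rank) and
    the top ``k`` form the signature, emitted as a one-set collection.
    """
    usable = [r for r in results if not r.skipped]
    if len(usable) < 2:
        raise ValueError("need >=2 non-skipped cohort results")
    tables = []
    for r in usable:
        t = r.final_de.table.set_index("gene")[["log2fc", "padj"]]
        tables.append(t)
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    rows = []
    for g in common:
        padjs = [float(t.loc[g, "padj"]) for t in tables]
        lfcs = [float(t.loc[g, "log2fc"]) for t in tables]
        if all(p < alpha for p in padjs) and all(f > 0 for f in lfcs):
            rows.append((g, max(padjs)))
    if not rows:
        counts = [
            int(((t["padj"] < alpha) & (t["log2fc"] > 0)).sum()) for t in tables
        ]
        raise ValueError(
            f"empty cross-cohort intersection (per-cohort up-candidates: {counts})"
        )
    rows.sort(key=lambda x: (x[1], x[0]))
    genes = [g for g, _ in rows[:k]]
    desc = (
        f"top-{k} genes up in NRF2-active tumors in all "
        f"{len(usable)} cohorts, ranked by worst adjusted p"
    )
    return GeneSetCollection({signature_name: (desc, genes)}, provenance="derived")


def cross_validate(
    bundle: CohortBundle,
    config: DerivationConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    labels: pd.Series | None = None,
    norm: NormalizedMatrix | None = None,
) -> dict:
    """Leakage-free stratified k-fold CV of the derivation-time classifier.

    Panel selection (DE on the training fold only), centroid training and
    high-confidence filtering are all repeated inside each training fold;
    the held-out fold is classified with the fold's model and scored against
    the mutation-defined labels.  Returns mean accuracy and per-fold
    confusion matrices.
    """
    config = config or DerivationConfig()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if labels is None:
        status = call_nrf2_active(bundle, config.variant_classes)
        labels = pd.Series(
            {
                s: (ACTIVE if s in status.altered_samples() else INACTIVE)
                for s in bundle.shared_samples
            }
        )
    if norm is None:
        norm = _preprocess(bundle, config)
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for cls in (ACTIVE, INACTIVE):
        members = list(labels.index[labels == cls])
        if len(members) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(members)} samples < {n_folds} folds"
            )
        members = [members[i] for i in rng.permutation(len(members))]
        for i, s in enumerate(members):
            folds[i % n_folds].append(s)

    accuracies, confusions = [], []
    for i, test in enumerate(folds):
        train = [s for j, f in enumerate(folds) if j != i for s in f]
        tr_labels = labels.loc[train]
        act = list(tr_labels.index[tr_labels == ACTIVE])
        inact = list(tr_labels.index[tr_labels == INACTIVE])
        de = moderated_t_de(norm, act, inact)
        panel = _top_panel(de, config.panel_size)
        model = train_centroid(norm, tr_labels, panel, config.tau)
        try:
            retained, _ = select_high_confidence(model, norm, tr_labels)
            de2_act = [s for s in retained if labels.loc[s] == ACTIVE]
            de2_inact = [s for s in retained if labels.loc[s] == INACTIVE]
            if len(de2_act) >= 2 and len(de2_inact) >= 2:
                de2 = moderated_t_de(norm, de2_act, de2_inact)
                panel = _top_panel(de2, config.panel_size)
                model = train_centroid(norm, tr_labels.loc[retained], panel, config.tau)
        except ValueError:
            pass  # filtering emptied a class: fall back to the unfiltered model
        conf = {(a, b): 0 for a in (ACTIVE, INACTIVE) for b in (ACTIVE, INACTIVE)}
        correct = 0
        for s in test:
            pred, _ = classify(model, norm.values[s])
            conf[(labels.loc[s], pred)] += 1
            correct += pred == labels.loc[s]
        accuracies.append(correct / len(test))
        confusions.append(conf)
    return {
        "mean_accuracy": float(np.mean(accuracies)),
        "fold_accuracies": [float(a) for a in accuracies],
        "confusions": confusions,
    }
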