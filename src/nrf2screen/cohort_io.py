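"""Readers, writers and containers for cohort-level inputs.

The pipeline consumes three evidence sources per tumor cohort — a per-gene
RNA read-count matrix, a MAF-like somatic variant table and a Gistic-style
discretized copy-number matrix — plus GMT gene-set collections.  This module
parses the plain-text dialects of those formats, enforces their invariants
(unique identifiers, value ranges) and harmonizes sample identifiers across
the three sources into a single :class:`CohortBundle`.

Gene identifiers are treated as opaque, case-sensitive symbols: no alias
resolution or liftover is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("nrf2screen")

#: Variant classifications recognised as part of the standard MAF vocabulary.
VARIANT_CLASS_VOCABULARY = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)

#: Length of a TCGA sample-level barcode (project-TSS-participant-sample).
TCGA_SAMPLE_BARCODE_LEN = 15


class FormatError(ValueError):
    """Malformed input file; the message names the offending location."""


@dataclass
class CountMatrix:
    """Nonnegative integer read counts, genes x samples."""

    counts: pd.DataFrame  # index = gene symbols, columns = sample ids

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dups)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, samples].copy())


@dataclass
class VariantTable:
    """Per-sample somatic variant records (gene, sample, variant_class)."""

    records: pd.DataFrame  # columns: gene, sample, variant_class

    REQUIRED = ("gene", "sample", "variant_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        unknown = set(self.records["variant_class"]) - VARIANT_CLASS_VOCABULARY
        if unknown:
            logger.warning(
                "variant classes outside the standard vocabulary "
                "(preserved, not dropped): %s",
                sorted(unknown),
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["sample"]))

    def __len__(self) -> int:
        return len(self.records)

    def subset_samples(self, samples: list[str]) -> "VariantTable":
        keep = self.records["sample"].isin(set(samples))
        return VariantTable(self.records.loc[keep].reset_index(drop=True))


GISTIC_VALUES = frozenset({-2, -1, 0, 1, 2})


@dataclass
class CnvMatrix:
    """Discretized Gistic copy-number scores in {-2,...,+2}, genes x samples."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")
        bad = set(np.unique(self.scores.to_numpy())) - GISTIC_VALUES
        if bad:
            raise ValueError(f"Gistic scores outside -2..+2: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def subset_samples(self, samples: list[str]) -> "CnvMatrix":
        return CnvMatrix(self.scores.loc[:, samples].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, ordered genes)."""

    sets: dict[str, tuple[str, list[str]]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(genes) != len(set(genes)):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class CohortBundle:
    """One cohort's three evidence sources restricted to shared samples."""

    cohort_name: str
    count_matrix: CountMatrix
    variants: VariantTable
    cnv: CnvMatrix
    shared_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_counts(
    path,
    orientation: str = "genes_as_rows",
    duplicate_policy: str = "sum",
    round_fractional: bool = True,
) -> CountMatrix:
    """Read a TSV count matrix.

    Parameters
    ----------
    orientation:
        ``"genes_as_rows"`` (default) or ``"genes_as_columns"``.
    duplicate_policy:
        How to collapse duplicate gene symbols: ``"sum"`` (default, the usual
        multi-transcript collapse), ``"max"`` or ``"first"``.
    round_fractional:
        Some upstream quantifiers emit fractional expected counts; these are
        rounded half-to-even with a warning so that downstream count-based
        normalization stays well-defined.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")
    if orientation == "genes_as_columns":
        df = df.T
    elif orientation != "genes_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric count in column {col!r}, "
                f"row {bad.index[0]!r}"
            )
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if not np.allclose(values, np.round(values)):
        if not round_fractional:
            raise FormatError(f"{path}: fractional counts present")
        logger.warning("%s: fractional counts rounded half-to-even", path)
        df = pd.DataFrame(
            np.round(values), index=df.index, columns=df.columns
        )

    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        logger.warning(
            "%s: %d duplicate gene symbols collapsed by %r (e.g. %s)",
            path, len(dups), duplicate_policy, list(dups)[:3],
        )
        grouped = df.groupby(level=0, sort=False)
        if duplicate_policy == "sum":
            df = grouped.sum()
        elif duplicate_policy == "max":
            df = grouped.max()
        elif duplicate_policy == "first":
            df = grouped.first()
        else:
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return CountMatrix(df.astype(np.int64))


def read_variants_maf(path, column_map: dict[str, str] | None = None) -> VariantTable:
    """Read a MAF-like tab-delimited variant table.

    Requires gene-symbol, sample-barcode and variant-classification columns
    (standard MAF names ``Hugo_Symbol``, ``Tumor_Sample_Barcode``,
    ``Variant_Classification``; ``column_map`` maps other headers onto the
    canonical ``gene`` / ``sample`` / ``variant_class`` names).  Comment lines
    beginning '#' are skipped.  No class filtering happens here — silent and
    other non-coding classes are retained for downstream predicates to judge.
    """
    defaults = {
        "Hugo_Symbol": "gene",
        "Tumor_Sample_Barcode": "sample",
        "Variant_Classification": "variant_class",
        "gene": "gene",
        "sample": "sample",
        "variant_class": "variant_class",
    }
    if column_map:
        defaults.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    df = df.rename(columns=defaults)
    missing = [c for c in VariantTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    if df.empty:
        logger.warning("%s: header-only variant file (0 records)", path)
    return VariantTable(df[list(VariantTable.REQUIRED)].reset_index(drop=True))


def read_gistic(path, dialect: str = "auto") -> CnvMatrix:
    """Read a Gistic2 all_thresholded-style discretized copy-number TSV.

    ``dialect`` is ``"one_column"`` (gene symbol only), ``"three_column"``
    (gene symbol / locus id / cytoband, the Firehose layout) or ``"auto"``
    which sniffs the header for the extra metadata columns.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    meta_names = {"locus id", "locus_id", "cytoband", "gene id", "gene_id"}
    if dialect == "auto":
        extra = [c for c in df.columns[1:3] if c.strip().lower() in meta_names]
        n_meta = 1 + len(extra)
    elif dialect == "one_column":
        n_meta = 1
    elif dialect == "three_column":
        n_meta = 3
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = df.set_index(df.columns[0]).iloc[:, n_meta - 1:]
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        g = values.index[values.isna().any(axis=1)][0]
        raise FormatError(f"{path}: non-numeric Gistic score at gene {g!r}")
    arr = values.to_numpy()
    if not np.allclose(arr, np.round(arr)) or (np.abs(arr) > 2).any():
        g, s = np.argwhere((np.abs(arr) > 2) | (arr != np.round(arr)))[0]
        raise FormatError(
            f"{path}: Gistic score {arr[g, s]} outside -2..+2 at "
            f"gene {values.index[g]!r}, sample {values.columns[s]!r}"
        )
    out = values.astype(np.int64)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    out.index.name = None
    out.columns.name = None
    return CnvMatrix(out)


def read_gmt(path, provenance: str = "") -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes; tab-delimited)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s:%d: set %r has duplicate genes; deduplicated",
                    path, lineno, name,
                )
            sets[name] = (desc, deduped)
    return GeneSetCollection(sets, provenance=provenance or str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Sample harmonization
# ---------------------------------------------------------------------------

def _looks_like_tcga(ids) -> bool:
    sample = [s for s in ids if s]
    return bool(sample) and all(
        s.startswith("TCGA-") and len(s) >= TCGA_SAMPLE_BARCODE_LEN for s in sample
    )


def _normalize_ids(ids: list[str], policy: str) -> dict[str, str]:
    """Map raw identifiers onto normalized ones (first occurrence wins)."""
    if policy == "identity":
        trunc = None
    elif policy == "tcga15":
        trunc = TCGA_SAMPLE_BARCODE_LEN
    elif policy == "auto":
        trunc = TCGA_SAMPLE_BARCODE_LEN if _looks_like_tcga(ids) else None
    else:
        raise ValueError(f"unknown barcode policy {policy!r}")
    mapping: dict[str, str] = {}
    seen: set[str] = set()
    for raw in ids:
        norm = raw[:trunc] if trunc else raw
        if norm in seen:
            continue  # keep-first for multi-sample patients
        seen.add(norm)
        mapping[raw] = norm
    return mapping


def harmonize_samples(
    counts: CountMatrix,
    variants: VariantTable,
    cnv: CnvMatrix,
    barcode_policy: str = "auto",
    cohort_name: str = "cohort",
) -> CohortBundle:
    """Intersect sample identifiers across the three evidence sources.

    ``barcode_policy``: ``"auto"`` truncates to the 15-character sample
    barcode when identifiers look like TCGA barcodes, else exact match;
    ``"tcga15"`` and ``"identity"`` force either behaviour.  When several raw
    identifiers collapse to one normalized barcode, the first is kept.
    """
    maps = {
        "counts": _normalize_ids(counts.sample_ids, barcode_policy),
        "variants": _normalize_ids(variants.sample_ids, barcode_policy),
        "cnv": _normalize_ids(cnv.sample_ids, barcode_policy),
    }
    norm_sets = {k: set(m.values()) for k, m in maps.items()}
    shared = norm_sets["counts"] & norm_sets["variants"] & norm_sets["cnv"]
    if not shared:
        raise ValueError("no shared samples across counts, variants and CNV")
    # stable order: follow the count matrix
    ordered = [s for s in maps["counts"].values() if s in shared]
    for src, m in maps.items():
        dropped = len(set(m.values()) - shared)
        if dropped:
            logger.info("harmonize: dropped %d samples from %s", dropped, src)

    inv_counts = {v: k for k, v in maps["counts"].items()}
    inv_cnv = {v: k for k, v in maps["cnv"].items()}
    cm = counts.counts[[inv_counts[s] for s in ordered]].copy()
    cm.columns = ordered
    cv = cnv.scores[[inv_cnv[s] for s in ordered]].copy()
    cv.columns = ordered
    vt = variants.records.copy()
    vt["sample"] = vt["sample"].map(maps["variants"])
    vt = vt[vt["sample"].isin(shared)].reset_index(drop=True)
    return CohortBundle(
        cohort_name=cohort_name,
        count_matrix=CountMatrix(cm),
        variants=VariantTable(vt),
        cnv=CnvMatrix(cv),
        shared_samples=ordered,
    )
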