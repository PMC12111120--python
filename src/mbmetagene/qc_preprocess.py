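"""Quality control and preprocessing for 450K beta-value matrices.

The chain applied to a cohort before factorization is:

1. :func:`mask_low_confidence` — set beta values with a detection p-value
   above the threshold (strict ``>``) to missing.
2. :func:`filter_probes` — remove the union of four probe categories:
   sex-chromosome (X/Y) probes, cross-reactive probes, probes with a SNP of
   minor allele frequency >= the threshold within 50 bp, and probes whose
   post-masking missing fraction exceeds the maximum (strict ``>``).
3. :func:`filter_samples` — drop samples labelled Non-classifiable.
4. :func:`knn_impute` — complete remaining missing values from the k nearest
   samples.
5. :func:`select_top_variance` — keep the n most variable probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.impute import KNNImputer

from .matrix_io import (
    NON_CLASSIFIABLE,
    SEX_CHROMOSOMES,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)


@dataclass
class QCConfig:
    """Thresholds for the QC chain.

    detection_p_threshold
        Beta values with detection p strictly above this are masked (0.05).
    max_missing_fraction
        Probes with post-masking missing fraction strictly above this are
        removed (0.5).
    maf_threshold
        Probes with a nearby SNP of minor allele frequency >= this are
        removed (0.05; the rule is inclusive).
    n_top_variance
        Number of highest-variance probes retained (10000).
    knn_k
        Neighbours for imputation (10).
    """

    detection_p_threshold: float = 0.05
    max_missing_fraction: float = 0.5
    maf_threshold: float = 0.05
    n_top_variance: int = 10000
    knn_k: int = 10

    def __post_init__(self) -> None:
        for name in ("detection_p_threshold", "max_missing_fraction", "maf_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_top_variance <= 0 or self.knn_k <= 0:
            raise ValueError("n_top_variance and knn_k must be positive")


@dataclass
class FilterReport:
    """Per-category probe-removal accounting.

    A probe may fall in several categories; ``n_unique_removed`` counts the
    union, so it is at most the sum of the category counts, with equality
    exactly when the categories are pairwise disjoint.
    """

    removed_ids_by_category: dict[str, set] = field(repr=False)

    CATEGORIES = ("xy", "cross_reactive", "snp", "low_confidence")

    def __post_init__(self) -> None:
        for c in self.CATEGORIES:
            self.removed_ids_by_category.setdefault(c, set())

    @property
    def n_xy(self) -> int:
        return len(self.removed_ids_by_category["xy"])

    @property
    def n_cross_reactive(self) -> int:
        return len(self.removed_ids_by_category["cross_reactive"])

    @property
    def n_snp(self) -> int:
        return len(self.removed_ids_by_category["snp"])

    @property
    def n_low_confidence(self) -> int:
        return len(self.removed_ids_by_category["low_confidence"])

    @property
    def union(self) -> set:
        out: set = set()
        for s in self.removed_ids_by_category.values():
            out |= s
        return out

    @property
    def n_unique_removed(self) -> int:
        return len(self.union)

    def counts(self) -> dict[str, int]:
        return {
            "xy": self.n_xy,
            "cross_reactive": self.n_cross_reactive,
            "snp": self.n_snp,
            "low_confidence": self.n_low_confidence,
            "unique_removed": self.n_unique_removed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.counts(), fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        rows = [
            ("XY mapped", self.n_xy),
            ("Non-specific binding", self.n_cross_reactive),
            ("SNPs affected", self.n_snp),
            ("Low confidence", self.n_low_confidence),
            ("Total unique", self.n_unique_removed),
        ]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("category\tcount\n")
            for name, n in rows:
                fh.write(f"{name}\t{n}\n")


def mask_low_confidence(bm: BetaMatrix, threshold: float = 0.05) -> BetaMatrix:
    """Mask beta values whose detection p-value exceeds ``threshold``.

    The comparison is strict: a value with p exactly equal to the threshold
    is retained.  detection_p itself is untouched.
    """
    if bm.detection_p is None:
        raise ValidationError("mask_low_confidence requires detection_p")
    out = bm.copy()
    mask = out.detection_p > threshold  # NaN p-values never mask
    out.beta[mask] = np.nan
    return out


def filter_probes(
    bm: BetaMatrix, ann: ProbeAnnotation, cfg: QCConfig | None = None
) -> tuple[BetaMatrix, FilterReport]:
    """Remove XY, cross-reactive, SNP-affected and high-missingness probes.

    Every probe in ``bm`` must be annotated.  Survivors keep their original
    order.  The low-confidence category is the set of probes whose missing
    fraction across samples (after any masking) strictly exceeds
    ``cfg.max_missing_fraction``.
    """
    cfg = cfg or QCConfig()
    idx = ann.indexed()
    unannotated = [p for p in bm.probe_ids if p not in idx.index]
    if unannotated:
        raise ValidationError(
            f"{len(unannotated)} probe(s) lack annotation, e.g. {unannotated[:5]}"
        )
    sub = idx.loc[bm.probe_ids]
    probe_arr = np.asarray(bm.probe_ids)

    chrom = sub["chromosome"].astype(str).to_numpy()
    xy = {p for p, c in zip(bm.probe_ids, chrom) if c in SEX_CHROMOSOMES}
    cross = set(probe_arr[sub["cross_reactive"].to_numpy(dtype=bool)])
    snp = set(probe_arr[sub["max_maf_within_50bp"].to_numpy(dtype=float) >= cfg.maf_threshold])
    miss_frac = np.isnan(bm.beta).mean(axis=1)
    low_conf = set(probe_arr[miss_frac > cfg.max_missing_fraction])

    report = FilterReport(
        {"xy": xy, "cross_reactive": cross, "snp": snp, "low_confidence": low_conf}
    )
    removed = report.union
    keep = [i for i, p in enumerate(bm.probe_ids) if p not in removed]
    if not keep:
        raise ValidationError("all probes removed by filtering; nothing survives")
    return bm.select_probes(keep), report


def filter_samples(bm: BetaMatrix, sheet: SampleSheet) -> tuple[BetaMatrix, SampleSheet]:
    """Drop samples labelled Non-classifiable from matrix and sheet."""
    labels = sheet.labels_for(bm.sample_ids)
    keep = [i for i, lab in enumerate(labels) if lab != NON_CLASSIFIABLE]
    if not keep:
        raise ValidationError("no classifiable samples remain")
    out = bm.select_samples(keep)
    return out, sheet.subset(out.sample_ids)


def knn_impute(bm: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Complete missing beta values by k-nearest-neighbour imputation.

    Samples are the imputation units (the matrix is transposed internally so
    samples are rows).  Distances between samples are Euclidean over mutually
    observed probes, rescaled by sqrt(n_probes / n_shared) so sparsity does
    not shrink distances; each missing value becomes the unweighted mean of
    the k nearest samples with an observed value at that probe.  Imputed
    values are clipped to [0, 1]; observed values are never altered.
    """
    if k >= bm.n_samples:
        raise ValidationError(f"knn_impute needs k < n_samples ({k} >= {bm.n_samples})")
    missing = bm.missing_mask()
    if not missing.any():
        return bm.copy()
    all_missing_probes = np.where(missing.all(axis=1))[0]
    if all_missing_probes.size:
        ids = [bm.probe_ids[i] for i in all_missing_probes[:5]]
        raise ValidationError(
            f"probe(s) missing in all samples (remove via filter_probes first): {ids}"
        )
    if missing.all(axis=0).any():
        raise ValidationError("a sample is entirely missing; cannot impute")
    X = bm.beta.T  # samples as rows
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    filled = imputer.fit_transform(X).T
    out = bm.copy()
    out.beta = np.clip(filled, 0.0, 1.0)
    out.beta[~missing] = bm.beta[~missing]
    return out


def select_top_variance(bm: BetaMatrix, n: int) -> BetaMatrix:
    """Keep the ``n`` probes with the largest sample variance (ddof=1).

    Ties at the selection boundary break toward the lexicographically
    smaller probe id; retained probes keep their original matrix order.
    Requires a complete (post-imputation) matrix.
    """
    if n > bm.n_probes:
        raise ValidationError(f"requested {n} probes but matrix has {bm.n_probes}")
    if bm.missing_mask().any():
        raise ValidationError("select_top_variance requires a complete matrix; impute first")
    var = bm.beta.var(axis=1, ddof=1)
    order = sorted(range(bm.n_probes), key=lambda i: (-var[i], bm.probe_ids[i]))
    chosen = set(order[:n])
    keep = [i for i in range(bm.n_probes) if i in chosen]
    return bm.select_probes(keep)
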