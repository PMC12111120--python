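"""Synthetic 450K-style cohorts with known latent structure.

The generator emulates the statistical features the pipeline assumes of a
real methylation cohort:

* a latent nonnegative rank-k structure — each metagene owns a disjoint
  block of probes with high basis loadings over a small background;
* seven subgroups with the primary cohort's class imbalance, where the
  Group 3 / Group 4 risk pairs sit close together in metagene space (a
  ``separation`` parameter controls the overlap) while WNT and SHH are well
  separated;
* bimodal beta marginals with peaks near 0 and 1, produced by passing the
  low-rank signal through a fixed monotone S-shaped warp (so the exact
  low-rank structure is preserved when the warp is disabled);
* detection p-values: small at observed entries, above 0.05 at planted
  masked positions, so detection-p masking reproduces the planted
  missingness exactly;
* planted annotation categories (sex-chromosome, cross-reactive,
  SNP-affected probes) at configurable fractions, disjoint from the signal
  blocks so QC removal does not destroy the latent structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import (
    SUBGROUP_LABELS,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
)

#: Classifiable class sizes of the primary cohort, in SUBGROUP_LABELS order
#: (WNT, SHH-Infant, SHH-Child, Group3-LowRisk, Group3-HighRisk,
#: Group4-LowRisk, Group4-HighRisk).
PRIMARY_CLASS_SIZES: dict[str, int] = {
    "WNT": 33,
    "SHH-Infant": 65,
    "SHH-Child": 38,
    "Group3-LowRisk": 50,
    "Group3-HighRisk": 65,
    "Group4-LowRisk": 73,
    "Group4-HighRisk": 85,
}

#: Default planted annotation fractions, scaled from the removal counts of a
#: full 485,512-probe array (11,648 XY / 37,639 cross-reactive / 59,284 SNP).
DEFAULT_ANNOTATION_FRACTIONS: dict[str, float] = {
    "xy": 11648 / 485512,
    "cross_reactive": 37639 / 485512,
    "snp": 59284 / 485512,
}

AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    W_true: np.ndarray
    H_true: np.ndarray
    labels: list[str]
    masked_positions: set
    planted_annotation: ProbeAnnotation
    noise: np.ndarray = field(repr=False, default=None)
    warp_sharpness: float | None = None


def table5_proportions() -> dict[str, float]:
    """Primary-cohort classifiable class proportions (sizes over 409)."""
    total = sum(PRIMARY_CLASS_SIZES.values())
    return {c: n / total for c, n in PRIMARY_CLASS_SIZES.items()}


def _warp(x: np.ndarray, g: float) -> np.ndarray:
    """Monotone S-shaped map [0,1] -> [0,1]; g > 1 pushes mass toward 0/1."""
    xg = np.power(x, g)
    return xg / (xg + np.power(1.0 - x, g))


def _allocate_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    # largest-remainder apportionment keeps counts integral and summing to n
    raw = {c: p * n for c, p in proportions.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_frac[:short]:
        counts[c] += 1
    return counts


def _subgroup_means(k: int, separation: float) -> dict[str, np.ndarray]:
    """Characteristic metagene coefficient vector per subgroup.

    Six of the seven subgroups anchor one metagene each; Group3-HighRisk is
    a mixture leaning from the Group3 anchor toward the Group4-HighRisk
    anchor, so the Group 3 / Group 4 risk classes overlap while WNT and the
    SHH classes stay well separated.
    """
    if k < 6:
        raise ValueError("subgroup structure requires k >= 6")
    e = np.eye(k)
    return {
        "WNT": e[0],
        "SHH-Infant": e[1],
        "SHH-Child": e[2],
        "Group3-LowRisk": e[3],
        "Group3-HighRisk": (1.0 - separation) * e[3] + separation * e[5],
        "Group4-LowRisk": e[4],
        "Group4-HighRisk": e[5],
    }


def generate_cohort(
    n_probes: int = 2000,
    n_samples: int = 350,
    k: int = 6,
    class_proportions: dict[str, float] | None = None,
    separation: float = 0.25,
    noise_sd: float = 0.02,
    missing_rate: float = 0.02,
    annotation_fractions: dict[str, float] | None = None,
    seed: int = 0,
    warp: bool = True,
    warp_sharpness: float = 2.0,
) -> tuple[BetaMatrix, SampleSheet, SyntheticTruth]:
    """Generate a seeded synthetic cohort.

    Parameters
    ----------
    n_probes, n_samples
        Cohort dimensions (defaults keep the whole pipeline testable in
        seconds while preserving the class-count arithmetic).
    k
        Latent rank; 6 mirrors the six-metagene structure of the arrays.
    class_proportions
        Subgroup proportions summing to 1; defaults to the primary cohort's
        (:func:`table5_proportions`).
    separation
        In [0, 0.5); smaller values pull Group3-HighRisk further from its
        Group3 anchor toward Group4-HighRisk.  0.25 keeps the risk pairs
        adjacent but resolvable.
    noise_sd
        Gaussian observation noise added to the low-rank signal.
    missing_rate
        Fraction of entries planted as low-confidence (detection p > 0.05).
    annotation_fractions
        Fractions of probes planted as xy / cross_reactive / snp categories
        (mutually disjoint, drawn outside the signal blocks).
    warp, warp_sharpness
        Apply the bimodality warp; disable for exact low-rank recovery
        tests.

    Returns (BetaMatrix with detection p-values, SampleSheet, SyntheticTruth).
    """
    if k > n_samples:
        raise ValueError("k must not exceed n_samples")
    proportions = class_proportions or table5_proportions()
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    fractions = dict(
        DEFAULT_ANNOTATION_FRACTIONS if annotation_fractions is None else annotation_fractions
    )
    if sum(fractions.values()) > 1.0:
        raise ValueError("combined annotation fractions exceed 1")
    if not (0.0 <= separation < 0.5):
        raise ValueError("separation must lie in [0, 0.5)")

    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]

    # subgroup labels, shuffled
    counts = _allocate_counts(proportions, n_samples)
    labels = [c for c in SUBGROUP_LABELS for _ in range(counts.get(c, 0))]
    order = rng.permutation(n_samples)
    labels = [labels[i] for i in order]

    # sparse nonnegative basis: disjoint high-loading blocks + low background
    block_size = max(1, int(0.6 * n_probes / k))
    W = rng.uniform(0.0, 0.05, size=(n_probes, k))
    for m in range(k):
        rows = slice(m * block_size, (m + 1) * block_size)
        W[rows, m] = rng.uniform(0.7, 1.0, size=block_size)
    signal_end = k * block_size

    # coefficients: characteristic subgroup vector, per-sample scale + jitter
    means = _subgroup_means(k, separation)
    H = np.empty((k, n_samples))
    for j, lab in enumerate(labels):
        gamma = rng.uniform(0.9, 1.1)
        H[:, j] = means[lab] * gamma + rng.uniform(0.0, 0.03, size=k)

    noise = rng.normal(0.0, noise_sd, size=(n_probes, n_samples)) if noise_sd > 0 else np.zeros((n_probes, n_samples))
    beta = np.clip(W @ H + noise, 0.0, 1.0)
    if warp:
        beta = _warp(beta, warp_sharpness)

    # detection p-values: confident everywhere except planted masked entries
    detection_p = rng.uniform(0.001, 0.04, size=(n_probes, n_samples))
    masked_positions: set = set()
    if missing_rate > 0:
        mask = rng.random((n_probes, n_samples)) < missing_rate
        detection_p[mask] = rng.uniform(0.051, 0.5, size=int(mask.sum()))
        pi, si = np.nonzero(mask)
        masked_positions = {(probe_ids[i], sample_ids[j]) for i, j in zip(pi, si)}

    # planted annotation categories on background (non-signal) probes
    n_xy = int(round(fractions.get("xy", 0.0) * n_probes))
    n_cross = int(round(fractions.get("cross_reactive", 0.0) * n_probes))
    n_snp = int(round(fractions.get("snp", 0.0) * n_probes))
    background = np.arange(signal_end, n_probes)
    pool = np.concatenate([rng.permutation(background), rng.permutation(signal_end)])
    if n_xy + n_cross + n_snp > n_probes:
        raise ValueError("annotation fractions exceed the probe universe")
    xy_idx = pool[:n_xy]
    cross_idx = pool[n_xy : n_xy + n_cross]
    snp_idx = pool[n_xy + n_cross : n_xy + n_cross + n_snp]

    chromosome = rng.choice(AUTOSOMES, size=n_probes).astype(object)
    chromosome[xy_idx] = rng.choice(["X", "Y"], size=n_xy)
    cross_reactive = np.zeros(n_probes, dtype=bool)
    cross_reactive[cross_idx] = True
    maf = np.zeros(n_probes)
    maf[snp_idx] = rng.uniform(0.05, 0.5, size=n_snp)
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "chromosome": chromosome,
                "cross_reactive": cross_reactive,
                "max_maf_within_50bp": maf,
            }
        )
    )

    bm = BetaMatrix(probe_ids, sample_ids, beta, detection_p)
    sheet = SampleSheet(pd.DataFrame({"sample_id": sample_ids, "label": labels}))
    truth = SyntheticTruth(
        W_true=W,
        H_true=H,
        labels=labels,
        masked_positions=masked_positions,
        planted_annotation=annotation,
        noise=noise,
        warp_sharpness=warp_sharpness if warp else None,
    )
    return bm, sheet, truth
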