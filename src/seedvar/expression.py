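"""Tissue-specificity screening and the differential-expression gate.

The tissue-specificity index tau over N tissues is the max-normalized
complement mean

    tau = sum_i (1 - x_hat_i) / (N - 1),   x_hat_i = x_i / max_j x_j,

computed by default on log2(FPKM + 1) values.  tau is 0 for a perfectly
uniform profile and 1 for single-tissue expression.  A gene is
*seed-specific* when its peak tissue is a seed-development stage and
tau > 0.6 (strict).

Differential expression between the large- and small-seeded cultivar at a
seed stage passes the gate at fold change >= 2 and q <= 0.05; candidate
screening asks for gate passes with higher expression in the large-seeded
cultivar at stage S3 and/or S5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExpressionMatrix, TissuePanel, ValidationError

TAU_THRESHOLD = 0.6
EXPRESSED_CUTOFF_FPKM = 1.0
MIN_FOLD = 2.0
MAX_Q = 0.05

UBIQUITOUS = "ubiquitous"
NON_SEED = "non_seed"
SEED_SPECIFIC = "seed_specific"
NOT_EXPRESSED = "not_expressed"


@dataclass
class SpecificityResult:
    gene_id: str
    tau: float | None  # None for not_expressed genes
    peak_tissue: str | None
    pattern: str


@dataclass
class DEResult:
    gene_id: str
    stage: str  # S1..S7
    log2fc: float  # large vs small
    q: float

    @property
    def higher_in(self) -> str:
        return "large" if self.log2fc > 0 else "small"


def tau_index(
    profile: np.ndarray | list[float], log_transform: bool = True
) -> tuple[float, int]:
    """tau and the argmax index (first index on ties).

    Raises on an all-zero profile; callers classify those as not_expressed.
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValidationError("tau needs >= 2 tissues")
    if (x < 0).any():
        raise ValidationError("negative expression value")
    if not x.any():
        raise ValidationError("all-zero profile has no tau")
    raw = x
    if log_transform:
        x = np.log2(x + 1.0)
        if x.max() == 0.0:  # all values underflow the log transform
            x = raw
    xhat = x / x.max()
    tau = float((1.0 - xhat).sum() / (x.size - 1))
    return tau, int(np.argmax(x))


def classify_pattern(
    profile: np.ndarray | list[float],
    panel: TissuePanel,
    expressed_cutoff_fpkm: float = EXPRESSED_CUTOFF_FPKM,
    tau_threshold: float = TAU_THRESHOLD,
    log_transform: bool = True,
) -> SpecificityResult:
    """Classify one gene's FPKM profile over the tissue panel."""
    panel.validate()
    x = np.asarray(profile, dtype=float)
    if x.size != len(panel.labels):
        raise ValidationError("profile length does not match tissue panel")
    if (x < expressed_cutoff_fpkm).all():
        return SpecificityResult("", None, None, NOT_EXPRESSED)
    tau, peak_idx = tau_index(x, log_transform=log_transform)
    peak = panel.labels[peak_idx]
    seed_mask = np.array([panel.is_seed[t] for t in panel.labels])
    if panel.is_seed[peak] and tau > tau_threshold:
        pattern = SEED_SPECIFIC
    elif (x[seed_mask] < expressed_cutoff_fpkm).all() and (
        x[~seed_mask] >= expressed_cutoff_fpkm
    ).any():
        pattern = NON_SEED
    else:
        pattern = UBIQUITOUS
    return SpecificityResult("", tau, peak, pattern)


def screen_specificity(
    matrix: ExpressionMatrix,
    expressed_cutoff_fpkm: float = EXPRESSED_CUTOFF_FPKM,
    tau_threshold: float = TAU_THRESHOLD,
    log_transform: bool = True,
) -> list[SpecificityResult]:
    out = []
    for gene_id, row in matrix.values.iterrows():
        r = classify_pattern(
            row.values,
            matrix.panel,
            expressed_cutoff_fpkm,
            tau_threshold,
            log_transform,
        )
        r.gene_id = gene_id
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# differential-expression gate
# ---------------------------------------------------------------------------

def de_gate(
    de: DEResult, min_fold: float = MIN_FOLD, max_q: float = MAX_Q
) -> bool:
    """Pass iff |log2fc| >= log2(min_fold) and q <= max_q."""
    return bool(abs(de.log2fc) >= np.log2(min_fold) and de.q <= max_q)


def s3s5_higher_in_large(
    de_results: list[DEResult],
    min_fold: float = MIN_FOLD,
    max_q: float = MAX_Q,
) -> bool:
    """True iff some S3 or S5 result passes the gate with higher expression
    in the large-seeded cultivar (inclusive or)."""
    return any(
        de.stage in ("S3", "S5") and de.higher_in == "large" and de_gate(de, min_fold, max_q)
        for de in de_results
    )


def de_results_from_table(df: pd.DataFrame) -> dict[str, list[DEResult]]:
    """Group a (gene_id, stage, log2fc, q) table into per-gene DEResults."""
    out: dict[str, list[DEResult]] = {}
    for r in df.itertuples():
        out.setdefault(r.gene_id, []).append(
            DEResult(r.gene_id, r.stage, float(r.log2fc), float(r.q))
        )
    return out


def de_from_replicates(
    large: pd.DataFrame, small: pd.DataFrame, stage: str
) -> list[DEResult]:
    """Synthetic stand-in for an external DE caller, for use when only
    replicate FPKMs are available (tests and simulations only).

    Fold change is the ratio of means with pseudocount 1; q-values are
    Benjamini-Hochberg-adjusted Welch t-test p-values across genes.
    """
    if not large.index.equals(small.index):
        raise ValidationError("replicate matrices must share the gene index")
    lfc = np.log2((large.mean(axis=1) + 1.0) / (small.mean(axis=1) + 1.0))
    t = stats.ttest_ind(large, small, axis=1, equal_var=False)
    pvals = np.nan_to_num(t.pvalue, nan=1.0)
    qvals = stats.false_discovery_control(pvals, method="bh")
    return [
        DEResult(g, stage, float(lfc.loc[g]), float(q))
        for g, q in zip(large.index, qvals)
    ]
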