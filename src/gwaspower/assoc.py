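"""MAF filtering, the allelic chi-square association test, and Bonferroni filtering.

The association test is the basic allelic (1 df) Pearson chi-square on the
2x2 table of risk-allele counts by case status, without continuity
correction.  Significance uses a strict ``p < threshold`` rule with the
threshold defaulting to the Bonferroni-corrected ``alpha / n_generated``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import StructuralError
from .sim_model import SnpDataset

__all__ = [
    "AssocRecord",
    "AssocTable",
    "maf_filter",
    "allelic_chisq",
    "bonferroni_threshold",
    "run_association",
]


@dataclass(frozen=True)
class AssocRecord:
    """Per-SNP association result (allele scale)."""

    snp_id: str
    truth: str
    a_count_cases: int
    a_count_controls: int
    f_a: float
    f_u: float
    chisq: float
    p_value: float
    or_estimate: float  # NaN when any 2x2 cell is zero


@dataclass
class AssocTable:
    """Association results for all SNPs surviving the MAF filter.

    ``frame`` has one row per tested SNP with the :class:`AssocRecord`
    columns plus a ``significant`` flag (strict ``p_value < threshold``).
    """

    frame: pd.DataFrame
    n_generated: int
    n_tested: int
    threshold: float | None

    def __post_init__(self) -> None:
        if self.n_tested > self.n_generated:
            raise ValueError("n_tested cannot exceed n_generated")

    @property
    def records(self) -> list[AssocRecord]:
        cols = [f.name for f in AssocRecord.__dataclass_fields__.values()]
        return [AssocRecord(**row) for row in self.frame[cols].to_dict("records")]

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def significant_counts(self) -> tuple[int, int]:
        """(disease SNPs significant, null SNPs significant)."""
        sig = self.significant
        n_disease = int((sig["truth"] == "disease").sum())
        return n_disease, len(sig) - n_disease


def maf_filter(dataset: SnpDataset, threshold: float) -> tuple[SnpDataset, SnpDataset]:
    """Split a dataset into (kept, removed) by pooled-sample minor allele frequency.

    MAF is ``min(f, 1-f)`` of the risk allele frequency in the pooled
    case+control sample; a SNP is removed iff ``MAF < threshold`` (strict),
    so a SNP sitting exactly on the bound is kept.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError(f"threshold must be in [0, 0.5), got {threshold}")
    total_alleles = 2 * (dataset.n_cases + dataset.n_controls)
    if total_alleles == 0:
        raise StructuralError("cannot compute MAF on a dataset with zero individuals")
    a_cases, a_controls = dataset.risk_allele_counts()
    freq = (a_cases + a_controls) / total_alleles
    maf = np.minimum(freq, 1.0 - freq)
    removed_mask = maf < threshold
    return dataset.subset(~removed_mask), dataset.subset(removed_mask)


def allelic_chisq(
    case_allele_counts: tuple[int, int],
    control_allele_counts: tuple[int, int],
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    allele-count table ``[[case A, case B], [control A, control B]]``.

    A pooled-monomorphic table (one allele absent overall) is reported as
    ``(0.0, 1.0)`` — such SNPs are the MAF filter's job to remove.
    """
    a_a, a_b = case_allele_counts
    u_a, u_b = control_allele_counts
    if min(a_a, a_b, u_a, u_b) < 0:
        raise ValueError("allele counts must be non-negative")
    if a_a + a_b == 0 or u_a + u_b == 0:
        raise ValueError("each group needs at least one allele")
    stat, p = _chisq_arrays(
        np.array([a_a]), np.array([u_a]), a_a + a_b, u_a + u_b
    )
    return float(stat[0]), float(p[0])


def _chisq_arrays(
    a_cases: np.ndarray,
    a_controls: np.ndarray,
    n_case_alleles: int,
    n_control_alleles: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised allelic chi-square over SNPs with common group allele totals."""
    a_cases = np.asarray(a_cases, dtype=float)
    a_controls = np.asarray(a_controls, dtype=float)
    n_total = n_case_alleles + n_control_alleles
    col_a = a_cases + a_controls
    col_b = n_total - col_a
    monomorphic = (col_a == 0) | (col_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_case_a = n_case_alleles * col_a / n_total
        e_case_b = n_case_alleles * col_b / n_total
        e_ctrl_a = n_control_alleles * col_a / n_total
        e_ctrl_b = n_control_alleles * col_b / n_total
        stat = (
            (a_cases - e_case_a) ** 2 / e_case_a
            + ((n_case_alleles - a_cases) - e_case_b) ** 2 / e_case_b
            + (a_controls - e_ctrl_a) ** 2 / e_ctrl_a
            + ((n_control_alleles - a_controls) - e_ctrl_b) ** 2 / e_ctrl_b
        )
    stat = np.where(monomorphic, 0.0, stat)
    p = chi2.sf(stat, df=1)
    p = np.where(monomorphic, 1.0, p)
    return stat, p


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise p-value threshold ``alpha / n_tests`` (exact, no rounding)."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return alpha / n_tests


def run_association(
    dataset: SnpDataset,
    alpha: float = 0.05,
    maf_threshold: float = 0.05,
    threshold_override: float | None = None,
) -> AssocTable:
    """MAF-filter, test every kept SNP with the allelic chi-square, and flag
    significance at a strict ``p < threshold``.

    The threshold is ``threshold_override`` when given (the replication runs
    pass the printed rounded value 5e-7), else the Bonferroni correction
    ``alpha / n_generated`` over the generated SNP count.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    kept, _removed = maf_filter(dataset, maf_threshold)
    threshold = threshold_override if threshold_override is not None else bonferroni_threshold(alpha, len(dataset))

    a_cases, a_controls = kept.risk_allele_counts()
    n_case_alleles = 2 * kept.n_cases
    n_control_alleles = 2 * kept.n_controls
    stat, p = _chisq_arrays(a_cases, a_controls, n_case_alleles, n_control_alleles)

    f_a = a_cases / n_case_alleles if n_case_alleles else np.full(len(kept), np.nan)
    f_u = a_controls / n_control_alleles if n_control_alleles else np.full(len(kept), np.nan)
    b_cases = n_case_alleles - a_cases
    b_controls = n_control_alleles - a_controls
    with np.errstate(divide="ignore", invalid="ignore"):
        or_est = (a_cases * b_controls) / (b_cases * a_controls)
    zero_cell = (a_cases == 0) | (b_cases == 0) | (a_controls == 0) | (b_controls == 0)
    or_est = np.where(zero_cell, np.nan, or_est)

    frame = pd.DataFrame(
        {
            "snp_id": kept.snp_ids,
            "truth": kept.truth,
            "a_count_cases": a_cases.astype(np.int64),
            "a_count_controls": a_controls.astype(np.int64),
            "f_a": f_a,
            "f_u": f_u,
            "chisq": stat,
            "p_value": p,
            "or_estimate": or_est,
            "significant": p < threshold,
        }
    )
    return AssocTable(frame=frame, n_generated=len(dataset), n_tested=len(kept), threshold=threshold)
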