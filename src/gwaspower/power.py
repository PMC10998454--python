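"""Estimated average power (S/m), the analytic power oracle, and the
between-design comparison of detection counts.

The analytic oracle treats the allelic test as a noncentral chi-square: with
expected case/control risk-allele frequencies ``q_A`` and ``q_U`` from the
disease model, the noncentrality of the 1-df Pearson statistic is

    lambda = (q_A - q_U)^2 / [ qbar (1 - qbar) (1/(2 N_A) + 1/(2 N_U)) ]

with ``qbar`` the allele-count-weighted pooled frequency.  Per-SNP power is
the upper tail of the noncentral chi-square at the central 1-df critical
value; average power integrates per-SNP power times the probability of
surviving the MAF filter over the uniform frequency distribution, with the
full disease-SNP count ``m`` as denominator (filtered SNPs count as
failures, matching the simulated S/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.integrate import quad
from scipy.stats import chi2, ncx2, norm

from .sim_model import SimConfig, genotype_dists_given_status, solve_baseline_odds

__all__ = [
    "PowerSummary",
    "ComparisonResult",
    "estimated_average_power",
    "analytic_snp_power",
    "maf_retention",
    "analytic_average_power",
    "compare_ratios",
    "pairwise_detection_chisq",
]


@dataclass(frozen=True)
class PowerSummary:
    """Detection summary for one simulated design."""

    s_detected: int
    m_total: int
    power_estimate: float
    n_sig_null: int
    threshold: float
    design: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.s_detected <= self.m_total):
            raise ValueError("require 0 <= s_detected <= m_total")


def estimated_average_power(s_detected: int, m_total: int) -> float:
    """Estimated average power S/m: the fraction of simulated disease SNPs
    declared significant.  Exact ratio; reporting layers round to 2 decimals."""
    if m_total < 1:
        raise ValueError("m_total must be >= 1")
    if not (0 <= s_detected <= m_total):
        raise ValueError("require 0 <= s_detected <= m_total")
    return s_detected / m_total


def _expected_allele_freqs(
    pop_freq: float, or_het: float, or_hom: float, prevalence_k: float
) -> tuple[float, float]:
    """Expected risk-allele frequency in cases and controls under the model."""
    model = solve_baseline_odds(pop_freq, or_het, or_hom, prevalence_k)
    dist = genotype_dists_given_status(model, prevalence_k)
    q_a = 0.5 * dist.case_probs[1] + dist.case_probs[2]
    q_u = 0.5 * dist.control_probs[1] + dist.control_probs[2]
    return q_a, q_u


def analytic_snp_power(
    pop_freq: float,
    or_het: float,
    or_hom: float,
    prevalence_k: float,
    n_cases: int,
    n_controls: int,
    threshold: float,
) -> float:
    """Noncentral chi-square power of the allelic test for a single SNP."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0,1)")
    q_a, q_u = _expected_allele_freqs(pop_freq, or_het, or_hom, prevalence_k)
    qbar = (n_cases * q_a + n_controls * q_u) / (n_cases + n_controls)
    if qbar <= 0.0 or qbar >= 1.0:
        return 0.0
    lam = (q_a - q_u) ** 2 / (
        qbar * (1.0 - qbar) * (1.0 / (2.0 * n_cases) + 1.0 / (2.0 * n_controls))
    )
    crit = chi2.isf(threshold, df=1)
    return float(ncx2.sf(crit, df=1, nc=lam))


def maf_retention(
    pop_freq: float,
    or_het: float,
    or_hom: float,
    prevalence_k: float,
    n_cases: int,
    n_controls: int,
    maf_threshold: float,
    exact: bool = False,
) -> float:
    """Probability that a SNP survives the pooled-sample MAF filter.

    Default: normal approximation to the pooled sample allele frequency
    around its expectation.  ``exact=True`` convolves the two group-level
    binomial allele-count distributions instead (slower; itself an
    approximation that ignores within-group departure from binomial
    allele sampling).
    """
    if maf_threshold <= 0.0:
        return 1.0
    q_a, q_u = _expected_allele_freqs(pop_freq, or_het, or_hom, prevalence_k)
    n_alleles = 2 * (n_cases + n_controls)
    qbar = (n_cases * q_a + n_controls * q_u) / (n_cases + n_controls)
    lo, hi = maf_threshold, 1.0 - maf_threshold
    if exact:
        ka = np.arange(2 * n_cases + 1)
        ku = np.arange(2 * n_controls + 1)
        from scipy.stats import binom

        pmf = np.convolve(binom.pmf(ka, 2 * n_cases, q_a), binom.pmf(ku, 2 * n_controls, q_u))
        counts = np.arange(n_alleles + 1)
        freq = counts / n_alleles
        return float(pmf[(freq >= lo) & (freq <= hi)].sum())
    var = qbar * (1.0 - qbar) / n_alleles
    if var <= 0.0:
        return float(lo <= qbar <= hi)
    sd = np.sqrt(var)
    return float(norm.cdf((hi - qbar) / sd) - norm.cdf((lo - qbar) / sd))


def analytic_average_power(
    config: SimConfig,
    design: tuple[int, int],
    threshold: float,
    exact_retention: bool = False,
) -> float:
    """Closed-form twin of the simulated S/m: per-SNP power times MAF-filter
    retention, integrated over the uniform frequency distribution.

    MAF-filtered disease SNPs count as failures (full-``m`` denominator).
    """
    n_cases, n_controls = design
    or_het, or_hom, k = config.or_het, config.resolved_or_hom, config.prevalence_k
    lo, hi = config.freq_lo, config.freq_hi
    if hi == lo:
        p = lo
        return analytic_snp_power(p, or_het, or_hom, k, n_cases, n_controls, threshold) * maf_retention(
            p, or_het, or_hom, k, n_cases, n_controls, config.maf_threshold, exact_retention
        )

    def integrand(p: float) -> float:
        pw = analytic_snp_power(p, or_het, or_hom, k, n_cases, n_controls, threshold)
        if pw == 0.0:
            return 0.0
        ret = maf_retention(
            p, or_het, or_hom, k, n_cases, n_controls, config.maf_threshold, exact_retention
        )
        return pw * ret

    interior = [p for p in (config.maf_threshold, 1.0 - config.maf_threshold) if lo < p < hi]
    value, _err = quad(integrand, lo, hi, limit=300, points=interior or None)
    return value / (hi - lo)


# ---------------------------------------------------------------------------
# Between-design comparison


@dataclass
class ComparisonResult:
    """Pairwise chi-square comparison of detected counts across designs.

    ``pairwise_p`` is symmetric with unit diagonal; ``groups`` is a compact
    letter display at the comparison level: designs sharing a letter do not
    differ significantly.
    """

    designs: list[str]
    detected: list[int]
    pairwise_p: np.ndarray
    groups: list[str]
    level: float = 0.05


def pairwise_detection_chisq(d_i: int, d_j: int, m_total: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    of detected vs not-detected counts out of ``m_total`` for two designs."""
    if m_total < 1:
        raise ValueError("m_total must be >= 1")
    for d in (d_i, d_j):
        if not (0 <= d <= m_total):
            raise ValueError("counts must lie in [0, m_total]")
    obs = np.array([[d_i, m_total - d_i], [d_j, m_total - d_j]], dtype=float)
    col = obs.sum(axis=0)
    if col[0] == 0 or col[1] == 0:
        return 0.0, 1.0
    expected = np.outer(obs.sum(axis=1), col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def _letter_groups(nonsig: np.ndarray, order: list[int]) -> list[str]:
    """Deterministic compact letter display: letters are the sorted maximal
    cliques of the non-significant-pair graph, so two designs share a letter
    iff they belong to a common clique of mutually non-different designs."""
    graph = nx.Graph()
    graph.add_nodes_from(order)
    k = len(order)
    for i in range(k):
        for j in range(i + 1, k):
            if nonsig[i, j]:
                graph.add_edge(i, j)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: (min(c), -len(c), c))
    letters = [""] * k
    for rank, clique in enumerate(cliques):
        letter = chr(ord("a") + rank)
        for node in clique:
            letters[node] += letter
    return letters


def compare_ratios(
    detected: list[int],
    m_total: int,
    labels: list[str] | None = None,
    level: float = 0.05,
) -> ComparisonResult:
    """Compare detected-SNP counts between designs with pairwise 2x2 Pearson
    chi-square tests and assign compact-letter-display groups at ``level``.

    No multiplicity adjustment is applied across pairs (an approximation
    noted in reports); designs with identical counts always share a letter.
    """
    if len(detected) < 2:
        raise ValueError("need at least two designs to compare")
    if m_total < 1:
        raise ValueError("m_total must be >= 1")
    k = len(detected)
    if labels is None:
        labels = [f"design_{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match detected length")
    pairwise = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _stat, p = pairwise_detection_chisq(detected[i], detected[j], m_total)
            pairwise[i, j] = pairwise[j, i] = p
    nonsig = pairwise >= level
    groups = _letter_groups(nonsig, list(range(k)))
    return ComparisonResult(
        designs=list(labels), detected=list(detected), pairwise_p=pairwise, groups=groups, level=level
    )
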