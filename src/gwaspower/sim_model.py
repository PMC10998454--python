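"""Case/control genotype simulator under an odds-ratio penetrance disease model.

The generator draws, for every SNP, a population risk-allele frequency ``p``
uniform on a configured interval, builds Hardy--Weinberg genotype frequencies
``(q^2, 2pq, p^2)`` for the (hom-ref, het, hom-risk) genotypes, and — for
disease SNPs — a penetrance model in which the disease odds of the
heterozygote and risk homozygote are ``or_het`` and ``or_hom`` times the
baseline odds of the reference homozygote.  The baseline odds is solved so
that the HWE-weighted mean penetrance equals the population prevalence ``K``.
Case and control genotype distributions then follow by Bayes inversion:

    P(G | case)    = HWE(G) * f(G) / K
    P(G | control) = HWE(G) * (1 - f(G)) / (1 - K)

Genotype counts per group are multinomial draws from these distributions,
so a full 100,400-SNP dataset is simulated at the count level in well under
a second.  Individual-level expansion exists only for PED/MAP export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleTargetError, ModelInfeasibleError, StructuralError

__all__ = [
    "GENOTYPE_ORDER",
    "SimConfig",
    "PenetranceModel",
    "GenotypeDistribution",
    "SnpCounts",
    "SnpDataset",
    "solve_baseline_odds",
    "genotype_dists_given_status",
    "hwe_probs",
    "simulate_dataset",
    "expand_to_individuals",
    "calibrate_or",
    "paper2024",
]

#: Genotype index convention used throughout: 0, 1, 2 copies of the risk allele A.
GENOTYPE_ORDER = ("hom_ref", "het", "hom_risk")

# Multiplicative sentinel: or_hom = or_het ** 2.
MULTIPLICATIVE = "mult"


@dataclass(frozen=True)
class SimConfig:
    """All simulation parameters for one study.

    Parameters
    ----------
    n_null, n_disease
        Number of null (no-effect) and disease-associated SNPs to generate.
    freq_lo, freq_hi
        Bounds of the uniform population risk-allele-frequency distribution.
    or_het
        Heterozygote odds ratio shared by all disease SNPs.
    or_hom
        Risk-homozygote odds ratio, or ``None`` for the multiplicative
        default ``or_het ** 2``.
    prevalence_k
        Population disease prevalence (probability of being a case).
    maf_threshold
        Minor-allele-frequency bound below which SNPs are excluded from
        association testing (strict ``<``).
    alpha
        Family-wise significance level used for the Bonferroni threshold.
    seed
        Root RNG seed.
    """

    n_null: int = 100_000
    n_disease: int = 400
    freq_lo: float = 0.0
    freq_hi: float = 1.0
    or_het: float = 1.0
    or_hom: float | None = None
    prevalence_k: float = 0.01
    maf_threshold: float = 0.05
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.freq_lo <= self.freq_hi <= 1.0):
            raise ValueError(f"require 0 <= freq_lo <= freq_hi <= 1, got [{self.freq_lo}, {self.freq_hi}]")
        if not (0.0 < self.prevalence_k < 1.0):
            raise ValueError(f"prevalence_k must be in (0,1), got {self.prevalence_k}")
        if self.or_het <= 0:
            raise ValueError(f"or_het must be > 0, got {self.or_het}")
        if self.or_hom is not None and self.or_hom <= 0:
            raise ValueError(f"or_hom must be > 0, got {self.or_hom}")
        if not (0.0 <= self.maf_threshold < 0.5):
            raise ValueError(f"maf_threshold must be in [0, 0.5), got {self.maf_threshold}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_null < 0 or self.n_disease < 0:
            raise ValueError("SNP counts must be non-negative")

    @property
    def resolved_or_hom(self) -> float:
        """Homozygote odds ratio with the multiplicative default applied."""
        return self.or_het ** 2 if self.or_hom is None else self.or_hom

    @property
    def n_total(self) -> int:
        return self.n_null + self.n_disease

    def with_effect(self, or_het: float, or_hom: float | None = None) -> "SimConfig":
        return replace(self, or_het=or_het, or_hom=or_hom)


def paper2024(or_het: float = 1.0, or_hom: float | None = None) -> SimConfig:
    """The replication preset: 100,000 null + 400 disease SNPs, frequencies
    uniform on [0, 1], prevalence 0.01, alpha 0.05.

    ``maf_threshold`` is 0 in this preset: the reference study ran no
    quality-control filter on the generated set (all 100,400 SNPs were
    tested), and its printed power profile is only reproduced under that
    protocol.  Pass ``maf_threshold`` through :func:`dataclasses.replace`
    to study the filtered variant.
    """
    return SimConfig(
        n_null=100_000,
        n_disease=400,
        freq_lo=0.0,
        freq_hi=1.0,
        or_het=or_het,
        or_hom=or_hom,
        prevalence_k=0.01,
        maf_threshold=0.0,
        alpha=0.05,
    )


@dataclass(frozen=True)
class PenetranceModel:
    """Solved disease model for one SNP.

    ``f_*`` are penetrances (probability of disease given genotype); the
    odds-ratio relations ``odds(f_het) = or_het * baseline_odds`` and
    ``odds(f_hom_risk) = or_hom * baseline_odds`` hold by construction, and
    the HWE-weighted mean penetrance equals the prevalence.
    """

    p: float
    baseline_odds: float
    f_hom_ref: float
    f_het: float
    f_hom_risk: float

    @property
    def penetrances(self) -> np.ndarray:
        return np.array([self.f_hom_ref, self.f_het, self.f_hom_risk])

    @property
    def hwe_weights(self) -> np.ndarray:
        return hwe_probs(self.p)


@dataclass(frozen=True)
class GenotypeDistribution:
    """Genotype probability triples given case and control status."""

    case_probs: tuple[float, float, float]
    control_probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, probs in (("case_probs", self.case_probs), ("control_probs", self.control_probs)):
            arr = np.asarray(probs, dtype=float)
            if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
                raise ValueError(f"{name} entries must lie in [0,1]: {probs}")
            if abs(arr.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 within 1e-12: sum={arr.sum()!r}")


def hwe_probs(p: float | np.ndarray) -> np.ndarray:
    """Hardy--Weinberg genotype probabilities (q^2, 2pq, p^2) for risk-allele
    frequency ``p``; vectorised over ``p`` (last axis indexes genotype)."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def _prevalence_at(b: float, weights: np.ndarray, ors: np.ndarray) -> float:
    """HWE-weighted mean penetrance at baseline odds ``b``."""
    ob = ors * b
    return float(np.sum(weights * ob / (1.0 + ob)))


def solve_baseline_odds(
    p: float,
    or_het: float,
    or_hom: float,
    prevalence_k: float,
) -> PenetranceModel:
    """Solve the baseline (reference-homozygote) disease odds so that the
    HWE-weighted mean penetrance equals ``prevalence_k``.

    Deterministic bracketed root-finding on the baseline odds; the prevalence
    is strictly increasing in it, so the root is unique.  The initial upper
    bracket ``k/(1-k)`` (exact when both odds ratios are 1) is expanded as
    needed for protective odds ratios.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0,1], got {p}")
    if or_het <= 0 or or_hom <= 0 or not (0 < prevalence_k < 1):
        raise ValueError("odds ratios must be > 0 and prevalence in (0,1)")
    weights = hwe_probs(p)
    ors = np.array([1.0, or_het, or_hom])

    def objective(b: float) -> float:
        return _prevalence_at(b, weights, ors) - prevalence_k

    hi = prevalence_k / (1.0 - prevalence_k)
    for _ in range(200):
        if objective(hi) >= 0.0:
            break
        hi *= 2.0
    else:
        raise ModelInfeasibleError(
            f"no baseline odds reaches prevalence {prevalence_k} for "
            f"p={p}, or_het={or_het}, or_hom={or_hom}"
        )
    b = brentq(objective, 0.0, hi, xtol=1e-300, rtol=8.9e-16)
    f = ors * b / (1.0 + ors * b)
    return PenetranceModel(p=p, baseline_odds=float(b), f_hom_ref=float(f[0]), f_het=float(f[1]), f_hom_risk=float(f[2]))


def genotype_dists_given_status(model: PenetranceModel, prevalence_k: float) -> GenotypeDistribution:
    """Bayes-invert a solved penetrance model into genotype distributions
    conditional on case and on control status."""
    w = model.hwe_weights
    f = model.penetrances
    case = w * f / prevalence_k
    control = w * (1.0 - f) / (1.0 - prevalence_k)
    # Solver residual can leave the triples a hair off 1; renormalise within tolerance.
    case = case / case.sum()
    control = control / control.sum()
    return GenotypeDistribution(case_probs=tuple(case), control_probs=tuple(control))


def _case_control_probs(
    p: np.ndarray, or_het: float, or_hom: float, prevalence_k: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised case/control genotype probability matrices, one row per SNP."""
    p = np.asarray(p, dtype=float)
    if or_het == 1.0 and or_hom == 1.0:
        w = hwe_probs(p)
        return w.copy(), w.copy()
    case = np.empty((p.size, 3))
    control = np.empty((p.size, 3))
    for i, pi in enumerate(p):
        model = solve_baseline_odds(float(pi), or_het, or_hom, prevalence_k)
        dist = genotype_dists_given_status(model, prevalence_k)
        case[i] = dist.case_probs
        control[i] = dist.control_probs
    return case, control


# ---------------------------------------------------------------------------
# Count-level dataset container


@dataclass(frozen=True)
class SnpCounts:
    """Genotype counts for a single SNP, (hom-ref, het, hom-risk) per group."""

    snp_id: str
    truth: str  # "null" | "disease"
    pop_freq: float
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]


@dataclass
class SnpDataset:
    """Column-oriented collection of :class:`SnpCounts` (the count-level fast path).

    ``case_counts`` / ``control_counts`` are ``(n_snps, 3)`` integer arrays in
    the (hom-ref, het, hom-risk) genotype order; every row sums to the group
    size.  Iterating the dataset yields per-SNP :class:`SnpCounts` records.
    """

    snp_ids: np.ndarray
    truth: np.ndarray
    pop_freq: np.ndarray
    case_counts: np.ndarray
    control_counts: np.ndarray
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("truth", "pop_freq"):
            if len(getattr(self, name)) != n:
                raise StructuralError(f"{name} length mismatch")
        for name, group_n in (("case_counts", self.n_cases), ("control_counts", self.n_controls)):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n, 3):
                raise StructuralError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            if arr.min(initial=0) < 0:
                raise StructuralError(f"{name} contains negative counts")
            if n and not np.all(arr.sum(axis=1) == group_n):
                raise StructuralError(f"{name} rows must sum to the group size {group_n}")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __iter__(self) -> Iterator[SnpCounts]:
        for i in range(len(self)):
            yield SnpCounts(
                snp_id=str(self.snp_ids[i]),
                truth=str(self.truth[i]),
                pop_freq=float(self.pop_freq[i]),
                case_counts=tuple(int(c) for c in self.case_counts[i]),
                control_counts=tuple(int(c) for c in self.control_counts[i]),
            )

    def subset(self, mask: np.ndarray) -> "SnpDataset":
        mask = np.asarray(mask, dtype=bool)
        return SnpDataset(
            snp_ids=self.snp_ids[mask],
            truth=self.truth[mask],
            pop_freq=self.pop_freq[mask],
            case_counts=self.case_counts[mask],
            control_counts=self.control_counts[mask],
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )

    def risk_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Risk-allele (A) counts per SNP in cases and controls: 2*hom_risk + het."""
        a_cases = 2 * self.case_counts[:, 2] + self.case_counts[:, 1]
        a_controls = 2 * self.control_counts[:, 2] + self.control_counts[:, 1]
        return a_cases, a_controls

    @classmethod
    def from_records(cls, records: Sequence[SnpCounts], n_cases: int, n_controls: int) -> "SnpDataset":
        return cls(
            snp_ids=np.array([r.snp_id for r in records]),
            truth=np.array([r.truth for r in records]),
            pop_freq=np.array([r.pop_freq for r in records], dtype=float),
            case_counts=np.array([r.case_counts for r in records], dtype=np.int64).reshape(-1, 3),
            control_counts=np.array([r.control_counts for r in records], dtype=np.int64).reshape(-1, 3),
            n_cases=n_cases,
            n_controls=n_controls,
        )


def _multinomial_rows(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    """Row-wise Multinomial(n, probs[i]) counts via a vectorised binomial chain."""
    m = probs.shape[0]
    out = np.zeros((m, 3), dtype=np.int64)
    if n == 0 or m == 0:
        return out
    remaining = np.full(m, n, dtype=np.int64)
    consumed = np.zeros(m)
    for g in range(2):
        pg = probs[:, g]
        denom = 1.0 - consumed
        cond = np.where(denom > 1e-12, np.clip(pg / np.where(denom > 1e-12, denom, 1.0), 0.0, 1.0), 1.0)
        draw = rng.binomial(remaining, cond)
        out[:, g] = draw
        remaining -= draw
        consumed += pg
    out[:, 2] = remaining
    return out


def _dataset_rng(config: SimConfig, n_cases: int, n_controls: int, seed: int | None) -> np.random.Generator:
    root = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence((root, n_cases, n_controls)))


def simulate_dataset(
    config: SimConfig,
    n_cases: int,
    n_controls: int,
    seed: int | None = None,
) -> SnpDataset:
    """Simulate genotype counts for ``config.n_null`` null and ``config.n_disease``
    disease SNPs in ``n_cases`` cases and ``n_controls`` controls.

    Per-SNP population risk-allele frequencies are independent uniforms on
    ``[freq_lo, freq_hi]``.  Null SNPs are sampled from HWE genotype
    frequencies in both groups; disease SNPs from the Bayes-inverted
    case/control distributions of the solved penetrance model.  Fully
    reproducible from ``(config, n_cases, n_controls, seed)``; draws happen
    in a fixed order (frequencies, case counts, control counts) from one
    seed-derived stream.
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("group sizes must be non-negative")
    rng = _dataset_rng(config, n_cases, n_controls, seed)

    n_null, n_dis = config.n_null, config.n_disease
    pop_freq = rng.uniform(config.freq_lo, config.freq_hi, n_null + n_dis)

    case_probs = np.empty((n_null + n_dis, 3))
    control_probs = np.empty((n_null + n_dis, 3))
    w_null = hwe_probs(pop_freq[:n_null])
    case_probs[:n_null] = w_null
    control_probs[:n_null] = w_null
    case_probs[n_null:], control_probs[n_null:] = _case_control_probs(
        pop_freq[n_null:], config.or_het, config.resolved_or_hom, config.prevalence_k
    )

    case_counts = _multinomial_rows(rng, n_cases, case_probs)
    control_counts = _multinomial_rows(rng, n_controls, control_probs)

    width_null = max(len(str(max(n_null, 1))), 1)
    width_dis = max(len(str(max(n_dis, 1))), 1)
    snp_ids = np.array(
        [f"null_{i:0{width_null}d}" for i in range(1, n_null + 1)]
        + [f"disease_{i:0{width_dis}d}" for i in range(1, n_dis + 1)]
    )
    truth = np.array(["null"] * n_null + ["disease"] * n_dis)
    return SnpDataset(
        snp_ids=snp_ids,
        truth=truth,
        pop_freq=pop_freq,
        case_counts=case_counts,
        control_counts=control_counts,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def expand_to_individuals(dataset: SnpDataset, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Expand count-level data to an individual-level genotype matrix.

    Returns ``(genotypes, phenotypes)``: genotypes is ``(n_individuals, n_snps)``
    of risk-allele dosages 0/1/2 with cases first, phenotypes uses the PLINK
    coding 2 = case, 1 = control.  Per SNP, the genotype-to-individual
    assignment is an independent uniformly random permutation consistent with
    the counts, so column-wise recounting recovers the source counts exactly
    and distinct SNPs carry no linkage disequilibrium by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, len(dataset))))
    n_ind = dataset.n_cases + dataset.n_controls
    genotypes = np.empty((n_ind, len(dataset)), dtype=np.int8)
    codes = np.array([0, 1, 2], dtype=np.int8)
    for j in range(len(dataset)):
        case_vec = np.repeat(codes, dataset.case_counts[j])
        ctrl_vec = np.repeat(codes, dataset.control_counts[j])
        genotypes[: dataset.n_cases, j] = rng.permutation(case_vec)
        genotypes[dataset.n_cases :, j] = rng.permutation(ctrl_vec)
    phenotypes = np.concatenate(
        [np.full(dataset.n_cases, 2, dtype=np.int8), np.full(dataset.n_controls, 1, dtype=np.int8)]
    )
    return genotypes, phenotypes


def calibrate_or(
    target_power: float,
    design: tuple[int, int],
    config: SimConfig,
    tolerance: float = 1e-8,
    threshold: float | None = None,
) -> float:
    """Find the shared heterozygote odds ratio (``or_hom = or_het**2``) at which
    the analytic average power of ``design`` equals ``target_power``.

    Deterministic root-finding against :func:`gwaspower.power.analytic_average_power`.
    Raises :class:`InfeasibleTargetError` when the target exceeds the design's
    achievable average power (the MAF-retention ceiling).
    """
    from .assoc import bonferroni_threshold
    from .power import analytic_average_power

    if not (0.0 < target_power < 1.0):
        raise ValueError("target_power must be in (0,1)")
    n_cases, n_controls = design
    if threshold is None:
        threshold = bonferroni_threshold(config.alpha, config.n_total)

    def gap(or_het: float) -> float:
        cfg = config.with_effect(or_het=or_het, or_hom=None)
        return analytic_average_power(cfg, design, threshold) - target_power

    lo = 1.0 + 1e-9
    hi = 2.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 512.0:
            raise InfeasibleTargetError(
                f"target power {target_power} is above the achievable ceiling for design "
                f"({n_cases}, {n_controls}) at threshold {threshold}"
            )
    return float(brentq(gap, lo, hi, xtol=tolerance))
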