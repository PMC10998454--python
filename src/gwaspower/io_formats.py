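"""Plain-text file formats: simulation-parameter files, counts tables,
PED/MAP exports, association tables and power summaries.

All writers are deterministic byte-for-byte for identical inputs.  Numeric
fields are serialised with at least six significant digits.  Coordinates are
synthetic placeholders (chromosome 1, base-pair position = SNP ordinal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, StructuralError
from .sim_model import SnpDataset, expand_to_individuals

__all__ = [
    "SimParamLine",
    "read_sim_params",
    "write_sim_params",
    "write_counts_table",
    "read_counts_table",
    "write_plink_dataset",
    "read_plink_dataset",
    "write_assoc_table",
    "read_assoc_table",
    "write_power_summary",
]

_FLOAT_FMT = "%.8g"


@dataclass(frozen=True)
class SimParamLine:
    """One SNP-set line of a simulation-parameter file (PLINK dialect):
    ``<count> <label> <freq_lo> <freq_hi> <or_het> <or_hom|mult>``."""

    count: int
    label: str
    freq_lo: float
    freq_hi: float
    or_het: float
    or_hom: float | None  # None = "mult" sentinel (or_het**2 at model-build time)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not (0.0 <= self.freq_lo <= self.freq_hi <= 1.0):
            raise ValueError("require 0 <= freq_lo <= freq_hi <= 1")

    @property
    def resolved_or_hom(self) -> float:
        return self.or_het ** 2 if self.or_hom is None else self.or_hom


def read_sim_params(path: str | Path) -> list[SimParamLine]:
    """Parse a whitespace-separated simulation-parameter file.

    ``#`` starts a comment; blank lines are skipped.  Errors carry the
    1-based line number.
    """
    lines: list[SimParamLine] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        fields = text.split()
        if len(fields) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
        try:
            count = int(fields[0])
            freq_lo, freq_hi, or_het = (float(fields[i]) for i in (2, 3, 4))
            or_hom = None if fields[5].lower() == "mult" else float(fields[5])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        try:
            lines.append(
                SimParamLine(
                    count=count, label=fields[1], freq_lo=freq_lo, freq_hi=freq_hi, or_het=or_het, or_hom=or_hom
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return lines


def write_sim_params(lines: list[SimParamLine], path: str | Path) -> None:
    """Write simulation-parameter lines; the ``mult`` sentinel is preserved literally."""
    out = []
    for line in lines:
        or_hom = "mult" if line.or_hom is None else _FLOAT_FMT % line.or_hom
        out.append(
            f"{line.count} {line.label} {_FLOAT_FMT % line.freq_lo} "
            f"{_FLOAT_FMT % line.freq_hi} {_FLOAT_FMT % line.or_het} {or_hom}"
        )
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Counts table (TSV): AA = hom-risk, BB = hom-ref, A is the risk allele.

_COUNTS_COLUMNS = [
    "SNP",
    "SET",
    "POP_FREQ",
    "CASE_AA",
    "CASE_AB",
    "CASE_BB",
    "CTRL_AA",
    "CTRL_AB",
    "CTRL_BB",
]


def write_counts_table(dataset: SnpDataset, path: str | Path) -> None:
    """Write per-SNP genotype counts as TSV (one row per SNP)."""
    frame = pd.DataFrame(
        {
            "SNP": dataset.snp_ids,
            "SET": dataset.truth,
            "POP_FREQ": dataset.pop_freq,
            "CASE_AA": dataset.case_counts[:, 2],
            "CASE_AB": dataset.case_counts[:, 1],
            "CASE_BB": dataset.case_counts[:, 0],
            "CTRL_AA": dataset.control_counts[:, 2],
            "CTRL_AB": dataset.control_counts[:, 1],
            "CTRL_BB": dataset.control_counts[:, 0],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_counts_table(path: str | Path) -> SnpDataset:
    """Read a counts TSV back into a :class:`SnpDataset`.

    Group sizes are recovered from the (necessarily constant) row sums.
    """
    try:
        # keep_default_na: the SET value "null" is a label, not a missing value
        frame = pd.read_csv(path, sep="\t", dtype={"SNP": str, "SET": str}, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: unreadable counts table ({exc})") from None
    missing = set(_COUNTS_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    numeric = [c for c in _COUNTS_COLUMNS if c not in ("SNP", "SET")]
    try:
        frame[numeric] = frame[numeric].apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric field ({exc})") from None
    if frame[numeric].isna().any().any():
        raise FormatError(f"{path}: missing numeric value")
    case = frame[["CASE_BB", "CASE_AB", "CASE_AA"]].to_numpy(dtype=np.int64)
    ctrl = frame[["CTRL_BB", "CTRL_AB", "CTRL_AA"]].to_numpy(dtype=np.int64)
    n_cases = _constant_row_sum(case, path, "case")
    n_controls = _constant_row_sum(ctrl, path, "control")
    bad_set = set(frame["SET"].unique()) - {"null", "disease"}
    if bad_set:
        raise FormatError(f"{path}: unknown SET values {sorted(bad_set)}")
    return SnpDataset(
        snp_ids=frame["SNP"].to_numpy(dtype=object),
        truth=frame["SET"].to_numpy(dtype=object),
        pop_freq=frame["POP_FREQ"].to_numpy(dtype=float),
        case_counts=case,
        control_counts=ctrl,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def _constant_row_sum(counts: np.ndarray, path: str | Path, group: str) -> int:
    sums = counts.sum(axis=1)
    if len(sums) == 0:
        return 0
    if not np.all(sums == sums[0]):
        raise StructuralError(f"{path}: inconsistent {group} group sizes across SNPs")
    return int(sums[0])


# ---------------------------------------------------------------------------
# PED/MAP export

_GENOTYPE_PAIRS = {0: "B B", 1: "A B", 2: "A A"}


def write_plink_dataset(dataset: SnpDataset, path_prefix: str | Path, seed: int = 0) -> None:
    """Write individual-level PED + MAP files for a count-level dataset.

    MAP rows are ``1 <snp_id> 0 <ordinal>``; PED rows carry family/individual
    IDs, zeroed parental/sex fields, phenotype 2 = case / 1 = control, and
    genotypes as allele pairs over the A (risk) / B coding.
    """
    prefix = Path(path_prefix)
    genotypes, phenotypes = expand_to_individuals(dataset, seed=seed)
    with open(f"{prefix}.map", "w") as handle:
        for bp, snp_id in enumerate(dataset.snp_ids, start=1):
            handle.write(f"1 {snp_id} 0 {bp}\n")
    with open(f"{prefix}.ped", "w") as handle:
        for i in range(genotypes.shape[0]):
            status = "case" if phenotypes[i] == 2 else "ctrl"
            idx = i + 1 if phenotypes[i] == 2 else i + 1 - dataset.n_cases
            ind = f"{status}_{idx}"
            fields = [ind, ind, "0", "0", "0", str(int(phenotypes[i]))]
            fields.extend(_GENOTYPE_PAIRS[g] for g in genotypes[i])
            handle.write(" ".join(fields) + "\n")


def read_plink_dataset(path_prefix: str | Path) -> SnpDataset:
    """Recount a PED/MAP pair into a :class:`SnpDataset`.

    Truth labels are recovered from the SNP-id prefix (ids starting with
    ``disease`` are disease SNPs); population frequencies are not stored in
    PED/MAP and come back as the pooled sample frequency.  The missing
    genotype code ``0 0`` is recognised but rejected: the count container
    requires complete genotypes.
    """
    prefix = Path(path_prefix)
    map_path, ped_path = Path(f"{prefix}.map"), Path(f"{prefix}.ped")
    snp_ids: list[str] = []
    for lineno, raw in enumerate(map_path.read_text().splitlines(), start=1):
        fields = raw.split()
        if len(fields) != 4:
            raise FormatError(f"{map_path}:{lineno}: expected 4 fields, got {len(fields)}")
        snp_ids.append(fields[1])
    n_snps = len(snp_ids)
    pair_to_code = {pair: code for code, pair in _GENOTYPE_PAIRS.items()}
    case_counts = np.zeros((n_snps, 3), dtype=np.int64)
    control_counts = np.zeros((n_snps, 3), dtype=np.int64)
    n_cases = n_controls = 0
    for lineno, raw in enumerate(ped_path.read_text().splitlines(), start=1):
        fields = raw.split()
        if len(fields) != 6 + 2 * n_snps:
            raise FormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(fields)}"
            )
        phenotype = fields[5]
        if phenotype not in ("1", "2"):
            raise FormatError(f"{ped_path}:{lineno}: phenotype must be 1 or 2, got {phenotype!r}")
        is_case = phenotype == "2"
        target = case_counts if is_case else control_counts
        if is_case:
            n_cases += 1
        else:
            n_controls += 1
        for j in range(n_snps):
            pair = f"{fields[6 + 2 * j]} {fields[7 + 2 * j]}"
            if pair == "0 0":
                raise FormatError(
                    f"{ped_path}:{lineno}: missing genotype ('0 0') at SNP {snp_ids[j]} "
                    "is not representable in the count container"
                )
            normalised = " ".join(sorted(pair.split(), reverse=False))
            # allele pairs are unordered; canonicalise "B A" -> "A B"
            if normalised not in pair_to_code:
                raise FormatError(f"{ped_path}:{lineno}: bad genotype {pair!r} at SNP {snp_ids[j]}")
            target[j, pair_to_code[normalised]] += 1
    totals = 2 * (case_counts + control_counts).sum(axis=1)
    a_counts = (
        2 * (case_counts[:, 2] + control_counts[:, 2]) + case_counts[:, 1] + control_counts[:, 1]
    )
    with np.errstate(invalid="ignore"):
        pooled_freq = np.where(totals > 0, a_counts / np.maximum(totals, 1), 0.0)
    truth = np.array(["disease" if s.startswith("disease") else "null" for s in snp_ids], dtype=object)
    return SnpDataset(
        snp_ids=np.array(snp_ids, dtype=object),
        truth=truth,
        pop_freq=pooled_freq,
        case_counts=case_counts,
        control_counts=control_counts,
        n_cases=n_cases,
        n_controls=n_controls,
    )


# ---------------------------------------------------------------------------
# Association table (PLINK .assoc dialect)

_ASSOC_COLUMNS = ["CHR", "SNP", "BP", "A1", "F_A", "F_U", "A2", "CHISQ", "P", "OR"]


def write_assoc_table(table, path: str | Path) -> None:
    """Write an :class:`~gwaspower.assoc.AssocTable` in the PLINK .assoc
    column layout (CHR/BP are synthetic placeholders, A1 = risk allele A)."""
    frame = table.frame
    out = pd.DataFrame(
        {
            "CHR": 1,
            "SNP": frame["snp_id"],
            "BP": np.arange(1, len(frame) + 1),
            "A1": "A",
            "F_A": frame["f_a"],
            "F_U": frame["f_u"],
            "A2": "B",
            "CHISQ": frame["chisq"],
            "P": frame["p_value"],
            "OR": frame["or_estimate"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def read_assoc_table(path: str | Path):
    """Read a PLINK-style .assoc TSV back into an ``AssocTable``.

    Parsing is header-keyed, so shuffled-but-complete column orders are
    accepted.  Truth labels are recovered from the SNP-id prefix; the applied
    significance threshold is not stored in the format and comes back as
    ``None`` (no ``significant`` flags are set).
    """
    from .assoc import AssocTable

    try:
        frame = pd.read_csv(path, sep=r"\s+", na_values=["NA"], keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable association table ({exc})") from None
    missing = set(_ASSOC_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("A1", "A2"):
        values = frame[col].astype(str)
        if not values.str.fullmatch(r"[A-Za-z0-9]").all():
            raise FormatError(f"{path}: bad allele code in column {col}")
    numeric = ["CHR", "BP", "F_A", "F_U", "CHISQ", "P", "OR"]
    try:
        frame[numeric] = frame[numeric].apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric field ({exc})") from None
    if frame[["F_A", "F_U", "CHISQ", "P"]].isna().any().any():
        raise FormatError(f"{path}: missing required numeric value")
    snp_ids = frame["SNP"].astype(str)
    # allele counts are not recoverable from this format without group sizes
    records = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "truth": [("disease" if s.startswith("disease") else "null") for s in snp_ids],
            "a_count_cases": -1,
            "a_count_controls": -1,
            "f_a": frame["F_A"],
            "f_u": frame["F_U"],
            "chisq": frame["CHISQ"],
            "p_value": frame["P"],
            "or_estimate": frame["OR"],
            "significant": False,
        }
    )
    return AssocTable(frame=records, n_generated=len(records), n_tested=len(records), threshold=None)


def write_power_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write the per-design power summary TSV:
    ``SCENARIO DESIGN N_CASES N_CONTROLS S M POWER N_SIG_NULL THRESHOLD LETTER``."""
    out = pd.DataFrame(
        {
            "SCENARIO": summary["scenario"],
            "DESIGN": summary["design"],
            "N_CASES": summary["n_cases"],
            "N_CONTROLS": summary["n_controls"],
            "S": summary["mean_detected"],
            "M": summary["m_total"],
            "POWER": summary["mean_power"].round(2),
            "N_SIG_NULL": summary["mean_sig_null"],
            "THRESHOLD": summary["threshold"],
            "LETTER": summary["letter"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
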