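"""Peptide-level HDX-MS bookkeeping.

Deuterium uptake, back-exchange estimation and correction, fractional
uptake, cross-run z-normalization and sequence coverage for peptide-level
hydrogen-deuterium exchange mass spectrometry.

Conventions
-----------
* Residue numbering is 1-based and ranges are inclusive.
* Exchangeable backbone amides exclude prolines (no amide hydrogen) and,
  by default, the peptide's first residue, whose deuterium is lost to
  fast back exchange during quench/LC.  A two-residue N-terminal
  exclusion (common in other software) is available via
  ``n_term_excluded=2``.
* Uptake values are in daltons (Da); exposures in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "PeptideRecord",
    "UptakeMeasurement",
    "BackExchangeRecord",
    "NormalizationResult",
    "exchangeable_nh",
    "compute_uptake",
    "back_exchange_rate",
    "correct_back_exchange",
    "fractional_hdx",
    "normalize_hdx",
    "compute_coverage",
    "read_state_table",
    "write_state_table",
    "STATE_TABLE_COLUMNS",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: required columns of the peptide state table (CSV, UTF-8, header required)
STATE_TABLE_COLUMNS = [
    "protein",
    "sequence",
    "start",
    "end",
    "state",
    "exposure_s",
    "replicate",
    "uptake_da",
]


def exchangeable_nh(sequence: str, n_term_excluded: int = 1) -> int:
    """Number of backbone amide hydrogens that can retain deuterium.

    ``length - n_term_excluded - (# Pro beyond the excluded N-terminus)``.
    Prolines carry no amide hydrogen; the first residue (or two) exchanges
    back too fast to be measured.

    Raises
    ------
    ValueError
        if the sequence is empty or contains a non-standard character
        (the position of the offending character is reported).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise ValueError(
                f"non-amino-acid character {aa!r} at position {pos} in {sequence!r}"
            )
    if n_term_excluded < 1:
        raise ValueError("n_term_excluded must be >= 1")
    tail = sequence[n_term_excluded:]
    return max(len(sequence) - n_term_excluded - tail.count("P"), 0)


@dataclass(frozen=True)
class PeptideRecord:
    """One proteolytic peptide: sequence, residue span, exchangeable amides."""

    sequence: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    n_term_excluded: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}-{self.end} does not match sequence "
                f"length {len(self.sequence)} for {self.sequence!r}"
            )
        exchangeable_nh(self.sequence, self.n_term_excluded)  # validates

    @property
    def exchangeable_nh(self) -> int:
        return exchangeable_nh(self.sequence, self.n_term_excluded)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def label(self) -> str:
        return f"{self.start}-{self.end}"

    def observed_residues(self) -> list[int]:
        """Residue indices whose exchange this peptide actually reports:
        the span minus the excluded N-terminal residue(s) and prolines."""
        out = []
        for offset, aa in enumerate(self.sequence):
            if offset < self.n_term_excluded or aa == "P":
                continue
            out.append(self.start + offset)
        return out


@dataclass
class UptakeMeasurement:
    """One (peptide, state, exposure, replicate) deuterium uptake in Da."""

    peptide: PeptideRecord
    state: str
    exposure_s: float
    replicate: int
    uptake_da: float
    corrected_uptake_da: float | None = None
    clamped: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise ValueError(f"exposure must be > 0 s, got {self.exposure_s}")
        if self.uptake_da < 0:
            warnings.warn(
                f"negative uptake {self.uptake_da:.3f} Da for peptide "
                f"{self.peptide.label()} clamped to 0",
                stacklevel=2,
            )
            self.uptake_da = 0.0
            self.clamped = True


@dataclass(frozen=True)
class BackExchangeRecord:
    """Back-exchange fraction of a peptide from a maximally deuterated control."""

    peptide: PeptideRecord
    fully_deuterated_uptake_da: float
    be_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.be_fraction < 1.0):
            raise ValueError(f"be_fraction {self.be_fraction} outside [0, 1)")


def compute_uptake(envelope_t, envelope_ref) -> float:
    """Deuterium uptake as the neutral-centroid difference of two envelopes.

    Both envelopes must come from the same peptide at the same charge;
    ``envelope_ref`` is the undeuterated (or reference-time) spectrum.
    Returns Da.
    """
    from .envelope import centroid_mass  # local import to avoid cycle

    if envelope_t.charge != envelope_ref.charge:
        raise ValueError(
            f"charge mismatch: {envelope_t.charge} vs {envelope_ref.charge}"
        )
    return centroid_mass(envelope_t) - centroid_mass(envelope_ref)


def back_exchange_rate(full_deut: UptakeMeasurement) -> BackExchangeRecord:
    """Back-exchange fraction ``1 - uptake / exchangeable_nh`` from a
    maximally labeled control (typically >= 4 h in deuterated buffer).

    Uptake above the exchangeable-amide count (possible within noise) is
    clamped to a back-exchange fraction of 0 with a warning.
    """
    nh = full_deut.peptide.exchangeable_nh
    if nh == 0:
        raise ValueError(
            f"peptide {full_deut.peptide.label()} has no exchangeable amides"
        )
    be = 1.0 - full_deut.uptake_da / nh
    if be < 0.0:
        warnings.warn(
            f"fully deuterated uptake {full_deut.uptake_da:.3f} Da exceeds "
            f"exchangeable amides ({nh}) for {full_deut.peptide.label()}; "
            "back-exchange fraction clamped to 0",
            stacklevel=2,
        )
        be = 0.0
    return BackExchangeRecord(full_deut.peptide, full_deut.uptake_da, be)


def correct_back_exchange(
    m: UptakeMeasurement, be: BackExchangeRecord
) -> float:
    """Back-exchange-corrected uptake: observed / (1 - BE fraction).

    The corrected value is capped at the exchangeable-amide count with a
    warning.  Used for absolute-uptake displays only; differential
    free-vs-bound comparisons use uncorrected uptake, since the same
    back-exchange multiplies both states.
    """
    if be.peptide.span != m.peptide.span or be.peptide.sequence != m.peptide.sequence:
        raise ValueError(
            f"back-exchange record for {be.peptide.label()} applied to "
            f"measurement of {m.peptide.label()}"
        )
    corrected = m.uptake_da / (1.0 - be.be_fraction)
    nh = m.peptide.exchangeable_nh
    if corrected > nh:
        warnings.warn(
            f"corrected uptake {corrected:.3f} Da exceeds exchangeable amides "
            f"({nh}) for {m.peptide.label()}; capped",
            stacklevel=2,
        )
        corrected = float(nh)
    m.corrected_uptake_da = corrected
    return corrected


def fractional_hdx(m: UptakeMeasurement, corrected: bool = False) -> float:
    """Fractional uptake in percent: 100 x uptake / exchangeable amides."""
    nh = m.peptide.exchangeable_nh
    if nh == 0:
        raise ValueError(f"peptide {m.peptide.label()} has no exchangeable amides")
    uptake = m.corrected_uptake_da if corrected else m.uptake_da
    if corrected and m.corrected_uptake_da is None:
        raise ValueError("no corrected uptake available; run correct_back_exchange")
    return 100.0 * uptake / nh


@dataclass(frozen=True)
class NormalizationResult:
    """Per-group z-normalization of observed uptake.

    ``groups`` holds one row per group with ``mu`` (Da) and ``sigma`` (Da);
    ``z`` is a Series aligned with the input rows.
    """

    group_cols: tuple[str, ...]
    groups: pd.DataFrame
    z: pd.Series


def normalize_hdx(
    table: pd.DataFrame,
    group_cols: Sequence[str] = ("state", "exposure_s"),
    value_col: str = "uptake_da",
) -> NormalizationResult:
    """Z-score uptake within groups (default: one group per run/exposure).

    Compensates day-to-day variation between HDX runs so that uptake of
    the same peptide can be compared semi-quantitatively across runs.
    Each group needs >= 2 distinct uptake values; a zero-variance group is
    an error (z-scores would be undefined).
    """
    group_cols = tuple(group_cols)
    missing = [c for c in (*group_cols, value_col) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    grouped = table.groupby(list(group_cols), sort=True)[value_col]
    stats = grouped.agg(mu="mean", sigma="std", n="size").reset_index()
    bad = stats[(stats["n"] < 2) | (stats["sigma"] == 0) | stats["sigma"].isna()]
    if len(bad):
        keys = bad[list(group_cols)].to_records(index=False).tolist()
        raise ValueError(
            f"groups with <2 values or zero variance cannot be normalized: {keys}"
        )
    z = grouped.transform(lambda v: (v - v.mean()) / v.std(ddof=1))
    z.name = "normalized_hdx"
    return NormalizationResult(group_cols, stats, z)


def compute_coverage(
    peptides: Iterable[PeptideRecord], protein_length: int
) -> float:
    """Percent of residues covered by at least one peptide."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    covered: set[int] = set()
    for p in peptides:
        if p.start < 1 or p.end > protein_length:
            raise ValueError(
                f"peptide {p.label()} outside protein 1-{protein_length}"
            )
        covered.update(range(p.start, p.end + 1))
    return 100.0 * len(covered) / protein_length


def read_state_table(path) -> pd.DataFrame:
    """Read a peptide-level state table (CSV, UTF-8, header required).

    Columns: protein, sequence, start, end, state, exposure_s, replicate,
    uptake_da (``centroid_mass_da`` accepted as an alias carrying centroid
    masses, renamed on read).  Schema violations are reported with row
    numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "centroid_mass_da" in cols and "uptake_da" not in cols:
        df = df.rename(columns={"centroid_mass_da": "uptake_da"})
    missing = [c for c in STATE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"state table {path} missing columns {missing}")
    bad_rows = df.index[df["exposure_s"] <= 0].tolist()
    if bad_rows:
        raise ValueError(
            f"state table {path}: non-positive exposure_s in rows "
            f"{[i + 1 for i in bad_rows]}"
        )
    bad_rows = df.index[df["end"] - df["start"] + 1 != df["sequence"].str.len()]
    if len(bad_rows):
        raise ValueError(
            f"state table {path}: span/sequence length mismatch in rows "
            f"{[i + 1 for i in bad_rows]}"
        )
    return df


def write_state_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in STATE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"state table missing columns {missing}")
    df.to_csv(path, index=False, float_format="%.6f")
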