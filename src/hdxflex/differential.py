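"""Differential HDX between states.

Per-peptide uptake differences (ΔHDX = mean bound − mean free), one-tailed
pooled-variance significance tests, a global replicate-derived confidence
threshold (Houde-style average CI half-width), protection/deprotection
calls over the exposure ladder, summed fractional differences for
structure mapping, and peptide-to-residue consolidation.

Sign convention: negative ΔHDX is protection (slower exchange in the
bound state), positive is deprotection.  A difference is significant only
when both the p-value clears ``alpha`` and its magnitude exceeds the
global threshold; the two rules are applied jointly, with no
multiple-testing correction by default (Benjamini–Hochberg available
behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hdx import PeptideRecord, UptakeMeasurement

__all__ = [
    "DeltaRecord",
    "SignificanceConfig",
    "one_tailed_ttest",
    "delta_hdx",
    "global_confidence_threshold",
    "classify_protection",
    "summed_fractional_difference",
    "residue_consolidate",
    "delta_table",
    "benjamini_hochberg",
]

PROTECTION = "Protection"
DEPROTECTION = "Deprotection"
MIXED = "Mixed"
ND = "ND"


@dataclass
class SignificanceConfig:
    """Significance rules for differential calls.

    ``alpha`` defaults to 0.05 for free-vs-bound comparisons (use 0.01
    for free-state mutant-vs-WT comparisons); ``threshold_da`` is the
    global confidence threshold in Da, normally computed from replicate
    scatter, with 0.3 Da as the fallback when no replicate information
    exists.
    """

    alpha: float = 0.05
    threshold_da: float | None = None
    fallback_threshold_da: float = 0.3
    two_tailed: bool = False
    fdr: bool = False  # optional Benjamini-Hochberg across peptides

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.threshold_da is not None and self.threshold_da < 0:
            raise ValueError("threshold_da must be >= 0")


@dataclass
class DeltaRecord:
    """ΔHDX of one peptide at one exposure."""

    peptide: PeptideRecord
    exposure_s: float
    delta_da: float  # mean(bound) - mean(free)
    sd_free: float
    sd_bound: float
    n_free: int
    n_bound: int
    p_value: float
    significant: bool = False
    flag: str = ""

    @property
    def protected(self) -> bool:
        return self.delta_da < 0


def one_tailed_ttest(
    a: Sequence[float],
    b: Sequence[float],
    direction: str = "b>a",
) -> tuple[float, str]:
    """Two-sample pooled-variance Student's t, one-tailed.

    ``direction`` is ``"b>a"`` or ``"b<a"`` (the alternative hypothesis);
    ``df = n_a + n_b - 2``.  Returns ``(p, flag)``; degenerate
    zero-variance inputs are flagged: p = 0.5 when the means are equal
    too, p -> 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 replicates per state, got {len(a)} and {len(b)}")
    if direction not in ("b>a", "b<a"):
        raise ValueError(f"direction must be 'b>a' or 'b<a', got {direction!r}")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.5, "zero-variance-equal-means"
        observed = (b.mean() > a.mean()) if direction == "b>a" else (b.mean() < a.mean())
        return (0.0 if observed else 1.0), "zero-variance-unequal-means"
    alternative = "greater" if direction == "b>a" else "less"
    res = stats.ttest_ind(b, a, equal_var=True, alternative=alternative)
    return float(res.pvalue), ""


def delta_hdx(
    free: Sequence[UptakeMeasurement],
    bound: Sequence[UptakeMeasurement],
    config: SignificanceConfig | None = None,
    direction: str = "auto",
) -> DeltaRecord:
    """ΔHDX record for one (peptide, exposure): mean(bound) − mean(free).

    ``direction`` chooses the one-tailed alternative: ``"protection"``
    tests bound < free, ``"deprotection"`` tests bound > free, ``"auto"``
    tests in the direction of the observed difference, and
    ``"two-sided"`` doubles the one-tailed p (capped at 1).  Significance
    requires both p < alpha and |Δ| above the global threshold when a
    config with a threshold is supplied.
    """
    free = list(free)
    bound = list(bound)
    if not free or not bound:
        raise ValueError("need measurements in both states")
    pep = free[0].peptide
    exp = free[0].exposure_s
    for m in (*free, *bound):
        if m.peptide.span != pep.span or m.peptide.sequence != pep.sequence:
            raise ValueError(
                f"mixed peptides: {m.peptide.label()} vs {pep.label()}"
            )
        if m.exposure_s != exp:
            raise ValueError(f"mixed exposures: {m.exposure_s} vs {exp}")
    if len(free) < 2 or len(bound) < 2:
        raise ValueError("need n >= 2 replicates in each state")

    uf = np.array([m.uptake_da for m in free])
    ub = np.array([m.uptake_da for m in bound])
    delta = float(ub.mean() - uf.mean())

    if direction == "auto":
        dir_flag = "b<a" if delta < 0 else "b>a"
        p, flag = one_tailed_ttest(uf, ub, dir_flag)
    elif direction == "protection":
        p, flag = one_tailed_ttest(uf, ub, "b<a")
    elif direction == "deprotection":
        p, flag = one_tailed_ttest(uf, ub, "b>a")
    elif direction == "two-sided":
        p, flag = one_tailed_ttest(uf, ub, "b<a" if delta < 0 else "b>a")
        p = min(2 * p, 1.0)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    rec = DeltaRecord(
        peptide=pep,
        exposure_s=exp,
        delta_da=delta,
        sd_free=float(uf.std(ddof=1)),
        sd_bound=float(ub.std(ddof=1)),
        n_free=len(uf),
        n_bound=len(ub),
        p_value=p,
        flag=flag,
    )
    if config is not None:
        threshold = (
            config.threshold_da
            if config.threshold_da is not None
            else config.fallback_threshold_da
        )
        rec.significant = (p < config.alpha) and (abs(delta) > threshold)
    return rec


def global_confidence_threshold(
    deltas: Iterable[DeltaRecord],
    alpha: float = 0.05,
    fallback: float = 0.3,
) -> float:
    """Global significance threshold in Da: the Student-t critical value
    at the pooled degrees of freedom times the average standard error of
    the per-peptide uptake difference,

        t_{1-alpha, df} x mean_p sqrt(sd_free^2/n_free + sd_bound^2/n_bound).

    With triplicates at 0.15 Da replicate SD this gives ~0.26 Da, the
    usual "ca. 0.3 Da" scale of peptide-level HDX-MS.  Records without
    replicate scatter information contribute nothing; with no usable
    records at all the configured fallback is returned with a warning.
    """
    ses, dfs = [], []
    for rec in deltas:
        if rec.n_free < 2 or rec.n_bound < 2:
            continue
        ses.append(np.sqrt(rec.sd_free**2 / rec.n_free + rec.sd_bound**2 / rec.n_bound))
        dfs.append(rec.n_free + rec.n_bound - 2)
    if not ses:
        warnings.warn(
            f"no replicate information; falling back to {fallback} Da threshold",
            stacklevel=2,
        )
        return fallback
    df = float(np.mean(dfs))
    return float(stats.t.ppf(1.0 - alpha, df) * np.mean(ses))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def classify_protection(
    deltas: Sequence[DeltaRecord], config: SignificanceConfig
) -> tuple[str, str]:
    """Table-style protection call over a peptide's exposures.

    ``Protection`` if any exposure shows a significant negative Δ,
    ``Deprotection`` if any shows a significant positive Δ, ``Mixed``
    (with a flag listing both) when both occur, else ``ND``.  Returns
    ``(label, flag)``.
    """
    if not deltas:
        raise ValueError("need deltas at >= 1 exposure")
    threshold = (
        config.threshold_da
        if config.threshold_da is not None
        else config.fallback_threshold_da
    )
    prot, deprot = [], []
    for rec in deltas:
        sig = (rec.p_value < config.alpha) and (abs(rec.delta_da) > threshold)
        if sig and rec.delta_da < 0:
            prot.append(rec.exposure_s)
        elif sig and rec.delta_da > 0:
            deprot.append(rec.exposure_s)
    if prot and deprot:
        return MIXED, (
            f"protection at exposures {prot} but deprotection at {deprot}"
        )
    if prot:
        return PROTECTION, ""
    if deprot:
        return DEPROTECTION, ""
    return ND, ""


def summed_fractional_difference(
    deltas: Sequence[DeltaRecord], exposures: Sequence[float]
) -> float:
    """Summed fractional ΔHDX in percent over selected exposures:
    Σ_t 100 x Δ(t) / exchangeable_nh (e.g. the 1-min + 10-min sum used
    for structure maps)."""
    by_exp = {rec.exposure_s: rec for rec in deltas}
    missing = [t for t in exposures if t not in by_exp]
    if missing:
        raise ValueError(f"missing exposures: {missing}")
    pep = deltas[0].peptide
    nh = pep.exchangeable_nh
    if nh == 0:
        raise ValueError(f"peptide {pep.label()} has no exchangeable amides")
    return float(sum(100.0 * by_exp[t].delta_da / nh for t in exposures))


def residue_consolidate(
    peptide_values: Sequence[tuple[PeptideRecord, float]],
    protein_length: int,
) -> pd.Series:
    """Average per-peptide values onto residues for structure mapping.

    Each residue a peptide actually reports on (its span minus the
    excluded N-terminal residue(s) and prolines) receives the mean over
    all covering peptides; residues with no data are NaN.
    """
    sums = np.zeros(protein_length + 1)
    counts = np.zeros(protein_length + 1)
    for pep, value in peptide_values:
        for resid in pep.observed_residues():
            if 1 <= resid <= protein_length:
                sums[resid] += value
                counts[resid] += 1
    with np.errstate(invalid="ignore"):
        vals = np.where(counts[1:] > 0, sums[1:] / np.maximum(counts[1:], 1), np.nan)
    return pd.Series(vals, index=pd.RangeIndex(1, protein_length + 1, name="resid"))


def delta_table(deltas: Sequence[DeltaRecord]) -> pd.DataFrame:
    """Tidy (Woods-plot-ready) DataFrame of delta records."""
    return pd.DataFrame(
        {
            "sequence": [r.peptide.sequence for r in deltas],
            "start": [r.peptide.start for r in deltas],
            "end": [r.peptide.end for r in deltas],
            "exposure_s": [r.exposure_s for r in deltas],
            "delta_da": [r.delta_da for r in deltas],
            "sd_free": [r.sd_free for r in deltas],
            "sd_bound": [r.sd_bound for r in deltas],
            "n_free": [r.n_free for r in deltas],
            "n_bound": [r.n_bound for r in deltas],
            "p_value": [r.p_value for r in deltas],
            "significant": [r.significant for r in deltas],
            "flag": [r.flag for r in deltas],
        }
    )
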