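"""Isotope-envelope modelling for HDX-MS.

Centroiding, theoretical envelopes (natural isotope pattern convolved
with a deuteration distribution), unimodal/bimodal mixture fitting and
EX1/EX2 classification of envelope time courses.

Model
-----
A peptide's natural isotope pattern is computed from its exact elemental
composition; deuteration adds a continuous mass shift ``d`` (mean number
of retained deuterons) broadened by a Gaussian of width ``w`` (Da).  A
bimodal spectrum is a two-component mixture of such profiles sharing one
width, the signature of EX1 kinetics where a slow-exchanging (folded) and
a fast-exchanging (open) population coexist.  Model selection between the
one- and two-component fits uses small-sample corrected AIC with a
two-unit margin before the bimodal model is preferred.

Isotope peaks and deuteron shifts are placed on a uniform 1.0 Da grid;
uptake bookkeeping in Da is then exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pyteomics import mass as pmass
from scipy.optimize import least_squares

from .hdx import PeptideRecord, exchangeable_nh

__all__ = [
    "PROTON_MASS",
    "IsotopeEnvelope",
    "BimodalFit",
    "centroid_mz",
    "centroid_mass",
    "natural_isotope_pattern",
    "theoretical_envelope",
    "component_profile",
    "fit_bimodal",
    "classify_ex1_ex2",
    "read_envelope",
    "write_envelope",
]

PROTON_MASS = 1.007276466  # Da

# (mass-offset, abundance) per extra neutron, IUPAC 2013 representative values
_ISOTOPES = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0],
}


@dataclass
class IsotopeEnvelope:
    """One peptide/charge/exposure isotope envelope (m/z, intensity pairs)."""

    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    peptide: PeptideRecord | None = None
    exposure_s: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.mz) < 0):
            raise ValueError("peaks must be sorted by m/z")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if self.intensity.sum() <= 0:
            raise ValueError("zero total intensity")

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    def neutral_masses(self) -> np.ndarray:
        return self.charge * (self.mz - PROTON_MASS)


def centroid_mz(env: IsotopeEnvelope) -> float:
    """Intensity-weighted mean m/z."""
    return float(np.average(env.mz, weights=env.intensity))


def centroid_mass(env: IsotopeEnvelope) -> float:
    """Intensity-weighted centroid as a neutral mass (Da):
    ``charge x (mean m/z - proton mass)``."""
    return env.charge * (centroid_mz(env) - PROTON_MASS)


def _poly_power(p: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution of a probability vector (exponentiation by
    squaring; O(log n) convolutions)."""
    result = np.array([1.0])
    base = p.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def natural_isotope_pattern(
    sequence: str, threshold: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Natural isotope distribution of a peptide.

    Returns ``(monoisotopic_mass, probs)`` where ``probs[j]`` is the
    abundance of the isotopologue carrying ``j`` extra neutrons, truncated
    once the tail falls below ``threshold`` and renormalized to sum 1.
    The elemental composition is exact (from the sequence), not an
    averagine estimate.
    """
    comp = pmass.Composition(sequence=sequence)
    mono = pmass.calculate_mass(composition=comp)
    dist = np.array([1.0])
    for elem, counts in comp.items():
        if elem not in _ISOTOPES:
            continue
        dist = np.convolve(dist, _poly_power(np.array(_ISOTOPES[elem]), counts))
    # truncate negligible tail
    keep = np.nonzero(dist > threshold)[0]
    dist = dist[: keep[-1] + 1] if len(keep) else dist[:1]
    return float(mono), dist / dist.sum()


def _deuteration_kernel(x: np.ndarray, d: float, width: float) -> np.ndarray:
    """Deuteration profile evaluated at mass offsets ``x`` (Da): Gaussian
    of mean ``d`` and sd ``width``; degenerate width gives linear
    interpolation between the two neighbouring integer offsets, keeping
    the mean exactly ``d``."""
    if width <= 1e-9:
        lo = np.floor(d)
        w_hi = d - lo
        out = np.zeros_like(x, dtype=float)
        out[np.isclose(x, lo)] = 1.0 - w_hi
        out[np.isclose(x, lo + 1.0)] += w_hi
        return out
    return np.exp(-0.5 * ((x - d) / width) ** 2)


def component_profile(
    offsets: np.ndarray, natural: np.ndarray, d: float, width: float
) -> np.ndarray:
    """Intensity of one deuterated population at integer-spaced mass
    offsets: natural pattern convolved with the deuteration kernel."""
    offsets = np.asarray(offsets, dtype=float)
    out = np.zeros_like(offsets)
    for k, p_k in enumerate(natural):
        out += p_k * _deuteration_kernel(offsets - k, d, width)
    return out


def theoretical_envelope(
    sequence: str,
    n_deuterons_mean: float,
    width: float = 1.0,
    n_grid: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted envelope of a peptide carrying ``n_deuterons_mean``
    deuterons on average.

    Returns ``(neutral_masses, intensities)`` on a 1.0 Da grid starting at
    the monoisotopic mass, normalized to sum 1.  The centroid sits at the
    natural centroid plus ``n_deuterons_mean``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    mono, natural = natural_isotope_pattern(sequence)
    # the grid extends below the monoisotopic mass so the symmetric
    # broadening kernel is never truncated (those bins carry ~0 intensity)
    lo = min(0, int(np.floor(n_deuterons_mean - 6 * width)))
    if n_grid is None:
        n_grid = len(natural) + int(np.ceil(n_deuterons_mean + 6 * width)) + 2 - lo
    offsets = np.arange(lo, lo + n_grid, dtype=float)
    intens = component_profile(offsets, natural, n_deuterons_mean, width)
    total = intens.sum()
    if total <= 0:
        raise ValueError("degenerate envelope (no intensity on grid)")
    return mono + offsets, intens / total


@dataclass
class BimodalFit:
    """Result of unimodal-vs-bimodal mixture fitting for one envelope.

    ``centroids`` are neutral component centroid masses (light first);
    ``fraction_heavy`` is the heavier component's intensity fraction
    (0 when the unimodal model is preferred); ``preferred`` is True when
    the two-component model wins the corrected-AIC comparison.
    """

    n_components: int
    centroids: tuple[float, ...]
    widths: tuple[float, ...]
    fraction_heavy: float
    rss: float
    preferred: bool
    aicc_1: float
    aicc_2: float
    converged: bool = True
    shifts: tuple[float, ...] = field(default=())  # deuteron shifts, Da
    exposure_s: float | None = None

    @property
    def mixture_centroid(self) -> float:
        if self.n_components == 1:
            return self.centroids[0]
        f = self.fraction_heavy
        return (1 - f) * self.centroids[0] + f * self.centroids[1]


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return aic


def fit_bimodal(
    env: IsotopeEnvelope,
    sequence: str | None = None,
    max_shift: float | None = None,
    n_restarts: int = 3,
    min_separation_widths: float = 3.0,
    min_fraction: float = 0.10,
) -> BimodalFit:
    """Fit one- and two-component deuterated-envelope mixtures and pick a
    model by corrected AIC (two-unit margin before bimodal is preferred).

    The two components share one width, which suppresses the degeneracy
    of nearly-overlapping modes.  Fits are bounded (shifts within
    ``[0, max_shift]``, default the peptide's exchangeable-amide count)
    and restarted ``n_restarts`` times from jittered initial values; the
    jitter stream is fixed, so the fit is deterministic.

    A two-component winner is only reported as bimodal when the modes are
    actually resolvable: component separation at least
    ``min_separation_widths`` times the shared width and minor-component
    fraction at least ``min_fraction`` (populations closer than a few
    peak widths, or below ~10% abundance, cannot be distinguished from
    envelope noise at typical signal-to-noise); otherwise the unimodal
    fit is returned.

    Non-convergence is reported on the returned fit (``converged=False``),
    never silently replaced by a fallback.
    """
    if sequence is None:
        if env.peptide is None:
            raise ValueError("provide sequence= or attach a peptide to the envelope")
        sequence = env.peptide.sequence
    if env.n_peaks < 3:
        raise ValueError("need >= 3 peaks to fit a single-component model")

    mono, natural = natural_isotope_pattern(sequence)
    offsets = env.neutral_masses() - mono
    y = env.intensity / env.intensity.max()
    if max_shift is None:
        max_shift = float(exchangeable_nh(sequence)) if set(sequence) <= set(
            "ACDEFGHIKLMNPQRSTVWY"
        ) else float(offsets.max())
        max_shift = max(max_shift, 1.0)

    nat_centroid = float(np.dot(np.arange(len(natural)), natural))
    obs_centroid = float(np.average(offsets, weights=y)) - nat_centroid

    def scaled_residual(model: np.ndarray) -> tuple[np.ndarray, float]:
        denom = float(model @ model)
        scale = float(model @ y) / denom if denom > 0 else 0.0
        return y - scale * model, scale

    # --- one-component model: params (d, width)
    def resid1(p):
        return scaled_residual(component_profile(offsets, natural, p[0], p[1]))[0]

    w_lo, w_hi = 0.3, 6.0
    d0 = min(max(obs_centroid, 0.0), max_shift)
    best1 = None
    rng = np.random.default_rng(0)
    for r in range(n_restarts):
        jitter = 0.0 if r == 0 else rng.normal(0, 0.5)
        x0 = [np.clip(d0 + jitter, 0, max_shift), 1.0]
        sol = least_squares(
            resid1, x0, bounds=([0.0, w_lo], [max_shift, w_hi]), method="trf"
        )
        if best1 is None or sol.cost < best1.cost:
            best1 = sol
    rss1 = float(2 * best1.cost)
    aicc1 = _aicc(rss1, env.n_peaks, 3)  # d, width, scale

    # --- two-component model: params (d_a, d_b, frac_b, width); both shifts
    # bounded by the exchangeable-amide count, components sorted afterwards
    def resid2(p):
        da, db, f, w = p
        model = (1 - f) * component_profile(offsets, natural, da, w) + (
            f
        ) * component_profile(offsets, natural, db, w)
        return scaled_residual(model)[0]

    can_fit_2 = env.n_peaks >= 6
    best2 = None
    if can_fit_2:
        # quantile-split initialization at the intensity-weighted median
        order = np.argsort(offsets)
        csum = np.cumsum(y[order]) / y.sum()
        med_idx = np.searchsorted(csum, 0.5)
        lo_mask = np.arange(len(offsets)) <= med_idx
        lo_sel, hi_sel = order[lo_mask], order[~lo_mask]
        if len(hi_sel) == 0 or len(lo_sel) == 0:
            d_lo, d_hi = d0, min(d0 + 2.0, max_shift)
        else:
            d_lo = float(np.average(offsets[lo_sel], weights=y[lo_sel])) - nat_centroid
            d_hi = float(np.average(offsets[hi_sel], weights=y[hi_sel])) - nat_centroid
        d_lo = float(np.clip(d_lo, 0, max_shift))
        d_hi = float(np.clip(d_hi, 0, max_shift))
        for r in range(n_restarts):
            if r == 0:
                x0 = [d_lo, d_hi, 0.5, 1.0]
            else:
                x0 = [
                    np.clip(d_lo + rng.normal(0, 0.5), 0, max_shift),
                    np.clip(d_hi + rng.normal(0, 1.0), 0, max_shift),
                    np.clip(0.5 + rng.normal(0, 0.2), 0.02, 0.98),
                    1.0,
                ]
            sol = least_squares(
                resid2,
                x0,
                bounds=([0.0, 0.0, 0.0, w_lo], [max_shift, max_shift, 1.0, w_hi]),
                method="trf",
            )
            if best2 is None or sol.cost < best2.cost:
                best2 = sol
    rss2 = float(2 * best2.cost) if best2 is not None else np.inf
    aicc2 = _aicc(rss2, env.n_peaks, 5) if best2 is not None else np.inf

    prefer_2 = can_fit_2 and (aicc2 < aicc1 - 2.0)
    if prefer_2:
        da, db, f, w = best2.x
        resolvable = (abs(db - da) >= min_separation_widths * w) and (
            min_fraction <= f <= 1.0 - min_fraction
        )
        prefer_2 = prefer_2 and resolvable
    converged = bool(best1.success and (best2 is None or best2.success))

    nat_c = mono + nat_centroid
    if prefer_2:
        da, db, f, w = best2.x
        if da > db:  # sort so the light component comes first
            da, db, f = db, da, 1.0 - f
        return BimodalFit(
            n_components=2,
            centroids=(nat_c + da, nat_c + db),
            widths=(float(w), float(w)),
            fraction_heavy=float(f),
            rss=rss2,
            preferred=True,
            aicc_1=aicc1,
            aicc_2=aicc2,
            converged=converged,
            shifts=(float(da), float(db)),
            exposure_s=env.exposure_s,
        )
    d, w = best1.x
    return BimodalFit(
        n_components=1,
        centroids=(nat_c + d,),
        widths=(float(w),),
        fraction_heavy=0.0,
        rss=rss1,
        preferred=False,
        aicc_1=aicc1,
        aicc_2=aicc2,
        converged=converged,
        shifts=(float(d),),
        exposure_s=env.exposure_s,
    )


def classify_ex1_ex2(
    fits: Sequence[BimodalFit],
    exposures: Sequence[float] | None = None,
    centroid_drift_da: float = 0.5,
    min_centroid_rise_da: float = 0.1,
    fraction_tolerance: float = 0.05,
) -> str:
    """Classify an envelope time course as ``"EX1"``, ``"EX2"`` or
    ``"ambiguous"``.

    EX1: bimodal preferred at >= 2 exposures, each component centroid
    stable over time (drift < ``centroid_drift_da``), heavy fraction
    monotone nondecreasing (within ``fraction_tolerance``).  EX2: unimodal
    throughout with a centroid that rises by at least
    ``min_centroid_rise_da`` overall.  Anything else — including a flat,
    fully exchanged series — is ambiguous.
    """
    if len(fits) < 3:
        raise ValueError("need fits at >= 3 exposures to classify kinetics")
    if exposures is None:
        exposures = [f.exposure_s for f in fits]
        if any(e is None for e in exposures):
            raise ValueError("exposures not given and not attached to fits")
    order = np.argsort(np.asarray(exposures, dtype=float))
    fits = [fits[i] for i in order]

    bimodal = [f for f in fits if f.preferred and f.n_components == 2]
    if len(bimodal) >= 2:
        light = np.array([f.centroids[0] for f in bimodal])
        heavy = np.array([f.centroids[1] for f in bimodal])
        fracs = np.array([f.fraction_heavy for f in bimodal])
        stable = (np.ptp(light) < centroid_drift_da) and (
            np.ptp(heavy) < centroid_drift_da
        )
        monotone = bool(np.all(np.diff(fracs) >= -fraction_tolerance))
        if stable and monotone:
            return "EX1"
        return "ambiguous"

    if all(f.n_components == 1 for f in fits):
        centroids = np.array([f.centroids[0] for f in fits])
        rising = bool(
            np.all(np.diff(centroids) >= -0.05)
            and (centroids[-1] - centroids[0]) >= min_centroid_rise_da
        )
        if rising:
            return "EX2"
    return "ambiguous"


def write_envelope(env: IsotopeEnvelope, path) -> None:
    """Write an envelope as two-column m/z,intensity text with metadata in
    ``# key: value`` header comments."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# charge: {env.charge}\n")
        if env.peptide is not None:
            fh.write(f"# sequence: {env.peptide.sequence}\n")
            fh.write(f"# start: {env.peptide.start}\n")
            fh.write(f"# end: {env.peptide.end}\n")
        if env.exposure_s is not None:
            fh.write(f"# exposure_s: {env.exposure_s}\n")
        for mz, inten in zip(env.mz, env.intensity):
            fh.write(f"{mz:.6f}\t{inten:.6f}\n")


def read_envelope(path) -> IsotopeEnvelope:
    meta: dict[str, str] = {}
    mz, inten = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                continue
            a, b = line.split()
            mz.append(float(a))
            inten.append(float(b))
    peptide = None
    if {"sequence", "start", "end"} <= meta.keys():
        peptide = PeptideRecord(
            meta["sequence"], int(meta["start"]), int(meta["end"])
        )
    return IsotopeEnvelope(
        charge=int(meta.get("charge", 1)),
        mz=np.array(mz),
        intensity=np.array(inten),
        peptide=peptide,
        exposure_s=float(meta["exposure_s"]) if "exposure_s" in meta else None,
    )
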