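"""Synthetic HDX datasets and two-domain trajectories with known ground truth.

Every downstream stage (uptake statistics, differential calls, envelope
fitting, trajectory geometry) is testable against these generators
without any external data.

HDX model
---------
EX2 kinetics: each exchangeable amide ``i`` exchanges independently at
rate ``k_int,i / P_i`` where ``P_i >= 1`` is its protection factor, so the
noiseless peptide uptake is ``sum_i (1 - exp(-(k_int,i/P_i) t))``.  Back
exchange removes a fixed fraction of the incorporated deuterium per
peptide (multiplicative ``1 - BE``), and replicate noise is Gaussian on
the uptake in Da.

EX1 kinetics: a region opens irreversibly at rate ``k_open``; the open
(heavy) population exchanges fully while the closed (light) population
continues EX2 exchange, producing a bimodal envelope whose heavy fraction
``1 - exp(-k_open t)`` grows with time.

Trajectory model: two rigid Calpha domain blobs are placed each frame so
that the realized center-of-mass distance and linker-vertex angle are
exact draws from configured normal distributions; atomic jitter and
two-state (on/off Markov) bond dynamics are added on top.

Randomness: one root seed per config; independent per-purpose streams are
derived with ``numpy.random.SeedSequence(root, stream_id)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .envelope import IsotopeEnvelope, PROTON_MASS, component_profile, natural_isotope_pattern
from .geometry import DomainDefinition, Structure, Trajectory
from .hdx import PeptideRecord, UptakeMeasurement

__all__ = [
    "HDXSimConfig",
    "TrajSimConfig",
    "BondPairSpec",
    "simulate_peptide_uptake_ex2",
    "noiseless_uptake_ex2",
    "simulate_peptide_uptake_ex1",
    "simulate_bimodal_envelope",
    "simulate_trajectory",
    "simulate_state_table",
]

_STREAM_UPTAKE = 1
_STREAM_ENVELOPE = 2
_STREAM_BLOBS = 3
_STREAM_GEOMETRY = 4
_STREAM_JITTER = 5
_STREAM_BONDS = 6


def _stable_hash(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def _rng(seed: int, stream: int, *parts) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream, _stable_hash(*parts)))
    )


@dataclass
class HDXSimConfig:
    """Conditions of a simulated HDX experiment.

    ``k_int`` and ``protection_factor`` may be scalars (flat across the
    sequence) or per-residue arrays of the protein length.  Intrinsic
    rates default to a flat 1.0 /s — a per-residue table can be supplied
    when residue-specific chemistry matters.  Exposures default to the
    10 s / 1 min / 10 min / 60 min ladder typical of local-HDX time
    courses, back exchange to the 40% average typical of a quench/LC
    workflow, and replicate noise to 0.15 Da with triplicates.
    """

    protein_sequence: str
    k_int: float | np.ndarray = 1.0
    protection_factor: float | np.ndarray = 1.0
    ex1_regions: Sequence[tuple[int, int, float]] = field(default_factory=list)
    back_exchange_fraction: float = 0.40
    replicate_noise_sd: float = 0.15
    exposures: Sequence[float] = (10.0, 60.0, 600.0, 3600.0)
    n_replicates: int = 3
    envelope_width_da: float = 1.0
    envelope_snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.protein_sequence)
        if n == 0:
            raise ValueError("empty protein sequence")
        self.k_int = self._per_residue(self.k_int, "k_int")
        self.protection_factor = self._per_residue(
            self.protection_factor, "protection_factor"
        )
        if np.any(self.k_int <= 0):
            raise ValueError("k_int must be positive")
        if np.any(self.protection_factor < 1):
            raise ValueError("protection_factor must be >= 1 everywhere")
        if not (0.0 <= self.back_exchange_fraction < 1.0):
            raise ValueError("back_exchange_fraction must lie in [0, 1)")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        exp = np.asarray(self.exposures, dtype=float)
        if np.any(exp <= 0) or np.any(np.diff(exp) <= 0):
            raise ValueError("exposures must be strictly positive and sorted")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for start, end, k_open in self.ex1_regions:
            if not (1 <= start <= end <= n):
                raise ValueError(f"ex1 region {start}-{end} outside sequence")
            if k_open < 0:
                raise ValueError("k_open must be >= 0")

    def _per_residue(self, value, name: str) -> np.ndarray:
        n = len(self.protein_sequence)
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(n, float(arr))
        if arr.shape != (n,):
            raise ValueError(f"{name} must be scalar or length-{n} array")
        return arr.copy()


def _exchangeable_offsets(peptide: PeptideRecord) -> np.ndarray:
    """0-based offsets (within the peptide) of amides that retain label."""
    offs = [
        k
        for k, aa in enumerate(peptide.sequence)
        if k >= peptide.n_term_excluded and aa != "P"
    ]
    return np.array(offs, dtype=int)


def _check_span(config: HDXSimConfig, peptide: PeptideRecord) -> None:
    n = len(config.protein_sequence)
    if peptide.start < 1 or peptide.end > n:
        raise ValueError(
            f"peptide {peptide.label()} outside protein 1-{n}"
        )
    prot_seg = config.protein_sequence[peptide.start - 1 : peptide.end]
    if prot_seg != peptide.sequence:
        raise ValueError(
            f"peptide sequence {peptide.sequence!r} does not match protein "
            f"segment {prot_seg!r} at {peptide.label()}"
        )


def noiseless_uptake_ex2(
    config: HDXSimConfig, peptide: PeptideRecord, t: float
) -> float:
    """Noise- and back-exchange-free EX2 uptake (Da) at exposure ``t``."""
    _check_span(config, peptide)
    offs = _exchangeable_offsets(peptide)
    if len(offs) == 0:
        raise ValueError(
            f"peptide {peptide.sequence!r} ({peptide.label()}) has no "
            "exchangeable amides"
        )
    if t <= 0:
        return 0.0
    resid = peptide.start - 1 + offs  # 0-based protein indices
    k_obs = config.k_int[resid] / config.protection_factor[resid]
    return float(np.sum(1.0 - np.exp(-k_obs * t)))


def simulate_peptide_uptake_ex2(
    config: HDXSimConfig, peptide: PeptideRecord, state: str = "free"
) -> list[UptakeMeasurement]:
    """Simulate replicate EX2 uptake measurements across the configured
    exposures.  Back exchange is applied multiplicatively, then Gaussian
    replicate noise; negative draws clamp to zero (flagged on the
    measurement)."""
    rng = _rng(config.seed, _STREAM_UPTAKE, peptide.start, peptide.end, state)
    retain = 1.0 - config.back_exchange_fraction
    out: list[UptakeMeasurement] = []
    for t in config.exposures:
        clean = noiseless_uptake_ex2(config, peptide, float(t)) * retain
        noise = rng.normal(0.0, config.replicate_noise_sd, size=config.n_replicates)
        for rep in range(config.n_replicates):
            out.append(
                UptakeMeasurement(
                    peptide=peptide,
                    state=state,
                    exposure_s=float(t),
                    replicate=rep + 1,
                    uptake_da=clean + noise[rep],
                )
            )
    return out


def heavy_fraction(k_open: float, t: float) -> float:
    """EX1 open-population fraction after exposure ``t``: 1 - exp(-k_open t)."""
    return float(-np.expm1(-k_open * t))


def simulate_bimodal_envelope(
    peptide: PeptideRecord,
    d_light: float,
    d_heavy: float,
    fraction_heavy: float,
    width: float = 1.0,
    snr: float = 50.0,
    charge: int = 1,
    exposure_s: float | None = None,
    seed: int = 0,
) -> IsotopeEnvelope:
    """Two-population deuterated envelope with Gaussian intensity noise at
    the given signal-to-noise ratio (noise sd = max intensity / SNR).
    Intensities are clamped nonnegative and normalized to max 1."""
    if not (0.0 <= fraction_heavy <= 1.0):
        raise ValueError("fraction_heavy must lie in [0, 1]")
    mono, natural = natural_isotope_pattern(peptide.sequence)
    n_grid = len(natural) + int(np.ceil(max(d_light, d_heavy) + 6 * width)) + 2
    offsets = np.arange(n_grid, dtype=float)
    intens = (1 - fraction_heavy) * component_profile(
        offsets, natural, d_light, width
    ) + fraction_heavy * component_profile(offsets, natural, d_heavy, width)
    intens = intens / intens.max()
    if snr and np.isfinite(snr):
        rng = _rng(seed, _STREAM_ENVELOPE, peptide.start, peptide.end, exposure_s)
        intens = intens + rng.normal(0.0, 1.0 / snr, size=intens.shape)
        intens = np.clip(intens, 0.0, None)
        intens = intens / intens.max()
    mz = (mono + offsets) / charge + PROTON_MASS
    return IsotopeEnvelope(
        charge=charge, mz=mz, intensity=intens, peptide=peptide,
        exposure_s=exposure_s,
    )


def simulate_peptide_uptake_ex1(
    config: HDXSimConfig, peptide: PeptideRecord, t: float
) -> IsotopeEnvelope:
    """Bimodal EX1 envelope at exposure ``t`` for a peptide overlapping a
    configured EX1 region.

    The heavy (open, fully exchanged) population carries the fraction
    ``1 - exp(-k_open t)``; the light population exchanges per EX2.
    """
    _check_span(config, peptide)
    region = next(
        (
            r
            for r in config.ex1_regions
            if not (peptide.end < r[0] or peptide.start > r[1])
        ),
        None,
    )
    if region is None:
        raise ValueError(
            f"peptide {peptide.label()} overlaps no EX1 region; use the EX2 "
            "uptake simulator instead"
        )
    k_open = region[2]
    f_heavy = heavy_fraction(k_open, t)
    retain = 1.0 - config.back_exchange_fraction
    d_light = noiseless_uptake_ex2(config, peptide, t) * retain
    d_heavy = peptide.exchangeable_nh * retain
    return simulate_bimodal_envelope(
        peptide,
        d_light=d_light,
        d_heavy=d_heavy,
        fraction_heavy=f_heavy,
        width=config.envelope_width_da,
        snr=config.envelope_snr,
        exposure_s=t,
        seed=config.seed,
    )


def simulate_state_table(
    config: HDXSimConfig,
    peptides: Sequence[PeptideRecord],
    states: dict[str, float | np.ndarray] | None = None,
    protein: str = "protein",
) -> pd.DataFrame:
    """Simulate a full peptide state table for one or more states.

    ``states`` maps state labels to protection-factor overrides (scalar or
    per-residue); ``None`` means a single ``"free"`` state at the config's
    protection factors.  Returns the CSV state-table schema consumed by
    the differential pipeline.
    """
    if states is None:
        states = {"free": config.protection_factor}
    rows = []
    for state, pf in states.items():
        cfg = HDXSimConfig(
            protein_sequence=config.protein_sequence,
            k_int=config.k_int,
            protection_factor=pf,
            ex1_regions=config.ex1_regions,
            back_exchange_fraction=config.back_exchange_fraction,
            replicate_noise_sd=config.replicate_noise_sd,
            exposures=config.exposures,
            n_replicates=config.n_replicates,
            envelope_width_da=config.envelope_width_da,
            envelope_snr=config.envelope_snr,
            seed=config.seed,
        )
        for peptide in peptides:
            for m in simulate_peptide_uptake_ex2(cfg, peptide, state=state):
                rows.append(
                    {
                        "protein": protein,
                        "sequence": peptide.sequence,
                        "start": peptide.start,
                        "end": peptide.end,
                        "state": m.state,
                        "exposure_s": m.exposure_s,
                        "replicate": m.replicate,
                        "uptake_da": m.uptake_da,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class BondPairSpec:
    """Two-state bond between named atoms of two residues.

    The on/off process is a two-state Markov chain with stationary on
    probability ``p_on`` and switching intensity ``k_switch`` per frame
    (``P(off->on) = k_switch * p_on``, ``P(on->off) = k_switch * (1 - p_on)``).
    """

    resid_i: int
    atom_i: str
    resid_j: int
    atom_j: str
    p_on: float
    k_switch: float = 1.0
    on_distance: float = 2.8
    off_distance: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_on <= 1.0):
            raise ValueError("p_on must lie in [0, 1]")
        if not (0.0 < self.k_switch <= 1.0):
            raise ValueError("k_switch must lie in (0, 1]")
        if self.on_distance <= 0 or self.off_distance <= self.on_distance:
            raise ValueError("need 0 < on_distance < off_distance")


@dataclass
class TrajSimConfig:
    """Conditions of a simulated two-domain Calpha trajectory.

    Defaults model a 165-residue two-domain protein (domains 1-76 and
    80-165 bridged by linker 77-79) sampled every 1 ns, with an
    interdomain COM distance of 30 +/- 1 A and a linker-vertex angle of
    100 +/- 2 degrees.
    """

    n_residues: int = 165
    domains: DomainDefinition = field(default_factory=DomainDefinition)
    n_frames: int = 1000
    frame_spacing_ns: float = 1.0
    distance_mean: float = 30.0
    distance_sd: float = 1.0
    angle_mean: float = 100.0
    angle_sd: float = 2.0
    domain_radius: float = 8.0
    bond_pairs: Sequence[BondPairSpec] = field(default_factory=list)
    positional_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < self.domains.ctd[1]:
            raise ValueError(
                f"n_residues {self.n_residues} smaller than CTD end "
                f"{self.domains.ctd[1]}"
            )
        for name in ("distance_sd", "angle_sd", "positional_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.distance_mean <= 0 or not (0 < self.angle_mean < 180):
            raise ValueError("distance_mean must be > 0 and angle_mean in (0, 180)")
        if self.distance_mean < 2 * self.domain_radius:
            raise ValueError(
                f"distance_mean {self.distance_mean} A is unsatisfiable: the "
                f"two domains (radius {self.domain_radius} A) would overlap"
            )


def _domain_blob(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Rigid blob of n points uniform in a ball, re-centered so the mean
    (= equal-mass COM) is exactly zero."""
    pts = np.empty((0, 3))
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=(2 * n, 3))
        cand = cand[np.linalg.norm(cand, axis=1) <= radius]
        pts = np.vstack([pts, cand])
    pts = pts[:n]
    return pts - pts.mean(axis=0)


def simulate_trajectory(config: TrajSimConfig) -> Trajectory:
    """Generate a Calpha trajectory whose per-frame interdomain COM
    distance and linker-vertex angle are exact draws from the configured
    normal distributions.

    Construction: per frame, sample distance ``d`` and angle ``theta``;
    place the linker COM at the vertex and both domain COMs at arm length
    ``r = d / (2 sin(theta/2))`` so both observables are realized exactly,
    then apply a random global rotation, per-atom Gaussian jitter, and
    two-state bond dynamics for any configured bond pairs (bond atoms are
    extra non-CA atoms; CA-only selections are unaffected).
    """
    dom = config.domains
    n_ntd = dom.ntd[1] - dom.ntd[0] + 1
    n_lnk = dom.linker[1] - dom.linker[0] + 1
    n_ctd = dom.ctd[1] - dom.ctd[0] + 1

    blob_rng = _rng(config.seed, _STREAM_BLOBS)
    ntd_blob = _domain_blob(blob_rng, n_ntd, config.domain_radius)
    lnk_blob = _domain_blob(blob_rng, n_lnk, 1.5)
    ctd_blob = _domain_blob(blob_rng, n_ctd, config.domain_radius)

    # topology: one CA per residue 1..n_residues (+ any bond atoms at the end)
    resids = list(range(1, config.n_residues + 1))
    names = ["CA"] * config.n_residues
    elements = ["C"] * config.n_residues
    resnames = ["ALA"] * config.n_residues
    for bp in config.bond_pairs:
        for resid, name in ((bp.resid_i, bp.atom_i), (bp.resid_j, bp.atom_j)):
            if not (1 <= resid <= config.n_residues):
                raise ValueError(f"bond residue {resid} outside protein")
            resids.append(resid)
            names.append(name)
            elements.append(name[:1].upper() if name[:1].upper() in "NOSCH" else "C")
            resnames.append("ALA")
    n_atoms = len(resids)
    resids_arr = np.array(resids)
    elements_arr = np.array(elements)
    from .geometry import ATOMIC_MASSES

    topo = Structure(
        names=np.array(names),
        elements=elements_arr,
        masses=np.array([ATOMIC_MASSES.get(e, 12.011) for e in elements_arr]),
        resids=resids_arr,
        resnames=np.array(resnames),
        chains=np.array(["A"] * n_atoms),
        coords=np.zeros((n_atoms, 3)),
    )

    geo_rng = _rng(config.seed, _STREAM_GEOMETRY)
    jit_rng = _rng(config.seed, _STREAM_JITTER)
    bond_rng = _rng(config.seed, _STREAM_BONDS)

    d_draws = geo_rng.normal(config.distance_mean, config.distance_sd, config.n_frames)
    a_draws = geo_rng.normal(config.angle_mean, config.angle_sd, config.n_frames)
    d_draws = np.clip(d_draws, 1e-3, None)
    a_draws = np.clip(a_draws, 1e-2, 180.0 - 1e-2)

    # two-state bond chains
    bond_states = np.zeros((len(config.bond_pairs), config.n_frames), dtype=bool)
    for b, bp in enumerate(config.bond_pairs):
        state = bond_rng.random() < bp.p_on
        for f in range(config.n_frames):
            bond_states[b, f] = state
            u = bond_rng.random()
            if state:
                state = not (u < bp.k_switch * (1.0 - bp.p_on))
            else:
                state = u < bp.k_switch * bp.p_on

    # index of each residue's CA (for anchoring bond atoms)
    ca_index = {r: i for i, r in enumerate(range(1, config.n_residues + 1))}

    frames = np.empty((config.n_frames, n_atoms, 3))
    from scipy.spatial.transform import Rotation as _R

    for f in range(config.n_frames):
        theta = np.radians(a_draws[f])
        r_arm = d_draws[f] / (2.0 * np.sin(theta / 2.0))
        u1 = np.array([np.cos(theta / 2), np.sin(theta / 2), 0.0])
        u2 = np.array([np.cos(theta / 2), -np.sin(theta / 2), 0.0])
        xyz = np.empty((n_atoms, 3))
        xyz[: n_ntd] = ntd_blob + r_arm * u1
        xyz[n_ntd : n_ntd + n_lnk] = lnk_blob
        xyz[n_ntd + n_lnk : config.n_residues] = ctd_blob + r_arm * u2
        # bond atoms anchored near their residues' CA
        base = config.n_residues
        for b, bp in enumerate(config.bond_pairs):
            anchor = xyz[ca_index[bp.resid_i]]
            dist = bp.on_distance if bond_states[b, f] else bp.off_distance
            xyz[base + 2 * b] = anchor + np.array([0.0, 0.0, 1.0])
            xyz[base + 2 * b + 1] = xyz[base + 2 * b] + np.array([dist, 0.0, 0.0])
        if config.positional_jitter_sd > 0:
            jitter = jit_rng.normal(0, config.positional_jitter_sd, (config.n_residues, 3))
            xyz[: config.n_residues] += jitter
        # random global rigid motion (does not change internal geometry)
        rot = _R.random(rng=geo_rng).as_matrix()
        shift = geo_rng.normal(0, 5.0, 3)
        frames[f] = xyz @ rot.T + shift

    return Trajectory(topo, frames, config.frame_spacing_ns)
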