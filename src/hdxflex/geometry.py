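"""Structure and trajectory geometry.

Rigid superposition (Kabsch), RMSD/RMSF, mass-weighted center-of-mass
interdomain distance and angle with empirical probability curves,
hydrogen-bond / salt-bridge occupancy, and per-residue B-factor
annotation of PDB files.

Coordinates are in angstroms throughout; nm cutoffs from the literature
are converted at the interface (0.3 nm = 3.0 A).  Residue numbering is
1-based with inclusive ranges.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import ecdf as _scipy_ecdf

__all__ = [
    "ATOMIC_MASSES",
    "HBOND_CUTOFF_A",
    "SALTBRIDGE_CUTOFF_A",
    "Structure",
    "Trajectory",
    "DomainDefinition",
    "GeometrySeries",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "superpose_structures",
    "pair_atoms",
    "rmsd_series",
    "rmsf_per_residue",
    "center_of_mass",
    "interdomain_distance",
    "interdomain_angle",
    "geometry_series",
    "probability_curve",
    "bond_occupancy",
    "write_bfactor",
]

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}

HBOND_CUTOFF_A = 3.0       # donor-acceptor distance, 0.3 nm
SALTBRIDGE_CUTOFF_A = 3.2  # acidic-O to basic-N distance, 0.32 nm

# side-chain atom sets for salt-bridge detection
_ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC_N = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
_BASIC_N_HIS = {"HIS": ("ND1", "NE2")}

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Structure:
    """Flat atom-array representation of one model.

    Parallel arrays: ``names`` (PDB atom names), ``elements``, ``masses``
    (amu), ``resids`` (1-based), ``resnames``, ``chains``, ``coords``
    (n_atoms x 3, A), optional ``bfactors``.
    """

    names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    bfactors: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.bfactors is None:
            self.bfactors = np.zeros(n)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def select(
        self,
        resid_range: tuple[int, int] | None = None,
        atom_names: Sequence[str] | None = None,
        chain: str | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if resid_range is not None:
            lo, hi = resid_range
            mask &= (self.resids >= lo) & (self.resids <= hi)
        if atom_names is not None:
            mask &= np.isin(self.names, list(atom_names))
        if chain is not None:
            mask &= self.chains == chain
        return mask

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            self.names[mask], self.elements[mask], self.masses[mask],
            self.resids[mask], self.resnames[mask], self.chains[mask],
            self.coords[mask], self.bfactors[mask],
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            self.names, self.elements, self.masses, self.resids,
            self.resnames, self.chains, coords, self.bfactors,
        )

    def chain_sequence(self, chain: str) -> tuple[str, list[int]]:
        """One-letter sequence of a chain from its CA atoms, plus the atom
        indices of those CA atoms."""
        idx = np.nonzero(self.select(atom_names=["CA"], chain=chain))[0]
        seq = "".join(_AA3TO1.get(self.resnames[i], "X") for i in idx)
        return seq, list(idx)


@dataclass
class Trajectory:
    """Ordered frames congruent with a topology Structure."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing_ns: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if self.frame_spacing_ns <= 0:
            raise ValueError("frame_spacing_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class DomainDefinition:
    """Two tandem domains joined by a short linker (defaults: BLIP)."""

    ntd: tuple[int, int] = (1, 76)
    linker: tuple[int, int] = (77, 79)
    ctd: tuple[int, int] = (80, 165)

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip(("ntd", "linker", "ctd"), self.ranges):
            if lo > hi:
                raise ValueError(f"{name} range {lo}-{hi} is empty")
        if not (self.ntd[1] < self.linker[0] and self.linker[1] < self.ctd[0]):
            raise ValueError("domain ranges must be disjoint and ordered")

    @property
    def ranges(self) -> tuple[tuple[int, int], ...]:
        return (self.ntd, self.linker, self.ctd)


@dataclass
class GeometrySeries:
    """Per-frame values of one geometric observable."""

    name: str
    unit: str
    values: np.ndarray
    frame_spacing_ns: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(self.values.mean())

    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_frames) * self.frame_spacing_ns
        return pd.DataFrame({"time_ns": t, self.name: self.values})


# ---------------------------------------------------------------------------
# PDB I/O (reading via Biopython; writing via an explicit wwPDB formatter so
# the B-factor column contract, columns 61-66, is guaranteed)


def _element_of(atom) -> str:
    el = (atom.element or "").strip().upper()
    if not el:
        el = atom.get_name().strip()[:1].upper()
    return el


def read_pdb(path) -> Trajectory:
    """Read a PDB or multi-model PDB into a Trajectory (single-model files
    become one-frame trajectories)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        struct = parser.get_structure("s", str(path))
    models = list(struct)
    if not models:
        raise ValueError(f"no models in {path}")

    names, elements, masses, resids, resnames, chains, coords, bfs = (
        [], [], [], [], [], [], [], []
    )
    for chain in models[0]:
        for res in chain:
            if res.id[0] != " ":  # skip heteroatoms/waters
                continue
            for atom in res:
                el = _element_of(atom)
                names.append(atom.get_name())
                elements.append(el)
                masses.append(ATOMIC_MASSES.get(el, 12.011))
                resids.append(res.id[1])
                resnames.append(res.get_resname())
                chains.append(chain.id)
                coords.append(atom.coord)
                bfs.append(atom.get_bfactor())
    topo = Structure(
        np.array(names), np.array(elements), np.array(masses),
        np.array(resids), np.array(resnames), np.array(chains),
        np.array(coords, dtype=float), np.array(bfs, dtype=float),
    )

    frames = [topo.coords]
    for model in models[1:]:
        xyz = []
        for chain in model:
            for res in chain:
                if res.id[0] != " ":
                    continue
                for atom in res:
                    xyz.append(atom.coord)
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != topo.coords.shape:
            raise ValueError(
                f"model {model.id + 1} in {path} has {len(xyz)} atoms, "
                f"expected {topo.n_atoms}"
            )
        frames.append(xyz)
    return Trajectory(topo, np.stack(frames))


def _pdb_atom_line(i: int, s: Structure, xyz: np.ndarray) -> str:
    name = s.names[i]
    # wwPDB: 1-letter element atom names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {i + 1 % 100000:5d} {name_field} "
        f"{s.resnames[i]:>3s} {str(s.chains[i])[:1]:1s}"
        f"{int(s.resids[i]):4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{s.bfactors[i]:6.2f}          "
        f"{s.elements[i]:>2s}\n"
    )


def write_pdb(obj: Structure | Trajectory, path) -> None:
    """Write a Structure (single model) or Trajectory (MODEL/ENDMDL
    multi-model) in wwPDB column layout, B-factor in columns 61-66."""
    if isinstance(obj, Structure):
        traj = Trajectory(obj, obj.coords[None, :, :])
    else:
        traj = obj
    s = traj.topology
    buf = io.StringIO()
    multi = traj.n_frames > 1
    for f in range(traj.n_frames):
        if multi:
            buf.write(f"MODEL     {f + 1:4d}\n")
        for i in range(s.n_atoms):
            buf.write(_pdb_atom_line(i, s, traj.frames[f, i]))
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets (Kabsch).

    Returns ``(rotation 3x3, translation, rmsd_A)`` such that
    ``mobile @ R.T + t`` best fits ``reference`` in the least-squares
    sense.  Reflections are not permitted.  Degenerate (collinear)
    selections are flagged with a warning — the in-plane component of the
    rotation is then arbitrary, although the RMSD is still optimal.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 paired atoms, got {n}")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    a = mobile - mu_m
    b = reference - mu_r
    sing = np.linalg.svd(a, compute_uv=False)
    if sing[1] < 1e-8 * max(sing[0], 1.0):
        warnings.warn("collinear atom selection: rotation is not unique", stacklevel=2)
    rot, rssd = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = mu_r - R @ mu_m
    return R, t, float(rssd / np.sqrt(n))


def pair_atoms(
    a: Structure, b: Structure, mode: str = "identical"
) -> tuple[np.ndarray, np.ndarray]:
    """Match atoms between two structures.

    ``identical``: pair by (chain, residue index, atom name).
    ``aligned``: pair CA atoms of residues matched by global sequence
    alignment of each chain pair (BLOSUM62; only gap-free columns are
    paired), for comparing homologous, non-identical proteins.

    Returns parallel index arrays into ``a`` and ``b``.
    """
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("empty structure")
    if mode == "identical":
        key_b = {
            (b.chains[j], int(b.resids[j]), b.names[j]): j
            for j in range(b.n_atoms)
        }
        ia, ib = [], []
        for i in range(a.n_atoms):
            j = key_b.get((a.chains[i], int(a.resids[i]), a.names[i]))
            if j is not None:
                ia.append(i)
                ib.append(j)
    elif mode == "aligned":
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        aligner.mode = "global"
        chains_a = list(dict.fromkeys(a.chains))
        chains_b = list(dict.fromkeys(b.chains))
        ia, ib = [], []
        for ch_a, ch_b in zip(chains_a, chains_b):
            seq_a, idx_a = a.chain_sequence(ch_a)
            seq_b, idx_b = b.chain_sequence(ch_b)
            if not seq_a or not seq_b:
                continue
            aln = aligner.align(seq_a, seq_b)[0]
            for (sa, ea), (sb, eb) in zip(*aln.aligned):
                ia.extend(idx_a[sa:ea])
                ib.extend(idx_b[sb:eb])
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    if not ia:
        raise ValueError("no atoms could be paired")
    return np.array(ia), np.array(ib)


def superpose_structures(
    mobile: Structure,
    reference: Structure,
    mode: str = "identical",
    atom_names: Sequence[str] | None = ("CA",),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pair atoms, then Kabsch-superpose.  Returns (R, t, rmsd)."""
    ia, ib = pair_atoms(mobile, reference, mode=mode)
    if atom_names is not None:
        keep = np.isin(mobile.names[ia], list(atom_names))
        ia, ib = ia[keep], ib[keep]
    if len(ia) < 3:
        raise ValueError("fewer than 3 paired atoms after selection")
    return kabsch_superpose(mobile.coords[ia], reference.coords[ib])


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    atom_names: Sequence[str] | None = ("CA",),
    resid_range: tuple[int, int] | None = None,
) -> GeometrySeries:
    """Per-frame RMSD to a reference after per-frame optimal superposition."""
    mask_t = traj.topology.select(resid_range=resid_range, atom_names=atom_names)
    mask_r = reference.select(resid_range=resid_range, atom_names=atom_names)
    ref = reference.coords[mask_r]
    if mask_t.sum() != len(ref):
        raise ValueError(
            f"selection size mismatch: {mask_t.sum()} trajectory atoms vs "
            f"{len(ref)} reference atoms"
        )
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, vals[f] = kabsch_superpose(traj.frames[f][mask_t], ref)
    return GeometrySeries("rmsd", "A", vals, traj.frame_spacing_ns)


def rmsf_per_residue(
    traj: Trajectory, atom_names: Sequence[str] | None = ("CA",)
) -> pd.DataFrame:
    """Per-residue RMSF about the mean structure.

    Frames are first aligned to the first frame, the mean structure is
    formed, and all frames are re-aligned to that mean (one refinement
    pass — deterministic and seed-free); RMSF of each atom is then
    averaged within residues.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs >= 2 frames")
    mask = traj.topology.select(atom_names=atom_names)
    sel = traj.frames[:, mask, :]
    aligned = np.empty_like(sel)
    ref = sel[0]
    for _ in range(2):  # initial alignment + one refinement to the mean
        for f in range(sel.shape[0]):
            R, t, _ = kabsch_superpose(sel[f], ref)
            aligned[f] = sel[f] @ R.T + t
        ref = aligned.mean(axis=0)
    dev = aligned - ref[None]
    rmsf_atom = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    df = pd.DataFrame(
        {"resid": traj.topology.resids[mask], "rmsf": rmsf_atom}
    )
    return df.groupby("resid", as_index=False)["rmsf"].mean()


# ---------------------------------------------------------------------------
# interdomain geometry


def center_of_mass(
    s: Structure,
    resid_range: tuple[int, int] | None = None,
    atom_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Mass-weighted mean coordinate of a selection (A)."""
    mask = s.select(resid_range=resid_range, atom_names=atom_names)
    if not mask.any():
        raise ValueError(f"empty selection (residues {resid_range}, atoms {atom_names})")
    w = s.masses[mask]
    return np.average(s.coords[mask], axis=0, weights=w)


def _check_domain(s: Structure, rng: tuple[int, int], name: str) -> None:
    present = np.unique(s.resids[s.select(resid_range=rng)])
    missing = sorted(set(range(rng[0], rng[1] + 1)) - set(int(r) for r in present))
    if missing:
        raise ValueError(f"{name} residues missing from structure: {missing}")


def interdomain_distance(
    frame: Structure,
    domains: DomainDefinition = DomainDefinition(),
    atom_names: Sequence[str] | None = None,
) -> float:
    """Euclidean distance (A) between the NTD and CTD centers of mass."""
    _check_domain(frame, domains.ntd, "NTD")
    _check_domain(frame, domains.ctd, "CTD")
    c1 = center_of_mass(frame, domains.ntd, atom_names)
    c2 = center_of_mass(frame, domains.ctd, atom_names)
    return float(np.linalg.norm(c1 - c2))


def interdomain_angle(
    frame: Structure,
    domains: DomainDefinition = DomainDefinition(),
    atom_names: Sequence[str] | None = None,
) -> float:
    """Angle (degrees, in [0, 180]) between the vectors from the linker
    center of mass to the NTD and CTD centers of mass."""
    _check_domain(frame, domains.linker, "linker")
    cl = center_of_mass(frame, domains.linker, atom_names)
    v1 = center_of_mass(frame, domains.ntd, atom_names) - cl
    v2 = center_of_mass(frame, domains.ctd, atom_names) - cl
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("domain COM coincides with linker COM; angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def geometry_series(
    traj: Trajectory,
    metric: str,
    domains: DomainDefinition = DomainDefinition(),
    atom_names: Sequence[str] | None = ("CA",),
) -> GeometrySeries:
    """Per-frame interdomain ``"distance"`` (A) or ``"angle"`` (degrees)."""
    fn = {"distance": interdomain_distance, "angle": interdomain_angle}.get(metric)
    if fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    vals = np.array(
        [fn(traj.frame(f), domains, atom_names) for f in range(traj.n_frames)]
    )
    unit = "A" if metric == "distance" else "deg"
    return GeometrySeries(metric, unit, vals, traj.frame_spacing_ns)


def probability_curve(series: GeometrySeries | np.ndarray) -> pd.DataFrame:
    """Empirical CDF of a geometry series: the S-shaped probability curve
    of a normally distributed ensemble.  Monotone, bounded by [0, 1]."""
    values = series.values if isinstance(series, GeometrySeries) else np.asarray(series)
    if len(values) < 10:
        raise ValueError("need >= 10 frames for a probability curve")
    res = _scipy_ecdf(values).cdf
    return pd.DataFrame({"value": res.quantiles, "probability": res.probabilities})


# ---------------------------------------------------------------------------
# bond occupancy


def _bond_atom_indices(
    s: Structure, resid: int, kind: str, role: str, atom_names: Sequence[str] | None
) -> np.ndarray:
    if atom_names is not None:
        idx = np.nonzero(s.select(resid_range=(resid, resid), atom_names=atom_names))[0]
    elif kind == "saltbridge":
        resname_idx = np.nonzero(s.select(resid_range=(resid, resid)))[0]
        if len(resname_idx) == 0:
            raise ValueError(f"residue {resid} not in structure")
        resname = s.resnames[resname_idx[0]]
        table = dict(_ACIDIC_O) if role == "i" else {**_BASIC_N, **_BASIC_N_HIS}
        names = table.get(resname)
        if names is None:
            raise ValueError(
                f"residue {resid} ({resname}) has no {role} salt-bridge atoms"
            )
        idx = np.nonzero(s.select(resid_range=(resid, resid), atom_names=names))[0]
    else:
        raise ValueError("hbond pairs require explicit donor/acceptor atom names")
    if len(idx) == 0:
        raise ValueError(f"no atoms found for residue {resid} ({role})")
    return idx


def bond_occupancy(
    traj: Trajectory,
    resid_i: int,
    resid_j: int,
    kind: str = "hbond",
    atoms_i: Sequence[str] | None = None,
    atoms_j: Sequence[str] | None = None,
    cutoff: float | None = None,
) -> tuple[float, GeometrySeries]:
    """Fraction of frames in which a hydrogen bond or salt bridge is formed.

    A frame counts as bonded when the minimum distance over all
    (atom_i, atom_j) combinations is at or below the cutoff: 3.0 A
    donor-acceptor for ``kind="hbond"``, 3.2 A acidic-O/basic-N for
    ``kind="saltbridge"`` (the distance-only criterion; no angle term).
    For salt bridges the atom sets default to Asp/Glu carboxylate oxygens
    against Lys NZ / Arg NH1, NH2, NE (His ND1/NE2 accepted when named
    explicitly).  Returns ``(occupancy, per-frame minimum distances)``.
    """
    if kind not in ("hbond", "saltbridge"):
        raise ValueError(f"unknown bond kind {kind!r}")
    if cutoff is None:
        cutoff = HBOND_CUTOFF_A if kind == "hbond" else SALTBRIDGE_CUTOFF_A
    s = traj.topology
    idx_i = _bond_atom_indices(s, resid_i, kind, "i", atoms_i)
    idx_j = _bond_atom_indices(s, resid_j, kind, "j", atoms_j)
    a = traj.frames[:, idx_i, :]  # (F, ni, 3)
    b = traj.frames[:, idx_j, :]  # (F, nj, 3)
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    dmin = d.min(axis=(1, 2))
    occ = float(np.mean(dmin <= cutoff))
    series = GeometrySeries(
        f"dist_{resid_i}_{resid_j}", "A", dmin, traj.frame_spacing_ns
    )
    return occ, series


def write_bfactor(
    structure: Structure,
    per_residue: dict[int, float],
    path,
    sentinel: float = 0.0,
) -> Structure:
    """Write a PDB with per-residue values in the B-factor column.

    Every atom of a scored residue carries the value (printed %6.2f);
    residues absent from ``per_residue`` get the sentinel.  Values outside
    the printable range [-99.99, 999.99] are an error.
    """
    for resid, val in per_residue.items():
        if not (-99.99 <= val <= 999.99):
            raise ValueError(
                f"value {val} for residue {resid} outside printable B-factor "
                "range [-99.99, 999.99]"
            )
    bf = np.array(
        [per_residue.get(int(r), sentinel) for r in structure.resids], dtype=float
    )
    annotated = Structure(
        structure.names, structure.elements, structure.masses,
        structure.resids, structure.resnames, structure.chains,
        structure.coords, bf,
    )
    write_pdb(annotated, path)
    return annotated
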