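"""Idealized construction of the RH1-LZI dimer model.

The model is assembled from parametric secondary-structure geometry alone:

* the LZI coiled coil (and its helical hinge and C-terminal continuation)
  is generated from a Crick parameterization -- a minor alpha-helix wound
  on a left-handed superhelix of given radius and pitch, two chains related
  by a two-fold rotation about the superhelical axis;
* the RH1 domain is an idealized four-helix bundle: each protomer
  contributes an antiparallel alpha1/alpha2 hairpin, the two protomers are
  related by the same two-fold axis, and helix axes sit on the corners of a
  square of side ``interhelix_distance``;
* the alpha1-alpha2 loop is a coil arc and the N-terminal Gly-Ser-His tag
  remnant plus residues 22-25 continue the alpha1 helix.

Coordinates are in Angstroms, the coiled-coil axis is z, residue numbering
is the 1-based numbering of the full-length protein (tag residues 19-21).
Only Calpha centers are built; residues are represented downstream by
per-residue scattering weights and beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .sequence_features import RegionAnnotation, SequenceRecord, extract_region

__all__ = [
    "Structure",
    "CrickParameters",
    "BundleGeometry",
    "BuildError",
    "build_ideal_helix",
    "build_parallel_dimer_cc",
    "build_rh1_dimer",
    "assemble_rh1_lzi_dimer",
    "axial_length",
    "max_extent",
    "thickness",
    "radius_of_gyration",
    "chain_symmetry_rmsd",
    "read_pdb",
    "write_pdb",
]

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


class BuildError(RuntimeError):
    """Raised when a geometric construction produces clashing atoms."""


@dataclass
class Structure:
    """A Calpha-level coordinate model.

    Parallel arrays over atoms; within a chain residue numbers are strictly
    increasing.  ``provenance`` records how the model was built.
    """

    chain: np.ndarray          # (N,) unicode chain ids
    resnum: np.ndarray         # (N,) int residue numbers (paper numbering)
    resname: np.ndarray        # (N,) 3-letter residue names
    atomname: np.ndarray       # (N,) atom names (CA)
    xyz: np.ndarray            # (N, 3) float Angstrom
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = len(self.xyz)
        if not (len(self.chain) == len(self.resnum) == len(self.resname)
                == len(self.atomname) == n):
            raise ValueError("inconsistent atom array lengths")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.chain.tolist()))

    def select(self, chain: str | None = None,
               resrange: tuple[int, int] | None = None) -> "Structure":
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if resrange is not None:
            m &= (self.resnum >= resrange[0]) & (self.resnum <= resrange[1])
        return Structure(self.chain[m], self.resnum[m], self.resname[m],
                         self.atomname[m], self.xyz[m], dict(self.provenance))

    def sorted_by_chain(self) -> "Structure":
        order = np.lexsort((self.resnum, self.chain))
        return Structure(self.chain[order], self.resnum[order], self.resname[order],
                         self.atomname[order], self.xyz[order], dict(self.provenance))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    about: np.ndarray | None = None) -> "Structure":
        """Rigidly transform; ``about`` is the rotation center (default origin)."""
        xyz = self.xyz.copy()
        if rotation is not None:
            c = np.zeros(3) if about is None else np.asarray(about, float)
            xyz = (xyz - c) @ np.asarray(rotation).T + c
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        return Structure(self.chain.copy(), self.resnum.copy(), self.resname.copy(),
                         self.atomname.copy(), xyz, dict(self.provenance))

    def validate(self, min_separation: float = 1.0) -> None:
        """Check the container invariants (monotone numbering, no fused atoms)."""
        for ch in self.chains:
            nums = self.resnum[self.chain == ch]
            if np.any(np.diff(nums) <= 0):
                raise ValueError(f"residue numbers not strictly increasing in chain {ch}")
        if len(self) >= 2 and pdist(self.xyz).min() < min_separation:
            raise ValueError(f"atoms closer than {min_separation} A")


def _concat(parts: list[Structure], provenance: dict | None = None) -> Structure:
    return Structure(
        np.concatenate([p.chain for p in parts]),
        np.concatenate([p.resnum for p in parts]),
        np.concatenate([p.resname for p in parts]),
        np.concatenate([p.atomname for p in parts]),
        np.vstack([p.xyz for p in parts]),
        provenance or {},
    )


def _atoms_from_seq(seq: SequenceRecord, xyz: np.ndarray, chain: str) -> Structure:
    n = len(seq)
    return Structure(
        chain=np.array([chain] * n),
        resnum=np.arange(seq.first_residue_number, seq.first_residue_number + n),
        resname=np.array([THREE_LETTER[a] for a in seq.residues]),
        atomname=np.array(["CA"] * n),
        xyz=np.asarray(xyz, float),
    )


@dataclass(frozen=True)
class CrickParameters:
    """Crick parameterization of a dimeric coiled coil.

    Defaults describe a canonical left-handed parallel two-stranded coil:
    superhelix radius 4.9 A and pitch 190 A, minor helix radius 2.26 A with
    3.62 residues/turn and an axial rise of 1.485 A/residue.
    """

    superhelix_radius: float = 4.9
    superhelix_pitch: float = 190.0
    alpha_radius: float = 2.26
    #: minor-helix periodicity in the rotating superhelical frame; 3.5
    #: residues/turn (two turns per heptad) keeps the a/d seam facing the
    #: partner chain along the whole coil, the Crick ideal for a heptad coil
    residues_per_turn_minor: float = 3.5
    rise_per_residue_axial: float = 1.485
    register_phase: str = "a"
    chain_offset_deg: float = 180.0

    def __post_init__(self) -> None:
        if min(self.superhelix_radius, self.superhelix_pitch, self.alpha_radius,
               self.residues_per_turn_minor, self.rise_per_residue_axial) <= 0:
            raise ValueError("Crick parameters must be positive")
        if self.superhelix_pitch <= 20 * self.rise_per_residue_axial:
            raise ValueError("superhelix pitch implausibly short")
        if self.register_phase not in "abcdefg":
            raise ValueError("register_phase must be a..g")


@dataclass(frozen=True)
class BundleGeometry:
    """Four-helix-bundle geometry for the RH1 dimer.

    Helix axes sit on a square of side ``interhelix_distance`` centered on
    the two-fold axis; each protomer is an antiparallel alpha1/alpha2
    hairpin closed by a coil loop (default residues 44-49).
    """

    interhelix_distance: float = 10.5
    loop_residues: tuple[int, int] = (44, 49)
    helix_rise: float = 1.5
    helix_radius: float = 2.3
    residues_per_turn: float = 3.6

    def __post_init__(self) -> None:
        if self.interhelix_distance <= 0:
            raise ValueError("interhelix distance must be positive")
        # nearest axis pair in the square layout is the side itself
        if self.interhelix_distance < 8.0:
            raise ValueError("helix axes closer than 8 A")


def build_ideal_helix(seq: SequenceRecord,
                      origin=(0.0, 0.0, 0.0),
                      axis=(0.0, 0.0, 1.0),
                      rise: float = 1.5,
                      radius: float = 2.3,
                      residues_per_turn: float = 3.6,
                      phase: float = 0.0,
                      chain: str = "A") -> Structure:
    """Calpha trace of an ideal right-handed alpha-helix along ``axis``."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    axis = np.asarray(axis, float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero-length helix axis")
    w = axis / norm
    # any perpendicular pair completes the frame
    ref = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    i = np.arange(len(seq))
    theta = phase + 2 * np.pi * i / residues_per_turn
    xyz = (np.asarray(origin, float)
           + np.outer(rise * i, w)
           + np.outer(radius * np.cos(theta), u)
           + np.outer(radius * np.sin(theta), v))
    return _atoms_from_seq(seq, xyz, chain)


def _crick_chain(seq: SequenceRecord, p: CrickParameters,
                 phi0: float, chain: str) -> Structure:
    """One chain of the coiled coil; residue 0 of the chain starts at z=0."""
    i = np.arange(len(seq))
    d = p.rise_per_residue_axial
    # left-handed supercoil: azimuth decreases as z increases
    omega0 = -2 * np.pi * d / p.superhelix_pitch
    phi = phi0 + omega0 * i
    s = np.column_stack([p.superhelix_radius * np.cos(phi),
                         p.superhelix_radius * np.sin(phi),
                         d * i])
    # local Frenet-style frame of the superhelix
    tangent = np.column_stack([-p.superhelix_radius * omega0 * np.sin(phi),
                               p.superhelix_radius * omega0 * np.cos(phi),
                               np.full_like(phi, d)])
    tangent /= np.linalg.norm(tangent, axis=1)[:, None]
    normal = -np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
    binormal = np.cross(tangent, normal)
    omega1 = 2 * np.pi / p.residues_per_turn_minor
    # phase anchored so the a/d core faces the dimer interface: theta is
    # measured from the inward normal, with 'a' at +26 deg and 'd' three
    # residues later at -61 deg, straddling the seam
    k_to_a = (7 - "abcdefg".index(p.register_phase)) % 7
    theta0 = np.deg2rad(26.0) - k_to_a * omega1
    theta = theta0 + omega1 * i
    xyz = s + p.alpha_radius * (np.cos(theta)[:, None] * normal
                                + np.sin(theta)[:, None] * binormal)
    return _atoms_from_seq(seq, xyz, chain)


def build_parallel_dimer_cc(seq: SequenceRecord,
                            params: CrickParameters | None = None) -> Structure:
    """Two-chain parallel coiled coil; chain B is chain A rotated by the
    chain offset about the superhelical (z) axis."""
    params = params or CrickParameters()
    if len(seq) < 7:
        raise ValueError("coiled coil needs at least one heptad")
    a = _crick_chain(seq, params, phi0=0.0, chain="A")
    off = np.deg2rad(params.chain_offset_deg)
    rot = np.array([[np.cos(off), -np.sin(off), 0.0],
                    [np.sin(off), np.cos(off), 0.0],
                    [0.0, 0.0, 1.0]])
    b = _crick_chain(seq, params, phi0=0.0, chain="B").transformed(rotation=rot)
    s = _concat([a, b], provenance={"builder": "crick_parallel_dimer",
                                    "n_residues_per_chain": len(seq)})
    s.validate()
    return s


def _coil_bridge(start: np.ndarray, end: np.ndarray, n: int,
                 target_spacing: float = 3.2) -> np.ndarray:
    """``n`` coil residues bridging two anchors along a downward arc.

    A quadratic Bezier with its control point below the chord midpoint,
    with depth solved so consecutive spacing (anchors included) is close to
    ``target_spacing``; points are placed at equal arc length.
    """
    from scipy.optimize import brentq

    start = np.asarray(start, float)
    end = np.asarray(end, float)
    want = (n + 1) * target_spacing
    chord = np.linalg.norm(end - start)

    def path_len(depth: float) -> float:
        ctrl = (start + end) / 2 + np.array([0.0, 0.0, -depth])
        t = np.linspace(0, 1, 200)[:, None]
        pts = (1 - t) ** 2 * start + 2 * (1 - t) * t * ctrl + t ** 2 * end
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    if want <= chord:
        depth = 0.0
    else:
        depth = brentq(lambda d: path_len(d) - want, 1e-3, 5 * want)
    ctrl = (start + end) / 2 + np.array([0.0, 0.0, -depth])
    t = np.linspace(0, 1, 400)[:, None]
    dense = (1 - t) ** 2 * start + 2 * (1 - t) * t * ctrl + t ** 2 * end
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, arc[-1], n + 2)[1:-1]
    out = np.empty((n, 3))
    for k, s_t in enumerate(targets):
        j = np.searchsorted(arc, s_t)
        j = min(max(j, 1), len(arc) - 1)
        f = (s_t - arc[j - 1]) / max(arc[j] - arc[j - 1], 1e-12)
        out[k] = dense[j - 1] * (1 - f) + dense[j] * f
    return out


def _protomer_hairpin(alpha1: SequenceRecord, alpha2: SequenceRecord,
                      loop: SequenceRecord, geom: BundleGeometry,
                      corner1: np.ndarray, corner2: np.ndarray,
                      chain: str) -> Structure:
    """One antiparallel alpha1/alpha2 hairpin; alpha2 ends at z=0."""
    n1, n2 = len(alpha1), len(alpha2)
    rise = geom.helix_rise
    z50 = -(n2 - 1) * rise                       # alpha2 ascends to z=0
    # phase chosen so the last alpha2 residue points toward the bundle axis:
    # it must meet the first coil residue, which sits near the dyad
    inward = np.arctan2(-corner2[1], -corner2[0])
    phase2 = (inward + np.pi / 2.0) - (n2 - 1) * 2 * np.pi / geom.residues_per_turn
    a2 = build_ideal_helix(alpha2, origin=(*corner2, z50), axis=(0, 0, 1),
                           rise=rise, radius=geom.helix_radius,
                           residues_per_turn=geom.residues_per_turn,
                           phase=phase2, chain=chain)
    z_top1 = z50 + (n1 - 1) * rise               # alpha1 bottom meets alpha2 bottom
    a1 = build_ideal_helix(alpha1, origin=(*corner1, z_top1), axis=(0, 0, -1),
                           rise=rise, radius=geom.helix_radius,
                           residues_per_turn=geom.residues_per_turn, chain=chain)
    loop_xyz = _coil_bridge(a1.xyz[-1], a2.xyz[0], len(loop))
    lp = _atoms_from_seq(loop, loop_xyz, chain)
    return _concat([a1, lp, a2])


def build_rh1_dimer(alpha1: SequenceRecord, alpha2: SequenceRecord,
                    loop: SequenceRecord,
                    geom: BundleGeometry | None = None) -> Structure:
    """Idealized RH1 homodimer: a four-helix antiparallel bundle.

    Helix axes sit at the corners of a square of side
    ``geom.interhelix_distance``; the two protomers are related by a
    two-fold rotation about the bundle (z) axis.
    """
    geom = geom or BundleGeometry()
    h = geom.interhelix_distance / 2.0
    a_chain = _protomer_hairpin(alpha1, alpha2, loop, geom,
                                corner1=np.array([h, h]),
                                corner2=np.array([h, -h]), chain="A")
    flip = np.diag([-1.0, -1.0, 1.0])            # 180 deg about z
    b_chain = a_chain.transformed(rotation=flip)
    b_chain.chain[:] = "B"
    s = _concat([a_chain, b_chain], provenance={"builder": "rh1_four_helix_bundle"})
    d = pdist(s.xyz)
    if d.min() < 2.0:
        raise BuildError(f"bundle geometry clashes: min distance {d.min():.2f} A")
    return s


DEFAULT_SEGMENTS = {
    "nterm": (19, 25),       # Gly-Ser-His tag remnant (19-21) + 22-25
    "alpha1": (26, 43),
    "loop": (44, 49),
    "alpha2": (50, 73),
    "hinge": (74, 77),       # helical, built as part of the coil
    "coil": (78, 180),
    "cterm": (181, 187),     # helical continuation of the coil
}


def assemble_rh1_lzi_dimer(full_seq: SequenceRecord,
                           cc_params: CrickParameters | None = None,
                           geom: BundleGeometry | None = None,
                           segments: dict | None = None) -> Structure:
    """Assemble the full RH1-LZI dimer model (tag + residues 22-187).

    The hinge (74-77), coil (78-180) and C-terminal continuation (181-187)
    are one continuous Crick coiled coil with residue 74 at z=0.  The RH1
    bundle (26-73, alpha2 top at residue 73) plus the N-terminal extension
    is docked below it by a rigid rotation about z and an axial shift,
    chosen so the 73-74 Calpha-Calpha virtual bond is 3.8 A and the blocks
    do not clash; both blocks are two-fold symmetric about z so the docking
    preserves the dimer symmetry exactly.
    """
    cc_params = cc_params or CrickParameters()
    geom = geom or BundleGeometry()
    seg = dict(DEFAULT_SEGMENTS)
    if segments:
        seg.update(segments)
    _check_segments(seg, full_seq)

    def region(name: str) -> SequenceRecord:
        lo, hi = seg[name]
        return extract_region(full_seq, RegionAnnotation(name, lo, hi))

    coil_seq = SequenceRecord(
        id=full_seq.id + "/coil",
        residues=(region("hinge").residues + region("coil").residues
                  + region("cterm").residues),
        first_residue_number=seg["hinge"][0])
    coil = build_parallel_dimer_cc(coil_seq, cc_params)

    bundle = build_rh1_dimer(region("alpha1"), region("alpha2"), region("loop"), geom)
    # N-terminal extension continues alpha1 upward (helical continuation of
    # the alpha1 cylinder, built N->C downward toward residue 26)
    nt = region("nterm")
    h = geom.interhelix_distance / 2.0
    n_ext = len(nt)
    z_top = -(len(region("alpha2")) - 1) * geom.helix_rise \
        + (len(region("alpha1")) - 1) * geom.helix_rise + n_ext * geom.helix_rise
    phase = -2 * np.pi * n_ext / geom.residues_per_turn
    ext_a = build_ideal_helix(nt, origin=(h, h, z_top), axis=(0, 0, -1),
                              rise=geom.helix_rise, radius=geom.helix_radius,
                              residues_per_turn=geom.residues_per_turn,
                              phase=phase, chain="A")
    ext_b = ext_a.transformed(rotation=np.diag([-1.0, -1.0, 1.0]))
    ext_b.chain[:] = "B"
    lower = _concat([bundle, ext_a, ext_b], provenance={"builder": "rh1_block"})

    placed = _dock_blocks(lower, coil, bond=3.8, clash=2.5)
    model = _concat([placed, coil], provenance={
        "builder": "rh1_lzi_assembly",
        "segments": seg,
        "crick": cc_params.__dict__ if hasattr(cc_params, "__dict__") else str(cc_params),
    }).sorted_by_chain()
    model.validate()
    return model


def _check_segments(seg: dict, full_seq: SequenceRecord) -> None:
    order = ["nterm", "alpha1", "loop", "alpha2", "hinge", "coil", "cterm"]
    prev_end = None
    for name in order:
        lo, hi = seg[name]
        if lo > hi:
            raise ValueError(f"segment {name} inverted: [{lo}-{hi}]")
        if prev_end is not None and lo != prev_end + 1:
            raise ValueError(f"segment {name} does not abut previous (gap/overlap at {lo})")
        prev_end = hi
    if seg["nterm"][0] != full_seq.first_residue_number \
            or seg["cterm"][1] != full_seq.last_residue_number:
        raise ValueError("segments do not cover the sequence record")


def _dock_blocks(lower: Structure, coil: Structure,
                 bond: float, clash: float) -> Structure:
    """Rotate ``lower`` about z and shift it axially under ``coil``."""
    ca73 = lower.xyz[(lower.chain == "A") & (lower.resnum == lower.resnum[
        lower.chain == "A"].max())][0]
    ca74 = coil.xyz[(coil.chain == "A")][0]
    best = None
    for theta_deg in range(0, 360):
        th = np.deg2rad(theta_deg)
        rot = np.array([[np.cos(th), -np.sin(th), 0.0],
                        [np.sin(th), np.cos(th), 0.0],
                        [0.0, 0.0, 1.0]])
        p73 = rot @ ca73
        rho = np.hypot(p73[0] - ca74[0], p73[1] - ca74[1])
        if rho > bond - 0.3:
            continue
        gap = np.sqrt(bond ** 2 - rho ** 2)
        dz = (ca74[2] - gap) - p73[2]
        cand = lower.transformed(rotation=rot, translation=np.array([0, 0, dz]))
        if cdist(cand.xyz, coil.xyz).min() >= clash:
            if best is None or rho < best[0]:
                best = (rho, cand)
    if best is None:
        raise BuildError("could not dock RH1 block under the coiled coil without clashes")
    return best[1]


def axial_length(s: Structure, selection: tuple[int, int] | None = None) -> float:
    """Extent of (selected) Calpha coordinates along their first principal axis."""
    sub = s if selection is None else s.select(resrange=selection)
    if len(sub) == 0:
        raise ValueError("empty selection")
    x = sub.xyz - sub.xyz.mean(axis=0)
    if len(sub) == 1:
        return 0.0
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    proj = x @ vt[0]
    return float(proj.max() - proj.min())


def max_extent(s: Structure) -> float:
    """Maximum pairwise atom-center distance (model-space Dmax)."""
    if len(s) < 2:
        raise ValueError("max_extent needs at least two atoms")
    return float(pdist(s.xyz).max())


def thickness(s: Structure) -> float:
    """Transverse caliper: maximum pairwise distance perpendicular to the
    first principal axis."""
    x = s.xyz - s.xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    perp = x - np.outer(x @ vt[0], vt[0])
    return float(pdist(perp).max())


def radius_of_gyration(s: Structure, weights: np.ndarray | None = None) -> float:
    w = np.ones(len(s)) if weights is None else np.asarray(weights, float)
    c = np.average(s.xyz, axis=0, weights=w)
    return float(np.sqrt(np.average(((s.xyz - c) ** 2).sum(axis=1), weights=w)))


def chain_symmetry_rmsd(s: Structure) -> float:
    """RMSD of chain A onto chain B after optimal (Kabsch) superposition."""
    a = s.select(chain="A").sorted_by_chain().xyz
    b = s.select(chain="B").sorted_by_chain().xyz
    if len(a) != len(b):
        raise ValueError("chains have different residue counts")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(ac.T @ bc)
    dsign = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, dsign]) @ vt
    diff = ac @ rot - bc
    return float(np.sqrt((diff ** 2).sum() / len(a)))


def principal_axis(s: Structure) -> np.ndarray:
    x = s.xyz - s.xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    v = vt[0]
    return v if v[2] >= 0 else -v


def write_pdb(s: Structure, path) -> None:
    """Write fixed-column ATOM records (chains as built, occ 1.00, B 0.00)."""
    import gemmi

    st = gemmi.Structure()
    st.name = str(s.provenance.get("builder", "model"))
    model = gemmi.Model("1")
    for ch_name in s.chains:
        ch = gemmi.Chain(ch_name)
        sub = s.select(chain=ch_name).sorted_by_chain()
        for i in range(len(sub)):
            res = gemmi.Residue()
            res.name = str(sub.resname[i])
            res.seqid = gemmi.SeqId(int(sub.resnum[i]), " ")
            atom = gemmi.Atom()
            atom.name = str(sub.atomname[i])
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*sub.xyz[i])
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path) -> Structure:
    """Read ATOM records back into a Structure (coordinates to 0.001 A)."""
    import gemmi

    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    chains, resnums, resnames, atomnames, xyz = [], [], [], [], []
    for model in st:
        for ch in model:
            for res in ch:
                for atom in res:
                    chains.append(ch.name)
                    resnums.append(res.seqid.num)
                    resnames.append(res.name)
                    atomnames.append(atom.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break
    if not xyz:
        raise ValueError(f"no ATOM records in {path}")
    return Structure(np.array(chains), np.array(resnums), np.array(resnames),
                     np.array(atomnames), np.array(xyz),
                     provenance={"source": str(path)})
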