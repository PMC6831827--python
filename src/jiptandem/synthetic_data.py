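"""Synthetic inputs: simulated SAXS curves, decoy conformers, fixtures.

The curve simulator emulates a SEC-SAXS setup of the SWING type (12 keV,
1.5 m detector): a linear q grid of 500 points over 0.008-0.5 1/A, a
multiplicative intensity scale, and Gaussian noise with counting-statistics
shape, sigma(q) = k sqrt(I(q)) + floor * I(q), where k is set so the
signal-to-noise at the first point matches a target (default 100).  Decoy
conformers bend the model at the RH1/coil hinge by prescribed angles and
are the ground truth for refinement-recovery tests.

The packaged sequence fixtures are *synthetic stand-ins* for the JIP3/JIP4
N-terminal sequences: they satisfy the constraints the source study states
in prose (region limits, named interface residues, hinge sequence, construct
masses, region identities, heptad composition) but are not the database
sequences; accession ids are recorded in the FASTA headers for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model_builder import BuildError, Structure, max_extent
from .refinement import (ConformerParams, FlexibilityMask, apply_conformer,
                         _has_clash)
from .scattering import ScatteringCurve, debye_intensity
from .sequence_features import SequenceRecord

__all__ = [
    "InstrumentSetup",
    "NoiseModel",
    "simulate_curve",
    "make_decoys",
    "fixture_sequences",
    "fixture_construct",
    "poly_heptad",
    "fixture_manifest",
]

#: JIP3 region annotations (paper numbering) used throughout the pipeline.
JIP3_REGIONS = {
    "nterm": (1, 21),
    "RH1": (22, 73),
    "alpha1": (26, 43),
    "loop": (44, 49),
    "alpha2": (50, 73),
    "hinge": (74, 77),
    "LZI": (74, 177),
    "cterm": (178, 187),
}


@dataclass(frozen=True)
class InstrumentSetup:
    """Linear q grid approximating the SWING SEC-SAXS configuration."""

    q_min: float = 0.008
    q_max: float = 0.5
    n_points: int = 500

    def __post_init__(self) -> None:
        if not 0 <= self.q_min < self.q_max:
            raise ValueError("need 0 <= q_min < q_max")
        if self.n_points < 50:
            raise ValueError("need at least 50 points")

    def grid(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_points)

    @staticmethod
    def q_from_geometry(energy_kev: float, distance_m: float,
                        r_detector_m: float) -> float:
        """q (1/A) at a detector radius: q = (4 pi / lambda) sin(theta/2)."""
        wavelength_a = 12.39842 / energy_kev
        theta = np.arctan2(r_detector_m, distance_m)
        return float(4.0 * np.pi / wavelength_a * np.sin(theta / 2.0))


@dataclass(frozen=True)
class NoiseModel:
    """Counting-statistics-shaped Gaussian noise.

    sigma(q) = k sqrt(I(q)) + relative_floor * I(q), with k fixed by the
    target signal-to-noise ratio at the first grid point.
    """

    snr_at_qmin: float = 100.0
    relative_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_at_qmin <= 0 or self.relative_floor < 0:
            raise ValueError("invalid noise parameters")

    def sigma(self, I: np.ndarray) -> np.ndarray:
        I = np.asarray(I, float)
        k = np.sqrt(I[0]) / self.snr_at_qmin
        return k * np.sqrt(np.clip(I, 0.0, None)) + self.relative_floor * I


def simulate_curve(s: Structure,
                   setup: InstrumentSetup | None = None,
                   noise: NoiseModel | None = None,
                   i0_scale: float = 1.0,
                   add_noise: bool = True) -> ScatteringCurve:
    """Simulated SEC-SAXS curve of a structure (seed-reproducible)."""
    setup = setup or InstrumentSetup()
    noise = noise or NoiseModel()
    q = setup.grid()
    ideal = debye_intensity(s, q, method="histogram")
    I = ideal.I * i0_scale / ideal.I[0]
    sigma = noise.sigma(I)
    if add_noise:
        rng = np.random.default_rng(noise.seed)
        I = I + rng.normal(0.0, sigma)
    return ScatteringCurve(q, I, sigma, metadata={
        "source": "simulated", "seed": noise.seed, "snr_at_qmin": noise.snr_at_qmin,
        "i0_scale": i0_scale, "noisy": add_noise,
    })


def make_decoys(s: Structure, mask: FlexibilityMask | None = None,
                bend_angles_deg=(10.0, 20.0, 30.0),
                clash_cutoff: float = 2.5) -> list[Structure]:
    """One clash-free hinge-bent conformer per requested angle."""
    mask = mask or FlexibilityMask()
    out = []
    for angle in bend_angles_deg:
        cand = apply_conformer(s, ConformerParams(hinge_bend=(0.0, float(angle))),
                               mask)
        if _has_clash(cand, mask, clash_cutoff):
            raise BuildError(f"decoy at {angle} deg bend clashes")
        cand.provenance["decoy_bend_deg"] = float(angle)
        out.append(cand)
    return out


def _data_path(name: str):
    return resources.files("jiptandem.data").joinpath(name)


def fixture_sequences() -> dict[str, SequenceRecord]:
    """Packaged synthetic JIP3/JIP4 N-terminal records, keyed by name."""
    from .sequence_features import read_fasta

    with resources.as_file(_data_path("fixtures_synthetic.fasta")) as p:
        records = read_fasta(p)
    out = {}
    for rec in records:
        key = rec.id.split("_")[0] + ("_mouse" if "MOUSE" in rec.id else "")
        out[key] = rec
    return out


def fixture_construct(which: str = "JIP3", nterm_extra: str = "GSH",
                      start: int = 22, end: int = 187) -> SequenceRecord:
    """The expression construct: tag remnant + residues ``start..end``.

    Tag residues are numbered immediately before ``start`` (19-21 for GSH
    ahead of residue 22), preserving paper numbering for the body.
    """
    rec = fixture_sequences()[which]
    body = rec.residues[start - 1:end]
    return SequenceRecord(
        id=f"{rec.id}_construct[{start}-{end}]",
        residues=nterm_extra + body,
        first_residue_number=start - len(nterm_extra),
        description=f"{nterm_extra}+[{start}-{end}] expression construct",
    )


def poly_heptad(n_repeats: int, repeat: str = "LEALEGK") -> SequenceRecord:
    """Synthetic (LEALEGK)n test sequence: L at heptad a/d by construction."""
    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    return SequenceRecord(id=f"polyheptad_{n_repeats}x{repeat}",
                          residues=repeat * n_repeats)


def fixture_manifest() -> dict[str, str]:
    """SHA-256 checksums pinning the packaged fixture contents."""
    out = {}
    for name in ("fixtures_synthetic.fasta",):
        data = _data_path(name).read_bytes()
        out[name] = hashlib.sha256(data).hexdigest()
    return out
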