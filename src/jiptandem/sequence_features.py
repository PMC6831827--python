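"""Region bookkeeping on annotated protein sequences.

The JIP3/JIP4 N-terminus is handled as a set of fixed, length-matched
regions in the numbering of the full protein (1-based): the RH1 four-helix
bundle domain (JIP3 residues 22-73), the LZI leucine-zipper coiled coil
(74-177, fourteen heptad repeats), and the flanking termini.  Everything in
this module is plain positional arithmetic on those regions: ungapped
identities, heptad counting and register assignment, helix-residue
bookkeeping from CD helix fractions, and average-mass sums for construct
masses as printed in biophysics tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SequenceRecord",
    "RegionAnnotation",
    "extract_region",
    "percent_identity_ungapped",
    "count_complete_heptads",
    "assign_heptad_register",
    "best_heptad_phase",
    "helix_residue_count",
    "sequence_mass_kda",
    "sequence_mass_da",
    "read_fasta",
    "write_fasta",
    "AVERAGE_RESIDUE_MASS_DA",
    "WATER_MASS_DA",
]

#: Average (not monoisotopic) residue masses in Da, i.e. amino-acid mass
#: minus one water; a peptide mass is the residue sum plus one water.
AVERAGE_RESIDUE_MASS_DA = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS_DA = 18.0153

_HEPTAD = "abcdefg"
#: Residues counted as coiled-coil-core hydrophobics at heptad a/d.
CORE_HYDROPHOBICS = "ILVMF"


@dataclass(frozen=True)
class SequenceRecord:
    """A one-letter amino-acid sequence anchored to paper numbering.

    ``first_residue_number`` is the 1-based number of the first residue in
    the full-length protein, so a record for JIP3 LZI has
    ``first_residue_number=74`` and residue numbers 74..177.
    """

    id: str
    residues: str
    first_residue_number: int = 1
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(AVERAGE_RESIDUE_MASS_DA)
        if bad:
            raise ValueError(f"non-standard residue codes in {self.id!r}: {sorted(bad)}")
        if self.first_residue_number < 1:
            raise ValueError("first_residue_number must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.residues) - 1

    def residue_at(self, number: int) -> str:
        """One-letter code at a paper residue number."""
        if not self.first_residue_number <= number <= self.last_residue_number:
            raise ValueError(f"residue {number} outside {self.id!r} "
                             f"[{self.first_residue_number}-{self.last_residue_number}]")
        return self.residues[number - self.first_residue_number]


@dataclass(frozen=True)
class RegionAnnotation:
    """An inclusive residue range with a semantic label (RH1, LZI, hinge, ...)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name!r}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


def extract_region(seq: SequenceRecord, region: RegionAnnotation) -> SequenceRecord:
    """Slice ``region`` out of ``seq``, keeping paper numbering."""
    if region.start < seq.first_residue_number or region.end > seq.last_residue_number:
        raise ValueError(
            f"region {region.name!r} [{region.start}-{region.end}] outside "
            f"{seq.id!r} [{seq.first_residue_number}-{seq.last_residue_number}]")
    lo = region.start - seq.first_residue_number
    hi = region.end - seq.first_residue_number + 1
    return SequenceRecord(
        id=f"{seq.id}/{region.name}[{region.start}-{region.end}]",
        residues=seq.residues[lo:hi],
        first_residue_number=region.start,
        description=seq.description,
    )


def percent_identity_ungapped(a: SequenceRecord, b: SequenceRecord) -> float:
    """Position-by-position identity of two equal-length records, in percent.

    The fixed region pairs compared here (e.g. JIP3 RH1 [22-73] against
    JIP4 RH1 [17-68]) are length-matched by construction, so no alignment
    is performed.  Reported to one decimal, as identities are printed.
    """
    if len(a) != len(b):
        raise ValueError(f"ungapped identity needs equal lengths: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty sequences")
    same = sum(x == y for x, y in zip(a.residues, b.residues))
    return round(100.0 * same / len(a), 1)


def count_complete_heptads(region_length: int) -> int:
    """Number of complete abcdefg repeats in a region of given length."""
    if region_length < 0:
        raise ValueError("region length must be >= 0")
    return region_length // 7


def assign_heptad_register(region: SequenceRecord, phase_of_first: str) -> str:
    """Cyclic ``abcdefg`` register string for ``region``.

    ``phase_of_first`` is the heptad letter of the region's first residue.
    """
    if phase_of_first not in _HEPTAD:
        raise ValueError(f"heptad phase must be one of {_HEPTAD!r}, got {phase_of_first!r}")
    k = _HEPTAD.index(phase_of_first)
    return "".join(_HEPTAD[(k + i) % 7] for i in range(len(region)))


def best_heptad_phase(region: SequenceRecord,
                      hydrophobics: str = CORE_HYDROPHOBICS) -> tuple[str, float]:
    """Phase maximizing the hydrophobic fraction at core a/d positions.

    Scans all seven phases and returns ``(phase, fraction)``; ties break on
    the earlier heptad letter so the choice is deterministic.
    """
    best: tuple[str, float] | None = None
    for phase in _HEPTAD:
        reg = assign_heptad_register(region, phase)
        core = [aa for aa, r in zip(region.residues, reg) if r in "ad"]
        frac = sum(aa in hydrophobics for aa in core) / len(core) if core else 0.0
        if best is None or frac > best[1]:
            best = (phase, frac)
    assert best is not None
    return best


def helix_residue_count(helix_fraction: float, n_residues: int) -> int:
    """Residue count corresponding to a CD helix percentage."""
    if not 0.0 <= helix_fraction <= 100.0:
        raise ValueError("helix fraction must be in [0, 100]")
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    return round(helix_fraction / 100.0 * n_residues)


def sequence_mass_da(seq: SequenceRecord, nterm_extra: str = "GSH") -> float:
    """Average-mass molecular weight in Da of ``nterm_extra + seq`` plus one water.

    ``nterm_extra`` defaults to the Gly-Ser-His left on the construct after
    thrombin cleavage of the expression tag.
    """
    try:
        extra = sum(AVERAGE_RESIDUE_MASS_DA[a] for a in nterm_extra)
        body = sum(AVERAGE_RESIDUE_MASS_DA[a] for a in seq.residues)
    except KeyError as exc:  # pragma: no cover - SequenceRecord already validates
        raise ValueError(f"unknown residue code {exc.args[0]!r}") from exc
    return extra + body + WATER_MASS_DA


def sequence_mass_kda(seq: SequenceRecord, nterm_extra: str = "GSH") -> float:
    """Construct mass in kDa, rounded to one decimal (table presentation)."""
    return round(sequence_mass_da(seq, nterm_extra) / 1000.0, 1)


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords (numbering starts at 1)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper(),
                                      description=rec.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord as BioRecord

    bio = [BioRecord(Seq(r.residues), id=r.id, description=r.description) for r in records]
    seqio_write(bio, str(path), "fasta")
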