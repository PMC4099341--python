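"""Protein sequence handling, tryptic digestion and monoisotopic mass arithmetic.

Trypsin cleaves C-terminal to Lys and Arg.  Two situations suppress a
cleavage here: the classical proline rule (no cleavage before Pro, on by
default) and chemical blocking of a lysine side chain, e.g. by an
amine-reactive crosslinker, which removes the residue from trypsin's
substrate repertoire entirely.  Blocked lysines therefore never count as
missed cleavages: the missed-cleavage budget applies only to cleavable
(unblocked) internal sites.

All residue numbering is 1-based and inclusive, in "protein numbering",
i.e. shifted by the configured offset of the first residue so that positions
can be compared directly against published residue numbers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

from Bio import SeqIO

__all__ = [
    "N_TERMINUS",
    "ResidueMassTable",
    "ProteinSpec",
    "Peptide",
    "DigestParams",
    "tryptic_digest",
    "peptide_mono_mass",
    "mh_plus",
]

#: Pseudo-site for the protein N-terminal alpha-amine, distinct from any
#: residue position.  Amine-reactive crosslinkers hit it like a Lys side chain.
N_TERMINUS = "N"

#: A crosslinkable site: a residue position or the N-terminal pseudo-site.
Site = Union[int, str]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

WATER_MONO = 18.010565
PROTON_MONO = 1.0072765
CARBAMIDOMETHYL = 57.02146


def _load_default_masses() -> dict[str, float]:
    text = (
        importlib.resources.files("oligoxl.data")
        .joinpath("monoisotopic_masses.tsv")
        .read_text()
    )
    masses: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, mass = line.split("\t")
        masses[residue] = float(mass)
    return masses


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic masses of the 20 canonical residues plus constants.

    ``fixed_modifications`` holds per-residue mass deltas applied exactly
    once to every occurrence of the residue; the default is
    carbamidomethylation of Cys (+57.02146 Da) from iodoacetamide
    alkylation after reduction.
    """

    residue_masses: Mapping[str, float]
    water: float = WATER_MONO
    proton: float = PROTON_MONO
    fixed_modifications: Mapping[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )

    def __post_init__(self) -> None:
        missing = set(CANONICAL_RESIDUES) - set(self.residue_masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")

    @classmethod
    def default(cls) -> "ResidueMassTable":
        """Table loaded from the plain-text data file shipped with the package."""
        return cls(residue_masses=_load_default_masses())

    def residue_mass(self, residue: str) -> float:
        try:
            base = self.residue_masses[residue]
        except KeyError:
            raise ValueError(f"unknown residue code {residue!r}") from None
        return base + self.fixed_modifications.get(residue, 0.0)

    def sequence_mass(self, sequence: str) -> float:
        """Neutral monoisotopic mass of a linear peptide (residues + water)."""
        return sum(self.residue_mass(c) for c in sequence) + self.water


@dataclass(frozen=True)
class ProteinSpec:
    """Target sequence with numbering, reactive amine sites and exclusions.

    ``offset`` is the protein number of the first residue in ``sequence``
    (1 unless a construct is numbered against a parent sequence).
    ``excluded_sites`` are positions whose covering peptides are flagged
    unobservable — e.g. a heterogeneously glycosylated Asn whose tryptic
    fragments never show up in MALDI fingerprints.
    """

    identifier: str
    sequence: str
    offset: int = 1
    excluded_sites: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(CANONICAL_RESIDUES)
        if bad:
            raise ValueError(f"non-canonical residues in sequence: {sorted(bad)}")
        if not seq:
            raise ValueError("empty sequence")
        for pos in self.excluded_sites:
            if not (self.offset <= pos <= self.last):
                raise ValueError(
                    f"excluded position {pos} outside [{self.offset}, {self.last}]"
                )

    @property
    def last(self) -> int:
        return self.offset + len(self.sequence) - 1

    def residue_at(self, position: int) -> str:
        if not (self.offset <= position <= self.last):
            raise ValueError(f"position {position} outside protein numbering")
        return self.sequence[position - self.offset]

    def slice(self, start: int, end: int) -> str:
        """Sequence of residues ``start..end`` inclusive, protein numbering."""
        if not (self.offset <= start <= end <= self.last):
            raise ValueError(f"range {start}-{end} outside protein numbering")
        return self.sequence[start - self.offset : end - self.offset + 1]

    @property
    def lysine_positions(self) -> tuple[int, ...]:
        return tuple(
            i + self.offset for i, c in enumerate(self.sequence) if c == "K"
        )

    @property
    def reactive_sites(self) -> tuple[Site, ...]:
        """N-terminal alpha-amine plus every lysine epsilon-amine."""
        return (N_TERMINUS, *self.lysine_positions)

    @classmethod
    def from_fasta(
        cls,
        path,
        offset: int = 1,
        excluded_sites: Iterable[int] = (),
    ) -> "ProteinSpec":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected exactly one FASTA record in {path}, found {len(records)}"
            )
        rec = records[0]
        return cls(
            identifier=rec.id,
            sequence=str(rec.seq),
            offset=offset,
            excluded_sites=frozenset(excluded_sites),
        )


@dataclass(frozen=True, order=True)
class Peptide:
    """A tryptic fragment in protein numbering (1-based, inclusive).

    ``missed_cleavages`` counts internal cleavable sites that trypsin
    skipped, i.e. excluding crosslinker-blocked lysines and (with the
    proline rule) K/R followed by P.
    """

    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    contains_excluded_site: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("peptide end before start")
        if self.sequence and len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match residue range")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    def overlaps(self, other: "Peptide") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings threaded through candidate enumeration."""

    max_unmodified_missed: int = 1
    proline_rule: bool = True


def cleavage_positions(
    protein: ProteinSpec,
    blocked_sites: frozenset[int] | set[int] = frozenset(),
    proline_rule: bool = True,
) -> tuple[int, ...]:
    """Positions after which trypsin cleaves (excluding the C-terminus)."""
    blocked = set(blocked_sites)
    bad = blocked - set(protein.lysine_positions)
    if bad:
        raise ValueError(f"blocked positions are not lysines: {sorted(bad)}")
    cuts = []
    for pos in range(protein.offset, protein.last):  # last residue is a boundary anyway
        res = protein.residue_at(pos)
        if res not in "KR":
            continue
        if pos in blocked:
            continue
        if proline_rule and protein.residue_at(pos + 1) == "P":
            continue
        cuts.append(pos)
    return tuple(cuts)


def tryptic_digest(
    protein: ProteinSpec,
    blocked_sites: frozenset[int] | set[int] = frozenset(),
    max_unmodified_missed: int = 1,
    proline_rule: bool = True,
) -> list[Peptide]:
    """Tryptic peptides with up to ``max_unmodified_missed`` skipped cuts.

    ``blocked_sites`` are lysines chemically modified (e.g. crosslinked)
    and hence invisible to trypsin: they are obligatory missed cleavages
    and do not consume the missed-cleavage budget.

    Raises ``ValueError`` if a blocked position is not a lysine.
    """
    if max_unmodified_missed < 0:
        raise ValueError("max_unmodified_missed must be >= 0")
    cuts = cleavage_positions(protein, blocked_sites, proline_rule)
    starts = [protein.offset] + [c + 1 for c in cuts]
    ends = list(cuts) + [protein.last]
    peptides = []
    for i, start in enumerate(starts):
        for j in range(i, min(i + max_unmodified_missed, len(ends) - 1) + 1):
            end = ends[j]
            peptides.append(
                Peptide(
                    start=start,
                    end=end,
                    sequence=protein.slice(start, end),
                    missed_cleavages=j - i,
                    contains_excluded_site=any(
                        start <= p <= end for p in protein.excluded_sites
                    ),
                )
            )
    return peptides


def peptide_mono_mass(
    peptide: Peptide | str, table: ResidueMassTable | None = None
) -> float:
    """Neutral monoisotopic mass (Da) including fixed modifications and water."""
    table = table or ResidueMassTable.default()
    sequence = peptide if isinstance(peptide, str) else peptide.sequence
    if not sequence:
        raise ValueError("peptide has no sequence to compute a mass from")
    return table.sequence_mass(sequence)


def mh_plus(neutral_mass: float, table: ResidueMassTable | None = None) -> float:
    """Singly protonated [M+H]+ m/z from a neutral mass."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    table = table or ResidueMassTable.default()
    return neutral_mass + table.proton
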