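"""Crosslinker profiles and enumeration of theoretical crosslinked-peptide masses.

A homobifunctional amine-reactive crosslinker such as dimethylsuberimidate
(DMS) joins two primary amines — lysine epsilon-amines or the protein
N-terminal alpha-amine.  Two product topologies matter for peptide mass
fingerprinting:

* a **loop-link**, both ends attached within one tryptic peptide;
* a **cross-link**, joining two distinct tryptic peptides (possibly two
  copies of the same peptide from different subunits of an oligomer).

A crosslinked lysine is no longer a trypsin substrate, so it must sit at
an internal (non-cleaved) position of its peptide; conversely every
additional unmodified internal K/R consumes the missed-cleavage budget.
Site choices that yield the same mass are collapsed into a single
candidate carrying an ambiguity set (rendered ``190/193-200``), never
silently resolved.

Two DMS profiles ship.  ``dms`` adds 208.0534 Da per crosslink — the
monoisotopic mass of C8H14N2Cl2 (the dihydrochloride minus two methanol
leaving groups) — which is the constant that reproduces published MALDI
assignment tables produced with classic assignment software.  ``dms-amidine``
adds 136.1000 Da (C8H12N2), the bridge expected from clean amidination
chemistry.  The table-consistent profile is the default; see the methods
note for the discrepancy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .digest import (
    N_TERMINUS,
    DigestParams,
    Peptide,
    ProteinSpec,
    ResidueMassTable,
    Site,
    cleavage_positions,
    mh_plus,
    peptide_mono_mass,
    tryptic_digest,
)

__all__ = [
    "CrosslinkerProfile",
    "CrosslinkCandidate",
    "Ledger",
    "LedgerEntry",
    "dms_profile",
    "dms_amidine_profile",
    "get_profile",
    "enumerate_loop_links",
    "enumerate_cross_links",
    "build_ledger",
]

#: Monoisotopic mass of C8H14N2Cl2 (DMS·2HCl minus two CH3OH leaving groups).
DMS_BRIDGE_TABLE = 208.053404
#: Monoisotopic mass of C8H12N2, the amidine bridge of textbook DMS chemistry.
DMS_BRIDGE_AMIDINE = 136.100048

#: Candidates closer than this (Da) are merged into one ledger entry.
LEDGER_MERGE_DA = 0.001


@dataclass(frozen=True)
class CrosslinkerProfile:
    """Geometry and mass bookkeeping for a homobifunctional amine crosslinker."""

    name: str
    bridge_mass: float  # Da added per formed crosslink
    arm_length: float  # A, spacer between the two reactive ends
    side_chain_reach: float = 6.5  # A, Lys side-chain contribution per end
    reactive_residues: frozenset[str] = frozenset({"K"})
    links_n_terminus: bool = True

    def __post_init__(self) -> None:
        if self.bridge_mass <= 0:
            raise ValueError("bridge mass must be positive")

    @property
    def max_span(self) -> float:
        """Maximum Calpha-Calpha distance bridgeable: arm + 2x side-chain reach."""
        return self.arm_length + 2.0 * self.side_chain_reach


def dms_profile() -> CrosslinkerProfile:
    """DMS with the bridge constant that reproduces published MALDI tables.

    Max span 24.0 A: 11 A arm plus two 6.5 A lysine side chains.
    """
    return CrosslinkerProfile(name="dms", bridge_mass=DMS_BRIDGE_TABLE, arm_length=11.0)


def dms_amidine_profile() -> CrosslinkerProfile:
    """DMS with the chemically expected amidine bridge (C8H12N2)."""
    return CrosslinkerProfile(
        name="dms-amidine", bridge_mass=DMS_BRIDGE_AMIDINE, arm_length=11.0
    )


_PROFILES = {
    "dms": dms_profile,
    "dms-amidine": dms_amidine_profile,
}


def get_profile(name: str) -> CrosslinkerProfile:
    try:
        return _PROFILES[name.lower()]()
    except KeyError:
        raise ValueError(
            f"unknown crosslinker {name!r}; available: {sorted(_PROFILES)}"
        ) from None


def _site_key(site: Site) -> tuple[int, int]:
    # N-terminal pseudo-site sorts before every residue position
    return (0, 0) if site == N_TERMINUS else (1, int(site))


def _render_sites(sites: set[Site]) -> str:
    return "/".join(str(s) for s in sorted(sites, key=_site_key))


@dataclass(frozen=True)
class CrosslinkCandidate:
    """A theoretical loop- or cross-link with its exact [M+H]+ mass.

    ``site_pairs`` lists every mass-identical placement of the two
    crosslinker ends; the first member of each pair belongs to
    ``peptides[0]`` and the second to ``peptides[-1]``.
    """

    kind: str  # "loop" | "cross"
    peptides: tuple[Peptide, ...]
    site_pairs: tuple[tuple[Site, Site], ...]
    mz: float
    observable: bool = True
    self_pair: bool = False  # same peptide twice: inter-subunit only

    def __post_init__(self) -> None:
        if self.kind not in ("loop", "cross"):
            raise ValueError(f"bad candidate kind {self.kind!r}")
        if self.kind == "loop" and len(self.peptides) != 1:
            raise ValueError("loop candidate must have exactly one peptide")
        if self.kind == "cross" and len(self.peptides) != 2:
            raise ValueError("cross candidate must have exactly two peptides")
        if not self.site_pairs:
            raise ValueError("candidate without any site placement")

    @property
    def sites_label(self) -> str:
        """Per-end ambiguity sets, e.g. ``190/193-200``."""
        left = {p[0] for p in self.site_pairs}
        right = {p[1] for p in self.site_pairs}
        return f"{_render_sites(left)}-{_render_sites(right)}"

    @property
    def peptides_label(self) -> str:
        return ", ".join(p.label for p in self.peptides)

    @property
    def all_sites(self) -> frozenset[Site]:
        return frozenset(s for pair in self.site_pairs for s in pair)

    def overlapping_peptides(self) -> bool:
        if self.kind != "cross":
            return False
        a, b = self.peptides
        return a.overlaps(b)

    @classmethod
    def from_intervals(
        cls,
        mz: float,
        intervals: tuple[tuple[int, int], ...],
        site_pairs: tuple[tuple[Site, Site], ...],
    ) -> "CrosslinkCandidate":
        """Candidate from printed residue ranges, without sequences.

        Supports classifying published assignment tables where only the
        peptide intervals, sites and theoretical m/z are known.
        """
        peptides = tuple(Peptide(start=s, end=e, sequence="") for s, e in intervals)
        kind = "loop" if len(peptides) == 1 else "cross"
        self_pair = kind == "cross" and peptides[0].interval == peptides[1].interval
        return cls(
            kind=kind,
            peptides=peptides,
            site_pairs=site_pairs,
            mz=mz,
            self_pair=self_pair,
        )


def _eligible_sites(
    fragment: Peptide, protein: ProteinSpec, linker: CrosslinkerProfile
) -> list[Site]:
    """Crosslinkable sites on a tryptic fragment.

    A reactive residue qualifies only at an internal position: a residue
    at the peptide C-terminus was cleaved by trypsin, hence unmodified —
    except at the protein C-terminus, which is a chain end, not a cut.
    """
    sites: list[Site] = []
    if linker.links_n_terminus and fragment.start == protein.offset:
        sites.append(N_TERMINUS)
    for pos in range(fragment.start, fragment.end + 1):
        if protein.residue_at(pos) not in linker.reactive_residues:
            continue
        if pos == fragment.end and pos != protein.last:
            continue
        sites.append(pos)
    return sites


def _internal_cleavable(
    fragment: Peptide, cuts: tuple[int, ...]
) -> tuple[int, ...]:
    return tuple(c for c in cuts if fragment.start <= c < fragment.end)


def _fragments_for_enumeration(
    protein: ProteinSpec, params: DigestParams, extra_budget: int
) -> list[Peptide]:
    # crosslinked Lys are obligatory missed cleavages on top of the
    # unmodified budget; enumerate fragments generously, filter per candidate
    return tryptic_digest(
        protein,
        blocked_sites=frozenset(),
        max_unmodified_missed=params.max_unmodified_missed + extra_budget,
        proline_rule=params.proline_rule,
    )


def enumerate_loop_links(
    protein: ProteinSpec,
    linker: CrosslinkerProfile,
    params: DigestParams = DigestParams(),
    table: ResidueMassTable | None = None,
) -> list[CrosslinkCandidate]:
    """All loop-link candidates: both crosslinker ends within one peptide."""
    table = table or ResidueMassTable.default()
    cuts = cleavage_positions(protein, proline_rule=params.proline_rule)
    candidates = []
    for frag in _fragments_for_enumeration(protein, params, extra_budget=2):
        sites = _eligible_sites(frag, protein, linker)
        if len(sites) < 2:
            continue
        cleavable = set(_internal_cleavable(frag, cuts))
        valid_pairs = []
        for i, j in itertools.combinations(sites, 2):
            blocked = len({i, j} & cleavable)
            if len(cleavable) - blocked <= params.max_unmodified_missed:
                valid_pairs.append((i, j))
        if not valid_pairs:
            continue
        mz = mh_plus(peptide_mono_mass(frag, table) + linker.bridge_mass, table)
        candidates.append(
            CrosslinkCandidate(
                kind="loop",
                peptides=(frag,),
                site_pairs=tuple(valid_pairs),
                mz=mz,
                observable=not frag.contains_excluded_site,
            )
        )
    return candidates


def enumerate_cross_links(
    protein: ProteinSpec,
    linker: CrosslinkerProfile,
    params: DigestParams = DigestParams(),
    table: ResidueMassTable | None = None,
) -> list[CrosslinkCandidate]:
    """All cross-link candidates between unordered peptide pairs.

    Pairs with overlapping residue intervals — and a peptide paired with
    itself — are emitted: on a single chain they are impossible, which is
    exactly what makes them diagnostic of inter-subunit contacts, and that
    classification happens downstream.
    """
    table = table or ResidueMassTable.default()
    cuts = cleavage_positions(protein, proline_rule=params.proline_rule)
    fragments = _fragments_for_enumeration(protein, params, extra_budget=1)

    # per-fragment: sites valid as the single crosslinked site
    frag_info = []
    for frag in fragments:
        cleavable = set(_internal_cleavable(frag, cuts))
        ok_sites = [
            s
            for s in _eligible_sites(frag, protein, linker)
            if len(cleavable) - (1 if s in cleavable else 0)
            <= params.max_unmodified_missed
        ]
        if ok_sites:
            frag_info.append((frag, ok_sites))

    candidates = []
    for (a, sites_a), (b, sites_b) in itertools.combinations_with_replacement(
        frag_info, 2
    ):
        self_pair = a.interval == b.interval
        if self_pair:
            pairs = tuple(
                (i, j)
                for i, j in itertools.combinations_with_replacement(
                    sorted(sites_a, key=_site_key), 2
                )
            )
        else:
            pairs = tuple(itertools.product(sites_a, sites_b))
        mz = mh_plus(
            peptide_mono_mass(a, table)
            + peptide_mono_mass(b, table)
            + linker.bridge_mass,
            table,
        )
        candidates.append(
            CrosslinkCandidate(
                kind="cross",
                peptides=(a, b),
                site_pairs=pairs,
                mz=mz,
                observable=not (
                    a.contains_excluded_site or b.contains_excluded_site
                ),
                self_pair=self_pair,
            )
        )
    return candidates


@dataclass(frozen=True)
class LedgerEntry:
    """One theoretical mass with every candidate explanation within 0.001 Da."""

    mz: float
    candidates: tuple[CrosslinkCandidate, ...]

    @property
    def observable(self) -> bool:
        return any(c.observable for c in self.candidates)


@dataclass(frozen=True)
class Ledger:
    """Mass-sorted list of theoretical crosslink candidates."""

    entries: tuple[LedgerEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(e.mz for e in self.entries)

    def to_frame(self):
        """Tabular view mirroring published assignment-table columns."""
        import pandas as pd

        rows = []
        for entry in self.entries:
            for cand in entry.candidates:
                rows.append(
                    {
                        "sites": cand.sites_label,
                        "peptides": cand.peptides_label,
                        "sequences": "; ".join(p.sequence for p in cand.peptides),
                        "kind": cand.kind,
                        "theoretical_mz": round(entry.mz, 4),
                        "observable": cand.observable,
                        "self_pair": cand.self_pair,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "sites",
                "peptides",
                "sequences",
                "kind",
                "theoretical_mz",
                "observable",
                "self_pair",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def find(self, mz: float, tol_da: float = 0.01) -> LedgerEntry | None:
        best = None
        for entry in self.entries:
            d = abs(entry.mz - mz)
            if d <= tol_da and (best is None or d < abs(best.mz - mz)):
                best = entry
        return best


def build_ledger(
    protein: ProteinSpec,
    linker: CrosslinkerProfile,
    params: DigestParams = DigestParams(),
    table: ResidueMassTable | None = None,
) -> Ledger:
    """Union of loop- and cross-link candidates, mass-sorted and merged.

    Candidates within 0.001 Da collapse into one entry listing every
    explanation; isobaric assignments stay visibly ambiguous.
    """
    table = table or ResidueMassTable.default()
    cands = enumerate_loop_links(protein, linker, params, table)
    cands += enumerate_cross_links(protein, linker, params, table)
    cands.sort(key=lambda c: c.mz)
    entries: list[LedgerEntry] = []
    group: list[CrosslinkCandidate] = []
    for cand in cands:
        if group and cand.mz - group[0].mz > LEDGER_MERGE_DA:
            entries.append(LedgerEntry(mz=group[0].mz, candidates=tuple(group)))
            group = []
        group.append(cand)
    if group:
        entries.append(LedgerEntry(mz=group[0].mz, candidates=tuple(group)))
    return Ledger(entries=tuple(entries))
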