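"""Shared fixtures: the published peptide region, crosslinker profiles and
the published assignment tables (masses, peptide intervals, site pairs)."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from oligoxl import (
    CrosslinkCandidate,
    LedgerEntry,
    MassMatch,
    ProteinSpec,
    ResidueMassTable,
    dms_profile,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("deterministic")

#: Region of the glycine-binding protein printed with its crosslink
#: assignments: FILKEEKDLR (187-196), EEKDLR (191-196), DLRYCTKHYNTGK
#: (194-206), treated as a mini-protein with offset 187.
REGION_SEQUENCE = "FILKEEKDLRYCTKHYNTGK"
REGION_OFFSET = 187


@pytest.fixture
def table() -> ResidueMassTable:
    return ResidueMassTable.default()


@pytest.fixture
def region() -> ProteinSpec:
    return ProteinSpec("region-187-206", REGION_SEQUENCE, offset=REGION_OFFSET)


@pytest.fixture
def dms():
    return dms_profile()


@pytest.fixture
def region_linker(dms):
    # the region is an excised window: residue 187 is not a protein
    # N-terminus, so the alpha-amine pseudo-site does not apply
    return dataclasses.replace(dms, links_n_terminus=False)


# Published monomer-band assignments: (theoretical m/z, peptide intervals,
# site pairs).  "N" is the protein N-terminal alpha-amine.
MONOMER_TABLE = [
    (1498.795, ((187, 196),), ((190, 193),)),
    (2268.040, ((191, 196), (197, 206)), ((193, 200),)),
    (2357.048, ((197, 213),), ((200, 206),)),
    (2430.195, ((1, 2), (3, 20)), (("N", 6), ("N", 16))),
    (2593.214, ((191, 196), (201, 213)), ((193, 206),)),
    (2652.252, ((191, 196), (194, 206)), ((193, 200),)),
    (3145.452, ((191, 200), (201, 213)), ((193, 206),)),
    (3153.584, ((187, 196), (194, 206)), ((190, 200), (193, 200))),
    (3204.489, ((191, 200), (194, 206)), ((193, 200),)),
    (3478.711, ((3, 16), (105, 119)), ((6, 116),)),
    (3646.783, ((187, 196), (197, 213)), ((190, 200), (190, 206), (193, 200), (193, 206))),
    (3705.849, ((1, 16), (105, 119)), (("N", 116), (6, 116))),
]

# Oligomer-band assignments: every monomer-band mass plus six masses unique
# to the oligomer band.
OLIGOMER_ONLY_TABLE = [
    (2385.159, ((187, 193), (197, 206)), ((190, 200),)),
    (2769.371, ((187, 193), (194, 206)), ((190, 200),)),
    (3230.549, ((105, 119), (197, 206)), ((116, 200),)),
    (3262.571, ((187, 193), (197, 213)), ((190, 200), (190, 206))),
    (3555.724, ((105, 119), (201, 213)), ((116, 206),)),
    (3614.761, ((105, 119), (194, 206)), ((116, 200),)),
]

OLIGOMER_TABLE = MONOMER_TABLE + OLIGOMER_ONLY_TABLE

#: Oligomer-band masses absent from the monomer band (inter by band evidence).
OLIGOMER_UNIQUE_MZS = {mz for mz, _, _ in OLIGOMER_ONLY_TABLE}

#: Masses whose only explanations pair overlapping peptides (inter by logic).
OVERLAP_FORCED_MZS = {2652.252, 3153.584, 3204.489}


def oracle_digest(sequence, offset, blocked, max_missed, proline_rule=True):
    """Independent digestion oracle: brute force over all substrings.

    Both ends must be cleavage boundaries and the interior must respect
    the unmodified missed-cleavage budget.  Returns (start, end, missed).
    """

    def cleavable(pos):  # pos in protein numbering
        res = sequence[pos - offset]
        if res not in "KR" or pos in blocked:
            return False
        if pos == offset + len(sequence) - 1:
            return False
        if proline_rule and sequence[pos - offset + 1] == "P":
            return False
        return True

    last = offset + len(sequence) - 1
    out = set()
    for start in range(offset, last + 1):
        for end in range(start, last + 1):
            if start != offset and not cleavable(start - 1):
                continue
            if end != last and not cleavable(end):
                continue
            internal = sum(cleavable(p) for p in range(start, end))
            if internal <= max_missed:
                out.add((start, end, internal))
    return out


def find_candidate(ledger, intervals):
    """Ledger candidate whose peptide intervals match exactly, or None."""
    intervals = tuple(sorted(intervals))
    for entry in ledger:
        for cand in entry.candidates:
            if tuple(sorted(p.interval for p in cand.peptides)) == intervals:
                return cand
    return None


def table_matches(rows, band):
    """MassMatch lists for published table rows, sharing one pseudo-ledger."""
    entries = {}
    for mz, intervals, pairs in rows:
        if mz not in entries:
            entries[mz] = LedgerEntry(
                mz=mz,
                candidates=(
                    CrosslinkCandidate.from_intervals(mz, intervals, pairs),
                ),
            )
    return [
        MassMatch(observed=mz, band=band, assignments=((entries[mz], 0.0),))
        for mz, _, _ in rows
    ]


@pytest.fixture
def monomer_table_matches():
    return table_matches(MONOMER_TABLE, "monomer")


@pytest.fixture
def oligomer_table_matches():
    return table_matches(OLIGOMER_TABLE, "oligomer")
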