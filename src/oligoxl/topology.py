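"""Intra- vs inter-subunit classification of matched crosslinks.

Two independent rules, applied in order of logical strength:

1. **Overlap rule** (deductive): a cross-link between peptides whose
   residue intervals intersect — including a peptide paired with a second
   copy of itself — cannot come from a single chain, because one chain
   cannot yield both peptides.  Such a mass is necessarily inter-subunit
   wherever it is observed.

2. **Band-differential rule** (inferential): after SDS-PAGE of a
   crosslinked homo-oligomer, the monomer band can only contain
   intra-subunit crosslinks, while oligomer bands may contain both kinds.
   A mass seen in the monomer band is therefore intra-subunit; a mass
   seen *only* in oligomer bands is assigned inter-subunit.

When the two rules disagree — an overlap-forced mass shows up in the
monomer band — the deductive rule wins and the call carries a
``monomer-band conflict`` flag rather than being silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .linkers import CrosslinkCandidate, LedgerEntry
from .peaks import MassMatch

__all__ = [
    "TopologyCall",
    "overlap_forced_inter",
    "entry_overlap_forced",
    "band_differential_classify",
    "summarize_calls",
    "export_restraints",
]

VERDICTS = ("intra", "inter", "either")
EVIDENCE = ("overlap-forced", "band-differential", "band-monomer", "unresolved")


def overlap_forced_inter(candidate: CrosslinkCandidate) -> bool:
    """True iff the candidate cannot arise within a single chain.

    Loop-links are never forced; cross-links are forced when the two
    peptide intervals intersect (identical intervals included).
    """
    if candidate.kind != "cross":
        return False
    return candidate.self_pair or candidate.overlapping_peptides()


def entry_overlap_forced(entry: LedgerEntry) -> bool:
    """A mass is forced inter only if *every* explanation is overlap-forced."""
    return all(overlap_forced_inter(c) for c in entry.candidates)


@dataclass(frozen=True)
class TopologyCall:
    """Verdict for one matched theoretical mass, with its evidence rule."""

    entry: LedgerEntry
    verdict: str
    evidence: str
    bands_seen: tuple[str, ...]
    conflict: bool = False
    rationale: str = ""
    n_per_band: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"bad verdict {self.verdict!r}")
        if self.evidence not in EVIDENCE:
            raise ValueError(f"bad evidence {self.evidence!r}")


def _entries_by_mass(matches: Iterable[MassMatch]) -> dict[float, LedgerEntry]:
    out: dict[float, LedgerEntry] = {}
    for m in matches:
        for entry, _ in m.assignments:
            key = round(entry.mz, 6)
            prior = out.get(key)
            if prior is not None and prior is not entry and prior.candidates != entry.candidates:
                raise ValueError(
                    f"match sets reference inconsistent ledgers at m/z {entry.mz:.4f}"
                )
            out[key] = entry
    return out


def band_differential_classify(
    monomer_matches: Iterable[MassMatch],
    oligomer_matches: Iterable[MassMatch],
    monomer_replicates: dict | None = None,
    oligomer_replicates: dict | None = None,
) -> list[TopologyCall]:
    """Classify every matched mass as intra- or inter-subunit.

    Both match sets must derive from the same candidate ledger.  Every
    matched mass receives exactly one verdict.
    """
    mono = _entries_by_mass(monomer_matches)
    olig = _entries_by_mass(oligomer_matches)
    for key in mono.keys() & olig.keys():
        if mono[key].candidates != olig[key].candidates:
            raise ValueError("monomer and oligomer matches use different ledgers")

    calls = []
    for key in sorted(mono.keys() | olig.keys()):
        entry = mono.get(key) or olig[key]
        in_mono = key in mono
        in_olig = key in olig
        bands = tuple(
            b for b, seen in (("monomer", in_mono), ("oligomer", in_olig)) if seen
        )
        n_per_band = {}
        if monomer_replicates and key in {round(k, 6) for k in monomer_replicates}:
            n_per_band["monomer"] = next(
                v.n for k, v in monomer_replicates.items() if round(k, 6) == key
            )
        if oligomer_replicates and key in {round(k, 6) for k in oligomer_replicates}:
            n_per_band["oligomer"] = next(
                v.n for k, v in oligomer_replicates.items() if round(k, 6) == key
            )

        if entry_overlap_forced(entry):
            conflict = in_mono
            rationale = (
                "crosslinked peptides overlap; cannot arise within one chain"
                + ("; WARNING: observed in monomer band" if conflict else "")
            )
            calls.append(
                TopologyCall(
                    entry=entry,
                    verdict="inter",
                    evidence="overlap-forced",
                    bands_seen=bands,
                    conflict=conflict,
                    rationale=rationale,
                    n_per_band=n_per_band,
                )
            )
        elif in_mono:
            calls.append(
                TopologyCall(
                    entry=entry,
                    verdict="intra",
                    evidence="band-monomer",
                    bands_seen=bands,
                    rationale="observed in monomer band, where only "
                    "intra-subunit crosslinks can occur",
                    n_per_band=n_per_band,
                )
            )
        else:
            calls.append(
                TopologyCall(
                    entry=entry,
                    verdict="inter",
                    evidence="band-differential",
                    bands_seen=bands,
                    rationale="observed only in oligomer band(s), absent "
                    "from the monomer band",
                    n_per_band=n_per_band,
                )
            )
    return calls


def summarize_calls(calls: Iterable[TopologyCall]) -> pd.DataFrame:
    """One row per call, stable m/z ordering, conflicts flagged."""
    rows = []
    for call in sorted(calls, key=lambda c: c.entry.mz):
        rows.append(
            {
                "theoretical_mz": round(call.entry.mz, 4),
                "sites": "; ".join(
                    c.sites_label for c in call.entry.candidates
                ),
                "peptides": "; ".join(
                    c.peptides_label for c in call.entry.candidates
                ),
                "verdict": call.verdict,
                "evidence": call.evidence,
                "bands": ",".join(call.bands_seen),
                "n_monomer": call.n_per_band.get("monomer", ""),
                "n_oligomer": call.n_per_band.get("oligomer", ""),
                "conflict": call.conflict,
                "rationale": call.rationale,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "theoretical_mz",
            "sites",
            "peptides",
            "verdict",
            "evidence",
            "bands",
            "n_monomer",
            "n_oligomer",
            "conflict",
            "rationale",
        ],
    )


def export_restraints(
    calls: Iterable[TopologyCall], max_span: float
) -> pd.DataFrame:
    """Distance-restraint table (site pair, topology, max span) for modelling.

    Ambiguous site sets are expanded to one row per member pair; the
    restraint applies to at least one of them.
    """
    rows = []
    for call in calls:
        for cand in call.entry.candidates:
            for i, j in cand.site_pairs:
                rows.append(
                    {
                        "site_i": str(i),
                        "site_j": str(j),
                        "topology": call.verdict,
                        "max_span_A": max_span,
                        "ambiguous": len(cand.site_pairs) > 1,
                        "theoretical_mz": round(call.entry.mz, 4),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["site_i", "site_j", "topology", "max_span_A", "ambiguous", "theoretical_mz"],
    )
    return df.drop_duplicates().reset_index(drop=True)
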