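"""Peak-list I/O and ppm-tolerance matching of observed MALDI masses.

Peak lists are plain TSV — one row per peak, ``m/z`` and optional
``intensity`` columns — labelled with the SDS-PAGE gel band they came
from.  The band vocabulary is closed: ``monomer``, ``oligomer``,
``control`` (untreated protein, plain tryptic fingerprint) and ``native``
(no gel separation).

Deviations are signed ppm, (observed - theoretical)/theoretical x 1e6.
Published tables report the *maximum* deviation over replicate spectra,
which is a different number from the deviation of any single
representative spectrum; ``replicate_count`` reproduces that convention.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import pandas as pd

from .linkers import Ledger, LedgerEntry

__all__ = [
    "BANDS",
    "PeakList",
    "MassMatch",
    "MatchResult",
    "ReplicateStats",
    "ppm_deviation",
    "match_peaks",
    "differential_masses",
    "replicate_count",
]

BANDS = ("monomer", "oligomer", "control", "native")


@dataclass(frozen=True)
class PeakList:
    """One spectrum's peaks, sorted ascending, tagged with its gel band."""

    spectrum_id: str
    band: str
    mzs: tuple[float, ...]
    intensities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"band {self.band!r} not in {BANDS}")
        if any(m <= 0 for m in self.mzs):
            raise ValueError("all m/z values must be positive")
        order = sorted(range(len(self.mzs)), key=lambda i: self.mzs[i])
        object.__setattr__(self, "mzs", tuple(self.mzs[i] for i in order))
        if self.intensities is not None:
            if len(self.intensities) != len(self.mzs):
                raise ValueError("intensity count does not match peak count")
            object.__setattr__(
                self, "intensities", tuple(self.intensities[i] for i in order)
            )

    def __len__(self) -> int:
        return len(self.mzs)

    @classmethod
    def read_tsv(cls, path, band: str, spectrum_id: str | None = None) -> "PeakList":
        df = pd.read_csv(path, sep="\t", comment="#")
        if "mz" not in df.columns:
            # headerless two-column form
            df = pd.read_csv(
                path, sep="\t", comment="#", header=None, names=["mz", "intensity"]
            )
        intensities = None
        if "intensity" in df.columns and df["intensity"].notna().all():
            intensities = tuple(float(x) for x in df["intensity"])
        return cls(
            spectrum_id=spectrum_id or str(path),
            band=band,
            mzs=tuple(float(x) for x in df["mz"]),
            intensities=intensities,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"mz": self.mzs})
        if self.intensities is not None:
            df["intensity"] = self.intensities
        df.to_csv(path, sep="\t", index=False)


def ppm_deviation(observed: float, theoretical: float) -> float:
    """Signed relative deviation, (obs - theo)/theo x 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class MassMatch:
    """One observed peak with its candidate assignments ranked by |ppm|."""

    observed: float
    band: str
    assignments: tuple[tuple[LedgerEntry, float], ...]  # (entry, signed ppm)

    @property
    def best(self) -> LedgerEntry:
        return self.assignments[0][0]

    @property
    def best_ppm(self) -> float:
        return self.assignments[0][1]


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[MassMatch, ...]
    unmatched: tuple[float, ...]

    @property
    def matched_entries(self) -> tuple[LedgerEntry, ...]:
        seen, out = set(), []
        for m in self.matches:
            for entry, _ in m.assignments:
                if id(entry) not in seen:
                    seen.add(id(entry))
                    out.append(entry)
        return tuple(out)


def _entry_simplicity(entry: LedgerEntry) -> int:
    # fewer total sites = simpler explanation, used to break |ppm| ties
    return min(len(c.all_sites) for c in entry.candidates)


def match_peaks(
    peaks: PeakList,
    ledger: Ledger,
    tolerance_ppm: float = 50.0,
    include_unobservable: bool = False,
) -> MatchResult:
    """Assign every peak to all ledger entries within the ppm tolerance."""
    if tolerance_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    mzs = ledger.mzs
    matches, unmatched = [], []
    for obs in peaks.mzs:
        # tolerance is relative to the theoretical mass; window on obs is safe
        half = obs * tolerance_ppm * 1e-6 * 1.001 + 1e-9
        lo = bisect.bisect_left(mzs, obs - half)
        hi = bisect.bisect_right(mzs, obs + half)
        hits = []
        for entry in ledger.entries[lo:hi]:
            if not entry.observable and not include_unobservable:
                continue
            ppm = ppm_deviation(obs, entry.mz)
            if abs(ppm) <= tolerance_ppm:
                hits.append((entry, ppm))
        if hits:
            hits.sort(key=lambda h: (abs(h[1]), _entry_simplicity(h[0])))
            matches.append(
                MassMatch(observed=obs, band=peaks.band, assignments=tuple(hits))
            )
        else:
            unmatched.append(obs)
    return MatchResult(matches=tuple(matches), unmatched=tuple(unmatched))


def differential_masses(
    sample: PeakList, reference: PeakList, tolerance_ppm: float = 50.0
) -> PeakList:
    """Sample peaks with no reference peak within tolerance.

    One-sided: peaks unique to the reference are not reported.  This is
    the control-subtraction step that isolates masses appearing only
    after crosslinking.
    """
    if tolerance_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    unique = []
    for i, obs in enumerate(sample.mzs):
        shared = any(
            abs(ppm_deviation(obs, ref)) <= tolerance_ppm for ref in reference.mzs
        )
        if not shared:
            unique.append(i)
    return PeakList(
        spectrum_id=f"{sample.spectrum_id}-minus-{reference.spectrum_id}",
        band=sample.band,
        mzs=tuple(sample.mzs[i] for i in unique),
        intensities=None
        if sample.intensities is None
        else tuple(sample.intensities[i] for i in unique),
    )


@dataclass(frozen=True)
class ReplicateStats:
    """Replicate support for one theoretical mass within one gel band."""

    theoretical_mz: float
    n: int  # spectra containing a peak within tolerance
    max_ppm: float  # signed deviation of largest magnitude over those spectra

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("replicate stats require at least one observation")


def replicate_count(
    spectra: list[PeakList],
    ledger: Ledger,
    tolerance_ppm: float = 50.0,
    include_unobservable: bool = False,
) -> dict[float, ReplicateStats]:
    """Per-theoretical-mass replicate support across spectra of one band.

    N counts spectra with at least one peak within tolerance; the reported
    deviation is the maximum-|ppm| one over those spectra (the convention
    of published assignment tables).  Masses never seen are omitted.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    bands = {s.band for s in spectra}
    if len(bands) > 1:
        raise ValueError(f"spectra from mixed bands: {sorted(bands)}")
    out: dict[float, ReplicateStats] = {}
    for entry in ledger.entries:
        if not entry.observable and not include_unobservable:
            continue
        n, worst = 0, 0.0
        for spec in spectra:
            in_tol = [
                ppm_deviation(obs, entry.mz)
                for obs in spec.mzs
                if abs(ppm_deviation(obs, entry.mz)) <= tolerance_ppm
            ]
            if in_tol:
                n += 1
                local = max(in_tol, key=abs)
                if abs(local) > abs(worst):
                    worst = local
        if n:
            out[entry.mz] = ReplicateStats(theoretical_mz=entry.mz, n=n, max_ppm=worst)
    return out
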