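"""Calpha-distance validation of crosslink calls against a structural model.

A crosslinker of known geometry bounds the Calpha-Calpha distance of the
two linked residues (arm length plus twice the side-chain reach; 24 A for
a Lys-Lys DMS crosslink).  Given a multi-chain model of the oligomer —
optionally multi-model, each MODEL record treated as a trajectory frame —
this module measures, for a site pair (i, j):

* the **intra-subunit** distance i-j within each chain, and
* the **inter-subunit** distance between i on one chain and j on its
  ring-adjacent neighbour, in both orientations around the ring,

averaged over chains/interfaces and frames, and asks which topology the
span can satisfy.  Homo-oligomer rings are treated as cycles of adjacent
chains; crosslinks between non-adjacent subunits are not considered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio.PDB import PDBParser

from .digest import N_TERMINUS, Site
from .linkers import CrosslinkCandidate, CrosslinkerProfile

__all__ = [
    "StructureModel",
    "RingAdjacency",
    "DistanceStats",
    "DistanceAssessment",
    "load_structure",
    "ring_adjacency",
    "site_pair_distances",
    "assess_candidate",
    "write_ca_pdb",
]


@dataclass(frozen=True)
class StructureModel:
    """Calpha coordinates per chain and residue, over one or more frames.

    ``coords[chain][resnum]`` is an (n_frames, 3) array in Angstroms,
    with residue numbers already reconciled to protein numbering.
    """

    chain_ids: tuple[str, ...]
    coords: dict[str, dict[int, np.ndarray]]
    n_frames: int
    missing_ca: tuple[tuple[str, int], ...] = ()

    def resolved(self, chain: str) -> tuple[int, ...]:
        return tuple(sorted(self.coords[chain]))

    def site_coords(self, chain: str, site: Site) -> np.ndarray | None:
        """(n_frames, 3) coordinates of a site, or None if unresolved.

        The N-terminal pseudo-site maps to the first resolved residue's
        Calpha of that chain.
        """
        chain_coords = self.coords[chain]
        if site == N_TERMINUS:
            if not chain_coords:
                return None
            return chain_coords[min(chain_coords)]
        return chain_coords.get(int(site))

    def chain_centroid(self, chain: str) -> np.ndarray:
        arrs = list(self.coords[chain].values())
        return np.mean(np.stack(arrs), axis=(0, 1))

    def transformed(self, scale: float = 1.0, shift=(0.0, 0.0, 0.0)) -> "StructureModel":
        shift = np.asarray(shift, dtype=float)
        return StructureModel(
            chain_ids=self.chain_ids,
            coords={
                ch: {r: xyz * scale + shift for r, xyz in resmap.items()}
                for ch, resmap in self.coords.items()
            },
            n_frames=self.n_frames,
            missing_ca=self.missing_ca,
        )


def load_structure(
    path,
    chain_map: dict[str, str] | None = None,
    numbering_offset: int = 0,
) -> StructureModel:
    """Read Calpha coordinates from a (possibly multi-model) PDB file.

    ``numbering_offset`` is added to PDB residue numbers to obtain
    protein numbering.  ``chain_map`` optionally renames (and restricts
    to) chains of interest.  Residues lacking a Calpha are recorded in
    ``missing_ca`` rather than raising.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models found in {path}")

    missing: set[tuple[str, int]] = set()
    chain_order: list[str] = []
    frames: list[dict[str, dict[int, np.ndarray]]] = []
    for model in models:
        frame: dict[str, dict[int, np.ndarray]] = {}
        for chain in model:
            cid = chain.id
            if chain_map is not None:
                if cid not in chain_map:
                    continue
                cid = chain_map[cid]
            if cid not in chain_order:
                chain_order.append(cid)
            resmap = frame.setdefault(cid, {})
            for residue in chain:
                hetflag, resseq, _ = residue.id
                if hetflag.strip():
                    continue
                num = resseq + numbering_offset
                if "CA" in residue:
                    resmap[num] = np.asarray(residue["CA"].coord, dtype=float)
                else:
                    missing.add((cid, num))
        frames.append(frame)
    if not chain_order:
        raise ValueError(f"no usable chains in {path}")

    # keep residues resolved in every frame; the rest are reported missing
    coords: dict[str, dict[int, np.ndarray]] = {}
    for cid in chain_order:
        common = set.intersection(*(set(f.get(cid, {})) for f in frames))
        union = set.union(*(set(f.get(cid, {})) for f in frames))
        missing.update((cid, num) for num in union - common)
        coords[cid] = {
            num: np.stack([f[cid][num] for f in frames]) for num in sorted(common)
        }
    return StructureModel(
        chain_ids=tuple(chain_order),
        coords=coords,
        n_frames=len(frames),
        missing_ca=tuple(sorted(missing)),
    )


@dataclass(frozen=True)
class RingAdjacency:
    """Ordered cycle of chains around the oligomer ring.

    ``orientation`` is "ccw" when traversing ``cycle`` circulates
    counterclockwise viewed down the ring axis from the N-terminal side,
    "cw" otherwise.  Mirroring the coordinates flips the tag.
    """

    cycle: tuple[str, ...]
    orientation: str

    def successor(self, chain: str) -> str:
        i = self.cycle.index(chain)
        return self.cycle[(i + 1) % len(self.cycle)]

    def ordered_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((c, self.successor(c)) for c in self.cycle)


def ring_adjacency(model: StructureModel) -> RingAdjacency:
    """Ring order of chains from centroid geometry, plus handedness.

    The cycle is found by nearest-neighbour traversal of chain centroids
    and validated: each chain's two cycle neighbours must be its two
    nearest centroids, otherwise the geometry is not an unambiguous ring
    and an explicit adjacency must be configured.
    """
    chains = model.chain_ids
    if len(chains) < 3:
        raise ValueError("ring adjacency requires at least 3 chains")
    centroids = {c: model.chain_centroid(c) for c in chains}

    cycle = [chains[0]]
    remaining = set(chains[1:])
    while remaining:
        cur = centroids[cycle[-1]]
        nxt = min(remaining, key=lambda c: float(np.linalg.norm(centroids[c] - cur)))
        cycle.append(nxt)
        remaining.discard(nxt)

    # ring validation: cycle neighbours must be the two nearest centroids
    n = len(cycle)
    for idx, c in enumerate(cycle):
        others = sorted(
            (o for o in chains if o != c),
            key=lambda o: float(np.linalg.norm(centroids[o] - centroids[c])),
        )
        neighbours = {cycle[(idx - 1) % n], cycle[(idx + 1) % n]}
        if set(others[:2]) != neighbours:
            raise ValueError(
                "chain centroids do not form an unambiguous ring; "
                "configure the adjacency cycle explicitly"
            )

    pts = np.stack([centroids[c] for c in cycle])
    center = pts.mean(axis=0)
    centered = pts - center
    # ring-plane normal: direction of least centroid variance
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    # point the normal toward the N-terminal side of the chains
    nterm = np.mean(
        [model.site_coords(c, N_TERMINUS)[0] for c in chains], axis=0
    )
    if np.dot(nterm - center, normal) < 0:
        normal = -normal
    circulation = sum(
        float(np.dot(np.cross(centered[i], centered[(i + 1) % n]), normal))
        for i in range(n)
    )
    orientation = "ccw" if circulation > 0 else "cw"
    return RingAdjacency(cycle=tuple(cycle), orientation=orientation)


@dataclass(frozen=True)
class DistanceStats:
    mean: float
    min: float
    max: float
    n: int

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "DistanceStats | None":
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            return None
        return cls(
            mean=float(vals.mean()),
            min=float(vals.min()),
            max=float(vals.max()),
            n=int(vals.size),
        )

    def statistic(self, criterion: str) -> float:
        if criterion == "mean":
            return self.mean
        if criterion == "min":
            return self.min
        raise ValueError(f"unknown criterion {criterion!r}; use 'mean' or 'min'")


@dataclass(frozen=True)
class DistanceAssessment:
    """Intra and adjacent-inter Calpha-Calpha statistics for one site pair.

    ``inter`` holds one entry per ring orientation: ``"ab"`` places site i
    on a chain and site j on its cycle successor, ``"ba"`` the reverse.
    """

    pair: tuple[Site, Site]
    intra: DistanceStats | None
    inter: dict[str, DistanceStats]
    unresolved_chains: tuple[str, ...] = ()

    def satisfiable_as(self, span: float, criterion: str = "mean") -> str:
        intra_ok = self.intra is not None and self.intra.statistic(criterion) <= span
        inter_ok = any(
            s is not None and s.statistic(criterion) <= span
            for s in self.inter.values()
        )
        if intra_ok and inter_ok:
            return "both"
        if intra_ok:
            return "intra"
        if inter_ok:
            return "inter"
        return "neither"


def site_pair_distances(
    model: StructureModel,
    i: Site,
    j: Site,
    adjacency: RingAdjacency | None = None,
) -> DistanceAssessment:
    """Distance statistics for sites i, j over chains/interfaces x frames."""
    adjacency = adjacency or ring_adjacency(model)
    unresolved = []
    intra_vals: list[float] = []
    for chain in model.chain_ids:
        ci = model.site_coords(chain, i)
        cj = model.site_coords(chain, j)
        if ci is None or cj is None:
            unresolved.append(chain)
            continue
        intra_vals.extend(np.linalg.norm(ci - cj, axis=1))
    if unresolved:
        warnings.warn(
            f"sites ({i}, {j}) unresolved on chains {unresolved}; excluded",
            stacklevel=2,
        )

    inter: dict[str, list[float]] = {"ab": [], "ba": []}
    for a, b in adjacency.ordered_pairs():
        for orientation, (ch_i, ch_j) in (("ab", (a, b)), ("ba", (b, a))):
            ci = model.site_coords(ch_i, i)
            cj = model.site_coords(ch_j, j)
            if ci is None or cj is None:
                continue
            inter[orientation].extend(np.linalg.norm(ci - cj, axis=1))

    return DistanceAssessment(
        pair=(i, j),
        intra=DistanceStats.from_values(intra_vals),
        inter={
            k: s
            for k, v in inter.items()
            if (s := DistanceStats.from_values(v)) is not None
        },
        unresolved_chains=tuple(unresolved),
    )


def assess_candidate(
    candidate: CrosslinkCandidate,
    model: StructureModel,
    linker: CrosslinkerProfile,
    criterion: str = "mean",
    adjacency: RingAdjacency | None = None,
) -> str:
    """Which topology the linker span can satisfy for a candidate.

    An ambiguity set is satisfiable if any member site pair is.
    Returns "intra", "inter", "both" or "neither".
    """
    adjacency = adjacency or ring_adjacency(model)
    span = linker.max_span
    intra_ok = inter_ok = False
    for i, j in candidate.site_pairs:
        verdict = site_pair_distances(model, i, j, adjacency).satisfiable_as(
            span, criterion
        )
        intra_ok = intra_ok or verdict in ("intra", "both")
        inter_ok = inter_ok or verdict in ("inter", "both")
    if intra_ok and inter_ok:
        return "both"
    if intra_ok:
        return "intra"
    if inter_ok:
        return "inter"
    return "neither"


def distance_report(
    model: StructureModel,
    pairs: Iterable[tuple[Site, Site]],
    span: float,
    criterion: str = "mean",
    adjacency: RingAdjacency | None = None,
):
    """Distance-report table: one row per site pair."""
    import pandas as pd

    adjacency = adjacency or ring_adjacency(model)
    rows = []
    for i, j in pairs:
        a = site_pair_distances(model, i, j, adjacency)
        row = {"site_i": str(i), "site_j": str(j)}
        for name, stats in (("intra", a.intra),):
            row.update(
                {
                    f"{name}_mean": None if stats is None else round(stats.mean, 2),
                    f"{name}_min": None if stats is None else round(stats.min, 2),
                    f"{name}_max": None if stats is None else round(stats.max, 2),
                }
            )
        for orientation in ("ab", "ba"):
            stats = a.inter.get(orientation)
            row.update(
                {
                    f"inter_{orientation}_mean": None
                    if stats is None
                    else round(stats.mean, 2),
                    f"inter_{orientation}_min": None
                    if stats is None
                    else round(stats.min, 2),
                    f"inter_{orientation}_max": None
                    if stats is None
                    else round(stats.max, 2),
                }
            )
        row["satisfiable_as"] = a.satisfiable_as(span, criterion)
        rows.append(row)
    return pd.DataFrame(rows)


def write_ca_pdb(model: StructureModel, path) -> None:
    """Write a Calpha-only multi-model PDB (plain text, frames as MODELs)."""
    with open(path, "w") as fh:
        for frame in range(model.n_frames):
            if model.n_frames > 1:
                fh.write(f"MODEL     {frame + 1:4d}\n")
            serial = 1
            for chain in model.chain_ids:
                for resnum in model.resolved(chain):
                    x, y, z = model.coords[chain][resnum][frame]
                    fh.write(
                        f"ATOM  {serial:5d}  CA  ALA {chain:1s}{resnum:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                    )
                    serial += 1
                fh.write("TER\n")
            if model.n_frames > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")
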