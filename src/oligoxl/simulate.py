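"""Deterministic synthetic fixtures: ring oligomers, planted crosslinks,
and simulated band-labelled peak lists.

The generator emulates the observable surface of a crosslinking/MALDI
experiment on a homo-oligomeric ring: a random compact Calpha trace is
replicated by rotation about the ring axis, lysines are planted at a
configurable density, every amine pair within the crosslinker span is
eligible to form a link, and formed links are converted to the peptide
masses a MALDI fingerprint of the monomer and oligomer gel bands would
show — intra-subunit products in both bands, inter-subunit products only
in the oligomer band, plain tryptic peptides in the control.  Gaussian
ppm noise and uniform decoy peaks model instrument error and background.

Chain traces are geometric, not protein-realistic (no Ramachandran
constraints): only inter-site distances matter for the logic under test.
A single explicit seed threads through all stages; no global random state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .digest import (
    N_TERMINUS,
    DigestParams,
    ProteinSpec,
    ResidueMassTable,
    Site,
    cleavage_positions,
    mh_plus,
    peptide_mono_mass,
    tryptic_digest,
)
from .linkers import CrosslinkerProfile
from .peaks import PeakList
from .structure import StructureModel
from .topology import TopologyCall

__all__ = [
    "SimulationConfig",
    "PlantedLink",
    "SimulatedSpectra",
    "make_ring_structure",
    "plant_crosslinks",
    "simulate_peaklists",
    "score_recovery",
]

CA_STEP = 3.8  # A, consecutive Calpha spacing


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic experiment; the seed fixes every output."""

    seed: int = 0
    n_subunits: int = 5
    subunit_length: int = 60
    lysine_density: float = 0.10
    ring_radius: float = 14.0  # centroid ring radius; subunits in contact
    ppm_noise_sd: float = 10.0
    n_decoys: int = 5
    observable_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ValueError("a ring needs at least 3 subunits")
        if not (0.0 <= self.observable_fraction <= 1.0):
            raise ValueError("observable_fraction must be in [0, 1]")


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _compact_trace(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random Calpha walk with 3.8 A steps, confined to a globular volume.

    The confinement radius scales as n^(1/3), giving a radius of gyration
    close to that of a compact protein domain of the same length — adjacent
    subunits of the ring must be in contact for interface crosslinks to
    exist at all.
    """
    pos = np.zeros((n, 3))
    confine = 2.5 * n ** (1.0 / 3.0)
    for k in range(1, n):
        step = rng.normal(size=3)
        r = np.linalg.norm(pos[k - 1])
        if r > confine:
            step -= 1.5 * pos[k - 1] / r
        step /= np.linalg.norm(step)
        pos[k] = pos[k - 1] + CA_STEP * step
    return pos - pos.mean(axis=0)


def _random_sequence(rng: np.random.Generator, config: SimulationConfig) -> str:
    others = "ACDEFGHILMNQSTVWY"  # no K/R/P: those are placed explicitly
    seq = []
    for _ in range(config.subunit_length):
        u = rng.random()
        if u < config.lysine_density:
            seq.append("K")
        elif u < config.lysine_density + 0.05:
            seq.append("R")
        else:
            seq.append(others[rng.integers(len(others))])
    # the tested logic needs at least one crosslinkable Lys pair
    while seq.count("K") < 2:
        seq[int(rng.integers(1, config.subunit_length - 1))] = "K"
    return "".join(seq)


def make_ring_structure(
    config: SimulationConfig,
) -> tuple[StructureModel, ProteinSpec]:
    """Random homo-oligomeric ring: one trace, rotated copies, one frame.

    Chain centroids sit on a regular n-gon of the configured radius in
    the z = 0 plane; chain k is chain A rotated by 360/n degrees about z.
    """
    rng = np.random.default_rng(config.seed)
    sequence = _random_sequence(rng, config)
    protein = ProteinSpec(identifier=f"synthetic-ring-{config.seed}", sequence=sequence)

    trace = _compact_trace(rng, config.subunit_length)
    base = trace + np.array([config.ring_radius, 0.0, 0.0])
    chain_ids = tuple("ABCDEFGHIJKLMNOP"[: config.n_subunits])
    coords = {}
    for k, cid in enumerate(chain_ids):
        rot = _rotation_z(2.0 * math.pi * k / config.n_subunits)
        xyz = base @ rot.T
        coords[cid] = {
            resnum: xyz[resnum - 1][None, :].copy()
            for resnum in range(1, config.subunit_length + 1)
        }
    model = StructureModel(chain_ids=chain_ids, coords=coords, n_frames=1)
    return model, protein


@dataclass(frozen=True)
class PlantedLink:
    """Ground-truth crosslink with its label and theoretical product mass."""

    site_i: Site
    site_j: Site
    label: str  # "intra" | "inter"
    mz: float
    kind: str  # "loop" | "cross"


def _site_xyz(model: StructureModel, chain: str, site: Site) -> np.ndarray:
    return model.site_coords(chain, site)[0]


def _product_mass(
    protein: ProteinSpec,
    linker: CrosslinkerProfile,
    sites: tuple[Site, ...],
    per_chain: bool,
    params: DigestParams,
    table: ResidueMassTable,
) -> tuple[float, str]:
    """[M+H]+ of the fully-cleaved crosslink product and its topology kind.

    ``per_chain`` False: both ends on one chain (blocked together);
    True: one end per chain (each chain blocks only its own site).
    """

    def fragment_for(site: Site, blocked: frozenset[int]):
        cuts = cleavage_positions(protein, blocked, params.proline_rule)
        starts = [protein.offset] + [c + 1 for c in cuts]
        ends = list(cuts) + [protein.last]
        pos = protein.offset if site == N_TERMINUS else int(site)
        for s, e in zip(starts, ends):
            if s <= pos <= e:
                return (s, e)
        raise AssertionError("site outside protein")

    positions = frozenset(int(s) for s in sites if s != N_TERMINUS)
    if per_chain:
        frags = [
            fragment_for(site, frozenset({int(site)} if site != N_TERMINUS else ()))
            for site in sites
        ]
        mass = sum(
            peptide_mono_mass(protein.slice(*f), table) for f in frags
        )
        kind = "cross"
    else:
        frags = sorted({fragment_for(site, positions) for site in sites})
        mass = sum(peptide_mono_mass(protein.slice(*f), table) for f in frags)
        kind = "loop" if len(frags) == 1 else "cross"
    return mh_plus(mass + linker.bridge_mass, table), kind


def plant_crosslinks(
    model: StructureModel,
    protein: ProteinSpec,
    linker: CrosslinkerProfile,
    config: SimulationConfig,
    params: DigestParams = DigestParams(),
    table: ResidueMassTable | None = None,
) -> list[PlantedLink]:
    """Seeded ground-truth link set from the planted geometry.

    Every amine pair whose Calpha-Calpha distance fits the span is
    eligible — within one chain (intra) or across one adjacent interface
    (inter, either orientation; both residues may be the same position on
    the two chains).  A seeded subset of eligible pairs forms.
    """
    table = table or ResidueMassTable.default()
    rng = np.random.default_rng(config.seed + 1)
    span = linker.max_span
    sites = protein.reactive_sites
    a, b = model.chain_ids[0], model.chain_ids[1]

    links = []
    for i, j in itertools.combinations(sites, 2):
        d = np.linalg.norm(_site_xyz(model, a, i) - _site_xyz(model, a, j))
        if d <= span:
            mz, kind = _product_mass(
                protein, linker, (i, j), per_chain=False, params=params, table=table
            )
            links.append(PlantedLink(i, j, "intra", mz, kind))
    for i, j in itertools.combinations_with_replacement(sites, 2):
        d_ab = np.linalg.norm(_site_xyz(model, a, i) - _site_xyz(model, b, j))
        d_ba = np.linalg.norm(_site_xyz(model, b, i) - _site_xyz(model, a, j))
        if min(d_ab, d_ba) <= span:
            mz, kind = _product_mass(
                protein, linker, (i, j), per_chain=True, params=params, table=table
            )
            links.append(PlantedLink(i, j, "inter", mz, kind))

    keep = rng.random(len(links)) < config.observable_fraction
    return [link for link, k in zip(links, keep) if k]


@dataclass(frozen=True)
class SimulatedSpectra:
    monomer: list[PeakList]
    oligomer: list[PeakList]
    control: list[PeakList]


def simulate_peaklists(
    truth: list[PlantedLink],
    protein: ProteinSpec,
    linker: CrosslinkerProfile,
    config: SimulationConfig,
    n_spectra: int = 1,
    params: DigestParams = DigestParams(),
    table: ResidueMassTable | None = None,
) -> SimulatedSpectra:
    """Band-labelled peak lists for the planted truth.

    Monomer spectra carry intra-link masses only, oligomer spectra carry
    all link masses, control spectra the plain tryptic fingerprint; every
    spectrum gets seeded Gaussian ppm noise and uniform decoy peaks.
    """
    table = table or ResidueMassTable.default()
    rng = np.random.default_rng(config.seed + 2)
    intra = sorted({l.mz for l in truth if l.label == "intra"})
    all_links = sorted({l.mz for l in truth})
    control_masses = sorted(
        {
            mh_plus(peptide_mono_mass(p, table), table)
            for p in tryptic_digest(
                protein,
                max_unmodified_missed=params.max_unmodified_missed,
                proline_rule=params.proline_rule,
            )
        }
    )

    def spectrum(masses, band, idx) -> PeakList:
        noisy = [
            m * (1.0 + rng.normal(0.0, config.ppm_noise_sd) * 1e-6) for m in masses
        ]
        decoys = list(rng.uniform(500.0, 4500.0, size=config.n_decoys))
        return PeakList(
            spectrum_id=f"sim-{band}-{idx}", band=band, mzs=tuple(noisy + decoys)
        )

    return SimulatedSpectra(
        monomer=[
            spectrum(intra + control_masses, "monomer", k) for k in range(n_spectra)
        ],
        oligomer=[
            spectrum(all_links + control_masses, "oligomer", k)
            for k in range(n_spectra)
        ],
        control=[spectrum(control_masses, "control", k) for k in range(n_spectra)],
    )


@dataclass(frozen=True)
class RecoveryScore:
    """Precision/recall of pipeline verdicts against the planted labels."""

    precision: dict[str, float | None]
    recall: dict[str, float | None]
    n_truth: dict[str, int]


def truth_mass_labels(
    truth: list[PlantedLink], merge_tol_da: float = 0.001
) -> dict[float, str]:
    """Ground-truth label per observable *mass*.

    The gel-band readout carries information at the mass level only: an
    inter-subunit link whose product mass is also produced by a formed
    intra-subunit link shows up in the monomer band regardless, and no
    band-based method can recover its inter identity.  A mass is
    therefore labelled "intra" when any formed intra link produces it and
    "inter" when only inter links do.
    """
    masses: dict[float, str] = {}
    for link in sorted(truth, key=lambda l: l.mz):
        key = next(
            (m for m in masses if abs(m - link.mz) <= merge_tol_da), link.mz
        )
        prior = masses.get(key)
        masses[key] = (
            "intra" if prior == "intra" or link.label == "intra" else link.label
        )
    return masses


def score_recovery(
    calls: list[TopologyCall],
    truth: list[PlantedLink],
    match_tol_da: float = 0.01,
) -> RecoveryScore:
    """Compare verdicts to planted mass labels, per label.

    A truth mass is recovered when some call within ``match_tol_da``
    carries its label; a call is correct when its mass belongs to a truth
    mass of its verdict.  Labels with no truth masses score None.
    """
    labels = truth_mass_labels(truth)
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    n_truth: dict[str, int] = {}
    for label in ("intra", "inter"):
        relevant = [m for m, lab in labels.items() if lab == label]
        n_truth[label] = len(relevant)
        if relevant:
            hits = sum(
                any(
                    call.verdict == label
                    and abs(call.entry.mz - m) <= match_tol_da
                    for call in calls
                )
                for m in relevant
            )
            recall[label] = hits / len(relevant)
        else:
            recall[label] = None
        verdict_calls = [c for c in calls if c.verdict == label]
        if verdict_calls:
            good = sum(
                any(
                    lab == label and abs(call.entry.mz - m) <= match_tol_da
                    for m, lab in labels.items()
                )
                for call in verdict_calls
            )
            precision[label] = good / len(verdict_calls)
        else:
            precision[label] = None
    return RecoveryScore(precision=precision, recall=recall, n_truth=n_truth)
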