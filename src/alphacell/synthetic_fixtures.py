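"""Synthetic inputs with known ground truth for every pipeline stage.

These generators produce inputs whose expected outputs are known by
construction — event clouds whose clustering outcome is provable from the
placement geometry, toy decay chains with enumerable alpha yields, and
free-standing line tracks with analytic Poisson statistics — so each
stage of the pipeline can be tested without external data.  They validate
contracts, not physics: real track structure is far more correlated than
these clouds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alpha_transport import IonizationParams
from .damage_clustering import DamageParams
from .decay_model import (
    DecayBranch,
    DecayDataError,
    Emission,
    EmissionKind,
    Nuclide,
    NuclideLibrary,
)

__all__ = [
    "ClusterSpec",
    "GroundTruth",
    "make_event_cloud",
    "make_toy_nuclide",
    "make_line_track_events",
    "EVENT_DTYPE",
]

EVENT_DTYPE = [("x", float), ("y", float), ("z", float), ("edep", float)]


@dataclass
class GroundTruth:
    n_ssb: int
    n_sdsb: int
    n_cdsb: int


@dataclass
class ClusterSpec:
    """Blueprint of an event cloud with a provable clustering outcome.

    ``centres`` (nm) must be pairwise separated by more than ``2 * eps``
    and each cluster's points stay within ``spread < eps / 2`` of its
    centre, which guarantees intended co-clustering and inter-cluster
    separation.  ``strand_patterns`` gives per-cluster strand labels;
    ``n_singletons`` adds isolated background breaks.
    """

    centres: np.ndarray                       # (k, 3) nm
    strand_patterns: list[tuple[int, ...]]    # one tuple per cluster
    spread_nm: float = 0.5
    n_singletons: int = 0
    eps_nm: float = 3.2

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        if self.centres.size == 0:
            self.centres = self.centres.reshape(0, 3)
        else:
            self.centres = np.atleast_2d(self.centres)
        if len(self.centres) != len(self.strand_patterns):
            raise ValueError("one strand pattern required per centre")
        if self.spread_nm >= self.eps_nm / 2.0:
            raise ValueError("spread must be < eps/2 for guaranteed clustering")
        for i, j in itertools.combinations(range(len(self.centres)), 2):
            d = float(np.linalg.norm(self.centres[i] - self.centres[j]))
            if d <= 2.0 * self.eps_nm:
                raise ValueError(
                    f"centres {i},{j} separated by {d:.2f} nm <= 2*eps"
                )

    def expected(self) -> GroundTruth:
        n_ssb = self.n_singletons
        n_sdsb = n_cdsb = 0
        for pattern in self.strand_patterns:
            size = len(pattern)
            both = len(set(pattern)) == 2
            if both and size == 2:
                n_sdsb += 1
            elif both:
                n_cdsb += 1
            else:
                n_ssb += size
        return GroundTruth(n_ssb, n_sdsb, n_cdsb)


def make_event_cloud(
    spec: ClusterSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, GroundTruth, DamageParams]:
    """Generate events plus strand labels realising ``spec`` exactly.

    Event energies are set above the damage-probability plateau and the
    returned params force ``dna_fraction=1`` so the thinning stage is
    deterministic and the clustering stage alone decides the outcome.
    """
    positions: list[np.ndarray] = []
    strands: list[int] = []
    for centre, pattern in zip(spec.centres, spec.strand_patterns):
        for s in pattern:
            offset = rng.standard_normal(3)
            offset *= (rng.random() * spec.spread_nm) / max(
                float(np.linalg.norm(offset)), 1e-12
            )
            positions.append(centre + offset)
            strands.append(int(s))
    # park singletons on a far-away line, 3*eps apart: isolated by construction
    base = (
        spec.centres.max(axis=0) if len(spec.centres) else np.zeros(3)
    ) + 10.0 * spec.eps_nm
    for i in range(spec.n_singletons):
        positions.append(base + np.array([3.0 * spec.eps_nm * i, 0.0, 0.0]))
        strands.append(1 + i % 2)
    events = np.empty(len(positions), dtype=EVENT_DTYPE)
    pos = np.array(positions) if positions else np.empty((0, 3))
    events["x"], events["y"], events["z"] = pos.T if len(pos) else ([], [], [])
    events["edep"] = 100.0      # eV, above the ramp plateau
    params = DamageParams(dna_fraction=1.0, eps_nm=spec.eps_nm)
    return events, np.array(strands, dtype=int), spec.expected(), params


def make_toy_nuclide(
    branch_table: list[dict],
    name: str = "Toy-200",
    half_life_s: float = 1.0,
) -> tuple[Nuclide, NuclideLibrary]:
    """Build an in-memory nuclide (plus closing library) from a branch table.

    Each row: ``{"probability": p, "mode": m, "daughter": d,
    "emissions": [(kind, energy_mev), ...]}``.  Daughters not defined in
    the table are created as stable terminators.
    """
    total = sum(float(row["probability"]) for row in branch_table)
    if abs(total - 1.0) > 1e-9:
        raise DecayDataError(f"branch probabilities sum to {total}, not 1")
    branches = []
    daughters = set()
    for row in branch_table:
        emissions = tuple(
            Emission(EmissionKind(kind), float(e), name)
            for kind, e in row.get("emissions", ())
        )
        branches.append(
            DecayBranch(
                probability=float(row["probability"]),
                mode=str(row["mode"]),
                daughter=str(row["daughter"]),
                emissions=emissions,
            )
        )
        daughters.add(str(row["daughter"]))
    parent = Nuclide(name, half_life_s, tuple(branches))
    stable_daughters = [
        Nuclide(d, float("inf"), (), stable=True) for d in sorted(daughters)
    ]
    return parent, NuclideLibrary([parent, *stable_daughters])


def make_line_track_events(
    edep_mev: float,
    length_um: float,
    params: IonizationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ionization events on a free-standing line along +z from the origin.

    Uses the same sampler statistics as the transport stage: count is
    Poisson(edep/W̄), longitudinal positions uniform over the line,
    lateral Gaussian σ_r, energies exponential rescaled to conserve the
    deposit exactly.  Expected linear event density is
    ``edep / (W̄ · length)``.
    """
    if edep_mev < 0.0 or length_um <= 0.0:
        raise ValueError("edep must be >= 0 and length positive")
    edep_ev = edep_mev * 1e6
    events = np.empty(0, dtype=EVENT_DTYPE)
    if edep_ev == 0.0:
        return events
    n = max(int(rng.poisson(edep_ev / params.w_bar_ev)), 1)
    z = rng.random(n) * length_um * 1e3
    xy = rng.normal(scale=params.sigma_r_nm, size=(n, 2))
    e = rng.exponential(params.w_bar_ev, size=n)
    e *= edep_ev / e.sum()
    events = np.empty(n, dtype=EVENT_DTYPE)
    events["x"], events["y"] = xy.T
    events["z"] = z + rng.normal(scale=params.sigma_r_nm, size=n)
    events["edep"] = e
    return events
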