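"""Radioactive decay chains of the four clinical alpha emitters.

This module holds the nuclear data for the ²²⁵Ac, ²²³Ra, ²¹²Pb and ²¹¹At
chains and samples complete decay cascades down to a stable nuclide.  A
parent "decay" in this package always means the full cascade: all chain
members decay instantly at the parent's position (no half-life weighting,
no daughter diffusion), which is the standard cellular S-value convention
for per-decay quantities.

Every alpha emission is paired with the recoiling daughter nucleus,
``E_recoil = E_alpha * m_alpha / m_daughter`` (mass numbers), ~100 keV per
alpha decay.  Beta emissions carry a single energy drawn from an
exponential surrogate with the tabulated mean beta energy; gammas are
recorded but never transported (they escape a 30 μm world).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "EmissionKind",
    "Emission",
    "DecayBranch",
    "Nuclide",
    "NuclideLibrary",
    "DiscreteAlphaSpectrum",
    "ConfigurationError",
    "DecayDataError",
    "load_default_library",
    "sample_decay_chain",
    "discrete_alpha_spectrum",
    "mean_alpha_yield",
]

ALPHA_MASS_NUMBER = 4

#: Alpha-line energies of all packaged chains fall in this window (MeV).
ALPHA_ENERGY_WINDOW = (4.0, 10.0)


class ConfigurationError(ValueError):
    """An unknown nuclide, source location or run option was requested."""


class DecayDataError(ValueError):
    """The decay-data file violates its schema or internal invariants."""


class EmissionKind(str, Enum):
    ALPHA = "alpha"
    BETA = "beta"
    ELECTRON = "electron"          # monoenergetic conversion/Auger electron
    ELECTRON_CAPTURE = "electron_capture"
    GAMMA = "gamma"
    RECOIL = "recoil"


@dataclass(frozen=True)
class Emission:
    """A single emitted particle: kind, kinetic energy (MeV), emitting parent."""

    kind: EmissionKind
    energy: float
    parent: str

    def __post_init__(self) -> None:
        if self.energy <= 0.0:
            raise DecayDataError(
                f"non-positive emission energy {self.energy} from {self.parent}"
            )


@dataclass(frozen=True)
class DecayBranch:
    probability: float
    mode: str
    daughter: str
    emissions: tuple[Emission, ...] = ()


@dataclass(frozen=True)
class Nuclide:
    name: str
    half_life: float               # seconds; inf for stable
    branches: tuple[DecayBranch, ...] = ()
    stable: bool = False

    @property
    def mass_number(self) -> int:
        return mass_number(self.name)


@dataclass(frozen=True)
class DiscreteAlphaSpectrum:
    """Alpha line energies (MeV) with per-parent-decay emission weights."""

    energies: np.ndarray
    weights: np.ndarray

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.energies), size=n, p=self.weights)
        return self.energies[idx]


_NAME_RE = re.compile(r"^[A-Za-z]+-(\d+)$")


def mass_number(name: str) -> int:
    m = _NAME_RE.match(name)
    if m is None:
        raise DecayDataError(f"cannot parse mass number from nuclide name {name!r}")
    return int(m.group(1))


class NuclideLibrary(Mapping[str, Nuclide]):
    """A validated, cycle-free collection of nuclides forming closed chains."""

    def __init__(self, nuclides: Iterable[Nuclide]):
        self._nuclides = {n.name: n for n in nuclides}
        self._validate()

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, name: str) -> Nuclide:
        try:
            return self._nuclides[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown nuclide {name!r}; available: {sorted(self._nuclides)}"
            ) from None

    def __iter__(self):
        return iter(self._nuclides)

    def __contains__(self, name: object) -> bool:
        return name in self._nuclides

    def __len__(self) -> int:
        return len(self._nuclides)

    # ----------------------------------------------------------------------
    def _validate(self) -> None:
        for nuc in self._nuclides.values():
            if nuc.stable != (len(nuc.branches) == 0):
                raise DecayDataError(
                    f"{nuc.name}: stable flag must match an empty branch list"
                )
            if nuc.stable:
                continue
            total = sum(b.probability for b in nuc.branches)
            if abs(total - 1.0) > 1e-9:
                raise DecayDataError(
                    f"{nuc.name}: branch probabilities sum to {total!r}, not 1"
                )
            for br in nuc.branches:
                if br.daughter not in self._nuclides:
                    raise DecayDataError(
                        f"{nuc.name}: daughter {br.daughter!r} not in library"
                    )
                for em in br.emissions:
                    if em.kind is EmissionKind.ALPHA and not (
                        ALPHA_ENERGY_WINDOW[0] <= em.energy <= ALPHA_ENERGY_WINDOW[1]
                    ):
                        raise DecayDataError(
                            f"{nuc.name}: alpha line {em.energy} MeV outside "
                            f"{ALPHA_ENERGY_WINDOW}"
                        )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS three-colour cycle detection over the daughter graph.
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {name: WHITE for name in self._nuclides}

        def visit(name: str) -> None:
            colour[name] = GREY
            for br in self._nuclides[name].branches:
                d = br.daughter
                if colour[d] == GREY:
                    raise DecayDataError(f"cycle in decay chain at {d}")
                if colour[d] == WHITE:
                    visit(d)
            colour[name] = BLACK

        for name in self._nuclides:
            if colour[name] == WHITE:
                visit(name)

    # ----------------------------------------------------------------------
    def reach_probabilities(self, parent: str) -> dict[str, float]:
        """Probability that each nuclide appears in a cascade begun at parent."""
        probs: dict[str, float] = {}

        def walk(name: str, p: float) -> None:
            probs[name] = probs.get(name, 0.0) + p
            for br in self._nuclides[name].branches:
                walk(br.daughter, p * br.probability)

        walk(self[parent].name, 1.0)
        return probs

    def expected_alpha_lines(self, parent: str) -> dict[float, float]:
        """Expected number of alphas emitted per parent decay, by line energy."""
        lines: dict[float, float] = {}
        for name, p_reach in self.reach_probabilities(parent).items():
            for br in self._nuclides[name].branches:
                for em in br.emissions:
                    if em.kind is EmissionKind.ALPHA:
                        w = p_reach * br.probability
                        lines[em.energy] = lines.get(em.energy, 0.0) + w
        return lines

    def expected_alpha_yield(self, parent: str) -> float:
        """Exact mean alphas per parent decay by branch-graph enumeration."""
        return float(sum(self.expected_alpha_lines(parent).values()))


def _parse_branch(nuclide_name: str, raw: dict) -> DecayBranch:
    emissions = tuple(
        Emission(
            kind=EmissionKind(e["kind"]),
            energy=float(e["energy_mev"]),
            parent=nuclide_name,
        )
        for e in raw.get("emissions", ())
    )
    return DecayBranch(
        probability=float(raw["probability"]),
        mode=str(raw["mode"]),
        daughter=str(raw["daughter"]),
        emissions=emissions,
    )


def load_library(text: str) -> NuclideLibrary:
    """Parse a decay-chain YAML document into a validated library."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or doc.get("schema") != "alphacell-decay-v1":
        raise DecayDataError("decay data must declare schema alphacell-decay-v1")
    nuclides = []
    for name, raw in doc["nuclides"].items():
        branches = tuple(_parse_branch(name, b) for b in raw.get("branches", ()))
        nuclides.append(
            Nuclide(
                name=str(name),
                half_life=float(raw["half_life_s"]),
                branches=branches,
                stable=bool(raw.get("stable", False)),
            )
        )
    return NuclideLibrary(nuclides)


_DEFAULT_LIBRARY: NuclideLibrary | None = None


def load_default_library() -> NuclideLibrary:
    """The packaged four-chain library (cached)."""
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        text = (
            resources.files("alphacell.data")
            .joinpath("decay_chains.yaml")
            .read_text()
        )
        _DEFAULT_LIBRARY = load_library(text)
    return _DEFAULT_LIBRARY


def _recoil_for(alpha: Emission, daughter: str) -> Emission:
    e_rec = alpha.energy * ALPHA_MASS_NUMBER / mass_number(daughter)
    return Emission(kind=EmissionKind.RECOIL, energy=e_rec, parent=alpha.parent)


def sample_decay_chain(
    parent: Nuclide | str,
    rng: np.random.Generator,
    library: NuclideLibrary | None = None,
    max_half_life: float | None = None,
) -> list[Emission]:
    """Sample one complete cascade from ``parent`` to stability.

    Returns the emissions in decay order.  Each alpha is immediately
    followed by its daughter-recoil emission.  Beta energies are single
    draws from an exponential with the tabulated mean.

    Parameters
    ----------
    max_half_life:
        Optional truncation: nuclides with a longer half-life (seconds) are
        treated as chain terminators (e.g. ²⁰⁷Bi at 31.5 y in the ²¹¹At
        chain).  Default keeps everything.
    """
    lib = library if library is not None else load_default_library()
    nuc = lib[parent] if isinstance(parent, str) else parent
    out: list[Emission] = []
    while not nuc.stable:
        if max_half_life is not None and nuc.half_life > max_half_life:
            break
        probs = [b.probability for b in nuc.branches]
        branch = nuc.branches[rng.choice(len(probs), p=probs)]
        for em in branch.emissions:
            if em.kind is EmissionKind.BETA:
                out.append(
                    Emission(
                        kind=EmissionKind.BETA,
                        energy=float(rng.exponential(em.energy)) + 1e-12,
                        parent=em.parent,
                    )
                )
            else:
                out.append(em)
                if em.kind is EmissionKind.ALPHA:
                    out.append(_recoil_for(em, branch.daughter))
        nuc = lib[branch.daughter]
    return out


def discrete_alpha_spectrum(
    parent: Nuclide | str, library: NuclideLibrary | None = None
) -> DiscreteAlphaSpectrum:
    """The chain's alpha lines weighted by expected per-decay frequency.

    This is the "alpha-only" source model: one alpha per decay with line
    weights matching how often each line occurs in the full cascade,
    renormalised to 1.
    """
    lib = library if library is not None else load_default_library()
    name = parent if isinstance(parent, str) else parent.name
    lines = lib.expected_alpha_lines(name)
    if not lines:
        raise ConfigurationError(f"{name} chain emits no alphas")
    energies = np.array(sorted(lines))
    weights = np.array([lines[e] for e in energies])
    weights = weights / weights.sum()
    return DiscreteAlphaSpectrum(energies=energies, weights=weights)


def mean_alpha_yield(
    parent: Nuclide | str,
    n_samples: int,
    rng: np.random.Generator,
    library: NuclideLibrary | None = None,
) -> float:
    """Monte-Carlo mean number of alpha emissions per parent decay."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    total = 0
    for _ in range(n_samples):
        chain = sample_decay_chain(parent, rng, library=library)
        total += sum(1 for e in chain if e.kind is EmissionKind.ALPHA)
    return total / n_samples
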