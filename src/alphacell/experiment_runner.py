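"""Orchestration of the cellular dosimetry experiment grid.

A run places ``n_sources`` parent radionuclides uniformly in one
sub-volume of the two-sphere cell, samples each parent's full decay
cascade (or a single alpha from the chain's discrete line spectrum),
transports every alpha by straight-track CSDA, applies the light-particle
policy, and scores per-parent-decay quantities:

* absorbed dose to the nucleus (cGy/decay), total and alpha-only — the
  cellular S-value for the chosen source compartment;
* particles crossing the nucleus outer surface per decay ("hits"), total
  and alpha-only (unique-particle counting);
* optionally SSB/sDSB/cDSB yields from the density-clustering damage
  scorer.

Each run is repeated ``n_repeats`` times with independent child seeds
(``SeedSequence([master_seed, repeat_index])``) and quantities are
reported as mean ± SD over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decay_model as dm
from .alpha_transport import (
    AlphaTrack,
    IonizationParams,
    StoppingPowerTable,
    deposit_light_particles,
    generate_ionization_events,
    load_alpha_stopping_table,
    load_electron_range_table,
    transport_alpha,
)
from .cell_geometry import (
    CellModel,
    Region,
    SourceLocation,
    isotropic_direction,
    sample_source_position,
    sphere_segments,
)
from .damage_clustering import DamageParams, DamageSummary, score_damage
from .decay_model import (
    ConfigurationError,
    Emission,
    EmissionKind,
    NuclideLibrary,
    load_default_library,
)

__all__ = [
    "RunConfig",
    "DoseResult",
    "dose_from_energy",
    "run_experiment",
    "run_grid",
    "PAPER_RADIONUCLIDES",
]

MEV_TO_JOULE = 1.602176634e-13
GY_TO_CGY = 100.0

PAPER_RADIONUCLIDES = ("At-211", "Pb-212", "Ac-225", "Ra-223")


@dataclass(frozen=True)
class RunConfig:
    radionuclide: str = "At-211"
    location: SourceLocation = SourceLocation.NUCLEUS_VOLUME
    source_model: str = "full_chain"          # or "discrete_alpha"
    n_sources: int = 100
    n_repeats: int = 20
    seed: int = 0
    damage_enabled: bool = False
    light_particle_policy: str = "local_below_range_cut"
    recoil_policy: str = "local"
    range_cut_um: float = 1.0
    w_bar_ev: float = 37.5
    sigma_r_nm: float = 3.0
    max_half_life_s: float | None = None      # truncate long-lived members
    wall_inside: bool = False
    damage_params: DamageParams = field(default_factory=DamageParams)

    def __post_init__(self) -> None:
        if self.n_sources < 1 or self.n_repeats < 1:
            raise ValueError("n_sources and n_repeats must be >= 1")
        if self.source_model not in ("full_chain", "discrete_alpha"):
            raise ConfigurationError(
                f"unknown source model {self.source_model!r}; "
                "valid: full_chain, discrete_alpha"
            )
        # validate early so bad names fail before any sampling
        SourceLocation(self.location)


@dataclass
class QuantityStat:
    mean: float
    sd: float


@dataclass
class DoseResult:
    """Per-decay nucleus dose and surface-hit statistics, mean ± SD."""

    dose_total: QuantityStat
    dose_alpha: QuantityStat
    hits_total: QuantityStat
    hits_alpha: QuantityStat
    alpha_dose_fraction_pct: float
    n_repeats: int
    config: RunConfig

    def as_dict(self) -> dict[str, float]:
        return {
            "dose_total_cgy_per_decay": self.dose_total.mean,
            "dose_total_sd": self.dose_total.sd,
            "dose_alpha_cgy_per_decay": self.dose_alpha.mean,
            "dose_alpha_sd": self.dose_alpha.sd,
            "hits_total_per_decay": self.hits_total.mean,
            "hits_total_sd": self.hits_total.sd,
            "hits_alpha_per_decay": self.hits_alpha.mean,
            "hits_alpha_sd": self.hits_alpha.sd,
            "alpha_dose_fraction_pct": self.alpha_dose_fraction_pct,
        }


def dose_from_energy(edep_mev: float, cell: CellModel, n_decays: int) -> float:
    """Convert nucleus energy deposit to absorbed dose in cGy per decay."""
    if n_decays < 1:
        raise ValueError("n_decays must be >= 1")
    gray = edep_mev * MEV_TO_JOULE / cell.nucleus_mass_kg
    return gray * GY_TO_CGY / n_decays


def _alpha_crossed_nucleus(
    origin: np.ndarray,
    direction: np.ndarray,
    energy: float,
    cell: CellModel,
    table: StoppingPowerTable,
) -> bool:
    """True if the alpha traverses the nucleus outer surface before stopping."""
    travel = float(table.csda_range(energy))
    for seg in sphere_segments(origin, direction, cell):
        if seg.region is Region.NUCLEUS:
            if seg.entry_distance > 0.0:          # enters from outside
                return travel > seg.entry_distance
            return travel > seg.exit_distance     # born inside: must exit
    return False


def _ray_hits_nucleus(origin: np.ndarray, direction: np.ndarray,
                      cell: CellModel) -> bool:
    r = float(np.linalg.norm(origin))
    if r < cell.r_nucleus:
        return True
    return any(
        seg.region is Region.NUCLEUS
        for seg in sphere_segments(origin, direction, cell)
    )


def _run_repeat(
    config: RunConfig,
    cell: CellModel,
    table: StoppingPowerTable,
    library: NuclideLibrary,
    rng: np.random.Generator,
):
    """One statistically independent repeat; returns per-repeat tallies."""
    ion_params = IonizationParams(config.w_bar_ev, config.sigma_r_nm)
    spectrum = None
    if config.source_model == "discrete_alpha":
        spectrum = dm.discrete_alpha_spectrum(config.radionuclide, library)

    edep_total = 0.0
    edep_alpha = 0.0
    hits_total = 0
    hits_alpha = 0
    events_by_decay: dict[int, list[np.ndarray]] = {}

    positions = sample_source_position(
        SourceLocation(config.location), cell, rng,
        n=config.n_sources, wall_inside=config.wall_inside,
    )
    for decay_id in range(config.n_sources):
        position = positions[decay_id]
        if spectrum is not None:
            e_alpha = float(spectrum.sample(1, rng)[0])
            emissions = [Emission(EmissionKind.ALPHA, e_alpha,
                                  config.radionuclide)]
        else:
            emissions = dm.sample_decay_chain(
                config.radionuclide, rng, library=library,
                max_half_life=config.max_half_life_s,
            )

        for em in emissions:
            if em.kind is not EmissionKind.ALPHA:
                continue
            direction = isotropic_direction(rng)[0]
            track = AlphaTrack(position, direction, em.energy, decay_id)
            for dep in transport_alpha(track, cell, table):
                if dep.region is Region.NUCLEUS:
                    edep_total += dep.edep
                    edep_alpha += dep.edep
                    if config.damage_enabled and dep.edep > 0.0:
                        ev = generate_ionization_events(
                            dep, rng, ion_params, cell.r_nucleus
                        )
                        events_by_decay.setdefault(decay_id, []).append(ev)
            if _alpha_crossed_nucleus(position, direction, em.energy,
                                      cell, table):
                hits_total += 1
                hits_alpha += 1

        light = deposit_light_particles(
            emissions, position, cell,
            policy=config.light_particle_policy,
            range_cut_um=config.range_cut_um,
            recoil_policy=config.recoil_policy,
            decay_id=decay_id,
        )
        for dep in light:
            if dep.region is Region.NUCLEUS:
                edep_total += dep.edep
                if config.damage_enabled and dep.edep > 0.0:
                    point_dep = _as_point_deposit(dep, position)
                    ev = generate_ionization_events(
                        point_dep, rng, ion_params, cell.r_nucleus
                    )
                    events_by_decay.setdefault(decay_id, []).append(ev)
        # escaping electrons/gammas still cross surfaces geometrically
        etab = load_electron_range_table()
        for em in emissions:
            if em.kind in (EmissionKind.BETA, EmissionKind.ELECTRON):
                local = (
                    config.light_particle_policy == "local_below_range_cut"
                    and float(etab.range_um(em.energy)) < config.range_cut_um
                )
                if local:
                    continue
            elif em.kind is not EmissionKind.GAMMA:
                continue          # alphas counted above; recoils never move
            direction = isotropic_direction(rng)[0]
            if _ray_hits_nucleus(position, direction, cell):
                hits_total += 1

    merged = {
        k: (np.concatenate(v) if len(v) > 1 else v[0])
        for k, v in events_by_decay.items()
    }
    return edep_total, edep_alpha, hits_total, hits_alpha, merged


def run_experiment(
    config: RunConfig,
    cell: CellModel | None = None,
    library: NuclideLibrary | None = None,
    table: StoppingPowerTable | None = None,
) -> tuple[DoseResult, dict | None]:
    """Run one configuration with repeat statistics.

    Returns the dose/hit result and, when damage scoring is enabled, a
    dict of SSB/sDSB/cDSB per-decay means and SDs over repeats.
    """
    cell = cell or CellModel()
    library = library or load_default_library()
    table = table or load_alpha_stopping_table()
    if config.radionuclide not in library:
        raise ConfigurationError(
            f"unknown radionuclide {config.radionuclide!r}; "
            f"valid: {sorted(library)}"
        )

    dose_t, dose_a, hit_t, hit_a = [], [], [], []
    dmg = {"ssb": [], "sdsb": [], "cdsb": []}
    for repeat in range(config.n_repeats):
        rng = np.random.default_rng(
            np.random.SeedSequence([abs(int(config.seed)), repeat])
        )
        et, ea, ht, ha, events = _run_repeat(config, cell, table, library, rng)
        n = config.n_sources
        dose_t.append(dose_from_energy(et, cell, n))
        dose_a.append(dose_from_energy(ea, cell, n))
        hit_t.append(ht / n)
        hit_a.append(ha / n)
        if config.damage_enabled:
            _, agg = score_damage(events, config.damage_params, rng)
            dmg["ssb"].append(agg.n_ssb / n)
            dmg["sdsb"].append(agg.n_sdsb / n)
            dmg["cdsb"].append(agg.n_cdsb / n)

    def stat(xs: list[float]) -> QuantityStat:
        arr = np.asarray(xs)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return QuantityStat(float(arr.mean()), sd)

    dt, da = stat(dose_t), stat(dose_a)
    fraction = 100.0 * da.mean / dt.mean if dt.mean > 0 else 0.0
    result = DoseResult(
        dose_total=dt,
        dose_alpha=da,
        hits_total=stat(hit_t),
        hits_alpha=stat(hit_a),
        alpha_dose_fraction_pct=fraction,
        n_repeats=config.n_repeats,
        config=config,
    )
    damage_out = None
    if config.damage_enabled:
        damage_out = {
            f"{k}_per_decay": stat(v).mean for k, v in dmg.items()
        } | {f"{k}_per_decay_sd": stat(v).sd for k, v in dmg.items()}
    return result, damage_out


def _as_point_deposit(dep, position_um: np.ndarray):
    """Give a local (zero-path) deposit the chord fields event generation needs."""
    from dataclasses import replace

    return replace(
        dep,
        entry_point=np.asarray(position_um, dtype=float),
        direction=np.array([0.0, 0.0, 1.0]),
    )


def run_grid(
    configs: list[RunConfig],
    cell: CellModel | None = None,
) -> pd.DataFrame:
    """Run several configurations into one long-format results table."""
    if not configs:
        raise ValueError("need at least one configuration")
    rows = []
    for cfg in configs:
        result, damage = run_experiment(cfg, cell=cell)
        quantities = {
            "dose_total_cgy_per_decay": result.dose_total,
            "dose_alpha_cgy_per_decay": result.dose_alpha,
            "hits_total_per_decay": result.hits_total,
            "hits_alpha_per_decay": result.hits_alpha,
        }
        for name, q in quantities.items():
            rows.append(
                {
                    "radionuclide": cfg.radionuclide,
                    "location": SourceLocation(cfg.location).value,
                    "source_model": cfg.source_model,
                    "quantity": name,
                    "mean": q.mean,
                    "sd": q.sd,
                    "n_sources": cfg.n_sources,
                    "n_repeats": cfg.n_repeats,
                    "seed": cfg.seed,
                }
            )
        rows.append(
            {
                "radionuclide": cfg.radionuclide,
                "location": SourceLocation(cfg.location).value,
                "source_model": cfg.source_model,
                "quantity": "alpha_dose_fraction_pct",
                "mean": result.alpha_dose_fraction_pct,
                "sd": float("nan"),
                "n_sources": cfg.n_sources,
                "n_repeats": cfg.n_repeats,
                "seed": cfg.seed,
            }
        )
        if damage is not None:
            for k in ("ssb", "sdsb", "cdsb"):
                rows.append(
                    {
                        "radionuclide": cfg.radionuclide,
                        "location": SourceLocation(cfg.location).value,
                        "source_model": cfg.source_model,
                        "quantity": f"{k}_per_decay",
                        "mean": damage[f"{k}_per_decay"],
                        "sd": damage[f"{k}_per_decay_sd"],
                        "n_sources": cfg.n_sources,
                        "n_repeats": cfg.n_repeats,
                        "seed": cfg.seed,
                    }
                )
    return pd.DataFrame(rows)
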