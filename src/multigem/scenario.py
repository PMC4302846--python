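"""Declarative description of a whole-plant scenario.

A :class:`PlantScenario` lists the tissues with their mass fractions and
trophic mode, the diurnal periods with their time fractions, the interstitial
common pools, the temporal storage pools, the penalty-weighted translocation
steps, the nitrogen source and the photon objective.  Scenarios can be read
from / written to a YAML file whose schema mirrors the dataclasses below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .core import SEP, BaseGEM, ModelError

MASS_FRACTION_TOL = 1e-9

NITROGEN_SOURCES = ("nitrate", "ammonium", "both")


def _check_token(token: str, what: str) -> None:
    if not token or SEP in token:
        raise ModelError(f"{what} {token!r} must be non-empty and not contain {SEP!r}")


@dataclass
class TissueSpec:
    """One tissue replica: its weight, trophic mode and fixed growth."""

    name: str
    mass_fraction: float
    phototrophic: bool = False
    biomass_reaction: str | None = None
    growth_rate: float = 0.0  # fixed biomass flux, mmol gDW^-1 h^-1 equivalent
    disabled_reactions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_token(self.name, "tissue name")
        if not 0.0 < self.mass_fraction < 1.0 + MASS_FRACTION_TOL:
            raise ModelError(
                f"tissue {self.name!r}: mass fraction must lie in (0, 1], "
                f"got {self.mass_fraction}"
            )
        if self.growth_rate < 0:
            raise ModelError(f"tissue {self.name!r}: growth rate must be >= 0")


@dataclass
class Period:
    """One temporal slice of the cycle (e.g. day / night)."""

    name: str
    time_fraction: float
    light: bool = True

    def __post_init__(self) -> None:
        _check_token(self.name, "period name")
        if not 0.0 < self.time_fraction <= 1.0:
            raise ModelError(
                f"period {self.name!r}: time fraction must lie in (0, 1]"
            )


@dataclass
class CommonPoolSpec:
    """A zero-storage interstitial pool shared by a pair of tissues."""

    name: str
    members: tuple[str, str]
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_token(self.name, "common pool name")
        self.members = tuple(self.members)  # type: ignore[assignment]
        if len(self.members) != 2 or self.members[0] == self.members[1]:
            raise ModelError(
                f"common pool {self.name!r}: members must be two distinct tissues"
            )


@dataclass
class StoragePoolSpec:
    """A temporal pool: accumulation in some periods, release in others.

    ``sign_constraints`` maps each period name to "accumulate" (flux >= 0),
    "release" (flux <= 0) or "free".
    """

    species: str
    tissue: str
    sign_constraints: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for period, sign in self.sign_constraints.items():
            if sign not in ("accumulate", "release", "free"):
                raise ModelError(
                    f"storage pool {self.species!r}: bad sign {sign!r} "
                    f"for period {period!r}"
                )


@dataclass
class TranslocationSpec:
    """ATP cost of moving one mole of a species between a tissue and a pool.

    ``penalty_weight`` is the pw parameter: moles of ATP hydrolyzed per mole
    translocated; zero encodes passive diffusion.  The penalty attaches to
    the exporting side by default (``direction="export"``); ``"import"`` and
    ``"both"`` are accepted.
    """

    species: str
    from_tissue: str
    to_pool: str
    penalty_weight: float = 0.0
    direction: str = "export"

    def __post_init__(self) -> None:
        if self.penalty_weight < 0:
            raise ModelError("penalty weight must be >= 0")
        if self.direction not in ("export", "import", "both"):
            raise ModelError(f"bad penalty direction {self.direction!r}")


@dataclass
class PlantScenario:
    tissues: list[TissueSpec]
    periods: list[Period]
    common_pools: list[CommonPoolSpec] = field(default_factory=list)
    storage_pools: list[StoragePoolSpec] = field(default_factory=list)
    translocations: list[TranslocationSpec] = field(default_factory=list)
    nitrogen_source: str = "both"
    photon_reaction: str | None = None
    nitrate_uptake_reaction: str | None = None
    ammonium_uptake_reaction: str | None = None
    objective: str = "min_photon"
    name: str = "scenario"
    #: base-GEM ids of the ATP/ADP/Pi/H2O species charged by penalties
    energy_species: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.nitrogen_source not in NITROGEN_SOURCES:
            raise ModelError(
                f"nitrogen source must be one of {NITROGEN_SOURCES}, "
                f"got {self.nitrogen_source!r}"
            )
        if self.objective != "min_photon":
            raise ModelError(f"unsupported objective {self.objective!r}")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ModelError("duplicate tissue names")
        pnames = [p.name for p in self.periods]
        if len(set(pnames)) != len(pnames):
            raise ModelError("duplicate period names")
        total_mass = sum(t.mass_fraction for t in self.tissues)
        if abs(total_mass - 1.0) > MASS_FRACTION_TOL:
            raise ModelError(
                f"tissue mass fractions must sum to 1, got {total_mass}"
            )
        total_time = sum(p.time_fraction for p in self.periods)
        if abs(total_time - 1.0) > MASS_FRACTION_TOL:
            raise ModelError(
                f"period time fractions must sum to 1, got {total_time}"
            )
        for pool in self.common_pools:
            for member in pool.members:
                if member not in names:
                    raise ModelError(
                        f"common pool {pool.name!r}: unknown tissue {member!r}"
                    )
        for sp in self.storage_pools:
            if sp.tissue not in names:
                raise ModelError(f"storage pool: unknown tissue {sp.tissue!r}")
            missing = set(pnames) - set(sp.sign_constraints)
            if missing:
                raise ModelError(
                    f"storage pool {sp.species!r}: sign constraints missing "
                    f"periods {sorted(missing)}"
                )
        pool_names = [p.name for p in self.common_pools]
        for tr in self.translocations:
            if tr.from_tissue not in names:
                raise ModelError(f"translocation: unknown tissue {tr.from_tissue!r}")
            if tr.to_pool not in pool_names:
                raise ModelError(f"translocation: unknown pool {tr.to_pool!r}")

    # -- helpers ---------------------------------------------------------
    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise ModelError(f"unknown tissue {name!r}")

    def penalty(self, species: str, tissue: str, pool: str) -> TranslocationSpec | None:
        for tr in self.translocations:
            if (tr.species, tr.from_tissue, tr.to_pool) == (species, tissue, pool):
                return tr
        return None

    def validate_against(self, base: BaseGEM) -> None:
        """Check every reaction/metabolite reference against a base GEM."""
        for t in self.tissues:
            for rid in t.disabled_reactions:
                if not base.has_reaction(rid):
                    raise ModelError(
                        f"tissue {t.name!r}: unknown disabled reaction {rid!r}"
                    )
            if t.biomass_reaction is not None and not base.has_reaction(
                t.biomass_reaction
            ):
                raise ModelError(
                    f"tissue {t.name!r}: unknown biomass reaction "
                    f"{t.biomass_reaction!r}"
                )
        for pool in self.common_pools:
            for species in pool.species:
                if not base.has_metabolite(species):
                    raise ModelError(
                        f"common pool {pool.name!r}: unknown species {species!r}"
                    )
        for sp in self.storage_pools:
            if not base.has_metabolite(sp.species):
                raise ModelError(f"storage pool: unknown species {sp.species!r}")
        for attr in ("photon_reaction", "nitrate_uptake_reaction",
                     "ammonium_uptake_reaction"):
            rid = getattr(self, attr)
            if rid is not None and not base.has_reaction(rid):
                raise ModelError(f"{attr}: unknown reaction {rid!r}")
        if self.photon_reaction is None:
            raise ModelError("scenario must name exactly one photon reaction")


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------


def scenario_to_dict(scenario: PlantScenario) -> dict:
    d = asdict(scenario)
    for pool in d["common_pools"]:
        pool["members"] = list(pool["members"])
    return d


def save_scenario(scenario: PlantScenario, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(scenario_to_dict(scenario), handle, sort_keys=False)


def load_scenario(path) -> PlantScenario:
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    return scenario_from_dict(data)


def scenario_from_dict(data: dict) -> PlantScenario:
    try:
        return PlantScenario(
            tissues=[TissueSpec(**t) for t in data["tissues"]],
            periods=[Period(**p) for p in data["periods"]],
            common_pools=[
                CommonPoolSpec(**{**p, "members": tuple(p["members"])})
                for p in data.get("common_pools", [])
            ],
            storage_pools=[
                StoragePoolSpec(**s) for s in data.get("storage_pools", [])
            ],
            translocations=[
                TranslocationSpec(**t) for t in data.get("translocations", [])
            ],
            nitrogen_source=data.get("nitrogen_source", "both"),
            photon_reaction=data.get("photon_reaction"),
            nitrate_uptake_reaction=data.get("nitrate_uptake_reaction"),
            ammonium_uptake_reaction=data.get("ammonium_uptake_reaction"),
            objective=data.get("objective", "min_photon"),
            name=data.get("name", "scenario"),
            energy_species=data.get("energy_species"),
        )
    except KeyError as exc:
        raise ModelError(f"scenario file missing key {exc}") from exc
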