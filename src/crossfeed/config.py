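"""Strain, medium, and simulation configuration.

Units are fixed package-wide: lengths in um, time in hours internally
(the diffusion timestep ``t_u`` is configured in seconds and converted),
amounts in fmole, and concentrations in fmol/um^3.  The conversion to
molarity is convenient: 1 fmol/um^3 = 1 M, so 1 uM = 1e-6 fmol/um^3.

The three-strain community follows the engineered yeast system:

* cooperator ``R`` requires lysine and continuously releases adenine,
* partner ``G`` requires adenine and releases lysine when it dies,
* cheater ``C`` requires lysine, releases nothing, and carries an
  intrinsic fitness advantage expressed as a multiplier on its maximum
  uptake rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import yaml

__all__ = [
    "UM",
    "LYSINE",
    "ADENINE",
    "GLUCOSE",
    "StrainSpec",
    "MediumSpec",
    "SimulationConfig",
    "InvalidSpecError",
    "derive_vm",
    "default_panel",
    "load_config",
    "save_config",
]

#: 1 micromolar expressed in package concentration units (fmol/um^3).
UM = 1e-6

LYSINE = "lysine"
ADENINE = "adenine"
GLUCOSE = "glucose"


class InvalidSpecError(ValueError):
    """A strain/medium/simulation specification violates its invariants."""


@dataclass
class StrainSpec:
    """Kinetic and release parameters of one strain.

    Parameters marked ASSUMED have defaults chosen by this package (the
    published source-data table is not reproduced here); they give a
    minimum doubling time of ~2 hr and visible community growth within
    eight generations.
    """

    id: str
    required_metabolite: str  # "lysine" or "adenine"
    quota_alpha: float  # fmole of required metabolite per division (ASSUMED)
    glucose_quota: float  # fmole of shared resource per division (ASSUMED)
    r_max: float  # maximum growth rate, 1/hr (ASSUMED: ln2/2 hr doubling)
    monod_K: float  # half-saturation of required metabolite, fmol/um^3 (ASSUMED)
    fitness_multiplier: float = 1.0  # dimensionless scaling of max uptake
    release_mode: str = "none"  # "continuous" | "on_death" | "none"
    release_rate_gamma: float = 0.0  # fmol per live cell per hr (continuous)
    release_on_death_beta: float = 0.0  # fmole released on death
    release_fraction_d: float = 1.0  # 0..1 scaling of continuous release
    death_rate: float = 0.0  # 1/hr
    glucose_K: float = 500 * UM  # half-saturation for glucose (ASSUMED)
    glucose_uptake_factor: float = 2.0  # glucose v_m relative to quota rate (ASSUMED)

    def __post_init__(self) -> None:
        if self.required_metabolite not in (LYSINE, ADENINE):
            raise InvalidSpecError(
                f"{self.id}: required_metabolite must be lysine or adenine"
            )
        if self.quota_alpha <= 0 or self.glucose_quota <= 0:
            raise InvalidSpecError(f"{self.id}: quotas must be positive")
        if self.r_max <= 0:
            raise InvalidSpecError(f"{self.id}: r_max must be positive")
        if self.fitness_multiplier <= 0:
            raise InvalidSpecError(f"{self.id}: fitness_multiplier must be > 0")
        if not 0.0 <= self.release_fraction_d <= 1.0:
            raise InvalidSpecError(f"{self.id}: release_fraction_d must be in [0, 1]")
        if self.death_rate < 0:
            raise InvalidSpecError(f"{self.id}: death_rate must be >= 0")
        if self.release_mode not in ("continuous", "on_death", "none"):
            raise InvalidSpecError(f"{self.id}: unknown release_mode")
        if self.release_mode == "none" and (
            self.release_rate_gamma != 0 or self.release_on_death_beta != 0
        ):
            raise InvalidSpecError(
                f"{self.id}: release_mode 'none' requires gamma = beta = 0"
            )

    @property
    def released_metabolite(self) -> str | None:
        """The metabolite this strain releases (the one it does not require)."""
        if self.release_mode == "none":
            return None
        return ADENINE if self.required_metabolite == LYSINE else LYSINE

    @property
    def max_uptake_rate(self) -> float:
        return derive_vm(self)

    @property
    def glucose_vm(self) -> float:
        """Maximum glucose uptake, fmol/hr/cell.

        Scaled ``glucose_uptake_factor``-fold above the quota-matched rate
        so that the required metabolite, not the shared resource, is the
        rate-limiting acquisition when both are abundant.
        """
        return self.glucose_uptake_factor * self.glucose_quota * self.r_max / math.log(2)


def derive_vm(spec: StrainSpec) -> float:
    """Maximum uptake rate v_m of the required metabolite, fmol/hr/cell.

    v_m = fitness_multiplier * alpha * r_max / ln 2: a cell taking up at
    v_m accumulates one division quota per minimum doubling time, and the
    intrinsic fitness advantage scales the uptake rate (equivalently the
    maximum growth rate) at all concentrations.
    """
    if spec.quota_alpha <= 0 or spec.r_max <= 0:
        raise InvalidSpecError(f"{spec.id}: quota and r_max must be positive")
    return spec.fitness_multiplier * spec.quota_alpha * spec.r_max / math.log(2)


# Package defaults (ASSUMED; see docs/methods.md for the calibration
# rationale -- chosen for a ~2 hr minimum doubling time, community growth
# to 6-8 generations within ~2 days, and cross-fed benefits that stay
# spatially localized at desk scale).
_ALPHA_LYS = 2.0  # fmole lysine per R/C division
_ALPHA_ADE = 1.0  # fmole adenine per G division
_ALPHA_GLU = 30.0  # fmole glucose per division, all strains
# Exactly a 2 hr minimum doubling time.  This also makes the baseline
# division interval an exact multiple of the 6 min cell-update window, so
# quota accumulation is not systematically penalized by interval rounding
# (a fitness multiplier then shifts the realized interval as intended).
_R_MAX = math.log(2) / 2.0  # 1/hr
_K_LYS = 1.0 * UM
_K_ADE = 0.2 * UM
# The adenine release rate is kept below the partner population's maximum
# uptake capacity (gamma < ~0.5 v_m,G) so the shared pool stays
# demand-limited and the benefit remains spatially localized; the lysine
# death payload is kept small for the same reason (see docs/methods.md).
_GAMMA_A = 0.22  # fmol adenine / live R cell / hr
_BETA_L = 3.5  # fmole lysine released per G death
_DEATH_RC = 0.01  # 1/hr
_DEATH_G = 0.20  # 1/hr


def default_panel(
    cheater_advantage: float = 0.02,
    release_fraction_d: float = 0.0,
    third_id: str | None = None,
) -> tuple[StrainSpec, StrainSpec, StrainSpec]:
    """Build the standard three-strain panel (R, G, third).

    The third strain requires lysine like R and releases adenine at a
    rate ``d``-fold (0 <= d <= 1) of R's; ``d = 0`` reproduces the
    non-releasing cheater C, ``0 < d < 1`` the partial releaser, and
    ``d = 1`` with zero advantage an exact clone of R.  Its maximum
    uptake rate is scaled by ``1 + cheater_advantage``.
    """
    if cheater_advantage < 0:
        raise InvalidSpecError("cheater_advantage must be >= 0")
    if third_id is None:
        third_id = "C" if release_fraction_d == 0 else "Rd"
    r = StrainSpec(
        id="R",
        required_metabolite=LYSINE,
        quota_alpha=_ALPHA_LYS,
        glucose_quota=_ALPHA_GLU,
        r_max=_R_MAX,
        monod_K=_K_LYS,
        release_mode="continuous",
        release_rate_gamma=_GAMMA_A,
        release_fraction_d=1.0,
        death_rate=_DEATH_RC,
    )
    g = StrainSpec(
        id="G",
        required_metabolite=ADENINE,
        quota_alpha=_ALPHA_ADE,
        glucose_quota=_ALPHA_GLU,
        r_max=_R_MAX,
        monod_K=_K_ADE,
        release_mode="on_death",
        release_on_death_beta=_BETA_L,
        death_rate=_DEATH_G,
    )
    third = StrainSpec(
        id=third_id,
        required_metabolite=LYSINE,
        quota_alpha=_ALPHA_LYS,
        glucose_quota=_ALPHA_GLU,
        r_max=_R_MAX,
        monod_K=_K_LYS,
        fitness_multiplier=1.0 + cheater_advantage,
        release_mode="continuous" if release_fraction_d > 0 else "none",
        release_rate_gamma=_GAMMA_A if release_fraction_d > 0 else 0.0,
        release_fraction_d=release_fraction_d,
        death_rate=_DEATH_RC,
    )
    return r, g, third


@dataclass
class MediumSpec:
    """Agarose medium composition and geometry.

    Concentrations in fmol/um^3 (= molar); the competition medium is
    supplemented with 650 uM lysine and 430 uM adenine, the cooperation
    and cheating medium with neither.
    """

    supplemented_lysine: float = 0.0
    supplemented_adenine: float = 0.0
    initial_glucose: float = 0.111  # fmol/um^3 = 111 mM (2% glucose), ASSUMED non-limiting
    agarose_height: float = 1500.0  # um (desk-scaled pad thickness)

    def __post_init__(self) -> None:
        if min(self.supplemented_lysine, self.supplemented_adenine, self.initial_glucose) < 0:
            raise InvalidSpecError("concentrations must be >= 0")
        if self.agarose_height <= 0:
            raise InvalidSpecError("agarose_height must be > 0")

    @classmethod
    def supplemented(cls) -> "MediumSpec":
        """Competition medium: 650 uM lysine and 430 uM adenine.

        A deeper agarose reservoir keeps the supplements effectively
        unlimited over 6-8 generations, as on a real pad.
        """
        return cls(supplemented_lysine=650 * UM, supplemented_adenine=430 * UM,
                   agarose_height=2520.0)

    @classmethod
    def unsupplemented(cls) -> "MediumSpec":
        """Cooperation-and-cheating medium: no lysine or adenine."""
        return cls()


@dataclass
class SimulationConfig:
    """Geometry, numerics, and variant flags for one simulation.

    The physical diffusion timestep ``diffusion_timestep_tu`` (t_u = 3.5 s)
    with D = 360 um^2/s on a 60 um grid exceeds the explicit 3-D stability
    bound, so the solver sub-steps internally while the cell engine still
    sees whole t_u updates.
    """

    domain_um: tuple[float, float] = (300.0, 300.0)  # lateral extent, periodic
    community_height_um: float = 180.0  # community + air above agarose
    cell_pitch: float = 5.0  # um
    community_grid: float = 15.0  # um
    agarose_grid: float = 60.0  # um
    diffusion_timestep_tu: float = 3.5  # s
    cell_update_interval_tau: float = 6.0  # min
    D_agarose: float = 360.0  # um^2/s
    D_community_max: float = 20.0  # um^2/s
    D_air: float = 0.0  # um^2/s
    vertical_bud_probability: float = 0.7
    enclosure_radius_cells: int = 5
    mixing_interval: float | None = None  # hr; 12 for the mixed protocol
    target_generations: float | None = 6.0
    max_hours: float = 72.0
    rng_seed: int = 0
    excess_release_factor: float = 1.0  # 200 for the delocalization variant
    instant_distribution: bool = False
    uniform_D: bool = False  # single-grid variant: D = D_agarose everywhere
    snapshot_every_generation: float = 1.0
    # a division whose vertical push would cross the domain ceiling is
    # deferred to a later window ("arrest") or raises ("error")
    overflow_policy: str = "arrest"

    def __post_init__(self) -> None:
        if self.community_grid % self.cell_pitch != 0:
            raise InvalidSpecError("community_grid must be a multiple of cell_pitch")
        if self.agarose_grid % self.community_grid != 0:
            raise InvalidSpecError("agarose_grid must be a multiple of community_grid")
        for length in self.domain_um:
            if length % self.agarose_grid != 0:
                raise InvalidSpecError("domain extent must be a multiple of agarose_grid")
        if self.community_height_um % self.community_grid != 0:
            raise InvalidSpecError(
                "community_height_um must be a multiple of community_grid"
            )
        tau_s = self.cell_update_interval_tau * 60.0
        if tau_s < 2 * self.diffusion_timestep_tu:
            raise InvalidSpecError("tau must be much larger than t_u")
        if not 0.0 <= self.vertical_bud_probability <= 1.0:
            raise InvalidSpecError("vertical_bud_probability must be in [0, 1]")

    @property
    def tau_hours(self) -> float:
        return self.cell_update_interval_tau / 60.0

    @property
    def tu_hours(self) -> float:
        return self.diffusion_timestep_tu / 3600.0

    @property
    def steps_per_tau(self) -> int:
        """Whole t_u steps per cell-update window."""
        return max(1, round(self.cell_update_interval_tau * 60.0 / self.diffusion_timestep_tu))


# -- flat YAML round trip ---------------------------------------------------

_SCHEMA_VERSION = 1


def save_config(
    path,
    strains: list[StrainSpec],
    medium: MediumSpec,
    sim: SimulationConfig,
) -> None:
    """Write a flat, versioned YAML document describing a full setup."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "strains": [asdict(s) for s in strains],
        "medium": asdict(medium),
        "simulation": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(sim).items()
        },
    }
    with open(path, "w") as fh:
        fh.write("# crossfeed configuration (units: um, hr, fmole, fmol/um^3)\n")
        fh.write("# v_m,i = alpha_i * r_m,i / ln2 is derived, not stored.\n")
        fh.write("# Kinetic defaults are ASSUMED (see docs/methods.md).\n")
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[list[StrainSpec], MediumSpec, SimulationConfig]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise InvalidSpecError(f"unsupported schema_version {doc.get('schema_version')}")
    strains = [StrainSpec(**s) for s in doc["strains"]]
    medium = MediumSpec(**doc["medium"])
    simdoc = dict(doc["simulation"])
    simdoc["domain_um"] = tuple(simdoc["domain_um"])
    sim = SimulationConfig(**simdoc)
    return strains, medium, sim


def clone(spec: StrainSpec, **changes) -> StrainSpec:
    """Copy a StrainSpec with field overrides (re-validates)."""
    return replace(spec, **changes)
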