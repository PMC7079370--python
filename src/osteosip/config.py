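"""Simulation configuration: network, compartments, stimulus, parameters.

This module is the single source of truth for a run.  The default network
is a documented skeleton of the osteoblast mechanotransduction cascade:
load-driven integrin activation at the membrane, the RAF -> MEK -> ERK ->
RUNX2 module with timer-governed activation-cycle switches (ACS), and a
minimal transcription/translation tail (RUNX2 -> mRNA -> ribosome ->
vesicle -> ECM protein).  All timer means are exposed as configuration so
the sensitivity sweep over the six ACS parameters can be expressed
declaratively.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .labels import ANY, COMPARTMENTS, L, StateLabel


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration input."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionRule:
    """One interaction rule of the agent model.

    kind:
      * ``binding``      -- two reactants; the first ("seeker") queries all
        molecules within the interaction range and reacts with the nearest
        eligible partner.  If the product labels carry a ``bound`` species a
        complex is formed, otherwise the contact only changes states.
      * ``state_transition`` -- one reactant, timer driven.
      * ``dissociation`` -- one bound reactant (the complex carrier), timer
        driven; first product is the carrier's new label, second the
        partner's, any further products are newly created agents.
      * ``production``   -- one reactant, timer driven and recurring; extra
        products are created next to the reactant.
      * ``degradation``  -- one reactant, timer driven; the agent is removed.

    ``timer_mean`` is the ACS parameter T for timer-driven kinds; timers are
    drawn uniformly on ``timer_support`` (default [0, 2 T]), which makes the
    per-complex dissociation times uniformly distributed as in a Poisson
    decay bookkeeping over the population.
    """

    name: str
    kind: str
    reactant_labels: tuple[StateLabel, ...]
    product_labels: tuple[StateLabel, ...]
    timer_mean: float | None = None
    timer_support: tuple[float, float] | None = None
    range_limited: bool = False

    def __post_init__(self) -> None:
        kinds = ("binding", "state_transition", "dissociation", "production",
                 "degradation")
        if self.kind not in kinds:
            raise ConfigError(f"rule {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "binding":
            if len(self.reactant_labels) != 2:
                raise ConfigError(
                    f"rule {self.name!r}: binding needs exactly 2 reactants")
            if len(self.product_labels) != 2:
                raise ConfigError(
                    f"rule {self.name!r}: binding needs exactly 2 products")
        else:
            if len(self.reactant_labels) != 1:
                raise ConfigError(
                    f"rule {self.name!r}: {self.kind} needs exactly 1 reactant")
            if self.timer_mean is None or self.timer_mean < 0:
                raise ConfigError(
                    f"rule {self.name!r}: timer-driven rule needs timer_mean >= 0")
            support = self.timer_support or (0.0, 2.0 * self.timer_mean)
            lo, hi = support
            if hi < lo:
                raise ConfigError(f"rule {self.name!r}: timer support hi < lo")
            if not (lo <= self.timer_mean <= hi):
                raise ConfigError(
                    f"rule {self.name!r}: timer_mean outside its support")
            object.__setattr__(self, "timer_support", (float(lo), float(hi)))

    @property
    def support(self) -> tuple[float, float]:
        if self.timer_support is not None:
            return self.timer_support
        return (0.0, 2.0 * (self.timer_mean or 0.0))


@dataclass(frozen=True)
class MechanicalStimulus:
    """Square-wave load: magnitude M for the first half period, baseline m0
    for the second, phase 0.  All magnitudes in micro-pascal."""

    magnitude: float = 10_000.0
    period: float = 1_000.0
    baseline: float = 100.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (self.magnitude >= self.baseline > 0):
            raise ConfigError("stimulus requires M >= m0 > 0")
        if self.period <= 0:
            raise ConfigError("stimulus period must be positive")


@dataclass(frozen=True)
class CompartmentGeometry:
    """Nested concentric spheres: nucleus < cell < extracellular boundary.

    Lengths are in arbitrary micrometre-like units; only ratios relative to
    the interaction range matter for the dynamics.
    """

    nucleus_radius: float = 2.0
    cell_radius: float = 5.0
    extracellular_radius: float = 7.0

    def __post_init__(self) -> None:
        if not (0 < self.nucleus_radius < self.cell_radius
                < self.extracellular_radius):
            raise ConfigError("compartment radii must be nested and positive")

    def compartment_of(self, radius: float) -> str:
        if radius < self.nucleus_radius:
            return "nucleus"
        if radius <= self.cell_radius:
            return "cytoplasm"
        return "extracellular"


#: radial shell [lo, hi] each species may occupy, as attribute names of
#: CompartmentGeometry (None meaning the centre).  Membrane species are
#: static on the cell surface.
SPECIES_SHELLS: dict[str, tuple[str | None, str]] = {
    "integrin": ("cell_radius", "cell_radius"),
    "RAF": ("nucleus_radius", "cell_radius"),
    "MEK": ("nucleus_radius", "cell_radius"),
    "ERK": ("nucleus_radius", "cell_radius"),
    "RUNX2": (None, "cell_radius"),
    "mRNA": (None, "cell_radius"),
    "ribosome": ("nucleus_radius", "cell_radius"),
    "vesicle": ("nucleus_radius", "cell_radius"),
    "ECMprotein": ("nucleus_radius", "extracellular_radius"),
}

STATIC_SPECIES = frozenset({"integrin"})

#: default split of the 8890 initial agents across species (all start
#: inactive and unbound); integrin-heavy membrane pool, balanced MAPK pools.
DEFAULT_COUNTS: dict[str, int] = {
    "integrin": 2000,
    "RAF": 1200,
    "MEK": 1500,
    "ERK": 1500,
    "RUNX2": 800,
    "ribosome": 1500,
    "vesicle": 200,
    "ECMprotein": 190,
    "mRNA": 0,
}

#: the six simulation-dependent ACS timers of the RAF-MEK-ERK module plus
#: the fixed auxiliary timers of the skeleton network (seconds).
DEFAULT_TIMERS: dict[str, float] = {
    # varied in the sensitivity sweep
    "T_RAFact+MEKd->MEKact": 90.0,
    "T_MEKact->MEKd": 90.0,
    "T_MEKact+ERKd->ERKact": 10.0,
    "T_MEKact+ERKd->MEKact": 90.0,
    "T_ERKact->ERKd": 90.0,
    "T_ERKact+RUNX2d->ERKact": 10.0,
    # fixed skeleton timers
    "T_integrin_deact": 50.0,
    "T_RAFact->RAFd": 90.0,
    "T_RUNX2act->RUNX2d": 300.0,
    "T_transcription": 2000.0,
    "T_translation": 300.0,
    "T_secretion": 200.0,
    "T_mRNA_decay": 2000.0,
    "T_mRNA_clearance": 300.0,
}


def build_rules(timers: dict[str, float] | None = None) -> tuple[ReactionRule, ...]:
    """Construct the default reaction network from a timer-mean table."""
    T = dict(DEFAULT_TIMERS)
    if timers:
        unknown = set(timers) - set(T)
        if unknown:
            raise ConfigError(f"unknown timer name(s): {sorted(unknown)}")
        T.update(timers)

    def rule(name, kind, reac, prod, mean=None, range_limited=False):
        return ReactionRule(name, kind, tuple(reac), tuple(prod),
                            timer_mean=mean, range_limited=range_limited)

    return (
        # membrane: active integrin touches inactive RAF -> RAF activates
        rule("integrin_activates_RAF", "binding",
             [L("integrin", "active"), L("RAF", "inactive")],
             [L("integrin", "active"), L("RAF", "active")],
             range_limited=True),
        rule("integrin_deactivation", "state_transition",
             [L("integrin", "active")], [L("integrin", "inactive")],
             mean=T["T_integrin_deact"]),
        rule("RAF_deactivation", "state_transition",
             [L("RAF", "active")], [L("RAF", "inactive")],
             mean=T["T_RAFact->RAFd"]),
        # RAFact + MEKd -> RAF:MEK complex; on timer expiry MEK activates
        # and, being the state-changed molecule, breaks away (partial
        # dissociation); RAF is released still active.
        rule("RAF_MEK_binding", "binding",
             [L("RAF", "active"), L("MEK", "inactive")],
             [L("RAF", "active", "MEK"), L("MEK", "inactive", "RAF")],
             range_limited=True),
        rule("RAF_MEK_activation", "dissociation",
             [L("MEK", "inactive", "RAF")],
             [L("MEK", "active"), L("RAF", "active")],
             mean=T["T_RAFact+MEKd->MEKact"]),
        rule("MEK_deactivation", "state_transition",
             [L("MEK", "active")], [L("MEK", "inactive")],
             mean=T["T_MEKact->MEKd"]),
        # MEKact + ERKd -> MEK:ERK complex with two competing outcomes
        rule("MEK_ERK_binding", "binding",
             [L("MEK", "active"), L("ERK", "inactive")],
             [L("MEK", "active", "ERK"), L("ERK", "inactive", "MEK")],
             range_limited=True),
        rule("MEK_ERK_activation", "dissociation",
             [L("ERK", "inactive", "MEK")],
             [L("ERK", "active"), L("MEK", "active")],
             mean=T["T_MEKact+ERKd->ERKact"]),
        rule("MEK_ERK_relaxation", "dissociation",
             [L("ERK", "inactive", "MEK")],
             [L("ERK", "inactive"), L("MEK", "active")],
             mean=T["T_MEKact+ERKd->MEKact"]),
        rule("ERK_deactivation", "state_transition",
             [L("ERK", "active")], [L("ERK", "inactive")],
             mean=T["T_ERKact->ERKd"]),
        # ERKact + RUNX2d -> ERK:RUNX2; RUNX2 is phosphorylated and released
        rule("ERK_RUNX2_binding", "binding",
             [L("ERK", "active"), L("RUNX2", "inactive")],
             [L("ERK", "active", "RUNX2"), L("RUNX2", "inactive", "ERK")],
             range_limited=True),
        rule("ERK_RUNX2_activation", "dissociation",
             [L("RUNX2", "inactive", "ERK")],
             [L("RUNX2", "active"), L("ERK", "active")],
             mean=T["T_ERKact+RUNX2d->ERKact"]),
        rule("RUNX2_deactivation", "state_transition",
             [L("RUNX2", "active")], [L("RUNX2", "inactive")],
             mean=T["T_RUNX2act->RUNX2d"]),
        # transcription / translation skeleton: an active RUNX2 produces
        # mRNA; a ribosome translates each transcript once (the spent
        # transcript, marked "active", is cleared), packaging the protein
        # into a vesicle that matures into extracellular-matrix protein.
        rule("transcription", "production",
             [L("RUNX2", "active")], [L("RUNX2", "active"), L("mRNA")],
             mean=T["T_transcription"]),
        rule("translation_binding", "binding",
             [L("mRNA", "inactive"), L("ribosome", "inactive")],
             [L("mRNA", "inactive", "ribosome"),
              L("ribosome", "inactive", "mRNA")],
             range_limited=True),
        rule("translation", "dissociation",
             [L("mRNA", "inactive", "ribosome")],
             [L("mRNA", "active"), L("ribosome", "inactive"),
              L("vesicle", "active")],
             mean=T["T_translation"]),
        rule("secretion", "state_transition",
             [L("vesicle", "active")], [L("ECMprotein", "inactive")],
             mean=T["T_secretion"]),
        rule("mRNA_decay", "degradation",
             [L("mRNA", "inactive")], (),
             mean=T["T_mRNA_decay"]),
        rule("mRNA_clearance", "degradation",
             [L("mRNA", "active")], (),
             mean=T["T_mRNA_clearance"]),
    )


@dataclass
class SimulationConfig:
    """Complete description of one run; validated on construction."""

    seed: int = 0
    duration: float = 9.0e4
    dt: float = 1.0
    initial_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS))
    timers: dict[str, float] = field(default_factory=dict)
    rules: tuple[ReactionRule, ...] | None = None
    stimulus: MechanicalStimulus = field(default_factory=MechanicalStimulus)
    geometry: CompartmentGeometry = field(default_factory=CompartmentGeometry)
    r_inter: float = 1.0
    diffusion_step: float = 0.5
    #: per-step integrin activation probability at the reference magnitude
    activation_rate: float = 0.05
    reference_magnitude: float = 10_000.0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.rules is None:
            self.rules = build_rules(self.timers)
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        n_steps = self.duration / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigError("duration must be a multiple of dt")
        if self.r_inter <= 0:
            raise ConfigError("r_inter must be positive")
        if self.diffusion_step < 0:
            raise ConfigError("diffusion_step must be non-negative")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be positive")
        if not (0 <= self.activation_rate <= 1):
            raise ConfigError("activation_rate must be a probability")
        if self.reference_magnitude <= self.stimulus.baseline:
            raise ConfigError("reference_magnitude must exceed the baseline")
        for sp, n in self.initial_counts.items():
            if sp not in SPECIES_SHELLS:
                raise ConfigError(f"unknown species {sp!r} in initial_counts")
            if n < 0 or n != int(n):
                raise ConfigError(f"count for {sp!r} must be a non-negative int")
        # species absent from initial_counts start at zero (they may be
        # produced at run time); species outside the registry are errors
        for r in self.rules:
            for lab in (*r.reactant_labels, *r.product_labels):
                if lab.species not in SPECIES_SHELLS:
                    raise ConfigError(
                        f"rule {r.name!r} references unknown species "
                        f"{lab.species!r}")

    # -- derived -----------------------------------------------------------
    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def total_agents(self) -> int:
        return int(sum(self.initial_counts.values()))

    def timer_table(self) -> dict[str, float]:
        table = dict(DEFAULT_TIMERS)
        table.update(self.timers)
        return table


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def apply_scale(config: SimulationConfig, s: float) -> SimulationConfig:
    """Rescale molecular counts by ``s`` and the interaction range by
    ``s**(-1/3)``.

    Keeping ``n * R_inter**3`` constant preserves the expected number of
    potential partners inside each molecule's interaction sphere, which is
    what keeps the average binding kinetics unchanged when the population
    is thinned.
    """
    if s <= 0:
        raise ConfigError("scale factor must be positive")
    counts = {sp: int(math.floor(n * s + 0.5))
              for sp, n in config.initial_counts.items()}
    for sp, n in counts.items():
        if n == 0 and config.initial_counts[sp] > 0:
            import warnings
            warnings.warn(
                f"species {sp!r} scaled to zero agents while its rules remain",
                stacklevel=2)
    new = copy.deepcopy(config)
    new.initial_counts = counts
    new.r_inter = config.r_inter * s ** (-1.0 / 3.0)
    new.scale_factor = config.scale_factor * s
    new.validate()
    return new


_STIM_KEYS = ("magnitude", "period", "baseline", "phase")
_GEOM_KEYS = ("nucleus_radius", "cell_radius", "extracellular_radius")
_SCALAR_KEYS = ("seed", "duration", "dt", "r_inter", "diffusion_step",
                "activation_rate", "reference_magnitude", "scale_factor")


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        **{k: getattr(config, k) for k in _SCALAR_KEYS},
        "initial_counts": dict(config.initial_counts),
        "timers": dict(config.timers),
        "stimulus": {k: getattr(config.stimulus, k) for k in _STIM_KEYS},
        "geometry": {k: getattr(config.geometry, k) for k in _GEOM_KEYS},
    }


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML/JSON configuration file.

    Unspecified fields take the documented defaults; a minimal file naming
    only ``seed`` yields the baseline network with 8890 agents.  An
    optional top-level ``scale`` other than 1 is applied via
    :func:`apply_scale` after loading (``scale_factor`` itself is stored
    provenance: the cumulative scale already baked into the counts).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimulationConfig:
    raw = dict(raw)
    scale = float(raw.pop("scale", 1.0))
    kwargs: dict = {}
    for key in _SCALAR_KEYS:
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "initial_counts" in raw:
        counts = dict(DEFAULT_COUNTS)
        counts.update(raw.pop("initial_counts"))
        kwargs["initial_counts"] = counts
    if "timers" in raw:
        kwargs["timers"] = dict(raw.pop("timers"))
    if "stimulus" in raw:
        kwargs["stimulus"] = MechanicalStimulus(**raw.pop("stimulus"))
    if "geometry" in raw:
        kwargs["geometry"] = CompartmentGeometry(**raw.pop("geometry"))
    if raw:
        raise ConfigError(f"unknown configuration key(s): {sorted(raw)}")
    try:
        config = SimulationConfig(**kwargs)
    except TypeError as exc:  # bad field types
        raise ConfigError(str(exc)) from exc
    if scale != 1.0:
        config = apply_scale(config, scale)
    return config


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration such that :func:`load_config` round-trips."""
    d = config_to_dict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(config: SimulationConfig) -> str:
    import hashlib
    import json

    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
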