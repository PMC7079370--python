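"""Categorical state labels for molecular subpopulations.

A simulated molecule is described by four categorical attributes: its
species, its activation state, the species it is bound to (if any) and the
compartment it currently occupies.  Position and velocity are deliberately
not part of the label: the analysed signals are the per-time-step sums of
molecules sharing the same label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ACTIVATIONS = ("inactive", "active")
COMPARTMENTS = ("nucleus", "cytoplasm", "membrane", "extracellular")

#: wildcard compartment used in reaction-rule reactant patterns
ANY = "any"


@dataclass(frozen=True, order=True)
class StateLabel:
    """Hashable, totally ordered molecular state label.

    Two agents with an equal label are statistically exchangeable.  The
    ``compartment`` may be :data:`ANY` in rule patterns; recorded count
    columns always carry a concrete compartment.
    """

    species: str
    activation: str = "inactive"
    bound: str | None = field(default=None)
    compartment: str = ANY

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation state {self.activation!r}")
        if self.compartment not in COMPARTMENTS + (ANY,):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def token(self) -> str:
        """Dotted column token, e.g. ``MEK.inactive.RAF.cytoplasm``."""
        bound = self.bound if self.bound is not None else "none"
        return f"{self.species}.{self.activation}.{bound}.{self.compartment}"

    @classmethod
    def from_token(cls, token: str) -> "StateLabel":
        parts = token.split(".")
        if len(parts) != 4:
            raise ValueError(f"malformed label token {token!r}")
        species, activation, bound, compartment = parts
        return cls(
            species=species,
            activation=activation,
            bound=None if bound == "none" else bound,
            compartment=compartment,
        )

    def matches(self, other: "StateLabel") -> bool:
        """Pattern match ignoring a wildcard compartment on either side."""
        if (self.species, self.activation, self.bound) != (
            other.species,
            other.activation,
            other.bound,
        ):
            return False
        return (
            self.compartment == ANY
            or other.compartment == ANY
            or self.compartment == other.compartment
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.token


def L(species: str, activation: str = "inactive", bound: str | None = None,
      compartment: str = ANY) -> StateLabel:
    """Shorthand constructor used throughout the default network."""
    return StateLabel(species, activation, bound, compartment)
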