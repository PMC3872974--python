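"""Model parameters for the Tconv/Treg/IL-2 activation models.

All rates are dimensionless (a common time unit is implied throughout);
populations are in cells and IL-2 in molecules. The canonical parameter set
used for all headline analyses ships as :func:`table1` and as the packaged
``data/table1.toml`` fixture.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

__all__ = ["ParameterSet", "table1", "DEFAULT_G"]

#: Default natural death rate of naive T cells and resting Tregs. The value
#: is not fixed by the headline threshold analysis (the reduced activation-
#: driven system does not contain g), and every g-dependent output reports
#: the g actually used.
DEFAULT_G = 0.1

_RATE_FIELDS = (
    "a", "b", "c", "d", "e", "f", "g", "beta", "gamma", "epsilon", "N0", "lam",
)


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants of the nested activation models.

    Parameters
    ----------
    a : float
        IL-2-dependent proliferation rate of activated T cells
        [molecules^-1 time^-1].
    b : float
        Natural death rate of activated T cells and activated Tregs
        [time^-1].
    c : float
        Fratricide (activation-induced cell death) rate of activated
        T cells [cells^-1 time^-1].
    d : float
        IL-2 secretion rate of activated T cells
        [molecules cells^-1 time^-1].
    e : float
        IL-2 consumption rate of activated cells [cells^-1 time^-1].
    f : float
        IL-2 decay rate [time^-1].
    g : float
        Natural death rate of naive T cells and resting Tregs [time^-1].
    beta : float
        Antigen-stimulation rate of naive T cells and resting Tregs
        [time^-1].
    gamma : float
        Treg-mediated suppression rate of activated T cells
        [cells^-1 time^-1].
    epsilon : float
        Ratio of the IL-2-dependent proliferation rates of activated Tregs
        and activated T cells [dimensionless].
    N0 : float
        Renewal (thymic output) rate of naive T cells [cells time^-1].
    lam : float
        Ratio of resting-Treg renewal to naive T cell renewal,
        ``Nhat0 / N0`` [dimensionless].
    nhat0 : float, optional
        Resting-Treg renewal rate [cells time^-1]. Constrained to equal
        ``lam * N0``; passing an inconsistent value raises ``ValueError``.
    """

    a: float = 0.4
    b: float = 0.1
    c: float = 1e-5
    d: float = 0.01
    e: float = 0.01
    f: float = 1.0
    g: float = DEFAULT_G
    beta: float = 0.0
    gamma: float = 0.1
    epsilon: float = 0.6
    N0: float = 4.0
    lam: float = 0.006
    nhat0: float | None = None

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"parameter {name!r} must be finite and >= 0, got {value!r}"
                )
        expected = self.lam * self.N0
        if self.nhat0 is None:
            object.__setattr__(self, "nhat0", expected)
        elif not math.isclose(self.nhat0, expected, rel_tol=1e-12, abs_tol=1e-15):
            raise ValueError(
                f"nhat0={self.nhat0!r} inconsistent with lam*N0={expected!r}; "
                "the resting-Treg renewal is constrained to lam * N0"
            )

    @property
    def Nhat0(self) -> float:
        """Resting-Treg renewal rate, always ``lam * N0``."""
        return self.lam * self.N0

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields changed.

        ``lam`` and ``N0`` changes re-derive ``nhat0`` unless it is given
        explicitly.
        """
        if ("lam" in changes or "N0" in changes) and "nhat0" not in changes:
            changes["nhat0"] = None
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in _RATE_FIELDS} | {
            "nhat0": self.nhat0
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        known = set(_RATE_FIELDS) | {"nhat0"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**data)


def table1(lam: float = 0.006, beta: float = 0.0, g: float = DEFAULT_G) -> ParameterSet:
    """The canonical parameter set used throughout the analysis.

    ``lam`` defaults to 0.006, the responsive case; 0.02 is the
    unresponsive counterpart. ``g`` is exposed because only outputs of the
    full (naive-compartment) models depend on it.
    """
    return ParameterSet(lam=lam, beta=beta, g=g)
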