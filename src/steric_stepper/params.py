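"""Parameter containers for the confined-walker model.

Unit conventions used throughout the package: lengths in nm, times in s,
energies in units of the thermal energy kT (so beta = 1/kT never appears on
its own).  The stiffnesses only ever enter the model through the products
beta*k, beta*k', beta*k'' and are therefore stored directly as ``beta_k``
(nm^-2), ``beta_k_prime`` (nm^-2) and ``beta_k_dprime`` (nm^-2).
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import asdict, dataclass, replace
from typing import Iterable

import yaml

#: Scenario tags for the four track designs (plus the full-series trench
#: variant, which needs the extra stiffness ``beta_k_dprime``).
SCENARIOS = ("baseline", "tail", "trench", "trench_series", "combined")

#: Scenarios whose vertical motion is slit-confined by a tailed foothold.
TAIL_SCENARIOS = ("tail", "combined")
#: Scenarios laterally confined by origami trench walls.
TRENCH_SCENARIOS = ("trench", "trench_series", "combined")


class ParameterError(ValueError):
    """Invalid or inconsistent model parameters."""


@dataclass(frozen=True)
class ConfinementParams:
    """Geometry and stiffness of the walker-foothold complex and its track.

    Parameters
    ----------
    beta_k : float
        Stiffness of the harmonic shell confining the free end near the
        contour length, in nm^-2.
    L : float
        Mean length of the walker-foothold complex, in nm.
    beta_k_prime : float, optional
        Effective stiffness of the double-stranded foothold tail that damps
        high-order vertical modes, in nm^-2.  Required by the tail and
        combined scenarios.
    z_max : float, optional
        Height of the vertical slit imposed by the tail, in nm.  Required by
        the tail and combined scenarios.
    beta_k_dprime : float, optional
        Stiffness of the full trench cosine series, in nm^-2.  Only used by
        the ``trench_series`` scenario; it has no established default.
    h_max : float, optional
        Width of the trench, in nm.  Required by the trench and combined
        scenarios.
    n_terms : int
        Truncation order of the confinement series (default 20).
    """

    beta_k: float
    L: float
    beta_k_prime: float | None = None
    z_max: float | None = None
    beta_k_dprime: float | None = None
    h_max: float | None = None
    n_terms: int = 20

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta_k) and self.beta_k > 0):
            raise ParameterError(f"beta_k must be positive, got {self.beta_k}")
        if not (math.isfinite(self.L) and self.L > 0):
            raise ParameterError(f"L must be positive, got {self.L}")
        for name in ("beta_k_prime", "z_max", "beta_k_dprime", "h_max"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive when set, got {v}")
        if int(self.n_terms) != self.n_terms or self.n_terms < 1:
            raise ParameterError(f"n_terms must be an integer >= 1, got {self.n_terms}")

    # -- scenario bookkeeping -------------------------------------------------

    def require_for(self, scenario: str) -> None:
        """Raise :class:`ParameterError` if fields needed by *scenario* are unset."""
        if scenario not in SCENARIOS:
            raise ParameterError(
                f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
            )
        if scenario in TAIL_SCENARIOS:
            if self.z_max is None or self.beta_k_prime is None:
                raise ParameterError(
                    f"scenario {scenario!r} requires z_max and beta_k_prime"
                )
        if scenario in TRENCH_SCENARIOS and self.h_max is None:
            raise ParameterError(f"scenario {scenario!r} requires h_max")
        if scenario == "trench_series" and self.beta_k_dprime is None:
            raise ParameterError("scenario 'trench_series' requires beta_k_dprime")

    @property
    def sigma(self) -> float:
        """Radial width 1/sqrt(beta_k) of the harmonic shell, nm."""
        return 1.0 / math.sqrt(self.beta_k)

    @property
    def reach(self) -> float:
        """Practical outer reach L + 6/sqrt(beta_k) of the free end, nm."""
        return self.L + 6.0 * self.sigma

    def replace(self, **kw) -> "ConfinementParams":
        return replace(self, **kw)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        d["n_terms"] = int(self.n_terms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConfinementParams":
        known = {
            "beta_k", "L", "beta_k_prime", "z_max",
            "beta_k_dprime", "h_max", "n_terms",
        }
        extra = set(d) - known
        if extra:
            raise ParameterError(f"unknown parameter keys: {sorted(extra)}")
        return cls(**d)

    def save(self, path: str | pathlib.Path) -> None:
        save_config(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "ConfinementParams":
        return cls.from_dict(load_config(path))


@dataclass(frozen=True)
class KineticParams:
    """Transport and reaction parameters of the free end.

    ``D`` is the free-end diffusion coefficient in nm^2/s and ``kappa`` the
    intrinsic (sequence-dependent) reactivity of the contact boundary in nm/s.
    """

    D: float
    kappa: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.D) and self.D > 0):
            raise ParameterError(f"D must be positive, got {self.D}")
        if not (math.isfinite(self.kappa) and self.kappa > 0):
            raise ParameterError(f"kappa must be positive, got {self.kappa}")


@dataclass(frozen=True)
class TargetGeometry:
    """Placement of the binding target relative to the tether.

    The tether sits at the origin and the target at ``(a, 0, 0)`` on the
    substrate plane; binding occurs when the free end comes within the
    contact distance ``epsilon`` of the target (the toehold reach is folded
    into ``epsilon``).
    """

    a: float
    epsilon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and self.a >= 0):
            raise ParameterError(f"a must be >= 0, got {self.a}")
        if not (math.isfinite(self.epsilon) and self.epsilon > 0):
            raise ParameterError(f"epsilon must be positive, got {self.epsilon}")

    def validate_against(self, params: ConfinementParams) -> None:
        if self.epsilon >= self.a + params.reach:
            raise ParameterError(
                "contact distance epsilon exceeds the accessible range "
                f"(epsilon={self.epsilon}, a + reach={self.a + params.reach:.3f})"
            )


# -- reference parameter sets -------------------------------------------------

def walker36_params() -> ConfinementParams:
    """Parameter set of the 36-bp cartwheeling walker-foothold complex.

    beta_k = 5 nm^-2 and L = 11.5 nm describe the hemispherical shell sampled
    by the bare complex; beta_k_prime = 0.75 nm^-2 and z_max = 12.5 nm the
    slit confinement of a 12-bp tailed foothold; h_max = 9 nm a trench three
    helices wide.
    """
    return ConfinementParams(
        beta_k=5.0, L=11.5, beta_k_prime=0.75, z_max=12.5, h_max=9.0, n_terms=20
    )


def default_kinetics(kappa: float = 1.0) -> KineticParams:
    """Transport parameters of the cartwheeling walker (D = 50 um^2/s)."""
    return KineticParams(D=5.0e7, kappa=kappa)


# -- flat key/value config files ----------------------------------------------

def load_config(path: str | pathlib.Path) -> dict:
    """Read a flat key-value config file (YAML dialect; JSON is valid YAML)."""
    text = pathlib.Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a mapping, got {type(data).__name__}")
    return data


def save_config(data: dict, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
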