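"""Parameter sets and stimulus protocols for the erythrocyte ATP release pathway.

The kinetic model tracks four pool-normalized species — activated G-protein
(GPa), cAMP, activated PKA (PKAa), and activated CFTR (CFTRa) — driven by the
fraction of desaturated (tense-state) hemoglobin, tHb = 1 - sO2.  All rate
constants are per-second; concentrations are dimensionless fractions of their
conserved pools, which sets the pathway's ~100 ms response time scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = ["PathwayParameters", "StimulusProtocol"]

# Rate constants (1/s unless noted) that must be non-negative.
_RATE_FIELDS = (
    "ac_base",
    "k_camp_f",
    "k_camp_i",
    "v0",
    "k_pde3",
    "pde3_rel",
    "k_pka_f",
    "k_pka_r",
    "k_gp_f",
    "k_gp_r",
    "k_cftr_f",
    "k_cftr_r",
    "k_atp_flux",
)


@dataclass(frozen=True)
class PathwayParameters:
    """Rate constants, exponents and pool totals of the release cascade.

    Defaults are the published baseline set for healthy human erythrocytes.
    ``pde3_rel`` is the relative phosphodiesterase-3 activity (1 at baseline;
    insulin raises it), and the cAMP degradation rate is ``v0 * pde3_rel``.
    """

    ac_base: float = 0.0        # baseline cAMP production (conc/s); 0 => no release at full sO2
    k_camp_f: float = 49.5      # cAMP production per unit GPa (1/s)
    k_camp_i: float = 2.47      # PKAa feedback gain dividing cAMP production (dimensionless)
    v0: float = 101.0           # baseline cAMP degradation rate (1/s)
    pde3_rel: float = 1.0       # relative PDE3 activity (dimensionless, >= 0)
    k_pde3: float = 1.0         # half-max cAMP concentration of PDE3 (conc units)
    k_pka_f: float = 60.5       # PKA activation by cAMP (1/(conc*s))
    k_pka_r: float = 10.0       # PKA deactivation (1/s)
    k_gp_f: float = 25.0        # G-protein activation by tHb^alpha (1/s)
    alpha: float = 1.2          # tHb -> GPa coupling exponent (> 0)
    k_gp_r: float = 3.36        # G-protein deactivation (1/s)
    k_cftr_f: float = 181.0     # CFTR activation by PKAa^beta (1/s)
    beta: float = 6.3           # PKAa -> CFTR coupling exponent (> 0)
    k_cftr_r: float = 11.3      # CFTR deactivation (1/s)
    k_atp_flux: float = 2.0     # ATP flux per unit CFTRa (release-rate units)
    gp_total: float = 1.0       # conserved G-protein pool
    pka_total: float = 1.0      # conserved PKA pool
    cftr_total: float = 1.0     # conserved CFTR pool

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("gp_total", "pka_total", "cftr_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def replace(self, **changes: float) -> "PathwayParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PathwayParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PathwayParameters":
        """Load a flat key-value parameter file (YAML or JSON)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat mapping of parameter names")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant hemoglobin saturation versus time.

    ``intervals`` is an ordered sequence of ``(t_start, t_end, sO2)`` rows that
    must be contiguous from t = 0.  After the last interval the hemoglobin is
    taken to be fully saturated (sO2 = 1, i.e. no stimulus).
    """

    intervals: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("protocol needs at least one interval")
        object.__setattr__(
            self, "intervals", tuple((float(a), float(b), float(s)) for a, b, s in self.intervals)
        )
        prev_end = 0.0
        for t0, t1, s in self.intervals:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sO2 must be in [0, 1], got {s}")
            if t1 <= t0:
                raise ValueError(f"empty interval ({t0}, {t1})")
            if abs(t0 - prev_end) > 1e-12:
                raise ValueError(f"intervals must be contiguous from t=0; gap at t={t0}")
            prev_end = t1

    @classmethod
    def pulse(cls, sO2: float, duration: float = 0.040) -> "StimulusProtocol":
        """A desaturation step of the given duration starting at t = 0."""
        return cls(((0.0, float(duration), float(sO2)),))

    @classmethod
    def from_rows(cls, rows: Iterable[Sequence[float]]) -> "StimulusProtocol":
        return cls(tuple((r[0], r[1], r[2]) for r in rows))

    @property
    def end_time(self) -> float:
        return self.intervals[-1][1]

    def sO2_at(self, t: float) -> float:
        for t0, t1, s in self.intervals:
            if t0 <= t < t1:
                return s
        return 1.0

    def thb_at(self, t: float) -> float:
        """Fraction of tense-state (desaturated) hemoglobin at time t."""
        return 1.0 - self.sO2_at(t)
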