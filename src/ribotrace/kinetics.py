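"""Kinetic parameters for ribosome traffic: rates, pause/damage sites, drugs.

Rates follow the conventions of the imaging literature: initiation and
elongation in events per second, translational state switching as a two-state
telegraph process (shutdown in events per hour, reinitiation in events per
second), steric exclusion through a ribosome footprint in codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "PauseSite",
    "DamageSite",
    "KineticParameters",
    "DrugEvent",
    "DRUGS",
    "DEFAULT_ENTRY_DELAY_S",
]

#: drugs with an implemented effect contract
DRUGS = ("harringtonine", "puromycin", "cycloheximide", "hippuristanol")

#: default cell-entry delays in seconds (time from addition to effect)
DEFAULT_ENTRY_DELAY_S = {
    "harringtonine": 60.0,
    "hippuristanol": 60.0,
    "puromycin": 30.0,
    "cycloheximide": 60.0,
}


@dataclass(frozen=True)
class PauseSite:
    """A sequence-encoded pause: crossing inserts an extra dwell.

    The dwell is a two-component mixture: with probability ``long_fraction``
    the ribosome stalls with mean ``long_dwell_mean_s``, otherwise it is only
    briefly delayed (``short_dwell_mean_s``).  ``single_long=True`` lets at
    most one ribosome per mRNA draw the long component (a roadblock left by a
    single defective ribosome); ``fixed_dwell=True`` makes dwells
    deterministic at their mean instead of exponential.
    """

    position: int
    short_dwell_mean_s: float
    long_dwell_mean_s: float = 0.0
    long_fraction: float = 0.0
    single_long: bool = False
    fixed_dwell: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("pause position must be >= 1")
        if self.short_dwell_mean_s < 0 or self.long_dwell_mean_s < 0:
            raise ValueError("dwell means must be >= 0")
        if not 0.0 <= self.long_fraction <= 1.0:
            raise ValueError("long_fraction must be in [0, 1]")
        if self.long_fraction > 0 and self.long_dwell_mean_s <= 0:
            raise ValueError("long_dwell_mean_s must be > 0 when long_fraction > 0")


@dataclass(frozen=True)
class DamageSite:
    """A chemically damaged nucleotide: every ribosome crossing is delayed."""

    position: int
    dwell_mean_s: float
    fixed_dwell: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("damage position must be >= 1")
        if not self.dwell_mean_s > 0:
            raise ValueError("dwell_mean_s must be > 0")


@dataclass(frozen=True)
class KineticParameters:
    """Rates governing ribosome traffic on one mRNA.

    Parameters
    ----------
    k_init : float
        Initiation attempts per second while the mRNA is in the translating
        state and the entry region is free.
    k_elong : float
        Mean elongation rate in codons per second (exponential per-codon
        waiting times unless the simulator runs in deterministic mode).
    footprint_codons : int
        Steric exclusion length; two ribosomes never come closer than this.
    k_shutdown_per_hr, k_reinit_per_s : float
        Telegraph switching between the translating ("on") and the
        non-translating ("off") state; switching gates initiation only,
        elongating ribosomes finish normally.
    """

    k_init: float
    k_elong: float
    footprint_codons: int = 10
    k_shutdown_per_hr: float = 0.0
    k_reinit_per_s: float = 0.0
    pause_sites: tuple[PauseSite, ...] = ()
    damage_sites: tuple[DamageSite, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pause_sites", tuple(self.pause_sites))
        object.__setattr__(self, "damage_sites", tuple(self.damage_sites))
        for name in ("k_init", "k_elong", "k_shutdown_per_hr", "k_reinit_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.footprint_codons < 1:
            raise ValueError("footprint_codons must be >= 1")
        if self.k_shutdown_per_hr > 0 and self.k_reinit_per_s <= 0:
            raise ValueError("k_reinit_per_s must be > 0 when shutdown is enabled")

    def with_overrides(self, **kwargs) -> "KineticParameters":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class DrugEvent:
    """A translation inhibitor added at ``add_time_s``, acting after a cell-entry delay.

    Effect contracts:

    - harringtonine / hippuristanol: block all new initiation, ribosomes
      already elongating run off normally;
    - puromycin: instantly release all nascent chains (site intensity drops to
      zero) and block initiation;
    - cycloheximide: freeze all ribosome movement and initiation.
    """

    drug: str
    add_time_s: float = 0.0
    entry_delay_s: float | None = None

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")
        if self.entry_delay_s is None:
            object.__setattr__(self, "entry_delay_s", DEFAULT_ENTRY_DELAY_S[self.drug])
        if self.entry_delay_s < 0:
            raise ValueError("entry_delay_s must be >= 0")

    @property
    def effective_time_s(self) -> float:
        return self.add_time_s + self.entry_delay_s

    @property
    def blocks_initiation(self) -> bool:
        return True  # every implemented drug blocks initiation once active
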