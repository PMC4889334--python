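"""Reporter geometry and the nascent-chain fluorescence intensity model.

A translation reporter carries an N-terminal array of SunTag epitopes followed
by a gene body, and an array of PP7 hairpins in the 3' UTR.  A ribosome at
codon ``x`` has synthesized every epitope whose last codon lies at least the
exit-tunnel offset behind ``x``, so its nascent chain carries a
position-dependent fraction ``f(x)`` of the maximal scFv-GFP label.  The
translation-site intensity is the sum of ``f`` over all ribosome positions,
expressed throughout the package in units of one fully synthesized, fully
labeled mature reporter protein (f = 1).

This module holds the geometric description of a reporter, the intensity
function ``f``, the mean positional correction used to convert site intensity
into a ribosome count, and the expected brightness of the PP7/mCherry mRNA
label relative to the single-protein standard.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ReporterConstruct",
    "LabelStoichiometry",
    "CalibrationUnit",
    "exposed_epitope_fraction",
    "site_intensity",
    "mean_positional_correction",
    "estimate_ribosome_count",
    "expected_label_ratio",
    "uniform_epitope_positions",
    "get_preset",
    "list_presets",
    "load_construct",
    "save_construct",
]

#: codon spacing of one SunTag repeat (24 repeats over 634 codons)
EPITOPE_SPACING_CODONS = 26.4

#: default codon distance between peptide-bond formation and scFv accessibility
DEFAULT_EXIT_TUNNEL_CODONS = 35


def uniform_epitope_positions(n: int, spacing: float = EPITOPE_SPACING_CODONS) -> tuple[int, ...]:
    """Uniformly spaced epitope completion positions ``round(spacing * i)``, i = 1..n."""
    if n < 1:
        raise ValueError("need at least one epitope")
    # round-half-even matches np.round; spacing*i is never exactly .5 for 26.4
    return tuple(int(round(spacing * i)) for i in range(1, n + 1))


@dataclass(frozen=True)
class ReporterConstruct:
    """Geometric description of a tagged reporter ORF.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"kif18b_suntag24"``.
    orf_length_codons : int
        Total ORF length L in codons (tag array + gene body).
    epitope_positions : tuple of int
        Strictly increasing codon indices e_1 < ... < e_K at which each
        epitope's last codon is translated.
    exit_tunnel_codons : int
        Offset Δ between peptide-bond formation and antibody accessibility.
    hairpin_count : int
        Number of PP7 hairpins in the 3' UTR (mRNA label).
    """

    name: str
    orf_length_codons: int
    epitope_positions: tuple[int, ...]
    exit_tunnel_codons: int = DEFAULT_EXIT_TUNNEL_CODONS
    hairpin_count: int = 24

    def __post_init__(self) -> None:
        object.__setattr__(self, "epitope_positions", tuple(int(e) for e in self.epitope_positions))
        L = self.orf_length_codons
        if L < 1:
            raise ValueError("orf_length_codons must be >= 1")
        if self.exit_tunnel_codons < 0:
            raise ValueError("exit_tunnel_codons must be >= 0")
        if self.hairpin_count < 0:
            raise ValueError("hairpin_count must be >= 0")
        e = self.epitope_positions
        if len(e) < 1:
            raise ValueError("need at least one epitope position")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("epitope positions must be strictly increasing")
        if e[0] < 1 or e[-1] > L:
            raise ValueError("epitope positions must lie in [1, L]")

    # -- derived geometry ----------------------------------------------------
    @property
    def n_epitopes(self) -> int:
        return len(self.epitope_positions)

    @property
    def first_visible_codon(self) -> int:
        """Position at which the first epitope becomes antibody-accessible (e_1 + Δ)."""
        return self.epitope_positions[0] + self.exit_tunnel_codons

    @property
    def last_visible_codon(self) -> int:
        """Position at which the nascent chain reaches full brightness (e_K + Δ)."""
        return self.epitope_positions[-1] + self.exit_tunnel_codons

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epitopes"] = list(d.pop("epitope_positions"))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReporterConstruct":
        d = dict(d)
        epitopes = d.pop("epitopes", None)
        if epitopes is None:
            epitopes = d.pop("epitope_positions")
        return cls(
            name=d["name"],
            orf_length_codons=int(d["orf_length_codons"]),
            epitope_positions=tuple(int(e) for e in epitopes),
            exit_tunnel_codons=int(d.get("exit_tunnel_codons", DEFAULT_EXIT_TUNNEL_CODONS)),
            hairpin_count=int(d.get("hairpin_count", 24)),
        )


@dataclass(frozen=True)
class LabelStoichiometry:
    """Fluorophore accounting for the PP7/mCherry mRNA label.

    PP7 binds its hairpin as a dimer and each PP7 carries tandem mCherry
    copies; the reference standard is a single mature SunTag protein decorated
    with ``reference_fluorophores`` fluorescent antibodies.
    """

    hairpin_count: int = 24
    pp7_per_hairpin: int = 2
    fluorophores_per_pp7: int = 2
    occupancy: float = 0.5
    reference_fluorophores: int = 24

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        for name in ("hairpin_count", "pp7_per_hairpin", "fluorophores_per_pp7", "reference_fluorophores"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CalibrationUnit:
    """Intensity of one fully synthesized, fully labeled mature protein in raw camera units."""

    single_mature_intensity: float

    def __post_init__(self) -> None:
        if not (self.single_mature_intensity > 0):
            raise ValueError("single_mature_intensity must be > 0")

    def to_single_protein_units(self, raw: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(raw, dtype=float) / self.single_mature_intensity


# ---------------------------------------------------------------------------
# intensity model
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _visible_positions(construct: ReporterConstruct) -> np.ndarray:
    return np.asarray(construct.epitope_positions, dtype=np.int64) + construct.exit_tunnel_codons


@lru_cache(maxsize=64)
def _fraction_table(construct: ReporterConstruct) -> np.ndarray:
    """f(x) for x = 0..L as a lookup table (discrete step form)."""
    L = construct.orf_length_codons
    vis = _visible_positions(construct)
    x = np.arange(L + 1)
    return np.searchsorted(vis, x, side="right") / construct.n_epitopes


def exposed_epitope_fraction(
    position: float | np.ndarray,
    construct: ReporterConstruct,
    mode: str = "discrete",
) -> float | np.ndarray:
    """Fraction of maximal nascent-chain brightness for a ribosome at ``position``.

    ``mode="discrete"`` counts epitopes whose completion position plus the
    exit-tunnel offset lies at or before ``position``; ``mode="ramp"`` is the
    continuum linear simplification rising from the first to the last visible
    position, used by the runoff fitter.
    """
    pos = np.asarray(position, dtype=float)
    L = construct.orf_length_codons
    if np.any(pos < 0) or np.any(pos > L):
        raise ValueError(f"position must lie in [0, {L}]")
    if mode == "discrete":
        vis = _visible_positions(construct)
        out = np.searchsorted(vis, np.floor(pos + 1e-9), side="right") / construct.n_epitopes
    elif mode == "ramp":
        a = construct.first_visible_codon
        b = construct.last_visible_codon
        if b == a:
            out = np.where(pos >= a, 1.0, 0.0)
        else:
            out = np.clip((pos - a) / (b - a), 0.0, 1.0)
    else:
        raise ValueError("mode must be 'discrete' or 'ramp'")
    return float(out) if np.isscalar(position) else out


def site_intensity(
    positions: Iterable[int],
    construct: ReporterConstruct,
    mode: str = "discrete",
) -> float:
    """Total translation-site intensity: sum of f over ribosome positions.

    Additive in ribosomes; 0 for an empty site.  Positions must be in [1, L].
    """
    pos = np.asarray(list(positions) if not isinstance(positions, np.ndarray) else positions)
    if pos.size == 0:
        return 0.0
    if np.any(pos < 1) or np.any(pos > construct.orf_length_codons):
        raise ValueError("ribosome positions must lie in [1, L]")
    return float(np.sum(exposed_epitope_fraction(pos.astype(float), construct, mode=mode)))


@lru_cache(maxsize=64)
def mean_positional_correction(construct: ReporterConstruct, mode: str = "discrete") -> float:
    """Mean per-ribosome intensity c̄ = (1/L) Σ_{x=1..L} f(x).

    The expected brightness contribution of a ribosome uniformly positioned on
    the ORF; dividing a site intensity by c̄ gives the ribosome count.
    """
    L = construct.orf_length_codons
    x = np.arange(1, L + 1, dtype=float)
    return float(np.mean(exposed_epitope_fraction(x, construct, mode=mode)))


def estimate_ribosome_count(
    site_intensity_units: float,
    construct: ReporterConstruct,
    integer: bool = False,
) -> float | int:
    """Ribosome number from a background-subtracted site intensity.

    Inverts the forward model in expectation for uniformly distributed
    ribosomes: N = I / c̄.  Small negative intensities left over from
    background subtraction are clamped to zero.
    """
    I = float(site_intensity_units)
    if not math.isfinite(I):
        raise ValueError("site intensity must be finite")
    I = max(I, 0.0)
    n = I / mean_positional_correction(construct)
    return int(round(n)) if integer else n


def expected_label_ratio(stoich: LabelStoichiometry) -> float:
    """Expected mRNA-spot brightness relative to the single-protein standard.

    (hairpins x PP7 per hairpin x fluorophores per PP7 x occupancy) divided by
    the fluorophore count of the reference single mature protein.
    """
    if stoich.reference_fluorophores == 0:
        raise ValueError("reference_fluorophores must be nonzero")
    return (
        stoich.hairpin_count
        * stoich.pp7_per_hairpin
        * stoich.fluorophores_per_pp7
        * stoich.occupancy
        / stoich.reference_fluorophores
    )


# ---------------------------------------------------------------------------
# presets and I/O
# ---------------------------------------------------------------------------

_KIF18B_CDS_CODONS = 833     # 2.5 kb kinesin gene body
_U2AF2_CDS_CODONS = 475      # codon-optimized splicing-factor gene body


def _tag_array_codons(n: int) -> int:
    return uniform_epitope_positions(n)[-1]


def _make_presets() -> dict[str, ReporterConstruct]:
    e24 = uniform_epitope_positions(24)
    presets = {
        # 24x tag + kinesin gene body: L = 634 + 833 = 1467 (4.4 kb ORF)
        "kif18b_suntag24": ReporterConstruct(
            "kif18b_suntag24", _tag_array_codons(24) + _KIF18B_CDS_CODONS, e24
        ),
        "suntag5": ReporterConstruct(
            "suntag5", _tag_array_codons(5) + _KIF18B_CDS_CODONS, uniform_epitope_positions(5)
        ),
        "suntag10": ReporterConstruct(
            "suntag10", _tag_array_codons(10) + _KIF18B_CDS_CODONS, uniform_epitope_positions(10)
        ),
        # Emi1 5' UTR variants share the 24x/Kif18b ORF geometry (the UTR only
        # changes initiation kinetics, not the coding geometry)
        "emi1_long_5utr": ReporterConstruct(
            "emi1_long_5utr", _tag_array_codons(24) + _KIF18B_CDS_CODONS, e24
        ),
        # 24x reporter with a strong pause sequence in the 3' region of the CDS;
        # the pause site itself is a kinetic parameter (see kinetics.PauseSite)
        "xbp1_pause": ReporterConstruct(
            "xbp1_pause", _tag_array_codons(24) + _KIF18B_CDS_CODONS, e24
        ),
        "u2af2_codonopt": ReporterConstruct(
            "u2af2_codonopt", _tag_array_codons(24) + _U2AF2_CDS_CODONS, e24
        ),
    }
    return presets


_PRESETS = _make_presets()


def get_preset(name: str) -> ReporterConstruct:
    """Return a built-in named reporter construct."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown construct preset {name!r}; available: {sorted(_PRESETS)}") from None


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def load_construct(path: str | Path) -> ReporterConstruct:
    """Read a construct description from YAML or JSON (keyed by file suffix)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ReporterConstruct.from_dict(data)


def save_construct(construct: ReporterConstruct, path: str | Path) -> None:
    path = Path(path)
    d = construct.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
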