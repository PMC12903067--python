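"""Small-molecule mass arithmetic and matrix-sprayer bookkeeping.

Negative-mode MALDI assignments in this package are tentative, by accurate
mass: a theoretical monoisotopic m/z is computed for a candidate ion formula
and compared with the measured centre, typically requiring agreement within
a few ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Monoisotopic atomic masses (u), CODATA/IUPAC values.
MONOISOTOPIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Br": 78.9183371,
    "I": 126.904473,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

ADDUCT_KINDS = ("deprotonated", "chloride_adduct", "radical_anion")


@dataclass
class SprayParams:
    """TM-sprayer matrix application settings.

    concentration in mg/mL, flow_rate in mL/min, velocity in mm/min,
    track_spacing in mm, passes a non-negative integer.
    """

    concentration: float
    flow_rate: float
    velocity: float
    track_spacing: float
    passes: int

    def __post_init__(self) -> None:
        if self.velocity <= 0 or self.track_spacing <= 0:
            raise ValueError("velocity and track_spacing must be positive")
        if self.concentration <= 0 or self.flow_rate <= 0:
            raise ValueError("concentration and flow_rate must be positive")
        if self.passes < 0:
            raise ValueError("passes must be >= 0")


def sprayer_matrix_density(p: SprayParams) -> float:
    """Deposited matrix surface density in mg/mm^2.

    Each pass deposits ``concentration * flow_rate`` mg/min of matrix over a
    swath advancing at ``velocity`` mm/min with ``track_spacing`` mm between
    tracks, i.e. ``velocity * track_spacing`` mm^2/min of coverage, so

        density = concentration * flow_rate / (velocity * track_spacing) * passes
    """
    return p.concentration * p.flow_rate / (p.velocity * p.track_spacing) * p.passes


@dataclass
class IonFormula:
    """A singly charged anion described by its neutral-molecule element counts
    and an adduct kind.

    ``deprotonated`` is [M-H]-; ``chloride_adduct`` is [M+Cl]-;
    ``radical_anion`` treats the element counts as those of the anion itself
    (electron attachment only), which covers printed ions like HSO4-.
    """

    elements: dict[str, int] = field(default_factory=dict)
    adduct: str = "deprotonated"

    def __post_init__(self) -> None:
        for sym, n in self.elements.items():
            if sym not in MONOISOTOPIC_MASS:
                raise KeyError(f"unknown element symbol {sym!r}")
            if n < 0 or int(n) != n:
                raise ValueError(f"element count for {sym} must be a non-negative integer")
        if self.adduct not in ADDUCT_KINDS:
            raise ValueError(f"adduct must be one of {ADDUCT_KINDS}")

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic mass of the neutral formula (u)."""
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self.elements.items())


def theoretical_mz(f: IonFormula, decimals: int | None = 4) -> float:
    """Theoretical m/z of a singly charged anion.

    The electron gained on ionization is included: for [M-H]- a proton
    (H minus its electron) is removed from the neutral; for [M+Cl]- the mass
    of Cl plus one electron is added; a radical anion gains one electron.
    Rounded to 4 decimals by default (pass ``decimals=None`` for the raw
    value).
    """
    m = f.neutral_mass
    if f.adduct == "deprotonated":
        mz = m - PROTON_MASS
    elif f.adduct == "chloride_adduct":
        mz = m + MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS
    else:  # radical_anion
        mz = m + ELECTRON_MASS
    return round(mz, decimals) if decimals is not None else mz


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed mass error of a measured m/z in parts per million."""
    return (measured - theoretical) / theoretical * 1e6
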