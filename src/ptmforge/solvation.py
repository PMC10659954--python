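"""Ion-count planning for MD solvation via the SLTCAP closed form.

SLTCAP (Screening Layer Tally by Container Average Potential) gives the
number of cations and anions that reproduce a bulk monovalent salt
concentration around a solute of net charge Q when only the *water* volume
of the periodic box is available to the ions (the solute volume is
excluded, mimicking dilute conditions).  With

    N0 = c0 * NA * V_water,     t = Q / (2 N0),

the continuous counts are

    N+ = N0 (sqrt(1 + t^2) - t),    N- = N0 (sqrt(1 + t^2) + t),

which satisfy N+ - N- = -Q (exact neutralization) and N+ * N- = N0^2.
Counts are rounded half-up; because the continuous difference is exactly
-Q, neutrality survives rounding and is asserted.

The protein volume is estimated from bundled mean per-residue volumes
(Laguerre-tessellation-style averages).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

from .structure import Protein

__all__ = [
    "IonPlan",
    "sltcap_ion_counts",
    "protein_volume",
    "box_volume",
    "AVOGADRO_PER_NM3",
]

#: ions per nm^3 at 1 mol/L: NA * 1e-24.
AVOGADRO_PER_NM3 = 0.602214076


@dataclass(frozen=True)
class IonPlan:
    protein_charge: float          # elementary charges
    bulk_concentration: float      # mol / L
    water_volume: float            # nm^3
    n_cations: int
    n_anions: int
    #: continuous counts before rounding (diagnostic)
    continuous_cations: float = 0.0
    continuous_anions: float = 0.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sltcap_ion_counts(Q: float, c0: float, V_water: float) -> IonPlan:
    """Monovalent ion counts for protein charge ``Q`` (e), salt ``c0``
    (mol/L) and available water volume ``V_water`` (nm^3)."""
    if c0 < 0:
        raise ValueError("concentration must be non-negative")
    if V_water <= 0:
        raise ValueError("water volume must be positive")
    q_int = _round_half_up(Q) if abs(Q - round(Q)) < 1e-9 else None
    if c0 == 0.0:
        # pure neutralization
        if q_int is None:
            raise ValueError("cannot neutralize a non-integer charge with ions")
        return IonPlan(Q, c0, V_water, max(-q_int, 0), max(q_int, 0),
                       float(max(-Q, 0.0)), float(max(Q, 0.0)))
    n0 = c0 * AVOGADRO_PER_NM3 * V_water
    t = Q / (2.0 * n0)
    s = math.sqrt(1.0 + t * t)
    n_plus = n0 * (s - t)
    n_minus = n0 * (s + t)
    assert abs(n_plus * n_minus - n0 * n0) <= 1e-9 * n0 * n0
    n_cat = _round_half_up(n_plus)
    n_an = n_cat + (q_int if q_int is not None else _round_half_up(Q))
    if n_an < 0:
        n_cat -= n_an
        n_an = 0
    assert n_cat - n_an == -(q_int if q_int is not None else round(Q))
    return IonPlan(Q, c0, V_water, n_cat, n_an, n_plus, n_minus)


def _load_volumes() -> dict[str, float]:
    text = resources.files("ptmforge.data").joinpath(
        "residue_volumes.csv").read_text()
    rows = csv.DictReader(l for l in text.splitlines() if not l.startswith("#"))
    return {r["residue"]: float(r["volume_A3"]) for r in rows}


_VOLUMES = _load_volumes()


def protein_volume(protein: Protein) -> float:
    """Sum of bundled per-residue volumes, in nm^3."""
    total_a3 = 0.0
    for _, res in protein.iter_residues():
        try:
            total_a3 += _VOLUMES[res.name]
        except KeyError:
            raise KeyError(f"no volume entry for residue {res.name!r}") from None
    return total_a3 * 1e-3


def box_volume(image_distance: float, box_type: str = "dodecahedron") -> float:
    """Volume (nm^3) of a periodic box with the given image distance (nm).

    ``dodecahedron`` is the rhombic dodecahedron (volume d^3 / sqrt(2), the
    compact cell MD setups favor); ``cubic`` is d^3.
    """
    if image_distance <= 0:
        raise ValueError("image distance must be positive")
    if box_type == "dodecahedron":
        return image_distance ** 3 / math.sqrt(2.0)
    if box_type == "cubic":
        return image_distance ** 3
    raise ValueError(f"unknown box type {box_type!r}")
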