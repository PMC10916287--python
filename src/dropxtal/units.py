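"""Unit conventions and converters used package-wide.

Every public function in :mod:`dropxtal` sticks to one system:

==============  ==========
quantity        unit
==============  ==========
volume          picolitre (pl)
diameter/length micrometre (µm)
number density  per nanolitre (nl⁻¹)
frequency       kilohertz (kHz)
velocity        mm s⁻¹
time            millisecond (ms)
concentration   mg ml⁻¹
diffusivity     µm² s⁻¹
==============  ==========

Converters are centralized here so that no magic factor appears twice.
"""

from __future__ import annotations

#: µm³ in one picolitre (1 pl = 1e-12 l = 1e-12 * 1e15 µm³ / 1e3 ... = 1000 µm³)
UM3_PER_PL = 1000.0
#: picolitres in one nanolitre
PL_PER_NL = 1000.0
#: picolitres in one femtolitre
PL_PER_FL = 1e-3
#: millilitres expressed in nanolitres
NL_PER_ML = 1e6


def pl_to_um3(volume_pl: float) -> float:
    """Convert a volume in picolitres to cubic micrometres."""
    return volume_pl * UM3_PER_PL


def um3_to_pl(volume_um3: float) -> float:
    """Convert a volume in cubic micrometres to picolitres."""
    return volume_um3 / UM3_PER_PL


def fl_to_pl(volume_fl: float) -> float:
    """Convert femtolitres to picolitres (82 fl -> 0.082 pl)."""
    return volume_fl * PL_PER_FL


def per_ml_to_per_nl(density_per_ml: float) -> float:
    """Convert a number density from ml⁻¹ to nl⁻¹ (1e7 ml⁻¹ -> 10 nl⁻¹)."""
    return density_per_ml / NL_PER_ML


def per_nl_to_per_ml(density_per_nl: float) -> float:
    """Convert a number density from nl⁻¹ to ml⁻¹."""
    return density_per_nl * NL_PER_ML


def mm_s_to_um_s(velocity_mm_s: float) -> float:
    """Convert a velocity from mm s⁻¹ to µm s⁻¹."""
    return velocity_mm_s * 1000.0


def ms_to_s(time_ms: float) -> float:
    return time_ms * 1e-3


def s_to_ms(time_s: float) -> float:
    return time_s * 1e3
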