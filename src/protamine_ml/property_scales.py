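"""Physicochemical scales used by the sequence-order correlation factors.

These are the three scales of Chou's original pseudo amino acid composition
web server, also shipped by the propy3 descriptor library:

- hydrophobicity: Tanford-style transfer free energies as tabulated by Chou;
- hydrophilicity: Hopp & Woods (1981) values;
- side-chain mass: residue side-chain masses in daltons (glycine = 1).

Each scale is standardised over the 20 residues (zero mean, unit population
standard deviation) before use, so the three squared differences entering a
correlation factor are on a common scale.
"""

from __future__ import annotations

import numpy as np

from .seqio import STANDARD_AA

HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0,
    "Q": 72.0, "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0,
    "L": 57.0, "K": 73.0, "M": 75.0, "F": 91.0, "P": 42.0,
    "S": 31.0, "T": 45.0, "W": 130.0, "Y": 107.0, "V": 43.0,
}


def as_array(scale: dict[str, float]) -> np.ndarray:
    """Scale values ordered by the alphabetical one-letter residue order."""
    return np.array([scale[a] for a in STANDARD_AA], dtype=float)


def normalize(scale: dict[str, float]) -> dict[str, float]:
    """Standardise a scale to zero mean and unit population SD over the 20 residues."""
    values = as_array(scale)
    centred = values - values.mean()
    sd = np.sqrt(np.mean(centred**2))
    return dict(zip(STANDARD_AA, centred / sd))
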