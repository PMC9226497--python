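"""Per-residue intrinsic amide exchange rates (Bai-Englander chemistry).

The intrinsic rate of an unstructured backbone amide in D2O is the sum of
acid-, base- and water-catalyzed branches,

    k_int,i = k_A * 10^(-pD) * F_A(i)  +  k_B * 10^(pD - pK_D) * F_B(i)
              + k_W * F_B_w(i)

where each branch's sequence factor F(i) combines the inductive effect of
residue i's own side chain (lambda) and of the preceding side chain (rho),
on a log10 scale, from the published poly-DL-alanine reference tables.  The
water branch shares the base-catalysis factors.  N-terminal ammonium and
C-terminal carboxylate groups contribute additional factors to the second
and last amides.  The three reference rate constants are Arrhenius-corrected
from 293 K with activation energies of 14, 17 and 19 kcal/mol.

Rates are returned in min^-1.  Residue 1 (a free amine, not an amide) and
prolines (no amide hydrogen) are non-exchanging.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

# Reference poly-DL-alanine rate constants, log10, D2O, 293 K.
LOG_KA_REF = 1.62    # M^-1 min^-1, acid catalysis (k_D+)
LOG_KB_REF = 10.05   # M^-1 min^-1, base catalysis (k_OD-)
LOG_KW_REF = -1.50   # min^-1, water catalysis
PKD = 15.05          # ion product of D2O
T_REF_K = 293.0
EA_ACID = 14.0       # kcal/mol
EA_BASE = 17.0
EA_WATER = 19.0
R_GAS = 1.987204e-3  # kcal / (mol K)

# Terminal-group factors (log10): the N-terminal ND3+ acts on residue 2's
# amide (rho-like); the C-terminal carboxylate acts on the last amide
# (lambda-like).
NTERM_ACID = -1.32
NTERM_BASE = 1.62
CTERM_ACID = 0.96
CTERM_BASE = -1.80


def _load_factors() -> dict[str, tuple[float, float, float, float]]:
    table = {}
    ref = resources.files("hdxpipe.data") / "englander_factors.csv"
    with ref.open() as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].startswith("#") and r[0] != "residue"]
    for res, la, ra, lb, rb in rows:
        table[res] = (float(la), float(ra), float(lb), float(rb))
    return table


FACTORS = _load_factors()


@dataclass
class ResidueRates:
    """Intrinsic exchange rates for every position of one sequence.

    ``k_int_per_min[i-1]`` is residue i's rate in min^-1; non-exchanging
    positions (residue 1, prolines) hold NaN and are listed in
    ``non_exchanging``.
    """

    sequence: str
    pD: float
    temperature_K: float
    k_int_per_min: np.ndarray
    non_exchanging: list[int]
    options: dict = field(default_factory=dict)

    def rate(self, residue: int) -> float:
        """Rate of 1-based residue index, min^-1 (NaN if non-exchanging)."""
        return float(self.k_int_per_min[residue - 1])

    def exchanging_residues(self) -> list[int]:
        return [i + 1 for i in range(len(self.sequence))
                if np.isfinite(self.k_int_per_min[i])]


def intrinsic_rates(sequence: str, pH_read: float, temperature_K: float,
                    apply_pD_correction: bool = True) -> ResidueRates:
    """Compute per-residue intrinsic exchange rates for ``sequence``.

    ``pH_read`` is the glass-electrode reading in D2O; by default the
    standard pD = pH_read + 0.4 correction is applied.  Unknown residue
    letters raise a ValueError naming the position.
    """
    if not 0.0 < pH_read < 14.0:
        raise ValueError(f"pH_read {pH_read} outside (0, 14)")
    sequence = sequence.upper()
    for pos, aa in enumerate(sequence, start=1):
        if aa not in FACTORS:
            raise ValueError(f"unknown residue letter {aa!r} at position {pos}")
    pD = pH_read + 0.4 if apply_pD_correction else pH_read
    T = float(temperature_K)

    arr_acid = np.exp(-EA_ACID / R_GAS * (1.0 / T - 1.0 / T_REF_K))
    arr_base = np.exp(-EA_BASE / R_GAS * (1.0 / T - 1.0 / T_REF_K))
    arr_water = np.exp(-EA_WATER / R_GAS * (1.0 / T - 1.0 / T_REF_K))

    n = len(sequence)
    k = np.full(n, np.nan)
    non_exch = []
    for i in range(1, n + 1):
        aa = sequence[i - 1]
        if i == 1 or aa == "P":
            non_exch.append(i)
            continue
        left = sequence[i - 2]   # preceding residue contributes rho
        la, _, lb, _ = FACTORS[aa]
        _, ra, _, rb = FACTORS[left]
        fa = la + ra
        fb = lb + rb
        if i == 2:
            fa += NTERM_ACID
            fb += NTERM_BASE
        if i == n:
            fa += CTERM_ACID
            fb += CTERM_BASE
        k_acid = 10.0 ** (LOG_KA_REF + fa - pD) * arr_acid
        k_base = 10.0 ** (LOG_KB_REF + fb + pD - PKD) * arr_base
        k_water = 10.0 ** (LOG_KW_REF + fb) * arr_water
        k[i - 1] = k_acid + k_base + k_water

    return ResidueRates(
        sequence=sequence, pD=pD, temperature_K=T, k_int_per_min=k,
        non_exchanging=non_exch,
        options={
            "reference": "poly-DL-alanine, low salt, D2O",
            "pD_correction": apply_pD_correction,
            "log10_k_ref": (LOG_KA_REF, LOG_KB_REF, LOG_KW_REF),
            "pKD": PKD,
            "Ea_kcal_mol": (EA_ACID, EA_BASE, EA_WATER),
        })


def rates_to_dataframe(rates: ResidueRates):
    """Per-residue CSV-ready frame (residue, aa, k_int_per_min, exchanging)."""
    import pandas as pd
    n = len(rates.sequence)
    return pd.DataFrame({
        "residue": np.arange(1, n + 1),
        "aa": list(rates.sequence),
        "k_int_per_min": rates.k_int_per_min,
        "exchanging": np.isfinite(rates.k_int_per_min),
    })
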