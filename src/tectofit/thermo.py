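"""Equilibrium models and free-energy calculus for tectoRNA assembly.

Two closed-form mass-action models:

* homodimer, 2M <=> D with an active fraction beta (the maximum fraction of
  molecules competent to dimerize):

      fD(M0) = ((4 beta M0 + Kd) - sqrt(8 M0 beta Kd + Kd^2)) / (4 M0)

  evaluated here in the algebraically equivalent conjugate form
  4 beta^2 M0 / (4 beta M0 + Kd + sqrt(8 M0 beta Kd + Kd^2)), which is exact
  and free of catastrophic cancellation at M0 << Kd.

* heterodimer, A + B <=> AB with equimolar partners at concentration C each.

Free energies use dG = R T ln(Kd in mol/L) with R = 1.987e-3 kcal/(K mol):
the association free energy, negative for sub-molar Kd. Differences
ddG = R T ln(Kd_n / Kd_o) compare a construct against a reference, and
ddG_FA = R T ln(Kd(+FA) / Kd(-FA)) is negative when the ligand (folinic
acid) stabilizes assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "R_KCAL_PER_K_MOL",
    "NM_TO_M",
    "EquilibriumParams",
    "Condition",
    "ThermoRecord",
    "homodimer_fraction",
    "heterodimer_fraction",
    "delta_g",
    "ddg",
    "ddg_fa",
    "fold_change",
    "add_free_energies",
]

#: Gas constant as printed on gel-shift analyses, kcal K^-1 mol^-1.
R_KCAL_PER_K_MOL = 1.987e-3
#: Exact nM -> mol/L conversion.
NM_TO_M = 1e-9

#: Temperature of the native-gel experiments (7 degC).
T_GEL_K = 280.0
#: Temperature of the lead-cleavage experiments (20 degC).
T_LEAD_K = 293.0


@dataclass(frozen=True)
class EquilibriumParams:
    """Homodimer equilibrium parameters: Kd (nM) and active fraction beta."""

    Kd_nM: float
    beta: float = 1.0

    def __post_init__(self):
        if not self.Kd_nM > 0:
            raise ValueError(f"Kd must be > 0 nM, got {self.Kd_nM}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")


@dataclass(frozen=True)
class Condition:
    """Buffer/temperature context of one measurement."""

    mg_mM: float = 2.0
    temperature_K: float = T_GEL_K
    fa_uM: float = 0.0
    buffer_tag: str = ""

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")
        if self.mg_mM < 0 or self.fa_uM < 0:
            raise ValueError("mg_mM and fa_uM must be >= 0")


@dataclass
class ThermoRecord:
    """Kd and derived free energies for one construct under one condition."""

    construct_id: str
    condition: Condition
    Kd_nM: float
    dG_kcal_mol: float
    ddG_vs_reference_kcal_mol: Optional[float] = None
    ddG_FA_kcal_mol: Optional[float] = None


def _positive(name: str, x):
    x = np.asarray(x, dtype=float)
    if not np.all(x > 0):
        raise ValueError(f"{name} must be > 0")
    return x


def homodimer_fraction(M0_nM, Kd_nM, beta: float = 1.0):
    """Fraction of all molecules dimerized at total concentration M0.

    Follows mass action for 2M <=> D with only a fraction *beta* of the
    population competent to dimerize; fD ranges over [0, beta), approaches
    beta as M0 -> infinity, and for beta = 1 satisfies the midpoint identity
    fD = 1/2 at M0 = Kd.

    Accepts scalars or arrays for ``M0_nM``.
    """
    M0 = _positive("M0_nM", M0_nM)
    Kd = float(Kd_nM)
    if Kd <= 0:
        raise ValueError(f"Kd must be > 0 nM, got {Kd_nM}")
    if not 0 < beta <= 1:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    root = np.sqrt(8.0 * M0 * beta * Kd + Kd * Kd)
    out = 4.0 * beta * beta * M0 / (4.0 * beta * M0 + Kd + root)
    return out if out.ndim else float(out)


def heterodimer_fraction(C_nM, Kd_nM):
    """Fraction of each partner dimerized for A + B <=> AB, [A]0=[B]0=C.

    Solves the quadratic m^2/Kd + m - C = 0 for the free monomer m of each
    species; the dimerized fraction 1 - m/C is monotone increasing in C and
    equals (3 - sqrt(5))/2 at C = Kd.
    """
    C = _positive("C_nM", C_nM)
    Kd = float(_positive("Kd_nM", Kd_nM))
    m = 0.5 * (-Kd + np.sqrt(Kd * Kd + 4.0 * Kd * C))
    out = 1.0 - m / C
    return out if out.ndim else float(out)


def delta_g(Kd_nM, T_K: float = T_GEL_K) -> float:
    """Association free energy dG = R T ln(Kd in mol/L), kcal/mol."""
    Kd = float(_positive("Kd_nM", Kd_nM))
    T = float(_positive("T_K", T_K))
    return R_KCAL_PER_K_MOL * T * np.log(Kd * NM_TO_M)


def ddg(Kd_n_nM, Kd_o_nM, T_K: float = T_GEL_K) -> float:
    """ddG = dG_n - dG_o = R T ln(Kd_n / Kd_o), kcal/mol.

    Negative when construct *n* assembles more strongly than the reference
    *o* (the 4LVV construct in the standard ledger).
    """
    Kd_n = float(_positive("Kd_n_nM", Kd_n_nM))
    Kd_o = float(_positive("Kd_o_nM", Kd_o_nM))
    T = float(_positive("T_K", T_K))
    return R_KCAL_PER_K_MOL * T * np.log(Kd_n / Kd_o)


def ddg_fa(Kd_plusFA_nM, Kd_minusFA_nM, T_K: float = T_GEL_K) -> float:
    """Ligand-responsiveness ddG_FA = R T ln(Kd(+FA)/Kd(-FA)), kcal/mol.

    Negative when folinic acid stabilizes self-assembly.
    """
    return ddg(Kd_plusFA_nM, Kd_minusFA_nM, T_K)


def fold_change(Kd_minusFA_nM, Kd_plusFA_nM) -> float:
    """Kd fold-reduction on ligand addition: Kd(-FA) / Kd(+FA)."""
    a = float(_positive("Kd_minusFA_nM", Kd_minusFA_nM))
    b = float(_positive("Kd_plusFA_nM", Kd_plusFA_nM))
    return a / b


def add_free_energies(df, reference_construct: Optional[str] = None):
    """Append dG (and ddG vs a reference) columns to a Kd table.

    *df* needs columns ``construct_id``, ``Kd_nM`` and (optionally)
    ``temperature_K`` (default 280 K). When *reference_construct* is given,
    ``ddG_kcal_mol`` is computed against that construct within each
    condition group (grouped on whichever of ``mg_mM``, ``temperature_K``,
    ``fa_uM`` are present).
    """
    import pandas as pd

    out = df.copy()
    T = out["temperature_K"] if "temperature_K" in out else pd.Series(
        T_GEL_K, index=out.index
    )
    out["dG_kcal_mol"] = [
        round(delta_g(k, t), 4) for k, t in zip(out["Kd_nM"], T)
    ]
    if reference_construct is not None:
        cond_cols = [c for c in ("mg_mM", "temperature_K", "fa_uM") if c in out]
        if not (out["construct_id"] == reference_construct).any():
            raise ValueError(
                f"reference construct {reference_construct!r} absent from table"
            )
        ddg_col = []
        groups = out.groupby(cond_cols) if cond_cols else [((), out)]
        ref_dg = {}
        for key, grp in groups:
            if not isinstance(key, tuple):
                key = (key,)
            ref_rows = grp[grp["construct_id"] == reference_construct]
            ref_dg[key] = (
                float(ref_rows["dG_kcal_mol"].iloc[0]) if len(ref_rows) else None
            )
        for _, row in out.iterrows():
            key = tuple(row[c] for c in cond_cols) if cond_cols else ()
            ref = ref_dg.get(key)
            ddg_col.append(
                round(row["dG_kcal_mol"] - ref, 4) if ref is not None else None
            )
        out["ddG_kcal_mol"] = ddg_col
    return out
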