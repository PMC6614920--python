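"""Synthetic assay generators with the statistical structure the fits assume.

Forward models:

* gel shift - fD_true from the homodimer isotherm; observed fD adds
  Gaussian noise (clipped to [0, 1]); band intensities are back-computed
  with a lognormal per-lane loading factor;
* lead cleavage - per lane fM = 1 - fD(M0; Kd, beta=1); each position mixes
  its full-monomer and full-dimer intensities linearly in fM, times
  multiplicative Gaussian noise, floored at 0; the +FA condition swaps in
  the ligand-bound Kd;
* heterodimer - equimolar two-partner fractions from the quadratic model
  with additive Gaussian noise.

Default concentration ladders mirror the assay protocols (two-fold steps,
5-20 000 nM for both assays; 2-2 000 nM for the heterodimer). Everything is
seeded through numpy Generators: the same spec and seed reproduce the same
tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gelshift import TitrationPoint, TitrationSeries
from .lead import CleavageProfile, Direction
from .signature import write_fasta
from .thermo import Condition, heterodimer_fraction, homodimer_fraction
from .variants import curated_variants

__all__ = [
    "two_fold_ladder",
    "GelShiftSimSpec",
    "LeadSimSpec",
    "HeterodimerSimSpec",
    "simulate_gelshift",
    "simulate_lead_profiles",
    "simulate_heterodimer",
    "make_variant_fixtures",
]


def two_fold_ladder(low: float = 5.0, high: float = 20000.0) -> np.ndarray:
    """Two-fold concentration steps from *low*, capped with *high* itself."""
    vals = []
    c = float(low)
    while c < high:
        vals.append(c)
        c *= 2.0
    vals.append(float(high))
    return np.array(vals)


@dataclass
class GelShiftSimSpec:
    true_Kd_nM: float
    true_beta: float = 0.85
    concentrations_nM: np.ndarray = field(default_factory=two_fold_ladder)
    noise_sd_fD: float = 0.02
    loading_sd_log: float = 0.05
    n_replicates: int = 3
    seed: int = 0
    construct_id: str = "sim"
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self):
        conc = np.asarray(self.concentrations_nM, dtype=float)
        if conc.size < 4 or np.any(np.diff(conc) <= 0):
            raise ValueError("ladder must be strictly increasing with >= 4 points")
        if self.noise_sd_fD < 0 or self.loading_sd_log < 0:
            raise ValueError("noise parameters must be >= 0")
        self.concentrations_nM = conc


@dataclass
class LeadSimSpec:
    true_Kd_noFA_nM: float
    true_Kd_FA_nM: float
    positions: list[tuple[str, Direction, float, float]] = field(
        default_factory=lambda: [
            ("10", Direction.DECREASING, 1.0, 0.2),
            ("18", Direction.DECREASING, 0.8, 0.1),
            ("6", Direction.INCREASING, 0.2, 1.0),
        ]
    )
    concentrations_nM: np.ndarray = field(default_factory=two_fold_ladder)
    noise_sd_frac: float = 0.03
    seed: int = 0
    construct_id: str = "sim"
    mg_mM: float = 0.5
    temperature_K: float = 293.0

    def __post_init__(self):
        conc = np.asarray(self.concentrations_nM, dtype=float)
        if conc.size < 4 or np.any(np.diff(conc) <= 0):
            raise ValueError("ladder must be strictly increasing with >= 4 points")
        if self.true_Kd_FA_nM > self.true_Kd_noFA_nM:
            raise ValueError(
                "a responsive construct has Kd(+FA) <= Kd(-FA); got "
                f"{self.true_Kd_FA_nM} > {self.true_Kd_noFA_nM}"
            )
        for label, _, i_mono, i_dim in self.positions:
            if i_mono == i_dim:
                raise ValueError(f"position {label}: I_monomer must differ from I_dimer")
        self.concentrations_nM = conc


@dataclass
class HeterodimerSimSpec:
    true_Kd_nM: float
    concentrations_nM: np.ndarray = field(
        default_factory=lambda: two_fold_ladder(2.0, 2000.0)
    )
    noise_sd_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        conc = np.asarray(self.concentrations_nM, dtype=float)
        if conc.size < 4 or np.any(np.diff(conc) <= 0):
            raise ValueError("ladder must be strictly increasing with >= 4 points")
        self.concentrations_nM = conc


def simulate_gelshift(spec: GelShiftSimSpec) -> tuple[list[TitrationSeries], dict]:
    """Simulate replicate gel-shift titrations; returns (series, truth)."""
    rng = np.random.default_rng(spec.seed)
    fD_true = homodimer_fraction(spec.concentrations_nM, spec.true_Kd_nM, spec.true_beta)
    series = []
    for rep in range(spec.n_replicates):
        fD_obs = np.clip(
            fD_true + rng.normal(0.0, spec.noise_sd_fD, size=fD_true.shape)
            if spec.noise_sd_fD > 0
            else fD_true,
            0.0,
            1.0,
        )
        loading = (
            rng.lognormal(0.0, spec.loading_sd_log, size=fD_obs.shape)
            if spec.loading_sd_log > 0
            else np.ones_like(fD_obs)
        )
        points = [
            TitrationPoint(
                M0_nM=float(m0),
                monomer_intensity=float((1.0 - f) * L),
                dimer_intensity=float(f * L),
            )
            for m0, f, L in zip(spec.concentrations_nM, fD_obs, loading)
        ]
        series.append(
            TitrationSeries(
                construct_id=spec.construct_id,
                condition=spec.condition,
                replicate_id=f"rep{rep + 1}",
                points=points,
            )
        )
    truth = {
        "true_Kd_nM": spec.true_Kd_nM,
        "true_beta": spec.true_beta,
        "noise_sd_fD": spec.noise_sd_fD,
        "seed": spec.seed,
    }
    return series, truth


def _lead_profile(spec: LeadSimSpec, Kd: float, fa_uM: float, rng) -> CleavageProfile:
    fM = 1.0 - homodimer_fraction(spec.concentrations_nM, Kd, 1.0)
    lanes = []
    for m0, f in zip(spec.concentrations_nM, fM):
        lane = {}
        for label, _, i_mono, i_dim in spec.positions:
            mean = f * i_mono + (1.0 - f) * i_dim
            noise = rng.normal(0.0, spec.noise_sd_frac) if spec.noise_sd_frac > 0 else 0.0
            lane[label] = max(mean * (1.0 + noise), 0.0)
        lanes.append((float(m0), lane))
    cond = Condition(
        mg_mM=spec.mg_mM, temperature_K=spec.temperature_K, fa_uM=fa_uM
    )
    return CleavageProfile(
        construct_id=spec.construct_id, condition=cond, lanes=lanes
    )


def simulate_lead_profiles(
    spec: LeadSimSpec,
) -> tuple[CleavageProfile, CleavageProfile, dict]:
    """Simulate a -FA / +FA cleavage-profile pair; returns (noFA, FA, truth)."""
    rng = np.random.default_rng(spec.seed)
    profile_no_fa = _lead_profile(spec, spec.true_Kd_noFA_nM, 0.0, rng)
    profile_fa = _lead_profile(spec, spec.true_Kd_FA_nM, 200.0, rng)
    truth = {
        "true_Kd_noFA_nM": spec.true_Kd_noFA_nM,
        "true_Kd_FA_nM": spec.true_Kd_FA_nM,
        "noise_sd_frac": spec.noise_sd_frac,
        "seed": spec.seed,
        "positions": [
            (label, d.value, i_m, i_d) for label, d, i_m, i_d in spec.positions
        ],
    }
    return profile_no_fa, profile_fa, truth


def simulate_heterodimer(spec: HeterodimerSimSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate one equimolar heterodimer titration; returns (C, fraction, truth)."""
    rng = np.random.default_rng(spec.seed)
    frac_true = heterodimer_fraction(spec.concentrations_nM, spec.true_Kd_nM)
    frac_obs = np.clip(
        frac_true + rng.normal(0.0, spec.noise_sd_frac, size=frac_true.shape)
        if spec.noise_sd_frac > 0
        else frac_true,
        0.0,
        1.0,
    )
    truth = {"true_Kd_nM": spec.true_Kd_nM, "seed": spec.seed}
    return spec.concentrations_nM.copy(), frac_obs, truth


def make_variant_fixtures(path: Optional[str] = None):
    """Emit the curated (synthetic) signature set, optionally as FASTA.

    Returns the variants; when *path* is given also writes them as FASTA
    with stem/source/label metadata in the headers.
    """
    variants = curated_variants()
    if path is not None:
        write_fasta(variants, path)
    return variants
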