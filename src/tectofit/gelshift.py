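"""Gel-shift (EMSA) titration quantification and homodimer Kd fitting.

A titration series is a ladder of total RNA concentrations with monomer and
dimer band intensities per lane. Because only a trace of the RNA carries the
label, the probability that a labeled molecule sits in a dimer equals the
bulk fraction of molecules dimerized, so fD = I_D / (I_M + I_D) with no
stoichiometric correction. Each replicate is fitted independently to the
homodimer isotherm and replicate estimates are averaged (mean +/- sample
standard deviation), mirroring how gel-shift Kd values are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import HeterodimerIsothermRegressor, HomodimerIsothermRegressor
from .thermo import Condition

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "FitResult",
    "fraction_dimer_from_bands",
    "series_fractions",
    "fit_homodimer",
    "fit_heterodimer",
    "aggregate_replicates",
    "read_titration_csv",
    "fits_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TitrationPoint:
    """One lane: total concentration plus band intensities (or direct fD)."""

    M0_nM: float
    monomer_intensity: float = 0.0
    dimer_intensity: float = 0.0
    fD: Optional[float] = None

    def __post_init__(self):
        if not self.M0_nM > 0:
            raise ValueError(f"M0_nM must be > 0, got {self.M0_nM}")
        if self.monomer_intensity < 0 or self.dimer_intensity < 0:
            raise ValueError("band intensities must be >= 0")
        if self.fD is not None and not 0 <= self.fD <= 1:
            raise ValueError(f"fD must be in [0, 1], got {self.fD}")


@dataclass
class TitrationSeries:
    """One construct x condition x replicate titration."""

    construct_id: str
    condition: Condition
    replicate_id: str
    points: list[TitrationPoint] = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 4:
            raise ValueError(
                f"{self.construct_id}/{self.replicate_id}: need >= 4 points, "
                f"got {len(self.points)}"
            )
        conc = [p.M0_nM for p in self.points]
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError(
                f"{self.construct_id}/{self.replicate_id}: concentrations "
                "must be strictly increasing"
            )


@dataclass
class FitResult:
    """Kd/beta estimate with uncertainty and status flags."""

    Kd_nM: float
    beta: float
    Kd_sd_nM: Optional[float] = None
    beta_sd: Optional[float] = None
    rss: float = 0.0
    converged: bool = True
    below_detection: bool = False
    no_assembly: bool = False
    noisy: bool = False
    kd_is_bound: bool = False
    n_replicates: int = 1
    construct_id: str = ""

    @property
    def flags(self) -> list[str]:
        out = []
        if not self.converged:
            out.append("NOT_CONVERGED")
        if self.below_detection:
            out.append("BELOW_DETECTION")
        if self.no_assembly:
            out.append("NO_ASSEMBLY")
        if self.noisy:
            out.append("NOISY")
        return out


def fraction_dimer_from_bands(point: TitrationPoint) -> float:
    """fD for one lane: pre-quantified value if present, else band ratio."""
    if point.fD is not None:
        return float(point.fD)
    total = point.monomer_intensity + point.dimer_intensity
    if total <= 0:
        raise ValueError("both band intensities are zero; lane is unquantifiable")
    return point.dimer_intensity / total


def series_fractions(series: TitrationSeries) -> tuple[np.ndarray, np.ndarray]:
    """(M0, fD) arrays for a series; unquantifiable lanes are skipped."""
    M0, fD = [], []
    for p in series.points:
        try:
            f = fraction_dimer_from_bands(p)
        except ValueError:
            logger.warning(
                "%s/%s: skipping blank lane at %g nM",
                series.construct_id,
                series.replicate_id,
                p.M0_nM,
            )
            continue
        M0.append(p.M0_nM)
        fD.append(f)
    return np.asarray(M0), np.asarray(fD)


def fit_homodimer(
    series: TitrationSeries,
    fix_beta: Optional[float] = None,
    detection_limit_nM: float = 1.0,
    seed: int = 0,
) -> FitResult:
    """Least-squares Kd/beta estimate for one titration series.

    Deterministic given the data (the multi-start grid is log-spaced, not
    random); *seed* is accepted for interface stability.
    """
    M0, fD = series_fractions(series)
    est = HomodimerIsothermRegressor(
        fix_beta=fix_beta, detection_limit_nM=detection_limit_nM
    ).fit(M0, fD)
    return FitResult(
        Kd_nM=est.kd_nM_,
        beta=est.beta_,
        rss=est.rss_,
        converged=est.converged_,
        below_detection=est.below_detection_,
        no_assembly=est.no_assembly_,
        kd_is_bound=est.kd_is_bound_,
        construct_id=series.construct_id,
    )


def fit_heterodimer(C_nM, fraction) -> FitResult:
    """Kd estimate for an equimolar two-partner titration."""
    est = HeterodimerIsothermRegressor().fit(np.asarray(C_nM), np.asarray(fraction))
    return FitResult(
        Kd_nM=est.kd_nM_, beta=1.0, rss=est.rss_, converged=est.converged_
    )


def aggregate_replicates(fits: Sequence[FitResult]) -> FitResult:
    """Average replicate estimates: mean Kd/beta, sample sd, OR-ed flags."""
    if not fits:
        raise ValueError("no fits to aggregate")
    if len(fits) < 3:
        logger.warning(
            "aggregating %d replicate(s); reported values usually average "
            "at least three independent experiments",
            len(fits),
        )
    kds = np.array([f.Kd_nM for f in fits], dtype=float)
    betas = np.array([f.beta for f in fits], dtype=float)
    n = len(fits)
    return FitResult(
        Kd_nM=float(kds.mean()),
        beta=float(np.nanmean(betas)),
        Kd_sd_nM=float(kds.std(ddof=1)) if n > 1 else None,
        beta_sd=float(np.nanstd(betas, ddof=1)) if n > 1 else None,
        rss=float(np.sum([f.rss for f in fits])),
        converged=all(f.converged for f in fits),
        below_detection=any(f.below_detection for f in fits),
        no_assembly=any(f.no_assembly for f in fits),
        noisy=any(f.noisy for f in fits),
        kd_is_bound=any(f.kd_is_bound for f in fits),
        n_replicates=n,
        construct_id=fits[0].construct_id,
    )


_COND_COLS = ["mg_mM", "temperature_K", "fa_uM"]


def read_titration_csv(path) -> list[TitrationSeries]:
    """Load titration lanes from CSV.

    Columns: construct_id, replicate_id, mg_mM, temperature_K, fa_uM,
    M0_nM, monomer_intensity, dimer_intensity[, fD].
    """
    df = pd.read_csv(path)
    required = {"construct_id", "replicate_id", "M0_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    series = []
    keys = ["construct_id", "replicate_id"] + [c for c in _COND_COLS if c in df]
    for key, grp in df.groupby(keys, sort=True):
        key = dict(zip(keys, key))
        grp = grp.sort_values("M0_nM")
        cond = Condition(
            mg_mM=float(key.get("mg_mM", 2.0)),
            temperature_K=float(key.get("temperature_K", 280.0)),
            fa_uM=float(key.get("fa_uM", 0.0)),
        )
        points = [
            TitrationPoint(
                M0_nM=row.M0_nM,
                monomer_intensity=getattr(row, "monomer_intensity", 0.0),
                dimer_intensity=getattr(row, "dimer_intensity", 0.0),
                fD=getattr(row, "fD", None)
                if "fD" in df.columns and not pd.isna(getattr(row, "fD", None))
                else None,
            )
            for row in grp.itertuples()
        ]
        series.append(
            TitrationSeries(
                construct_id=str(key["construct_id"]),
                condition=cond,
                replicate_id=str(key["replicate_id"]),
                points=points,
            )
        )
    return series


def fits_to_frame(results: dict) -> pd.DataFrame:
    """Flatten {(construct, condition): FitResult} into a Kd table."""
    rows = []
    for (construct, cond), fit in results.items():
        rows.append(
            {
                "construct_id": construct,
                "mg_mM": cond.mg_mM,
                "temperature_K": cond.temperature_K,
                "fa_uM": cond.fa_uM,
                "Kd_nM": fit.Kd_nM,
                "Kd_sd_nM": fit.Kd_sd_nM,
                "beta": fit.beta,
                "beta_sd": fit.beta_sd,
                "n_replicates": fit.n_replicates,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows)
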