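"""Lead(II)-cleavage footprinting quantification and two-state Kd fitting.

Pb(II) cleaves flexible or single-stranded backbone positions; assembly of
the loop-receptor interface protects some 3'-phosphate linkages and enhances
others (induced flexibility). Per-position band intensities across a
concentration ladder are normalized between the full-monomer and full-dimer
extremes (the two-state convention) to yield a relative monomer fraction fM,
which is fitted with the homodimer isotherm at beta = 1 to give an apparent
Kd. Positions come in two flavors:

* DECREASING - cleavage drops on dimerization (e.g. long-range pairing
  positions A10, U11, C18): the maximum intensity is the full monomer;
* INCREASING - cleavage grows on dimerization (e.g. C6 in the 980 family):
  the minimum intensity is the full monomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import TwoStateCleavageRegressor
from .gelshift import FitResult
from .thermo import Condition

__all__ = [
    "Direction",
    "ProtectionKind",
    "CleavageProfile",
    "MonomerFractionSeries",
    "ProtectionCall",
    "integrate_band",
    "quantify_lane_profiles",
    "read_profile_tsv",
    "normalize_two_state",
    "position_series",
    "fit_two_state",
    "call_protections",
    "call_fa_response",
    "read_cleavage_csv",
]


class Direction(Enum):
    """How a position's cleavage intensity responds to dimerization."""

    DECREASING = "decreasing"
    INCREASING = "increasing"


class ProtectionKind(Enum):
    PROTECTED_IN_DIMER = "protected_in_dimer"
    ENHANCED_IN_DIMER = "enhanced_in_dimer"
    FA_SPECIFIC_PROTECTED = "fa_specific_protected"
    FA_SPECIFIC_ENHANCED = "fa_specific_enhanced"
    UNCHANGED = "unchanged"


@dataclass
class CleavageProfile:
    """Per-position cleavage intensities across a concentration ladder."""

    construct_id: str
    condition: Condition
    lanes: list[tuple[float, dict[str, float]]]
    controls: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.lanes) < 2:
            raise ValueError("a cleavage profile needs at least 2 lanes")
        conc = [c for c, _ in self.lanes]
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("lane concentrations must be strictly increasing")
        positions = set(self.lanes[0][1])
        for c, lane in self.lanes[1:]:
            if set(lane) != positions:
                raise ValueError(f"lane at {c} nM has inconsistent positions")

    @property
    def positions(self) -> list[str]:
        from .positions import sort_labels

        return sort_labels(self.lanes[0][1])


@dataclass
class MonomerFractionSeries:
    """Relative monomer fraction at one position across the ladder."""

    position: str
    points: list[tuple[float, float]]
    direction_used: Direction


@dataclass
class ProtectionCall:
    position: str
    direction: ProtectionKind
    magnitude: float

    def __post_init__(self):
        if self.direction is not ProtectionKind.UNCHANGED and self.magnitude < 1:
            raise ValueError("non-UNCHANGED calls require magnitude >= 1")


def integrate_band(
    trace: Sequence[float],
    window: tuple[int, int],
    baseline_half_width: int = 3,
) -> float:
    """Integrate one band of a 1-D lane profile with local baseline removal.

    Sums the trace over ``window = (start, stop)`` (half-open) and subtracts
    the median of the two flanking segments of ``baseline_half_width`` bins,
    scaled by the window length; negative totals floor at 0.
    """
    trace = np.asarray(trace, dtype=float)
    start, stop = window
    if baseline_half_width < 1:
        raise ValueError("baseline_half_width must be >= 1")
    if not (0 <= start < stop <= trace.size):
        raise ValueError(f"window {window} outside trace of size {trace.size}")
    if start - baseline_half_width < 0 or stop + baseline_half_width > trace.size:
        raise ValueError("window touches trace end; no flank for the baseline")
    flanks = np.concatenate(
        [trace[start - baseline_half_width : start], trace[stop : stop + baseline_half_width]]
    )
    baseline = float(np.median(flanks))
    return max(float(trace[start:stop].sum() - baseline * (stop - start)), 0.0)


def quantify_lane_profiles(
    traces: Mapping[str, Sequence[float]],
    windows: Mapping[str, tuple[int, int]],
    baseline_half_width: int = 3,
) -> dict[str, dict[str, float]]:
    """Integrate every band window in every lane trace.

    *traces* maps lane id -> ordered 1-D intensity profile; *windows* maps
    position label -> (start, stop) bin range shared across lanes. Returns
    lane id -> {position: integrated intensity}.
    """
    return {
        lane_id: {
            pos: integrate_band(trace, win, baseline_half_width)
            for pos, win in windows.items()
        }
        for lane_id, trace in traces.items()
    }


def read_profile_tsv(path) -> dict[str, np.ndarray]:
    """Read raw lane profiles from TSV: lane_id, then ordered trace values."""
    traces = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or parts[0].startswith("#"):
                continue
            traces[parts[0]] = np.array([float(x) for x in parts[1:]])
    return traces


def normalize_two_state(
    intensities: Sequence[tuple[float, float]],
    direction: Direction,
    position: str = "",
) -> MonomerFractionSeries:
    """Map intensities linearly between the full-monomer/full-dimer extremes.

    DECREASING positions: fM = (I - I_min) / (I_max - I_min) (the maximum
    observed intensity is the full-monomer state); INCREASING positions use
    the mirrored form. Values are clipped to [0, 1].
    """
    if len(intensities) < 2:
        raise ValueError("need at least 2 intensities to normalize")
    conc = np.array([c for c, _ in intensities], dtype=float)
    I = np.array([i for _, i in intensities], dtype=float)
    i_min, i_max = float(I.min()), float(I.max())
    if i_max == i_min:
        raise ValueError(
            f"position {position or '?'}: constant intensity across the "
            "ladder; uninformative for two-state normalization"
        )
    if direction is Direction.DECREASING:
        fM = (I - i_min) / (i_max - i_min)
    else:
        fM = (i_max - I) / (i_max - i_min)
    fM = np.clip(fM, 0.0, 1.0)
    return MonomerFractionSeries(
        position=position,
        points=list(zip(conc.tolist(), fM.tolist())),
        direction_used=direction,
    )


def position_series(
    profile: CleavageProfile, position: str
) -> list[tuple[float, float]]:
    """(concentration, intensity) pairs for one position of a profile."""
    if position not in profile.lanes[0][1]:
        raise ValueError(
            f"{profile.construct_id}: position {position} not in profile"
        )
    return [(c, lane[position]) for c, lane in profile.lanes]


def fit_two_state(
    series: MonomerFractionSeries,
    fit_endpoints: bool = True,
    noisy_rmse: float = 0.10,
) -> FitResult:
    """Apparent Kd from a monomer-fraction series (two-state model, beta=1)."""
    M0 = np.array([c for c, _ in series.points])
    fM = np.array([f for _, f in series.points])
    est = TwoStateCleavageRegressor(
        fit_endpoints=fit_endpoints, noisy_rmse=noisy_rmse
    ).fit(M0, fM)
    return FitResult(
        Kd_nM=est.kd_nM_,
        beta=1.0,
        rss=est.rss_,
        converged=est.converged_,
        no_assembly=est.no_assembly_,
        noisy=est.noisy_,
        kd_is_bound=est.kd_is_bound_,
    )


def _ratio_calls(
    state_a: Mapping[str, float],
    state_b: Mapping[str, float],
    fold_threshold: float,
    kinds: tuple[ProtectionKind, ProtectionKind],
    pseudocount: Optional[float] = None,
) -> list[ProtectionCall]:
    if set(state_a) != set(state_b):
        raise ValueError("position sets of the two states differ")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    values = [v for m in (state_a, state_b) for v in m.values()]
    if pseudocount is None:
        med = float(np.median(values))
        pseudocount = 0.01 * med if med > 0 else 1e-9
    calls = []
    from .positions import sort_labels

    for pos in sort_labels(state_a):
        r = (state_a[pos] + pseudocount) / (state_b[pos] + pseudocount)
        magnitude = max(r, 1.0 / r)
        if r >= fold_threshold:
            kind = kinds[0]
        elif r <= 1.0 / fold_threshold:
            kind = kinds[1]
        else:
            kind = ProtectionKind.UNCHANGED
            magnitude = max(magnitude, 1.0)
        calls.append(ProtectionCall(position=pos, direction=kind, magnitude=magnitude))
    return calls


def call_protections(
    monomer_state: Mapping[str, float],
    dimer_state: Mapping[str, float],
    fold_threshold: float = 1.5,
    pseudocount: Optional[float] = None,
) -> list[ProtectionCall]:
    """Classify positions as protected/enhanced upon dimerization.

    The ratio r = I_monomer / I_dimer (with a pseudo-count of 1% of the
    median intensity) is compared to *fold_threshold*: r >= threshold means
    the position is protected in the dimer, r <= 1/threshold enhanced.
    """
    return _ratio_calls(
        monomer_state,
        dimer_state,
        fold_threshold,
        (ProtectionKind.PROTECTED_IN_DIMER, ProtectionKind.ENHANCED_IN_DIMER),
        pseudocount,
    )


def call_fa_response(
    dimer_no_fa: Mapping[str, float],
    dimer_fa: Mapping[str, float],
    fold_threshold: float = 1.5,
    pseudocount: Optional[float] = None,
) -> list[ProtectionCall]:
    """Classify ligand-specific changes between the two dimer states.

    Positions less cleaved in the dimer with folinic acid than without are
    FA-specific protections; more cleaved, FA-specific enhancements.
    """
    return _ratio_calls(
        dimer_no_fa,
        dimer_fa,
        fold_threshold,
        (ProtectionKind.FA_SPECIFIC_PROTECTED, ProtectionKind.FA_SPECIFIC_ENHANCED),
        pseudocount,
    )


def read_cleavage_csv(path) -> list[CleavageProfile]:
    """Load cleavage intensity tables from CSV.

    Columns: construct_id, mg_mM, temperature_K, fa_uM, M0_nM, position,
    intensity.
    """
    df = pd.read_csv(path, dtype={"position": str})
    required = {"construct_id", "M0_nM", "position", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cleavage CSV missing columns: {sorted(missing)}")
    profiles = []
    cond_cols = [c for c in ("mg_mM", "temperature_K", "fa_uM") if c in df]
    for key, grp in df.groupby(["construct_id"] + cond_cols, sort=True):
        key = dict(zip(["construct_id"] + cond_cols, key))
        cond = Condition(
            mg_mM=float(key.get("mg_mM", 2.0)),
            temperature_K=float(key.get("temperature_K", 293.0)),
            fa_uM=float(key.get("fa_uM", 0.0)),
        )
        lanes = []
        for conc, lane_grp in grp.groupby("M0_nM", sort=True):
            lanes.append(
                (float(conc), dict(zip(lane_grp["position"], lane_grp["intensity"])))
            )
        profiles.append(
            CleavageProfile(
                construct_id=str(key["construct_id"]), condition=cond, lanes=lanes
            )
        )
    return profiles
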