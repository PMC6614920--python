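"""End-to-end orchestration: config-driven runs and summary tables.

``run_pipeline`` executes the fitting modules over the inputs declared in a
TOML config and writes a report bundle:

* ``kd_table.csv`` - one row per construct x condition with Kd, beta,
  replicate sd and status flags;
* ``ddg_ledger.csv`` - free energies and ddG against the reference
  construct (default 4LVV), strongest binder first; unmeasurable entries
  carry bound markers instead of numbers;
* ``fa_response.csv`` - matched +/- folinic-acid pairs with Kd fold-change
  and ddG_FA;
* ``signature_report.tsv`` and ``consensus.txt`` - families, pairing
  classes, distances and the >= 75%-conservation consensus;
* ``manifest.json`` - config hash, seed, package/library versions and
  output checksums, so a bundle is auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import gelshift, lead, signature, thermo
from .variants import curated_variants

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "query_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str
    inputs: list[dict] = field(default_factory=list)
    reference_construct: Optional[str] = "4LVV"
    detection_limit_nM: float = 1.0
    fold_threshold: float = 1.5
    fix_beta: Optional[float] = None
    seed: int = 0
    signature_fasta: Optional[str] = None
    config_path: Optional[str] = None

    def __post_init__(self):
        for inp in self.inputs:
            if "path" not in inp or "assay" not in inp:
                raise ValueError("each [[inputs]] entry needs 'path' and 'assay'")
            if inp["assay"] not in ("gelshift", "lead"):
                raise ValueError(f"unknown assay {inp['assay']!r}")
            if not Path(inp["path"]).exists():
                raise FileNotFoundError(inp["path"])


def load_run_config(path) -> RunConfig:
    """Parse a run config from TOML (a [run] table plus [[inputs]])."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run = raw.get("run", {})
    return RunConfig(
        outdir=run.get("outdir", "tectofit_out"),
        inputs=raw.get("inputs", []),
        reference_construct=run.get("reference_construct", "4LVV"),
        detection_limit_nM=run.get("detection_limit_nM", 1.0),
        fold_threshold=run.get("fold_threshold", 1.5),
        fix_beta=run.get("fix_beta"),
        seed=run.get("seed", 0),
        signature_fasta=run.get("signature_fasta"),
        config_path=str(path),
    )


def _fit_gelshift_input(path, config: RunConfig) -> list[dict]:
    series = gelshift.read_titration_csv(path)
    groups: dict = {}
    for s in series:
        groups.setdefault((s.construct_id, s.condition), []).append(s)
    rows = []
    for (construct, cond), reps in sorted(groups.items(), key=lambda kv: kv[0][0]):
        try:
            fits = [
                gelshift.fit_homodimer(
                    s,
                    fix_beta=config.fix_beta,
                    detection_limit_nM=config.detection_limit_nM,
                    seed=config.seed,
                )
                for s in reps
            ]
            agg = gelshift.aggregate_replicates(fits)
        except Exception as exc:
            rows.append({"construct_id": construct, "error": str(exc)})
            continue
        rows.append(_fit_row(construct, cond, agg, assay="gelshift"))
    return rows


def _fit_lead_input(path, config: RunConfig, positions: list[dict]) -> list[dict]:
    profiles = lead.read_cleavage_csv(path)
    rows = []
    for profile in profiles:
        try:
            fits = []
            for pos in positions:
                label = str(pos["label"])
                if label not in profile.lanes[0][1]:
                    continue
                direction = lead.Direction(pos.get("direction", "decreasing"))
                series = lead.normalize_two_state(
                    lead.position_series(profile, label), direction, position=label
                )
                fits.append(lead.fit_two_state(series))
            if not fits:
                raise ValueError(
                    f"{profile.construct_id}: none of the configured positions "
                    "are present in the profile"
                )
            agg = gelshift.aggregate_replicates(fits)
        except Exception as exc:
            rows.append({"construct_id": profile.construct_id, "error": str(exc)})
            continue
        agg.construct_id = profile.construct_id
        rows.append(_fit_row(profile.construct_id, profile.condition, agg, assay="lead"))
    return rows


def _fit_row(construct, cond, fit: gelshift.FitResult, assay: str) -> dict:
    return {
        "construct_id": construct,
        "assay": assay,
        "mg_mM": cond.mg_mM,
        "temperature_K": cond.temperature_K,
        "fa_uM": cond.fa_uM,
        "Kd_nM": fit.Kd_nM,
        "Kd_sd_nM": fit.Kd_sd_nM,
        "beta": fit.beta,
        "beta_sd": fit.beta_sd,
        "n_replicates": fit.n_replicates,
        "kd_is_bound": fit.kd_is_bound,
        "flags": ";".join(fit.flags),
    }


def _ddg_ledger(kd_table: pd.DataFrame, reference: str) -> pd.DataFrame:
    measurable = kd_table[~kd_table["kd_is_bound"]].copy()
    if not (measurable["construct_id"] == reference).any():
        raise ValueError(
            f"reference construct {reference!r} absent from measurable results; "
            "cannot build the ddG ledger"
        )
    ledger = thermo.add_free_energies(measurable, reference_construct=reference)
    ledger = ledger.sort_values(
        "ddG_kcal_mol", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    bounds = kd_table[kd_table["kd_is_bound"]].copy()
    if len(bounds):
        bounds["Kd_bound"] = [f"> {k:g} nM" for k in bounds["Kd_nM"]]
        bounds["Kd_nM"] = np.nan
        ledger = pd.concat([ledger, bounds], ignore_index=True)
    return ledger


def _fa_response(kd_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    keys = ["construct_id", "assay", "mg_mM", "temperature_K"]
    for key, grp in kd_table.groupby(keys):
        minus = grp[grp["fa_uM"] == 0]
        plus = grp[grp["fa_uM"] > 0]
        if minus.empty or plus.empty:
            continue
        kd_minus = float(minus["Kd_nM"].iloc[0])
        kd_plus = float(plus["Kd_nM"].iloc[0])
        T = float(minus["temperature_K"].iloc[0])
        rows.append(
            {
                **dict(zip(keys, key)),
                "Kd_minusFA_nM": kd_minus,
                "Kd_plusFA_nM": kd_plus,
                "fold_change": round(thermo.fold_change(kd_minus, kd_plus), 3),
                "ddG_FA_kcal_mol": round(thermo.ddg_fa(kd_plus, kd_minus, T), 4),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> tuple[dict, list[str]]:
    """Execute all configured inputs and write the report bundle.

    Returns (bundle, errors); *errors* collects per-construct failures that
    did not stop the rest of the run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, errors = [], []
    for inp in config.inputs:
        if inp["assay"] == "gelshift":
            new_rows = _fit_gelshift_input(inp["path"], config)
        else:
            new_rows = _fit_lead_input(inp["path"], config, inp.get("positions", []))
        for r in new_rows:
            if "error" in r:
                errors.append(f"{r['construct_id']}: {r['error']}")
                logger.error("fit failed for %s: %s", r["construct_id"], r["error"])
            else:
                rows.append(r)

    bundle: dict = {}
    kd_table = pd.DataFrame(rows)
    kd_table.to_csv(outdir / "kd_table.csv", index=False)
    bundle["kd_table"] = kd_table

    if len(kd_table) and config.reference_construct:
        ledger = _ddg_ledger(kd_table, config.reference_construct)
        ledger.to_csv(outdir / "ddg_ledger.csv", index=False)
        bundle["ddg_ledger"] = ledger

    if len(kd_table):
        fa = _fa_response(kd_table)
        fa.to_csv(outdir / "fa_response.csv", index=False)
        bundle["fa_response"] = fa

    variants = (
        signature.read_fasta(config.signature_fasta)
        if config.signature_fasta
        else curated_variants()
    )
    ref_id = (
        config.reference_construct
        if config.reference_construct in {v.id for v in variants}
        else None
    )
    sig = signature.signature_report(variants, reference_id=ref_id)
    sig.to_csv(outdir / "signature_report.tsv", sep="\t", index=False)
    bundle["signature_report"] = sig
    cons = signature.consensus(signature.SignatureAlignment(list(variants)))
    (outdir / "consensus.txt").write_text(cons + "\n")
    bundle["consensus"] = cons

    manifest = _manifest(config, outdir)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle, errors


def _manifest(config: RunConfig, outdir: Path) -> dict:
    import tectofit

    config_hash = None
    if config.config_path and Path(config.config_path).exists():
        config_hash = hashlib.sha256(
            Path(config.config_path).read_bytes()
        ).hexdigest()
    outputs = {}
    for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.tsv")):
        outputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return {
        "tectofit_version": tectofit.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_sha256": config_hash,
        "outputs_sha256": outputs,
    }


_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


def query_report(
    kd_table: pd.DataFrame, predicate: str, column: str = "Kd_nM"
) -> int:
    """Count constructs whose *column* satisfies a threshold predicate.

    *predicate* is an operator plus number, e.g. ``"<100"`` or ``"<=26"``
    (inclusive operators are inclusive: a value exactly at the threshold
    counts under ``<=``/``>=``).
    """
    if column not in kd_table.columns:
        raise ValueError(f"unknown column {column!r}")
    pred = predicate.strip()
    for op in ("<=", ">=", "<", ">"):
        if pred.startswith(op):
            threshold = float(pred[len(op):])
            values = kd_table[column].to_numpy(dtype=float)
            return int(np.sum(_OPS[op](values, threshold)))
    raise ValueError(f"malformed predicate {predicate!r}")
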