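"""Table schemas, validated CSV I/O, and the end-to-end pipeline.

The pipeline mirrors the experimental workflow: isotopologue spectra →
natural-abundance correction and enrichment → plastidial pool
partitioning → cascade-model flux fits per replicate → FTSW/RTR drought
staging → group statistics report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cascade, isotopologue, physiology, stats_report

__all__ = ["SCHEMAS", "PipelineConfig", "read_table", "write_table", "run_pipeline"]

logger = logging.getLogger("mepflux")

#: required column -> whether it must parse as a finite float
SCHEMAS: dict[str, dict[str, bool]] = {
    "time_courses": {"replicate_id": False, "species_id": False,
                     "time_min": True, "fraction": True},
    "spectra": {"sample_id": False, "species_id": False,
                "mass_shift": True, "intensity": True},
    "pools": {"replicate_id": False, "species_id": False,
              "total_pool_nmol_gDW": True, "final_enrichment": True},
    "pot_weights": {"tree_id": False, "day": True, "weight_g": True},
    "anchors": {"tree_id": False, "initial_g": True, "final_g": True},
    "measurements": {"variable_id": False, "treatment": False,
                     "tree_id": False, "value": True},
    "calibration": {"concentration": True, "signal": True},
}


def read_table(path, schema_id: str) -> pd.DataFrame:
    """Read a CSV/TSV table and validate it against a named schema.

    Errors name the offending column and row.  Decimal parsing is
    locale-independent ("." separator).
    """
    if schema_id not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_id!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    schema = SCHEMAS[schema_id]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    for col, numeric in schema.items():
        if not numeric:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r}, "
                f"row {int(bad[0]) + 2} (1-based incl. header)"
            )
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a DataFrame as UTF-8 CSV/TSV ('.' decimals, empty = missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, index=False, sep=sep)
    return path


@dataclass
class PipelineConfig:
    """Paths and options for a full pipeline run."""

    input_dir: str | Path
    out_dir: str | Path
    p_natural: float = isotopologue.NATURAL_13C_ABUNDANCE
    alpha: float = 0.05
    detect_threshold: float = 0.2
    control_label: str = "control"
    reference_species: str = "IDP+DMADP"
    correct_na: bool = True
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in vars(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def enrichment_table(spectra: pd.DataFrame, p_natural: float,
                     correct_na: bool = True) -> pd.DataFrame:
    """Per-sample, per-species fractional ¹³C enrichment from spectra.

    Long-format input (sample_id, species_id, mass_shift, intensity);
    natural-abundance correction is applied before the enrichment sum
    unless disabled.
    """
    rows = []
    for (sample, species), grp in spectra.groupby(["sample_id", "species_id"],
                                                  sort=False):
        grp = grp.sort_values("mass_shift")
        n = int(grp["mass_shift"].max())
        intens = np.zeros(n + 1)
        intens[grp["mass_shift"].astype(int).to_numpy()] = grp["intensity"].to_numpy()
        spec = isotopologue.IsotopologueSpectrum(n, intens, str(species))
        if correct_na:
            spec = isotopologue.correct_natural_abundance(spec, p_natural)
        rows.append({"sample_id": sample, "species_id": species,
                     "fraction_13C": isotopologue.enrichment_fraction(spec)})
    return pd.DataFrame(rows)


def plastidial_pool_table(pools: pd.DataFrame,
                          reference_species: str = "IDP+DMADP") -> pd.DataFrame:
    """Partition whole-tissue pools into plastidial pools per replicate.

    The reference species is taken as fully plastidial; other species are
    scaled by the ratio of their final enrichment to the reference's.
    """
    rows = []
    for rep, grp in pools.groupby("replicate_id", sort=False):
        ref = grp[grp["species_id"] == reference_species]
        if ref.empty:
            raise ValueError(f"replicate {rep!r}: reference species "
                             f"{reference_species!r} missing from pools")
        ref_enr = float(ref["final_enrichment"].iloc[0])
        for rec in grp.itertuples():
            meas = cascade.PoolMeasurement(
                rec.total_pool_nmol_gDW, rec.final_enrichment, rec.species_id
            )
            rows.append({
                "replicate_id": rep,
                "species_id": rec.species_id,
                "total_pool_nmol_gDW": rec.total_pool_nmol_gDW,
                "plastidial_pool_nmol_gDW": cascade.plastidial_pool(meas, ref_enr),
            })
    return pd.DataFrame(rows)


def fits_table(time_courses: pd.DataFrame, plastidial: pd.DataFrame,
               detect_threshold: float = 0.2,
               species_order=("DXP", "MEcDP", "IDP+DMADP")) -> pd.DataFrame:
    """Per-replicate cascade fits of the isoprene labeling time courses."""
    plast = plastidial.pivot_table(index="replicate_id", columns="species_id",
                                   values="plastidial_pool_nmol_gDW")
    rows = []
    iso = time_courses[time_courses["species_id"] == "isoprene"]
    for rep, grp in iso.groupby("replicate_id", sort=False):
        grp = grp.sort_values("time_min")
        tc = cascade.LabelingTimeCourse(
            grp["time_min"].to_numpy(), grp["fraction"].to_numpy(),
            "isoprene", str(rep),
        )
        if rep not in plast.index:
            raise ValueError(f"replicate {rep!r}: no plastidial pools")
        pools = tuple(float(plast.loc[rep, sp]) for sp in species_order)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = cascade.fit_flux(tc, pools, detect_threshold=detect_threshold)
        row = {"replicate_id": rep, "J_hat": res.flux_hat, "m_hat": res.plateau_hat,
               "sse": res.sse, "n_points": res.n_points,
               "converged": res.converged, "detectable": res.detectable,
               "identifiable": res.identifiable}
        if "treatment" in grp.columns:
            row["treatment"] = grp["treatment"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis on a directory of input tables.

    Expects the CSV bundle written by the synthetic generator (or real
    data in the same schemas); writes enrichment, plastidial pools, flux
    fits, drought staging and statistics report plus a JSON run log, and
    returns the output paths.  Deterministic for fixed inputs and config.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    caught: list[str] = []

    def _stage(name, fn):
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                result = fn()
            caught.extend(f"{name}: {w.message}" for w in wlist)
            logger.info("stage %s complete", name)
            return result
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    spectra = _stage("load", lambda: read_table(in_dir / "spectra.csv", "spectra"))
    enr = _stage("enrich", lambda: enrichment_table(
        spectra, config.p_natural, config.correct_na))
    outputs["enrichment"] = write_table(enr, out_dir / "enrichment.csv")

    pools = read_table(in_dir / "pools.csv", "pools")
    plast = _stage("pools", lambda: plastidial_pool_table(
        pools, config.reference_species))
    outputs["plastidial_pools"] = write_table(plast, out_dir / "plastidial_pools.csv")

    tcs = read_table(in_dir / "time_courses.csv", "time_courses")
    if tcs.empty:
        raise RuntimeError("pipeline stage 'fit' failed: empty time-course table")
    fits = _stage("fit", lambda: fits_table(tcs, plast, config.detect_threshold))
    outputs["fits"] = write_table(fits, out_dir / "fits.tsv")

    weights = read_table(in_dir / "pot_weights.csv", "pot_weights")
    anchors = read_table(in_dir / "anchors.csv", "anchors")
    reference = read_table(in_dir / "reference_weights.csv", "pot_weights")
    staging = _stage("ftsw", lambda: physiology.staging_table(
        weights, anchors, reference))
    outputs["staging"] = write_table(staging, out_dir / "staging.csv")

    meas = read_table(in_dir / "measurements.csv", "measurements")
    report = _stage("report", lambda: stats_report.report_table(
        meas, alpha=config.alpha, control=config.control_label))
    outputs["report"] = write_table(report, out_dir / "report.csv")

    log = {
        "config_digest": config.digest(),
        "inputs": str(in_dir),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "warnings": caught,
        "n_fits": int(len(fits)),
        "n_not_detectable": int((~fits["detectable"]).sum()),
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    outputs["log"] = log_path
    return outputs
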