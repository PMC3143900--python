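"""File formats: curve tables, assay/model configuration, call reports.

The interchange curve format is a long-format delimited text table with
header ``well_id,snp_id,temperature,fluorescence`` (comma or tab,
auto-detected).  Proprietary instrument exports (e.g. SDS) are not parsed;
users convert or export to this open dialect.

Configuration is a single YAML file carrying per-SNP assay records and the
calling-model block; the published "paper-2011" coefficient preset can be
selected by name instead of explicit coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import DissociationCurve
from .errors import DataIntegrityError
from .model import CallResult, OrdinalCallModel, get_preset
from .peaks import SnpAssayDef

__all__ = [
    "CURVE_COLUMNS",
    "RunConfig",
    "read_curves",
    "write_curves",
    "read_config",
    "write_config",
    "read_truth",
    "write_calls",
    "calls_to_frame",
]

CURVE_COLUMNS = ("well_id", "snp_id", "temperature", "fluorescence")


@dataclass
class RunConfig:
    """Parsed configuration: assays keyed by snp_id plus the calling model."""

    assays: dict[str, SnpAssayDef]
    model: OrdinalCallModel
    smoothing_sigma: float | None = None


def _read_table(path: str | Path) -> pd.DataFrame | None:
    import csv

    try:
        return pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        # empty file: nothing for the delimiter sniffer to work with
        return None


def read_curves(path: str | Path) -> list[DissociationCurve]:
    """Read a long-format curve table into per-well dissociation curves.

    Rows are grouped by well; within a well they are sorted by temperature
    (with a warning if the file was unsorted).  Duplicate
    (well, temperature) rows and non-numeric cells are hard errors that
    name the offending file row (header = row 1).
    """
    df = _read_table(path)
    if df is None or df.empty:
        warnings.warn(f"{path}: no curve rows found", stacklevel=2)
        return []
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise DataIntegrityError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )

    # header occupies file row 1; data row i (0-based) is file row i + 2
    for col in ("temperature", "fluorescence"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise DataIntegrityError(
                f"{path}: non-numeric {col} value {df[col][bad].iloc[0]!r} "
                f"at row {row}"
            )
        df[col] = numeric
    if df[["well_id", "temperature"]].isna().any().any():
        raise DataIntegrityError(f"{path}: empty well_id or temperature cell")

    dup = df.duplicated(subset=["well_id", "temperature"], keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise DataIntegrityError(
            f"{path}: duplicate (well_id, temperature) pair starting at row {row}"
        )

    curves = []
    for well_id, grp in df.groupby("well_id", sort=False):
        snps = grp["snp_id"].unique()
        if len(snps) > 1:
            raise DataIntegrityError(
                f"{path}: well {well_id!r} maps to multiple snp_ids {list(snps)}"
            )
        t = grp["temperature"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            warnings.warn(
                f"{path}: well {well_id!r} temperatures unsorted; sorting",
                stacklevel=2,
            )
            grp = grp.sort_values("temperature")
        curves.append(
            DissociationCurve(
                temperatures=grp["temperature"].to_numpy(dtype=float),
                intensities=grp["fluorescence"].to_numpy(dtype=float),
                well_id=str(well_id),
                snp_id=str(snps[0]),
            )
        )
    return curves


def write_curves(curves: list[DissociationCurve], path: str | Path) -> None:
    """Write curves to the long-format table (CSV, 6 significant decimals)."""
    frames = [
        pd.DataFrame(
            {
                "well_id": c.well_id,
                "snp_id": c.snp_id,
                "temperature": c.temperatures,
                "fluorescence": c.intensities,
            }
        )
        for c in curves
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CURVE_COLUMNS))
    )
    out.to_csv(path, index=False, float_format="%.6f")


def read_config(path: str | Path) -> RunConfig:
    """Parse the YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "snps" not in raw:
        raise DataIntegrityError(f"{path}: config must contain a 'snps' list")
    assays: dict[str, SnpAssayDef] = {}
    for rec in raw["snps"]:
        assay = SnpAssayDef(
            snp_id=str(rec["snp_id"]),
            tm_a=float(rec["tm_a"]),
            tm_b=float(rec["tm_b"]),
            allele_a=str(rec.get("allele_a", "A")),
            allele_b=str(rec.get("allele_b", "B")),
            delta=float(rec.get("delta", 0.0)),
        )
        if assay.snp_id in assays:
            raise DataIntegrityError(f"{path}: duplicate snp_id {assay.snp_id!r}")
        assays[assay.snp_id] = assay

    mblock = raw.get("model", {}) or {}
    rho = float(mblock.get("rho", 0.05))
    if "preset" in mblock:
        preset = get_preset(mblock["preset"])
        model = OrdinalCallModel(
            alpha1=preset.alpha1, alpha2=preset.alpha2, beta=preset.beta, rho=rho
        )
    else:
        try:
            model = OrdinalCallModel(
                alpha1=float(mblock["alpha1"]),
                alpha2=float(mblock["alpha2"]),
                beta=float(mblock["beta"]),
                rho=rho,
            )
        except KeyError as e:
            raise DataIntegrityError(
                f"{path}: model block needs either 'preset' or "
                f"alpha1/alpha2/beta (missing {e})"
            ) from None
    sigma = mblock.get("smoothing_sigma")
    return RunConfig(
        assays=assays,
        model=model,
        smoothing_sigma=float(sigma) if sigma else None,
    )


def write_config(config: RunConfig, path: str | Path) -> None:
    """Serialise a configuration (e.g. after training) back to YAML."""
    doc = {
        "model": {
            "alpha1": float(config.model.alpha1),
            "alpha2": float(config.model.alpha2),
            "beta": float(config.model.beta),
            "rho": float(config.model.rho),
            "smoothing_sigma": config.smoothing_sigma,
        },
        "snps": [
            {
                "snp_id": a.snp_id,
                "tm_a": float(a.tm_a),
                "tm_b": float(a.tm_b),
                "allele_a": a.allele_a,
                "allele_b": a.allele_b,
                "delta": float(a.delta),
            }
            for a in config.assays.values()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a truth table (well_id, genotype in {1,2,3}; snp_id optional)."""
    df = _read_table(path)
    if df is None or df.empty:
        raise DataIntegrityError(f"{path}: empty truth table")
    if not {"well_id", "genotype"} <= set(df.columns):
        raise DataIntegrityError(f"{path}: truth table needs well_id, genotype")
    genos = pd.to_numeric(df["genotype"], errors="coerce")
    if genos.isna().any() or not genos.isin([1, 2, 3]).all():
        raise DataIntegrityError(f"{path}: genotype values must be 1, 2 or 3")
    df["genotype"] = genos.astype(int)
    return df


def genotype_string(call_class: int | None, assay: SnpAssayDef) -> str:
    """Render an ordinal class as a base-pair string (class 2 of C/G -> 'CG')."""
    if call_class == 1:
        return assay.allele_a * 2
    if call_class == 2:
        return assay.allele_a + assay.allele_b
    if call_class == 3:
        return assay.allele_b * 2
    return ""


def calls_to_frame(
    results: list[CallResult], assays: dict[str, SnpAssayDef]
) -> pd.DataFrame:
    """Tabulate call results (probabilities and ratios at 4 decimals)."""

    def fmt(v: float | None) -> float | str:
        return "" if v is None else round(v, 4)

    rows = []
    for r in results:
        assay = assays.get(r.snp_id)
        p = r.probabilities
        rows.append(
            {
                "well_id": r.well_id,
                "snp_id": r.snp_id,
                "call": r.call.value,
                "genotype": genotype_string(r.call.ordinal, assay) if assay else "",
                "x": fmt(r.x),
                "X": fmt(r.x_adjusted),
                "p1": fmt(p.p1 if p else None),
                "p2": fmt(p.p2 if p else None),
                "p3": fmt(p.p3 if p else None),
                "reason": r.reason.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "well_id", "snp_id", "call", "genotype",
            "x", "X", "p1", "p2", "p3", "reason",
        ],
    )


def write_calls(
    results: list[CallResult],
    assays: dict[str, SnpAssayDef],
    path: str | Path,
) -> None:
    """Write the per-well call report as CSV."""
    calls_to_frame(results, assays).to_csv(path, index=False)
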