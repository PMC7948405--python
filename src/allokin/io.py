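"""Delimited-text I/O, run configuration and consolidated reporting.

One interchange dialect: comma-separated values with a JSON metadata block
in ``#``-prefixed header comments.  Schemas are validated on read (required
columns, numeric cells, nonnegative concentrations) with errors naming the
offending row.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .datasets import DoseResponseDataset, ProgressCurve, TitrationDataset, TransientSeries
from .thermo import CorrelationPoint

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "read_correlation_points",
    "write_correlation_points",
    "build_report",
    "render_report",
]


class ThermoConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gas_constant: float = 1.987e-3
    temperature: float = 298.15
    k_iso_baseline: float = 13.0
    k_rel: float = 2.5


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    weighted: bool = True
    bootstrap: int = 0
    aggregate: str = "mean"


class IOConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    delimiter: str = ","
    decimals: int = 6


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    thermo: ThermoConfig = ThermoConfig()
    fitting: FitConfig = FitConfig()
    io: IOConfig = IOConfig()
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


_SCHEMAS = {
    "dose_response": ["dose_nM", "response", "replicate_id"],
    "titration": ["ligand_total_nM", "signal_au", "replicate_id"],
    "progress": ["time_s", "signal_au"],
    "kobs_series": ["ligand_uM", "k_obs_s", "k_obs_sd_s"],
}
_NONNEGATIVE = {"dose_nM", "ligand_total_nM", "time_s", "ligand_uM"}


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    text = Path(path).read_text()
    meta_lines, data_lines = [], []
    for line in text.splitlines():
        (meta_lines if line.startswith("#") else data_lines).append(line)
    meta = {}
    raw = "\n".join(ln.lstrip("# ") for ln in meta_lines).strip()
    if raw:
        meta = json.loads(raw)
    frame = pd.read_csv(_io.StringIO("\n".join(data_lines)))
    return frame, meta


def _validate(frame: pd.DataFrame, schema_kind: str) -> pd.DataFrame:
    required = _SCHEMAS[schema_kind]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{schema_kind}: missing columns {missing}")
    for col in required:
        if col == "replicate_id":
            continue
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[numeric.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(f"{schema_kind}: non-numeric value in column "
                             f"'{col}' at row {int(bad[0])}")
        if frame[col].isna().any():
            raise ValueError(f"{schema_kind}: empty cell in column '{col}' at row "
                             f"{int(frame.index[frame[col].isna()][0])}")
        frame[col] = numeric
        if col in _NONNEGATIVE and (numeric < 0).any():
            row = int(frame.index[numeric < 0][0])
            raise ValueError(f"{schema_kind}: negative value in column '{col}' "
                             f"at row {row}")
    return frame


def read_dataset(path, schema_kind: str):
    """Read a delimited dataset of the given schema into its typed container."""
    frame, meta = _read_csv_with_meta(path)
    frame = _validate(frame, schema_kind)
    if schema_kind == "dose_response":
        return DoseResponseDataset(
            doses=frame["dose_nM"].to_numpy(),
            responses=frame["response"].to_numpy(),
            response_kind=meta.get("response_kind", "in_vitro_rate"),
            e_total=meta.get("e_total_nM"),
            replicate_ids=frame["replicate_id"].to_numpy(),
            compound_id=meta.get("compound_id", ""),
            metadata=meta,
        )
    if schema_kind == "titration":
        return TitrationDataset(
            ligand_totals=frame["ligand_total_nM"].to_numpy(),
            signals=frame["signal_au"].to_numpy(),
            site_concentration=meta["site_concentration_nM"],
            background=meta.get("background", "E"),
            replicate_ids=frame["replicate_id"].to_numpy(),
            metadata=meta,
        )
    if schema_kind == "progress":
        return ProgressCurve(
            times=frame["time_s"].to_numpy(),
            signals=frame["signal_au"].to_numpy(),
            ligand_um=meta["ligand_uM"],
            site_concentration_nm=meta["site_concentration_nM"],
            n_averaged=meta.get("n_averaged", 1),
            metadata=meta,
        )
    if schema_kind == "kobs_series":
        sds = frame["k_obs_sd_s"].to_numpy()
        return TransientSeries(
            ligand_concentrations=frame["ligand_uM"].to_numpy(),
            k_obs_values=frame["k_obs_s"].to_numpy(),
            k_obs_sds=None if np.all(np.isnan(sds)) else sds,
            metadata=meta,
        )
    raise ValueError(f"unknown schema_kind {schema_kind!r}")


def write_dataset(dataset, path, decimals: int = 6) -> None:
    """Write a typed dataset with its metadata as ``#`` JSON header comments."""
    if isinstance(dataset, DoseResponseDataset):
        meta = dict(dataset.metadata)
        meta.update(
            response_kind=dataset.response_kind,
            e_total_nM=dataset.e_total,
            compound_id=dataset.compound_id,
        )
        frame = pd.DataFrame({
            "dose_nM": dataset.doses,
            "response": dataset.responses,
            "replicate_id": dataset.replicate_ids
            if dataset.replicate_ids is not None else np.zeros(dataset.doses.size, int),
        })
    elif isinstance(dataset, TitrationDataset):
        meta = dict(dataset.metadata)
        meta.update(site_concentration_nM=dataset.site_concentration,
                    background=dataset.background)
        frame = pd.DataFrame({
            "ligand_total_nM": dataset.ligand_totals,
            "signal_au": dataset.signals,
            "replicate_id": dataset.replicate_ids
            if dataset.replicate_ids is not None
            else np.zeros(dataset.ligand_totals.size, int),
        })
    elif isinstance(dataset, ProgressCurve):
        meta = dict(dataset.metadata)
        meta.update(ligand_uM=dataset.ligand_um,
                    site_concentration_nM=dataset.site_concentration_nm,
                    n_averaged=dataset.n_averaged)
        frame = pd.DataFrame({"time_s": dataset.times, "signal_au": dataset.signals})
    elif isinstance(dataset, TransientSeries):
        meta = dict(dataset.metadata)
        frame = pd.DataFrame({
            "ligand_uM": dataset.ligand_concentrations,
            "k_obs_s": dataset.k_obs_values,
            "k_obs_sd_s": dataset.k_obs_sds
            if dataset.k_obs_sds is not None
            else np.full(dataset.k_obs_values.size, np.nan),
        })
    else:
        raise TypeError(f"cannot serialize {type(dataset).__name__}")

    header = "\n".join(
        "# " + line for line in json.dumps(meta, indent=1, default=float).splitlines()
    )
    body = frame.to_csv(index=False, float_format=f"%.{decimals}g")
    Path(path).write_text(header + "\n" + body)


def read_correlation_points(path) -> list[CorrelationPoint]:
    frame, _ = _read_csv_with_meta(path)
    required = ["compound_id", "ddg_calc_kcal_mol", "ddg_exp_kcal_mol"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"correlation file missing columns {missing}")
    return [
        CorrelationPoint(str(r.compound_id), float(r.ddg_calc_kcal_mol),
                         float(r.ddg_exp_kcal_mol))
        for r in frame.itertuples()
    ]


def write_correlation_points(points, path) -> None:
    frame = pd.DataFrame({
        "compound_id": [p.compound_id for p in points],
        "ddg_calc_kcal_mol": [p.ddg_calc for p in points],
        "ddg_exp_kcal_mol": [p.ddg_exp for p in points],
    })
    frame.to_csv(path, index=False)


def build_report(fits: dict, correlation=None) -> dict:
    """Consolidated per-compound parameter report plus the correlation line.

    ``fits`` maps compound id to a dict that may hold InhibitorParams under
    'in_vitro', ExVivoParams under 'ex_vivo' and BindingFit under 'binding'.
    """
    if not fits:
        raise ValueError("no fits to report")
    rows = {}
    for compound, blocks in fits.items():
        row: dict = {}
        if "in_vitro" in blocks:
            p = blocks["in_vitro"]
            row["k_i_nM"] = p.k_i
            row["k_i_sd_nM"] = p.k_i_sd
            row["alpha"] = p.alpha
            row["pct_inhibition_saturation"] = p.pct_inh_sat
        if "ex_vivo" in blocks:
            p = blocks["ex_vivo"]
            row["ic50_nM"] = p.ic50
            row["ic50_sd_nM"] = p.ic50_sd
            row["pct_inhibition_saturation_exvivo"] = p.pct_inh_sat
        if "binding" in blocks:
            p = blocks["binding"]
            row["k_d_nM"] = p.k_d
            row["k_d_sd_nM"] = p.k_d_sd
        rows[compound] = row
    report = {"compounds": rows}
    if correlation is not None:
        report["correlation"] = {
            "slope": correlation.slope_,
            "intercept_kcal_mol": correlation.intercept_,
            "pearson_r": correlation.r_,
            "slope_se": correlation.slope_se_,
        }
    return report


def render_report(report: dict, decimals: int = 3) -> str:
    """Human-readable rendering of a build_report dict."""
    lines = ["compound  quantity  value  (1 SD)", "-" * 40]
    for compound, row in report["compounds"].items():
        for key, val in row.items():
            if key.endswith("_sd_nM") or val is None:
                continue
            sd = row.get(key.replace("_nM", "_sd_nM")) if key.endswith("_nM") else None
            sd_txt = f" ({sd:.{decimals}g})" if sd is not None else ""
            lines.append(f"{compound}  {key}  {val:.{decimals}g}{sd_txt}")
    if "correlation" in report:
        c = report["correlation"]
        lines.append(
            f"correlation  slope {c['slope']:.{decimals}g} "
            f"(SE {c['slope_se']:.{decimals}g})  R {c['pearson_r']:.{decimals}g}"
        )
    return "\n".join(lines)
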