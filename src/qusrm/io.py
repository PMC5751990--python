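"""File formats: HDF5 RF containers, CSV tables, map sidecars.

The RF container is an HDF5 file with a float dataset ``"rf"``
(samples x lines) and one attribute per acquisition field plus
``origin_depth`` and a schema version.  Cohorts serialize to three CSVs
(patients, features, survival); parametric maps to a CSV grid with a JSON
sidecar carrying parameter name, units and window-grid geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig, RFFrame
from .features import (FEATURE_NAMES, PatientRecord, SCAN_TIMES,
                       scan_feature_names)
from .spectral import ParametricMap

__all__ = [
    "write_rf_container",
    "read_rf_container",
    "write_cohort_tables",
    "read_feature_table",
    "write_map_csv",
    "read_map_csv",
]

_SCHEMA_VERSION = 1
_ACQ_ATTRS = ("sampling_rate", "center_frequency", "band", "sound_speed",
              "line_pitch", "pulse_bandwidth_fraction")


def write_rf_container(frame: RFFrame, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("rf", data=frame.samples)
        h5.attrs["schema_version"] = _SCHEMA_VERSION
        h5.attrs["origin_depth"] = frame.origin_depth
        for name in _ACQ_ATTRS:
            h5.attrs[name] = getattr(frame.acquisition, name)


def read_rf_container(path: str | Path) -> RFFrame:
    try:
        with h5py.File(path, "r") as h5:
            if "rf" not in h5:
                raise ValueError(f"{path}: missing dataset 'rf'")
            version = h5.attrs.get("schema_version")
            if version != _SCHEMA_VERSION:
                raise ValueError(
                    f"{path}: unsupported schema version {version!r}")
            missing = [a for a in _ACQ_ATTRS + ("origin_depth",)
                       if a not in h5.attrs]
            if missing:
                raise ValueError(f"{path}: missing attributes {missing}")
            kwargs = {name: h5.attrs[name] for name in _ACQ_ATTRS}
            kwargs["band"] = tuple(np.atleast_1d(kwargs["band"]))
            acq = AcquisitionConfig(**{
                k: (v if k == "band" else float(v))
                for k, v in kwargs.items()})
            return RFFrame(samples=h5["rf"][()], acquisition=acq,
                           origin_depth=float(h5.attrs["origin_depth"]))
    except OSError as exc:
        raise ValueError(f"{path}: unreadable RF container ({exc})") from exc


def write_cohort_tables(records: list[PatientRecord], out_dir: str | Path
                        ) -> dict[str, Path]:
    """patients.csv / features.csv / survival.csv for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = pd.DataFrame([{
        "id": r.id, "label": r.label.value, "pre_size_cm": r.pre_size,
        "post_size_cm": r.post_size, "invasive_residual": r.invasive_residual,
        "cellularity_decreased": r.cellularity_decreased,
        "clinical_tumor_evidence": r.clinical_tumor_evidence,
        "ER": int(r.molecular.er), "PR": int(r.molecular.pr),
        "HER2": int(r.molecular.her2)} for r in records])
    rows = []
    for r in records:
        for t in SCAN_TIMES:
            if t in r.scans:
                row = {"id": r.id, "label": r.label.value, "scan_time": t}
                row.update({n: r.scans[t][n] for n in scan_feature_names()})
                rows.append(row)
    features = pd.DataFrame(rows)
    survival = pd.DataFrame([{
        "id": r.id, "group": r.label.value,
        "time_months": r.recurrence_time, "event": int(r.event)}
        for r in records])
    paths = {}
    for name, df in (("patients", patients), ("features", features),
                     ("survival", survival)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "label", "scan_time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_map_csv(pmap: ParametricMap, path: str | Path,
                  geometry: dict | None = None) -> None:
    path = Path(path)
    values = pmap.values.copy()
    values[~pmap.mask] = np.nan
    np.savetxt(path, values, delimiter=",")
    sidecar = {"parameter": pmap.parameter_name, "units": pmap.units,
               "shape": list(pmap.values.shape)}
    if geometry:
        sidecar["geometry"] = geometry
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_map_csv(path: str | Path) -> ParametricMap:
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ParametricMap(values, meta["parameter"], units=meta.get("units", ""))
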