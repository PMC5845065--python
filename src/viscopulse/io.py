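"""Reading and writing material cards, records, fields and spectra.

Material cards are JSON or YAML mappings with keys
``{model: "maxwell"|"zener", E0_Pa, E1_Pa, tau_s}``; values may instead
use ``_MPa`` / ``_mm`` suffixed keys, converted to SI on ingest.
Records and fields are plain delimited text with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd
import yaml

from viscopulse.constitutive import MaxwellMaterial, ZenerMaterial
from viscopulse.fitting import StressStrainRecord
from viscopulse.spectral import DecaySpectrum, TubeGeometry
from viscopulse.waves import PressureField

__all__ = [
    "load_material_card", "dump_material_card",
    "load_geometry", "read_record", "write_record",
    "write_field", "read_field", "spectrum_frame",
]

Material = Union[MaxwellMaterial, ZenerMaterial]

_UNIT_FACTORS = {"Pa": 1.0, "MPa": 1e6, "kPa": 1e3,
                 "s": 1.0, "ms": 1e-3,
                 "m": 1.0, "mm": 1e-3}


def _si(mapping: Dict, base: str) -> float:
    """Fetch ``base`` allowing unit-suffixed keys (E0_Pa, E0_MPa, ...)."""
    for key, value in mapping.items():
        if key == base:
            return float(value)
        if key.startswith(base + "_"):
            unit = key[len(base) + 1:]
            if unit in _UNIT_FACTORS:
                return float(value) * _UNIT_FACTORS[unit]
    raise KeyError(f"no key for quantity {base!r} in {sorted(mapping)}")


def _load_mapping(path: Union[str, Path]) -> Dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def material_from_dict(card: Dict) -> Material:
    model = str(card.get("model", "")).lower()
    if model == "maxwell":
        return MaxwellMaterial(E1=_si(card, "E1"), tau=_si(card, "tau"))
    if model == "zener":
        return ZenerMaterial(E0=_si(card, "E0"), E1=_si(card, "E1"),
                             tau=_si(card, "tau"))
    raise ValueError(f"unknown material model {card.get('model')!r}")


def load_material_card(path: Union[str, Path]) -> Material:
    return material_from_dict(_load_mapping(path))


def dump_material_card(material: Material, path: Union[str, Path]) -> None:
    if isinstance(material, ZenerMaterial):
        card = {"model": "zener", "E0_Pa": material.E0,
                "E1_Pa": material.E1, "tau_s": material.tau}
    else:
        card = {"model": "maxwell", "E1_Pa": material.E1,
                "tau_s": material.tau}
    Path(path).write_text(json.dumps(card, indent=2) + "\n")


def geometry_from_dict(mapping: Dict) -> TubeGeometry:
    return TubeGeometry(r=_si(mapping, "r"), e=_si(mapping, "e"),
                        L=_si(mapping, "L"), rho=_si(mapping, "rho"))


def load_geometry(path: Union[str, Path]) -> TubeGeometry:
    return geometry_from_dict(_load_mapping(path))


def read_record(path: Union[str, Path]) -> StressStrainRecord:
    """Read a (t, eps[, sigma]) delimited table; a JSON sidecar
    ``<path>.meta.json`` is restored as metadata when present."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "t" not in cols or "eps" not in cols:
        raise ValueError(f"record must have columns t, eps[, sigma]; "
                         f"got {list(df.columns)}")
    sigma = df[cols["sigma"]].to_numpy() if "sigma" in cols \
        else np.zeros(len(df))
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return StressStrainRecord(t=df[cols["t"]].to_numpy(),
                              eps=df[cols["eps"]].to_numpy(),
                              sigma=sigma, meta=meta)


def write_record(record: StressStrainRecord, path: Union[str, Path]) -> None:
    pd.DataFrame({"t": record.t, "eps": record.eps,
                  "sigma": record.sigma}).to_csv(path, index=False)
    if record.meta:
        Path(str(path) + ".meta.json").write_text(
            json.dumps(record.meta, indent=2) + "\n")


def write_field(field: PressureField, path: Union[str, Path]) -> None:
    """Long-format (t, x, p) table."""
    tt, xx = np.meshgrid(field.t, field.x, indexing="ij")
    pd.DataFrame({"t": tt.ravel(), "x": xx.ravel(),
                  "p": field.p.ravel()}).to_csv(path, index=False)


def read_field(path: Union[str, Path]) -> PressureField:
    df = pd.read_csv(path)
    t = np.unique(df["t"].to_numpy())
    x = np.unique(df["x"].to_numpy())
    p = df["p"].to_numpy().reshape(t.size, x.size)
    return PressureField(x=x, t=t, p=p)


def spectrum_frame(spectrum: DecaySpectrum) -> pd.DataFrame:
    """Per-mode table: n, lambda_n, Re/Im of each rate, regime."""
    rows = []
    for mode in spectrum.modes:
        row = {"n": mode.n, "lambda_n": mode.lambda_n,
               "regime": mode.regime, "omega_n": mode.omega_n}
        for k, z in enumerate(mode.rates, start=1):
            row[f"rate{k}_re"] = z.real
            row[f"rate{k}_im"] = z.imag
        rows.append(row)
    return pd.DataFrame(rows)
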