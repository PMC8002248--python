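"""Readers and writers for spectrum CSVs, model JSON files and campaign exports.

Formats
-------
Spectrum CSV
    Header ``frequency_hz,relative_permittivity,conductivity_s_per_m``, one
    row per grid point in ascending frequency, UTF-8, '.' decimal separator.
Model JSON
    ``{"model": "debye"|"cole_cole", "eps_inf": .., "sigma_s": ..,
    "poles": [{"delta_eps": .., "tau_s": .., "alpha": ..}, ...]}`` with tau in
    seconds (``alpha`` only for cole_cole).  Published tables often print tau
    in nanoseconds; :func:`debye_from_table_row` converts.
Metadata sidecar
    A JSON file written next to every exported spectrum (``<name>.meta.json``)
    carrying the reporting metadata for dielectric measurements (species,
    tissue part, temperature, time from excision, instrument, probe, notes).
Campaign CSV
    One row per measurement record referencing its spectrum file:
    ``heart_id,location,part,repeat,instrument,time_from_excision_min,
    temperature_c,spectrum_file``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .campaign import MeasurementLocation, MeasurementRecord, TissuePart
from .models import (
    ColeColeParameters,
    DebyeParameters,
    FrequencyGrid,
    PermittivitySpectrum,
    Pole,
)

__all__ = [
    "SPECTRUM_COLUMNS",
    "SpectrumParseError",
    "MetadataSidecar",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_model_json",
    "write_model_json",
    "debye_from_table_row",
    "load_heart_models",
    "write_sidecar",
    "read_sidecar",
    "write_campaign_csv",
    "read_campaign_csv",
]

SPECTRUM_COLUMNS = ("frequency_hz", "relative_permittivity", "conductivity_s_per_m")


class SpectrumParseError(ValueError):
    """A spectrum CSV violated the format contract."""


def read_spectrum_csv(path: str | Path, **kwargs) -> PermittivitySpectrum:
    """Read a spectrum CSV, validating the header and frequency ordering.

    Out-of-order rows are sorted (with a warning); duplicate frequencies and
    non-numeric cells raise :class:`SpectrumParseError` naming the offending
    row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if tuple(df.columns) != SPECTRUM_COLUMNS:
        raise SpectrumParseError(
            f"{path}: expected header {','.join(SPECTRUM_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    for col in SPECTRUM_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
            raise SpectrumParseError(f"{path}: non-numeric or missing value in row {row}")
        df[col] = numeric
    f = df["frequency_hz"].to_numpy(dtype=float)
    if np.unique(f).size != f.size:
        dup = f[np.flatnonzero(np.diff(np.sort(f)) == 0)[0]]
        raise SpectrumParseError(f"{path}: duplicate frequency {dup:g} Hz")
    if np.any(np.diff(f) < 0):
        warnings.warn(f"{path}: rows out of frequency order; sorting", stacklevel=2)
        df = df.sort_values("frequency_hz", kind="stable")
    return PermittivitySpectrum(
        FrequencyGrid(df["frequency_hz"].to_numpy(dtype=float)),
        df["relative_permittivity"].to_numpy(dtype=float),
        df["conductivity_s_per_m"].to_numpy(dtype=float),
        **kwargs,
    )


def write_spectrum_csv(spectrum: PermittivitySpectrum, path: str | Path) -> None:
    """Write a spectrum CSV at full precision (lossless round-trip)."""
    df = pd.DataFrame(
        {
            "frequency_hz": spectrum.grid.frequencies,
            "relative_permittivity": spectrum.eps_r,
            "conductivity_s_per_m": spectrum.sigma,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _pole_dicts(params: DebyeParameters) -> list[dict]:
    out = []
    alphas = params.alphas if isinstance(params, ColeColeParameters) else None
    for i, p in enumerate(params.poles):
        d = {"delta_eps": p.delta_eps, "tau_s": p.tau}
        if alphas is not None:
            d["alpha"] = alphas[i]
        out.append(d)
    return out


def write_model_json(params: DebyeParameters, path: str | Path) -> None:
    """Write Debye/Cole-Cole parameters as model JSON (tau in seconds)."""
    doc = {
        "model": "cole_cole" if isinstance(params, ColeColeParameters) else "debye",
        "eps_inf": params.eps_inf,
        "sigma_s": params.sigma_s,
        "poles": _pole_dicts(params),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_model_json(path: str | Path) -> DebyeParameters:
    """Read a model JSON file; validation errors name the missing field."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return model_from_dict(doc, source=str(path))


def model_from_dict(doc: dict, source: str = "<dict>") -> DebyeParameters:
    kind = doc.get("model", "debye")
    for key in ("eps_inf", "sigma_s", "poles"):
        if key not in doc:
            raise ValueError(f"{source}: missing field {key!r}")
    poles = []
    alphas = []
    for i, p in enumerate(doc["poles"]):
        for key in ("delta_eps", "tau_s"):
            if key not in p:
                raise ValueError(f"{source}: pole {i} missing field {key!r}")
        poles.append(Pole(float(p["delta_eps"]), float(p["tau_s"])))
        alphas.append(float(p.get("alpha", 0.0)))
    if kind == "cole_cole":
        return ColeColeParameters(
            float(doc["eps_inf"]), float(doc["sigma_s"]), tuple(poles), tuple(alphas)
        )
    if kind != "debye":
        raise ValueError(f"{source}: unknown model kind {kind!r}")
    if any(a != 0.0 for a in alphas):
        raise ValueError(f"{source}: alpha given for a 'debye' model")
    return DebyeParameters(float(doc["eps_inf"]), float(doc["sigma_s"]), tuple(poles))


def debye_from_table_row(
    eps_inf: float, sigma_s: float, *pole_pairs_ns: tuple[float, float]
) -> DebyeParameters:
    """Build parameters from a published table row with tau printed in ns."""
    poles = tuple(Pole(de, tau_ns * 1e-9) for de, tau_ns in pole_pairs_ns)
    return DebyeParameters(eps_inf, sigma_s, poles)


def load_heart_models() -> dict[tuple[str, TissuePart], DebyeParameters]:
    """The packaged per-(heart, part) fitted three-pole Debye models (24 sets)."""
    text = (
        resources.files("dielspec").joinpath("data/heart_debye_models.json").read_text("utf-8")
    )
    doc = json.loads(text)
    out: dict[tuple[str, TissuePart], DebyeParameters] = {}
    for entry in doc["models"]:
        poles = tuple(Pole(p["delta_eps"], p["tau_s"]) for p in entry["poles"])
        key = (entry["heart_id"], TissuePart(entry["part"]))
        out[key] = DebyeParameters(entry["eps_inf"], entry["sigma_s"], poles)
    return out


@dataclass(frozen=True)
class MetadataSidecar:
    """Reporting metadata written alongside every exported spectrum."""

    species: str = ""
    tissue_part: str = ""
    temperature_c: float = float("nan")
    time_from_excision_min: float = float("nan")
    instrument: str = ""
    probe: str = ""
    notes: str = ""


def _sidecar_path(spectrum_path: str | Path) -> Path:
    p = Path(spectrum_path)
    return p.with_suffix(p.suffix + ".meta.json") if p.suffix != ".csv" else p.with_suffix(".meta.json")


def write_sidecar(meta: MetadataSidecar, spectrum_path: str | Path) -> Path:
    path = _sidecar_path(spectrum_path)
    path.write_text(json.dumps(asdict(meta), indent=2) + "\n", encoding="utf-8")
    return path


def read_sidecar(spectrum_path: str | Path) -> MetadataSidecar:
    path = _sidecar_path(spectrum_path)
    return MetadataSidecar(**json.loads(path.read_text(encoding="utf-8")))


def write_campaign_csv(
    records: list[MeasurementRecord], out_dir: str | Path, with_sidecars: bool = True
) -> Path:
    """Export a campaign: one index CSV plus one spectrum CSV per record."""
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        name = f"{rec.heart_id}_{rec.location.label}_r{rec.repeat_index:02d}_{i:04d}.csv"
        write_spectrum_csv(rec.spectrum, spectra_dir / name)
        if with_sidecars:
            write_sidecar(
                MetadataSidecar(
                    species="ovine",
                    tissue_part=rec.part.value,
                    temperature_c=rec.temperature_c,
                    time_from_excision_min=rec.time_from_excision_min,
                    instrument=rec.instrument,
                    probe="open-ended coaxial (slim form)",
                ),
                spectra_dir / name,
            )
        rows.append(
            {
                "heart_id": rec.heart_id,
                "location": rec.location.label,
                "part": rec.part.value,
                "repeat": rec.repeat_index,
                "instrument": rec.instrument,
                "time_from_excision_min": rec.time_from_excision_min,
                "temperature_c": rec.temperature_c,
                "spectrum_file": f"spectra/{name}",
            }
        )
    index = out_dir / "campaign.csv"
    pd.DataFrame(rows).to_csv(index, index=False, float_format="%.17g")
    return index


def read_campaign_csv(index_path: str | Path) -> list[MeasurementRecord]:
    """Load a campaign exported by :func:`write_campaign_csv`."""
    index_path = Path(index_path)
    df = pd.read_csv(index_path)
    records = []
    for _, row in df.iterrows():
        spectrum = read_spectrum_csv(index_path.parent / row["spectrum_file"])
        records.append(
            MeasurementRecord(
                heart_id=str(row["heart_id"]),
                location=MeasurementLocation(str(row["location"]), TissuePart(row["part"])),
                repeat_index=int(row["repeat"]),
                time_from_excision_min=float(row["time_from_excision_min"]),
                temperature_c=float(row["temperature_c"]),
                instrument=str(row["instrument"]),
                spectrum=spectrum,
            )
        )
    return records
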