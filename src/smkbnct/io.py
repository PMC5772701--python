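"""File formats: PD tables, spectra, segments, survival records, configs.

All formats are plain text.  PD and spectrum files are TSV with ``# key=value``
header lines; survival records are CSV; fit results are JSON; run
configurations are YAML with a versioned schema.  Numeric payloads round-trip
exactly (within 1e-12 relative) through write/read.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, SurvivalRecord
from .microdose import SpecificEnergyPD, TrackSegments
from .survival import SMKParams
from .transport import SpectrumSource

__all__ = [
    "write_pd", "read_pd", "write_spectrum", "read_spectrum",
    "write_segments", "read_segments", "write_records", "read_records",
    "write_fit_result", "read_fit_result", "load_run_config",
    "bundled_spectrum", "default_params",
]

_REQUIRED_PD_KEYS = ("site",)


def _read_headers(path) -> tuple[dict, int]:
    headers, n_skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                headers[key.strip()] = val.strip()
    return headers, n_skip


def write_pd(path, pd_obj: SpecificEnergyPD, component: str = "",
             compartment: str = "") -> None:
    meta = dict(pd_obj.meta)
    site = meta.get("site", "nucleus")
    with open(path, "w") as fh:
        fh.write(f"# component={component or meta.get('component', '')}\n")
        fh.write(f"# compartment={compartment or meta.get('compartment', '')}\n")
        fh.write(f"# site={site}\n")
        if site == "domain":
            fh.write(f"# r_site_um={meta.get('r_site_um', '')}\n")
        fh.write(f"# n_events={pd_obj.n_events}\n")
        fh.write(f"# n_histories={pd_obj.n_histories}\n")
        fh.write(f"# event_rate={float(pd_obj.event_rate)!r}\n")
        fh.write("z_low_Gy\tz_high_Gy\tpdf_per_Gy\n")
        for lo, hi, d in zip(pd_obj.bin_edges[:-1], pd_obj.bin_edges[1:],
                             pd_obj.density):
            fh.write(f"{float(lo)!r}\t{float(hi)!r}\t{float(d)!r}\n")


def read_pd(path) -> SpecificEnergyPD:
    headers, n_skip = _read_headers(path)
    for key in _REQUIRED_PD_KEYS:
        if key not in headers:
            raise ValueError(f"{path}: malformed PD header, missing key {key!r}")
    try:
        data = np.loadtxt(path, skiprows=n_skip + 1, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable PD table: {exc}") from exc
    if data.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, found {data.shape[1]}")
    if np.any(np.abs(data[1:, 0] - data[:-1, 1]) > 1e-9 * data[1:, 0]):
        raise ValueError(f"{path}: bins are not contiguous")
    edges = np.concatenate([data[:, 0], data[-1:, 1]])
    meta = {"site": headers["site"]}
    for k in ("component", "compartment"):
        if headers.get(k):
            meta[k] = headers[k]
    if headers.get("r_site_um"):
        meta["r_site_um"] = float(headers["r_site_um"])
    return SpecificEnergyPD(
        edges, data[:, 2],
        n_events=int(headers.get("n_events", 0) or 0),
        n_histories=int(headers.get("n_histories", 0) or 0),
        event_rate=float(headers.get("event_rate", 1.0) or 1.0),
        meta=meta)


def write_spectrum(path, spec: SpectrumSource, note: str = "") -> None:
    with open(path, "w") as fh:
        if note:
            fh.write(f"# note={note}\n")
        fh.write("species\tenergy_MeV\tweight\n")
        for s, e, w in zip(spec.species, spec.energy_mev, spec.weight):
            fh.write(f"{s}\t{float(e)!r}\t{float(w)!r}\n")


def read_spectrum(path) -> SpectrumSource:
    _, n_skip = _read_headers(path)
    frame = pd.read_csv(path, sep="\t", skiprows=n_skip)
    for col in ("species", "energy_MeV", "weight"):
        if col not in frame.columns:
            raise ValueError(f"{path}: spectrum file missing column {col!r}")
    return SpectrumSource(list(frame["species"]),
                          frame["energy_MeV"].to_numpy(),
                          frame["weight"].to_numpy())


def write_segments(path, segs: TrackSegments) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_histories={float(segs.n_histories)!r}\n")
        fh.write(f"# species_names={','.join(segs.species_names)}\n")
        fh.write("species\te_mid_MeV\tlength_um\n")
        for c, e, ln in zip(segs.species_code, segs.e_mid, segs.length):
            fh.write(f"{segs.species_names[c]}\t{float(e)!r}\t{float(ln)!r}\n")


def read_segments(path) -> TrackSegments:
    headers, n_skip = _read_headers(path)
    if "species_names" not in headers or "n_histories" not in headers:
        raise ValueError(f"{path}: malformed segments header")
    names = tuple(headers["species_names"].split(","))
    frame = pd.read_csv(path, sep="\t", skiprows=n_skip)
    codes = np.array([names.index(s) for s in frame["species"]], dtype=np.int8)
    return TrackSegments(codes, frame["e_mid_MeV"].to_numpy(),
                         frame["length_um"].to_numpy(), names,
                         float(headers["n_histories"]))


RECORD_COLUMNS = ("condition_id", "dose_Gy", "sf", "sf_sigma", "time_h")


def write_records(path, frame: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"records table missing columns {missing}")
    frame.to_csv(path, index=False)


def read_records(path) -> list[SurvivalRecord]:
    frame = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: records file missing columns {missing}")
    out = []
    for i, row in frame.iterrows():
        try:
            out.append(SurvivalRecord(str(row.condition_id), float(row.dose_Gy),
                                      float(row.sf), float(row.sf_sigma),
                                      float(row.time_h)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_fit_result(path, result: FitResult) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def read_fit_result(path) -> FitResult:
    with open(path) as fh:
        d = json.load(fh)
    return FitResult(params=SMKParams(**d["params"]),
                     uncertainties=d["uncertainties"], chi2=d["chi2"],
                     chi2_per_dof=d["chi2_per_dof"],
                     adjusted_r2=d["adjusted_r2"],
                     rd_profile={float(k): v for k, v in d["rd_profile"].items()},
                     n_records=d["n_records"])


def load_run_config(path) -> dict:
    """Versioned YAML run configuration; validates units-bearing keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "schema_version" not in cfg:
        raise ValueError(f"{path}: run config must carry a schema_version key")
    geom = cfg.get("geometry", {})
    for key in geom:
        if not key.endswith(("_um", "_n", "mode", "seed")):
            raise ValueError(f"{path}: geometry key {key!r} lacks a unit suffix")
    for block in ("irradiation", "model"):
        for key, val in cfg.get(block, {}).items():
            if isinstance(val, (int, float)) and key.endswith(("_Gy", "_Gy_h",
                                                               "_h", "_ppm")):
                if val < 0:
                    raise ValueError(f"{path}: {block}.{key} must be >= 0")
    for key in ("pd_files", "spectrum_files"):
        for name in cfg.get(key, []) or []:
            if not Path(name).exists():
                raise FileNotFoundError(f"{path}: referenced file {name} missing")
    return cfg


def _data_file(name: str):
    return resources.files("smkbnct.data") / name


def bundled_spectrum(component: str) -> SpectrumSource:
    """Bundled simplified charged-particle spectra (synthetic stand-ins).

    'hydrogen': recoil protons of an epithermal-beam-like field;
    'photon': secondary-electron spectrum.  Both are simplified synthetic
    defaults -- externally computed spectra can be supplied as files instead.
    """
    names = {"hydrogen": "spectrum_hydrogen_synthetic.tsv",
             "photon": "spectrum_photon_electrons_synthetic.tsv"}
    if component not in names:
        raise ValueError(f"no bundled spectrum for component {component!r}")
    with resources.as_file(_data_file(names[component])) as p:
        return read_spectrum(p)


def default_params() -> dict:
    """Bundled reference parameters and KUR-like irradiation defaults."""
    with _data_file("default_params.yaml").open() as fh:
        return yaml.safe_load(fh)
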