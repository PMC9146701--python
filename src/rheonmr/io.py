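"""CSV and JSON schemas for every pipeline artefact.

All CSV columns carry their unit in the header (``r_m``, ``v_m_per_s``,
``t_min``, ``tau0_Pa``, ``g_T_per_m``, ``E``, ``t_s``) so files are
self-describing; scalar metadata (time stamp, applied rate) travel as
``# key: value`` comment lines. Extra columns are accepted and preserved
in the object's metadata. Floats are written with numpy's shortest
round-trip representation, so read(write(x)) == x bit for bit.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .dt2 import DT2Map, T2Calibration
from .dropletsize import DropletSizeDistribution, PFGDecay
from .flowcurve import HBFit
from .kinetics import SKMFit
from .velocimetry import LocalFlowCurve, SchemaError, VelocityProfile

def _shortest_repr(value) -> str:
    """Shortest decimal string that parses back to the same float64."""
    return repr(float(value))


def _read_csv(path):
    meta = {}
    lines = Path(path).read_text().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
        else:
            body.append(line)
    df = pd.read_csv(StringIO("\n".join(body)), float_precision="round_trip")
    return df, meta


def _meta_float(meta: dict, key: str, default=None):
    """Parse an optional numeric metadata entry; 'None'/absent -> default."""
    raw = meta.get(key)
    if raw is None or raw == "None":
        return default
    try:
        return float(raw)
    except ValueError as exc:
        raise SchemaError(f"metadata {key!r} is not numeric: {raw!r}") from exc


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _write_csv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            if value is not None:
                fh.write(f"# {key}: {_shortest_repr(value)}\n")
        # pandas' default float formatting is the shortest round-trip repr
        df.to_csv(fh, index=False)


def write_profile_csv(path, profile: VelocityProfile) -> None:
    df = pd.DataFrame({"r_m": profile.r, "v_m_per_s": profile.v})
    for key, vals in profile.metadata.items():
        df[key] = vals
    _write_csv(path, df, {
        "time_stamp_min": profile.time_stamp,
        "applied_rate_per_s": profile.applied_rate,
    })


def read_profile_csv(path) -> VelocityProfile:
    df, meta = _read_csv(path)
    _require(df, ["r_m", "v_m_per_s"], path)
    extras = {c: df[c].to_numpy() for c in df.columns if c not in ("r_m", "v_m_per_s")}
    r = df["r_m"].to_numpy(dtype=float)
    if np.any(np.diff(r) <= 0.0):
        raise SchemaError(f"{path}: column r_m must be strictly ascending")
    return VelocityProfile(
        r=r,
        v=df["v_m_per_s"].to_numpy(dtype=float),
        time_stamp=_meta_float(meta, "time_stamp_min", 0.0),
        applied_rate=_meta_float(meta, "applied_rate_per_s"),
        metadata=extras,
    )


def write_lfc_csv(path, lfc: LocalFlowCurve) -> None:
    df = pd.DataFrame(
        {"gamma_dot_per_s": lfc.gamma_dot, "sigma_Pa": lfc.sigma, "r_m": lfc.r}
    )
    _write_csv(path, df, {"time_stamp_min": lfc.time_stamp})


def read_lfc_csv(path) -> LocalFlowCurve:
    df, meta = _read_csv(path)
    _require(df, ["gamma_dot_per_s", "sigma_Pa", "r_m"], path)
    return LocalFlowCurve(
        gamma_dot=df["gamma_dot_per_s"].to_numpy(dtype=float),
        sigma=df["sigma_Pa"].to_numpy(dtype=float),
        r=df["r_m"].to_numpy(dtype=float),
        time_stamp=_meta_float(meta, "time_stamp_min", 0.0),
    )


def write_series_csv(path, times, tau0_values, tau0_errors=None) -> None:
    data = {"t_min": np.asarray(times, float), "tau0_Pa": np.asarray(tau0_values, float)}
    if tau0_errors is not None:
        data["tau0_err_Pa"] = np.asarray(tau0_errors, float)
    _write_csv(path, pd.DataFrame(data))


def read_series_csv(path):
    df, _meta = _read_csv(path)
    _require(df, ["t_min", "tau0_Pa"], path)
    err = df["tau0_err_Pa"].to_numpy(float) if "tau0_err_Pa" in df.columns else None
    return df["t_min"].to_numpy(float), df["tau0_Pa"].to_numpy(float), err


def write_torque_csv(path, times, torques) -> None:
    _write_csv(path, pd.DataFrame(
        {"t_min": np.asarray(times, float), "torque_N_m": np.asarray(torques, float)}
    ))


def read_torque_csv(path):
    df, _meta = _read_csv(path)
    _require(df, ["t_min", "torque_N_m"], path)
    return df["t_min"].to_numpy(float), df["torque_N_m"].to_numpy(float)


def write_decay_csv(path, decay: PFGDecay) -> None:
    _write_csv(path, pd.DataFrame(
        {"g_T_per_m": decay.gradient_strengths, "E": decay.attenuation}
    ))


def read_decay_csv(path) -> PFGDecay:
    df, _meta = _read_csv(path)
    _require(df, ["g_T_per_m", "E"], path)
    return PFGDecay(
        gradient_strengths=df["g_T_per_m"].to_numpy(float),
        attenuation=df["E"].to_numpy(float),
    )


def write_dt2_csv(prefix, dataset) -> None:
    """Matrix CSV plus the two axis CSVs (``<prefix>.csv``, ``_g.csv``, ``_t.csv``)."""
    prefix = Path(prefix)
    _write_csv(prefix.with_suffix(".csv"), pd.DataFrame(dataset.signal))
    _write_csv(prefix.parent / (prefix.name + "_g.csv"),
               pd.DataFrame({"g_T_per_m": dataset.gradient_strengths}))
    _write_csv(prefix.parent / (prefix.name + "_t.csv"),
               pd.DataFrame({"t_s": dataset.echo_times}))


def read_dt2_csv(prefix, pgse=None):
    from .dt2 import DT2Dataset
    from .params import PGSEParams

    prefix = Path(prefix)
    S = pd.read_csv(prefix.with_suffix(".csv"),
                    float_precision="round_trip").to_numpy(dtype=float)
    gdf, _ = _read_csv(prefix.parent / (prefix.name + "_g.csv"))
    tdf, _ = _read_csv(prefix.parent / (prefix.name + "_t.csv"))
    _require(gdf, ["g_T_per_m"], prefix)
    _require(tdf, ["t_s"], prefix)
    g = gdf["g_T_per_m"].to_numpy(float)
    t = tdf["t_s"].to_numpy(float)
    if pgse is None:
        pgse = PGSEParams(gradient_strengths=tuple(g), gradient_duration=1e-3,
                          diffusion_time=0.2)
    return DT2Dataset(gradient_strengths=g, echo_times=t, signal=S, pgse=pgse)


def write_map_csv(prefix, dt2_map: DT2Map) -> None:
    prefix = Path(prefix)
    _write_csv(prefix.with_suffix(".csv"), pd.DataFrame(dt2_map.amplitude))
    _write_csv(prefix.parent / (prefix.name + "_D.csv"),
               pd.DataFrame({"D_m2_per_s": dt2_map.D_grid}))
    _write_csv(prefix.parent / (prefix.name + "_T2.csv"),
               pd.DataFrame({"T2_s": dt2_map.T2_grid}))


def _json_dump(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_hb_fits_json(path, fits: list[HBFit]) -> None:
    records = [
        {
            "time_stamp_min": f.time_stamp,
            "tau0_Pa": f.params.yield_stress,
            "K_Pa_sn": f.params.consistency,
            "n": f.params.flow_index,
            "stderr": f.stderr,
            "residual_norm_Pa": f.residual_norm,
            "shared_n": f.shared_n,
        }
        for f in fits
    ]
    _json_dump(path, records)


def write_skm_json(path, fit: SKMFit, time_unit: str = "min") -> None:
    _json_dump(path, {
        "tau00_Pa": fit.params.tau00,
        "tau0e_Pa": fit.params.tau0e,
        "ks_per_time_unit": fit.params.ks,
        "time_unit": time_unit,
        "breakdown_ratio": fit.breakdown_ratio,
        "uncertainties": fit.uncertainties,
        "residual_norm_Pa": fit.residual_norm,
        "flags": list(fit.flags),
    })


def write_distribution_json(path, dist: DropletSizeDistribution,
                            ratio_vs_baseline: float | None = None) -> None:
    _json_dump(path, {
        "D33_um": dist.D33,
        "alpha": dist.alpha,
        "d_oil_m2_per_s": dist.d_oil,
        "fit_residual": dist.fit_residual,
        "uncertainties": dist.uncertainties,
        "ratio_vs_baseline": ratio_vs_baseline,
        "flags": list(dist.flags),
    })


def write_peaks_json(path, dt2_map: DT2Map) -> None:
    _json_dump(path, {
        "regularization_weight": dt2_map.regularization_weight,
        "flags": list(dt2_map.flags),
        "peaks": [
            {
                "D_m2_per_s": p.D,
                "T2_s": p.T2,
                "mass": p.mass,
                "D_centroid_m2_per_s": p.D_centroid,
                "T2_centroid_s": p.T2_centroid,
                "T2_mass_weighted_mean_s": p.T2_mean,
            }
            for p in dt2_map.peaks
        ],
    })


def write_calibration_json(path, cal: T2Calibration) -> None:
    _json_dump(path, {
        "slope_s_per_conc": cal.slope,
        "intercept_s": cal.intercept,
        "r_squared": cal.r_squared,
    })
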