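"""Readers and writers for the package's CSV/JSON artifacts.

Barcode tables use a long CSV format (one row per emission line):
``cell_id, line_index, energy_meV`` with optional ``plet_id`` and
``scalar`` columns.  Spectra tables hold one row per grid point:
``origin_id, x, y, energy_meV, intensity`` (x/y blank in flow mode).
Numbers are serialized with 17 significant digits so that write-then-read
round-trips exactly.  Stochastic commands write a JSON provenance sidecar
(config, seed, package version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import BarcodePool
from .spectra import Spectrum
from .theory import (
    JointBarcodeDistribution,
    NoiseModel,
    SpectralDistribution,
    TaggingMixture,
)

__all__ = [
    "read_barcode_table",
    "write_barcode_table",
    "read_spectra_table",
    "write_spectra_table",
    "load_config",
    "parse_planning_config",
    "write_json",
    "write_provenance",
]

_FLOAT_FMT = "%.17g"


def write_barcode_table(pool: BarcodePool, path) -> None:
    """Write a pool as a long-format CSV (full float precision)."""
    rows = {"cell_id": [], "line_index": [], "energy_meV": []}
    has_plets = pool.plet_ids is not None
    if has_plets:
        rows["plet_id"] = []
    has_scalars = pool.scalars is not None
    if has_scalars:
        rows["scalar"] = []
    for i in range(len(pool)):
        e = pool.energies[i]
        rows["cell_id"].extend([pool.cell_ids[i]] * e.size)
        rows["line_index"].extend(range(e.size))
        rows["energy_meV"].extend(e)
        if has_plets:
            rows["plet_id"].extend(pool.plet_ids[i])
        if has_scalars:
            rows["scalar"].extend([pool.scalars[i]] * e.size)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_barcode_table(path) -> BarcodePool:
    """Read a long-format barcode CSV; energies are re-sorted per cell."""
    df = pd.read_csv(path, dtype={"cell_id": str},
                     float_precision="round_trip")
    required = {"cell_id", "energy_meV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    energies_num = pd.to_numeric(df["energy_meV"], errors="coerce")
    bad = df.index[energies_num.isna() & df["energy_meV"].notna()]
    bad = bad.union(df.index[df["energy_meV"].isna()])
    if len(bad):
        # +2: header line and 1-based numbering, as in the file on disk
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"non-numeric or missing energy at CSV row(s) {rows}")
    df = df.assign(energy_meV=energies_num)
    has_plets = "plet_id" in df.columns
    has_scalars = "scalar" in df.columns
    ids, energies, plets, scalars = [], [], [], []
    for cid, grp in df.groupby("cell_id", sort=True):
        order = np.argsort(grp["energy_meV"].to_numpy(), kind="stable")
        ids.append(cid)
        energies.append(grp["energy_meV"].to_numpy()[order])
        if has_plets:
            plets.append(grp["plet_id"].to_numpy()[order])
        if has_scalars:
            scalars.append(float(grp["scalar"].iloc[0]))
    return BarcodePool(ids, energies,
                       plet_ids=plets if has_plets else None,
                       scalars=scalars if has_scalars else None,
                       provenance={"source": str(path)})


def write_spectra_table(spectra, path) -> None:
    """Write spectra as one CSV row per grid point."""
    frames = []
    for spec in spectra:
        origin = spec.origin
        if isinstance(origin, tuple):
            oid, x, y = f"{origin[0]}_{origin[1]}", origin[0], origin[1]
        else:
            oid, x, y = str(origin), np.nan, np.nan
        frames.append(pd.DataFrame({
            "origin_id": oid, "x": x, "y": y,
            "energy_meV": spec.energy, "intensity": spec.intensity}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def read_spectra_table(path) -> list[Spectrum]:
    """Read a spectra CSV back into :class:`Spectrum` objects."""
    df = pd.read_csv(path, dtype={"origin_id": str},
                     float_precision="round_trip")
    required = {"origin_id", "energy_meV", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    out = []
    for oid, grp in df.groupby("origin_id", sort=True):
        if "x" in grp.columns and grp["x"].notna().all():
            origin = (int(grp["x"].iloc[0]), int(grp["y"].iloc[0]))
        else:
            origin = oid
        order = np.argsort(grp["energy_meV"].to_numpy(), kind="stable")
        out.append(Spectrum(grp["energy_meV"].to_numpy()[order],
                            grp["intensity"].to_numpy()[order], origin=origin))
    return out


# ---------------------------------------------------------------------------
# Planning configuration
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a JSON (or YAML) configuration file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def parse_planning_config(cfg: dict):
    """Validate and build (joint, noise, tagging, N, eps0, mc) from a config.

    Schema::

        {"distribution": {"kind": "uniform", "delta_meV": 300.0, ...},
         "noise": {"family": "gaussian", "sigma_phi_meV": 0.1} |
                  {"family": "generalized-gaussian", "alpha_meV": .., "beta": ..},
         "tagging": {"mode": "fixed", "m": 3} | {"mode": "poisson", "lambda": 6},
         "N": 10000, "eps0": 0.01,
         "mc": {"n_samples": 100000, "seed": 1}}
    """
    problems = []
    dist_cfg = cfg.get("distribution")
    noise_cfg = cfg.get("noise")
    tag_cfg = cfg.get("tagging")
    for key, val in (("distribution", dist_cfg), ("noise", noise_cfg),
                     ("tagging", tag_cfg)):
        if not isinstance(val, dict):
            problems.append(key)
    if "N" not in cfg:
        problems.append("N")
    if "eps0" not in cfg:
        problems.append("eps0")
    if problems:
        raise ValueError(f"config missing or malformed keys: {problems}")

    kind = dist_cfg.get("kind", "uniform")
    if kind == "uniform":
        base = SpectralDistribution.uniform(
            float(dist_cfg["delta_meV"]),
            center=float(dist_cfg.get("center_meV", 950.0)))
    elif kind == "gaussian":
        if "sigma_meV" in dist_cfg:
            base = SpectralDistribution.gaussian(
                sigma=float(dist_cfg["sigma_meV"]),
                center=float(dist_cfg.get("center_meV", 950.0)))
        else:
            base = SpectralDistribution.gaussian(
                delta_big=float(dist_cfg["delta_meV"]),
                center=float(dist_cfg.get("center_meV", 950.0)))
    elif kind in ("gaussian-mixture", "mixture"):
        base = SpectralDistribution.gaussian_mixture(
            [tuple(c) for c in dist_cfg["components"]])
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    joint = JointBarcodeDistribution(
        base=base, f_dm=float(dist_cfg.get("f_dm", 0.0)),
        fsr_lo=float(dist_cfg.get("fsr_lo_meV", 50.0)),
        fsr_hi=float(dist_cfg.get("fsr_hi_meV", 70.0)))

    family = noise_cfg.get("family", "gaussian")
    if family == "gaussian":
        noise = NoiseModel.gaussian(float(noise_cfg["sigma_phi_meV"]))
    elif family == "generalized-gaussian":
        noise = NoiseModel.generalized(float(noise_cfg["alpha_meV"]),
                                       float(noise_cfg["beta"]))
    else:
        raise ValueError(f"unknown noise family {family!r}")

    mode = tag_cfg.get("mode", "fixed")
    if mode == "fixed":
        tagging = TaggingMixture(mode="fixed", m=int(tag_cfg["m"]))
    else:
        tagging = TaggingMixture(mode="poisson",
                                 lam=float(tag_cfg["lambda"]))

    mc = cfg.get("mc", {})
    return (joint, noise, tagging, int(cfg["N"]), float(cfg["eps0"]),
            {"n_samples": int(mc.get("n_samples", 100_000)),
             "seed": mc.get("seed")})


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_provenance(path, config: dict, seed=None) -> None:
    """Write the JSON provenance sidecar for a generated artifact."""
    from . import __version__
    write_json({"config": config, "seed": seed, "version": __version__}, path)
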