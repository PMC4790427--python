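"""File formats: tidy curve CSVs, network YAML, results JSON.

There is no domain-standard container for dynamic 13C-MRS turnover curves,
so datasets travel as a tidy CSV (one row per time point per curve) with a
JSON sidecar holding the generating truth, acquisition spec and seed:

    time_min, metabolite, position, pattern, fe, sd

Patterns use the fixed vocabulary of the multiplet module (total, S, D43,
D45, D23, D21, D, T, Q, S+T).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, MCResult, ScanResult
from .network import FluxSet, Network, Pool, Product, Reaction
from .synth import AcquisitionSpec, LabelingCurve, SyntheticDataset

__all__ = [
    "write_curves",
    "read_curves",
    "save_network",
    "load_network",
    "fit_result_to_dict",
    "mc_result_to_dict",
    "scan_result_to_dict",
    "write_results",
]

log = logging.getLogger("cumoflux")

CURVE_COLUMNS = ["time_min", "metabolite", "position", "pattern", "fe", "sd"]


def write_curves(dataset: SyntheticDataset, path: "str | Path") -> None:
    """Write a dataset as tidy CSV + JSON sidecar (same stem, .json)."""
    path = Path(path)
    # %.17g round-trips float64 exactly
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "variant": dataset.variant,
        "truth": dataset.truth.as_dict(derived=False) if dataset.truth else None,
        "spec": asdict(dataset.spec),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_curves(path: "str | Path") -> SyntheticDataset:
    """Read a tidy curve CSV (and its sidecar, if present) back to a dataset."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve file {path} lacks required columns: {missing}")
    dup = df.duplicated(subset=["time_min", "metabolite", "position", "pattern"])
    if dup.any():
        raise ValueError(f"duplicate (time, metabolite, position, pattern) rows "
                         f"in {path} (first at index {int(np.argmax(dup.values))})")
    out_of_range = (df["fe"] < 0) | (df["fe"] > 1.05)
    if out_of_range.any():
        log.warning("%d fe values outside [0, 1.05] in %s", int(out_of_range.sum()), path)

    spec, truth, variant = AcquisitionSpec(), None, "bonded"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spec = AcquisitionSpec(**meta["spec"])
        variant = meta.get("variant", variant)
        if meta.get("truth"):
            truth = FluxSet(**meta["truth"])

    curves = []
    for (met, pos, pattern), g in df.groupby(
            ["metabolite", "position", "pattern"], sort=False):
        g = g.sort_values("time_min")
        curves.append(LabelingCurve(
            str(met), int(pos), str(pattern),
            g["time_min"].to_numpy(float), g["fe"].to_numpy(float),
            g["sd"].to_numpy(float)))
    return SyntheticDataset(tuple(curves), truth, spec, variant)


# ---------------------------------------------------------------------------
# network YAML
# ---------------------------------------------------------------------------

def _src_str(src) -> str:
    return "unlabeled" if src is None else f"{src[0]}.{src[1]}"


def _src_parse(s: str):
    if s == "unlabeled":
        return None
    pool, carbon = s.rsplit(".", 1)
    return (pool, int(carbon))


def network_to_dict(net: Network) -> dict:
    def pool_dict(p: Pool) -> dict:
        d = {"name": p.name, "compartment": p.compartment,
             "n_carbons": p.n_carbons, "concentration": p.concentration}
        if p.is_input:
            d["is_input"] = True
        if p.bond_breaks:
            d["bond_breaks"] = list(p.bond_breaks)
        if p.input_labeled_positions:
            d["input_labeled_positions"] = list(p.input_labeled_positions)
        return d

    return {
        "pools": [pool_dict(p) for p in net.pools.values()],
        "reactions": [
            {
                "name": r.name,
                "flux_label": r.flux_label,
                "substrates": list(r.substrates),
                **({"substrate_stoich": dict(r.substrate_stoich)}
                   if r.substrate_stoich else {}),
                "products": [
                    {"pool": p.pool,
                     "atom_maps": [{c: _src_str(s) for c, s in m.items()}
                                   for m in p.atom_maps]}
                    for p in r.products
                ],
            }
            for r in net.reactions
        ],
        "measured_pools": {k: list(v) for k, v in net.measured_pools.items()},
        "constants": dict(net.constants),
    }


def network_from_dict(d: dict) -> Network:
    pools = {}
    for pd_ in d["pools"]:
        pd_ = dict(pd_)
        for tup in ("bond_breaks", "input_labeled_positions"):
            if tup in pd_:
                pd_[tup] = tuple(pd_[tup])
        pools[pd_["name"]] = Pool(**pd_)
    reactions = []
    for rd in d["reactions"]:
        products = tuple(
            Product(p["pool"],
                    tuple({int(c): _src_parse(s) for c, s in m.items()}
                          for m in p["atom_maps"]))
            for p in rd["products"])
        reactions.append(Reaction(
            rd["name"], rd["flux_label"], tuple(rd["substrates"]), products,
            dict(rd.get("substrate_stoich", {}))))
    return Network(pools, tuple(reactions),
                   {k: tuple(v) for k, v in d["measured_pools"].items()},
                   dict(d.get("constants", {})))


def save_network(net: Network, path: "str | Path") -> None:
    Path(path).write_text(yaml.safe_dump(network_to_dict(net), sort_keys=False))


def load_network(path: "str | Path") -> Network:
    return network_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# results JSON
# ---------------------------------------------------------------------------

def fit_result_to_dict(r: FitResult) -> dict:
    return {
        "variant": r.variant,
        "estimates": r.estimates.as_dict(),
        "residual": r.residual,
        "n_curves": r.n_curves,
        "success": r.success,
        "message": r.message,
        "nfev": r.nfev,
        "init": r.init.as_dict(derived=False),
        "fixed": dict(r.fixed) if r.fixed else None,
    }


def mc_result_to_dict(r: MCResult) -> dict:
    return {
        "base": fit_result_to_dict(r.base),
        "n_mc": r.n_mc,
        "n_failed": r.n_failed,
        "mean": r.mean.to_dict(),
        "sd": r.sd.to_dict(),
        "gamma_params": ({k: list(v) for k, v in r.gamma_params.items()}
                         if r.gamma_params else None),
        "fwhm": dict(r.fwhm) if r.fwhm else None,
        "correlation": (r.correlation.to_dict() if r.correlation is not None
                        else None),
        "samples": r.samples.to_dict(orient="list"),
    }


def scan_result_to_dict(r: ScanResult) -> dict:
    return {
        "flux_name": r.flux_name,
        "grid": list(r.grid),
        "converged": list(r.converged),
        "fits": [fit_result_to_dict(f) for f in r.fits],
        "curves": [
            {f"{met}C{pos}:{pat}": np.asarray(v).tolist()
             for (met, pos, pat), v in point.items()}
            for point in r.curves
        ],
    }


def write_results(obj, path: "str | Path") -> None:
    """Serialize a Fit/MC/Scan result (or a plain dict) to JSON."""
    if isinstance(obj, FitResult):
        d = fit_result_to_dict(obj)
    elif isinstance(obj, MCResult):
        d = mc_result_to_dict(obj)
    elif isinstance(obj, ScanResult):
        d = scan_result_to_dict(obj)
    else:
        d = obj
    Path(path).write_text(json.dumps(d, indent=2))
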