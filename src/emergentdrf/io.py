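"""Readers/writers: quantal CSV tables, model configs, fit reports.

Dataset format: a CSV with one row per dose group, one column per named
stressor (non-negative doses, stressor-specific units), plus ``n``
(responders) and ``N`` (group size).

Model configs are YAML or JSON naming the family, the background mode
and the parameters with their conventional symbols (c, d_b, xi, eta,
d0, q0..qk, mu, sigma).  Mixture configs name their stressors and list
per-stressor and per-pair parameters; an optional ``fit`` section marks
free parameters (with optional bounds) for estimation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import DRFResults, FailedFit, ModelSpec, QuantalData, results_table
from .models import (
    BackgroundSpec,
    FrechetModel,
    FrechetParams,
    LognormalModel,
    LognormalParams,
    MultistageModel,
    MultistageParams,
)
from .mixtures import (
    CommonModeModel,
    CommonModeParams,
    DissimilarModeModel,
    DissimilarModeParams,
    StressorParams,
)

__all__ = [
    "read_quantal_csv",
    "write_quantal_csv",
    "model_to_config",
    "model_from_config",
    "load_model",
    "save_model",
    "spec_to_dict",
    "spec_from_dict",
    "load_model_spec",
    "write_report",
    "read_report",
    "model_from_report_entry",
]


# ---------------------------------------------------------------------------
# datasets


def read_quantal_csv(path, n_col: str = "n", N_col: str = "N") -> QuantalData:
    """Read and validate a quantal dose-response CSV.

    All columns other than ``n`` and ``N`` are dose columns; validation
    failures name the offending (1-based) data row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    for col in (n_col, N_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dose_cols = [c for c in df.columns if c not in (n_col, N_col)]
    if not dose_cols:
        raise ValueError(f"{path}: no dose columns found")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for idx, row in df.iterrows():
        rownum = idx + 1
        for c in dose_cols + [n_col, N_col]:
            if pd.isna(row[c]):
                raise ValueError(f"{path}: row {rownum}: missing value in column {c!r}")
        for c in dose_cols:
            if row[c] < 0:
                raise ValueError(f"{path}: row {rownum}: negative dose in column {c!r}")
        if row[N_col] < 1:
            raise ValueError(f"{path}: row {rownum}: group size N must be >= 1")
        if row[n_col] < 0 or row[n_col] > row[N_col]:
            raise ValueError(
                f"{path}: row {rownum}: n = {row[n_col]} outside [0, N = {row[N_col]}]"
            )
    return QuantalData(
        doses=df[dose_cols].to_numpy(dtype=float),
        n=df[n_col].to_numpy(dtype=float),
        N=df[N_col].to_numpy(dtype=float),
        stressor_names=tuple(dose_cols),
    )


def write_quantal_csv(data: QuantalData, path) -> None:
    data.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model configs


def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_structured(obj: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def model_to_config(model, stressor_names: Sequence[str] | None = None) -> dict:
    """Serialize a fixed model to a plain config dict."""
    if isinstance(model, FrechetModel):
        cfg = {
            "family": "frechet",
            "params": {"xi": model.params.xi, "eta": model.params.eta, "d0": model.params.d0},
        }
        bg = model.background
        if bg.mode == "DMB":
            cfg["background"] = {"mode": "DMB", "c": bg.c}
        elif bg.mode == "CMB":
            cfg["background"] = {"mode": "CMB", "d_b": bg.d_b}
        return cfg
    if isinstance(model, LognormalModel):
        cfg = {
            "family": "lognormal",
            "params": {"mu": model.params.mu, "sigma": model.params.sigma},
        }
        if model.background.mode != "none":
            cfg["background"] = {"mode": model.background.mode, "c": model.background.c}
        return cfg
    if isinstance(model, MultistageModel):
        return {
            "family": "multistage",
            "params": {f"q{i}": v for i, v in enumerate(model.params.q)},
        }
    if isinstance(model, CommonModeModel):
        p = model.params
        names = list(stressor_names or (f"stressor_{j + 1}" for j in range(p.n_stressors)))
        return {
            "family": "common_mode",
            "stressors": names,
            "kernel": p.kernel,
            "params": {
                "xi": {names[j]: p.xi[j] for j in range(p.n_stressors)},
                "eta": p.eta,
                "d0": p.d0,
                "d_b": p.d_b,
            },
            "interactions": [
                {"pair": [names[j], names[k]], "xi": v}
                for (j, k), v in sorted(p.interactions.items())
            ],
        }
    if isinstance(model, DissimilarModeModel):
        p = model.params
        names = list(stressor_names or (f"stressor_{j + 1}" for j in range(p.n_stressors)))
        return {
            "family": "dissimilar_mode",
            "stressors": names,
            "kernel": p.kernel,
            "params": {
                names[i]: {"xi": s.xi, "eta": s.eta, "d0": s.d0}
                for i, s in enumerate(p.per_stressor)
            },
            "interactions": [
                {
                    "pair": [names[j], names[k]],
                    "xi": p.interactions.get((j, k), 0.0),
                    "d0": p.interaction_thresholds.get((j, k), 0.0),
                }
                for (j, k) in sorted(
                    set(p.interactions) | set(p.interaction_thresholds)
                )
            ],
        }
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def _pair_indices(entry: Mapping, names: list[str], where: str) -> tuple[int, int]:
    pair = entry.get("pair")
    if not pair or len(pair) != 2:
        raise ValueError(f"{where}: each interaction needs a 'pair' of two stressor names")
    try:
        j, k = names.index(pair[0]), names.index(pair[1])
    except ValueError as exc:
        raise ValueError(f"{where}: interaction pair {pair} not among stressors {names}") from exc
    return tuple(sorted((j, k)))


def model_from_config(cfg: Mapping):
    """Build a fixed response model from a config dict."""
    family = cfg.get("family")
    params = dict(cfg.get("params") or {})
    bg_cfg = cfg.get("background") or {}
    if family == "frechet":
        bg = BackgroundSpec(
            bg_cfg.get("mode", "none"),
            c=float(bg_cfg.get("c", 0.0)),
            d_b=float(bg_cfg.get("d_b", 0.0)),
        )
        return FrechetModel(
            FrechetParams(params["xi"], params["eta"], params.get("d0", 0.0)), bg
        )
    if family == "lognormal":
        bg = BackgroundSpec(bg_cfg.get("mode", "none"), c=float(bg_cfg.get("c", 0.0)))
        return LognormalModel(LognormalParams(params["mu"], params["sigma"]), bg)
    if family == "multistage":
        ks = sorted(int(k[1:]) for k in params)
        q = tuple(params[f"q{i}"] for i in range(max(ks) + 1))
        return MultistageModel(MultistageParams(q))
    if family == "common_mode":
        names = list(cfg["stressors"])
        inter = {}
        for entry in cfg.get("interactions") or []:
            inter[_pair_indices(entry, names, "common_mode")] = float(entry.get("xi", 0.0))
        p = CommonModeParams(
            xi=tuple(float(params["xi"][nm]) for nm in names),
            eta=float(params["eta"]),
            d0=float(params.get("d0", 0.0)),
            d_b=float(params.get("d_b", 0.0)),
            interactions=inter,
            kernel=cfg.get("kernel", "geometric"),
        )
        model = CommonModeModel(p)
        model.stressor_names = tuple(names)
        return model
    if family == "dissimilar_mode":
        names = list(cfg["stressors"])
        inter, thr = {}, {}
        for entry in cfg.get("interactions") or []:
            key = _pair_indices(entry, names, "dissimilar_mode")
            inter[key] = float(entry.get("xi", 0.0))
            thr[key] = float(entry.get("d0", 0.0))
        p = DissimilarModeParams(
            per_stressor=tuple(
                StressorParams(
                    float(params[nm]["xi"]),
                    float(params[nm]["eta"]),
                    float(params[nm].get("d0", 0.0)),
                )
                for nm in names
            ),
            interactions=inter,
            interaction_thresholds=thr,
            kernel=cfg.get("kernel", "geometric"),
        )
        model = DissimilarModeModel(p)
        model.stressor_names = tuple(names)
        return model
    raise ValueError(f"unknown model family {family!r}")


def load_model(path):
    """Load a fixed model from a YAML/JSON config file."""
    return model_from_config(_load_structured(path))


def save_model(model, path, stressor_names: Sequence[str] | None = None) -> None:
    _dump_structured(model_to_config(model, stressor_names), path)


# ---------------------------------------------------------------------------
# fit specs


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "family": spec.family,
        "background": spec.background,
        "degree": spec.degree,
        "n_stressors": spec.n_stressors,
        "pairs": [list(p) for p in spec.pairs],
        "kernel": spec.kernel,
        "label": spec.label,
        "params": dict(spec.params),
        "free": {k: (list(v) if v is not None else None) for k, v in spec.free.items()},
    }


def spec_from_dict(d: Mapping) -> ModelSpec:
    return ModelSpec(
        family=d["family"],
        background=d.get("background", "none"),
        params=d.get("params") or {},
        free=d.get("free"),
        degree=d.get("degree", 2),
        n_stressors=d.get("n_stressors", 1),
        pairs=[tuple(p) for p in d.get("pairs") or []],
        kernel=d.get("kernel", "geometric"),
        label=d.get("label"),
    )


def _flatten_mixture_config(cfg: Mapping) -> dict:
    """Rewrite a named-stressor mixture config into canonical flat names."""
    family = cfg["family"]
    names = list(cfg["stressors"])
    params = dict(cfg.get("params") or {})
    flat: dict[str, float] = {}
    pairs: list[tuple[int, int]] = []
    if family == "common_mode":
        for j, nm in enumerate(names):
            if "xi" in params and nm in params["xi"]:
                flat[f"xi_{j + 1}"] = float(params["xi"][nm])
        for key in ("eta", "d0", "d_b"):
            if key in params:
                flat[key] = float(params[key])
    else:
        for i, nm in enumerate(names):
            rec = params.get(nm) or {}
            for key, canon in (("xi", f"xi_{i + 1}"), ("eta", f"eta_{i + 1}"), ("d0", f"d0_{i + 1}")):
                if key in rec:
                    flat[canon] = float(rec[key])
    for entry in cfg.get("interactions") or []:
        j, k = _pair_indices(entry, names, family)
        pairs.append((j, k))
        if "xi" in entry:
            flat[f"xi_{j + 1}_{k + 1}"] = float(entry["xi"])
        if family == "dissimilar_mode" and "d0" in entry:
            flat[f"d0_{j + 1}_{k + 1}"] = float(entry["d0"])
    return {"params": flat, "pairs": pairs, "n_stressors": len(names), "names": names}


def load_model_spec(path) -> ModelSpec:
    """Load a fit specification (family + params + ``fit`` section).

    The ``fit.free`` entry is a list of canonical parameter names, or a
    map name -> [lo, hi] bounds (null = default bounds).  Mixture
    configs use named stressors; free names use the canonical flat form
    (xi_1, eta, xi_1_2, ...) with stressors numbered in listed order.
    """
    cfg = _load_structured(path)
    family = cfg.get("family")
    fit_cfg = cfg.get("fit") or {}
    free = fit_cfg.get("free")
    if family in ("common_mode", "dissimilar_mode"):
        flat = _flatten_mixture_config(cfg)
        return ModelSpec(
            family=family,
            params=flat["params"],
            free=free,
            n_stressors=flat["n_stressors"],
            pairs=flat["pairs"],
            kernel=cfg.get("kernel", "geometric"),
            label=cfg.get("label"),
        )
    bg_cfg = cfg.get("background") or {}
    params = dict(cfg.get("params") or {})
    mode = bg_cfg.get("mode", "none")
    if mode == "DMB" and "c" in bg_cfg:
        params.setdefault("c", float(bg_cfg["c"]))
    if mode == "CMB" and "d_b" in bg_cfg:
        params.setdefault("d_b", float(bg_cfg["d_b"]))
    if mode == "CMB" and "c" in bg_cfg:
        params.setdefault("c", float(bg_cfg["c"]))
    degree = cfg.get("degree")
    if degree is None and family == "multistage":
        qs = [int(k[1:]) for k in params if k.startswith("q")]
        degree = max(qs) if qs else 2
    return ModelSpec(
        family=family,
        background=mode,
        params=params,
        free=free,
        degree=degree or 2,
        label=cfg.get("label"),
    )


# ---------------------------------------------------------------------------
# reports


def write_report(results: Sequence[DRFResults | FailedFit] | DRFResults, path) -> None:
    """Write fit results to JSON (machine-readable) or CSV (tabular).

    The JSON report embeds each spec so that the fitted model can be
    rebuilt and its deviance re-evaluated exactly.
    """
    if isinstance(results, (DRFResults, FailedFit)):
        results = [results]
    path = Path(path)
    if path.suffix.lower() == ".csv":
        results_table(results).to_csv(path, index=False)
        return
    entries = []
    for r in results:
        if isinstance(r, FailedFit):
            entries.append({"label": r.spec.label, "error": r.error, "spec": spec_to_dict(r.spec)})
        else:
            d = r.to_dict()
            d["spec"] = spec_to_dict(r.spec)
            entries.append(d)
    path.write_text(json.dumps({"results": entries}, indent=2) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def model_from_report_entry(entry: Mapping):
    """Rebuild the exact fitted model object from a JSON report entry."""
    spec = spec_from_dict(entry["spec"])
    return spec.build(entry["params"])
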