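"""Save/load fitted models: JSON metadata plus npz weight arrays."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ttegast.discrete import DiscreteNetSpec, DiscreteSurvivalModel
from ttegast.grid import TimeGrid
from ttegast.nn import MLP
from ttegast.preprocess import CovariateEncoder
from ttegast.schema import CovariateSpec
from ttegast.spline import SplineModel


def _schema_json(schema):
    return [{"name": s.name, "kind": s.kind, "unit": s.unit,
             "levels": list(s.levels), "role": s.role} for s in schema]


def _schema_from(meta):
    return [CovariateSpec(d["name"], d["kind"], d["unit"], tuple(d["levels"]), d["role"])
            for d in meta]


def _encoder_json(enc: CovariateEncoder):
    if enc is None:
        return None
    return {"schema": _schema_json(enc.schema), "columns": enc.columns,
            "loc": enc.loc, "scale": enc.scale, "feature_names": enc.feature_names}


def _encoder_from(meta):
    if meta is None:
        return None
    enc = CovariateEncoder(_schema_from(meta["schema"]))
    enc.columns = meta["columns"]
    enc.loc = meta["loc"]
    enc.scale = meta["scale"]
    enc.feature_names = meta["feature_names"]
    return enc


def save_model(model, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(model, DiscreteSurvivalModel):
        meta = {
            "type": "discrete",
            "spec": {"scheme": model.spec.scheme, "hidden_layers": list(model.spec.hidden_layers),
                     "dropout": model.spec.dropout, "batch_norm": model.spec.batch_norm,
                     "m_bins": model.spec.m_bins, "grid_rule": model.spec.grid_rule},
            "grid": model.grid.boundaries.tolist(),
            "encoder": _encoder_json(model.encoder),
        }
        arrays = {f"W{i}": w for i, w in enumerate(model.net.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(model.net.b)})
        if model.net.batch_norm:
            for i in range(model.net.n_hidden):
                arrays[f"gamma{i}"] = model.net.gamma[i]
                arrays[f"beta{i}"] = model.net.beta[i]
                arrays[f"rmean{i}"] = model.net.run_mean[i]
                arrays[f"rvar{i}"] = model.net.run_var[i]
        np.savez(path / "weights.npz", **arrays)
    elif isinstance(model, SplineModel):
        meta = {
            "type": "spline",
            "scale": model.scale,
            "knots": model.knots.tolist(),
            "gamma": model.gamma.tolist(),
            "beta": model.beta.tolist(),
            "feature_names": model.feature_names,
            "encoder": _encoder_json(model.encoder),
        }
    else:
        raise TypeError(f"cannot persist {type(model).__name__}")
    (path / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(path):
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    enc = _encoder_from(meta.get("encoder"))
    if meta["type"] == "spline":
        return SplineModel(scale=meta["scale"], knots=np.array(meta["knots"]),
                           gamma=np.array(meta["gamma"]), beta=np.array(meta["beta"]),
                           feature_names=meta["feature_names"], encoder=enc)
    spec = DiscreteNetSpec(**meta["spec"])
    grid = TimeGrid(np.array(meta["grid"]))
    data = np.load(path / "weights.npz")
    n_layers = sum(1 for k in data.files if k.startswith("W"))
    in_dim = data["W0"].shape[0]
    hidden = [data[f"W{i}"].shape[1] for i in range(n_layers - 1)]
    net = MLP(in_dim, hidden, data[f"W{n_layers - 1}"].shape[1],
              dropout=spec.dropout, batch_norm=spec.batch_norm)
    net.W = [data[f"W{i}"] for i in range(n_layers)]
    net.b = [data[f"b{i}"] for i in range(n_layers)]
    if spec.batch_norm:
        net.gamma = [data[f"gamma{i}"] for i in range(net.n_hidden)]
        net.beta = [data[f"beta{i}"] for i in range(net.n_hidden)]
        net.run_mean = [data[f"rmean{i}"] for i in range(net.n_hidden)]
        net.run_var = [data[f"rvar{i}"] for i in range(net.n_hidden)]
    return DiscreteSurvivalModel(spec, grid, net, enc)
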