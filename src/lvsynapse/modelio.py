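"""Coefficient-file serialization for trained Volterra models.

Models are stored as JSON: human-diffable, with sorted keys and shortest
round-trip float formatting, so save -> load -> save is byte-identical and
a fitted model is fully portable (the canonical term index is written out
explicitly rather than re-derived on load).
"""

from __future__ import annotations

import json

import numpy as np

from .laguerre import build_basis
from .volterra import MAX_ORDER, VolterraModel

__all__ = ["save_model", "load_model", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def _model_dict(model: VolterraModel, provenance: dict | None) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "order": model.order,
        "cross_terms": bool(model.cross_terms),
        "memory_window_s": model.memory_window,
        "dt_s": model.dt,
        "sets": [
            {"p": b.p, "p_units": b.p_units, "L": b.L}
            for b in model.bases
        ],
        "c0": float(model.c0),
        "coefficients": [float(c) for c in model.coefficients],
        "term_index": [[list(pair) for pair in term]
                       for term in model.term_index],
        "provenance": provenance or {},
    }


def save_model(model: VolterraModel, path,
               provenance: dict | None = None) -> None:
    """Serialize a model to a coefficient JSON file (deterministic)."""
    model.validate()
    with open(path, "w") as fh:
        json.dump(_model_dict(model, provenance), fh, sort_keys=True,
                  indent=1, separators=(",", ": "))
        fh.write("\n")


def load_model(path) -> VolterraModel:
    """Load a coefficient file; validates schema, order cap, and lengths."""
    with open(path) as fh:
        d = json.load(fh)
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unknown coefficient-file schema version {version}")
    order = int(d["order"])
    if not (1 <= order <= MAX_ORDER):
        raise ValueError(f"unsupported model order {order} in file")
    term_index = [tuple(tuple(pair) for pair in term)
                  for term in d["term_index"]]
    coefficients = np.asarray(d["coefficients"], dtype=float)
    if coefficients.size != len(term_index):
        raise ValueError(
            "coefficient-file schema error: coefficient array length "
            f"{coefficients.size} does not match term index length "
            f"{len(term_index)}")
    bases = [build_basis(s["p"], s["L"], d["dt_s"], d["memory_window_s"],
                         p_units=s["p_units"]) for s in d["sets"]]
    return VolterraModel(order=order, bases=bases,
                         cross_terms=bool(d["cross_terms"]),
                         term_index=term_index, c0=float(d["c0"]),
                         coefficients=coefficients)
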