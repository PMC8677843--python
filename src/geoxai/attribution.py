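"""Per-county break-down attributions assembled into contribution surfaces.

Running the break-down explainer for every unit of a county table yields an
attribution table: rows are units, columns are per-feature contributions to
that unit's prediction, plus the shared intercept and the prediction itself.
Mapping one column over space shows where a risk factor pushes predicted
mortality up or down — the spatially varying analogue of a regression
coefficient surface.

For cross-unit comparability the default uses one fixed feature ordering for
every county (the global permutation-importance ranking when available);
per-unit greedy orderings are retained as an option since they match how
single-county break-down plots are usually presented, but their columns are
not strictly comparable across units.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .explain import break_down, permutation_importance

__all__ = [
    "attribution_map",
    "lattice_polygons",
    "export_choropleth",
    "read_choropleth",
]


def _fixed_order_map(
    model, X: pd.DataFrame, ids, order: list[str], ref: pd.DataFrame,
    max_rows: int = 200_000,
) -> pd.DataFrame:
    """Vectorized fixed-order break-down over all units.

    E_k(unit) = mean over reference rows of the model with the first k
    ordered features clamped to the unit's values; deltas are successive
    differences.  Units are processed in chunks so the stacked design matrix
    stays modest.
    """
    n_ref = len(ref)
    n_units = len(X)
    chunk = max(1, max_rows // n_ref)
    intercept = float(np.asarray(model.predict(ref), dtype=float).mean())
    deltas = np.empty((n_units, len(order)))
    for start in range(0, n_units, chunk):
        stop = min(start + chunk, n_units)
        m = stop - start
        big = pd.concat([ref] * m, ignore_index=True)
        e_prev = np.full(m, intercept)
        for k, f in enumerate(order):
            vals = np.repeat(X[f].to_numpy()[start:stop], n_ref)
            big[f] = vals
            preds = np.asarray(model.predict(big), dtype=float).reshape(m, n_ref)
            e_new = preds.mean(axis=1)
            deltas[start:stop, k] = e_new - e_prev
            e_prev = e_new
    out = pd.DataFrame(deltas, columns=order, index=pd.Index(ids, name="unit_id"))
    out.insert(0, "intercept", intercept)
    # every ordered feature is clamped, so the final expectation collapses to
    # the model's own prediction for each unit — store that, making the
    # additivity invariant a real check rather than a bookkeeping identity
    out["prediction"] = np.asarray(model.predict(X), dtype=float)
    return out


def attribution_map(
    model,
    table: pd.DataFrame,
    features: list[str],
    ordering: str = "fixed",
    order: list[str] | None = None,
    y=None,
    n_ref: int | None = 400,
    seed: int = 0,
    ref: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Break-down attribution for every unit; returns units x features deltas.

    ``ordering='fixed'`` uses one order for all units: ``order`` if given,
    else the global permutation-importance ranking (requires ``y``), else the
    listed feature order.  ``ordering='greedy'`` re-derives the order per
    unit.  The reference data for the expectations is a seeded subsample of
    ``n_ref`` units (the full table if smaller).  Output columns:
    ``intercept``, one delta per feature, ``prediction``; each row satisfies
    intercept + sum(deltas) = prediction.
    """
    if ordering not in ("fixed", "greedy"):
        raise ValueError(f"unknown ordering {ordering!r}")
    X = table[features]
    if ordering == "fixed" and order is None:
        if y is not None:
            imp = permutation_importance(model, X, y, n_repeats=5, seed=seed)
            order = imp.ranking()
        else:
            order = list(features)

    if ref is None:
        ref = X
        if n_ref is not None and n_ref < len(X):
            rng = np.random.default_rng(seed)
            ref = X.iloc[rng.choice(len(X), size=n_ref, replace=False)]
    else:
        ref = ref[features]

    if ordering == "fixed":
        out = _fixed_order_map(model, X, table["unit_id"].astype(str), order, ref)
        out = out[["intercept"] + list(features) + ["prediction"]]
        out.attrs["ordering"] = "fixed"
        out.attrs["order"] = list(order)
        return out

    records = []
    for i in range(len(table)):
        uid = str(table["unit_id"].iloc[i])
        try:
            bd = break_down(
                model,
                ref,
                X.iloc[i],
                order=None,
                unit_id=uid,
            )
        except Exception as exc:  # re-raise with spatial context
            raise RuntimeError(f"break-down failed for unit {uid!r}") from exc
        rec = {"unit_id": uid, "intercept": bd.intercept}
        for f, _, delta in bd.contributions:
            rec[f] = delta
        rec["prediction"] = bd.prediction
        records.append(rec)
    out = pd.DataFrame.from_records(records).set_index("unit_id")
    cols = ["intercept"] + list(features) + ["prediction"]
    out = out[cols]
    out.attrs["ordering"] = ordering
    if ordering == "fixed":
        out.attrs["order"] = list(order)
    return out


def lattice_polygons(table: pd.DataFrame, cell_size: float | None = None) -> dict[str, list]:
    """Unit-square polygon (GeoJSON ring) per unit id from lattice indices."""
    cell = float(cell_size or table.attrs.get("cell_size", 1.0))
    polys = {}
    for uid, r, c in zip(table["unit_id"], table["row"], table["col"]):
        x0, y0 = c * cell, r * cell
        polys[str(uid)] = [
            [
                [x0, y0],
                [x0 + cell, y0],
                [x0 + cell, y0 + cell],
                [x0, y0 + cell],
                [x0, y0],
            ]
        ]
    return polys


def export_choropleth(
    attr: pd.DataFrame,
    geometry: dict[str, list],
    feature: str,
    path,
) -> None:
    """Write one attribution column as a GeoJSON FeatureCollection.

    ``geometry`` maps unit id -> GeoJSON polygon coordinates (e.g. from
    :func:`lattice_polygons`).  Property order is deterministic: unit_id,
    contribution, prediction.
    """
    if feature not in attr.columns:
        raise ValueError(f"no attribution column {feature!r}")
    missing = [u for u in attr.index if u not in geometry]
    if missing:
        raise ValueError(f"missing geometry for unit(s): {missing[:5]}")
    features = []
    for uid in attr.index:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": geometry[uid]},
                "properties": {
                    "unit_id": uid,
                    "contribution": float(attr.loc[uid, feature]),
                    "prediction": float(attr.loc[uid, "prediction"]),
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "feature_name": feature,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=None, separators=(",", ":"))


def read_choropleth(path) -> pd.DataFrame:
    """Read back a choropleth written by :func:`export_choropleth`."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = [
        {
            "unit_id": f["properties"]["unit_id"],
            "contribution": f["properties"]["contribution"],
            "prediction": f["properties"]["prediction"],
        }
        for f in doc["features"]
    ]
    return pd.DataFrame(rows).set_index("unit_id")
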