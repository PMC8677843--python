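"""End-to-end orchestration: simulate -> weights -> EDA -> split -> train ->
evaluate -> explain -> attribute, with a reproducibility manifest.

Each stage draws its randomness from a seed derived deterministically from
the root seed and a stage index, so individual stages can be re-run in
isolation and a saved manifest identifies a run completely (config hash,
derived seeds, per-artifact checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr_mod
from . import evaluation as eval_mod
from . import explain as explain_mod
from .config import RunConfig
from .eda import bivariate_local_moran, discretize_for_q, gi_star, q_statistic
from .learners import (
    default_grids,
    feature_columns,
    fit_stack,
    oof_predictions,
    small_grids,
    tune_learners,
)
from .split import stratified_split
from .spatial_regression import fit_gw_ols, fit_spatial_error, fit_spatial_lag
from .synthetic import (
    LatticeSpec,
    make_lattice,
    simulate_response,
    simulate_risk_factors,
    write_county_csv,
)
from .weights import contiguity_weights, distance_band_weights, write_gal

__all__ = ["run_pipeline", "stage_seed"]

log = logging.getLogger("geoxai")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

_STAGES = (
    "simulate",
    "response",
    "split",
    "train",
    "explain",
    "attribution",
    "lmi",
)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    k = _STAGES.index(stage)
    return int(np.random.SeedSequence([root_seed, k]).generate_state(1)[0] % 2**31)


def _info(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis on a synthetic county map; return manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index)
        artifacts.append(path)

    # --- simulate ----------------------------------------------------------
    _info("simulate", f"lattice {cfg.lattice.nrows}x{cfg.lattice.ncols}")
    table = make_lattice(
        LatticeSpec(cfg.lattice.nrows, cfg.lattice.ncols, cfg.lattice.cell_size)
    )
    table = simulate_risk_factors(
        table,
        spatial_range=cfg.simulate.spatial_range,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    table = simulate_response(table, seed=stage_seed(cfg.seed, "response"))
    eff = table.attrs["effect_spec"]

    # --- weights -----------------------------------------------------------
    if cfg.weights.band is not None:
        w_star = distance_band_weights(table, cfg.weights.band, include_self=True)
        w_plain = distance_band_weights(table, cfg.weights.band, include_self=False)
    else:
        w_star = contiguity_weights(table, cfg.weights.rule, include_self=True)
        w_plain = contiguity_weights(table, cfg.weights.rule, include_self=False)
    write_gal(w_plain, out / "weights.gal")
    artifacts.append(out / "weights.gal")
    _info("weights", f"{w_plain.n} units, rule={cfg.weights.rule}, band={cfg.weights.band}")

    # --- exploratory spatial statistics ------------------------------------
    hotspots = gi_star(table["response"], w_star)
    table["gi_z"] = hotspots.gi_z
    table["gi_bin"] = hotspots.gi_bin
    _info("eda", f"hotspot units (|bin|=3): {int((np.abs(hotspots.gi_bin) == 3).sum())}")

    factors = feature_columns(table)
    qrows = []
    for f in factors:
        if f in table.attrs.get("categorical_features", []):
            labels = table[f].to_numpy()
        else:
            labels = discretize_for_q(table[f].to_numpy(), k_strata=5)
        qres = q_statistic(table["response"].to_numpy(), labels)
        qrows.append({"factor": f, "q": qres.q, "p_value": qres.p_value,
                      "strata": qres.strata_count})
    qtable = pd.DataFrame(qrows).sort_values("q", ascending=False)
    save_csv(qtable, "q_table.csv")

    lmi = bivariate_local_moran(
        table["response"],
        table[cfg.explain.lmi_factor],
        w_plain.row_standardized(),
        n_perm=cfg.explain.lmi_permutations,
        seed=stage_seed(cfg.seed, "lmi"),
    )
    table["lmi_cluster"] = lmi.cluster

    # --- split -------------------------------------------------------------
    assignment = stratified_split(
        table, "gi_bin", tuple(cfg.split.fractions), seed=stage_seed(cfg.seed, "split")
    )
    table["partition"] = assignment.partition
    write_county_csv(table, out / "counties.csv")
    artifacts.append(out / "counties.csv")
    _info("split", str(table["partition"].value_counts().to_dict()))

    # --- train -------------------------------------------------------------
    seed_train = stage_seed(cfg.seed, "train")
    X = table[factors]
    y = table["response"].to_numpy()
    parts = {p: table["partition"].to_numpy() == p for p in ("train", "valid", "test")}
    Xtr, ytr = X[parts["train"]], y[parts["train"]]

    specs = default_grids() if cfg.train.grids == "default" else small_grids(
        include_mlp=cfg.train.include_mlp
    )
    learners = tune_learners(specs, Xtr, ytr, folds=cfg.train.folds, seed=seed_train)
    meta = oof_predictions(learners, Xtr, ytr, folds=cfg.train.folds, seed=seed_train)
    stack = fit_stack(learners, meta, ytr, mode=cfg.train.mode, feature_names=factors)
    _info("train", f"{len(learners)} candidates; stack mode={cfg.train.mode}")

    cards = [t.card() for t in learners]
    (out / "model_cards.json").write_text(json.dumps(cards, indent=2))
    artifacts.append(out / "model_cards.json")

    # --- evaluate ----------------------------------------------------------
    from .learners import best_of_family

    rows = []
    models: list[tuple[str, str, object]] = [
        (t.label, "base-learner", t) for t in best_of_family(learners)
    ]
    models.append((f"stack[{cfg.train.mode}]", "stack-ensemble", stack))

    # spatial regression comparisons on the training units
    coords_tr = table.loc[parts["train"], ["x", "y"]].to_numpy()
    Xtr_mat = Xtr.to_numpy(dtype=float)
    band = 1.5 * cfg.lattice.cell_size
    w_train = distance_band_weights(table[parts["train"]], band).row_standardized()
    lag_fit = fit_spatial_lag(ytr, Xtr_mat, w_train, feature_names=factors)
    err_fit = fit_spatial_error(ytr, Xtr_mat, w_train, feature_names=factors)
    extent = np.linalg.norm(coords_tr.max(axis=0) - coords_tr.min(axis=0))
    # widen the kernel until every location has enough effective sample for
    # the local fit (small maps with many covariates need a broader kernel)
    bw = extent / 6.0
    while True:
        try:
            gw_fit = fit_gw_ols(ytr, Xtr_mat, coords_tr, bandwidth=bw,
                                feature_names=factors)
            break
        except ValueError:
            bw *= 1.5
            if bw > 10 * extent:
                raise
    _info("evaluate", f"gw-ols bandwidth {bw:.3g}")

    for part, mask in parts.items():
        Xp, yp = X[mask], y[mask]
        for label, kind, model in models:
            rep = eval_mod.evaluate(yp, model.predict(Xp))
            rows.append({"model": label, "type": kind, "partition": part,
                         **rep.to_dict()})
        for label, fit in (("spatial-lag", lag_fit), ("spatial-error", err_fit)):
            rep = eval_mod.evaluate(yp, fit.trend(Xp.to_numpy(dtype=float)))
            rows.append({"model": label, "type": "spatial-regression",
                         "partition": part, **rep.to_dict()})
        coords_p = table.loc[mask, ["x", "y"]].to_numpy()
        rep = eval_mod.evaluate(yp, gw_fit.predict(Xp.to_numpy(dtype=float), coords_p))
        rows.append({"model": "gw-ols", "type": "spatial-regression",
                     "partition": part, **rep.to_dict()})
    eval_table = pd.DataFrame(rows)
    save_csv(eval_table, "eval_report.csv")
    test_rmse = eval_table.query(
        "partition == 'test' and type == 'stack-ensemble'"
    )["rmse"].iloc[0]
    _info("evaluate", f"stack test RMSE {test_rmse:.3f}")

    # --- explain -----------------------------------------------------------
    seed_explain = stage_seed(cfg.seed, "explain")
    Xte, yte = X[parts["test"]], y[parts["test"]]
    imp = explain_mod.permutation_importance(
        stack, Xte, yte, n_repeats=cfg.explain.n_repeats, seed=seed_explain
    )
    imp_table = imp.table.reset_index()
    imp_table.insert(1, "baseline_loss", imp.baseline_loss)
    save_csv(imp_table, "importance.csv")
    top = imp.ranking()[: cfg.explain.top_features]
    _info("explain", f"top features: {top}")

    prof_rows = []
    for f in top:
        if f in table.attrs.get("categorical_features", []):
            continue  # profiles for continuous factors only
        for maker, kw in (
            (explain_mod.pd_profile, {"grid_size": cfg.explain.profile_points}),
            (explain_mod.ld_profile, {"grid_size": cfg.explain.profile_points}),
            (explain_mod.al_profile, {"n_intervals": cfg.explain.al_intervals}),
        ):
            prof = maker(stack, Xte, f, **kw)
            prof_rows.append(prof.to_frame())
    save_csv(pd.concat(prof_rows, ignore_index=True), "profiles.csv")

    lo_unit = table.loc[table["response"].idxmin()]
    hi_unit = table.loc[table["response"].idxmax()]
    bd_docs = {}
    for unit in (lo_unit, hi_unit):
        bd = explain_mod.break_down(
            stack, X, unit[factors], unit_id=str(unit["unit_id"]),
            n_ref=cfg.explain.n_ref, seed=seed_explain,
        )
        bd_docs[bd.unit_id] = {
            "intercept": bd.intercept,
            "prediction": bd.prediction,
            "contributions": [
                {"feature": f, "value": float(v), "delta": float(d)}
                for f, v, d in bd.contributions
            ],
        }
    (out / "breakdown.json").write_text(json.dumps(bd_docs, indent=2))
    artifacts.append(out / "breakdown.json")

    # --- spatial attribution ------------------------------------------------
    seed_attr = stage_seed(cfg.seed, "attribution")
    top_cont = [f for f in imp.ranking() if f not in
                table.attrs.get("categorical_features", [])][: cfg.explain.top_features]
    attr_table = attr_mod.attribution_map(
        stack, table, factors, ordering="fixed", order=imp.ranking(),
        n_ref=cfg.explain.n_ref, seed=seed_attr,
    )
    save_csv(attr_table[["intercept"] + top_cont + ["prediction"]],
             "attributions.csv", index=True)
    geometry = attr_mod.lattice_polygons(table)
    attr_mod.export_choropleth(attr_table, geometry, top_cont[0], out / "map.geojson")
    artifacts.append(out / "map.geojson")
    _info("attribution", f"mapped contribution of {top_cont[0]!r}")

    # --- manifest ----------------------------------------------------------
    cfg_json = json.dumps(cfg.model_dump(), sort_keys=True)
    manifest = {
        "config": cfg.model_dump(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
        "n_units": int(len(table)),
        "stack_test_rmse": float(test_rmse),
        "noise_sd": float(eff.noise_sd),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _info("manifest", f"wrote {out / 'manifest.json'}")
    return manifest
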