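"""End-to-end pipeline stages: simulate, fit, analyze.

``run_simulate`` writes a phantom cohort (node table, ground-truth
parameters, voxel/ROI forward signals) to disk; ``run_fit`` re-estimates
the nine parameters from those signals with the model fitters;
``run_analyze`` produces the four table-shaped reports (volumes, paired
pre/post contrasts, RG-vs-NRG contrasts, ROC diagnostics) plus a machine-
readable statistics JSON.

Two percent-change conventions coexist in the reports and are never
swapped silently: node volumes are reported as a reduction ratio (positive
= shrinkage), while parameter changes use the signed (post-pre)/pre form.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dce, diffusion, phantom, stats
from .config import PipelineConfig
from .errors import DataError
from .nodes import classify_recist, pct_change, reduction_ratio
from .scales import PARAM_NAMES, from_report, to_report

__all__ = ["run_simulate", "run_fit", "run_analyze"]

_GROUND_TRUTH_COLUMNS = ["node_id", "timepoint", *PARAM_NAMES]


def _phantom_spec(cfg: PipelineConfig) -> phantom.PhantomSpec:
    return phantom.PhantomSpec(seed=cfg.seed, **cfg.phantom)


def _write_manifest(out: Path, cfg: PipelineConfig, stage: str) -> None:
    import scipy

    manifest = {
        "stage": stage,
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "versions": {
            "nodemri": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_simulate(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Generate and persist a phantom cohort.

    Writes ``cohort.csv`` (one row per node x timepoint, reporting scales),
    ``ground_truth.csv`` (the parameter subset used by recovery tests),
    long-format forward signals for the three diffusion schemes and the DCE
    curves, a manifest, and (optionally) NIfTI parameter maps for selected
    nodes.
    """
    cfg.validate()
    out = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = _phantom_spec(cfg)
    nodes = phantom.generate_cohort(spec)
    cohort = phantom.cohort_to_frame(nodes)
    paths = {"cohort": out / "cohort.csv", "ground_truth": out / "ground_truth.csv"}
    cohort.to_csv(paths["cohort"], index=False)
    cohort[_GROUND_TRUTH_COLUMNS].to_csv(paths["ground_truth"], index=False)

    s0 = 1000.0
    sigma = spec.noise_sd * s0
    schemes = {
        "mono": diffusion.BValueScheme(cfg.dwi_bvalues),
        "dki": diffusion.BValueScheme(cfg.dki_bvalues),
        "ivim": diffusion.BValueScheme(cfg.ivim_bvalues),
    }
    diff_rows, dce_rows = [], []
    times = dce.default_times()
    for i, node in enumerate(nodes):
        for j, (tp, params) in enumerate(
            (("pre", node.params_pre), ("post", node.params_post))
        ):
            for model, scheme in schemes.items():
                rng = np.random.default_rng([cfg.seed, 11, i, j, len(model)])
                meas = phantom.simulate_diffusion_signal(
                    params, scheme, model=model, s0=s0, noise_sd=sigma, rng=rng
                )
                for b, sig in zip(meas.b_values, meas.signal):
                    diff_rows.append(
                        {
                            "node_id": node.node_id,
                            "timepoint": tp,
                            "model": model,
                            "b_value": b,
                            "signal": sig,
                        }
                    )
            clean_peak = dce.tofts_concentration(
                params.ktrans, params.kep, times, cfg.aif
            ).max()
            rng = np.random.default_rng([cfg.seed, 13, i, j])
            series = phantom.simulate_dce_series(
                params.ktrans,
                params.kep,
                times,
                aif=cfg.aif,
                noise_sd=spec.noise_sd * clean_peak,
                rng=rng,
            )
            for t, c in zip(series.times, series.concentration):
                dce_rows.append(
                    {
                        "node_id": node.node_id,
                        "timepoint": tp,
                        "time_min": t,
                        "concentration": c,
                    }
                )
    paths["signals_diffusion"] = out / "signals_diffusion.csv"
    paths["signals_dce"] = out / "signals_dce.csv"
    pd.DataFrame(diff_rows).to_csv(paths["signals_diffusion"], index=False)
    pd.DataFrame(dce_rows).to_csv(paths["signals_dce"], index=False)

    if cfg.write_maps:
        import nibabel as nib

        wanted = set(cfg.map_node_ids) or {nodes[0].node_id}
        map_dir = out / "maps"
        map_dir.mkdir(exist_ok=True)
        for i, node in enumerate(nodes):
            if node.node_id not in wanted:
                continue
            for tp in ("pre", "post"):
                maps, mask = phantom.render_parameter_maps(
                    node, timepoint=tp, rng=np.random.default_rng([cfg.seed, 17, i])
                )
                affine = np.eye(4)
                for name, vol in maps.items():
                    nib.save(
                        nib.Nifti1Image(vol.astype(np.float32), affine),
                        map_dir / f"{node.node_id}_{tp}_{name}.nii",
                    )
                nib.save(
                    nib.Nifti1Image(mask.astype(np.uint8), affine),
                    map_dir / f"{node.node_id}_{tp}_mask.nii",
                )

    _write_manifest(out, cfg, "simulate")
    return paths


def run_fit(cfg: PipelineConfig, in_dir: str | Path, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Re-estimate the nine parameters from simulated (or imported) signals.

    Expects ``signals_diffusion.csv`` and ``signals_dce.csv`` in ``in_dir``;
    writes ``fitted.csv`` with the same schema as ``ground_truth.csv``.
    """
    cfg.validate()
    in_dir = Path(in_dir)
    out = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diff_path = in_dir / "signals_diffusion.csv"
    dce_path = in_dir / "signals_dce.csv"
    for p in (diff_path, dce_path):
        if not p.exists():
            raise DataError(f"missing input file: {p}")
    diff = pd.read_csv(diff_path)
    dyn = pd.read_csv(dce_path)
    if diff.empty or dyn.empty:
        raise DataError("signal tables are empty")

    records: dict[tuple[str, str], dict] = {}
    for (node_id, tp, model), grp in diff.groupby(["node_id", "timepoint", "model"]):
        grp = grp.sort_values("b_value")
        meas = diffusion.DiffusionMeasurement(
            diffusion.BValueScheme(tuple(grp["b_value"])), tuple(grp["signal"])
        )
        rec = records.setdefault((node_id, tp), {})
        if model == "mono":
            rec["adc"] = diffusion.adc_fit(meas).adc
        elif model == "dki":
            fit = diffusion.dki_fit(meas)
            rec["md"], rec["mk"] = fit.md, fit.mk
        elif model == "ivim":
            fit = diffusion.ivim_fit(meas, refine=cfg.ivim_refine)
            rec["d_slow"], rec["d_fast"], rec["pf"] = fit.d_slow, fit.d_fast, fit.pf
        else:
            raise DataError(f"unknown model tag {model!r} in {diff_path}")
    for (node_id, tp), grp in dyn.groupby(["node_id", "timepoint"]):
        grp = grp.sort_values("time_min")
        series = dce.DCESeries(
            tuple(grp["time_min"]),
            tuple(grp["concentration"]),
            n_baseline=int((grp["time_min"] < 0).sum()),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = dce.tofts_fit(series, aif=cfg.aif)
        rec = records.setdefault((node_id, tp), {})
        rec["ktrans"], rec["kep"], rec["ve"] = fit.ktrans, fit.kep, fit.ve

    rows = []
    for (node_id, tp), rec in sorted(records.items()):
        row = {"node_id": node_id, "timepoint": tp}
        for name in PARAM_NAMES:
            row[name] = to_report(rec[name], name) if name in rec else np.nan
        rows.append(row)
    fitted = pd.DataFrame(rows, columns=_GROUND_TRUTH_COLUMNS)
    fitted.to_csv(out / "fitted.csv", index=False)
    _write_manifest(out, cfg, "fit")
    return fitted


def _wide_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy node x timepoint table to one row per node."""
    meta_cols = [c for c in ("patient_id", "group", "category") if c in cohort]
    meta = cohort.drop_duplicates("node_id").set_index("node_id")[meta_cols]
    value_cols = [c for c in cohort.columns if c in PARAM_NAMES or c in ("diameter_mm", "volume_cm3")]
    wide = cohort.pivot(index="node_id", columns="timepoint", values=value_cols)
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return meta.join(wide)


def run_analyze(
    cfg: PipelineConfig,
    cohort: pd.DataFrame | str | Path,
    params: pd.DataFrame | str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Statistical report bundle from a tidy cohort table.

    ``cohort`` must hold one row per node x timepoint with the parameter
    columns on reporting scales plus diameters/volumes; ``params`` may
    override the parameter columns (e.g. with fitted values).  Labels are
    taken from the ``group`` column or derived from diameters via the
    RECIST rules when absent.  Writes four CSV reports and ``stats.json``.
    """
    cfg.validate()
    out = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    if params is not None:
        if not isinstance(params, pd.DataFrame):
            params = pd.read_csv(params)
        keep = [c for c in cohort.columns if c not in PARAM_NAMES]
        cohort = cohort[keep].merge(params, on=["node_id", "timepoint"], how="left")
    for col in ("node_id", "timepoint"):
        if col not in cohort:
            raise DataError(f"cohort table lacks required column {col!r}")

    wide = _wide_cohort(cohort)
    if "group" not in wide or wide["group"].isna().any():
        if "diameter_mm_pre" not in wide:
            raise DataError("cohort table needs either labels or diameters")
        labels = [
            classify_recist(r.diameter_mm_pre, r.diameter_mm_post, strict=cfg.strict_recist)
            for r in wide.itertuples()
        ]
        wide["group"] = [l.group for l in labels]
        wide["category"] = [l.category for l in labels]

    wide["volume_reduction_pct"] = [
        reduction_ratio(p, q)
        for p, q in zip(wide["volume_cm3_pre"], wide["volume_cm3_post"])
    ]
    rg = wide[wide["group"] == "RG"]
    nrg = wide[wide["group"] == "NRG"]
    report: dict = {"n_rg": int(len(rg)), "n_nrg": int(len(nrg))}

    def summarize(test: stats.ComparisonResult, a: np.ndarray, b: np.ndarray) -> dict:
        return {
            "mean_1": float(np.mean(a)),
            "sd_1": float(np.std(a, ddof=1)),
            "mean_2": float(np.mean(b)),
            "sd_2": float(np.std(b, ddof=1)),
            "statistic": test.statistic,
            "p_value": test.p_value,
            "test": test.test_name,
        }

    two_groups = len(rg) >= 3 and len(nrg) >= 3

    # -- volume table (reduction-ratio sign convention: positive = shrinkage)
    vol_rows = []
    if two_groups:
        for label, col in (
            ("volume_pre_cm3", "volume_cm3_pre"),
            ("volume_post_cm3", "volume_cm3_post"),
            ("volume_reduction_pct", "volume_reduction_pct"),
        ):
            res = stats.two_group_compare(rg[col], nrg[col])
            vol_rows.append({"quantity": label, **summarize(res, rg[col], nrg[col])})
    report["volume"] = vol_rows

    # -- paired pre/post contrasts over the whole cohort
    paired_rows = []
    for name in PARAM_NAMES:
        pre = wide[f"{name}_pre"].to_numpy()
        post = wide[f"{name}_post"].to_numpy()
        if np.isnan(pre).any() or np.isnan(post).any():
            continue
        res = stats.paired_compare(pre, post)
        paired_rows.append({"parameter": name, **summarize(res, pre, post)})
    report["paired"] = paired_rows

    # -- RG vs NRG contrasts: pre, post and signed percent change
    group_rows = []
    if two_groups:
        for name in PARAM_NAMES:
            for tp in ("pre", "post"):
                col = f"{name}_{tp}"
                if wide[col].isna().any():
                    continue
                res = stats.two_group_compare(rg[col], nrg[col])
                group_rows.append(
                    {"parameter": f"{name}_{tp}", **summarize(res, rg[col], nrg[col])}
                )
            if wide[f"{name}_pre"].isna().any() or wide[f"{name}_post"].isna().any():
                continue
            delta = pd.Series(
                [
                    pct_change(p, q)
                    for p, q in zip(wide[f"{name}_pre"], wide[f"{name}_post"])
                ],
                index=wide.index,
            )
            res = stats.two_group_compare(delta[rg.index], delta[nrg.index])
            group_rows.append(
                {
                    "parameter": f"delta_{name}_pct",
                    **summarize(res, delta[rg.index], delta[nrg.index]),
                }
            )
    report["groups"] = group_rows

    # -- ROC diagnostics for PF-pre, Ktrans-pre and the fitted PRE score
    diag_rows = []
    if two_groups:
        labels = wide["group"].tolist()
        pf_pre = wide["pf_pre"].to_numpy()
        kt_pre = wide["ktrans_pre"].to_numpy()
        predictors = {"pf_pre": pf_pre, "ktrans_pre": kt_pre}
        try:
            pre_model = stats.fit_pre_model(pf_pre, kt_pre, labels)
        except DataError as exc:
            warnings.warn(f"PRE model skipped: {exc}", stacklevel=2)
        else:
            predictors["pre_score"] = stats.pre_score(pf_pre, kt_pre, pre_model)
            report["pre_model"] = {
                "intercept": pre_model.intercept,
                "coef_pf": pre_model.coef_pf,
                "coef_ktrans": pre_model.coef_ktrans,
                "converged": pre_model.converged,
            }
        for name, scores in predictors.items():
            perf = stats.roc_analysis(scores, labels)
            diag_rows.append(
                {
                    "predictor": name,
                    "auc": perf.auc,
                    "auc_ci_low": perf.auc_ci_95[0],
                    "auc_ci_high": perf.auc_ci_95[1],
                    "youden": perf.youden,
                    "cutoff": perf.cutoff,
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                    "lr_pos": perf.lr_pos,
                    "lr_neg": perf.lr_neg,
                    "ppv": perf.ppv,
                    "npv": perf.npv,
                }
            )
    else:
        warnings.warn("single-class cohort: ROC stage skipped", stacklevel=2)
    report["diagnostics"] = diag_rows

    # -- intraclass correlation is only meaningful with two observers; the
    # phantom has one, so an ICC block appears only when *_obs2 columns exist
    icc_rows = []
    pre_rows = cohort[cohort["timepoint"] == "pre"]
    for name in PARAM_NAMES:
        col2 = f"{name}_obs2"
        if col2 in pre_rows.columns:
            icc_rows.append(
                {
                    "parameter": name,
                    "icc": stats.icc_two_observers(pre_rows[name], pre_rows[col2]),
                }
            )
    if icc_rows:
        report["icc"] = icc_rows

    pd.DataFrame(vol_rows).to_csv(out / "report_volume.csv", index=False)
    pd.DataFrame(paired_rows).to_csv(out / "report_paired.csv", index=False)
    pd.DataFrame(group_rows).to_csv(out / "report_groups.csv", index=False)
    pd.DataFrame(diag_rows).to_csv(out / "report_diagnostics.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    _write_manifest(out, cfg, "analyze")
    return report
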