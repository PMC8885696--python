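"""End-to-end orchestration: simulate -> fit -> classify -> explain.

Every artifact written by :func:`run_pipeline` is a pure function of the
configuration and its seed; rerunning with the same config reproduces the
outputs byte for byte.  A plain-text run log records the seed, the stage
order and the provenance of every file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    SELECTED_BAND,
    WHOLE_BAND,
    ClassifierSpec,
    band_comparison_experiment,
)
from .colecole import ColeColeModel
from .config import RunConfig
from .dataset import LabeledDataset
from .importance import (
    aggregate_attributions,
    pca_frequency_importance,
    select_band,
    shapley_attribution,
)
from .simulate import TABLE_ANCHORS, simulate_dataset
from .spectra import (
    FrequencyGrid,
    PermittivitySpectrum,
    write_spectra_csv,
)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _condition_of(meta) -> str | None:
    """Map specimen metadata onto one of the nine anchored condition labels."""
    if meta.phase == "control":
        return "Control"
    if meta.phase == "ischemia":
        label = f"I-{int(meta.ischemia_h)}h"
        return label if label in TABLE_ANCHORS else None
    label = f"I-{int(meta.ischemia_h)}h-R-{int(meta.reperfusion_h)}h"
    return label if label in TABLE_ANCHORS else None


def fit_conditions(data: LabeledDataset, seed: int) -> pd.DataFrame:
    """Fit the double Cole-Cole model to the mean spectrum of each anchored
    condition present in the dataset; returns a fit-report table (tau in ps)."""
    by_cond: dict[str, list[PermittivitySpectrum]] = {}
    for s in data.spectra:
        cond = _condition_of(s.meta)
        if cond is not None:
            by_cond.setdefault(cond, []).append(s)
    rows = []
    for cond in TABLE_ANCHORS:
        if cond not in by_cond:
            continue
        group = by_cond[cond]
        grid = group[0].grid
        mean_spec = PermittivitySpectrum(
            grid,
            np.mean([s.eps_real for s in group], axis=0),
            np.mean([s.eps_imag for s in group], axis=0),
        )
        res = ColeColeModel(mean_spec).fit(seed=seed)
        p = res.params
        rows.append(
            {
                "condition": cond,
                "n_spectra": len(group),
                "eps_inf": p.eps_inf,
                "delta_eps1": p.delta_eps1,
                "delta_eps2": p.delta_eps2,
                "tau1_ps": p.tau1 * 1e12,
                "tau2_ps": p.tau2 * 1e12,
                "alpha1": p.alpha1,
                "alpha2": p.alpha2,
                "r_squared": res.rsquared,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def _explain(data: LabeledDataset, cfg: RunConfig):
    """Train a linear reference classifier on relative-change features and
    attribute its non-viable probability over frequencies."""
    from sklearn.linear_model import LogisticRegression

    X, y = data.to_arrays()
    freqs = data.spectra[0].grid.points
    eps = X[:, :, 0]
    if cfg.explain.use_relative_change:
        ctrl = [i for i, s in enumerate(data.spectra) if s.meta.phase == "control"]
        ref = eps[ctrl].mean(axis=0) if ctrl else eps.mean(axis=0)
        F = 100.0 * (eps - ref) / ref
    else:
        F = eps
    model = LogisticRegression(max_iter=2000)
    model.fit(F, y)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 303)))
    # class-balanced background and explained records
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    nb = cfg.explain.n_background
    bg_idx = np.concatenate(
        [
            rng.choice(idx0, size=min(nb // 2, len(idx0)), replace=False),
            rng.choice(idx1, size=min(nb - nb // 2, len(idx1)), replace=False),
        ]
    )
    nr = cfg.explain.n_records
    rec_idx = np.concatenate(
        [
            rng.choice(idx0, size=min(nr // 2, len(idx0)), replace=False),
            rng.choice(idx1, size=min(nr - nr // 2, len(idx1)), replace=False),
        ]
    )
    predict = lambda M: model.predict_proba(M)[:, 1]
    reports = [
        shapley_attribution(
            predict,
            F[i],
            F[bg_idx],
            n_permutations=cfg.explain.n_permutations,
            seed=int(cfg.seed * 1000 + k),
            frequencies=freqs,
        )
        for k, i in enumerate(rec_idx)
    ]
    agg = aggregate_attributions(reports)
    pca = pca_frequency_importance(data)
    band = select_band(pca, agg)
    table = pca.to_frame().merge(agg, on="frequency_hz")
    return table, pca, band


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns a manifest of artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"drsviab {__version__}",
        f"seed: {cfg.seed}",
        f"grid: {cfg.grid.n_points} points, "
        f"{cfg.grid.f_min:g}-{cfg.grid.f_max:g} Hz",
    ]
    manifest: dict[str, str] = {}
    lib = cfg.state_library()
    grid = FrequencyGrid(
        np.linspace(cfg.grid.f_min, cfg.grid.f_max, cfg.grid.n_points)
    )

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise PipelineError(f"stage {name!r} failed: {e}") from e

    data = _stage(
        "simulate",
        lambda: simulate_dataset(cfg.design, lib, cfg.noise, seed=cfg.seed, grid=grid),
    )
    if cfg.stages.simulate:
        spectra_path = out / "spectra.csv"
        labels_path = out / "labels.csv"
        write_spectra_csv(data.spectra, spectra_path)
        data.labels_frame().to_csv(labels_path, index=False)
        (out / "provenance.txt").write_text("\n".join(data.provenance) + "\n")
        manifest["spectra"] = str(spectra_path)
        manifest["labels"] = str(labels_path)
        log_lines.append(
            f"simulate: {len(data)} records, phases {data.phase_counts()}"
            f" -> {spectra_path.name}, {labels_path.name}"
        )

    if cfg.stages.fit:
        fit_df = _stage("fit", lambda: fit_conditions(data, cfg.seed))
        fit_path = out / "fit_report.csv"
        fit_df.to_csv(fit_path, index=False, float_format="%.6f")
        manifest["fit_report"] = str(fit_path)
        log_lines.append(
            f"fit: {len(fit_df)} conditions, min R^2 "
            f"{fit_df['r_squared'].min():.6f} -> {fit_path.name}"
        )

    if cfg.stages.classify:
        specs = [
            ClassifierSpec(
                family=f,
                grid_points=None,
                max_epochs=cfg.classify.max_epochs,
                patience=cfg.classify.patience,
            )
            for f in cfg.classify.families
        ]
        # desk-scale the network grids via seeded subsampling
        specs = [
            sp
            if sp.family not in ("recurrent_sequence", "bidirectional_recurrent",
                                  "residual_bidirectional_recurrent", "conv1d")
            else ClassifierSpec(
                family=sp.family,
                grid_points=tuple(
                    map(
                        lambda d: tuple(d.items()),
                        (
                            dict(p)
                            for p in sp.grid.subsample(
                                cfg.classify.grid_subsample, seed=cfg.seed
                            )
                        ),
                    )
                ),
                max_epochs=sp.max_epochs,
                patience=sp.patience,
            )
            for sp in specs
        ]
        bands = {}
        if "whole" in cfg.classify.bands:
            bands["whole"] = WHOLE_BAND
        if "selected" in cfg.classify.bands:
            bands["selected"] = SELECTED_BAND
        report = _stage(
            "classify",
            lambda: band_comparison_experiment(
                data,
                specs,
                seed=cfg.seed,
                bands=bands,
                k_outer=cfg.classify.k_outer,
                k_inner=cfg.classify.k_inner,
                group_aware=cfg.classify.group_aware,
            ),
        )
        eval_path = out / "evaluation_report.csv"
        report.to_csv(eval_path)
        manifest["evaluation_report"] = str(eval_path)
        log_lines.append(
            f"classify: {len(report.rows)} (family, band) rows -> {eval_path.name}"
        )

    if cfg.stages.explain:
        table, pca, band = _stage("explain", lambda: _explain(data, cfg))
        imp_path = out / "importance.csv"
        table.to_csv(imp_path, index=False, float_format="%.8g")
        manifest["importance"] = str(imp_path)
        log_lines.append(
            "explain: dominant frequencies "
            + ", ".join(f"{f / 1e9:.2f} GHz" for f in pca.dominant_frequency)
            + f"; recommended band {band[0] / 1e9:.2f}-{band[1] / 1e9:.2f} GHz"
            + f" -> {imp_path.name}"
        )

    log_path = out / "run_log.txt"
    log_lines.append("manifest: " + json.dumps(manifest, sort_keys=True))
    log_path.write_text("\n".join(log_lines) + "\n")
    manifest["run_log"] = str(log_path)
    return manifest
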