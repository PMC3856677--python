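"""End-to-end analysis pipeline: simulate/load → preprocess → cycles →
alignment → statistics → report.

Every run is driven by one config mapping (YAML-friendly, see
``DEFAULT_CONFIG``) plus a master seed, writes tidy CSV tables, plots and
a manifest (config + seed + library versions + output checksums), and is
bit-identical across reruns of the same config for all tables.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as al
from . import cycles as cy
from . import preprocess as pp
from . import stats as st
from .io import load_bundle, write_bundle
from .simulate import (
    DEFAULT_LISTENER,
    ExperimentBundle,
    ListenerSimParams,
    make_design,
    simulate_experiment,
)

__all__ = ["DEFAULT_CONFIG", "StageError", "run_pipeline", "simulate_to_disk", "load_config"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "bundle_dir": None,  # load a bundle instead of simulating
    "simulate": {
        "n_listeners": 4,
        "trial_dur": 60.0,
        "fs": 200.0,
        "conditions": ["N", "L"],
        "readers": ["F", "M"],
        "n_texts_per_condition": 5,
        "coupling_mode": "independent",
        "coupling_phase": 0.15,
        "coupling_jitter_sd": 0.03,
        "artifact_rate": 0.0,
        "write_bundle": False,
    },
    "preprocess": {
        "band_low_hz": pp.DEFAULT_BAND[0],
        "band_high_hz": pp.DEFAULT_BAND[1],
        "target_fs": 200.0,
        "w_rc": 1.0,
        "w_ab": 1.0,
    },
    "detection": {
        "onset_frac": 0.1,
        "offset_frac": 0.1,
        "min_cycle_s": 1.0,
        "smooth_hz": 2.0,
    },
    "artifacts": {"vel_thresh_mult": 5.0, "smooth_hz": 5.0},
    "outliers": {"k": 1.5},
    "surrogate": {"n_draws": 1},
    "run_until": "stats",  # stop after "cycles", "align" or "stats"
    "model": {
        "p_method": "wald",  # "bootstrap" for resampled p-values
        "n_resamples": 1000,
        "alpha": 0.05,
        "responses": ["durC", "ampI"],
        "progression": True,
    },
    "plots": True,
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides)


def _listener_params(sim_cfg: dict) -> ListenerSimParams:
    from dataclasses import replace

    return replace(
        DEFAULT_LISTENER,
        coupling_mode=sim_cfg["coupling_mode"],
        coupling_phase=sim_cfg["coupling_phase"],
        coupling_jitter_sd=sim_cfg["coupling_jitter_sd"],
        artifact_rate=sim_cfg["artifact_rate"],
        fs=sim_cfg["fs"],
    )


def _simulate_bundle(cfg: dict) -> ExperimentBundle:
    from dataclasses import replace

    from .simulate import FEMALE_READER, MALE_READER

    sim = cfg["simulate"]
    design = make_design(
        sim["n_listeners"],
        conditions=tuple(sim["conditions"]),
        readers=tuple(sim["readers"]),
        n_texts_per_condition=sim["n_texts_per_condition"],
        seed=cfg["seed"],
    )
    presets = {"F": FEMALE_READER, "M": MALE_READER}
    reader_params = {
        r: replace(presets.get(r, FEMALE_READER),
                   trial_dur=sim["trial_dur"], fs=sim["fs"])
        for r in design["reader"].unique()
    }
    return simulate_experiment(
        design, reader_params=reader_params,
        listener_params=_listener_params(sim), seed=cfg["seed"],
    )


def _get_bundle(cfg: dict, out: Path) -> ExperimentBundle:
    if cfg.get("bundle_dir"):
        return load_bundle(cfg["bundle_dir"])
    bundle = _simulate_bundle(cfg)
    if cfg["simulate"].get("write_bundle"):
        write_bundle(bundle, out / "bundle")
    return bundle


def simulate_to_disk(cfg: dict, out_dir: str | Path) -> Path:
    """Simulate a bundle from config and write it under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return write_bundle(_simulate_bundle(cfg), out)


def _segment_trial(rec, md, pre, det, art):
    filtered = pp.filter_resample(
        rec,
        band=(pre["band_low_hz"], pre["band_high_hz"]),
        target_fs=min(pre["target_fs"], rec.fs),
    )
    trace = pp.combine_bands(filtered, pre["w_rc"], pre["w_ab"])
    events = cy.detect_inhalations(
        trace,
        onset_frac=det["onset_frac"],
        offset_frac=det["offset_frac"],
        min_cycle_s=det["min_cycle_s"],
        smooth_hz=det["smooth_hz"],
    )
    cycles = cy.build_cycles(events, trace, md, subject_id=rec.subject_id,
                             trial_id=rec.trial_id)
    cycles = cy.flag_artifacts(
        cycles, trace, vel_thresh_mult=art["vel_thresh_mult"],
        smooth_hz=art["smooth_hz"],
    )
    return trace, events, cycles


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None, out_dir: str | Path = "respalign_out") -> dict:
    """Run the full analysis; returns the in-memory tables it wrote."""
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    pre, det, art = cfg["preprocess"], cfg["detection"], cfg["artifacts"]

    try:
        bundle = _get_bundle(cfg, out)
    except Exception as e:
        raise StageError("simulate/load", e) from e

    # ---- preprocess: per-subject MD from VC maneuvers -------------------
    try:
        md = {}
        for subject, rec in bundle.vc.items():
            md[subject] = pp.compute_md(rec, pre["w_rc"], pre["w_ab"])
        missing = [
            s
            for s in set(bundle.design["listener"]) | set(bundle.design["reader"])
            if s not in md
        ]
        if missing:
            raise pp.FormatError(f"missing VC traces for subjects: {missing}")
    except StageError:
        raise
    except Exception as e:
        raise StageError("preprocess", e) from e

    # ---- cycles ---------------------------------------------------------
    try:
        reader_seg = {}
        for key, (rec, labels, _truth) in bundle.reader_trials.items():
            reader, _, _ = key
            reader_seg[key] = _segment_trial(rec, md[reader], pre, det, art) + (labels,)
        listener_seg = {}
        for key, (rec, _truth) in bundle.listener_trials.items():
            listener, _ = key
            listener_seg[key] = _segment_trial(rec, md[listener], pre, det, art)

        design = bundle.design
        tables = []
        for row in design.itertuples(index=False):
            key = (row.listener, int(row.trial_index))
            _, _, cycles = listener_seg[key]
            t = cy.cycles_to_table(cycles)
            for col, val in (
                ("listener", row.listener), ("reader", row.reader),
                ("text", row.text), ("condition", row.condition),
                ("order", row.order), ("trial_index", int(row.trial_index)),
            ):
                t[col] = val
            tables.append(t)
        cycle_table = pd.concat(tables, ignore_index=True)
        cycle_table, exclusion = cy.filter_outliers(
            cycle_table, k=cfg["outliers"]["k"], group_col="listener"
        )
        _write_table(cycle_table, out / "cycle_table.csv")
        _write_table(exclusion, out / "outlier_exclusion.csv")
        results["cycle_table"] = cycle_table
        results["outlier_exclusion"] = exclusion

        reader_tables, rsyll_tables = [], []
        for (reader, text, cond), (trace, events, cycles, labels) in reader_seg.items():
            t = cy.cycles_to_table(cycles)
            t["reader"], t["text"], t["condition"] = reader, text, cond
            reader_tables.append(t)
            rs = cy.syllable_rate(cycles, labels)
            if len(rs):
                rs["reader"], rs["text"], rs["condition"] = reader, text, cond
                rsyll_tables.append(rs)
        results["reader_cycle_table"] = pd.concat(reader_tables, ignore_index=True)
        results["rsyll"] = (
            pd.concat(rsyll_tables, ignore_index=True) if rsyll_tables else pd.DataFrame()
        )
        _write_table(results["reader_cycle_table"], out / "reader_cycle_table.csv")
        _write_table(results["rsyll"], out / "rsyll.csv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("cycles", e) from e

    if cfg.get("run_until") == "cycles":
        return _finish(cfg, out, results)

    # ---- alignment ------------------------------------------------------
    try:
        reader_onsets = {}
        for key, (trace, events, cycles, labels) in reader_seg.items():
            reader_onsets[key] = np.array(
                [e.onset_t for e in events]
            ) - labels.speech_onset_s
        listener_onsets = {}
        for row in design.itertuples(index=False):
            key = (row.listener, int(row.trial_index))
            _, events, _ = listener_seg[key]
            labels = bundle.reader_trials[(row.reader, row.text, row.condition)][1]
            # playback and listener recording share the trial clock, so the
            # reader's speech-onset label aligns both sides
            listener_onsets[key] = np.array(
                [e.onset_t for e in events]
            ) - labels.speech_onset_s
        original = al.posI_observations(design, listener_onsets, reader_onsets)
        surrogate = al.random_association(
            design, listener_onsets, reader_onsets,
            seed=cfg["seed"], n_draws=cfg["surrogate"]["n_draws"],
        )
        obs = pd.concat([original, surrogate], ignore_index=True)
        _write_table(obs, out / "posI.csv")
        reports = pd.concat(
            [al.posI_report(obs, subset=s) for s in ("all", "first_cycle")],
            ignore_index=True,
        )
        _write_table(reports, out / "ks_results.csv")
        results["posI"] = obs
        results["ks_results"] = reports
    except StageError:
        raise
    except Exception as e:
        raise StageError("alignment", e) from e

    if cfg.get("run_until") == "align":
        return _finish(cfg, out, results)

    # ---- statistics -----------------------------------------------------
    try:
        mdl = cfg["model"]
        model_frames = []
        for response in mdl["responses"]:
            spec = st.ModelSpec(response=response, alpha=mdl["alpha"])
            try:
                spec = st.check_residuals_and_transform(cycle_table, spec)
                fit = st.fit_condition_model(
                    cycle_table, spec,
                    n_resamples=mdl["n_resamples"], seed=cfg["seed"],
                    p_method=mdl["p_method"],
                )
            except (st.DesignError, st.TransformError) as err:
                warnings.warn(f"model for {response} skipped: {err}")
                continue
            frame = fit.to_frame()
            frame.insert(0, "response", response)
            model_frames.append(frame)
        models = (
            pd.concat(model_frames, ignore_index=True) if model_frames else pd.DataFrame()
        )
        _write_table(models, out / "model_results.csv")
        results["model_results"] = models

        summary = st.summarize_by_condition(cycle_table)
        _write_table(summary, out / "condition_summary.csv")
        results["condition_summary"] = summary

        if mdl.get("progression"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prog = st.progression_contrasts(cycle_table, seed=cfg["seed"])
            _write_table(prog, out / "progression_contrasts.csv")
            results["progression_contrasts"] = prog
    except StageError:
        raise
    except Exception as e:
        raise StageError("stats", e) from e

    return _finish(cfg, out, results)


def _finish(cfg: dict, out: Path, results: dict) -> dict:
    if cfg.get("plots"):
        try:
            _make_plots(results, out)
        except Exception as e:
            warnings.warn(f"plotting failed: {e}")
    manifest = {
        "config": _jsonable(cfg),
        "seed": cfg["seed"],
        "versions": _versions(),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _versions() -> dict:
    import importlib.metadata as im

    out = {}
    for pkg in ("respalign", "numpy", "scipy", "pandas", "statsmodels"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def _make_plots(results: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = results.get("posI")
    if obs is not None and len(obs):
        strata = sorted(obs.groupby(["condition", "reader"]).groups)
        fig, axes = plt.subplots(
            1, max(len(strata), 1), figsize=(4 * max(len(strata), 1), 3.2),
            squeeze=False,
        )
        for ax, key in zip(axes[0], strata):
            sub = obs[(obs["condition"] == key[0]) & (obs["reader"] == key[1])]
            for pairing, color in (("original", "C0"), ("surrogate", "0.6")):
                x = sub.loc[sub["pairing"] == pairing, "posI"].to_numpy()
                if len(x):
                    ax.hist(x, bins=20, range=(0, 1), density=True, alpha=0.5,
                            color=color, label=pairing)
                if len(x) >= 2:
                    grid, dens = al.reflected_kde(x)
                    ax.plot(grid, dens, color=color)
            ax.set_title(f"condition {key[0]}, reader {key[1]}")
            ax.set_xlabel("posI")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "posI_distributions.png", dpi=110)
        plt.close(fig)

    summary = results.get("condition_summary")
    if summary is not None and len(summary):
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
        for ax, (col, label) in zip(
            axes, (("durC_mean", "durC (s)"), ("ampI_mean", "ampI (%MD)"))
        ):
            labels = summary.apply(
                lambda r: f"{r['condition']}/{r['order']}/{r['reader']}", axis=1
            )
            ax.bar(labels, summary[col],
                   yerr=summary[col.replace("_mean", "_se")].fillna(0.0))
            ax.set_ylabel(label)
            ax.tick_params(axis="x", rotation=60, labelsize=7)
        fig.tight_layout()
        fig.savefig(out / "condition_means.png", dpi=110)
        plt.close(fig)
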