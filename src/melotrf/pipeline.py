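"""End-to-end synthetic experiment: melodies -> expectation models ->
simulated recordings -> TRF model comparison -> cluster statistics.

The experiment emulates a naturalistic listening study at desk scale: a test
set of generated melodies is scored by several expectation models; simulated
participants' recordings are driven by note onset, repetition and the
generator's own surprise; regression models with and without surprise are
compared by cross-validated predictive correlation.  Everything is
deterministic given the master seed (per-participant substreams are derived
from it).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .note_io import Corpus, NoteEvent, NoteSequence, write_notes_table
from .synthetic_data import (
    MelodyGenConfig,
    NeuralSimConfig,
    MarkovPredictor,
    default_trf_kernel,
    generate_corpus,
    simulate_neural,
)
from .expectation_models import (
    BothPredictor,
    NGramPredictor,
    STMPredictor,
    TemperleyPredictor,
    evaluate_model,
    fit_temperley_params,
    ngram_train,
    save_surprise_table,
)
from .feature_regressors import build_feature_tables, to_impulse_regressors
from .trf_core import (
    bandpass,
    compare_models,
    context_sweep,
    cv_predictive_r,
    fit_ols,
    select_channels,
    time_expand,
)
from .cluster_stats import ClusterTestConfig, baseline_correct, cluster_permutation

__all__ = ["ExperimentConfig", "run_experiment", "session_feature_table"]


@dataclass
class ExperimentConfig:
    """Single-seed configuration of the full synthetic experiment."""

    seed: int = 0
    out_dir: str = "results/experiment"
    # stimulus set
    n_compositions: int = 6
    n_notes: int = 100
    n_train_compositions: int = 24
    markov_order: int = 2
    interval_scale: float = 2.5
    momentum: float = 0.6
    motif_repeat_prob: float = 0.05
    tempo: float = 3.0
    # expectation models: name -> context length ({} for an onset-only run)
    models: dict = field(
        default_factory=lambda: {"temperley": 8, "stm": 8, "ltm": 8, "both": 8}
    )
    include_baseline: bool = True
    # simulated participants
    n_participants: int = 6
    n_channels: int = 6
    srate: float = 60.0
    noise_sd: float = 2.0
    noise_type: str = "pink"
    surprise_gain: float = 1.0
    repetition_gain: float = -0.5
    # TRF settings
    t_min: float = -0.2
    t_max: float = 1.0
    cv_window: tuple = (0.0, 0.6)
    n_folds: int = 5
    band: tuple | None = None  # e.g. (0.5, 8.0); None = no filtering
    method: str = "ols"
    # statistics
    n_permutations: int = 500
    sweep_k: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def session_feature_table(corpus: Corpus, gap: float = 2.0, **kwargs) -> pd.DataFrame:
    """Pooled feature table with a ``session_time`` column placing the
    compositions back to back (separated by ``gap`` seconds) on one timeline."""
    table = build_feature_tables(corpus, **kwargs)
    offset = 0.0
    session = np.zeros(len(table))
    for seq in corpus:
        m = table["composition_id"] == seq.composition_id
        session[m.to_numpy()] = table.loc[m, "onset_time"] + offset
        offset += seq.notes[-1].onset + seq.notes[-1].duration + gap
    table["session_time"] = session
    return table


def _make_predictor(name: str, k: int, train: Corpus, gen_cfg: MelodyGenConfig):
    if name == "temperley":
        return TemperleyPredictor(fit_temperley_params(train))
    if name == "ltm":
        return NGramPredictor(ngram_train(train, k))
    if name == "stm":
        return STMPredictor(k)
    if name == "both":
        return BothPredictor(ngram_train(train, k), k)
    if name == "generator":
        return MarkovPredictor(gen_cfg)
    raise ValueError(f"unknown expectation model {name!r}")


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full synthetic study; returns the result bundle and writes
    CSV outputs plus a manifest to ``cfg.out_dir``."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_cfg = MelodyGenConfig(
        n_notes=cfg.n_notes,
        markov_order=cfg.markov_order,
        interval_scale=cfg.interval_scale,
        momentum=cfg.momentum,
        motif_repeat_prob=cfg.motif_repeat_prob,
        tempo=cfg.tempo,
        seed=cfg.seed,
    )
    test = generate_corpus(gen_cfg, cfg.n_compositions, name="stimuli")
    train_cfg = MelodyGenConfig(**{**gen_cfg.__dict__, "seed": cfg.seed + 10_000})
    train = generate_corpus(train_cfg, cfg.n_train_compositions, name="train")

    # --- music analysis ----------------------------------------------------
    music_rows = []
    surprise_tables = {}
    for name, k in cfg.models.items():
        predictor = _make_predictor(name, k, train, gen_cfg)
        table, per_comp, overall = evaluate_model(predictor, test, k)
        surprise_tables[name] = table
        music_rows.append(overall)
        save_surprise_table(table, out / f"surprise_{name}.csv")
    # the generator's own law provides the ground-truth surprise
    truth_k = max(2, cfg.markov_order)
    gen_table, _, gen_overall = evaluate_model(
        MarkovPredictor(gen_cfg), test, truth_k
    )
    music_rows.append(gen_overall)
    music_summary = pd.DataFrame(music_rows)
    music_summary.to_csv(out / "music_summary.csv", index=False)

    # --- simulate participants --------------------------------------------
    features = session_feature_table(test)
    true_surprise = gen_table.records.sort_values(
        ["composition_id", "note_index"]
    )
    features = features.sort_values(["composition_id", "note_index"]).reset_index(
        drop=True
    )
    features["true_surprise"] = true_surprise["surprise"].to_numpy()
    srate = cfg.srate
    n_samples = int(np.ceil(features["session_time"].max() * srate)) + round(
        (cfg.t_max + 1.0) * srate
    )
    session_notes = [
        (t, p) for t, p in zip(features["session_time"], features["pitch"])
    ]
    session_seq = NoteSequence(
        [NoteEvent(int(p), float(t), 0.1) for t, p in session_notes],
        composition_id="session",
    )
    z_surprise = features["true_surprise"].to_numpy()
    z_surprise = (z_surprise - z_surprise.mean()) / z_surprise.std()
    driver = {
        "onset": np.ones(len(features)),
        "repetition": features["repetition"].to_numpy() * cfg.repetition_gain,
        "surprise": z_surprise * cfg.surprise_gain,
    }
    kernels = {
        "onset": default_trf_kernel(srate, cfg.t_min, cfg.t_max),
        "repetition": default_trf_kernel(srate, cfg.t_min, cfg.t_max),
        "surprise": default_trf_kernel(srate, cfg.t_min, cfg.t_max),
    }
    recordings = []
    for p in range(cfg.n_participants):
        sim = NeuralSimConfig(
            n_channels=cfg.n_channels,
            srate=srate,
            lag_span=(cfg.t_min, cfg.t_max),
            noise_sd=cfg.noise_sd,
            noise_type=cfg.noise_type,
            seed=cfg.seed * 1000 + p,  # per-participant substream
        )
        rec, _ = simulate_neural(session_seq, driver, sim, true_trfs=kernels)
        if cfg.band is not None:
            rec = bandpass(rec, *cfg.band)
        recordings.append(rec)
    n_samples = recordings[0].n_samples

    # --- regression models -------------------------------------------------
    def regs_for(columns, extra=None):
        tab = features.copy()
        if extra is not None:
            tab["surprise"] = extra
        return to_impulse_regressors(
            tab, srate, n_samples, columns=columns, onset_column="session_time"
        )

    base_cols = [
        "onset_flag", "high_pitch", "low_pitch", "composition_onset",
        "repetition", "rms", "flatness", "envelope_variance",
    ]
    # synthetic stimuli carry no audio: constant acoustic columns are dropped
    base_cols = [c for c in base_cols if features[c].nunique() > 1 or c == "onset_flag"]
    include_baseline = cfg.include_baseline or bool(cfg.models)
    onset_regs = regs_for(["onset_flag"])
    base_regs = regs_for(base_cols)
    cv_rows = []
    results: dict[str, list] = {"onset": []}
    if include_baseline:
        results["baseline"] = []
    selected = []
    for p, rec in enumerate(recordings):
        M_on = time_expand(onset_regs, cfg.t_min, cfg.t_max, rec.bad_mask)
        cv_on = cv_predictive_r(
            M_on, rec, cfg.n_folds, cfg.cv_window, cfg.method, model_label="onset"
        )
        sel = select_channels(cv_on)
        selected.append(sel)
        results["onset"].append(cv_on)
        if include_baseline:
            M_b = time_expand(base_regs, cfg.t_min, cfg.t_max, rec.bad_mask)
            results["baseline"].append(
                cv_predictive_r(
                    M_b, rec, cfg.n_folds, cfg.cv_window, cfg.method,
                    model_label="baseline",
                )
            )
    for name, table in surprise_tables.items():
        sur = table.records.sort_values(["composition_id", "note_index"])[
            "surprise"
        ].to_numpy()
        regs = regs_for(base_cols + ["surprise"], extra=sur)
        results[name] = []
        for p, rec in enumerate(recordings):
            M = time_expand(regs, cfg.t_min, cfg.t_max, rec.bad_mask)
            results[name].append(
                cv_predictive_r(
                    M, rec, cfg.n_folds, cfg.cv_window, cfg.method, model_label=name
                )
            )
    for label, cvs in results.items():
        for p, cv in enumerate(cvs):
            cv_rows.append(
                {
                    "model": label,
                    "participant": p,
                    "summary_r": cv.summary_r(selected[p]),
                }
            )
    cv_summary = pd.DataFrame(cv_rows)
    cv_summary.to_csv(out / "cv_summary.csv", index=False)

    pairs = ([("baseline", "onset")] if include_baseline else []) + [
        (name, "baseline") for name in surprise_tables
    ]
    if pairs:
        comparison = compare_models(results, pairs=pairs, selected=selected)
    else:
        comparison = pd.DataFrame(
            columns=["model_a", "model_b", "mean_delta_r", "sd_delta_r",
                     "t", "p", "cohens_d", "p_holm"]
        )
    comparison.to_csv(out / "model_comparison.csv", index=False)

    # --- TRF coefficient maps + cluster statistics -------------------------
    clusters = None
    if not surprise_tables:
        return _finish(cfg, out, t0, test, music_summary, cv_summary,
                       comparison, clusters, None, results, selected)
    sur_best = max(
        surprise_tables,
        key=lambda nm: comparison.set_index("model_a")["mean_delta_r"].get(nm, -np.inf),
    )
    sur = surprise_tables[sur_best].records.sort_values(
        ["composition_id", "note_index"]
    )["surprise"].to_numpy()
    full_regs = regs_for(base_cols + ["surprise"], extra=sur)
    coef_maps = []
    for rec in recordings:
        M = time_expand(full_regs, cfg.t_min, cfg.t_max, rec.bad_mask)
        trf = fit_ols(M, rec)
        coef_maps.append(trf.kernel("surprise").T)  # (channels, lags)
    lag_times = time_expand(full_regs, cfg.t_min, cfg.t_max).lag_times
    maps = baseline_correct(np.array(coef_maps), lag_times, (-0.2, 0.0))
    ct_cfg = ClusterTestConfig(
        n_permutations=cfg.n_permutations, seed=cfg.seed + 77
    )
    clusters = cluster_permutation(maps, ct_cfg)
    pd.DataFrame(
        {
            "cluster": range(len(clusters.p_values)),
            "mass": clusters.cluster_masses,
            "size": [len(m) for m in clusters.cluster_members],
            "p": clusters.p_values,
        }
    ).to_csv(out / "clusters.csv", index=False)

    # --- context sweep -----------------------------------------------------
    sweep_df = None
    if cfg.sweep_k:
        evals = {}
        sweep_cvs = {}
        for k in cfg.sweep_k:
            predictor = _make_predictor("ltm", k, train, gen_cfg)
            evals[k] = evaluate_model(predictor, test, k)
            sur_k = evals[k][0].records.sort_values(
                ["composition_id", "note_index"]
            )["surprise"].to_numpy()
            regs_k = regs_for(base_cols + ["surprise"], extra=sur_k)
            sweep_cvs[k] = [
                cv_predictive_r(
                    time_expand(regs_k, cfg.t_min, cfg.t_max, rec.bad_mask),
                    rec, cfg.n_folds, cfg.cv_window, cfg.method,
                    model_label=f"ltm-k{k}",
                )
                for rec in recordings
            ]
        sweep_df = context_sweep(evals, results["baseline"], sweep_cvs, selected)
        sweep_df.to_csv(out / "context_sweep.csv", index=False)

    return _finish(cfg, out, t0, test, music_summary, cv_summary, comparison,
                   clusters, sweep_df, results, selected)


def _finish(cfg, out, t0, test, music_summary, cv_summary, comparison,
            clusters, sweep_df, results, selected) -> dict:
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "wall_time_s": round(time.time() - t0, 2),
        "n_participants": cfg.n_participants,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for seq in test:
        write_notes_table(seq, out / f"{seq.composition_id}.notes.csv")
    return {
        "music_summary": music_summary,
        "cv_summary": cv_summary,
        "comparison": comparison,
        "clusters": clusters,
        "sweep": sweep_df,
        "manifest": manifest,
        "results": results,
        "selected": selected,
    }
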