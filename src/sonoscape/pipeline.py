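"""End-to-end orchestration: simulate -> features -> detect -> ordinate ->
regress -> report, driven by one :class:`RunConfig` with fixed seeds.

``run_pipeline`` renders the scheduled recordings of a synthetic study,
computes per-recording acoustic indices and per-plot means, optionally
trains the multi-label detector on synthesised clips and derives a
detector-based community table from file presences, ordinates the truth,
detector and insect communities (Bray-Curtis + NMDS, axis 1 oriented to
ascend with recovery), fits the five-index regressions (community axis,
log total richness, log old-growth richness, insect axis — plus the
detector-axis model when enabled), checks residual spatial independence
with a permutation correlogram, and writes all intermediate tables plus a
machine-readable summary.

``expert_schedule`` reproduces the expert listening protocol arithmetic:
a set of daily time windows of fixed length over a number of days.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detector as det
from . import indices as idx
from . import simulate as sim
from . import stats
from .audio import Waveform

__all__ = [
    "SimulatorConfig",
    "FeatureConfig",
    "DetectorBlock",
    "AnalysisConfig",
    "RunConfig",
    "make_song_classes",
    "make_training_clips",
    "make_validation_clips",
    "run_pipeline",
    "expert_schedule",
    "EXPERT_BIRD_WINDOWS",
]

logger = logging.getLogger(__name__)

#: Daily start times (hours) of the expert bird/mammal listening windows.
EXPERT_BIRD_WINDOWS = (6.0, 6.5, 7.0, 12.0, 16.0, 17.0, 18.0)


@dataclass
class SimulatorConfig:
    n_plots: int = 20
    n_species: int = 40
    n_visits: int = 10
    rate: int = 22_050
    noise_db: float = -45.0
    n_insect_species: int = 60
    turnover_strength: float = 8.0
    schedule_interval_s: float = 7200.0
    schedule_days: int = 2
    recording_s: float = 120.0


@dataclass
class FeatureConfig:
    frame_len: int = 512
    overlap: float = 0.0
    aci_window_s: float = 60.0
    saturation_threshold_db: float = 12.0
    events_threshold_db: float = 6.0
    band_width: float = 1000.0


@dataclass
class DetectorBlock:
    enabled: bool = True
    n_classes: int = 6
    n_pos_clips: int = 40
    n_neg_clips: int = 20
    n_val_clips: int = 60
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    hidden: int = 64
    dropout: float = 0.2
    target_pos: int = 200
    target_neg: int = 50
    min_pos: int = 10
    presence_threshold: float = 0.8
    max_files_per_plot: int = 12


@dataclass
class AnalysisConfig:
    nmds_k: int = 2
    n_restarts: int = 20
    max_iter: int = 300
    tol: float = 1e-6
    correlogram_bins: int = 5
    correlogram_perms: int = 199


@dataclass
class RunConfig:
    """All tunables of the pipeline in one round-trippable object."""

    seed_simulation: int = 0
    seed_training: int = 1
    seed_ordination: int = 2
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    detector: DetectorBlock = field(default_factory=DetectorBlock)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed_simulation=raw.get("seed_simulation", 0),
            seed_training=raw.get("seed_training", 1),
            seed_ordination=raw.get("seed_ordination", 2),
            simulator=SimulatorConfig(**raw.get("simulator", {})),
            features=FeatureConfig(**raw.get("features", {})),
            detector=DetectorBlock(**raw.get("detector", {})),
            analysis=AnalysisConfig(**raw.get("analysis", {})),
        )


# ---------------------------------------------------------------------------
# Detector data synthesis

def make_song_classes(pool: list[sim.SpeciesProfile],
                      n_classes: int) -> list[det.SongClassSpec]:
    """Pick a guild-balanced subset of diurnal species as song classes.

    Classes alternate between open-land and old-growth affiliates (falling
    back to generalists) so that every gradient position has detectable
    species, and bands are clipped to the detector's 50 Hz - 8 kHz range.
    """
    def usable(sp):
        lo, hi = sp.band()
        # classes below ~400 Hz sit in the 1/f background-noise floor
        return (sp.guild != "insect_nocturnal" and lo >= 400.0
                and max(lo, det.FMIN) < min(hi, det.FMAX) - 50)

    groups = {"open": [], "oldgrowth": [], "generalist": []}
    for sp in pool:
        if usable(sp):
            groups[sp.guild].append(sp)
    order = []
    for i in range(n_classes):
        for guild in (["open", "oldgrowth", "generalist"][i % 3],
                      "open", "oldgrowth", "generalist"):
            if groups[guild]:
                order.append(groups[guild].pop(0))
                break
    if len(order) < 2:
        raise ValueError("not enough diurnal species for song classes")
    specs = []
    for sp in order[:n_classes]:
        lo, hi = sp.band()
        specs.append(det.SongClassSpec(
            class_id=f"cls_{sp.species_id}", species_id=sp.species_id,
            band=(max(lo, det.FMIN), min(hi, det.FMAX))))
    return specs


def _clip_with_species(species_list, rate: int, noise_db: float,
                       rng: np.random.Generator) -> Waveform:
    """A 3-second clip of shaped noise plus one call per listed species."""
    n = int(det.CLIP_SECONDS * rate)
    out = sim._shaped_noise(n, rate, noise_db, rng)
    for species in species_list:
        f0, f1 = species.band()
        call = species.amplitude * sim._chirp(species.call_duration, f0, f1, rate)
        i0 = rng.integers(0, max(n - len(call), 1))
        out[i0:i0 + len(call)] += call[: n - i0]
    peak = np.max(np.abs(out))
    if peak > 0.99:
        out *= 0.99 / peak
    return Waveform(samples=out, rate=rate)


def make_training_clips(
    class_species: dict[str, sim.SpeciesProfile],
    n_pos: int, n_neg: int, rate: int, noise_db: float, seed: int,
    distractor_pool: list[sim.SpeciesProfile] | None = None,
) -> list[det.TrainingSample]:
    """Single-positive training clips for each song class.

    Positives contain the class's call over noise; negatives are noise
    alone or, half the time, another species' call (a realistic
    single-positive negative: the labelled class is absent, another may be
    present but unknown). When ``distractor_pool`` is given (normally the
    whole diurnal species pool), distractor calls are drawn from it — and
    occasionally added to positives too — so the model must discriminate
    the class from spectrally neighbouring species rather than from noise
    alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    distractors = list(distractor_pool or class_species.values())

    def pick_distractors(exclude_id, lam=3.0):
        """Poisson-many co-occurring calls, matching busy field windows."""
        cands = [d for d in distractors if d.species_id != exclude_id]
        if not cands or distractor_pool is None:
            return []
        k = min(int(rng.poisson(lam)), 6, len(cands))
        picks = rng.choice(len(cands), size=k, replace=False)
        return [cands[i] for i in picks]

    samples = []
    for class_id, sp in class_species.items():
        for _ in range(n_pos):
            present = [sp] + pick_distractors(sp.species_id)
            w = _clip_with_species(present, rate, noise_db, rng)
            samples.append(det.TrainingSample(det.make_model_input(w),
                                              class_id, True))
        for _ in range(n_neg):
            present = pick_distractors(sp.species_id)
            if distractor_pool is None and rng.uniform() < 0.7:
                cands = [d for d in distractors
                         if d.species_id != sp.species_id]
                if cands:
                    present = [cands[int(rng.integers(len(cands)))]]
            w = _clip_with_species(present, rate, noise_db, rng)
            samples.append(det.TrainingSample(det.make_model_input(w),
                                              class_id, False))
    return samples


def make_validation_clips(
    class_species: dict[str, sim.SpeciesProfile],
    n_clips: int, rate: int, noise_db: float, seed: int,
    distractor_pool: list[sim.SpeciesProfile] | None = None,
) -> list[tuple[det.ModelInput, np.ndarray]]:
    """Fully-labelled validation clips containing 0-2 classes each,
    optionally with a non-class distractor call mixed in."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 808]))
    class_ids = sorted(class_species)
    class_species_ids = {sp.species_id for sp in class_species.values()}
    extras = [d for d in (distractor_pool or [])
              if d.species_id not in class_species_ids]
    val = []
    for _ in range(n_clips):
        k = int(rng.integers(0, 3))
        chosen = list(rng.choice(class_ids, size=k, replace=False)) if k else []
        present = [class_species[c] for c in chosen]
        if extras:
            kx = min(int(rng.poisson(2.0)), 4, len(extras))
            picks = rng.choice(len(extras), size=kx, replace=False)
            present.extend(extras[i] for i in picks)
        w = _clip_with_species(present, rate, noise_db, rng)
        y = np.array([1.0 if c in chosen else 0.0 for c in class_ids])
        val.append((det.make_model_input(w), y))
    return val


# ---------------------------------------------------------------------------
# Pipeline

def _ordinate(community: pd.DataFrame, gradients: pd.Series,
              cfg: AnalysisConfig, seed: int) -> tuple[stats.OrdinationResult, list[str]]:
    """Ordinate a community, dropping (and reporting) all-zero plots."""
    keep = community.index[community.sum(axis=1) > 0]
    dropped = [p for p in community.index if p not in set(keep)]
    if dropped:
        logger.warning("dropping all-zero plots from ordination: %s", dropped)
    d = stats.bray_curtis(community.loc[keep])
    ordn = stats.nmds(d, k=cfg.nmds_k, n_restarts=cfg.n_restarts,
                      max_iter=cfg.max_iter, tol=cfg.tol, seed=seed)
    ordn = stats.orient_axis(ordn, gradients.loc[keep])
    return ordn, dropped


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None,
                 stages: tuple[str, ...] = ("simulate", "features", "detect",
                                            "analyze")) -> dict:
    """Run the configured stages and return the report dictionary.

    The report holds the synthetic dataset, per-recording and per-plot
    index tables, ordinations, regression tables and a JSON-serialisable
    ``summary`` of every headline number. When ``out_dir`` is given all
    tables plus ``summary.json`` are written there.
    """
    report: dict = {"summary": {"seed_simulation": cfg.seed_simulation}}

    # -- simulate -----------------------------------------------------------
    s = cfg.simulator
    ds = sim.make_dataset(
        n_plots=s.n_plots, n_species=s.n_species, n_visits=s.n_visits,
        seed=cfg.seed_simulation, rate=s.rate, noise_db=s.noise_db,
        n_insect_species=s.n_insect_species,
        turnover_strength=s.turnover_strength,
        schedule_interval_s=s.schedule_interval_s,
        schedule_days=s.schedule_days, recording_s=s.recording_s)
    report["dataset"] = ds
    gradients = ds.gradients
    if stages == ("simulate",) or "features" not in stages:
        _write_report(report, out_dir)
        return report

    # -- detector setup (trained before rendering so files are scored in the
    #    same pass that computes their indices) ------------------------------
    trained = None
    class_species: dict[str, sim.SpeciesProfile] = {}
    do_detect = cfg.detector.enabled and "detect" in stages
    if do_detect:
        d = cfg.detector
        specs = make_song_classes(ds.pool, d.n_classes)
        class_species = {c.class_id: next(sp for sp in ds.pool
                                          if sp.species_id == c.species_id)
                         for c in specs}
        diurnal = [sp for sp in ds.pool if sp.guild != "insect_nocturnal"]
        train = make_training_clips(class_species, d.n_pos_clips,
                                    d.n_neg_clips, s.rate, s.noise_db,
                                    cfg.seed_training,
                                    distractor_pool=diurnal)
        val = make_validation_clips(class_species, d.n_val_clips, s.rate,
                                    s.noise_db, cfg.seed_training + 1,
                                    distractor_pool=diurnal)
        det_cfg = det.DetectorConfig(
            epochs=d.epochs, batch_size=d.batch_size,
            learning_rate=d.learning_rate, hidden=d.hidden,
            dropout=d.dropout, target_pos=d.target_pos,
            target_neg=d.target_neg, min_pos=d.min_pos)
        trained = det.train_detector(train, val, specs, det_cfg,
                                     seed=cfg.seed_training)
        val_scores = trained.score([mi for mi, _ in val])
        val_truth = np.stack([y for _, y in val])
        metrics = det.evaluate(val_truth, val_scores,
                               threshold=d.presence_threshold)
        report["summary"]["detector_val_map"] = metrics["mAP"]
        report["summary"]["detector_val_f1"] = metrics["f1"]
        report["summary"]["detector_best_epoch"] = trained.best_epoch

    # -- render + features (+ scoring) --------------------------------------
    f = cfg.features
    index_sets = []
    scores_by_file: dict[str, list[det.DetectionScore]] = {}
    plot_of_file: dict[str, str] = {}
    files_scored: dict[str, int] = {}
    for w in sim.iter_recordings(ds):
        index_sets.append(idx.compute_indices(
            w, frame_len=f.frame_len, overlap=f.overlap,
            aci_window_s=f.aci_window_s,
            saturation_threshold_db=f.saturation_threshold_db,
            events_threshold_db=f.events_threshold_db,
            band_width=f.band_width))
        if trained is not None:
            n_done = files_scored.get(w.plot_id, 0)
            if n_done < cfg.detector.max_files_per_plot:
                fid = f"{w.plot_id}_{int(w.start_time):06d}"
                scores_by_file[fid] = det.score_file(trained, w, file_id=fid)
                plot_of_file[fid] = w.plot_id
                files_scored[w.plot_id] = n_done + 1

    per_recording = idx.indices_frame(index_sets)
    plot_summary = idx.summarize_plot_indices(per_recording)
    report["per_recording_indices"] = per_recording
    report["plot_indices"] = plot_summary

    detector_community = None
    if trained is not None:
        presence = det.call_presence(
            scores_by_file, trained.class_ids,
            threshold=cfg.detector.presence_threshold,
            plot_of_file=plot_of_file,
            species_of_class={c: spec.species_id for c, spec in
                              trained.class_specs.items()})
        detector_community = presence.frequency.reindex(gradients.index,
                                                        fill_value=0)
        report["presence"] = presence

    if "analyze" not in stages:
        _write_report(report, out_dir)
        return report

    # -- ordinations ---------------------------------------------------------
    a = cfg.analysis
    truth_ord, _ = _ordinate(ds.truth_community, gradients, a,
                             cfg.seed_ordination)
    insect_ord, _ = _ordinate(ds.insect_community, gradients, a,
                              cfg.seed_ordination + 1)
    report["truth_ordination"] = truth_ord
    report["insect_ordination"] = insect_ord
    report["summary"]["truth_nmds_stress"] = truth_ord.stress
    report["summary"]["insect_nmds_stress"] = insect_ord.stress
    report["summary"]["truth_axis1_gradient_pearson"] = stats.pearson(
        truth_ord.scores["axis1"],
        gradients.loc[truth_ord.scores.index])
    report["summary"]["insect_axis1_gradient_pearson"] = stats.pearson(
        insect_ord.scores["axis1"],
        gradients.loc[insect_ord.scores.index])

    cnn_ord = None
    if detector_community is not None:
        cnn_ord, dropped = _ordinate(detector_community, gradients, a,
                                     cfg.seed_ordination + 2)
        report["cnn_ordination"] = cnn_ord
        report["summary"]["cnn_nmds_stress"] = cnn_ord.stress
        report["summary"]["cnn_plots_dropped"] = len(dropped)
        from scipy.stats import spearmanr
        rho = spearmanr(cnn_ord.scores["axis1"],
                        gradients.loc[cnn_ord.scores.index]).statistic
        report["summary"]["cnn_axis1_gradient_spearman"] = float(rho)

    # -- richness + regressions ---------------------------------------------
    og_plots = [p.plot_id for p in ds.plots if p.category == "Oldgr"]
    richness = stats.richness_measures(ds.truth_community, og_plots)
    report["richness"] = richness

    predictors = plot_summary[idx.MODEL_INDICES]
    models = {
        "community_axis": (truth_ord.scores["axis1"], False),
        "total_richness": (richness["total_richness"], True),
        "oldgrowth_richness": (richness["oldgrowth_richness"], True),
        "insect_axis": (insect_ord.scores["axis1"], False),
    }
    if cnn_ord is not None:
        models["cnn_axis"] = (cnn_ord.scores["axis1"], False)
    report["regressions"] = {}
    for name, (resp, logt) in models.items():
        resp = resp.reindex(predictors.index).dropna()
        fitres = stats.fit_index_model(resp, predictors.loc[resp.index],
                                       log_response=logt)
        report["regressions"][name] = fitres
        report["summary"][f"adj_r2_{name}"] = fitres.adj_r2

    # residual spatial-independence check on the community-axis model
    coords = np.array([[p.x, p.y] for p in ds.plots
                       if p.plot_id in report["regressions"]
                       ["community_axis"].residuals.index])
    env = stats.correlogram_envelope(
        report["regressions"]["community_axis"].residuals.to_numpy(), coords,
        n_bins=a.correlogram_bins, n_perm=a.correlogram_perms,
        seed=cfg.seed_ordination)
    report["correlogram"] = env
    report["summary"]["correlogram_bins_outside_envelope"] = int(
        env["outside"].sum())

    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: str | Path | None) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = report.get("dataset")
    if ds is not None:
        sim.write_dataset(ds, out, write_audio=False)
    for key in ("per_recording_indices", "plot_indices", "richness",
                "correlogram"):
        if key in report:
            report[key].to_csv(out / f"{key}.csv")
    for key in ("truth_ordination", "insect_ordination", "cnn_ordination"):
        if key in report:
            report[key].scores.to_csv(out / f"{key}_scores.csv")
    if "presence" in report:
        report["presence"].presence.to_csv(out / "presence.csv")
        report["presence"].frequency.to_csv(out / "detector_community.csv")
    for name, fitres in report.get("regressions", {}).items():
        fitres.table().to_csv(out / f"regression_{name}.csv")
    (out / "summary.json").write_text(
        json.dumps(report["summary"], indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Expert listening schedule

def expert_schedule(daily_windows: list[float] | tuple[float, ...] = EXPERT_BIRD_WINDOWS,
                    n_days: int = 2, window_len_min: float = 2.0,
                    available_files: list[tuple[float, float]] | None = None,
                    ) -> tuple[float, list[tuple[int, float]]]:
    """Total listening minutes and (day, start-hour) file list.

    ``daily_windows`` are distinct start times in hours of day; total
    minutes = windows x days x window length. When ``available_files``
    (pairs of (day, start-hour)) is given, only matching files are listed
    and gaps are logged rather than failing.
    """
    if len(set(daily_windows)) != len(daily_windows):
        raise ValueError("daily windows must be distinct")
    wanted = [(day, h) for day in range(n_days) for h in daily_windows]
    if available_files is not None:
        have = set(available_files)
        files = [f for f in wanted if f in have]
        for f in wanted:
            if f not in have:
                logger.info("expert schedule gap: day %d %.2f h", *f)
    else:
        files = wanted
    total_minutes = len(daily_windows) * n_days * window_len_min
    return float(total_minutes), files


def field_recordings_per_day(interval_min: float, file_len_min: float) -> int:
    """Number of scheduled recordings per day for a fixed-interval
    protocol (e.g. 1-min files every 10 min -> 144/day)."""
    if interval_min <= 0 or file_len_min <= 0:
        raise ValueError("interval and file length must be positive")
    if file_len_min > interval_min:
        raise ValueError("file length exceeds the recording interval")
    return int(round(24 * 60 / interval_min))
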