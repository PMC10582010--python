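"""Synthetic tropical soundscapes along a forest-recovery gradient.

This module generates everything the downstream analysis consumes, so the
whole pipeline is testable without field data: a species pool with distinct
acoustic niches, plot layouts along a 0 -> 1 recovery gradient, ground-truth
occupancy communities, rendered audio of overlapping calls over shaped
background noise, and a correlated nocturnal-insect community table.

The statistical structure mirrors what passive acoustic studies of
post-agricultural recovery report: total vocalising richness decreases along
the gradient while the richness of old-growth-affiliated species increases,
and nocturnal insect communities turn over along the same gradient.
Occupancy of each species is logistic in the gradient position ``g``::

    P(present | g) = 1 / (1 + exp(-slope * (g - mid)))

Guild membership fixes the sign of ``slope``: open-land species decline with
recovery, old-growth species increase, generalists are near-flat, and
nocturnal insects increase (they recover quickly with regeneration).

Calls are rendered as band-limited linear chirps with Hann amplitude
envelopes — analytically band-limited and cheap — with Poisson call onsets
inside each species' diel activity window, summed over present species and
added to 1/f-shaped Gaussian background noise.

Everything is bitwise reproducible under a fixed seed: per-recording random
streams are spawned deterministically from the master seed and the
(plot, slot) identity of the recording.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import Waveform, write_wav

__all__ = [
    "Guild",
    "SpeciesProfile",
    "PlotSpec",
    "SyntheticDataset",
    "logistic_occupancy",
    "build_species_pool",
    "make_plots",
    "sample_communities",
    "render_recording",
    "simulate_insect_communities",
    "make_dataset",
    "default_schedule",
]

DAY_SECONDS = 86_400.0

# Guilds: open-land affiliates decline with recovery, old-growth affiliates
# increase, generalists are indifferent, nocturnal insects increase.
GUILDS = ("open", "generalist", "oldgrowth", "insect_nocturnal")
Guild = str

#: Desk-scale default guild mix: 24 open-skewed + 16 oldgrowth-skewed out of
#: 40 species reproduces declining total and rising old-growth richness.
DEFAULT_GUILD_FRACTIONS = {
    "open": 0.45,
    "generalist": 0.15,
    "oldgrowth": 0.30,
    "insect_nocturnal": 0.10,
}


@dataclass(frozen=True)
class SpeciesProfile:
    """Acoustic and ecological niche of one synthetic species."""

    species_id: str
    guild: Guild
    f_center: float            # Hz
    bandwidth: float           # Hz
    call_duration: float       # s, < 3
    call_rate: float           # calls per active minute
    diel_window: tuple[float, float]   # (start, stop) in day-seconds; may wrap
    occupancy_mid: float       # gradient position of the logistic midpoint
    occupancy_slope: float     # signed steepness of the logistic
    amplitude: float           # linear gain in (0, 1]

    def band(self) -> tuple[float, float]:
        return (self.f_center - self.bandwidth / 2,
                self.f_center + self.bandwidth / 2)


@dataclass(frozen=True)
class PlotSpec:
    """One monitoring plot on the recovery gradient.

    ``gradient`` is the recovery position in [0, 1]; ``category`` is its
    deterministic binning into the land-use stages used for reporting
    (active agriculture, early/late regeneration, old-growth). Coordinates
    are planar metres, used only for spatial-independence checks.
    """

    plot_id: str
    gradient: float
    category: str
    x: float
    y: float


@dataclass
class SyntheticDataset:
    """A complete generated study: plots, pool, truth, insects, schedule."""

    plots: list[PlotSpec]
    pool: list[SpeciesProfile]
    truth_community: pd.DataFrame      # plots x species counts
    insect_community: pd.DataFrame     # plots x insect-species counts
    recording_schedule: list[tuple[str, float, float]]  # (plot_id, start, dur)
    seed: int
    rate: int = 22_050
    noise_db: float = -45.0

    @property
    def gradients(self) -> pd.Series:
        return pd.Series({p.plot_id: p.gradient for p in self.plots})


def logistic_occupancy(profile: SpeciesProfile, g: float) -> float:
    """Presence probability of ``profile`` at gradient position ``g``."""
    return 1.0 / (1.0 + np.exp(-profile.occupancy_slope * (g - profile.occupancy_mid)))


def categorize(g: float, index: int = 0) -> str:
    """Bin a gradient position into a land-use category.

    Active agriculture (g < 0.1) alternates between Pasture and Cacao by
    plot index; early regeneration covers 0.1 <= g < 0.5, late regeneration
    0.5 <= g < 0.9, old-growth g >= 0.9.
    """
    if g < 0.1:
        return "Pasture" if index % 2 == 0 else "Cacao"
    if g < 0.5:
        return "RegI"
    if g < 0.9:
        return "RegII"
    return "Oldgr"


def _guild_counts(n_species: int, fractions: dict[str, float]) -> dict[str, int]:
    missing = set(fractions) - set(GUILDS)
    if missing:
        raise ValueError(f"unknown guilds: {sorted(missing)}")
    total = sum(fractions.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"guild fractions must sum to 1, got {total}")
    # largest-remainder apportionment so counts sum exactly to n_species
    raw = {g: n_species * fractions.get(g, 0.0) for g in GUILDS}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    short = n_species - sum(counts.values())
    for g in sorted(GUILDS, key=lambda g: raw[g] - counts[g], reverse=True)[:short]:
        counts[g] += 1
    return counts


# Diel windows per guild (day-seconds). Insects sing at night; the window
# wraps midnight.
_DIEL = {
    "open": (5 * 3600.0, 19 * 3600.0),
    "generalist": (5 * 3600.0, 19 * 3600.0),
    "oldgrowth": (5 * 3600.0, 19 * 3600.0),
    "insect_nocturnal": (19 * 3600.0, 5 * 3600.0),
}


def build_species_pool(
    n_species: int,
    guild_fractions: dict[str, float] | None = None,
    rate: int = 22_050,
    seed: int = 0,
    f_min: float = 300.0,
) -> list[SpeciesProfile]:
    """Create ``n_species`` profiles with non-overlapping acoustic niches.

    Frequency centres are laid on an even grid between ``f_min`` and the
    Nyquist frequency (with headroom for the widest band) so pairwise centre
    separation is at least half a bandwidth; bandwidths are drawn below
    twice the grid spacing to guarantee it. Raises if the grid cannot fit
    below Nyquist.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    fractions = dict(guild_fractions or DEFAULT_GUILD_FRACTIONS)
    counts = _guild_counts(n_species, fractions)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    nyquist = rate / 2.0
    f_max = nyquist - 700.0  # headroom for half the widest bandwidth
    spacing = (f_max - f_min) / max(n_species - 1, 1)
    if f_max <= f_min or spacing < 100.0:
        raise ValueError(
            f"cannot place {n_species} distinct frequency bands below the "
            f"Nyquist frequency {nyquist:.0f} Hz"
        )
    centers = f_min + spacing * np.arange(n_species)

    guild_of = np.repeat(
        [g for g in GUILDS for _ in range(counts[g])], 1
    )
    rng.shuffle(guild_of)  # decouple guild from frequency slot

    # Guild-specific acoustic traits emulate the qualitative soundscape
    # shift reported along recovery gradients: open-land communities produce
    # many short, loud, narrow-band calls (high event rates and amplitude
    # fluctuation), whereas old-growth communities spread longer, quieter
    # calls across wider frequency niches (broader spectral coverage).
    # Values are (bandwidth fraction of cap, call duration s, calls/min,
    # linear amplitude) ranges.
    traits = {
        "open": ((0.35, 0.55), (0.3, 0.8), (14.0, 24.0), (0.15, 0.30)),
        "generalist": ((0.45, 0.75), (0.5, 1.5), (8.0, 16.0), (0.10, 0.25)),
        "oldgrowth": ((0.75, 0.95), (1.2, 2.4), (4.0, 9.0), (0.08, 0.20)),
        "insect_nocturnal": ((0.40, 0.70), (0.5, 1.5), (20.0, 40.0),
                             (0.08, 0.20)),
    }
    pool: list[SpeciesProfile] = []
    for i, (fc, guild) in enumerate(zip(centers, guild_of)):
        bw_frac, dur, rate_rng, amp = traits[str(guild)]
        bw = float(rng.uniform(*bw_frac) * min(1200.0, 1.9 * spacing))
        bw = min(bw, 2.0 * (nyquist - fc) - 1.0, 2.0 * (fc - 50.0))
        if guild == "open":
            slope = -float(rng.uniform(6.0, 14.0))
            mid = float(rng.uniform(0.2, 0.8))
        elif guild == "oldgrowth":
            slope = float(rng.uniform(6.0, 14.0))
            mid = float(rng.uniform(0.2, 0.8))
        elif guild == "insect_nocturnal":
            slope = float(rng.uniform(4.0, 10.0))
            mid = float(rng.uniform(0.1, 0.5))
        else:  # generalist
            slope = float(rng.uniform(-2.0, 2.0))
            mid = float(rng.uniform(0.2, 0.8))
        pool.append(SpeciesProfile(
            species_id=f"sp{i:03d}",
            guild=str(guild),
            f_center=float(fc),
            bandwidth=bw,
            call_duration=float(rng.uniform(*dur)),
            call_rate=float(rng.uniform(*rate_rng)),
            diel_window=_DIEL[str(guild)],
            occupancy_mid=mid,
            occupancy_slope=slope,
            amplitude=float(rng.uniform(*amp)),
        ))
    return pool


def make_plots(n_plots: int = 20, seed: int = 0,
               extent_m: float = 2000.0) -> list[PlotSpec]:
    """Plots on a regular recovery gradient with random planar coordinates."""
    if n_plots < 2:
        raise ValueError("need at least 2 plots")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    gs = np.linspace(0.0, 1.0, n_plots)
    plots = []
    for i, g in enumerate(gs):
        plots.append(PlotSpec(
            plot_id=f"P{i:02d}",
            gradient=float(g),
            category=categorize(float(g), i),
            x=float(rng.uniform(0, extent_m)),
            y=float(rng.uniform(0, extent_m)),
        ))
    return plots


def sample_communities(
    pool: list[SpeciesProfile],
    plots: list[PlotSpec],
    n_visits: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the ground-truth community matrix (plots x species).

    Each cell is the number of visits (out of ``n_visits``) in which the
    species was present — a Binomial draw with the logistic occupancy
    probability at the plot's gradient position. This is the synthetic
    analogue of the "frequency per plot" metric: the number of files in
    which a species was recorded.
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    mat = np.zeros((len(plots), len(pool)), dtype=int)
    for j, sp in enumerate(pool):
        for i, plot in enumerate(plots):
            p = logistic_occupancy(sp, plot.gradient)
            mat[i, j] = rng.binomial(n_visits, p)
    return pd.DataFrame(mat,
                        index=[p.plot_id for p in plots],
                        columns=[s.species_id for s in pool])


def _active_overlap(window: tuple[float, float], start: float,
                    duration: float) -> list[tuple[float, float]]:
    """Intersect a (possibly midnight-wrapping) diel window with a
    recording interval; returns intervals in recording-local seconds."""
    lo, hi = window
    segments = [(lo, hi)] if lo <= hi else [(0.0, hi), (lo, DAY_SECONDS)]
    rec = [(start % DAY_SECONDS, min((start % DAY_SECONDS) + duration, DAY_SECONDS))]
    if (start % DAY_SECONDS) + duration > DAY_SECONDS:
        rec.append((0.0, (start % DAY_SECONDS) + duration - DAY_SECONDS))
    out = []
    offsets = [0.0, DAY_SECONDS - (start % DAY_SECONDS)]
    for (r0, r1), off in zip(rec, offsets):
        for s0, s1 in segments:
            a, b = max(r0, s0), min(r1, s1)
            if b > a:
                out.append((a - r0 + off, b - r0 + off))
    return out


def _chirp(duration: float, f0: float, f1: float, rate: int) -> np.ndarray:
    """Linear chirp from f0 to f1 with a Hann amplitude envelope."""
    n = max(int(round(duration * rate)), 2)
    t = np.arange(n) / rate
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * duration))
    env = np.hanning(n)
    return env * np.sin(phase)


def _shaped_noise(n: int, rate: int, noise_db: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, RMS at noise_db dBFS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    pink = np.fft.irfft(spec * shape, n)
    rms = np.sqrt(np.mean(pink ** 2))
    target = 10.0 ** (noise_db / 20.0)
    return pink * (target / rms) if rms > 0 else pink


def render_recording(
    plot: PlotSpec,
    truth_row: pd.Series,
    pool: list[SpeciesProfile],
    start_time: float,
    duration: float,
    rate: int = 22_050,
    noise_db: float | None = -45.0,
    seed: int = 0,
    rain_burst: bool = False,
) -> Waveform:
    """Render one recording: Poisson chirp trains of present, diel-active
    species plus 1/f background noise, peak-normalised to at most 1.

    ``truth_row`` maps species_id -> presence count for this plot; any
    positive count makes the species available to call. Species whose diel
    window does not intersect the recording interval contribute nothing.
    ``noise_db`` of None disables the noise floor entirely.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    max_edge = max((sp.band()[1] for sp in pool), default=0.0)
    if rate < 2 * max_edge:
        raise ValueError(
            f"rate {rate} below twice the highest band edge {max_edge:.0f} Hz")
    rng = np.random.default_rng(np.random.SeedSequence(
        [seed, 404, zlib.crc32(plot.plot_id.encode()), int(start_time)]))
    n = int(round(duration * rate))
    out = np.zeros(n)
    if noise_db is not None:
        out += _shaped_noise(n, rate, noise_db, rng)

    for sp in pool:
        if truth_row.get(sp.species_id, 0) <= 0:
            continue
        for a, b in _active_overlap(sp.diel_window, start_time, duration):
            active = b - a
            n_calls = rng.poisson(sp.call_rate * active / 60.0)
            if n_calls == 0:
                continue
            starts = rng.uniform(a, b, size=n_calls)
            f0, f1 = sp.band()
            call = sp.amplitude * _chirp(sp.call_duration, f0, f1, rate)
            for s in starts:
                i0 = int(round(s * rate))
                seg = call[: max(0, min(len(call), n - i0))]
                out[i0:i0 + len(seg)] += seg

    if rain_burst:
        # optional broadband contaminator for robustness experiments
        for _ in range(rng.poisson(duration / 20.0) + 1):
            i0 = rng.integers(0, max(n - rate // 2, 1))
            burst = rng.standard_normal(rate // 2) * 0.3
            burst *= np.hanning(len(burst))
            out[i0:i0 + len(burst)] += burst[: n - i0]

    peak = np.max(np.abs(out)) if n else 0.0
    if peak > 0.99:
        out *= 0.99 / peak
    return Waveform(samples=out, rate=rate, plot_id=plot.plot_id,
                    start_time=start_time)


def simulate_insect_communities(
    plots: list[PlotSpec],
    n_insect_species: int = 60,
    turnover_strength: float = 8.0,
    seed: int = 0,
    n_visits: int = 20,
) -> pd.DataFrame:
    """Nocturnal-insect community table correlated with the same gradient.

    Each insect species has a logistic occupancy in ``g`` with steepness
    ``turnover_strength`` and a random direction biased towards recovery
    (most species increase with regeneration), plus independent plot-level
    logit noise. ``turnover_strength=0`` makes occupancy independent of the
    gradient.
    """
    if turnover_strength < 0:
        raise ValueError("turnover_strength must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    mids = rng.uniform(0.1, 0.9, n_insect_species)
    # 70 % of species increase with recovery, 30 % decline
    direction = np.where(rng.uniform(size=n_insect_species) < 0.7, 1.0, -1.0)
    mat = np.zeros((len(plots), n_insect_species), dtype=int)
    for j in range(n_insect_species):
        for i, plot in enumerate(plots):
            logit = turnover_strength * direction[j] * (plot.gradient - mids[j])
            logit += rng.normal(0.0, 0.5)
            p = 1.0 / (1.0 + np.exp(-logit))
            mat[i, j] = rng.binomial(n_visits, p)
    return pd.DataFrame(mat,
                        index=[p.plot_id for p in plots],
                        columns=[f"ins{j:03d}" for j in range(n_insect_species)])


def default_schedule(
    plots: list[PlotSpec],
    interval_s: float = 7200.0,
    n_days: int = 2,
    duration_s: float = 120.0,
) -> list[tuple[str, float, float]]:
    """Desk-scale recording schedule: 2-min files every 2 h for 2 days.

    A downscale of the field protocol (2 min every 15 min for two weeks);
    interval, days and duration are all configurable.
    """
    schedule = []
    for plot in plots:
        for day in range(n_days):
            t = 0.0
            while t < DAY_SECONDS:
                schedule.append((plot.plot_id, day * DAY_SECONDS + t, duration_s))
                t += interval_s
    return schedule


def make_dataset(
    n_plots: int = 20,
    n_species: int = 40,
    n_visits: int = 10,
    seed: int = 0,
    rate: int = 22_050,
    noise_db: float = -45.0,
    guild_fractions: dict[str, float] | None = None,
    n_insect_species: int = 60,
    turnover_strength: float = 8.0,
    schedule_interval_s: float = 7200.0,
    schedule_days: int = 2,
    recording_s: float = 120.0,
) -> SyntheticDataset:
    """Generate a full synthetic study with one master seed."""
    plots = make_plots(n_plots, seed=seed)
    pool = build_species_pool(n_species, guild_fractions, rate=rate, seed=seed)
    truth = sample_communities(pool, plots, n_visits=n_visits, seed=seed)
    insects = simulate_insect_communities(
        plots, n_insect_species, turnover_strength, seed=seed)
    schedule = default_schedule(plots, schedule_interval_s, schedule_days,
                                recording_s)
    return SyntheticDataset(
        plots=plots, pool=pool, truth_community=truth,
        insect_community=insects, recording_schedule=schedule,
        seed=seed, rate=rate, noise_db=noise_db,
    )


def iter_recordings(ds: SyntheticDataset):
    """Yield rendered :class:`Waveform` objects for the dataset schedule."""
    plot_by_id = {p.plot_id: p for p in ds.plots}
    for plot_id, start, dur in ds.recording_schedule:
        plot = plot_by_id[plot_id]
        yield render_recording(
            plot, ds.truth_community.loc[plot_id], ds.pool,
            start_time=start, duration=dur, rate=ds.rate,
            noise_db=ds.noise_db, seed=ds.seed)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path,
                  write_audio: bool = True) -> None:
    """Write plots/communities as CSV and recordings as PCM-16 WAV files.

    Audio files are named ``<plot_id>_<DDDDDD-HHMMSS>.wav`` where the first
    field is the day index and the second the start time of day.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"plot_id": p.plot_id, "gradient": p.gradient,
          "category": p.category, "x": p.x, "y": p.y} for p in ds.plots]
    ).to_csv(out / "plots.csv", index=False)
    ds.truth_community.to_csv(out / "truth_community.csv")
    ds.insect_community.to_csv(out / "insect_community.csv")
    if write_audio:
        audio_dir = out / "audio"
        audio_dir.mkdir(exist_ok=True)
        for w in iter_recordings(ds):
            day = int(w.start_time // DAY_SECONDS)
            tod = w.start_time % DAY_SECONDS
            hh, rem = divmod(int(tod), 3600)
            mm, ss = divmod(rem, 60)
            name = f"{w.plot_id}_{day:02d}-{hh:02d}{mm:02d}{ss:02d}.wav"
            write_wav(audio_dir / name, w)
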