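"""Synthetic cohorts with known ground truth.

The generator emulates the neuronal-memory test paradigm this package
analyzes: awake birds previously exposed to conspecific songs (with limited,
20X, or extended, 200X, repetition counts, and post-exposure drug or vehicle
treatment) are played four test sets, each containing two familiar (F) and
two novel (N) conspecific songs, 25 repetitions per song, while multiunit
activity is recorded bilaterally from four electrodes per hemisphere in the
auditory region NCM and four in a non-NCM control region (Field L complex).

Each recording site adapts to each stimulus: the per-trial response
magnitude falls quickly over trials 1-5 (geometric fast phase) and then
declines linearly in trial number over trials 6-25, the window the slope
analysis fits. Novel stimuli decline at the configured ``novel_slope_pct``;
familiar stimuli decline at ``novel_slope_pct / fi_true`` for their
(group, hemisphere, region) cell, so the true Familiarity Index (novel rate
over familiar rate) of every familiar song equals ``fi_true`` by
construction. Trial noise is multiplicative lognormal, parameterized by its
coefficient of variation, so magnitudes stay positive.

Also provided: raw-voltage epoch synthesis (a fixture source for the
signal-processing stage) and qPCR CT tables with configurable per-cell
fold-changes for the companion gene-expression analysis.
"""

from __future__ import annotations

import json
import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .signalproc import Epoch, ResponseSeries

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_epochs",
    "generate_qpcr",
]

HEMISPHERES = ("left", "right")
REGIONS = ("NCM", "nonNCM")

#: Columns of the tidy trial-level table, in order.
TRIAL_COLUMNS = ("bird", "group", "hemisphere", "region", "site", "set",
                 "stimulus", "stim_class", "trial", "magnitude")

#: Number of initial trials carrying the geometric fast-phase component.
FAST_PHASE_TRIALS = 5
#: Per-trial decay ratio of the fast-phase component.
FAST_PHASE_DECAY = 0.5


Cell = tuple[str, str, str]  # (group, hemisphere, region)


@dataclass(frozen=True)
class CohortConfig:
    """Design and ground-truth parameters of one synthetic cohort.

    Parameters
    ----------
    n_birds_per_group : mapping of group name -> bird count
        Default mirrors the study design this emulates: 8 drug-treated
        (``hdac3i``) and 6 vehicle-treated birds with limited exposure, and
        6 birds with extended exposure (``x200``).
    electrodes_per_hemisphere_ncm, electrodes_per_hemisphere_nonncm : int
        Recording sites per hemisphere in each region; a region is omitted
        entirely when its count is 0.
    n_test_sets, familiar_per_set, novel_per_set, trials_per_song : int
        Test-session structure: 4 sets x (2 F + 2 N) songs x 25 repetitions.
        ``trials_per_song`` must be >= 7 so the linear fit window (trial 6
        onward) contains at least two points.
    amplitude_log_mean, amplitude_log_sd : float
        Per-site baseline response magnitude is lognormal with these
        parameters (arbitrary voltage units; magnitudes are never compared
        across sites unnormalized).
    novel_slope_pct : float
        True adaptation rate of novel songs, percent change per trial over
        the linear window; must be negative and shallow enough that the mean
        profile stays positive at the last trial.
    fi_true : mapping of (group, hemisphere, region) -> float
        Familiar-slope attenuation per cell; cells absent from the map have
        no memory effect (ratio 1.0). Values must be > 0.
    fast_phase_drop_frac : float
        Fraction of the baseline amplitude added at trial 1 and decaying
        geometrically over trials 1-5 (gone by the fit window).
    noise_cv : float
        Coefficient of variation of the multiplicative lognormal trial noise.
    seed : int
        Root seed; each site draws from an independent substream keyed by
        (seed, group, bird, hemisphere, region, site), so enlarging the
        cohort never perturbs previously generated sites.
    """

    n_birds_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"hdac3i": 8, "vehicle": 6, "x200": 6})
    fi_true: Mapping[Cell, float] = field(default_factory=dict)
    electrodes_per_hemisphere_ncm: int = 4
    electrodes_per_hemisphere_nonncm: int = 4
    n_test_sets: int = 4
    familiar_per_set: int = 2
    novel_per_set: int = 2
    trials_per_song: int = 25
    amplitude_log_mean: float = math.log(100.0)
    amplitude_log_sd: float = 0.4
    novel_slope_pct: float = -1.5
    fast_phase_drop_frac: float = 0.3
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_birds_per_group:
            raise ConfigurationError("n_birds_per_group: at least one group required")
        for g, n in self.n_birds_per_group.items():
            if int(n) < 1:
                raise ConfigurationError(f"n_birds_per_group[{g!r}] must be >= 1, got {n}")
        for name in ("n_test_sets", "familiar_per_set", "novel_per_set"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("electrodes_per_hemisphere_ncm", "electrodes_per_hemisphere_nonncm"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.electrodes_per_hemisphere_ncm + self.electrodes_per_hemisphere_nonncm < 1:
            raise ConfigurationError("electrodes_per_hemisphere_ncm: at least one region needs sites")
        if self.trials_per_song < 7:
            raise ConfigurationError(f"trials_per_song must be >= 7, got {self.trials_per_song}")
        if not self.novel_slope_pct < 0:
            raise ConfigurationError(f"novel_slope_pct must be negative, got {self.novel_slope_pct}")
        center = (6 + self.trials_per_song) / 2.0
        if 1 + self.novel_slope_pct / 100.0 * (self.trials_per_song - center) <= 0:
            raise ConfigurationError("novel_slope_pct too steep: mean profile crosses zero inside the window")
        if self.noise_cv < 0:
            raise ConfigurationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.amplitude_log_sd < 0:
            raise ConfigurationError(f"amplitude_log_sd must be >= 0, got {self.amplitude_log_sd}")
        if not 0 <= self.fast_phase_drop_frac:
            raise ConfigurationError(f"fast_phase_drop_frac must be >= 0, got {self.fast_phase_drop_frac}")
        for cell, r in self.fi_true.items():
            if len(cell) != 3:
                raise ConfigurationError(f"fi_true key {cell!r} is not (group, hemisphere, region)")
            g, h, reg = cell
            if g not in self.n_birds_per_group:
                raise ConfigurationError(f"fi_true: unknown group {g!r}")
            if h not in HEMISPHERES:
                raise ConfigurationError(f"fi_true: unknown hemisphere {h!r}")
            if reg not in REGIONS:
                raise ConfigurationError(f"fi_true: unknown region {reg!r}")
            if not r > 0:
                raise ConfigurationError(f"fi_true[{cell!r}] must be > 0, got {r}")
        if int(self.seed) < 0:
            raise ConfigurationError(f"seed must be a nonnegative integer, got {self.seed}")

    @property
    def regions(self) -> dict[str, int]:
        out = {}
        if self.electrodes_per_hemisphere_ncm:
            out["NCM"] = int(self.electrodes_per_hemisphere_ncm)
        if self.electrodes_per_hemisphere_nonncm:
            out["nonNCM"] = int(self.electrodes_per_hemisphere_nonncm)
        return out

    def fi_for(self, group: str, hemisphere: str, region: str) -> float:
        return float(self.fi_true.get((group, hemisphere, region), 1.0))

    def to_dict(self) -> dict:
        d = {
            "n_birds_per_group": dict(self.n_birds_per_group),
            "fi_true": {"/".join(k): v for k, v in self.fi_true.items()},
        }
        for name in ("electrodes_per_hemisphere_ncm", "electrodes_per_hemisphere_nonncm",
                     "n_test_sets", "familiar_per_set", "novel_per_set", "trials_per_song",
                     "amplitude_log_mean", "amplitude_log_sd", "novel_slope_pct",
                     "fast_phase_drop_frac", "noise_cv", "seed"):
            d[name] = getattr(self, name)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        fi = {tuple(k.split("/")): float(v) for k, v in d.pop("fi_true", {}).items()}
        return cls(fi_true=fi, **d)


def _site_key(bird: str, hemisphere: str, region: str, site: int) -> str:
    return f"{bird}|{hemisphere}|{region}|{site}"


def _series_key(bird: str, hemisphere: str, region: str, site: int, set_: int, stim: str) -> str:
    return f"{bird}|{hemisphere}|{region}|{site}|{set_}|{stim}"


@dataclass
class GroundTruth:
    """True generative parameters of a synthetic cohort.

    ``site_amplitudes`` is keyed by ``bird|hemisphere|region|site``;
    ``slopes_pct`` and ``slopes_mag`` (percent per trial and magnitude units
    per trial over the linear window) by ``...|set|stimulus``; ``fi_true``
    by ``group|hemisphere|region``. At ``noise_cv = 0`` the OLS slope of
    every generated series over the linear window equals ``slopes_mag``
    exactly and the downstream FI of every familiar song equals ``fi_true``
    for its cell.
    """

    site_amplitudes: dict[str, float]
    slopes_pct: dict[str, float]
    slopes_mag: dict[str, float]
    fi_true: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _site_rng(config: CohortConfig, gi: int, bi: int, hi: int, ri: int, si: int) -> np.random.Generator:
    # Keyed substream: stable under cohort enlargement in any dimension.
    return np.random.default_rng([int(config.seed), gi, bi, hi, ri, si])


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one cohort; returns the tidy trial table and its ground truth.

    The table has one row per (bird, hemisphere, region, site, set,
    stimulus, trial) with columns :data:`TRIAL_COLUMNS`. Identical
    ``config`` (including ``seed``) yields a bit-identical table.
    """
    T = config.trials_per_song
    trials = np.arange(1, T + 1)
    center = (6 + T) / 2.0  # anchor so the normalized slope equals the configured rate exactly
    fast = np.where(
        trials <= FAST_PHASE_TRIALS,
        config.fast_phase_drop_frac * FAST_PHASE_DECAY ** (trials - 1), 0.0)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2)) if config.noise_cv > 0 else 0.0

    stim_names = ([f"F{j+1}" for j in range(config.familiar_per_set)]
                  + [f"N{j+1}" for j in range(config.novel_per_set)])
    stim_classes = ["F"] * config.familiar_per_set + ["N"] * config.novel_per_set
    n_stim = len(stim_names)
    regions = config.regions

    gt = GroundTruth({}, {}, {}, {f"{g}|{h}|{r}": config.fi_for(g, h, r)
                                  for g in config.n_birds_per_group
                                  for h in HEMISPHERES for r in regions},
                     int(config.seed))

    frames = []
    for gi, (group, n_birds) in enumerate(config.n_birds_per_group.items()):
        for bi in range(int(n_birds)):
            bird = f"{group}_b{bi+1:02d}"
            for hi, hemi in enumerate(HEMISPHERES):
                for ri, (region, n_sites) in enumerate(regions.items()):
                    fi = config.fi_for(group, hemi, region)
                    slopes = np.array([
                        config.novel_slope_pct / fi if cls == "F" else config.novel_slope_pct
                        for cls in stim_classes])
                    for si in range(n_sites):
                        rng = _site_rng(config, gi, bi, hi, ri, si)
                        amp = float(rng.lognormal(config.amplitude_log_mean, config.amplitude_log_sd))
                        gt.site_amplitudes[_site_key(bird, hemi, region, si + 1)] = amp
                        # mean profile per stimulus: linear + truncated fast phase
                        mu = amp * (1.0 + slopes[:, None] / 100.0 * (trials - center) + fast)
                        if sigma > 0:
                            eps = rng.lognormal(-sigma * sigma / 2.0, sigma,
                                                size=(config.n_test_sets, n_stim, T))
                            mags = mu[None, :, :] * eps
                        else:
                            mags = np.broadcast_to(mu, (config.n_test_sets, n_stim, T)).copy()
                        for k in range(config.n_test_sets):
                            for j, stim in enumerate(stim_names):
                                key = _series_key(bird, hemi, region, si + 1, k + 1, stim)
                                gt.slopes_pct[key] = float(slopes[j])
                                gt.slopes_mag[key] = float(amp * slopes[j] / 100.0)
                        frames.append(pd.DataFrame({
                            "bird": bird, "group": group, "hemisphere": hemi,
                            "region": region, "site": si + 1,
                            "set": np.repeat(np.arange(1, config.n_test_sets + 1), n_stim * T),
                            "stimulus": np.tile(np.repeat(stim_names, T), config.n_test_sets),
                            "stim_class": np.tile(np.repeat(stim_classes, T), config.n_test_sets),
                            "trial": np.tile(trials, config.n_test_sets * n_stim),
                            "magnitude": mags.reshape(-1),
                        }))
    table = pd.concat(frames, ignore_index=True)
    return table, gt


def generate_epochs(series: ResponseSeries, sampling_rate: float = 25_000.0,
                    stim_window: tuple[float, float] = (0.5, 1.5),
                    baseline_window: tuple[float, float] = (0.0, 0.5),
                    seed: int = 0, noise_sd: float = 0.0) -> list[Epoch]:
    """Synthesize one raw voltage epoch per trial of a response series.

    Each epoch is Gaussian baseline noise of standard deviation ``noise_sd``
    everywhere, with the stimulus-window samples rescaled so their sample RMS
    is exactly ``magnitude + noise_sd``. Baseline-subtracted RMS extraction
    therefore recovers the series magnitudes up to the sampling fluctuation
    of the baseline-window RMS, which is O(noise_sd / sqrt(2 n_baseline));
    at ``noise_sd = 0`` recovery is exact to rounding.
    """
    if not sampling_rate > 0:
        raise ConfigurationError(f"sampling_rate must be positive, got {sampling_rate}")
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd}")
    for name, (a, b) in (("stim_window", stim_window), ("baseline_window", baseline_window)):
        if not b > a or a < 0:
            raise ConfigurationError(f"{name} must be a positive-duration interval, got {a}..{b}")
    lo, hi = sorted([stim_window, baseline_window])
    if hi[0] < lo[1]:
        raise ConfigurationError("stim_window and baseline_window overlap")

    duration = max(stim_window[1], baseline_window[1])
    n = int(round(duration * sampling_rate))
    i0 = int(round(stim_window[0] * sampling_rate))
    i1 = int(round(stim_window[1] * sampling_rate))
    rng = np.random.default_rng([int(seed), 0x5eed])
    epochs = []
    for mag in series.magnitudes:
        x = rng.standard_normal(n) * noise_sd if noise_sd > 0 else np.zeros(n)
        evoked = rng.standard_normal(i1 - i0)
        target = mag + noise_sd
        seg = x[i0:i1] + evoked  # evoked power on top of the noise floor
        seg = seg - seg.mean()
        rms = np.sqrt(np.mean(seg * seg))
        x[i0:i1] = seg * (target / rms) if rms > 0 else target
        epochs.append(Epoch(x, sampling_rate, stim_window, baseline_window))
    return epochs


def generate_qpcr(fold_changes: Mapping[tuple[str, str, str, str], float] | None = None,
                  n_per_cell: int | Mapping[str, int] | None = None,
                  seed: int = 0,
                  groups: tuple[str, ...] = ("hdac3i", "vehicle"),
                  regions: tuple[str, ...] = ("NCM", "AP"),
                  genes: tuple[str, ...] = ("zenk", "cfos"),
                  housekeeping_gene: str = "18s",
                  base_ct: Mapping[str, float] | None = None,
                  noise_sd: float = 0.25) -> pd.DataFrame:
    """Simulate a qPCR CT table (columns bird, group, hemisphere, region, gene, ct).

    The design this emulates samples left and right NCM from 5 drug and 5
    vehicle birds 30 min after limited song exposure, plus the anterior pole
    (AP, an auditory-uninvolved control region) from a 3-bird subset of each
    group, assaying the immediate early genes *zenk* and *c-fos* against the
    *18s* housekeeping gene.

    ``fold_changes`` maps (group, hemisphere, region, gene) to a true
    expression fold-change relative to baseline; unlisted cells are 1.0.
    Target CT = base CT - log2(fold-change) + N(0, noise_sd); housekeeping CT
    is independent of group. ``n_per_cell`` may be an int or a mapping from
    region to bird count (default ``{"NCM": 5, "AP": 3}``).
    """
    fold_changes = dict(fold_changes or {})
    for key, f in fold_changes.items():
        if len(key) != 4:
            raise ConfigurationError(f"fold_changes key {key!r} is not (group, hemisphere, region, gene)")
        if not f > 0:
            raise ConfigurationError(f"fold_changes[{key!r}] must be > 0, got {f}")
    if n_per_cell is None:
        n_per_cell = {"NCM": 5, "AP": 3}
    if isinstance(n_per_cell, int):
        n_per_cell = {r: n_per_cell for r in regions}
    base = dict(base_ct or {})
    base.setdefault(housekeeping_gene, 12.0)
    for g in genes:
        base.setdefault(g, 24.0)
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd}")

    rows = []
    for gi, group in enumerate(groups):
        n_birds = max(int(n_per_cell.get(r, 0)) for r in regions)
        for bi in range(n_birds):
            bird = f"{group}_q{bi+1:02d}"
            rng = np.random.default_rng([int(seed), 0x9bc, gi, bi])
            for hemi in HEMISPHERES:
                for region in regions:
                    if bi >= int(n_per_cell.get(region, 0)):
                        continue
                    for gene in (*genes, housekeeping_gene):
                        fold = 1.0 if gene == housekeeping_gene else \
                            fold_changes.get((group, hemi, region, gene), 1.0)
                        ct = base[gene] - math.log2(fold)
                        if noise_sd > 0:
                            ct += rng.normal(0.0, noise_sd)
                        rows.append((bird, group, hemi, region, gene, ct))
    return pd.DataFrame(rows, columns=["bird", "group", "hemisphere", "region", "gene", "ct"])
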