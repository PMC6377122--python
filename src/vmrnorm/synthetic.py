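"""Simulated plate-based visual-motor-response datasets with known truth.

The generator reproduces every systematic effect the normalization models
remove, on the activity scale the assay produces (Burst Duration in
[0, 1]):

* a radial light gradient across the 96-well plate — wells at the centre
  receive more stimulus light than corner wells;
* an additive activity response to light intensity (per W/m^2 slope);
* additive per-batch (biological replicate) shifts, summing to zero;
* per-group baseline activity levels;
* a stimulus-locked response: an activity peak at the first post-change
  second decaying exponentially;
* additive Gaussian noise, clamping to [0, 1], and optional zero-inflation
  (larvae that do not move within a second score exactly zero).

Default magnitudes match the scale of real recordings: baselines near
0.01, a light slope near -2e-4 per W/m^2, batch shifts near +/-1.6e-3.
Every draw is reproducible from the seed, and the returned
:class:`SimTruth` carries enough to compute the generating value of every
fitted coefficient (including how often clamping fired, so recovery checks
can restrict themselves to unclamped regimes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .plate_data import (
    DEFAULT_BASELINE_WINDOW,
    N_WELLS,
    all_wells,
    light_map_from_array,
    validate_light_map,
)

__all__ = [
    "GroupSpec",
    "SimConfig",
    "SimTruth",
    "simulate_light_map",
    "simulate_experiment",
    "DEFAULT_GROUPS",
]


@dataclass(frozen=True)
class GroupSpec:
    """Ground-truth behavioural profile of one strain x stage group."""

    strain: str
    stage_dpf: int
    baseline: float          # mean pre-stimulus Burst Duration
    peak: float              # response magnitude at t = 1
    decay: float             # exponential decay rate of the response (1/s)


#: Three developmental stages of one wild-type strain: 6 dpf larvae show the
#: highest baseline and the strongest light-onset response, 3 dpf larvae
#: barely respond.
DEFAULT_GROUPS = (
    GroupSpec("TL", 3, baseline=0.008, peak=0.05, decay=0.5),
    GroupSpec("TL", 6, baseline=0.015, peak=0.25, decay=0.8),
    GroupSpec("TL", 9, baseline=0.010, peak=0.15, decay=0.6),
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults define the standard study design.

    ``n_larvae`` is per group per batch; two batches of 48 give the usual
    96 larvae per group. ``light_center``/``light_edge`` are the W/m^2
    intensities at the plate centre and corners, interpolated linearly in
    the distance from the centre. ``batch_shifts`` defaults to a zero-sum
    pattern of magnitude 1.6e-3.
    """

    groups: tuple = DEFAULT_GROUPS
    n_batches: int = 2
    n_larvae: int = 48
    n_trials: int = 1
    stimulus: str = "LightOn"
    light_slope: float = -2e-4
    batch_shifts: tuple | None = None
    light_center: float = 30.0
    light_edge: float = 20.0
    noise_sd: float = 5e-4
    zero_inflation: float = 0.0
    t_range: tuple = (-30, 30)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.n_batches < 1 or self.n_larvae < 1 or self.n_trials < 1:
            raise ValueError("n_batches, n_larvae and n_trials must be >= 1")
        if self.n_larvae > N_WELLS:
            raise ValueError(f"n_larvae per plate cannot exceed {N_WELLS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def resolved_batch_shifts(self) -> np.ndarray:
        if self.batch_shifts is not None:
            shifts = np.asarray(self.batch_shifts, dtype=float)
            if len(shifts) != self.n_batches:
                raise ValueError("batch_shifts length must equal n_batches")
            return shifts
        if self.n_batches == 1:
            return np.zeros(1)
        # zero-sum ramp scaled so the extreme shifts are +/-1.6e-3
        ramp = np.linspace(-1.0, 1.0, self.n_batches)
        return 1.6e-3 * ramp


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    light_map: pd.Series
    light_slope: float
    batch_shifts: dict                 # batch label -> shift
    group_params: pd.DataFrame         # strain, stage_dpf, baseline, peak, decay
    assignments: pd.DataFrame          # larva_id, well, batch, strain, stage_dpf
    mean_activity: np.ndarray          # noiseless mean, aligned with the table
    n_clamped: int
    n_zeroed: int

    def true_batch_effects(self) -> dict:
        """Sum-to-zero batch effects implied by the generating shifts."""
        shifts = np.array(list(self.batch_shifts.values()))
        centered = shifts - shifts.mean()
        return dict(zip(self.batch_shifts.keys(), centered))

    def true_baseline_mean(self, spec: GroupSpec,
                           window=DEFAULT_BASELINE_WINDOW) -> float:
        """Expected baseline-window mean for a group (pre-noise, pre-clamp)."""
        mean_i = float(self.light_map.mean())
        mean_shift = float(np.mean(list(self.batch_shifts.values())))
        return spec.baseline + self.light_slope * mean_i + mean_shift


def simulate_light_map(center: float = 30.0, edge: float = 20.0) -> pd.Series:
    """Radial light map: intensity falls linearly with distance from the
    plate centre, from ``center`` at distance 0 to ``edge`` at the corners."""
    if center < edge or edge < 0:
        raise ValueError("require center >= edge >= 0")
    rows = np.arange(8)[:, None]
    cols = np.arange(12)[None, :]
    d = np.hypot(rows - 3.5, cols - 5.5)
    frac = d / d.max()
    grid = center - (center - edge) * frac
    return light_map_from_array(grid)


def simulate_experiment(config: SimConfig = SimConfig(),
                        seed: int | None = None):
    """Draw one full experiment.

    Returns ``(table, light_map, truth)`` where ``table`` is a valid raw
    activity table (one row per larva x trial x second), ``light_map`` the
    per-well intensities and ``truth`` the generating parameters.

    Per record the noiseless mean is::

        baseline_g + slope * I_well + shift_batch
            + peak_g * exp(-decay_g * (t - 1)) * 1[t >= 1]

    to which Gaussian noise is added; the sum is clamped to [0, 1] and then
    zeroed with probability ``zero_inflation``.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    lm = simulate_light_map(config.light_center, config.light_edge)
    wells = np.array([str(w) for w in all_wells()])
    shifts = config.resolved_batch_shifts()
    batch_labels = [f"R{k + 1}" for k in range(config.n_batches)]
    t_vals = np.arange(config.t_range[0], config.t_range[1] + 1)
    n_t = len(t_vals)

    frames = []
    assign_rows = []
    means = []
    # one loading pattern shared by all plates: real experiments fill every
    # plate the same way, which keeps batch and group balanced over the
    # light gradient
    plate_order = rng.permutation(N_WELLS)[:config.n_larvae]
    for spec in config.groups:
        resp = spec.peak * np.exp(-spec.decay * (t_vals - 1)) * (t_vals >= 1)
        for k, blab in enumerate(batch_labels):
            # each group x batch occupies its own plate
            larva_wells = wells[plate_order]
            intens = lm.loc[larva_wells].to_numpy()
            lids = np.array([
                f"{spec.strain}-{spec.stage_dpf}dpf-{blab}-L{i + 1:03d}"
                for i in range(config.n_larvae)])
            assign_rows.extend(
                (lids[i], larva_wells[i], blab, spec.strain, spec.stage_dpf)
                for i in range(config.n_larvae))
            base = spec.baseline + config.light_slope * intens + shifts[k]
            mu = base[:, None] + resp[None, :]      # larvae x seconds
            n_rep = config.n_trials * n_t
            frames.append(pd.DataFrame({
                "larva_id": np.repeat(lids, n_rep),
                "well": np.repeat(larva_wells, n_rep),
                "strain": spec.strain,
                "stage_dpf": spec.stage_dpf,
                "batch": blab,
                "trial": np.tile(np.repeat(
                    np.arange(1, config.n_trials + 1), n_t),
                    config.n_larvae),
                "stimulus": config.stimulus,
                "t": np.tile(t_vals, config.n_trials * config.n_larvae),
                "activity": np.repeat(mu, config.n_trials, axis=0).reshape(-1),
            }))
            means.append(np.repeat(mu, config.n_trials, axis=0).reshape(-1))

    table = pd.concat(frames, ignore_index=True)
    mean_activity = np.concatenate(means)
    noisy = mean_activity + rng.normal(0.0, config.noise_sd,
                                       size=len(mean_activity))
    clamped = np.clip(noisy, 0.0, 1.0)
    n_clamped = int(np.count_nonzero(clamped != noisy))
    if config.zero_inflation > 0:
        zero_mask = rng.random(len(clamped)) < config.zero_inflation
        clamped = np.where(zero_mask, 0.0, clamped)
        n_zeroed = int(zero_mask.sum())
    else:
        n_zeroed = 0
    table["activity"] = clamped
    table.attrs["provenance"] = [f"simulate_experiment(seed={config.seed})"]

    truth = SimTruth(
        config=config,
        light_map=validate_light_map(lm),
        light_slope=config.light_slope,
        batch_shifts=dict(zip(batch_labels, shifts.tolist())),
        group_params=pd.DataFrame(
            [(g.strain, g.stage_dpf, g.baseline, g.peak, g.decay)
             for g in config.groups],
            columns=["strain", "stage_dpf", "baseline", "peak", "decay"]),
        assignments=pd.DataFrame(
            assign_rows,
            columns=["larva_id", "well", "batch", "strain", "stage_dpf"]),
        mean_activity=mean_activity,
        n_clamped=n_clamped,
        n_zeroed=n_zeroed,
    )
    return table, lm, truth
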