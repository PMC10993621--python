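"""Synthetic microglia cohorts with fully known ground truth.

The simulator emulates the statistical structure of a chronic two-photon
imaging study of cortical microglia: per session it produces a wide-field
binary "population" image (for soma counting, spacing and displacement) and an
hour-long 12-frame binary time-lapse (for process dynamics), for two groups of
animals over an ordered session list, with programmed cell loss/gain
schedules, session-to-session soma drift, and per-frame process-pixel
turnover. Every quantity the analysis pipeline measures has a recorded ground
truth, so the pipeline is validated by parameter recovery rather than by real
data.

Generative model, in brief:

* Somas are placed by hard-core rejection sampling (all pairwise distances at
  least ``min_soma_separation_um``), emulating microglial territorial spacing.
* Each cell is a filled soma disk plus ``n_branches_per_cell`` process paths
  of length ``branch_length_um`` grown from the soma edge; with
  ``branch_tortuosity = 0`` the paths are straight rays at equally spaced
  angles, otherwise the heading diffuses along the path.
* Process turnover: the rendered branch pixels form a fixed scaffold; a
  constant-size random subset (``active_fraction`` of the scaffold) is "on"
  in each frame. Between frames each active pixel is dropped with probability
  ``turnover_prob`` and the same number of pixels is redrawn uniformly from
  scaffold pixels that were not active, so the per-frame positive area is
  exactly constant. Soma pixels are always on. For this rule the expected
  motility index is ``2 p A / (S + (1 - p) A)`` with ``S`` soma pixels and
  ``A`` active process pixels; this closed form is recorded in the ground
  truth as the recovery target.
* Across sessions surviving somas drift from their baseline anchor by an
  isotropic Gaussian displacement of scale ``soma_drift_sigma_um``; scheduled
  fractions of baseline cells are removed (lost) or added (gained).
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk as draw_disk
from skimage.filters import gaussian as gaussian_filter

from .segment import SomaRecord, TimeLapse

DEFAULT_SESSIONS: tuple[str, ...] = (
    "Baseline", "Day0", "Day1", "Week1", "Week2", "Week3", "Week4",
)


class CapacityError(RuntimeError):
    """Requested soma density cannot be packed at the required separation."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated field (population image or time-lapse).

    Defaults describe the dynamics acquisition: a 512x512 px field at
    0.25 um/px (128 um across, the high-zoom field used for hour-long
    time-lapses), ~15 microglia with ~3.5 um soma radius, six tortuous
    processes of ~25 um per cell, and 12 frames at 5-minute intervals.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.25
    n_cells: int = 15
    soma_radius_um: float = 3.5
    n_branches_per_cell: int = 6
    branch_length_um: float = 25.0
    branch_tortuosity: float = 0.3
    active_fraction: float = 0.6
    turnover_prob: float = 0.1
    n_frames: int = 12
    frame_interval_min: float = 5.0
    soma_drift_sigma_um: float = 3.0
    loss_schedule: Mapping[str, float] = field(default_factory=dict)
    gain_schedule: Mapping[str, float] = field(default_factory=dict)
    min_soma_separation_um: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 8 or w < 8:
            raise ValueError("field_size_px too small")
        for name in ("pixel_size_um", "soma_radius_um", "branch_length_um",
                     "frame_interval_min", "min_soma_separation_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("branch_tortuosity", "turnover_prob", "active_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for sched in (self.loss_schedule, self.gain_schedule):
            for s, f_ in sched.items():
                if not 0 <= f_ <= 1:
                    raise ValueError(f"schedule fraction for {s!r} outside [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.min_soma_separation_um < 2 * self.soma_radius_um:
            raise ValueError("min_soma_separation_um must be >= 2 * soma_radius_um")
        if self.soma_drift_sigma_um < 0:
            raise ValueError("soma_drift_sigma_um must be non-negative")
        if self.n_cells < 0 or self.n_branches_per_cell < 0:
            raise ValueError("counts must be non-negative")

    @property
    def field_size_um(self) -> tuple[float, float]:
        h, w = self.field_size_px
        return (h * self.pixel_size_um, w * self.pixel_size_um)


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline should recover."""

    soma_positions_by_session: dict[str, SomaRecord] = field(default_factory=dict)
    lost_labels: dict[str, list[int]] = field(default_factory=dict)
    gained_labels: dict[str, list[int]] = field(default_factory=dict)
    per_frame_pixel_counts: list[int] | None = None
    target_metrics: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for s in self.lost_labels:
            both = set(self.lost_labels[s]) & set(self.gained_labels.get(s, []))
            if both:
                raise ValueError(f"labels {sorted(both)} both lost and gained in {s!r}")


def place_somas(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_cells: int | None = None,
    margin_um: float | None = None,
    exclude_um: np.ndarray | None = None,
) -> np.ndarray:
    """Hard-core placement of soma centers; returns (n, 2) (x_um, y_um).

    Rejection sampling with bounded retries: each candidate is uniform in the
    field (inset by ``margin_um``, default the soma radius so disks fit) and
    kept if at least ``min_soma_separation_um`` from all accepted centers and
    from ``exclude_um`` positions. Deterministic under a fixed generator.

    Raises
    ------
    CapacityError
        If the requested count cannot be packed; the message names the
        achievable count at this separation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_cells if n_cells is None else n_cells
    margin = config.soma_radius_um if margin_um is None else margin_um
    h_um, w_um = config.field_size_um
    if w_um - 2 * margin <= 0 or h_um - 2 * margin <= 0:
        raise CapacityError("field smaller than twice the placement margin")
    sep2 = config.min_soma_separation_um**2
    taken = [] if exclude_um is None else [np.asarray(p, float) for p in exclude_um]
    n_excl = len(taken)
    placed = 0
    max_attempts = max(2000, 500 * n)
    attempts = 0
    while placed < n and attempts < max_attempts:
        attempts += 1
        cand = np.array([
            rng.uniform(margin, w_um - margin),
            rng.uniform(margin, h_um - margin),
        ])
        if all(np.sum((cand - p) ** 2) >= sep2 for p in taken):
            taken.append(cand)
            placed += 1
    if placed < n:
        raise CapacityError(
            f"placed only {placed} of {n} somas at separation >= "
            f"{config.min_soma_separation_um} um in a "
            f"{w_um:.0f} x {h_um:.0f} um field; reduce n_cells or the separation"
        )
    return np.array(taken[n_excl:], dtype=float).reshape(-1, 2)


def _branch_heading_offsets(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Equally spaced base headings; randomly rotated only when tortuous."""
    k = config.n_branches_per_cell
    base = 2 * np.pi * np.arange(k) / max(k, 1)
    if config.branch_tortuosity > 0 and k:
        base = base + rng.uniform(0, 2 * np.pi)
    return base


def _render_cell_parts(
    center_um: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell; returns flat pixel indices of (soma, branch) pixels.

    Branches are grown from the soma edge in steps of one pixel; the heading
    random-walks with a per-step angular scale proportional to
    ``branch_tortuosity``. Pixels outside the field are clipped.
    """
    h, w = config.field_size_px
    psz = config.pixel_size_um
    cx, cy = center_um / psz  # pixel coordinates (col, row)
    r_px = config.soma_radius_um / psz
    rr, cc = draw_disk((cy, cx), r_px, shape=(h, w))
    soma_idx = rr * w + cc

    step_px = 1.0
    n_steps = int(round(config.branch_length_um / psz / step_px))
    sigma = 0.25 * config.branch_tortuosity  # radians per pixel of path
    branch_pix: list[np.ndarray] = []
    for theta0 in _branch_heading_offsets(config, rng):
        # start just inside the soma rim so the path connects to the disk
        r0 = max(r_px - 1.0, 0.0)
        x, y = cx + r0 * np.cos(theta0), cy + r0 * np.sin(theta0)
        theta = theta0
        if n_steps:
            dtheta = rng.normal(0.0, sigma, size=n_steps) if sigma > 0 else np.zeros(n_steps)
            xs = np.empty(n_steps)
            ys = np.empty(n_steps)
            for i in range(n_steps):
                theta += dtheta[i]
                x += step_px * np.cos(theta)
                y += step_px * np.sin(theta)
                xs[i] = x
                ys[i] = y
            col = np.round(xs).astype(int)
            row = np.round(ys).astype(int)
            ok = (row >= 0) & (row < h) & (col >= 0) & (col < w)
            branch_pix.append(row[ok] * w + col[ok])
    branch_idx = (np.unique(np.concatenate(branch_pix))
                  if branch_pix else np.empty(0, dtype=int))
    return np.unique(soma_idx), branch_idx


def render_cell(
    soma_um: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary mask (field-sized) of one cell: filled soma disk plus branches."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    h, w = config.field_size_px
    soma_idx, branch_idx = _render_cell_parts(np.asarray(soma_um, float), config, rng)
    mask = np.zeros(h * w, dtype=np.uint8)
    mask[soma_idx] = 1
    mask[branch_idx] = 1
    return mask.reshape(h, w)


def _render_field(
    centers_um: np.ndarray,
    config: SimulationConfig,
    cell_rngs: Sequence[np.random.Generator],
) -> tuple[np.ndarray, np.ndarray]:
    """Union soma mask and process scaffold (branches minus somas), flat bool."""
    h, w = config.field_size_px
    soma = np.zeros(h * w, dtype=bool)
    branch = np.zeros(h * w, dtype=bool)
    for center, rng in zip(centers_um, cell_rngs):
        s_idx, b_idx = _render_cell_parts(np.asarray(center, float), config, rng)
        soma[s_idx] = True
        branch[b_idx] = True
    return soma, branch & ~soma


def _motility_target(s_px: int, a_px: int, p: float) -> float:
    denom = s_px + (1.0 - p) * a_px
    return float("nan") if denom == 0 else 2.0 * p * a_px / denom


def _surveillance_target(s_px: int, m_px: int, a_px: int, p: float,
                         n_frames: int, n_total: int) -> float:
    """Approximate expected union coverage (%, independence approximation)."""
    if m_px == 0 or a_px == 0:
        return 100.0 * (s_px + a_px) / n_total
    f = a_px / m_px
    q = min(1.0, p * a_px / max(m_px - a_px, 1))
    never = (1.0 - f) * (1.0 - q) ** (n_frames - 1)
    return 100.0 * (s_px + m_px * (1.0 - never)) / n_total


def _simulate_turnover_frames(
    soma: np.ndarray,
    scaffold: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    turnover_prob: float | None = None,
) -> tuple[np.ndarray, int, int]:
    """Run the drop/replace process; returns (frames (t,h,w) uint8, S, A)."""
    p = config.turnover_prob if turnover_prob is None else turnover_prob
    h, w = config.field_size_px
    scaffold_idx = np.flatnonzero(scaffold)
    m = scaffold_idx.size
    a = int(round(config.active_fraction * m))
    if m and p * a > (m - a):
        raise ValueError(
            "active_fraction too high for this turnover_prob: replacement "
            "needs active_fraction * turnover_prob <= 1 - active_fraction"
        )
    active = np.zeros(m, dtype=bool)
    if a:
        active[rng.choice(m, size=a, replace=False)] = True
    frames = np.empty((config.n_frames, h * w), dtype=np.uint8)
    for t in range(config.n_frames):
        frame = soma.copy()
        frame[scaffold_idx[active]] = True
        frames[t] = frame.view(np.uint8)
        if t == config.n_frames - 1:
            break
        drop = active & (rng.random(m) < p)
        n_drop = int(drop.sum())
        candidates = np.flatnonzero(~active)
        if n_drop > candidates.size:  # cannot happen under the validated config
            keep = np.flatnonzero(drop)[: n_drop - candidates.size]
            drop[keep] = False
            n_drop = candidates.size
        new = rng.choice(candidates, size=n_drop, replace=False) if n_drop else []
        active &= ~drop
        active[new] = True
    return frames.reshape(config.n_frames, h, w), int(soma.sum()), a


def simulate_timelapse(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    record_pixels: bool = False,
) -> tuple[TimeLapse, GroundTruth]:
    """Simulate one hour-long binary time-lapse of a microglia field.

    Returns the stack together with a :class:`GroundTruth` whose
    ``target_metrics`` record the analytic expectations for coverage,
    surveillance (independence approximation) and the motility index under
    the drop/replace turnover rule (see the module docstring for the closed
    form).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    centers = place_somas(config, rng)
    cell_rngs = [rng] * len(centers)
    soma, scaffold = _render_field(centers, config, cell_rngs)
    frames, s_px, a_px = _simulate_turnover_frames(soma, scaffold, config, rng)
    n_total = frames.shape[1] * frames.shape[2]
    stack = TimeLapse(
        frames=frames,
        pixel_size_um=config.pixel_size_um,
        timestamps_min=np.arange(config.n_frames) * config.frame_interval_min,
        binary=True,
    )
    gt = GroundTruth(
        soma_positions_by_session={
            "T0": SomaRecord("T0", np.arange(1, len(centers) + 1), centers,
                             pixel_size_um=config.pixel_size_um)
        },
        per_frame_pixel_counts=[int(f.sum()) for f in frames] if record_pixels else None,
        target_metrics={
            "soma_px": float(s_px),
            "process_px": float(a_px),
            "scaffold_px": float(scaffold.sum()),
            "coverage_pct": 100.0 * (s_px + a_px) / n_total,
            "surveillance_pct": _surveillance_target(
                s_px, int(scaffold.sum()), a_px, config.turnover_prob,
                config.n_frames, n_total),
            "motility": _motility_target(s_px, a_px, config.turnover_prob),
        },
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class GroupConfig:
    """Study design for one experimental group.

    ``population`` configures the wide soma-analysis field (its loss/gain
    schedules and drift apply to the cohort); ``timelapse`` configures the
    high-zoom dynamics field. ``coverage_scale`` and ``turnover_scale`` are
    per-session multipliers on the number of cells rendered in the time-lapse
    field and on its turnover probability — the knobs that program group
    effects on coverage and process motility. Unlisted sessions default to 1.
    """

    n_animals: int
    population: SimulationConfig
    timelapse: SimulationConfig
    coverage_scale: Mapping[str, float] = field(default_factory=dict)
    turnover_scale: Mapping[str, float] = field(default_factory=dict)


def _cumulative_fraction(schedule: Mapping[str, float], sessions: Sequence[str]) -> dict[str, float]:
    """Carry scheduled fractions forward so they are cumulative per session."""
    out: dict[str, float] = {}
    current = 0.0
    for s in sessions:
        if s in schedule:
            if schedule[s] < current - 1e-12:
                raise ValueError(f"schedule must be non-decreasing; {s!r} goes backwards")
            current = schedule[s]
        out[s] = current
    return out


def _simulate_animal_population(
    config: SimulationConfig,
    sessions: Sequence[str],
    rng: np.random.Generator,
) -> tuple[dict[str, SomaRecord], dict[str, list[int]], dict[str, list[int]]]:
    """Per-session labeled soma positions with programmed loss/gain and drift.

    Surviving cells drift from their baseline anchor by an independent
    isotropic Gaussian per session (so baseline-referenced displacement is
    N(0, sigma^2 I) regardless of the session gap). Gained cells are placed in
    territory unoccupied at baseline, so they cannot masquerade as returned
    lost cells.
    """
    sigma = config.soma_drift_sigma_um
    margin = config.soma_radius_um + 3.0 * sigma + 1.0
    baseline = place_somas(config, rng, margin_um=margin)
    n0 = len(baseline)
    loss = _cumulative_fraction(config.loss_schedule, sessions)
    gain = _cumulative_fraction(config.gain_schedule, sessions)
    if sessions and (loss[sessions[0]] or gain[sessions[0]]):
        raise ValueError("baseline session cannot schedule loss or gain")

    anchors: dict[int, np.ndarray] = {i + 1: baseline[i] for i in range(n0)}
    alive: list[int] = list(anchors)
    lost_so_far: list[int] = []
    gained_so_far: list[int] = []
    next_label = n0 + 1
    records: dict[str, SomaRecord] = {}
    lost_by_session: dict[str, list[int]] = {}
    gained_by_session: dict[str, list[int]] = {}
    h_um, w_um = config.field_size_um

    for s in sessions:
        n_lost_target = int(round(loss[s] * n0))
        n_gain_target = int(round(gain[s] * n0))
        baseline_alive = [l for l in alive if l <= n0]
        to_remove = n_lost_target - len(lost_so_far)
        if to_remove > len(baseline_alive):
            raise ValueError(
                f"loss schedule at {s!r} removes more cells than exist "
                f"({n_lost_target} of {n0} baseline cells, {len(baseline_alive)} alive)"
            )
        if to_remove > 0:
            removed = rng.choice(baseline_alive, size=to_remove, replace=False)
            for l in removed:
                alive.remove(int(l))
                lost_so_far.append(int(l))
        to_add = n_gain_target - len(gained_so_far)
        if to_add > 0:
            occupied = np.array([anchors[l] for l in anchors], dtype=float)
            new_pos = place_somas(config, rng, n_cells=to_add, margin_um=margin,
                                  exclude_um=occupied)
            for p in new_pos:
                anchors[next_label] = p
                alive.append(next_label)
                gained_so_far.append(next_label)
                next_label += 1

        labels = np.array(sorted(alive), dtype=int)
        pos = np.array([anchors[l] for l in labels], dtype=float)
        if s != sessions[0] and sigma > 0:
            pos = pos + rng.normal(0.0, sigma, size=pos.shape)
            pos[:, 0] = np.clip(pos[:, 0], margin / 2, w_um - margin / 2)
            pos[:, 1] = np.clip(pos[:, 1], margin / 2, h_um - margin / 2)
        records[s] = SomaRecord(s, labels, pos, pixel_size_um=config.pixel_size_um)
        lost_by_session[s] = sorted(lost_so_far)
        gained_by_session[s] = sorted(gained_so_far)
    return records, lost_by_session, gained_by_session


def _to_grayscale(mask: np.ndarray, rng: np.random.Generator,
                  sigma_px: float = 1.0, photons: float = 800.0,
                  background: float = 30.0) -> np.ndarray:
    """Optional imaging forward model: PSF blur plus Poisson shot noise."""
    blurred = gaussian_filter(mask.astype(float), sigma=sigma_px, preserve_range=True)
    return rng.poisson(blurred * photons + background).astype(np.uint16)


def simulate_cohort(
    out_dir: str | Path,
    groups: Mapping[str, GroupConfig],
    sessions: Sequence[str] = DEFAULT_SESSIONS,
    grayscale: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Write a full synthetic cohort to disk and return (manifest, ground truth).

    Per animal and session one single-page population TIFF and one multi-page
    time-lapse TIFF are written, along with ``manifest.csv`` and
    ``ground_truth.json``. All randomness derives from each group's
    ``population.seed``, so identical configs give byte-identical cohorts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not sessions:
        raise ValueError("session list is empty")
    rows = []
    truth: dict = {"sessions": list(sessions), "animals": {}}
    for group_name, gc in groups.items():
        scale_max = max([1.0, *gc.coverage_scale.values()])
        n_tl_max = int(round(gc.timelapse.n_cells * scale_max))
        for i in range(gc.n_animals):
            animal = f"{group_name[:4]}{i + 1:02d}"
            ss = np.random.SeedSequence([gc.population.seed, i])
            rng_pop, rng_tl = [np.random.default_rng(c) for c in ss.spawn(2)]
            records, lost, gained = _simulate_animal_population(
                gc.population, sessions, rng_pop)
            # fixed per-animal time-lapse field; sessions render nested subsets
            tl_cfg = gc.timelapse
            tl_centers = place_somas(tl_cfg, rng_tl, n_cells=n_tl_max)
            cell_seeds = ss.spawn(n_tl_max)
            animal_truth = {"group": group_name, "population": {},
                            "timelapse_targets": {}}
            for s in sessions:
                rec = records[s]
                pop_mask = np.zeros(gc.population.field_size_px, dtype=np.uint8)
                cell_rng = np.random.default_rng(ss.spawn(1)[0])
                for label, center in zip(rec.labels, rec.xy_um):
                    pop_mask |= render_cell(
                        center, gc.population,
                        np.random.default_rng(
                            np.random.SeedSequence([gc.population.seed, i, int(label)])),
                    )
                n_eff = int(round(tl_cfg.n_cells * gc.coverage_scale.get(s, 1.0)))
                n_eff = min(n_eff, n_tl_max)
                p_eff = min(1.0, tl_cfg.turnover_prob * gc.turnover_scale.get(s, 1.0))
                soma, scaffold = _render_field(
                    tl_centers[:n_eff], tl_cfg,
                    [np.random.default_rng(c) for c in cell_seeds[:n_eff]])
                frames, s_px, a_px = _simulate_turnover_frames(
                    soma, scaffold, tl_cfg, rng_tl, turnover_prob=p_eff)
                n_total = frames.shape[1] * frames.shape[2]

                pop_path = out_dir / f"{animal}_{s}_population.tif"
                tl_path = out_dir / f"{animal}_{s}_timelapse.tif"
                if grayscale:
                    tifffile.imwrite(pop_path, _to_grayscale(pop_mask, cell_rng))
                    tifffile.imwrite(
                        tl_path,
                        np.stack([_to_grayscale(f, cell_rng) for f in frames]))
                else:
                    tifffile.imwrite(pop_path, pop_mask)
                    tifffile.imwrite(tl_path, frames)
                rows.append({
                    "animal_id": animal, "group": group_name, "session": s,
                    "path_population": pop_path.name,
                    "path_timelapse": tl_path.name,
                    "pixel_size_um_population": gc.population.pixel_size_um,
                    "pixel_size_um_timelapse": tl_cfg.pixel_size_um,
                })
                animal_truth["population"][s] = {
                    "labels": rec.labels.tolist(),
                    "x_um": rec.xy_um[:, 0].round(4).tolist(),
                    "y_um": rec.xy_um[:, 1].round(4).tolist(),
                    "lost": lost[s], "gained": gained[s],
                }
                animal_truth["timelapse_targets"][s] = {
                    "n_cells": n_eff,
                    "turnover_prob": p_eff,
                    "coverage_pct": 100.0 * (s_px + a_px) / n_total,
                    "surveillance_pct": _surveillance_target(
                        s_px, int(scaffold.sum()), a_px, p_eff,
                        tl_cfg.n_frames, n_total),
                    "motility": _motility_target(s_px, a_px, p_eff),
                }
            truth["animals"][animal] = animal_truth
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest, truth


def default_cohort_groups(
    n_per_group: int = 6,
    seed: int = 0,
    population: SimulationConfig | None = None,
    timelapse: SimulationConfig | None = None,
) -> dict[str, GroupConfig]:
    """The default two-group study design: controls vs an insult group.

    Controls have no programmed effects. The insult ("irradiated") group loses
    30% of baseline cells by the final session, its time-lapse coverage falls
    to 80% of baseline, and its process turnover doubles — each ramping in
    from the first week, emulating a delayed radiation response.
    """
    pop = population or SimulationConfig(
        field_size_px=(512, 512), pixel_size_um=1.0, n_cells=40,
        soma_radius_um=4.0, branch_length_um=25.0, n_branches_per_cell=6,
        min_soma_separation_um=25.0, soma_drift_sigma_um=3.0, seed=seed,
    )
    tl = timelapse or SimulationConfig(
        field_size_px=(512, 512), pixel_size_um=0.25, n_cells=20,
        soma_radius_um=3.5, branch_length_um=25.0, n_branches_per_cell=6,
        min_soma_separation_um=18.0, turnover_prob=0.1, seed=seed,
    )
    loss = {"Week1": 0.1, "Week2": 0.175, "Week3": 0.25, "Week4": 0.3}
    coverage = {"Week1": 0.95, "Week2": 0.9, "Week3": 0.85, "Week4": 0.8}
    turnover = {"Week1": 1.25, "Week2": 1.5, "Week3": 1.75, "Week4": 2.0}
    return {
        "control": GroupConfig(n_per_group, population=pop, timelapse=tl),
        "irradiated": GroupConfig(
            n_per_group,
            population=replace(pop, loss_schedule=loss, seed=seed + 1),
            timelapse=replace(tl, seed=seed + 1),
            coverage_scale=coverage,
            turnover_scale=turnover,
        ),
    }
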