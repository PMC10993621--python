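"""Process-dynamics analytics on binary time-lapses.

An hour-long session is a stack of binarized frames (default 12 at 5-minute
intervals). For each consecutive frame pair, positive pixels are classified
as stable (present in both frames), extensions (second frame only) or
retractions (first frame only). Session metrics:

* coverage — percent of the field positive at the first frame (T0);
* surveillance — percent positive in the maximum T-projection (the union of
  positives over all frames), the territory sampled over the session;
* motility index — (extended + retracted) / stable per pair, averaged over
  the session's pairs; and the ratios motility/coverage and
  motility/surveillance (percent-scale denominators).

Exact identities: stable + retracted equals the first frame's positives and
stable + extended the second frame's, for every pair; surveillance >=
coverage always, with equality iff no pixel is ever gained after T0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import TimeLapse

# classified-map codes (overlay export): 0 background, 1 stable, 2 extension,
# 3 retraction
STABLE, EXTENSION, RETRACTION = 1, 2, 3


@dataclass
class PixelTurnover:
    """Pixel classification for one consecutive frame pair."""

    stable: int
    extended: int
    retracted: int
    classified_map: np.ndarray | None = None

    @property
    def ratio(self) -> float:
        """(extended + retracted) / stable; NaN when no stable pixels."""
        if self.stable == 0:
            return float("nan")
        return (self.extended + self.retracted) / self.stable


@dataclass
class DynamicsResult:
    """Per-session summary of process dynamics."""

    coverage_pct: float
    surveillance_pct: float
    motility_index: float
    motility_over_coverage: float
    motility_over_surveillance: float
    turnover: list[PixelTurnover]
    motility_missing: bool = False


def _check_binary_stack(stack: TimeLapse) -> np.ndarray:
    if not stack.binary:
        raise ValueError("dynamics metrics require a binarized stack")
    return stack.frames.astype(bool)


def classify_pair(f1: np.ndarray, f2: np.ndarray, return_map: bool = False) -> PixelTurnover:
    """Overlay two consecutive binary frames and classify positive pixels."""
    f1 = np.asarray(f1)
    f2 = np.asarray(f2)
    if f1.shape != f2.shape:
        raise ValueError(f"frame shapes differ: {f1.shape} vs {f2.shape}")
    a = f1.astype(bool)
    b = f2.astype(bool)
    stable = a & b
    ext = ~a & b
    ret = a & ~b
    cmap = None
    if return_map:
        cmap = np.zeros(a.shape, dtype=np.uint8)
        cmap[stable] = STABLE
        cmap[ext] = EXTENSION
        cmap[ret] = RETRACTION
    return PixelTurnover(int(stable.sum()), int(ext.sum()), int(ret.sum()), cmap)


def turnover_series(stack: TimeLapse) -> list[PixelTurnover]:
    """:func:`classify_pair` over all consecutive frame pairs."""
    frames = _check_binary_stack(stack)
    return [classify_pair(frames[t], frames[t + 1]) for t in range(len(frames) - 1)]


def motility_index(stack: TimeLapse, mode: str = "pair_mean") -> float:
    """Session motility index.

    ``pair_mean`` (default): the per-pair ratio (extended + retracted)/stable
    averaged over the session's consecutive pairs. ``pooled``: extended and
    retracted summed over all pairs divided by summed stable. Any pair with
    zero stable pixels makes the session value NaN rather than infinite.
    """
    if stack.n_frames < 2:
        raise ValueError("motility index needs at least two frames")
    series = turnover_series(stack)
    if mode == "pair_mean":
        ratios = [t.ratio for t in series]
        if any(np.isnan(r) for r in ratios):
            return float("nan")
        return float(np.mean(ratios))
    if mode == "pooled":
        stable = sum(t.stable for t in series)
        if stable == 0:
            return float("nan")
        return sum(t.extended + t.retracted for t in series) / stable
    raise ValueError(f"unknown mode {mode!r}")


def coverage(stack: TimeLapse) -> float:
    """Percent of the field positive at the first frame."""
    frames = _check_binary_stack(stack)
    if frames.shape[0] == 0:
        raise ValueError("empty stack")
    return 100.0 * float(frames[0].mean())


def surveillance(stack: TimeLapse) -> float:
    """Percent positive in the maximum T-projection over all frames."""
    frames = _check_binary_stack(stack)
    if frames.shape[0] == 0:
        return 0.0
    return 100.0 * float(frames.any(axis=0).mean())


def dynamics_summary(stack: TimeLapse, motility_mode: str = "pair_mean") -> DynamicsResult:
    """Assemble the per-session dynamics metrics and their ratios.

    Ratios divide the motility index by the percent-scale coverage and
    surveillance; a zero denominator (empty field) yields NaN. The subsequent
    within-animal baseline normalization cancels any constant scale factor.
    """
    series = turnover_series(stack)
    cov = coverage(stack)
    surv = surveillance(stack)
    mot = motility_index(stack, mode=motility_mode)
    missing = bool(np.isnan(mot))
    return DynamicsResult(
        coverage_pct=cov,
        surveillance_pct=surv,
        motility_index=mot,
        motility_over_coverage=mot / cov if cov > 0 else float("nan"),
        motility_over_surveillance=mot / surv if surv > 0 else float("nan"),
        turnover=series,
        motility_missing=missing,
    )
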