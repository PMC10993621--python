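"""Population-level soma analytics: counts, spacing, loss/gain, displacement.

Within a single timepoint the spatial organization of microglia is summarized
by per-soma nearest-neighbor distances (NND), the cell density, and the
spacing index (mean NND squared times density), a dimensionless regularity
measure that approaches 1 for grid-like spacing. Between timepoints two
distinct quantities are computed:

* one-to-one soma matching (:func:`match_somas`) yielding per-animal percent
  lost and gained cells, and
* the unconstrained cross-session nearest-neighbor distance
  (:func:`displacement_between`), a population-level lower bound on soma
  displacement that deliberately permits many-to-one assignment.

Distance histograms use the six bins <10, 10-20, 20-30, 30-40, 40-50 and
>50 um (half-open: [0,10), [10,20), ..., [50, inf)) and are reported as
percentages summing to 100.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .segment import SomaRecord

HIST_EDGES_UM = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf])
HIST_LABELS = ("<10", "10-20", "20-30", "30-40", "40-50", ">50")
STABLE_THRESHOLD_UM = 10.0


def distance_histogram_pct(distances_um: np.ndarray) -> np.ndarray:
    """Percent of distances per bin; bins are half-open, sums to 100."""
    d = np.asarray(distances_um, dtype=float)
    if d.size == 0:
        raise ValueError("no distances to bin")
    counts, _ = np.histogram(d, bins=HIST_EDGES_UM)
    return 100.0 * counts / d.size


@dataclass
class NNDResult:
    """Within-timepoint nearest-neighbor summary for one soma record."""

    n_somas: int
    density_cells_per_um2: float
    nnd_um: np.ndarray
    mean_nnd_um: float
    spacing_index: float
    histogram_pct: np.ndarray | None
    missing: bool = False  # fewer than two somas: distances undefined


@dataclass
class MatchResult:
    """One-to-one greedy matching of somas between two sessions."""

    pairs: list[tuple[int, int]]
    lost_labels: list[int]
    gained_labels: list[int]
    percent_lost: float
    percent_gained: float
    displacement_um: np.ndarray
    max_match_um: float


@dataclass
class DisplacementResult:
    """Cross-session NND from each reference soma to the target session."""

    displacement_um: np.ndarray
    mean_um: float
    histogram_pct: np.ndarray
    stable_fraction_pct: float  # percent with displacement < 10 um


def nnd_within(somas: SomaRecord, roi_area_um2: float) -> NNDResult:
    """Nearest-neighbor distances, density and spacing index for one session.

    density = n / roi_area; spacing_index = (mean NND)^2 * density. With
    fewer than two somas the NND fields are flagged missing but the count and
    density are still returned.
    """
    if roi_area_um2 <= 0:
        raise ValueError("roi_area_um2 must be positive")
    n = len(somas)
    density = n / roi_area_um2
    if n < 2:
        return NNDResult(n, density, np.empty(0), float("nan"), float("nan"),
                         None, missing=True)
    tree = cKDTree(somas.xy_um)
    dist, _ = tree.query(somas.xy_um, k=2)
    nnd = dist[:, 1]
    mean = float(nnd.mean())
    return NNDResult(
        n_somas=n,
        density_cells_per_um2=density,
        nnd_um=nnd,
        mean_nnd_um=mean,
        spacing_index=mean**2 * density,
        histogram_pct=distance_histogram_pct(nnd),
    )


def match_somas(a: SomaRecord, b: SomaRecord, max_match_um: float = 20.0) -> MatchResult:
    """Greedy mutual-nearest matching of somas between sessions a and b.

    Repeatedly pairs the globally closest unmatched (a, b) pair with distance
    <= ``max_match_um``; distance ties are broken by (label_a, label_b) order.
    Unmatched a-labels are lost, unmatched b-labels gained; percentages are
    relative to the size of ``a``.
    """
    na, nb = len(a), len(b)
    pairs: list[tuple[int, int]] = []
    disp: list[float] = []
    if na and nb:
        d = np.linalg.norm(a.xy_um[:, None, :] - b.xy_um[None, :, :], axis=2)
        ii, jj = np.nonzero(d <= max_match_um)
        order = sorted(
            range(ii.size),
            key=lambda k: (d[ii[k], jj[k]], a.labels[ii[k]], b.labels[jj[k]]),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((int(a.labels[i]), int(b.labels[j])))
            disp.append(float(d[i, j]))
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    lost = sorted(int(l) for l in a.labels if int(l) not in matched_a)
    gained = sorted(int(l) for l in b.labels if int(l) not in matched_b)
    denom = max(na, 1)
    return MatchResult(
        pairs=pairs,
        lost_labels=lost,
        gained_labels=gained,
        percent_lost=100.0 * len(lost) / denom,
        percent_gained=100.0 * len(gained) / denom,
        displacement_um=np.asarray(disp),
        max_match_um=max_match_um,
    )


def net_percent_change(a: SomaRecord, b: SomaRecord) -> float:
    """Net count change, percent of the reference count (sign: loss < 0).

    The alternative loss/gain reading based on net counts rather than
    matching; kept alongside :func:`match_somas` (the default)."""
    if len(a) == 0:
        raise ValueError("reference record is empty")
    return 100.0 * (len(b) / len(a) - 1.0)


def displacement_between(reference: SomaRecord, target: SomaRecord) -> DisplacementResult:
    """Per-soma cross-session NND from reference to target (lower bound).

    Each reference soma contributes the distance to the *nearest* target
    soma; a target soma may be the nearest neighbor of several reference
    somas. This is a population-level lower bound on true soma displacement,
    distinct from one-to-one :func:`match_somas`.
    """
    if len(reference) == 0:
        raise ValueError(f"reference session {reference.session!r} has no somas")
    if len(target) == 0:
        raise ValueError(f"target session {target.session!r} has no somas")
    tree = cKDTree(target.xy_um)
    dist, _ = tree.query(reference.xy_um, k=1)
    dist = np.atleast_1d(dist)
    return DisplacementResult(
        displacement_um=dist,
        mean_um=float(dist.mean()),
        histogram_pct=distance_histogram_pct(dist),
        stable_fraction_pct=100.0 * float((dist < STABLE_THRESHOLD_UM).mean()),
    )


def percent_change_count(counts: Mapping[str, float], baseline: str) -> dict[str, float]:
    """Per-session percent change in cell count relative to the baseline."""
    if baseline not in counts:
        raise ValueError(f"baseline session {baseline!r} missing from counts")
    b = counts[baseline]
    if b == 0:
        raise ValueError("baseline count is zero; percent change undefined")
    return {s: 100.0 * (v / b - 1.0) for s, v in counts.items()}
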