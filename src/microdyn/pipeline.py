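"""End-to-end cohort analysis: manifest in, tidy baseline-normalized table out.

For each animal and session the pipeline reads the wide-field population
image (soma counting, nearest-neighbor spacing, loss/gain matching against
baseline, displacement) and the hour-long binary time-lapse (coverage,
surveillance, motility and its ratios), then assembles everything into the
long-format cohort table with within-animal percent change versus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import io as mio
from . import spatial
from .cohort import BASELINE_SESSION, DEFAULT_SESSION_ORDER, build_cohort, group_summary
from .segment import SomaRecord, binarize, extract_somas

POPULATION_METRICS = (
    "cell_count", "mean_nnd_um", "spacing_index", "percent_lost",
    "percent_gained", "displacement_mean_um", "stable_fraction_pct",
)
DYNAMICS_METRICS = (
    "coverage_pct", "surveillance_pct", "motility_index",
    "motility_over_coverage", "motility_over_surveillance",
)


@dataclass
class CohortAnalysis:
    """Everything the cohort run produced."""

    table: pd.DataFrame                      # tidy long table with percent_change
    soma_records: dict[tuple[str, str], SomaRecord] = field(default_factory=dict)
    dynamics: dict[tuple[str, str], dyn.DynamicsResult] = field(default_factory=dict)

    def summary(self, value_col: str = "percent_change") -> pd.DataFrame:
        return group_summary(self.table, value_col=value_col)


def _analyze_population(
    rows: pd.DataFrame,
    baseline: str,
    max_match_um: float,
    soma_kwargs: dict,
) -> tuple[list[dict], dict[str, SomaRecord]]:
    animal = rows["animal_id"].iloc[0]
    group = rows["group"].iloc[0]
    records: dict[str, SomaRecord] = {}
    roi_areas: dict[str, float] = {}
    out: list[dict] = []
    for _, row in rows.iterrows():
        psz = float(row["pixel_size_um_population"])
        mask = binarize(mio.read_image(row["path_population"]))
        roi_areas[row["session"]] = mask.shape[0] * mask.shape[1] * psz**2
        records[row["session"]] = extract_somas(
            mask, psz, session=row["session"], animal_id=animal, **soma_kwargs)

    def emit(session: str, metric: str, value: float) -> None:
        out.append({"animal_id": animal, "group": group, "session": session,
                    "metric": metric, "value": value})

    base = records.get(baseline)
    for session, rec in records.items():
        # ROI area: the full field of this session's image
        nnd = spatial.nnd_within(rec, roi_areas[session])
        emit(session, "cell_count", float(len(rec)))
        emit(session, "mean_nnd_um", nnd.mean_nnd_um)
        emit(session, "spacing_index", nnd.spacing_index)
        if base is not None and len(base):
            match = spatial.match_somas(base, rec, max_match_um=max_match_um)
            emit(session, "percent_lost", match.percent_lost)
            emit(session, "percent_gained", match.percent_gained)
            if len(rec):
                disp = spatial.displacement_between(base, rec)
                emit(session, "displacement_mean_um", disp.mean_um)
                emit(session, "stable_fraction_pct", disp.stable_fraction_pct)
    return out, records


def analyze_cohort(
    manifest: str | Path | pd.DataFrame,
    session_order: tuple[str, ...] = DEFAULT_SESSION_ORDER,
    baseline: str = BASELINE_SESSION,
    max_match_um: float = 20.0,
    motility_mode: str = "pair_mean",
    soma_kwargs: dict | None = None,
) -> CohortAnalysis:
    """Run the full analysis over a cohort manifest.

    ``manifest`` is the CSV written by the simulator (or an equivalent table
    for real data: one row per animal per session with population and
    time-lapse image paths and pixel sizes). Percent lost/gained use one-to-
    one matching with radius ``max_match_um``; displacement uses the
    unconstrained cross-session nearest neighbor.
    """
    df = mio.read_manifest(manifest) if not isinstance(manifest, pd.DataFrame) else manifest
    soma_kwargs = soma_kwargs or {}
    rows: list[dict] = []
    soma_records: dict[tuple[str, str], SomaRecord] = {}
    dynamics: dict[tuple[str, str], dyn.DynamicsResult] = {}
    for animal, sub in df.groupby("animal_id", sort=False):
        pop_rows, records = _analyze_population(sub, baseline, max_match_um, soma_kwargs)
        rows.extend(pop_rows)
        for session, rec in records.items():
            soma_records[(animal, session)] = rec
        group = sub["group"].iloc[0]
        for _, row in sub.iterrows():
            stack = mio.read_timelapse(
                row["path_timelapse"], float(row["pixel_size_um_timelapse"]))
            if not stack.binary:
                raise ValueError(
                    f"{row['path_timelapse']}: time-lapse is not binary; run "
                    "preprocessing/binarization first")
            res = dyn.dynamics_summary(stack, motility_mode=motility_mode)
            dynamics[(animal, row["session"])] = res
            for metric in DYNAMICS_METRICS:
                attr = metric if metric != "coverage_pct" else "coverage_pct"
                rows.append({
                    "animal_id": animal, "group": group,
                    "session": row["session"], "metric": metric,
                    "value": getattr(res, attr),
                })
    metrics = pd.DataFrame(rows)
    table = build_cohort(metrics, session_order=session_order, baseline=baseline)
    return CohortAnalysis(table=table, soma_records=soma_records, dynamics=dynamics)


def recovery_report(
    analysis: CohortAnalysis,
    ground_truth: dict,
    session: str,
    insult_group: str = "irradiated",
) -> pd.DataFrame:
    """Compare pipeline group means with the simulator's programmed targets.

    For the given session, reports measured versus programmed values for the
    insult group: percent change in cell count, percent change in coverage,
    and the motility index versus its closed-form target (group means over
    animals).
    """
    tab = analysis.table
    sel = (tab["group"] == insult_group) & (tab["session"] == session)

    def mean_of(metric: str, col: str) -> float:
        v = tab.loc[sel & (tab["metric"] == metric), col]
        return float(v.mean())

    animals = [a for a, info in ground_truth["animals"].items()
               if info["group"] == insult_group]
    base_session = ground_truth["sessions"][0]

    def programmed_pct(key: str) -> float:
        vals = []
        for a in animals:
            t = ground_truth["animals"][a]["timelapse_targets"]
            vals.append(100.0 * (t[session][key] / t[base_session][key] - 1.0))
        return float(np.mean(vals))

    prog_loss = []
    for a in animals:
        pop = ground_truth["animals"][a]["population"]
        n0 = len(pop[base_session]["labels"])
        n_s = len(pop[session]["labels"])
        prog_loss.append(100.0 * (n_s / n0 - 1.0))

    rows = [
        {"effect": "cell_count_pct_change",
         "measured": mean_of("cell_count", "percent_change"),
         "programmed": float(np.mean(prog_loss))},
        {"effect": "coverage_pct_change",
         "measured": mean_of("coverage_pct", "percent_change"),
         "programmed": programmed_pct("coverage_pct")},
        {"effect": "motility_pct_change",
         "measured": mean_of("motility_index", "percent_change"),
         "programmed": programmed_pct("motility")},
    ]
    return pd.DataFrame(rows)
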