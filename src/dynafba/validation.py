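"""Scoring simulations against experimental data.

Two metrics: the R score comparing relative changes in final metabolite
concentrations between a genetically modified strain and its wild type (model
vs experiment), and per-species correlation between a simulated trajectory and
an experimental time series.

The R score used here is the difference-of-relative-changes form

    R = | (D_M_GM - D_M_WT)/D_M_WT  -  (D_E_GM - D_E_WT)/D_E_WT |

where D is the final concentration of a metabolite in the model (M) or
experiment (E), for the genetically modified (GM) or wild-type (WT) strain.
R = 0 means the model reproduced the experimental relative change exactly.
This algebra is an interpretation of a verbally specified score and is
isolated in :func:`r_score` so an alternative form is a one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSeriesError, InsufficientPointsError, UndefinedScoreError


@dataclass(frozen=True)
class FinalConcentrationQuad:
    """Final concentrations (g/L) of one metabolite: model/experiment x GM/WT."""

    metabolite: str
    D_M_GM: float
    D_M_WT: float
    D_E_GM: float
    D_E_WT: float


def r_score(q: FinalConcentrationQuad) -> float:
    """Relative-change disagreement between model and experiment (see module
    docstring); raises UndefinedScoreError when a wild-type value is zero."""
    if q.D_M_WT <= 0 or q.D_E_WT <= 0:
        raise UndefinedScoreError(
            f"{q.metabolite}: R score undefined for non-positive wild-type "
            f"concentration (model {q.D_M_WT}, experiment {q.D_E_WT})"
        )
    rel_model = (q.D_M_GM - q.D_M_WT) / q.D_M_WT
    rel_exp = (q.D_E_GM - q.D_E_WT) / q.D_E_WT
    return abs(rel_model - rel_exp)


def profile_correlation(
    traj, experiment: pd.DataFrame, method: str = "pearson"
) -> dict[str, float]:
    """Correlation (in percent) between simulation and experiment per species.

    ``experiment`` is tidy: columns ``time_h``, ``species``, ``value``.  The
    simulated trajectory is linearly interpolated onto the experimental time
    points; at least 3 matched points are required per species.  ``method``
    is ``pearson`` (default) or ``spearman``.
    """
    sim = traj.to_dataframe() if hasattr(traj, "to_dataframe") else traj
    out: dict[str, float] = {}
    for species, grp in experiment.groupby("species"):
        if species not in sim.columns:
            continue
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(float)
        exp_vals = grp["value"].to_numpy(float)
        in_range = (times >= sim["time_h"].iloc[0]) & (times <= sim["time_h"].iloc[-1])
        times, exp_vals = times[in_range], exp_vals[in_range]
        if len(times) < 3:
            raise InsufficientPointsError(
                f"{species}: only {len(times)} matched time points (need >= 3)"
            )
        sim_vals = np.interp(times, sim["time_h"], sim[species])
        if np.ptp(exp_vals) == 0 or np.ptp(sim_vals) == 0:
            raise DegenerateSeriesError(
                f"{species}: zero-variance series, correlation undefined"
            )
        if method == "spearman":
            from scipy.stats import spearmanr

            r = spearmanr(sim_vals, exp_vals).statistic
        else:
            r = np.corrcoef(sim_vals, exp_vals)[0, 1]
        out[species] = float(r * 100.0)
    return out


def score_mutant_table(
    wt_finals: dict[str, float],
    gm_finals: dict[str, float],
    table: pd.DataFrame,
) -> pd.DataFrame:
    """R scores for a mutant final-concentration table.

    ``table`` columns: ``metabolite``, ``D_E_GM``, ``D_E_WT`` (optionally
    ``study``).  Metabolites whose score is undefined (zero wild type) are
    flagged in the ``error`` column rather than aborting the whole table.
    """
    rows = []
    for _, rec in table.iterrows():
        met = rec["metabolite"]
        row = {"metabolite": met}
        if "study" in rec:
            row["study"] = rec["study"]
        try:
            q = FinalConcentrationQuad(
                metabolite=met,
                D_M_GM=gm_finals.get(met, 0.0),
                D_M_WT=wt_finals.get(met, 0.0),
                D_E_GM=float(rec["D_E_GM"]),
                D_E_WT=float(rec["D_E_WT"]),
            )
            row["R"] = r_score(q)
            row["error"] = ""
        except UndefinedScoreError as exc:
            row["R"] = float("nan")
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
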