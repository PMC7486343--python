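"""Plate-level screening statistics.

Compound wells are normalized plate-wise against the DMSO vehicle
controls (fold = migration area / same-plate control mean), replicates are
aggregated, and hits are called with symmetric cutoffs at
``control fold mean ± k·SD`` (k = 4 by default) over the pooled individual
control-well folds.  Candidates below the low cutoff must additionally
pass a viability gate — a mean dead fraction above the threshold reclasses
them toxic rather than low-migration.  Dose-response confirmation compares
each tested concentration's replicate folds against the same plates'
control folds with a Welch two-sample t test and reports the concentration
of maximal mean fold as the peak (ties resolve to the highest
concentration); an optional Holm correction is available for screen-wide
use, off by default to match per-concentration reporting.

Table schema (one row per well): ``compound, concentration_um, replicate,
plate, well, migration_area_um2, dead_fraction, role, excluded``; excluded
wells never enter any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContractError, NormalizationError

REQUIRED_COLUMNS = (
    "compound",
    "plate",
    "migration_area_um2",
    "dead_fraction",
    "role",
    "excluded",
)

HIT_CLASSES = ("high", "low", "none", "toxic", "excluded")


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ContractError(f"screen table missing columns {missing}")
    if (table["migration_area_um2"] < 0).any():
        raise ContractError("migration areas must be >= 0")
    dead = table["dead_fraction"].dropna()
    if ((dead < 0) | (dead > 1)).any():
        raise ContractError("dead fractions must be in [0, 1]")


def normalize_to_controls(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``fold`` column: migration area over the same-plate control mean.

    Control folds average exactly 1 on every plate by construction.
    Raises :class:`NormalizationError` for plates with fewer than two
    usable (non-excluded) control wells.
    """
    _validate_table(table)
    out = table.copy()
    out["fold"] = np.nan
    for plate, group in out.groupby("plate"):
        ctrl = group[(group["role"] == "control") & (~group["excluded"])]
        if len(ctrl) < 2:
            raise NormalizationError(
                f"plate {plate!r} has {len(ctrl)} usable control wells (need >= 2)"
            )
        mean = ctrl["migration_area_um2"].mean()
        if mean <= 0:
            raise NormalizationError(f"plate {plate!r} control mean is not positive")
        out.loc[group.index, "fold"] = group["migration_area_um2"] / mean
    return out


def aggregate_replicates(folds) -> tuple[float, float, int]:
    """Sample mean, sample SD (n−1 denominator; 0 for a single value), n."""
    f = np.asarray(list(folds), dtype=float)
    f = f[np.isfinite(f)]
    if f.size == 0:
        raise ContractError("no replicate values to aggregate")
    sd = float(f.std(ddof=1)) if f.size > 1 else 0.0
    return float(f.mean()), sd, int(f.size)


def toxicity_flag(dead_fraction: float, threshold: float = 0.5) -> bool:
    """True iff the dead fraction exceeds the viability threshold."""
    if not (0 <= dead_fraction <= 1 and 0 <= threshold <= 1):
        raise ContractError("dead_fraction and threshold must be in [0, 1]")
    return dead_fraction > threshold


def control_fold_stats(normalized: pd.DataFrame) -> tuple[float, float, float]:
    """(fold mean, fold SD, mean control area μm²) over pooled non-excluded
    individual control wells across all plates."""
    ctrl = normalized[(normalized["role"] == "control") & (~normalized["excluded"])]
    if len(ctrl) < 2:
        raise ContractError("need at least 2 usable control wells")
    folds = ctrl["fold"].to_numpy(float)
    return (
        float(folds.mean()),
        float(folds.std(ddof=1)),
        float(ctrl["migration_area_um2"].mean()),
    )


def call_hits(
    normalized: pd.DataFrame,
    k_sd: float = 4.0,
    viability_max_dead: float = 0.5,
) -> pd.DataFrame:
    """Classify every compound as high / low / none / toxic / excluded.

    Cutoffs are ``control fold mean ± k_sd × control fold SD`` with the SD
    taken over individual control wells pooled across plates; each
    compound is compared through its replicate-mean fold.  Low-cutoff
    candidates failing the viability gate are toxic; compounds whose
    replicates are all excluded are classed excluded.
    """
    if k_sd <= 0:
        raise ContractError("k_sd must be > 0")
    if "fold" not in normalized.columns:
        raise ContractError("table is not normalized (missing fold column)")
    ctrl_mean, ctrl_sd, ctrl_area = control_fold_stats(normalized)
    high_cutoff = ctrl_mean + k_sd * ctrl_sd
    low_cutoff = ctrl_mean - k_sd * ctrl_sd

    rows = []
    compounds = normalized[normalized["role"] == "compound"]
    for compound, group in compounds.groupby("compound", sort=True):
        usable = group[~group["excluded"]]
        if len(usable) == 0:
            rows.append(
                {
                    "compound": compound,
                    "fold": np.nan,
                    "fold_sd": np.nan,
                    "n": 0,
                    "dead_fraction": np.nan,
                    "call": "excluded",
                }
            )
            continue
        mean, sd, n = aggregate_replicates(usable["fold"])
        dead = float(usable["dead_fraction"].mean())
        if mean >= high_cutoff:
            call = "high"
        elif mean <= low_cutoff:
            call = "toxic" if toxicity_flag(dead, viability_max_dead) else "low"
        else:
            call = "none"
        rows.append(
            {
                "compound": compound,
                "fold": mean,
                "fold_sd": sd,
                "n": n,
                "dead_fraction": dead,
                "call": call,
            }
        )
    out = pd.DataFrame(rows)
    out["control_fold_mean"] = ctrl_mean
    out["control_fold_sd"] = ctrl_sd
    out["control_mean_area_um2"] = ctrl_area
    out["high_cutoff"] = high_cutoff
    out["low_cutoff"] = low_cutoff
    return out


@dataclass
class DoseResponseResult:
    compound: str
    per_concentration: pd.DataFrame  # concentration_um, fold, p_value, significant
    peak_concentration: float


def dose_response_analysis(
    normalized: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> list[DoseResponseResult]:
    """Per-compound dose-response: fold and Welch t test vs controls at each
    concentration; peak = concentration of maximal mean fold (ties → highest).

    ``normalized`` must contain the compound rows at ≥ 2 concentrations
    plus the control rows of the same plates (run
    :func:`normalize_to_controls` first).
    """
    if not 0 < alpha < 1:
        raise ContractError("alpha must be in (0, 1)")
    if "fold" not in normalized.columns:
        raise ContractError("table is not normalized (missing fold column)")
    results = []
    compounds = normalized[
        (normalized["role"] == "compound") & (~normalized["excluded"])
    ]
    controls = normalized[
        (normalized["role"] == "control") & (~normalized["excluded"])
    ]
    if controls.empty:
        raise ContractError("no usable control wells for dose-response testing")
    for compound, group in compounds.groupby("compound", sort=True):
        concentrations = np.sort(group["concentration_um"].unique())
        if len(concentrations) < 2:
            raise ContractError(
                f"compound {compound!r}: need >= 2 concentrations for dose-response"
            )
        rows = []
        for conc in concentrations:
            sub = group[group["concentration_um"] == conc]
            ctrl = controls[controls["plate"].isin(sub["plate"].unique())]
            if len(ctrl) < 2:
                raise ContractError(
                    f"compound {compound!r} at {conc} μM: no same-plate controls"
                )
            t, p = stats.ttest_ind(
                sub["fold"], ctrl["fold"], equal_var=False
            )
            rows.append(
                {
                    "concentration_um": float(conc),
                    "fold": float(sub["fold"].mean()),
                    "p_value": float(p),
                }
            )
        per_conc = pd.DataFrame(rows)
        if holm:
            order = np.argsort(per_conc["p_value"].to_numpy())
            m = len(per_conc)
            adjusted = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * per_conc["p_value"].iloc[idx])
                adjusted[idx] = min(running, 1.0)
            per_conc["p_adjusted"] = adjusted
            per_conc["significant"] = per_conc["p_adjusted"] < alpha
        else:
            per_conc["significant"] = per_conc["p_value"] < alpha
        best = per_conc["fold"].max()
        peak = float(
            per_conc.loc[per_conc["fold"] >= best - 1e-12, "concentration_um"].max()
        )
        results.append(DoseResponseResult(str(compound), per_conc, peak))
    return results
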