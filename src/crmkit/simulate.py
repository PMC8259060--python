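"""Monte-Carlo operating characteristics of the CRM design.

Whole trials are simulated cohort-by-cohort under assumed true dose-DLT
curves, and summarised by the five design performance measures: the
risk-adjusted accuracy index A_N, the probability of correctly selecting
the true MTD (PCS), the mean proportion of patients treated above the
true MTD, the mean proportion treated within one level of it, and the
mean number of patients treated.  A delta-grid harness re-runs the whole
calibration (skeleton + least-informative prior SD) and simulation for a
range of indifference-interval half-widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationSpec, build_skeleton, least_informative_sigma
from .design import DesignSpec, ToxicityHistory, ValidationError
from .escalation import CONTINUE, STOPPED_TOXIC, check_stopping

__all__ = [
    "Scenario",
    "OCResult",
    "TrialRecord",
    "plateau_curves",
    "simulate_trial",
    "simulate_oc",
    "accuracy_index",
    "delta_grid_evaluation",
]

# Plateau calibration levels for a 35% target: doses below the MTD sit at
# 0.21, the MTD at 0.35, doses above at 0.52.
_PLATEAU_LEVELS = {0.35: (0.21, 0.35, 0.52)}


@dataclass(frozen=True)
class Scenario:
    """An assumed true dose-DLT curve for simulation."""

    true_probs: tuple[float, ...]
    true_mtd_level: int = 0  # 1-based; 0 means derive from the curve
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "true_probs", tuple(float(p) for p in self.true_probs)
        )
        if any(not (0.0 < p < 1.0) for p in self.true_probs):
            raise ValidationError("true DLT probabilities must lie in (0, 1)")
        if any(b < a for a, b in zip(self.true_probs, self.true_probs[1:])):
            raise ValidationError("true DLT probabilities must be non-decreasing")
        if self.true_mtd_level == 0:
            object.__setattr__(self, "true_mtd_level", self.mtd_level(0.35))
        if not (1 <= self.true_mtd_level <= len(self.true_probs)):
            raise ValidationError("true_mtd_level out of range")

    def mtd_level(self, theta: float) -> int:
        """Level whose true DLT probability is closest to theta (ties lower)."""
        return int(np.argmin(np.abs(np.asarray(self.true_probs) - theta))) + 1


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial: allocations, outcomes and final state."""

    history: ToxicityHistory
    state: str
    mtd_level: int | None  # None after a toxic stop


@dataclass(frozen=True)
class OCResult:
    """Aggregated operating characteristics of one scenario."""

    selection_probs: tuple[float, ...]
    prob_no_selection: float
    accuracy_index: float  # K-multiplied form
    accuracy_index_unmultiplied: float
    pcs: float
    mean_prop_overdose: float
    mean_prop_within_one: float
    mean_n_treated: float
    n_reps: int
    seed: int
    se_pcs: float = 0.0
    se_mean_prop_overdose: float = 0.0
    se_mean_prop_within_one: float = 0.0
    se_mean_n_treated: float = 0.0
    scenario: Scenario = field(repr=False, default=None)


def plateau_curves(theta: float = 0.35, K: int = 5) -> list[Scenario]:
    """The K benchmark plateau curves: MTD at level m, 0.21 below, 0.52 above."""
    if K < 2:
        raise ValidationError("plateau curves require K >= 2")
    try:
        below, at, above = _PLATEAU_LEVELS[theta]
    except KeyError:
        raise ValidationError(
            f"plateau levels are only tabulated for theta=0.35, got {theta}"
        ) from None
    return [
        Scenario(
            true_probs=(below,) * m + (at,) + (above,) * (K - m - 1),
            true_mtd_level=m + 1,
            name=f"curve{m + 1}",
        )
        for m in range(K)
    ]


def simulate_trial(
    scenario: Scenario, spec: DesignSpec, rng: np.random.Generator
) -> TrialRecord:
    """Run one trial under the scenario, driving the escalation engine.

    Cohort outcomes are Binomial(cohort_size, true DLT probability at the
    assigned level); the trial follows the engine's recommendations and
    stopping decisions exactly.
    """
    if len(scenario.true_probs) != spec.n_levels:
        raise ValidationError("scenario and design have different numbers of levels")
    history = ToxicityHistory()
    level = spec.start_level
    while True:
        n_dlt = int(rng.binomial(spec.cohort_size, scenario.true_probs[level - 1]))
        history = history.extended(level, n_dlt, spec.cohort_size)
        status = check_stopping(history, spec)
        if status.state != CONTINUE:
            return TrialRecord(
                history=history, state=status.state, mtd_level=status.mtd_level
            )
        level = status.recommended_level


def accuracy_index(
    selection_probs,
    scenario: Scenario,
    theta: float,
    k_multiplied: bool = True,
) -> float:
    """Risk-adjusted average accuracy of the selection distribution.

    A = 1 - c * (sum_k rho_k |pi_k - theta|) / (sum_k |pi_k - theta|),
    where rho_k are per-level selection probabilities (any no-selection
    mass is simply absent from the numerator), pi_k the true DLT
    probabilities, and c = K in the standard form (``k_multiplied``) or 1
    in the unmultiplied variant.  Equals 1 when all selection mass sits
    on levels with pi_k = theta; 0 for a uniform selection.
    """
    rho = np.asarray(selection_probs, dtype=float)
    pi = np.asarray(scenario.true_probs)
    if rho.shape != pi.shape:
        raise ValidationError("selection_probs must have one entry per dose level")
    w = np.abs(pi - theta)
    denom = w.sum()
    if denom == 0.0:
        raise ValidationError(
            "accuracy index undefined: every dose sits exactly at the target"
        )
    c = len(rho) if k_multiplied else 1.0
    return float(1.0 - c * (rho @ w) / denom)


def _se_mean(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def simulate_oc(
    scenario: Scenario,
    spec: DesignSpec,
    n_reps: int = 20_000,
    seed: int = 0,
) -> OCResult:
    """Operating characteristics of the design under one scenario.

    Toxic stops contribute no dose selection: they enter
    ``prob_no_selection`` and the PCS/accuracy denominators (all trials),
    but not the selection numerators.  Allocation measures average the
    per-trial proportion over treated patients, each trial weighted
    equally.  Replicates use independent child streams spawned from the
    seed, so results are reproducible and order-independent.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    K = spec.n_levels
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    sel = np.zeros(K + 1)
    over = np.empty(n_reps)
    within = np.empty(n_reps)
    n_treated = np.empty(n_reps)
    tm = scenario.true_mtd_level
    for i, ss in enumerate(streams):
        rec = simulate_trial(scenario, spec, np.random.default_rng(ss))
        levels = np.array([r.dose_level for r in rec.history.records])
        over[i] = np.mean(levels > tm)
        within[i] = np.mean(np.abs(levels - tm) <= 1)
        n_treated[i] = len(levels)
        sel[K if rec.mtd_level is None else rec.mtd_level - 1] += 1
    sel /= n_reps
    selection_probs = tuple(float(p) for p in sel[:K])
    return OCResult(
        selection_probs=selection_probs,
        prob_no_selection=float(sel[K]),
        accuracy_index=accuracy_index(
            selection_probs, scenario, spec.target_theta, k_multiplied=True
        ),
        accuracy_index_unmultiplied=accuracy_index(
            selection_probs, scenario, spec.target_theta, k_multiplied=False
        ),
        pcs=float(sel[tm - 1]),
        mean_prop_overdose=float(over.mean()),
        mean_prop_within_one=float(within.mean()),
        mean_n_treated=float(n_treated.mean()),
        n_reps=n_reps,
        seed=seed,
        se_pcs=float(np.sqrt(sel[tm - 1] * (1.0 - sel[tm - 1]) / n_reps)),
        se_mean_prop_overdose=_se_mean(over),
        se_mean_prop_within_one=_se_mean(within),
        se_mean_n_treated=_se_mean(n_treated),
        scenario=scenario,
    )


def delta_grid_evaluation(
    delta_grid,
    theta: float = 0.35,
    nu: int = 3,
    K: int = 5,
    spec_template: DesignSpec | None = None,
    n_reps: int = 2_000,
    seed: int = 0,
    curves: tuple[int, ...] = (2, 3, 4, 5),
) -> pd.DataFrame:
    """Re-calibrate and simulate the design over a grid of delta values.

    For each delta the skeleton is rebuilt, the least-informative prior
    SD recomputed, and every plateau curve simulated.  One row per
    (delta, curve) plus a summary row per delta averaging the measures
    over ``curves`` (the levels where good performance matters) and
    reporting the 4-value sample SD of the accuracy index.
    """
    from .calibration import DEFAULT_DOSES_MG

    rows = []
    root = np.random.SeedSequence(seed)
    for j, delta in enumerate(delta_grid):
        cal = CalibrationSpec(delta=float(delta), target_theta=theta, nu=nu, K=K)
        skeleton = build_skeleton(cal)
        sigma = least_informative_sigma(skeleton, theta, cal.intercept)
        base = spec_template if spec_template is not None else DesignSpec(
            doses_mg=DEFAULT_DOSES_MG[:K], skeleton=skeleton, target_theta=theta
        )
        spec = base.with_(skeleton=skeleton, sigma_beta=sigma, target_theta=theta)
        per_curve = {}
        for m, scenario in enumerate(plateau_curves(theta, K), start=1):
            sub_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            oc = simulate_oc(scenario, spec, n_reps=n_reps, seed=sub_seed)
            per_curve[m] = oc
            rows.append(
                {
                    "delta": float(delta),
                    "curve": m,
                    "sigma_li": sigma,
                    "accuracy_index": oc.accuracy_index,
                    "pcs": oc.pcs,
                    "mean_prop_overdose": oc.mean_prop_overdose,
                    "mean_prop_within_one": oc.mean_prop_within_one,
                    "mean_n_treated": oc.mean_n_treated,
                }
            )
        sub = [per_curve[m] for m in curves]
        a_vals = np.array([oc.accuracy_index for oc in sub])
        rows.append(
            {
                "delta": float(delta),
                "curve": 0,  # summary over `curves`
                "sigma_li": sigma,
                "accuracy_index": float(a_vals.mean()),
                "pcs": float(np.mean([oc.pcs for oc in sub])),
                "mean_prop_overdose": float(
                    np.mean([oc.mean_prop_overdose for oc in sub])
                ),
                "mean_prop_within_one": float(
                    np.mean([oc.mean_prop_within_one for oc in sub])
                ),
                "mean_n_treated": float(np.mean([oc.mean_n_treated for oc in sub])),
                "sd_accuracy_index": float(a_vals.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
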