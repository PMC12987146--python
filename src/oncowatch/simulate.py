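"""Rule-based parametric simulator of weekly adverse-effect panels.

The model generates, for each patient ``i`` and week ``k``, a binary
vector over the M tracked adverse effects.  Each patient carries a
susceptibility factor ``F_sus`` drawn from a bounded Gaussian that scales
every baseline probability; each week the per-symptom probability

    P'  =  P_base(s) * F_sus(i) * M_temp(s, k)

is clamped to [0, 1] and symptoms are drawn sequentially in a fixed
order.  When a trigger symptom fires, every correlation rule with that
trigger additively boosts its target's probability for the remainder of
the same week.  Boosts never persist across weeks: the clamped baseline
probabilities are rebuilt at the start of every week.

Randomness uses one root seed with per-patient substreams, so enlarging
the cohort leaves earlier patients' trajectories unchanged.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CorrelationRule, SimulationConfig, SusceptibilityParams

__all__ = [
    "draw_susceptibility",
    "initial_probability",
    "simulate_patient_week",
    "simulate_cohort",
]


def draw_susceptibility(
    rng: np.random.Generator, params: SusceptibilityParams, size: int | None = None
) -> float | np.ndarray:
    """Draw patient susceptibility factor(s) from the bounded Gaussian.

    With ``method='truncate'`` draws are resampled until they fall inside
    ``[lower, upper]`` (a true truncated normal); ``'clip'`` projects
    out-of-range draws onto the bounds instead.
    """
    n = 1 if size is None else size
    if params.sd == 0:
        out = np.full(n, float(params.mean))
        if not (params.lower <= params.mean <= params.upper):
            raise ValueError("degenerate mean lies outside the bounds")
        return out[0] if size is None else out

    if params.method == "clip":
        out = np.clip(rng.normal(params.mean, params.sd, n), params.lower, params.upper)
        return float(out[0]) if size is None else out

    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draws = rng.normal(params.mean, params.sd, remaining.size)
        ok = (draws >= params.lower) & (draws <= params.upper)
        out[remaining[ok]] = draws[ok]
        remaining = remaining[~ok]
    return float(out[0]) if size is None else out


def initial_probability(p_base: float, f_sus: float, m_temp: float) -> float:
    """Weekly dynamic probability: ``clamp(p_base * f_sus * m_temp, 0, 1)``."""
    return max(0.0, min(1.0, p_base * f_sus * m_temp))


def simulate_patient_week(
    current_probs: Mapping[str, float],
    rules: Sequence[CorrelationRule],
    order: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Draw one week of binary symptom outcomes for one patient.

    Symptoms are drawn sequentially in ``order``; when a trigger fires,
    every matching rule's target probability is boosted (additively,
    clamped at 1) before that target is drawn.  Targets already drawn
    earlier in the order are unaffected — an inherent order-dependence of
    the sequential algorithm, which the default ordering avoids by
    placing triggers before their targets.
    """
    probs = dict(current_probs)
    unknown = set(order) - probs.keys()
    if unknown:
        raise ValueError(f"order references unknown symptoms: {sorted(unknown)}")
    for rule in rules:
        if rule.trigger not in probs or rule.target not in probs:
            raise ValueError(f"rule {rule.trigger}->{rule.target} references unknown symptom")

    flags: dict[str, int] = {}
    for name in order:
        u = rng.uniform()
        fired = int(u < probs[name])
        flags[name] = fired
        if fired:
            for rule in rules:
                if rule.trigger == name:
                    probs[rule.target] = min(1.0, probs[rule.target] + rule.boost)
    return flags


def _patient_rngs(seed: int, n_patients: int) -> list[np.random.Generator]:
    # SeedSequence children are a pure function of (root entropy, index):
    # patient i's stream is identical in cohorts of any size >= i+1.
    children = np.random.SeedSequence(seed).spawn(n_patients)
    return [np.random.default_rng(child) for child in children]


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort: patient profiles and the weekly panel.

    Returns
    -------
    profiles : DataFrame
        One row per patient: ``patient_id``, ``susceptibility``,
        ``bmi_baseline``.
    cohort : DataFrame
        ``n_patients * n_weeks`` rows: ``patient_id``, ``week`` (1-based)
        and one binary column per symptom, in the configured order of
        ``config.symptoms``.
    """
    names = config.symptom_names
    m_temp = {
        s.name: (s.temporal_modifiers if s.temporal_modifiers is not None else [1.0] * config.n_weeks)
        for s in config.symptoms
    }
    p_base = {s.name: s.p_base for s in config.symptoms}
    bmi_lo, bmi_hi = config.bmi_range

    profile_rows = []
    panel_rows = []
    for i, rng in enumerate(_patient_rngs(config.seed, config.n_patients)):
        pid = f"sim-{i + 1:04d}"
        f_sus = draw_susceptibility(rng, config.susceptibility)
        bmi = rng.uniform(bmi_lo, bmi_hi)
        profile_rows.append({"patient_id": pid, "susceptibility": f_sus, "bmi_baseline": bmi})
        for k in range(config.n_weeks):
            current = {
                name: initial_probability(p_base[name], f_sus, m_temp[name][k]) for name in names
            }
            flags = simulate_patient_week(current, config.correlation_rules, config.sampling_order, rng)
            row = {"patient_id": pid, "week": k + 1}
            row.update({name: flags[name] for name in names})
            panel_rows.append(row)

    profiles = pd.DataFrame(profile_rows, columns=["patient_id", "susceptibility", "bmi_baseline"])
    cohort = pd.DataFrame(panel_rows, columns=["patient_id", "week", *names])
    return profiles, cohort
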