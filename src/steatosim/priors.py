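"""Plausible-patient generation: log-normal parameter prior + Metropolis-Hastings.

A *plausible patient* is a parameter vector whose steady-state observables
(liver fat %, plasma TG) fall inside broad physiological limits.  The prior
is a diagonal joint log-normal over the calibration inputs, each centered on
its basal value with the spread set so that a stated probability mass (90 %
by default) lies between 0.25× and 4× baseline.  The sampler is a random-walk
Metropolis-Hastings chain in log-parameter space targeting

    prior(θ) × 1[steady-state observables of θ inside the plausibility box],

thinned and (optionally) split over independent sub-seeded chains.  Because
each draw is re-calibrated — the drawn pools and flux anchors are treated as
that patient's steady-state calibration inputs — every plausible patient sits
exactly at its own steady state by construction; the residual is checked
anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import ModelParameters, ModelState, Observables, compute_observables, rhs
from .registry import (
    CALIBRATION_INPUT_NAMES,
    DEFAULT_CALIBRATION_INPUTS,
    parameters_from_inputs,
)

__all__ = [
    "log_sd_from_fold_range",
    "ParameterPrior",
    "PlausibilityBox",
    "PlausiblePatient",
    "mh_generate_plausible",
    "population_to_frame",
    "patients_from_frame",
    "OBS_COLUMNS",
]

OBS_COLUMNS = ("liver_fat_pct", "plasma_tg")

#: Physiology constants get a tighter plausible range than the generic 4-fold
#: default: liver mass and plasma volume are well constrained in adults.
DEFAULT_FOLD_OVERRIDES = {"m_liver": 1.5, "v_pl": 1.5}


def log_sd_from_fold_range(fold_hi: float, mass: float = 0.90) -> float:
    """Log-space SD putting ``mass`` probability within [1/fold_hi, fold_hi]×base.

    The range is symmetric in log space, so the SD is
    ``ln(fold_hi) / Phi^-1(1 - (1 - mass)/2)``.
    """
    if not (fold_hi > 1.0 and math.isfinite(fold_hi)):
        raise ValueError(f"fold_hi must be > 1, got {fold_hi}")
    if not (0.0 < mass < 1.0):
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    return math.log(fold_hi) / norm.ppf(1.0 - (1.0 - mass) / 2.0)


@dataclass(frozen=True)
class ParameterPrior:
    """Diagonal log-normal prior over named positive parameters."""

    names: tuple
    log_median: np.ndarray
    log_sd: np.ndarray
    varied: np.ndarray  # bool mask; non-varied entries stay at their median

    def __post_init__(self):
        n = len(self.names)
        if not (self.log_median.shape == self.log_sd.shape == self.varied.shape == (n,)):
            raise ValueError("prior arrays must match the number of names")
        if np.any(self.log_sd[self.varied] <= 0):
            raise ValueError("log_sd must be > 0 for varied parameters")

    @classmethod
    def from_baseline(
        cls,
        baseline: dict | None = None,
        fold_hi: float = 4.0,
        mass: float = 0.90,
        fold_overrides: dict | None = None,
        varied: dict | None = None,
    ) -> "ParameterPrior":
        """Prior centered on the baseline calibration inputs.

        ``fold_overrides`` maps parameter names to alternative fold ranges
        (same mass); ``varied`` maps names to bools to freeze parameters.
        """
        baseline = dict(DEFAULT_CALIBRATION_INPUTS if baseline is None else baseline)
        names = tuple(k for k in CALIBRATION_INPUT_NAMES)
        overrides = dict(DEFAULT_FOLD_OVERRIDES)
        if fold_overrides is not None:
            overrides.update(fold_overrides)
        sd = np.array([
            log_sd_from_fold_range(overrides.get(k, fold_hi), mass) for k in names
        ])
        mask = np.array([bool((varied or {}).get(k, True)) for k in names])
        return cls(
            names=names,
            log_median=np.log(np.array([baseline[k] for k in names], dtype=float)),
            log_sd=sd,
            varied=mask,
        )

    def logpdf(self, log_theta: np.ndarray) -> float:
        """Unnormalised log-density over the varied coordinates."""
        z = (log_theta[self.varied] - self.log_median[self.varied]) / self.log_sd[self.varied]
        return -0.5 * float(z @ z)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n independent draws of log-parameter vectors."""
        z = rng.standard_normal((n, len(self.names)))
        out = self.log_median + np.where(self.varied, self.log_sd, 0.0) * z
        return out

    def to_dict(self, log_theta: np.ndarray) -> dict:
        return {k: float(v) for k, v in zip(self.names, np.exp(log_theta))}


@dataclass(frozen=True)
class PlausibilityBox:
    """Pre-defined steady-state limits a plausible patient must satisfy."""

    liver_fat_pct: tuple = (0.5, 50.0)
    plasma_tg: tuple = (30.0, 600.0)

    def __post_init__(self):
        for name, (lo, hi) in (("liver_fat_pct", self.liver_fat_pct),
                               ("plasma_tg", self.plasma_tg)):
            if not (0.0 < lo < hi):
                raise ValueError(f"box range for {name} must satisfy 0 < min < max")

    def contains(self, obs: Observables) -> bool:
        return (self.liver_fat_pct[0] <= obs.liver_fat_pct <= self.liver_fat_pct[1]
                and self.plasma_tg[0] <= obs.plasma_tg <= self.plasma_tg[1])

    @classmethod
    def unbounded(cls) -> "PlausibilityBox":
        """Box spanning the entire positive quadrant (disables screening)."""
        return cls(liver_fat_pct=(1e-12, 1e12), plasma_tg=(1e-12, 1e12))


@dataclass(frozen=True)
class PlausiblePatient:
    """A calibrated parameter vector sitting at its own steady state."""

    params: ModelParameters
    state: ModelState
    observables: Observables
    inputs: dict = field(default=None, repr=False)


def _patient_from_log_theta(prior: ParameterPrior, log_theta: np.ndarray):
    """Calibrate a draw; returns (patient, observables) or None if infeasible."""
    inputs = prior.to_dict(log_theta)
    try:
        params = parameters_from_inputs(inputs)
    except ValueError:
        return None  # e.g. implied negative clearance or oxidation
    state = params.basal_state
    obs = compute_observables(state, params)
    return PlausiblePatient(params=params, state=state, observables=obs, inputs=inputs)


def mh_generate_plausible(
    prior: ParameterPrior,
    box: PlausibilityBox,
    n_target: int,
    seed: int,
    step_scale: float = 0.25,
    thin: int = 10,
    burn_in: int = 1000,
    n_chains: int = 1,
    min_acceptance: float = 1e-3,
    acceptance_window: int = 20_000,
    residual_tol: float = 1e-6,
) -> list:
    """Generate exactly ``n_target`` plausible patients, reproducibly.

    Random-walk MH with per-parameter Gaussian steps of
    ``step_scale × log_sd`` in log space, targeting the box-restricted prior.
    Retained states are spaced ``thin`` accepted-or-rejected steps apart after
    ``burn_in`` steps.  The seed expands to independent substreams per chain.

    Raises ``RuntimeError`` if the chain's proposal acceptance rate over a
    diagnostic window drops below ``min_acceptance`` (advice: widen the box or
    shrink the proposal step).
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    per_chain = [n_target // n_chains] * n_chains
    for i in range(n_target % n_chains):
        per_chain[i] += 1

    step = step_scale * np.where(prior.varied, prior.log_sd, 0.0)
    patients: list = []
    for chain_seed, n_chain in zip(seeds, per_chain):
        if n_chain == 0:
            continue
        rng = np.random.default_rng(chain_seed)
        log_theta = prior.log_median.copy()
        current = _patient_from_log_theta(prior, log_theta)
        if current is None or not box.contains(current.observables):
            raise RuntimeError(
                "prior median is not a plausible patient; widen the box or "
                "re-center the prior"
            )
        logp = prior.logpdf(log_theta)
        collected = 0
        steps = accepted = window_steps = window_accepted = 0
        while collected < n_chain:
            proposal = log_theta + step * rng.standard_normal(len(log_theta))
            logp_prop = prior.logpdf(proposal)
            if math.log(rng.uniform()) < logp_prop - logp:
                cand = _patient_from_log_theta(prior, proposal)
                if cand is not None and box.contains(cand.observables):
                    log_theta, logp, current = proposal, logp_prop, cand
                    accepted += 1
                    window_accepted += 1
            steps += 1
            window_steps += 1
            if window_steps >= acceptance_window:
                if window_accepted < min_acceptance * window_steps:
                    raise RuntimeError(
                        "Metropolis-Hastings acceptance rate "
                        f"{window_accepted / window_steps:.2e} below "
                        f"{min_acceptance:.0e} over the last {window_steps} "
                        "proposals; widen the plausibility box or reduce "
                        "step_scale"
                    )
                window_steps = window_accepted = 0
            if steps > burn_in and steps % thin == 0:
                resid = float(np.max(np.abs(rhs(current.state, current.params))))
                scale = max(current.params.j_nefa, 1.0)
                if resid / scale > residual_tol:
                    raise RuntimeError(
                        f"plausible patient steady-state residual {resid:.3e} "
                        "exceeds tolerance"
                    )
                patients.append(current)
                collected += 1
    return patients


def population_to_frame(patients) -> pd.DataFrame:
    """One row per patient: the 22 parameters plus the two observables.

    Deterministic column order (registry order, then observables); the full
    model of any row can be rebuilt from its 22 parameter columns.
    """
    from .model import PARAM_NAMES

    rows = []
    for pat in patients:
        row = pat.params.as_dict()
        row["liver_fat_pct"] = pat.observables.liver_fat_pct
        row["plasma_tg"] = pat.observables.plasma_tg
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PARAM_NAMES) + list(OBS_COLUMNS))


def patients_from_frame(df: pd.DataFrame) -> list:
    """Rebuild plausible patients from a population table (22 param columns)."""
    from .model import PARAM_NAMES

    patients = []
    for _, row in df.iterrows():
        params = ModelParameters.from_dict({k: row[k] for k in PARAM_NAMES})
        state = params.basal_state
        patients.append(PlausiblePatient(
            params=params, state=state,
            observables=compute_observables(state, params),
        ))
    return patients
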