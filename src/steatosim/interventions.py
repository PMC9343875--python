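"""Therapy scenarios as sustained step changes in flux scalings.

Interventions are applied instantaneously at t = 0 and held constant for the
stated duration (24-hour-average pharmacology; no pharmacokinetics or
titration).  The endpoint is the percent change in liver fat % from each
patient's baseline steady state.

Two canned scenarios are provided:

* pioglitazone-like adipose insulin sensitization — a sustained 28 %
  reduction of adipose→liver NEFA delivery for 24 weeks;
* diet-like caloric restriction — chylomicron input −20 %, DNL −55 % and
  NEFA delivery −11 % simultaneously for 26 weeks.

The three diet effect sizes and the −28 % NEFA step are fixed constants of
the scenario definitions (derived in their source trials), not re-derived
here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    InterventionSpec,
    ModelParameters,
    compute_observables,
    simulate,
)
from .priors import PlausiblePatient

__all__ = [
    "pioglitazone_spec",
    "diet_spec",
    "simulate_intervention",
    "CohortResponse",
    "cohort_response",
    "load_intervention",
    "save_intervention",
]


def pioglitazone_spec() -> InterventionSpec:
    """Pioglitazone-like NEFA-uptake step: −28 % for 24 weeks (168 days)."""
    return InterventionSpec(u_nefa=0.72, duration_days=168.0)


def diet_spec() -> InterventionSpec:
    """Diet-like triple step: chylo −20 %, DNL −55 %, NEFA −11 %, 26 weeks."""
    return InterventionSpec(u_chylo=0.80, u_dnl=0.45, u_nefa=0.89,
                            duration_days=182.0)


def _params_of(patient) -> ModelParameters:
    if isinstance(patient, PlausiblePatient):
        return patient.params
    if isinstance(patient, ModelParameters):
        return patient
    raise TypeError("patient must be a PlausiblePatient or ModelParameters")


def simulate_intervention(
    patient, spec: InterventionSpec, rtol: float = 1e-8, atol: float = 1e-10
) -> float:
    """Percent change in liver fat % after ``spec.duration_days`` of therapy.

    The patient starts at its baseline steady state (its calibrated basal
    state); returns ``100 · (LF_end − LF_0) / LF_0``.
    """
    params = _params_of(patient)
    spec.validate()
    lf0 = compute_observables(params.basal_state, params).liver_fat_pct
    traj = simulate(
        params, spec, t_end_days=spec.duration_days,
        t_eval=[0.0, spec.duration_days], rtol=rtol, atol=atol,
    )
    lf_end = compute_observables(traj.final_state, params).liver_fat_pct
    return 100.0 * (lf_end - lf0) / lf0


@dataclass
class CohortResponse:
    """Per-patient and aggregate liver-fat response to one intervention."""

    pct_change: np.ndarray      # per-patient percent change in liver fat %
    mean: float
    sd: float
    duration_days: float
    baseline_lf: np.ndarray
    final_lf: np.ndarray
    failed_ids: list

    @property
    def n(self) -> int:
        return len(self.pct_change)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": np.arange(len(self.pct_change)),
            "baseline_liver_fat_pct": self.baseline_lf,
            "final_liver_fat_pct": self.final_lf,
            "pct_change": self.pct_change,
        })

    def summary(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n": self.n,
                "duration_days": self.duration_days,
                "n_failed": len(self.failed_ids)}


def cohort_response(cohort, spec: InterventionSpec) -> CohortResponse:
    """Apply an intervention to every patient in a cohort and aggregate.

    ``cohort``: iterable of patients (PlausiblePatient / ModelParameters) or a
    population DataFrame carrying the 22 parameter columns.  Individual
    integration failures are tolerated up to 1 % of the cohort and reported
    by patient id; beyond that the whole call fails.
    """
    from .priors import patients_from_frame

    if isinstance(cohort, pd.DataFrame):
        patients = patients_from_frame(cohort)
    else:
        patients = list(cohort)
    if len(patients) == 0:
        raise ValueError("cohort is empty")
    changes, lf0s, lf1s, failed = [], [], [], []
    for i, pat in enumerate(patients):
        params = _params_of(pat)
        try:
            pct = simulate_intervention(params, spec)
        except Exception as exc:  # noqa: BLE001 — per-patient fault isolation
            failed.append((i, repr(exc)))
            continue
        lf0 = compute_observables(params.basal_state, params).liver_fat_pct
        changes.append(pct)
        lf0s.append(lf0)
        lf1s.append(lf0 * (1.0 + pct / 100.0))
    if len(failed) > max(1, 0.01 * len(patients)):
        raise RuntimeError(f"intervention failed for {len(failed)} patients: {failed[:5]}")
    changes = np.asarray(changes)
    mean = float(changes.mean())
    # population SD: invariant under duplicating the cohort, 0 for a cohort of one
    sd = float(changes.std(ddof=0))
    return CohortResponse(
        pct_change=changes, mean=mean, sd=sd,
        duration_days=spec.duration_days,
        baseline_lf=np.asarray(lf0s), final_lf=np.asarray(lf1s),
        failed_ids=[i for i, _ in failed],
    )


def save_intervention(spec: InterventionSpec, path) -> None:
    Path(path).write_text(json.dumps(spec.as_dict(), indent=2) + "\n")


def load_intervention(path) -> InterventionSpec:
    return InterventionSpec(**json.loads(Path(path).read_text()))
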